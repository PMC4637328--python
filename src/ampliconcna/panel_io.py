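"""Reading and writing amplicon panels, depth matrices and call tables.

All on-disk formats are plain text: the panel is a five-column BED dialect
(chrom, start, end, amplicon_id, gene; 0-based half-open coordinates), depth
matrices are TSV with a header of sample ids and an ``amplicon_id`` first
column, and call tables are long-format TSV.  Parsing is side-effect free:
zero depths are accepted here and resolved during normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
TUMOR = "tumor"
VALID_ROLES = (CONTROL, TUMOR)


class PanelFormatError(ValueError):
    """A panel, depth or role file violates its format contract."""


class PanelMismatchError(ValueError):
    """A depth/call table does not line up with the amplicon panel."""


@dataclass(frozen=True)
class AmpliconRecord:
    """One target region amplified by a single primer pair."""

    amplicon_id: str
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelFormatError(
                f"amplicon {self.amplicon_id!r}: start ({self.start}) must be "
                f"< end ({self.end})"
            )
        if not self.gene:
            raise PanelFormatError(
                f"amplicon {self.amplicon_id!r} has an empty gene label"
            )


@dataclass(frozen=True)
class AmpliconPanel:
    """An ordered collection of amplicons, sorted by (chrom, start).

    The panel defines the row order of every depth matrix and call matrix in
    the pipeline; gene membership defines within-gene amplicon adjacency for
    the consistency score.
    """

    records: tuple[AmpliconRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.amplicon_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelFormatError(f"duplicate amplicon ids: {dupes}")
        ordered = sorted(self.records, key=lambda r: (r.chrom, r.start, r.end))
        object.__setattr__(self, "records", tuple(ordered))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmpliconPanel):
            return NotImplemented
        return self.records == other.records

    def __hash__(self) -> int:
        return hash(self.records)

    @property
    def amplicon_ids(self) -> list[str]:
        return [r.amplicon_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Unique gene labels in order of first appearance along the panel."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene, None)
        return list(seen)

    def gene_indices(self, gene: str) -> list[int]:
        """Panel-order row indices of a gene's amplicons."""
        idx = [i for i, r in enumerate(self.records) if r.gene == gene]
        if not idx:
            raise PanelMismatchError(f"gene {gene!r} not in panel")
        return idx

    @property
    def gene_index_map(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, r in enumerate(self.records):
            out.setdefault(r.gene, []).append(i)
        return out


@dataclass
class DepthMatrix:
    """Mean read depth per (amplicon, sample) with a role flag per sample.

    Rows follow panel order; ``values`` is non-negative and complete.
    """

    values: np.ndarray
    amplicon_ids: list[str]
    sample_ids: list[str]
    sample_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PanelFormatError("depth matrix must be 2-dimensional")
        m, n = self.values.shape
        if m != len(self.amplicon_ids):
            raise PanelMismatchError(
                f"{m} rows but {len(self.amplicon_ids)} amplicon ids"
            )
        if n != len(self.sample_ids):
            raise PanelMismatchError(
                f"{n} columns but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.sample_ids)) != n:
            raise PanelFormatError("duplicate sample ids in depth matrix")
        if not self.sample_roles:
            self.sample_roles = [TUMOR] * n
        if len(self.sample_roles) != n:
            raise PanelMismatchError("one role per sample required")
        bad = sorted(set(self.sample_roles) - set(VALID_ROLES))
        if bad:
            raise PanelFormatError(f"unknown sample roles: {bad}")
        if np.isnan(self.values).any():
            raise PanelFormatError("depth matrix contains missing values")
        if (self.values < 0).any():
            raise PanelFormatError("depth matrix contains negative values")

    @property
    def n_amplicons(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, role: str) -> "DepthMatrix":
        """Return the sub-matrix of samples with the given role."""
        if role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}, got {role!r}")
        keep = [i for i, r in enumerate(self.sample_roles) if r == role]
        return DepthMatrix(
            values=self.values[:, keep],
            amplicon_ids=list(self.amplicon_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            sample_roles=[role] * len(keep),
        )


# ---------------------------------------------------------------------------
# panel files


def read_panel(path: str | Path) -> AmpliconPanel:
    """Read a 5-column BED-dialect panel file (``#`` comment lines allowed)."""
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected >=5 tab-separated columns "
                    f"(chrom, start, end, amplicon_id, gene), got {len(fields)}"
                )
            chrom, start, end, amp_id, gene = fields[:5]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            records.append(
                AmpliconRecord(
                    amplicon_id=amp_id, gene=gene,
                    chrom=chrom, start=start_i, end=end_i,
                )
            )
    if not records:
        raise PanelFormatError(f"{path}: no amplicon records")
    return AmpliconPanel(records=tuple(records))


def write_panel(panel: AmpliconPanel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in panel.records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.amplicon_id}\t{r.gene}\n")


# ---------------------------------------------------------------------------
# depth matrices and roles


def read_roles(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, role) TSV into a role map."""
    path = Path(path)
    roles: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected 2 columns (sample_id, role)"
                )
            sid, role = fields
            if role not in VALID_ROLES:
                raise PanelFormatError(
                    f"{path}:{lineno}: role must be one of {VALID_ROLES}, "
                    f"got {role!r}"
                )
            if sid in roles:
                raise PanelFormatError(f"{path}:{lineno}: duplicate sample {sid!r}")
            roles[sid] = role
    return roles


def write_roles(roles: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, role in roles.items():
            fh.write(f"{sid}\t{role}\n")


def read_depth_matrix(
    path: str | Path,
    panel: AmpliconPanel,
    roles: Mapping[str, str] | None = None,
    default_role: str = TUMOR,
) -> DepthMatrix:
    """Read an amplicons x samples depth TSV, reordering rows to panel order.

    The file must contain every panel amplicon exactly once and no extras.
    ``roles`` maps sample id to ``control``/``tumor``; samples missing from
    the map get ``default_role``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "amplicon_id":
        raise PanelFormatError(
            f"{path}: first column must be 'amplicon_id', got {df.columns[0]!r}"
        )
    df = df.set_index("amplicon_id")
    file_ids = set(df.index)
    panel_ids = panel.amplicon_ids
    extra = sorted(file_ids - set(panel_ids))
    if extra:
        raise PanelMismatchError(f"{path}: amplicons not in panel: {extra[:5]}")
    missing = [a for a in panel_ids if a not in file_ids]
    if missing:
        raise PanelMismatchError(f"{path}: panel amplicons missing: {missing[:5]}")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()])
        raise PanelFormatError(f"{path}: duplicate amplicon rows: {dupes[:5]}")
    df = df.loc[panel_ids]
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise PanelFormatError(f"{path}: missing depth values")
    if (values < 0).any():
        raise PanelFormatError(f"{path}: negative depth values")
    sample_ids = [str(c) for c in df.columns]
    roles = dict(roles or {})
    sample_roles = [roles.get(s, default_role) for s in sample_ids]
    return DepthMatrix(
        values=values,
        amplicon_ids=list(panel_ids),
        sample_ids=sample_ids,
        sample_roles=sample_roles,
    )


def write_depth_matrix(depths: DepthMatrix, path: str | Path) -> None:
    """Write a depth matrix TSV (full ``repr`` float precision, round-trip safe)."""
    with Path(path).open("w") as fh:
        fh.write("amplicon_id\t" + "\t".join(depths.sample_ids) + "\n")
        for i, amp in enumerate(depths.amplicon_ids):
            row = "\t".join(repr(float(v)) for v in depths.values[i])
            fh.write(f"{amp}\t{row}\n")


# ---------------------------------------------------------------------------
# call tables

CALL_COLUMNS = [
    "amplicon_id", "gene", "chrom", "start", "end",
    "sample_id", "adjusted_residual", "call",
]


def write_calls(calls, panel: AmpliconPanel, path: str | Path) -> None:
    """Write per-amplicon calls as long-format TSV in panel x sample order.

    ``calls`` is a :class:`~ampliconcna.calling.CnaCallSet`; its rows must be
    aligned with ``panel``.
    """
    if calls.calls.shape[0] != len(panel):
        raise PanelMismatchError(
            f"call set has {calls.calls.shape[0]} rows, panel has {len(panel)}"
        )
    with Path(path).open("w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for i, rec in enumerate(panel.records):
            for j, sid in enumerate(calls.sample_ids):
                fh.write(
                    f"{rec.amplicon_id}\t{rec.gene}\t{rec.chrom}\t{rec.start}"
                    f"\t{rec.end}\t{sid}\t{repr(float(calls.adjusted[i, j]))}"
                    f"\t{calls.calls[i, j]}\n"
                )


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"amplicon_id": str, "sample_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing call columns {missing}")
    return df


def read_gene_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples state matrix TSV (first column ``gene``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene":
        raise PanelFormatError(f"{path}: first column must be 'gene'")
    return df.set_index("gene")
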