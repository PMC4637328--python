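"""Synthetic amplicon panels and depth matrices with known copy-number truth.

The generative model mirrors the normalization model: per-amplicon log2
depth is the sum of a global mean, a region (PCR-efficiency) effect shared
by all samples, a per-sample effect, a copy-number term and Gaussian noise,

    log2(y_ij) = log2(mean_depth) + alpha_i + beta_j
                 + log2(effective_CN_ij / 2) + N(0, noise_sd),

where effective_CN = purity * CN + (1 - purity) * 2 for tumors and 2 for
controls.  Read density is thus proportional to copy number up to the
region/sample biases, and at zero noise a CN=4 amplicon sits exactly one
log2 unit above baseline.

Noise is Gaussian on the log2 scale rather than count-level: at the
~2400-fold coverage these panels run at, counting noise is negligible next
to PCR variability, and the calling model is linear in log depth.  The
default ``noise_sd`` of 0.0289 log2 units corresponds to a per-region
coefficient of variation of raw control depths of about 0.02
(CV ~= noise_sd * ln 2 for small noise).

Copy-number events are spiked per (gene, tumor); a partial event covers a
contiguous prefix or suffix of the gene's amplicons, emulating a breakpoint
inside the gene.  One seed drives panel layout, effects, events and noise
through independent substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np

from .calling import AMP, DEL, NORMAL
from .panel_io import (
    CONTROL,
    TUMOR,
    AmpliconPanel,
    AmpliconRecord,
    DepthMatrix,
)

# substream tags appended to the seed so panel layout, effects, events and
# noise are independently reproducible
_STREAM_PANEL = 0
_STREAM_REGION = 1
_STREAM_SAMPLE = 2
_STREAM_EVENTS = 3
_STREAM_NOISE = 4


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe a 46-gene / 189-amplicon hotspot panel sequenced to a
    mean depth of 2443x with 16 unpaired normal controls and 100 tumors,
    clonal (purity 1) whole-gene events at 20% gene-sample frequency with
    CN=4 gains and CN=1 losses.
    """

    n_genes: int = 46
    n_amplicons: int = 189
    n_controls: int = 16
    n_tumors: int = 100
    mean_depth: float = 2443.0
    region_effect_sd: float = 0.5    # log2 units; amplification-efficiency spread
    sample_effect_sd: float = 0.01   # log2 units; library-size / batch spread
    noise_sd: float = 0.0289         # log2 units; control region CV ~= 0.02
    cna_gene_fraction: float = 0.2   # P(a gene carries an event in a tumor)
    amp_copy: int = 4
    del_copy: int = 1
    purity: float = 1.0
    partial_gene_prob: float = 0.0   # P(event covers only a prefix/suffix)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.n_amplicons < self.n_genes:
            raise SimConfigError(
                f"n_amplicons ({self.n_amplicons}) must be >= n_genes "
                f"({self.n_genes})"
            )
        if self.n_controls < 0 or self.n_tumors < 0:
            raise SimConfigError("sample counts must be >= 0")
        if self.mean_depth <= 0:
            raise SimConfigError("mean_depth must be > 0")
        for name in ("region_effect_sd", "sample_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        for name in ("cna_gene_fraction", "partial_gene_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if not 0 < self.purity <= 1:
            raise SimConfigError("purity must be in (0, 1]")
        if self.amp_copy <= 2:
            raise SimConfigError("amp_copy must be > 2")
        if not 0 <= self.del_copy < 2:
            raise SimConfigError("del_copy must be in [0, 2)")

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "SimConfig":
        known = {f.name: f.type for f in dc_fields(cls)}
        unknown = sorted(set(data) - set(known))
        if unknown:
            raise SimConfigError(f"unknown config keys: {unknown}")
        return cls(**{k: v for k, v in data.items()})  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SimTruth:
    """Ground-truth copy states for the simulated tumors.

    ``copy_state`` is gene x tumor integer copy number (2 = diploid);
    ``amplicon_state`` is the per-amplicon AMP/DEL/NORMAL state, which can
    disagree with the gene state past a partial-event breakpoint.  Controls
    are diploid everywhere by construction.
    """

    copy_state: np.ndarray       # (g, l) int
    amplicon_state: np.ndarray   # (m, l) str
    genes: list[str]
    tumor_ids: list[str]
    amplicon_ids: list[str]

    @property
    def gene_state(self) -> np.ndarray:
        """Gene x tumor AMP/DEL/NORMAL derived from integer copy number."""
        out = np.full(self.copy_state.shape, NORMAL, dtype="<U6")
        out[self.copy_state > 2] = AMP
        out[self.copy_state < 2] = DEL
        return out


def simulate_panel(config: SimConfig) -> AmpliconPanel:
    """Draw a synthetic panel: per-gene amplicon counts and coordinates.

    Every gene gets at least one amplicon; the remaining amplicons are
    distributed uniformly at random.  Genes are laid out on zero-padded
    chromosome names with increasing coordinates so panel order keeps each
    gene's amplicons adjacent and in genomic order.
    """
    rng = config._rng(_STREAM_PANEL)
    counts = np.ones(config.n_genes, dtype=int)
    extra = config.n_amplicons - config.n_genes
    if extra > 0:
        counts += np.bincount(
            rng.integers(0, config.n_genes, size=extra), minlength=config.n_genes
        )
    width = len(str(config.n_genes))
    records = []
    n_chroms = min(22, config.n_genes)
    pos = {c: 10_000 for c in range(n_chroms)}
    for gi in range(config.n_genes):
        gene = f"GENE{gi + 1:0{width}d}"
        chrom_i = gi % n_chroms
        chrom = f"chr{chrom_i + 1:02d}"
        start = pos[chrom_i]
        for ai in range(counts[gi]):
            records.append(
                AmpliconRecord(
                    amplicon_id=f"{gene}_A{ai + 1:02d}",
                    gene=gene,
                    chrom=chrom,
                    start=start,
                    end=start + 100,
                )
            )
            start += 150
        pos[chrom_i] = start + 50_000  # intergenic gap
    return AmpliconPanel(records=tuple(records))


def _spike_events(
    config: SimConfig,
    panel: AmpliconPanel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-(gene, tumor) events; return (copy_state, amplicon_state)."""
    genes = panel.genes
    gene_map = panel.gene_index_map
    g, l, m = len(genes), config.n_tumors, len(panel)
    copy_state = np.full((g, l), 2, dtype=int)
    amplicon_state = np.full((m, l), NORMAL, dtype="<U6")
    for gi, gene in enumerate(genes):
        idx = gene_map[gene]
        for j in range(l):
            if rng.random() >= config.cna_gene_fraction:
                continue
            cn = config.amp_copy if rng.random() < 0.5 else config.del_copy
            copy_state[gi, j] = cn
            covered = idx
            if len(idx) >= 2 and rng.random() < config.partial_gene_prob:
                length = int(rng.integers(1, len(idx)))
                covered = idx[:length] if rng.random() < 0.5 else idx[-length:]
            state = AMP if cn > 2 else DEL
            for i in covered:
                amplicon_state[i, j] = state
    return copy_state, amplicon_state


def simulate_depths(
    panel: AmpliconPanel,
    config: SimConfig,
    copy_state: np.ndarray | None = None,
) -> tuple[DepthMatrix, SimTruth]:
    """Generate control + tumor depths for a panel, with recorded truth.

    ``copy_state`` (gene x tumor integer copy numbers) overrides random
    event spiking with whole-gene events — useful for constructing exact
    test instances.  Deterministic given ``config.seed``.
    """
    m = len(panel)
    genes = panel.genes
    gene_map = panel.gene_index_map
    k, l = config.n_controls, config.n_tumors

    alpha = config._rng(_STREAM_REGION).normal(0.0, config.region_effect_sd, size=m)
    beta = config._rng(_STREAM_SAMPLE).normal(
        0.0, config.sample_effect_sd, size=k + l
    )

    if copy_state is None:
        copy_state, amplicon_state = _spike_events(
            config, panel, config._rng(_STREAM_EVENTS)
        )
    else:
        copy_state = np.asarray(copy_state, dtype=int)
        if copy_state.shape != (len(genes), l):
            raise SimConfigError(
                f"copy_state must be {(len(genes), l)}, got {copy_state.shape}"
            )
        amplicon_state = np.full((m, l), NORMAL, dtype="<U6")
        for gi, gene in enumerate(genes):
            idx = gene_map[gene]
            for j in range(l):
                if copy_state[gi, j] > 2:
                    amplicon_state[np.ix_(idx, [j])] = AMP
                elif copy_state[gi, j] < 2:
                    amplicon_state[np.ix_(idx, [j])] = DEL

    # per-amplicon integer CN implied by the amplicon states
    amp_cn = np.full((m, l), 2, dtype=int)
    for gi, gene in enumerate(genes):
        for i in gene_map[gene]:
            for j in range(l):
                if amplicon_state[i, j] != NORMAL:
                    amp_cn[i, j] = copy_state[gi, j]

    effective_cn = config.purity * amp_cn + (1 - config.purity) * 2.0
    cn_term = np.zeros((m, k + l))
    cn_term[:, k:] = np.log2(effective_cn / 2.0)

    noise = config._rng(_STREAM_NOISE).normal(0.0, config.noise_sd, size=(m, k + l))
    log_depth = (
        np.log2(config.mean_depth)
        + alpha[:, None]
        + beta[None, :]
        + cn_term
        + noise
    )
    values = np.power(2.0, log_depth)

    control_ids = [f"C{j + 1:03d}" for j in range(k)]
    tumor_ids = [f"T{j + 1:03d}" for j in range(l)]
    depths = DepthMatrix(
        values=values,
        amplicon_ids=panel.amplicon_ids,
        sample_ids=control_ids + tumor_ids,
        sample_roles=[CONTROL] * k + [TUMOR] * l,
    )
    truth = SimTruth(
        copy_state=copy_state,
        amplicon_state=amplicon_state,
        genes=genes,
        tumor_ids=tumor_ids,
        amplicon_ids=panel.amplicon_ids,
    )
    return depths, truth


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write gene-level truth as (gene, sample_id, copy_state) TSV."""
    with Path(path).open("w") as fh:
        fh.write("gene\tsample_id\tcopy_state\n")
        for gi, gene in enumerate(truth.genes):
            for j, sid in enumerate(truth.tumor_ids):
                fh.write(f"{gene}\t{sid}\t{truth.copy_state[gi, j]}\n")


def write_truth_matrix(truth: SimTruth, path: str | Path) -> None:
    """Write the genes x tumors AMP/DEL/NORMAL truth matrix TSV."""
    state = truth.gene_state
    with Path(path).open("w") as fh:
        fh.write("gene\t" + "\t".join(truth.tumor_ids) + "\n")
        for gi, gene in enumerate(truth.genes):
            fh.write(gene + "\t" + "\t".join(state[gi]) + "\n")
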