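import numpy as np
import pytest

from ampliconcna.panel_io import (
    CONTROL,
    TUMOR,
    AmpliconPanel,
    AmpliconRecord,
    DepthMatrix,
)


def make_panel(gene_sizes: dict[str, int]) -> AmpliconPanel:
    """Build a panel with the given amplicons-per-gene, on one chromosome."""
    records = []
    pos = 1000
    for gene, n in gene_sizes.items():
        for i in range(n):
            records.append(
                AmpliconRecord(
                    amplicon_id=f"{gene}_A{i + 1}",
                    gene=gene,
                    chrom="chr01",
                    start=pos,
                    end=pos + 100,
                )
            )
            pos += 150
        pos += 10_000
    return AmpliconPanel(records=tuple(records))


def make_depths(values: np.ndarray, roles: list[str]) -> DepthMatrix:
    m, n = np.asarray(values).shape
    return DepthMatrix(
        values=np.asarray(values, dtype=float),
        amplicon_ids=[f"A{i}" for i in range(m)],
        sample_ids=[f"S{j}" for j in range(n)],
        sample_roles=roles,
    )


def random_depths(rng, m, n_controls, n_tumors, low=100.0, high=5000.0):
    values = rng.uniform(low, high, size=(m, n_controls + n_tumors))
    return make_depths(values, [CONTROL] * n_controls + [TUMOR] * n_tumors)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def three_gene_panel():
    return make_panel({"TP53": 3, "PIK3CA": 2, "EGFR": 1})
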