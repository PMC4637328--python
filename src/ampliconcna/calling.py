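"""CNA calling from adjusted residuals and gene-level summarization.

An amplicon is called amplified when its adjusted residual exceeds the
overall mean of all adjusted residuals by more than ``gamma`` overall
standard deviations, and deleted when it falls more than ``gamma`` SDs
below; the mean and SD are taken over every cell of the adjusted-residual
matrix (all regions x all tumors), deliberately without per-region
recentering so that recurrently altered regions are not overcorrected.

The consistency score of a (gene, sample) pair is c = N_c / N_a, where N_a
counts the gene's copy-number-altered amplicons and N_c counts altered
amplicons with at least one adjacent amplicon (in within-gene panel order)
in the same altered state.  It is undefined for single-amplicon genes and
when N_a = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel_io import AmpliconPanel, PanelMismatchError

AMP = "AMP"
DEL = "DEL"
NORMAL = "NORMAL"
CALL_STATES = (AMP, DEL, NORMAL)

DEFAULT_GAMMA = 1.5


class CallingError(ValueError):
    """Inputs violate the calling contract."""


@dataclass
class CnaCallSet:
    """Per-amplicon x per-sample calls plus the thresholds that produced them."""

    calls: np.ndarray          # (m, l) array of AMP / DEL / NORMAL
    gamma: float
    overall_mean: float
    overall_sd: float
    adjusted: np.ndarray       # the residual matrix the calls came from
    sample_ids: list[str]

    @property
    def upper_threshold(self) -> float:
        return self.overall_mean + self.gamma * self.overall_sd

    @property
    def lower_threshold(self) -> float:
        return self.overall_mean - self.gamma * self.overall_sd


@dataclass
class GeneCallSet:
    """Gene-level calls, altered-amplicon counts and consistency scores.

    ``consistency`` holds NaN where the score is undefined (single-amplicon
    genes, or no altered amplicon in that gene/sample).
    """

    genes: list[str]
    sample_ids: list[str]
    gene_calls: np.ndarray     # (g, l) AMP / DEL / NORMAL
    n_amplicons: np.ndarray    # (g,) amplicons per gene
    n_amp: np.ndarray          # (g, l) amplicons called AMP
    n_del: np.ndarray          # (g, l) amplicons called DEL
    consistency: np.ndarray    # (g, l) float, NaN when undefined


def call_cna(
    adjusted: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    sample_ids: list[str] | None = None,
) -> CnaCallSet:
    """Threshold adjusted residuals at gamma overall SDs from the overall mean.

    The overall mean and SD (ddof=1) pool every cell of ``adjusted``.  With a
    degenerate matrix (overall SD of 0) no cell can strictly exceed the
    thresholds and everything is NORMAL.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    if not np.isfinite(adjusted).all():
        raise CallingError("adjusted residuals contain non-finite values")
    if gamma <= 0:
        raise CallingError(f"gamma must be > 0, got {gamma}")
    if adjusted.size <= 1 or np.all(adjusted == adjusted.flat[0]):
        # exact for a constant matrix, where np.mean/np.std leave roundoff
        overall_mean = float(adjusted.flat[0]) if adjusted.size else 0.0
        overall_sd = 0.0
    else:
        overall_mean = float(adjusted.mean())
        overall_sd = float(adjusted.std(ddof=1))
    upper = overall_mean + gamma * overall_sd
    lower = overall_mean - gamma * overall_sd
    calls = np.full(adjusted.shape, NORMAL, dtype="<U6")
    calls[adjusted > upper] = AMP
    calls[adjusted < lower] = DEL
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(adjusted.shape[1])]
    return CnaCallSet(
        calls=calls,
        gamma=float(gamma),
        overall_mean=overall_mean,
        overall_sd=overall_sd,
        adjusted=adjusted,
        sample_ids=list(sample_ids),
    )


def _gene_consistency(states: np.ndarray) -> float:
    """Consistency score for one gene's ordered amplicon states in one sample."""
    altered = states != NORMAL
    n_a = int(altered.sum())
    if n_a == 0:
        return math.nan
    n_c = 0
    n = len(states)
    for i in range(n):
        if not altered[i]:
            continue
        left_same = i > 0 and states[i - 1] == states[i]
        right_same = i < n - 1 and states[i + 1] == states[i]
        if left_same or right_same:
            n_c += 1
    return n_c / n_a


def summarize_gene(calls: CnaCallSet, panel: AmpliconPanel) -> GeneCallSet:
    """Collapse amplicon calls to gene level by majority among altered states.

    A gene is AMP in a sample when more of its amplicons are AMP than DEL
    (and at least one is AMP); DEL symmetrically; ties and all-normal genes
    are NORMAL.  Per-(gene, sample) consistency scores are computed alongside
    (NaN for single-amplicon genes and when no amplicon is altered).
    """
    if calls.calls.shape[0] != len(panel):
        raise PanelMismatchError(
            f"call set has {calls.calls.shape[0]} rows, panel has {len(panel)}"
        )
    gene_map = panel.gene_index_map
    genes = panel.genes
    n_samples = calls.calls.shape[1]
    g = len(genes)
    gene_calls = np.full((g, n_samples), NORMAL, dtype="<U6")
    n_amp = np.zeros((g, n_samples), dtype=int)
    n_del = np.zeros((g, n_samples), dtype=int)
    n_amplicons = np.zeros(g, dtype=int)
    consistency = np.full((g, n_samples), math.nan)
    for gi, gene in enumerate(genes):
        idx = gene_map[gene]
        n_amplicons[gi] = len(idx)
        sub = calls.calls[idx, :]
        n_amp[gi] = (sub == AMP).sum(axis=0)
        n_del[gi] = (sub == DEL).sum(axis=0)
        gene_calls[gi, n_amp[gi] > n_del[gi]] = AMP
        gene_calls[gi, n_del[gi] > n_amp[gi]] = DEL
        if len(idx) >= 2:
            for j in range(n_samples):
                consistency[gi, j] = _gene_consistency(sub[:, j])
    return GeneCallSet(
        genes=genes,
        sample_ids=list(calls.sample_ids),
        gene_calls=gene_calls,
        n_amplicons=n_amplicons,
        n_amp=n_amp,
        n_del=n_del,
        consistency=consistency,
    )


def consistency_score(
    calls: CnaCallSet,
    panel: AmpliconPanel,
    gene: str,
    sample: str,
) -> float:
    """Score one (gene, sample) pair; NaN when no amplicon is altered.

    Raises :class:`CallingError` for single-amplicon genes, for which
    adjacency (and hence the score) is undefined.
    """
    idx = panel.gene_indices(gene)
    if len(idx) < 2:
        raise CallingError(
            f"consistency score undefined for single-amplicon gene {gene!r}"
        )
    try:
        j = calls.sample_ids.index(sample)
    except ValueError:
        raise CallingError(f"unknown sample {sample!r}") from None
    return _gene_consistency(calls.calls[idx, j])


def cohort_consistency(calls: CnaCallSet, panel: AmpliconPanel) -> float:
    """Unweighted mean consistency over all defined (gene, sample) pairs."""
    gene_set = summarize_gene(calls, panel)
    defined = gene_set.consistency[~np.isnan(gene_set.consistency)]
    if defined.size == 0:
        raise CallingError("no (gene, sample) pair has a defined consistency score")
    return float(defined.mean())


GENE_CALL_COLUMNS = [
    "gene", "sample_id", "gene_call", "n_amplicons",
    "n_amp", "n_del", "consistency_score",
]


def write_gene_calls(gene_set: GeneCallSet, path: str | Path) -> None:
    """Write gene-level calls as long-format TSV (empty score when undefined)."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(GENE_CALL_COLUMNS) + "\n")
        for gi, gene in enumerate(gene_set.genes):
            for j, sid in enumerate(gene_set.sample_ids):
                c = gene_set.consistency[gi, j]
                score = "" if math.isnan(c) else repr(float(c))
                fh.write(
                    f"{gene}\t{sid}\t{gene_set.gene_calls[gi, j]}"
                    f"\t{gene_set.n_amplicons[gi]}\t{gene_set.n_amp[gi, j]}"
                    f"\t{gene_set.n_del[gi, j]}\t{score}\n"
                )


def write_gene_matrix(gene_set: GeneCallSet, path: str | Path) -> None:
    """Write the genes x samples call-state matrix TSV."""
    with Path(path).open("w") as fh:
        fh.write("gene\t" + "\t".join(gene_set.sample_ids) + "\n")
        for gi, gene in enumerate(gene_set.genes):
            fh.write(gene + "\t" + "\t".join(gene_set.gene_calls[gi]) + "\n")
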