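"""End-to-end convenience wrapper: depths in, gene-level CNA calls out."""

from __future__ import annotations

from dataclasses import dataclass

from .calling import CnaCallSet, DEFAULT_GAMMA, GeneCallSet, call_cna, summarize_gene
from .normalization import (
    ControlBaseline,
    DEFAULT_MIN_SD,
    DEFAULT_PSEUDOCOUNT,
    TumorNormalization,
    fit_control_baseline,
    normalize_tumors,
)
from .panel_io import CONTROL, TUMOR, AmpliconPanel, DepthMatrix


@dataclass
class PipelineResult:
    baseline: ControlBaseline
    normalization: TumorNormalization
    calls: CnaCallSet
    gene_calls: GeneCallSet


def run_pipeline(
    panel: AmpliconPanel,
    depths: DepthMatrix,
    gamma: float = DEFAULT_GAMMA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_sd: float = DEFAULT_MIN_SD,
    baseline: ControlBaseline | None = None,
) -> PipelineResult:
    """Fit controls, normalize tumors, call CNAs, summarize to gene level.

    ``depths`` holds both cohorts, distinguished by their sample roles; a
    pre-fitted ``baseline`` (e.g. reloaded from disk) skips the control fit.
    """
    if baseline is None:
        baseline = fit_control_baseline(depths.subset(CONTROL), pseudocount)
    norm = normalize_tumors(depths.subset(TUMOR), baseline, pseudocount, min_sd)
    calls = call_cna(norm.adjusted, gamma=gamma, sample_ids=norm.sample_ids)
    gene_calls = summarize_gene(calls, panel)
    return PipelineResult(
        baseline=baseline,
        normalization=norm,
        calls=calls,
        gene_calls=gene_calls,
    )
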