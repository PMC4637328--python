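"""Caller evaluation, cohort summaries, QC statistics and the c-index.

Accuracy against a truth (or orthogonal-platform) matrix is the fraction of
matching gene x sample cells; per-state sensitivity and specificity follow
the usual one-vs-rest definitions.  Control QC reports the mean pairwise
Pearson correlation of control log2-depth profiles and the mean per-region
coefficient of variation of raw depths — the two uniformity statistics used
to judge whether an unpaired control pool gives a stable baseline.

The concordance index is the fraction of comparable patient pairs in which
the patient with the earlier event time carries the higher predicted risk.
A pair is comparable when the times differ and the earlier time is an
observed event (pairs whose earlier time is censored are uninformative);
tied risks count 1/2.  0.5 is chance, 1.0 perfect ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import CALL_STATES, GeneCallSet, NORMAL
from .normalization import _log2_depths
from .panel_io import DepthMatrix, PanelFormatError


class EvaluationError(ValueError):
    """Inputs violate an evaluation contract."""


@dataclass(frozen=True)
class OutcomeRecord:
    """One patient's risk prediction and follow-up outcome."""

    sample_id: str
    risk: float
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise EvaluationError(f"{self.sample_id}: time must be >= 0")
        if self.event not in (0, 1):
            raise EvaluationError(f"{self.sample_id}: event must be 0 or 1")


@dataclass
class EvalReport:
    """Call-vs-truth agreement summary."""

    accuracy: float
    sensitivity: dict[str, float]   # per state; NaN when the state is absent
    specificity: dict[str, float]
    n_cells: int


def call_accuracy(calls: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Cellwise agreement between two gene x sample state matrices."""
    calls = np.asarray(calls, dtype="<U6")
    truth = np.asarray(truth, dtype="<U6")
    if calls.shape != truth.shape:
        raise EvaluationError(
            f"shape mismatch: calls {calls.shape} vs truth {truth.shape}"
        )
    if calls.size == 0:
        raise EvaluationError("empty call matrix")
    match = calls == truth
    sensitivity = {}
    specificity = {}
    for state in CALL_STATES:
        is_state = truth == state
        sensitivity[state] = (
            float(match[is_state].mean()) if is_state.any() else float("nan")
        )
        not_state = ~is_state
        specificity[state] = (
            float((calls[not_state] != state).mean())
            if not_state.any()
            else float("nan")
        )
    return EvalReport(
        accuracy=float(match.mean()),
        sensitivity=sensitivity,
        specificity=specificity,
        n_cells=int(calls.size),
    )


def occurrence_rate(gene_calls: GeneCallSet, sample: str) -> float:
    """Fraction of panel genes called altered (non-NORMAL) in one sample."""
    try:
        j = gene_calls.sample_ids.index(sample)
    except ValueError:
        raise EvaluationError(f"unknown sample {sample!r}") from None
    return float((gene_calls.gene_calls[:, j] != NORMAL).mean())


def call_frequency(gene_calls: GeneCallSet) -> pd.DataFrame:
    """Per-gene counts of AMP and DEL samples, sorted by total altered count.

    Ties break alphabetically by gene so the ordering is stable.
    """
    if gene_calls.gene_calls.size == 0:
        raise EvaluationError("empty gene call set")
    n_amp = (gene_calls.gene_calls == "AMP").sum(axis=1)
    n_del = (gene_calls.gene_calls == "DEL").sum(axis=1)
    df = pd.DataFrame(
        {"gene": gene_calls.genes, "n_amp": n_amp, "n_del": n_del}
    )
    df["n_altered"] = df["n_amp"] + df["n_del"]
    df = df.sort_values(
        ["n_altered", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df[["gene", "n_amp", "n_del", "n_altered"]]


@dataclass
class ControlQC:
    """Uniformity statistics of the control depth profiles."""

    mean_pairwise_correlation: float
    mean_region_cv: float
    n_controls: int


def control_qc(depths: DepthMatrix, pseudocount: float = 0.5) -> ControlQC:
    """Reproducibility of the control pool.

    Correlation is Pearson on log2 depth profiles (the model's scale),
    averaged over all unordered control pairs; CV is SD/mean of raw depth
    across controls, averaged over regions.
    """
    values = depths.values
    k = values.shape[1]
    if k < 2:
        raise EvaluationError(f"control QC needs >=2 controls, got {k}")
    log_y = _log2_depths(values, pseudocount)
    corr = np.corrcoef(log_y.T)
    iu = np.triu_indices(k, 1)
    mean_corr = float(corr[iu].mean())
    means = values.mean(axis=1)
    if (means == 0).any():
        raise EvaluationError("region with zero mean depth; CV undefined")
    cv = values.std(axis=1, ddof=1) / means
    return ControlQC(
        mean_pairwise_correlation=mean_corr,
        mean_region_cv=float(cv.mean()),
        n_controls=k,
    )


def concordance_index(outcomes: Sequence[OutcomeRecord]) -> float:
    """Concordance between predicted risks and observed event times.

    For each comparable pair (times differ, earlier time is an observed
    event), score 1 if the earlier-event patient has the higher risk, 1/2 on
    a risk tie, 0 otherwise; return the mean.  Raises
    :class:`EvaluationError` when no pair is comparable.
    """
    n = len(outcomes)
    risk = np.array([o.risk for o in outcomes], dtype=float)
    time = np.array([o.time for o in outcomes], dtype=float)
    event = np.array([o.event for o in outcomes], dtype=int)
    comparable = 0
    score = 0.0
    for a in range(n):
        if event[a] != 1:
            continue
        for b in range(n):
            if time[a] >= time[b] or a == b:
                continue
            comparable += 1
            if risk[a] > risk[b]:
                score += 1.0
            elif risk[a] == risk[b]:
                score += 0.5
    if comparable == 0:
        raise EvaluationError("no comparable pair (times tied or all censored)")
    return score / comparable


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    """Read (sample_id, risk, time, event) outcome triples from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "risk", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing outcome columns {missing}")
    return [
        OutcomeRecord(
            sample_id=row.sample_id,
            risk=float(row.risk),
            time=float(row.time),
            event=int(row.event),
        )
        for row in df.itertuples()
    ]


def format_report(report: EvalReport) -> str:
    """Human-readable accuracy block for standard output."""
    lines = [
        f"cells compared\t{report.n_cells}",
        f"accuracy\t{report.accuracy:.4f}",
    ]
    for state in CALL_STATES:
        lines.append(f"sensitivity[{state}]\t{report.sensitivity[state]:.4f}")
        lines.append(f"specificity[{state}]\t{report.specificity[state]:.4f}")
    return "\n".join(lines)
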