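"""Two-step linear-model normalization of amplicon read depths.

Step 1 fits a two-way additive model to the log2 depths of the control
cohort,

    log2(y_ij) = mu_N + alpha_i + beta_j + e_ij,

with sum-to-zero constraints on the region effects ``alpha`` and the sample
effects ``beta``, so that ``mu_N`` is the overall log2 control mean and
``mu_N + alpha_i`` is the basal log2 depth of region *i*.  The design is
balanced and complete, so the constrained least-squares solution has closed
forms: grand mean, row means and column means.

Step 2 subtracts the control baseline from tumor log2 depths
(``z_ij = log2(y_ij) - mu_N - alpha_i``), absorbs a per-tumor sample effect
(``z_ij = mu_C + beta_j + e_ij``), and standardizes the residuals per region
by their own standard deviation.  The residual equals the log2 ratio of
observed to model-expected depth, so the adjusted residual is the calling
statistic for relative copy number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel_io import DepthMatrix

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_SD = 1e-8


class NormalizationError(ValueError):
    """Inputs violate the normalization model's contract."""


@dataclass
class ControlBaseline:
    """Fitted control model: overall mean, region effects, sample effects.

    ``alpha`` and ``beta_control`` each sum to zero; ``sigma_n`` is the
    residual standard deviation on (m-1)(k-1) degrees of freedom, retained
    as a fit diagnostic.
    """

    mu_n: float
    alpha: np.ndarray
    beta_control: np.ndarray
    sigma_n: float
    amplicon_ids: list[str]


@dataclass
class TumorNormalization:
    """Baseline-adjusted tumor depths and their standardized residuals."""

    z: np.ndarray
    mu_c: float
    beta_tumor: np.ndarray
    residuals: np.ndarray
    region_sd: np.ndarray
    adjusted: np.ndarray
    sample_ids: list[str]
    amplicon_ids: list[str]


def _log2_depths(values: np.ndarray, pseudocount: float) -> np.ndarray:
    """log2-transform depths, adding ``pseudocount`` to zero cells only."""
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    values = np.asarray(values, dtype=float)
    zeros = values == 0
    if zeros.any():
        n = int(zeros.sum())
        rows, cols = np.nonzero(zeros)
        preview = list(zip(rows[:5].tolist(), cols[:5].tolist()))
        warnings.warn(
            f"{n} zero depth cell(s) replaced by pseudocount {pseudocount} "
            f"(first cells: {preview})",
            stacklevel=3,
        )
        values = np.where(zeros, pseudocount, values)
    if (values <= 0).any():
        raise NormalizationError(
            "depths must be positive after pseudocount handling "
            "(zero depths with pseudocount=0?)"
        )
    return np.log2(values)


def fit_control_baseline(
    depths: DepthMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ControlBaseline:
    """Fit the two-way control model by constrained least squares.

    ``depths`` must contain only the control samples.  Under the sum-to-zero
    constraints the balanced complete design gives mu_n as the grand mean of
    the log2 depths, alpha as row means minus the grand mean, and beta as
    column means minus the grand mean.

    Raises :class:`NormalizationError` for fewer than 2 controls or regions.
    """
    m, k = depths.values.shape
    if m < 2:
        raise NormalizationError(f"need >=2 regions to fit, got {m}")
    if k < 2:
        raise NormalizationError(f"need >=2 control samples to fit, got {k}")
    log_y = _log2_depths(depths.values, pseudocount)

    mu_n = float(log_y.mean())
    alpha = log_y.mean(axis=1) - mu_n
    beta = log_y.mean(axis=0) - mu_n
    fitted = mu_n + alpha[:, None] + beta[None, :]
    resid = log_y - fitted
    dof = (m - 1) * (k - 1)
    sigma_n = float(np.sqrt((resid**2).sum() / dof))
    return ControlBaseline(
        mu_n=mu_n,
        alpha=alpha,
        beta_control=beta,
        sigma_n=sigma_n,
        amplicon_ids=list(depths.amplicon_ids),
    )


def adjust_tumor(
    depths: DepthMatrix,
    baseline: ControlBaseline,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Remove the control baseline: z_ij = log2(y_ij) - mu_n - alpha_i."""
    if depths.amplicon_ids != baseline.amplicon_ids:
        if depths.values.shape[0] != baseline.alpha.shape[0]:
            raise NormalizationError(
                f"tumor matrix has {depths.values.shape[0]} regions, baseline "
                f"has {baseline.alpha.shape[0]}"
            )
        raise NormalizationError("tumor amplicon ids differ from baseline")
    log_y = _log2_depths(depths.values, pseudocount)
    return log_y - baseline.mu_n - baseline.alpha[:, None]


def fit_tumor_effects(z: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Fit z_ij = mu_c + beta_j + e_ij; return (mu_c, beta_tumor, residuals).

    The per-sample effect absorbs each tumor's column mean, so residuals sum
    to zero within every sample.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise NormalizationError("z must be a non-empty 2-D matrix")
    if z.shape[0] < 2:
        raise NormalizationError(f"need >=2 regions, got {z.shape[0]}")
    mu_c = float(z.mean())
    col_means = z.mean(axis=0)
    beta = col_means - mu_c
    residuals = z - col_means[None, :]
    return mu_c, beta, residuals


def scale_residuals(
    residuals: np.ndarray,
    min_sd: float = DEFAULT_MIN_SD,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize residuals per region by their own sample SD (ddof=1).

    Regions whose residual SD falls below ``min_sd`` (zero-variance regions,
    or pure floating-point roundoff) are flagged with a warning and their
    adjusted residuals are set to exactly 0, so they can never be called.
    """
    if min_sd <= 0:
        raise ValueError(f"min_sd must be > 0, got {min_sd}")
    residuals = np.asarray(residuals, dtype=float)
    if residuals.shape[1] < 2:
        raise NormalizationError(
            f"per-region SD needs >=2 tumor samples, got {residuals.shape[1]}"
        )
    region_sd = residuals.std(axis=1, ddof=1)
    low = region_sd < min_sd
    if low.any():
        warnings.warn(
            f"{int(low.sum())} region(s) with residual SD < {min_sd}; "
            "clamped (their adjusted residuals are ~0)",
            stacklevel=2,
        )
    adjusted = residuals / np.maximum(region_sd, min_sd)[:, None]
    adjusted[low, :] = 0.0
    return region_sd, adjusted


def normalize_tumors(
    depths: DepthMatrix,
    baseline: ControlBaseline,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_sd: float = DEFAULT_MIN_SD,
) -> TumorNormalization:
    """Run the full step-2 normalization on a tumor depth matrix."""
    z = adjust_tumor(depths, baseline, pseudocount)
    mu_c, beta, residuals = fit_tumor_effects(z)
    region_sd, adjusted = scale_residuals(residuals, min_sd)
    return TumorNormalization(
        z=z,
        mu_c=mu_c,
        beta_tumor=beta,
        residuals=residuals,
        region_sd=region_sd,
        adjusted=adjusted,
        sample_ids=list(depths.sample_ids),
        amplicon_ids=list(depths.amplicon_ids),
    )


# ---------------------------------------------------------------------------
# baseline persistence


def write_baseline(baseline: ControlBaseline, path: str | Path) -> None:
    """Persist a control fit as (parameter, index, value) TSV.

    Floats are written with ``repr`` so the round trip is bit-exact; amplicon
    ids are stored so a reloaded baseline can be checked against a panel.
    """
    with Path(path).open("w") as fh:
        fh.write("parameter\tindex\tvalue\n")
        fh.write(f"mu_n\t.\t{baseline.mu_n!r}\n")
        fh.write(f"sigma_n\t.\t{baseline.sigma_n!r}\n")
        for amp, a in zip(baseline.amplicon_ids, baseline.alpha):
            fh.write(f"alpha\t{amp}\t{float(a)!r}\n")
        for j, b in enumerate(baseline.beta_control):
            fh.write(f"beta_control\t{j}\t{float(b)!r}\n")


def read_baseline(path: str | Path) -> ControlBaseline:
    mu_n = sigma_n = None
    amp_ids: list[str] = []
    alpha: list[float] = []
    beta: list[float] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["parameter", "index", "value"]:
            raise NormalizationError(f"{path}: not a baseline file")
        for line in fh:
            param, index, value = line.rstrip("\n").split("\t")
            if param == "mu_n":
                mu_n = float(value)
            elif param == "sigma_n":
                sigma_n = float(value)
            elif param == "alpha":
                amp_ids.append(index)
                alpha.append(float(value))
            elif param == "beta_control":
                beta.append(float(value))
            else:
                raise NormalizationError(f"{path}: unknown parameter {param!r}")
    if mu_n is None or sigma_n is None or not alpha or not beta:
        raise NormalizationError(f"{path}: incomplete baseline file")
    return ControlBaseline(
        mu_n=mu_n,
        alpha=np.array(alpha),
        beta_control=np.array(beta),
        sigma_n=sigma_n,
        amplicon_ids=amp_ids,
    )
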