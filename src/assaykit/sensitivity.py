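"""Limit of detection (LOD) and limit of quantitation (LOQ) on the Cp scale.

Both limits come from the dilution series.  The LOD is the Cp corresponding
to a lower 95% confidence bound on the mean *natural-scale* expression
(2^-Cp) extrapolated to zero concentration: background signal admits a
finite zero-concentration plateau on the natural scale, and a lower bound on
that plateau translates into a later (larger) Cp — the earliest crossing one
could still attribute to background.  Estimates later than the reporting cap
(40 Cp by default, well inside the 45-cycle run) are reported at the cap.

The LOQ evaluates the validated linear calibration at the inverse prediction
of a minimal reliably detectable response ``y_min`` (defaulting to the LOD),
floored at the lower linear-range limit, and reports the one-sided upper 95%
confidence limit of the fitted mean Cp there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dilution import DilutionSeries
from .heterofit import HeteroscedasticPolynomialResults
from .linearity import inverse_predict

__all__ = [
    "LODEstimate",
    "LOQEstimate",
    "SensitivityResult",
    "estimate_lod",
    "estimate_loq",
    "check_sensitivity_criteria",
]


@dataclass(frozen=True)
class LODEstimate:
    lod_cp: float
    capped: bool
    background_mean: float      # fitted natural-scale expression at x = 0
    lower_bound: float          # one-sided lower confidence bound on it
    n_levels_used: int


@dataclass(frozen=True)
class LOQEstimate:
    loq_cp: float
    x_star_ng: float            # concentration at which the CI was evaluated
    at_range_limit: bool        # True when x* was floored at the linear range


@dataclass(frozen=True)
class SensitivityResult:
    gene: str
    lod_cp: float
    loq_cp: float
    y_min: float
    capped: bool


def _natural_level_stats(series: DilutionSeries):
    """Per-level mean/variance of natural-scale expression 2^-Cp.

    Non-detect wells carry signal below 2^-45 and enter as zero.
    """
    rows = []
    for lv in series.levels:
        u = [2.0 ** (-cp) for cp in lv.cps] + [0.0] * lv.n_nondetect
        n = len(u)
        if n == 0:
            continue
        rows.append(
            {
                "x": lv.x,
                "n": n,
                "mean_u": float(np.mean(u)),
                "var_u": float(np.var(u, ddof=1)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def estimate_lod(
    series: DilutionSeries,
    cap: float = 40.0,
    conf: float = 0.95,
    background_window_cp: float = 6.0,
    min_levels: int = 4,
) -> LODEstimate:
    """Lower confidence bound on mean expression at zero concentration.

    The near-background region (levels whose mean Cp lies within
    ``background_window_cp`` of the latest level mean) is fitted with the
    linear natural-scale mean model ``E[2^-Cp] = b_bg + b_sig * x`` by
    weighted least squares; weights are the per-level empirical variances of
    the level means (model-free).  ``LOD = -log2(lower bound on b_bg)``,
    capped at ``cap``.
    """
    tab = _natural_level_stats(series)
    if len(tab) < min_levels:
        raise ValueError(f"need at least {min_levels} levels with data")
    # mean Cp per level from the natural mean (guards zero means)
    with np.errstate(divide="ignore"):
        mean_cp = -np.log2(np.where(tab["mean_u"] > 0, tab["mean_u"], np.nan))
    latest = np.nanmax(mean_cp)
    keep = tab[(mean_cp >= latest - background_window_cp) | np.isnan(mean_cp)]
    if len(keep) < min_levels:
        keep = tab.nsmallest(max(min_levels + 1, 5), "x")
    x = keep["x"].to_numpy()
    m = keep["mean_u"].to_numpy()
    var_mean = keep["var_u"].to_numpy() / keep["n"].to_numpy()

    X = np.column_stack([np.ones_like(x), x])
    if np.all(var_mean <= 0):
        # Degenerate (noise-free) input: exact solve, zero-width bound.
        beta, *_ = np.linalg.lstsq(X, m, rcond=None)
        se_bg = 0.0
    else:
        w = 1.0 / np.maximum(var_mean, np.max(var_mean) * 1e-12)
        Xw = X * np.sqrt(w)[:, None]
        beta, *_ = np.linalg.lstsq(Xw, m * np.sqrt(w), rcond=None)
        cov = np.linalg.inv(Xw.T @ Xw)
        se_bg = float(np.sqrt(max(cov[0, 0], 0.0)))
    b_bg = float(beta[0])
    dof = max(len(keep) - 2, 1)
    lower = b_bg - stats.t.ppf(conf, dof) * se_bg
    if lower <= 0:
        return LODEstimate(cap, True, b_bg, lower, len(keep))
    lod = -np.log2(lower)
    if lod > cap:
        return LODEstimate(cap, True, b_bg, lower, len(keep))
    return LODEstimate(float(lod), False, b_bg, lower, len(keep))


def estimate_loq(
    series: DilutionSeries,
    linear_fit: HeteroscedasticPolynomialResults,
    linear_range: tuple[float, float],
    y_min: float,
    conf: float = 0.95,
) -> LOQEstimate:
    """Upper one-sided confidence limit of the fitted mean Cp at the inverse
    prediction of ``y_min`` (or at the lower linear-range limit when the
    inverse prediction falls below it)."""
    if linear_fit.degree != 1:
        raise ValueError("LOQ requires the final degree-1 calibration fit")
    b1 = linear_fit.params[1]
    if b1 >= 0:
        raise ValueError("calibration slope must be negative")
    x_star = float(inverse_predict(y_min, linear_fit))
    x_min = float(linear_range[0])
    at_limit = x_star < x_min
    if at_limit:
        x_star = x_min
    L = np.log2(x_star)
    upper = float(linear_fit.conf_int_mean(L, alpha=1 - conf, one_sided="upper"))
    return LOQEstimate(loq_cp=upper, x_star_ng=x_star, at_range_limit=at_limit)


def check_sensitivity_criteria(
    results: dict[str, SensitivityResult],
    lod_min_cp: float = 35.0,
    loq_criteria: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene acceptance: the LOD must be a later crossing than
    ``lod_min_cp`` (Cp > 35); per-gene LOQ minima are supplied by
    configuration when pre-specified."""
    loq_criteria = loq_criteria or {}
    rows = []
    for gene in sorted(results):
        r = results[gene]
        lod_pass = r.lod_cp > lod_min_cp
        loq_min = loq_criteria.get(gene)
        loq_pass = True if loq_min is None else r.loq_cp >= loq_min
        rows.append(
            {
                "gene": gene,
                "lod_cp": r.lod_cp,
                "loq_cp": r.loq_cp,
                "capped": r.capped,
                "lod_pass": bool(lod_pass),
                "loq_pass": bool(loq_pass),
                "pass": bool(lod_pass and loq_pass),
            }
        )
    return pd.DataFrame(rows)
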