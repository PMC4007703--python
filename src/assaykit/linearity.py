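"""Linearity assessment, amplification efficiency, and inverse-prediction
accuracy for dilution-series data.

The linearity procedure follows the polynomial-comparison method used for
assay evaluation: fit linear, quadratic and cubic heteroscedastic models;
test the higher-order terms for significance at a family-wise 0.05 level;
when nonlinearity is significant, compute the per-level deviation from
linearity (DL = polynomial prediction minus linear prediction) and trim
extreme concentrations until every retained level has |DL| < 1 Cp.  Before
any polynomial work, low concentrations at and below a level whose replicate
residual SD exceeds 1.5 Cp are removed (large residual variation at tiny
inputs is a known consequence of preamplifying small cDNA amounts).  The
surviving contiguous range is the gene's validated linear range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dilution import DilutionSeries
from .heterofit import HeteroscedasticPolynomial, HeteroscedasticPolynomialResults, lr_test

__all__ = [
    "LinearityResult",
    "fit_hetero_polynomial",
    "deviation_from_linearity",
    "nonlinearity_test",
    "assess_linearity",
    "compute_efficiency",
    "efficiency_confint",
    "inverse_predict",
    "compute_bias",
    "check_validation_criteria",
]


def fit_hetero_polynomial(
    series: DilutionSeries, degree: int, variance: str = "loglinear"
) -> HeteroscedasticPolynomialResults:
    """Convenience wrapper: ML heteroscedastic polynomial fit of a series."""
    return HeteroscedasticPolynomial.from_series(series, degree=degree, variance=variance).fit()


def deviation_from_linearity(
    fit_poly: HeteroscedasticPolynomialResults,
    fit_linear: HeteroscedasticPolynomialResults,
    log2x_levels: Sequence[float],
) -> np.ndarray:
    """DL(x) = polynomial prediction - linear prediction at each level."""
    if fit_linear.degree != 1:
        raise ValueError("fit_linear must be a degree-1 fit")
    L = np.asarray(log2x_levels, float)
    return fit_poly.predict(L) - fit_linear.predict(L)


def nonlinearity_test(
    series: DilutionSeries, alpha: float = 0.05
) -> tuple[bool, float, float, dict[int, HeteroscedasticPolynomialResults]]:
    """Test for significant nonlinearity at family-wise level ``alpha``.

    Fits linear, quadratic and cubic models; the cubic term is tested
    against the quadratic model and the quadratic term against the linear
    model by likelihood-ratio tests.  The two term-wise p-values are
    Bonferroni-combined (each compared with ``alpha/2``) so the overall
    type-I rate of *declaring nonlinearity on a truly linear curve* is held
    at ``alpha``.

    Returns ``(significant, p_quadratic, p_cubic, fits_by_degree)``.
    """
    fits = {d: fit_hetero_polynomial(series, d) for d in (1, 2, 3)}
    _, p_quad = lr_test(fits[2], fits[1])
    _, p_cubic = lr_test(fits[3], fits[2])
    significant = (p_quad < alpha / 2.0) or (p_cubic < alpha / 2.0)
    return significant, p_quad, p_cubic, fits


@dataclass
class LinearityResult:
    """Outcome of the full trimming loop for one gene."""

    gene: str
    valid: bool
    linear_range: tuple[float, float] | None   # (x_min, x_max) ng/well
    retained_levels: list[float]               # concentrations, descending
    removed_levels: list[tuple[float, str]]    # (x, reason in {"residual_sd","DL"})
    nonlinearity_significant: bool
    p_quadratic: float | None
    p_cubic: float | None
    max_abs_dl: float | None                   # None when linearity never rejected
    final_fit: HeteroscedasticPolynomialResults | None
    messages: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        """One report row shaped like a linear-range table entry."""
        lo = f"2^{math.log2(self.linear_range[0]):.1f}" if self.valid else ""
        hi = f"2^{math.log2(self.linear_range[1]):.1f}" if self.valid else ""
        return {
            "gene": self.gene,
            "linear_range_low_ng": self.linear_range[0] if self.valid else np.nan,
            "linear_range_high_ng": self.linear_range[1] if self.valid else np.nan,
            "linear_range_label": f"{lo} to {hi}" if self.valid else "none",
            "p_quadratic": self.p_quadratic,
            "p_cubic": self.p_cubic,
            "max_abs_dl": self.max_abs_dl if self.max_abs_dl is not None else np.nan,
            "n_levels_retained": len(self.retained_levels),
            "valid": self.valid,
        }


def assess_linearity(
    series: DilutionSeries,
    alpha: float = 0.05,
    dl_max: float = 1.0,
    resid_sd_max: float = 1.5,
    min_levels: int = 5,
) -> LinearityResult:
    """Run the complete linear-range determination loop for one gene.

    1. Remove concentrations at and below the highest level whose replicate
       residual SD exceeds ``resid_sd_max`` (1.5 Cp).
    2. Fit linear/quadratic/cubic heteroscedastic models and test for
       nonlinearity at level ``alpha``.
    3. If significant, evaluate DL from the best-fitting polynomial (cubic
       if the cubic term is significant, else quadratic); while the largest
       |DL| is >= ``dl_max`` (1 Cp), drop the extreme level (lowest or
       highest concentration) with the larger |DL| and repeat from 2 — so
       the retained range stays contiguous.

    Fewer than ``min_levels`` surviving levels yields a flagged
    "no valid linear range" result rather than an exception.
    """
    removed: list[tuple[float, str]] = []
    messages: list[str] = []
    levels = list(series.levels)  # descending x

    # Step 1: residual-SD trim of the low-concentration tail.
    sds = [lv.sd_cp for lv in levels]
    offenders = [i for i, sd in enumerate(sds) if np.isfinite(sd) and sd > resid_sd_max]
    if offenders:
        cut = min(offenders)  # highest concentration offender (descending order)
        for lv in levels[cut:]:
            removed.append((lv.x, "residual_sd"))
        messages.append(
            f"removed {len(levels) - cut} level(s) at/below "
            f"{levels[cut].x:.4g} ng (residual SD > {resid_sd_max} Cp)"
        )
        levels = levels[:cut]

    def result_invalid(reason: str) -> LinearityResult:
        return LinearityResult(
            gene=series.gene, valid=False, linear_range=None,
            retained_levels=[lv.x for lv in levels], removed_levels=removed,
            nonlinearity_significant=False, p_quadratic=None, p_cubic=None,
            max_abs_dl=None, final_fit=None, messages=messages + [reason],
        )

    ever_significant = False
    p_quad = p_cubic = None
    max_abs_dl: float | None = None

    while True:
        if len(levels) < min_levels:
            return result_invalid(
                f"only {len(levels)} level(s) survive trimming (< {min_levels})"
            )
        sub = DilutionSeries(series.gene, list(levels))
        significant, p_quad, p_cubic, fits = nonlinearity_test(sub, alpha=alpha)
        if not significant:
            break
        ever_significant = True
        best = fits[3] if p_cubic < alpha / 2.0 else fits[2]
        L = np.array([lv.log2x for lv in levels])
        dl = deviation_from_linearity(best, fits[1], L)
        max_abs_dl = float(np.max(np.abs(dl)))
        if max_abs_dl < dl_max:
            break
        # Drop the extreme level with the larger |DL| (keeps range contiguous).
        if abs(dl[0]) >= abs(dl[-1]):
            drop = 0  # highest concentration
        else:
            drop = len(levels) - 1  # lowest concentration
        removed.append((levels[drop].x, "DL"))
        messages.append(
            f"removed level {levels[drop].x:.4g} ng (|DL| = {abs(dl[drop]):.2f} Cp)"
        )
        del levels[drop]

    final_fit = fit_hetero_polynomial(DilutionSeries(series.gene, list(levels)), 1)
    xs = [lv.x for lv in levels]
    return LinearityResult(
        gene=series.gene,
        valid=True,
        linear_range=(min(xs), max(xs)),
        retained_levels=xs,
        removed_levels=removed,
        nonlinearity_significant=ever_significant,
        p_quadratic=p_quad,
        p_cubic=p_cubic,
        max_abs_dl=max_abs_dl if ever_significant else None,
        final_fit=final_fit,
        messages=messages,
    )


def compute_efficiency(slope: float) -> float:
    """Amplification efficiency (percent) from the dilution-curve slope:
    ``100 * (2^(-1/slope) - 1)``; exactly 100 at slope -1 (perfect
    per-cycle doubling)."""
    if slope >= 0:
        raise ValueError("slope must be negative (Cp decreases with input)")
    return 100.0 * (2.0 ** (-1.0 / slope) - 1.0)


def efficiency_confint(
    slope: float, slope_se: float, conf: float = 0.95
) -> tuple[float, float]:
    """Wald interval for the slope, transformed through the (monotone)
    efficiency formula."""
    from scipy import stats

    z = stats.norm.ppf(0.5 + conf / 2.0)
    ends = sorted(
        compute_efficiency(s) for s in (slope - z * slope_se, slope + z * slope_se)
    )
    return ends[0], ends[1]


def inverse_predict(cp, fit: HeteroscedasticPolynomialResults):
    """Invert the linear calibration: ``x_hat = 2^((cp - b0)/b1)`` ng/well."""
    if fit.degree != 1:
        raise ValueError("inverse prediction requires a degree-1 fit")
    b0, b1 = fit.params
    if b1 == 0:
        raise ZeroDivisionError("zero slope cannot be inverted")
    return 2.0 ** ((np.asarray(cp, float) - b0) / b1)


def compute_bias(
    series: DilutionSeries, fit: HeteroscedasticPolynomialResults
) -> pd.DataFrame:
    """Mean percent bias of inverse-predicted concentration at each level:
    ``100 * sum(x_hat - x_k) / (m * x_k)`` over the m valid wells at level k.
    Levels with no valid wells are skipped with a warning."""
    rows = []
    for lv in series.levels:
        if lv.n == 0:
            warnings.warn(f"level {lv.x:.4g} ng has no valid wells; skipped")
            continue
        xhat = inverse_predict(np.asarray(lv.cps, float), fit)
        rows.append(
            {
                "x_ng": lv.x,
                "log2x": lv.log2x,
                "n_wells": lv.n,
                "pct_bias": float(100.0 * np.mean((xhat - lv.x) / lv.x)),
            }
        )
    return pd.DataFrame(rows, columns=["x_ng", "log2x", "n_wells", "pct_bias"])


def check_validation_criteria(
    efficiencies: Mapping[str, float],
    biases: Mapping[str, pd.DataFrame],
    nominal_ng: Mapping[str, float],
    efficiency_tolerance: float = 20.0,
    bias_max_pct: float = 25.0,
) -> pd.DataFrame:
    """Acceptance evaluation across genes.

    Efficiency passes when within ``efficiency_tolerance`` percentage points
    of the across-gene median.  Bias passes when |mean percent bias| is
    below ``bias_max_pct`` at the nominal, one-half and one-quarter qPCR
    inputs (the design levels closest to those concentrations).
    """
    med = float(np.median(list(efficiencies.values())))
    rows = []
    for gene in sorted(efficiencies):
        eff = efficiencies[gene]
        eff_pass = abs(eff - med) <= efficiency_tolerance
        bias_tab = biases[gene]
        bias_vals = {}
        bias_pass = True
        for frac, label in ((1.0, "nominal"), (0.5, "half"), (0.25, "quarter")):
            target = nominal_ng[gene] * frac
            idx = (bias_tab["x_ng"] - target).abs().idxmin()
            val = float(bias_tab.loc[idx, "pct_bias"])
            bias_vals[f"bias_{label}_pct"] = val
            bias_pass &= abs(val) < bias_max_pct
        rows.append(
            {
                "gene": gene,
                "efficiency_pct": eff,
                "efficiency_median_pct": med,
                "efficiency_pass": bool(eff_pass),
                **bias_vals,
                "bias_pass": bool(bias_pass),
                "pass": bool(eff_pass and bias_pass),
            }
        )
    return pd.DataFrame(rows)
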