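"""Variance components for precision and reproducibility studies.

The study design is 10 tumor RNA samples x 3 RNA inputs (5/10/20 ng) x 3
replicates of an outcome Y (reference-normalized gene expression or the
100-unit score).  Two nested mixed models define the two figures of merit:

* precision:       Y_ijk = mu + alpha_i + lambda_j + eps_ijk
* reproducibility: Y_ijk = mu + alpha_i + eps_ijk

with random sample effects alpha_i ~ N(0, sigma_alpha^2) and residual
eps_ijk ~ N(0, sigma_eps^2).  In the precision model the fixed RNA-input
effect lambda_j absorbs between-input shifts, so sigma_eps is the
within-input SD; the reproducibility model omits it, pooling within- and
between-input variation into sigma_eps.  Estimation is REML: closed-form
(ANOVA) expressions on balanced data — to which REML reduces there — and a
direct numerical optimization of the restricted likelihood otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PrecisionStudy",
    "MixedVarianceModel",
    "VarianceComponentsResults",
    "fit_precision_model",
    "fit_reproducibility_model",
    "ci_residual_sd",
    "variance_fraction",
    "check_precision_criteria",
]


@dataclass
class PrecisionStudy:
    """Tidy precision/reproducibility table for one target.

    Columns: ``sample_id, rna_input_ng, replicate, value`` (an optional
    ``target`` column is carried through).
    """

    data: pd.DataFrame
    target: str = "GPS"

    REQUIRED = ("sample_id", "rna_input_ng", "replicate", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"study table missing column(s) {missing}")
        if "target" in self.data.columns:
            targets = self.data["target"].unique()
            if len(targets) > 1:
                raise ValueError(f"multiple targets {list(targets)}; split first")
            self.target = str(targets[0])
        self.data = self.data.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.data["sample_id"].nunique()

    @property
    def n_inputs(self) -> int:
        return self.data["rna_input_ng"].nunique()

    @property
    def nobs(self) -> int:
        return len(self.data)

    @property
    def is_balanced(self) -> bool:
        counts = self.data.groupby(["sample_id", "rna_input_ng"]).size()
        return (
            counts.nunique() == 1
            and len(counts) == self.n_samples * self.n_inputs
        )

    @classmethod
    def from_csv(cls, path, target: str | None = None) -> "PrecisionStudy":
        df = pd.read_csv(path)
        if target is not None and "target" in df.columns:
            df = df[df["target"] == target]
        return cls(df)


@dataclass
class VarianceComponentsResults:
    """REML estimates with the residual SD as the figure of merit."""

    model_kind: str                 # "precision" | "reproducibility"
    target: str
    mu: float
    sigma_alpha: float
    sigma_eps: float
    dof_resid: int
    lambda_effects: dict[float, float] = field(default_factory=dict)
    truncated: bool = False         # sigma_alpha^2 hit the zero boundary
    balanced: bool = True
    nobs: int = 0

    def ci_sigma_eps(self, conf: float = 0.95) -> tuple[float, float]:
        return ci_residual_sd(self.sigma_eps, self.dof_resid, conf=conf)

    def summary(self) -> str:
        lo, hi = self.ci_sigma_eps()
        lines = [
            f"{self.model_kind.capitalize()} variance components for "
            f"{self.target} (REML, {self.nobs} obs"
            + ("" if self.balanced else ", unbalanced")
            + ")",
            f"  between-sample SD (sigma_alpha): {self.sigma_alpha:.4f}"
            + ("  [truncated at 0]" if self.truncated else ""),
            f"  residual SD (sigma_eps):         {self.sigma_eps:.4f}"
            f"  (95% CL {lo:.4f} to {hi:.4f}, {self.dof_resid} dof)",
            f"  grand mean:                      {self.mu:.4f}",
        ]
        if self.lambda_effects:
            effs = ", ".join(
                f"{k:g} ng: {v:+.4f}" for k, v in sorted(self.lambda_effects.items())
            )
            lines.append(f"  RNA-input effects (vs overall):  {effs}")
        return "\n".join(lines)


class MixedVarianceModel:
    """Mixed model with a random sample intercept; ``fit()`` returns
    :class:`VarianceComponentsResults`.

    ``include_input_effect=True`` gives the precision model (fixed RNA-input
    effect), ``False`` the reproducibility model.
    """

    def __init__(self, study: PrecisionStudy, include_input_effect: bool = True):
        if study.n_samples < 2:
            raise ValueError("need at least 2 samples")
        counts = study.data.groupby(["sample_id", "rna_input_ng"]).size()
        if study.nobs - study.n_samples - (study.n_inputs - 1 if include_input_effect else 0) < 1:
            raise ValueError("degenerate design: no residual degrees of freedom")
        if (counts == 1).all() and study.n_inputs == 1:
            raise ValueError("degenerate design: one replicate everywhere")
        self.study = study
        self.include_input_effect = include_input_effect
        df = study.data
        self.y = df["value"].to_numpy(float)
        self.samples = pd.Categorical(df["sample_id"]).codes
        self.inputs_cat = pd.Categorical(df["rna_input_ng"])
        X = [np.ones(len(df))]
        if include_input_effect:
            for lev in self.inputs_cat.categories[1:]:
                X.append((df["rna_input_ng"] == lev).to_numpy(float))
        self.X = np.column_stack(X)

    @property
    def kind(self) -> str:
        return "precision" if self.include_input_effect else "reproducibility"

    # --- balanced-design closed forms (ANOVA = REML) --------------------
    def _fit_closed_form(self):
        df = self.study.data
        y = self.y
        grand = y.mean()
        I = self.study.n_samples
        N = len(y)
        per_sample = df.groupby("sample_id")["value"].mean()
        n_per_sample = N // I
        ss_sample = n_per_sample * float(((per_sample - grand) ** 2).sum())
        ms_sample = ss_sample / (I - 1)
        if self.include_input_effect:
            J = self.study.n_inputs
            per_input = df.groupby("rna_input_ng")["value"].mean()
            ss_input = (N // J) * float(((per_input - grand) ** 2).sum())
            resid = (
                y
                - per_sample.loc[df["sample_id"]].to_numpy()
                - per_input.loc[df["rna_input_ng"]].to_numpy()
                + grand
            )
            dof = N - I - J + 1
            sse = float((resid**2).sum())
        else:
            resid = y - per_sample.loc[df["sample_id"]].to_numpy()
            dof = N - I
            sse = float((resid**2).sum())
        s2_eps = sse / dof
        s2_alpha = (ms_sample - s2_eps) / n_per_sample
        return s2_alpha, s2_eps, dof

    # --- general REML ----------------------------------------------------
    def _reml_neg2(self, log_s2a: float, log_s2e: float) -> float:
        s2a, s2e = math.exp(log_s2a), math.exp(log_s2e)
        y, X, g = self.y, self.X, self.samples
        n = len(y)
        logdet_v = 0.0
        Vinv_y = np.empty(n)
        Vinv_X = np.empty_like(X)
        for grp in np.unique(g):
            idx = g == grp
            ni = int(idx.sum())
            shrink = s2a / (s2e + ni * s2a)
            logdet_v += (ni - 1) * math.log(s2e) + math.log(s2e + ni * s2a)
            yb = y[idx]
            Xb = X[idx]
            Vinv_y[idx] = (yb - shrink * yb.sum()) / s2e
            Vinv_X[idx] = (Xb - shrink * Xb.sum(axis=0)) / s2e
        XtVX = X.T @ Vinv_X
        XtVy = X.T @ Vinv_y
        beta = np.linalg.solve(XtVX, XtVy)
        r = y - X @ beta
        # r' V^-1 r computed via the same block inverse
        rVr = 0.0
        for grp in np.unique(g):
            idx = g == grp
            ni = int(idx.sum())
            shrink = s2a / (s2e + ni * s2a)
            rb = r[idx]
            rVr += float(rb @ rb - shrink * rb.sum() ** 2) / s2e
        sign, logdet_x = np.linalg.slogdet(XtVX)
        return logdet_v + logdet_x + rVr

    def _fit_numeric(self):
        var_y = float(np.var(self.y)) or 1.0
        best = None
        for start in ((0.5, 0.5), (0.05, 0.95), (0.95, 0.05)):
            x0 = [math.log(var_y * start[0] + 1e-10), math.log(var_y * start[1] + 1e-10)]
            res = optimize.minimize(
                lambda p: self._reml_neg2(p[0], p[1]),
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        s2a, s2e = math.exp(best.x[0]), math.exp(best.x[1])
        dof = len(self.y) - self.X.shape[1]
        return s2a, s2e, dof

    def fit(self, method: str = "auto") -> VarianceComponentsResults:
        """REML fit.  ``method`` in {"auto", "closed_form", "numeric"};
        "auto" uses closed forms on balanced data."""
        balanced = self.study.is_balanced
        if method == "auto":
            method = "closed_form" if balanced else "numeric"
        if method == "closed_form":
            if not balanced:
                raise ValueError("closed-form REML requires a balanced design")
            s2a, s2e, dof = self._fit_closed_form()
        elif method == "numeric":
            s2a, s2e, dof = self._fit_numeric()
        else:
            raise ValueError(f"unknown method {method!r}")

        truncated = s2a < 0 or s2a < 1e-10 * max(s2e, 1e-300)
        s2a = max(s2a, 0.0)
        df = self.study.data
        mu = float(self.y.mean())
        lambdas: dict[float, float] = {}
        if self.include_input_effect:
            per_input = df.groupby("rna_input_ng")["value"].mean()
            lambdas = {float(k): float(v - mu) for k, v in per_input.items()}
        return VarianceComponentsResults(
            model_kind=self.kind,
            target=self.study.target,
            mu=mu,
            sigma_alpha=math.sqrt(s2a),
            sigma_eps=math.sqrt(max(s2e, 0.0)),
            dof_resid=int(dof),
            lambda_effects=lambdas,
            truncated=bool(truncated),
            balanced=balanced,
            nobs=self.study.nobs,
        )


def fit_precision_model(
    study: PrecisionStudy | pd.DataFrame, method: str = "auto"
) -> VarianceComponentsResults:
    """Precision model: RNA input as a fixed effect; the residual SD is the
    within-input (precision) SD."""
    if isinstance(study, pd.DataFrame):
        study = PrecisionStudy(study)
    return MixedVarianceModel(study, include_input_effect=True).fit(method=method)


def fit_reproducibility_model(
    study: PrecisionStudy | pd.DataFrame, method: str = "auto"
) -> VarianceComponentsResults:
    """Reproducibility model: no input effect; the residual SD pools within-
    and between-input variation."""
    if isinstance(study, pd.DataFrame):
        study = PrecisionStudy(study)
    return MixedVarianceModel(study, include_input_effect=False).fit(method=method)


def ci_residual_sd(
    sigma_eps: float, dof: int, conf: float = 0.95
) -> tuple[float, float]:
    """Chi-square confidence interval for the residual SD:
    ``sqrt(dof * s^2 / chi2_{upper,lower})``."""
    if dof <= 0:
        raise ValueError("dof must be positive")
    a = (1.0 - conf) / 2.0
    s2 = sigma_eps**2
    lo = math.sqrt(dof * s2 / stats.chi2.ppf(1 - a, dof))
    hi = math.sqrt(dof * s2 / stats.chi2.ppf(a, dof))
    return lo, hi


def variance_fraction(component_sd: float, total_sd: float) -> float:
    """Percent of total variance attributable to a component:
    ``100 * component_sd^2 / total_sd^2``."""
    if total_sd <= 0:
        raise ValueError("total_sd must be positive")
    return 100.0 * component_sd**2 / total_sd**2


def check_precision_criteria(
    results: dict[str, VarianceComponentsResults],
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Compare per-target residual SDs with configured acceptance
    thresholds; with no thresholds the table is informational only."""
    thresholds = thresholds or {}
    rows = []
    for target in sorted(results):
        r = results[target]
        lo, hi = r.ci_sigma_eps()
        thr = thresholds.get(target)
        rows.append(
            {
                "target": target,
                "model": r.model_kind,
                "sd": r.sigma_eps,
                "lower_95cl": lo,
                "upper_95cl": hi,
                "threshold": thr if thr is not None else np.nan,
                "pass": bool(r.sigma_eps <= thr) if thr is not None else True,
            }
        )
    return pd.DataFrame(rows)
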