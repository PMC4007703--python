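"""REML variance components for the precision/reproducibility mixed models."""

import numpy as np
import pandas as pd
import pytest

import assaykit as ak
from assaykit.precision import (
    MixedVarianceModel,
    PrecisionStudy,
    check_precision_criteria,
    ci_residual_sd,
    variance_fraction,
)


def anova_oracle(df: pd.DataFrame, with_input: bool):
    """Closed-form balanced-design ANOVA/REML expressions, computed
    independently of the implementation."""
    y = df["value"].to_numpy()
    grand = y.mean()
    samples = df["sample_id"].unique()
    I, N = len(samples), len(y)
    nps = N // I
    sm = df.groupby("sample_id")["value"].mean()
    ms_sample = nps * ((sm - grand) ** 2).sum() / (I - 1)
    if with_input:
        im = df.groupby("rna_input_ng")["value"].mean()
        J = df["rna_input_ng"].nunique()
        resid = (
            y
            - sm.loc[df["sample_id"]].to_numpy()
            - im.loc[df["rna_input_ng"]].to_numpy()
            + grand
        )
        dof = N - I - J + 1
    else:
        resid = y - sm.loc[df["sample_id"]].to_numpy()
        dof = N - I
    s2e = (resid**2).sum() / dof
    s2a = max((ms_sample - s2e) / nps, 0.0)
    return np.sqrt(s2a), np.sqrt(s2e), dof


class TestPrecisionModel:
    def test_zero_noise_gives_zero_residual_sd(self):
        p = ak.PrecisionSimParams(sigma_alpha=1.0, sigma_eps=0.0)
        res = ak.fit_precision_model(ak.simulate_precision_study(p, seed=0))
        assert res.sigma_eps == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_oracle(self):
        df = ak.simulate_precision_study(seed=8)
        res = ak.fit_precision_model(df)
        sa, se, dof = anova_oracle(df, with_input=True)
        assert res.sigma_alpha == pytest.approx(sa, abs=1e-10)
        assert res.sigma_eps == pytest.approx(se, abs=1e-10)
        assert res.dof_resid == dof == 78

    def test_numeric_reml_agrees_with_closed_form(self):
        df = ak.simulate_precision_study(seed=9)
        st = PrecisionStudy(df)
        cf = MixedVarianceModel(st, True).fit(method="closed_form")
        num = MixedVarianceModel(st, True).fit(method="numeric")
        assert num.sigma_eps == pytest.approx(cf.sigma_eps, abs=1e-6)
        assert num.sigma_alpha == pytest.approx(cf.sigma_alpha, abs=1e-5)

    def test_unbalanced_data_agrees_with_mixedlm(self):
        import statsmodels.formula.api as smf

        df = ak.simulate_precision_study(seed=10).drop(index=[0, 4, 17, 33, 88])
        res = ak.fit_precision_model(df)
        assert not res.balanced
        m = smf.mixedlm(
            "value ~ C(rna_input_ng)", df, groups=df["sample_id"]
        ).fit(reml=True)
        assert res.sigma_eps == pytest.approx(np.sqrt(m.scale), rel=1e-3)
        assert res.sigma_alpha == pytest.approx(
            np.sqrt(float(m.cov_re.iloc[0, 0])), rel=1e-2
        )

    def test_mean_recovery_over_many_studies(self):
        p = ak.PrecisionSimParams(mu=9.0, sigma_alpha=0.8, sigma_eps=0.15,
                                  lambda_effects=(0.0, 0.05, -0.05))
        ests = [
            ak.fit_precision_model(
                ak.simulate_precision_study(p, seed=300_000 + i)
            ).sigma_eps
            for i in range(400)
        ]
        assert np.mean(ests) == pytest.approx(0.15, rel=0.02)

    def test_shift_invariance(self):
        df = ak.simulate_precision_study(seed=11)
        shifted = df.assign(value=df["value"] + 100.0)
        a = ak.fit_precision_model(df)
        b = ak.fit_precision_model(shifted)
        assert b.sigma_eps == pytest.approx(a.sigma_eps, abs=1e-9)
        assert b.sigma_alpha == pytest.approx(a.sigma_alpha, abs=1e-9)


class TestReproducibilityModel:
    def test_constant_data_gives_zero_components(self):
        p = ak.PrecisionSimParams(sigma_alpha=0.0, sigma_eps=0.0,
                                  lambda_effects=(0.0, 0.0, 0.0))
        res = ak.fit_reproducibility_model(ak.simulate_precision_study(p, seed=0))
        assert res.sigma_eps == 0.0
        assert res.sigma_alpha == 0.0

    def test_no_input_effect_matches_precision_sd(self):
        p = ak.PrecisionSimParams(mu=10.0, sigma_alpha=1.0, sigma_eps=0.3,
                                  lambda_effects=(0.0, 0.0, 0.0))
        prec, repro = [], []
        for i in range(200):
            df = ak.simulate_precision_study(p, seed=310_000 + i)
            prec.append(ak.fit_precision_model(df).sigma_eps)
            repro.append(ak.fit_reproducibility_model(df).sigma_eps)
        assert np.mean(repro) == pytest.approx(np.mean(prec), rel=0.02)

    def test_input_effects_inflate_reproducibility_sd(self):
        p = ak.PrecisionSimParams(mu=10.0, sigma_alpha=1.0, sigma_eps=0.3,
                                  lambda_effects=(0.0, 0.3, -0.3))
        prec, repro = [], []
        for i in range(200):
            df = ak.simulate_precision_study(p, seed=320_000 + i)
            prec.append(ak.fit_precision_model(df).sigma_eps)
            repro.append(ak.fit_reproducibility_model(df).sigma_eps)
        assert np.mean(repro) > np.mean(prec)
        # pooled truth: sqrt(0.3^2 + mean(lambda^2))
        pooled = np.sqrt(0.09 + (0.09 + 0.09) / 3)
        assert np.mean(repro) == pytest.approx(pooled, rel=0.05)

    def test_reproducibility_uses_more_residual_dof(self):
        df = ak.simulate_precision_study(seed=12)
        assert ak.fit_reproducibility_model(df).dof_resid == 80
        assert ak.fit_precision_model(df).dof_resid == 78


class TestResidualSDInterval:
    def test_contains_point_estimate(self):
        lo, hi = ci_residual_sd(0.21, 78)
        assert lo < 0.21 < hi

    def test_collapses_for_huge_dof(self):
        lo, hi = ci_residual_sd(0.21, 10**8)
        assert lo == pytest.approx(0.21, abs=1e-4)
        assert hi == pytest.approx(0.21, abs=1e-4)

    def test_coverage_near_nominal(self):
        p = ak.PrecisionSimParams(mu=0.0, sigma_alpha=1.0, sigma_eps=0.2,
                                  lambda_effects=(0.0, 0.1, -0.1))
        hits = 0
        n = 400
        for i in range(n):
            res = ak.fit_precision_model(
                ak.simulate_precision_study(p, seed=330_000 + i)
            )
            lo, hi = res.ci_sigma_eps()
            hits += lo <= 0.2 <= hi
        assert hits / n == pytest.approx(0.95, abs=0.03)


class TestVarianceFraction:
    def test_reported_discussion_arithmetic(self):
        assert variance_fraction(2.11, 11.4) == pytest.approx(3.4, abs=0.05)

    @pytest.mark.parametrize("c, t, expected", [(0.0, 11.4, 0.0), (11.4, 11.4, 100.0)])
    def test_edge_values(self, c, t, expected):
        assert variance_fraction(c, t) == pytest.approx(expected)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            variance_fraction(1.0, 0.0)


class TestCriteriaTable:
    def _results(self, sds):
        return {
            t: ak.VarianceComponentsResults(
                model_kind="precision", target=t, mu=0.0, sigma_alpha=1.0,
                sigma_eps=sd, dof_resid=78, nobs=90,
            )
            for t, sd in sds.items()
        }

    def test_thresholds_applied(self):
        table = check_precision_criteria(
            self._results({"KLK2": 0.08, "TPX2": 0.21, "GPS": 2.5}),
            thresholds={"KLK2": 0.21, "TPX2": 0.21, "GPS": 1.9},
        )
        idx = table.set_index("target")
        assert idx.loc["KLK2", "pass"] and idx.loc["TPX2", "pass"]
        assert not idx.loc["GPS", "pass"]

    def test_no_thresholds_is_informational(self):
        table = check_precision_criteria(self._results({"GPS": 5.0}))
        assert table["pass"].all()
        assert np.isnan(table["threshold"]).all()
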