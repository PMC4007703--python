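"""Linear-range determination, amplification efficiency, inverse prediction
and percent bias."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import assaykit as ak
from assaykit.linearity import (
    check_validation_criteria,
    compute_bias,
    compute_efficiency,
    deviation_from_linearity,
    efficiency_confint,
    inverse_predict,
)


class TestAssessLinearity:
    def test_noiseless_linear_series_keeps_full_range(self, make_exact_series):
        s = make_exact_series(b0=27.0, b1=-1.05)
        res = ak.assess_linearity(s)
        assert res.valid
        assert not res.nonlinearity_significant
        assert res.max_abs_dl is None  # no nonlinearity -> no DL computed
        assert len(res.retained_levels) == 14
        assert res.linear_range == pytest.approx((204.0 / 2**13, 204.0))

    def test_low_end_distortion_removed_by_dl_rule(self, make_exact_series):
        # A smoothly accelerating Cp excess at the lowest concentrations
        # emulates preamplification failure; the small symmetric spread
        # supplies residual variance without changing level means.
        s = make_exact_series(
            offsets={11: 1.2, 12: 3.0, 13: 5.5},
            spreads={i: 0.02 for i in range(14)},
        )
        res = ak.assess_linearity(s)
        assert res.valid
        assert res.nonlinearity_significant
        removed_x = {x for x, reason in res.removed_levels if reason == "DL"}
        assert 204.0 / 2**13 in removed_x
        assert 204.0 / 2**12 in removed_x
        assert res.max_abs_dl is not None and res.max_abs_dl < 1.0
        assert min(res.retained_levels) >= 204.0 / 2**11

    def test_noisy_low_tail_removed_by_residual_sd_rule(self, make_exact_series):
        # spread 1.5 between adjacent replicates -> level SD ~ 4 Cp > 1.5
        s = make_exact_series(spreads={13: 1.5, 12: 1.5, 5: 0.01})
        res = ak.assess_linearity(s)
        reasons = {x: r for x, r in res.removed_levels}
        assert reasons[204.0 / 2**13] == "residual_sd"
        assert reasons[204.0 / 2**12] == "residual_sd"
        assert res.valid and len(res.retained_levels) == 12

    def test_too_few_surviving_levels_flagged_not_raised(self, make_exact_series):
        s = make_exact_series(n_levels=6, spreads={1: 2.0})
        res = ak.assess_linearity(s)  # trim drops level 1 and everything below
        assert not res.valid
        assert res.linear_range is None
        assert any("survive" in m for m in res.messages)

    def test_retained_range_contiguous(self, make_exact_series):
        s = make_exact_series(offsets={13: 3.0, 12: 2.0}, spreads={i: 0.03 for i in range(14)})
        res = ak.assess_linearity(s)
        xs = sorted(res.retained_levels)
        ratios = [xs[i + 1] / xs[i] for i in range(len(xs) - 1)]
        assert np.allclose(ratios, 2.0)


class TestDeviationFromLinearity:
    def test_identical_fits_give_zero(self, make_exact_series):
        s = make_exact_series()
        lin = ak.fit_hetero_polynomial(s, 1)
        quad = ak.fit_hetero_polynomial(s, 2)
        L = [lv.log2x for lv in s.levels]
        assert np.allclose(deviation_from_linearity(quad, lin, L), 0.0, atol=1e-8)

    def test_matches_direct_curve_difference(self, make_exact_series):
        s = make_exact_series()
        lin = ak.fit_hetero_polynomial(s, 1)
        quad = ak.fit_hetero_polynomial(s, 2)
        bumped = dataclasses.replace(
            quad, params=np.array([*quad.params[:2], 0.01])
        )
        L = np.array([lv.log2x for lv in s.levels])
        dl = deviation_from_linearity(bumped, lin, L)
        expected = (bumped.params[0] + bumped.params[1] * L + 0.01 * L**2) - (
            lin.params[0] + lin.params[1] * L
        )
        assert np.allclose(dl, expected, atol=1e-10)


class TestEfficiency:
    def test_perfect_doubling(self):
        assert compute_efficiency(-1.0) == pytest.approx(100.0)

    def test_closed_form_at_slope_minus_two(self):
        assert compute_efficiency(-2.0) == pytest.approx(100.0 * (2**0.5 - 1), abs=1e-9)

    def test_printed_efficiency_inverts_to_its_slope(self):
        # slope = -1/log2(1 + eff/100): at 93.9% the slope is about -1.0468
        slope = -1.0 / math.log2(1.939)
        assert slope == pytest.approx(-1.0468, abs=5e-4)
        assert compute_efficiency(slope) == pytest.approx(93.9, abs=1e-9)

    def test_nonnegative_slope_rejected(self):
        with pytest.raises(ValueError):
            compute_efficiency(0.5)

    def test_monotone_increasing_in_slope(self):
        slopes = [-2.0, -1.5, -1.2, -1.0, -0.9]
        effs = [compute_efficiency(s) for s in slopes]
        assert all(a < b for a, b in zip(effs, effs[1:]))

    def test_confint_ordered_and_brackets_estimate(self):
        lo, hi = efficiency_confint(-1.05, 0.01)
        assert lo < compute_efficiency(-1.05) < hi


class TestInversePrediction:
    def test_round_trip_identity(self, make_exact_series):
        fit = ak.fit_hetero_polynomial(make_exact_series(b0=30.0, b1=-1.1), 1)
        for x in [0.03, 1.0, 17.5, 204.0]:
            cp = fit.predict(math.log2(x))
            assert inverse_predict(cp, fit) == pytest.approx(x, rel=1e-12)

    @pytest.mark.parametrize(
        "b0, b1, cp, expected",
        [
            (30.0, -1.0, 25.0, 32.0),
            (30.0, -1.0, 30.0, 1.0),
            (33.5, -1.05, 30.0, 2 ** (3.5 / 1.05)),
        ],
    )
    def test_closed_form_values(self, make_exact_series, b0, b1, cp, expected):
        fit = ak.fit_hetero_polynomial(make_exact_series(b0=b0, b1=b1), 1)
        assert inverse_predict(cp, fit) == pytest.approx(expected, rel=1e-9)

    def test_degree_two_fit_rejected(self, make_exact_series):
        quad = ak.fit_hetero_polynomial(make_exact_series(), 2)
        with pytest.raises(ValueError):
            inverse_predict(25.0, quad)


class TestBias:
    def test_perfect_predictions_zero_bias(self, make_exact_series):
        s = make_exact_series(b0=28.0, b1=-1.0)
        fit = ak.fit_hetero_polynomial(s, 1)
        bias = compute_bias(s, fit)
        assert np.allclose(bias["pct_bias"], 0.0, atol=1e-8)

    def test_ten_percent_overprediction(self, make_exact_series):
        s = make_exact_series(b0=28.0, b1=-1.0)
        fit = ak.fit_hetero_polynomial(s, 1)
        shifted = dataclasses.replace(
            fit, params=np.array([28.0 - (-1.0) * math.log2(1.1), -1.0])
        )
        bias = compute_bias(s, shifted)
        assert np.allclose(bias["pct_bias"], 10.0, atol=1e-6)

    def test_unbiased_on_average_over_simulations(self):
        p = ak.GeneSimParams(gamma0=2 * np.log(0.1), gamma1=0.0)
        means = []
        for i in range(200):
            s = ak.simulate_dilution_series(p, seed=50_000 + i)
            fit = ak.fit_hetero_polynomial(s, 1)
            means.append(compute_bias(s, fit)["pct_bias"].mean())
        assert abs(np.mean(means)) < 0.5  # percent


class TestValidationCriteria:
    # per-gene efficiencies with the reported spread: median 93.9, all
    # within 6.3 points
    TABLE_EFFS = {
        "ARF1": 93.9, "ATP5E": 90.2, "AZGP1": 88.1, "BGN": 92.5, "CLTC": 97.2,
        "COL1A1": 95.4, "FAM13C": 88.5, "FLNC": 96.9, "GPS1": 94.4, "GSN": 91.5,
        "GSTM2": 95.9, "KLK2": 92.4, "PGK1": 89.9, "SFRP4": 93.9, "SRD5A2": 98.7,
        "TPM2": 100.2, "TPX2": 98.9,
    }

    def _zero_bias(self, genes):
        tab = pd.DataFrame({"x_ng": [25.5, 12.75, 6.375], "log2x": 0.0,
                            "n_wells": 9, "pct_bias": 0.0})
        return {g: tab.copy() for g in genes}

    def test_reported_efficiency_spread_passes(self):
        effs = self.TABLE_EFFS
        table = check_validation_criteria(
            effs, self._zero_bias(effs), {g: 20.0 for g in effs}
        )
        assert table["efficiency_median_pct"].iloc[0] == pytest.approx(93.9)
        assert (table["efficiency_pct"] - 93.9).abs().max() == pytest.approx(6.3)
        assert table["pass"].all()

    def test_equal_efficiencies_pass(self):
        effs = {g: 95.0 for g in ["A", "B", "C"]}
        table = check_validation_criteria(
            effs, self._zero_bias(effs), {g: 20.0 for g in effs}
        )
        assert table["efficiency_pass"].all()

    def test_large_bias_at_nominal_input_fails_gene(self):
        effs = {"A": 95.0, "B": 95.0}
        biases = self._zero_bias(effs)
        biases["B"].loc[0, "pct_bias"] = -30.0
        table = check_validation_criteria(effs, biases, {g: 20.0 for g in effs})
        assert table.set_index("gene").loc["A", "pass"]
        assert not table.set_index("gene").loc["B", "bias_pass"]
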