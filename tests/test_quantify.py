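"""Well validation, Cp aggregation, normalization and plate QC."""

import numpy as np
import pytest

import assaykit as ak
from assaykit.panel import NON_DETECT, PlateData, WellMeasurement
from assaykit.quantify import (
    GeneFailure,
    MissingControlsError,
    SampleFailure,
    aggregate_gene_cp,
    gdna_qc,
    normalize_expression,
    plate_qc,
    reference_aggregate,
    validate_wells,
)


def wells(gene, cps, sample="s1", role="patient"):
    out = []
    for i, cp in enumerate(cps, start=1):
        out.append(
            WellMeasurement(
                plate_id="p1", well_id=f"w{i}", sample_id=sample, gene=gene,
                replicate_index=i, cp=cp, role=role,
            )
        )
    return out


class TestValidateWells:
    def test_single_non_detect_dropped(self):
        valid = validate_wells(wells("KLK2", [20.0, 20.2, NON_DETECT]))
        assert [w.cp for w in valid] == [20.0, 20.2]

    def test_fewer_than_two_valid_wells_fails_gene(self):
        with pytest.raises(GeneFailure) as err:
            validate_wells(wells("KLK2", [20.0, NON_DETECT, NON_DETECT]))
        assert err.value.gene == "KLK2"
        assert err.value.sample_id == "s1"

    def test_full_triplicate_retained(self):
        assert len(validate_wells(wells("KLK2", [20.0, 20.1, 20.2]))) == 3

    def test_revalidation_is_idempotent(self):
        v1 = validate_wells(wells("KLK2", [20.0, 20.2, NON_DETECT]))
        v2 = validate_wells(v1)
        assert v1 == v2


class TestAggregation:
    @pytest.mark.parametrize(
        "cps, weights, expected",
        [
            ([20.0, 20.2, 20.4], [1, 1, 1], 20.2),
            ([20.0, 20.2], [1, 1, 1], 20.1),
            ([20.0, 20.2, 20.4], [2, 1, 1], 20.15),
        ],
    )
    def test_weighted_mean(self, cps, weights, expected):
        assert aggregate_gene_cp(cps, weights) == pytest.approx(expected)

    def test_weights_follow_replicate_index_of_surviving_wells(self):
        # drop the heavy-weighted replicate 1: remaining weights renormalize
        ws = validate_wells(wells("KLK2", [NON_DETECT, 20.0, 21.0]))
        assert aggregate_gene_cp(ws, [5.0, 1.0, 3.0]) == pytest.approx(
            (20.0 * 1 + 21.0 * 3) / 4
        )

    def test_result_bounded_by_inputs(self):
        agg = aggregate_gene_cp([19.0, 21.0, 23.0], [0.2, 0.5, 0.3])
        assert 19.0 <= agg <= 23.0


class TestNormalization:
    def test_reference_aggregate_is_plain_mean(self, panel):
        refs = dict(zip(panel.reference_genes, [22.0, 23.0, 24.0, 25.0, 26.0]))
        assert reference_aggregate(refs, panel) == pytest.approx(24.0)

    def test_missing_reference_gene_fails_sample(self, panel):
        refs = {g: 24.0 for g in panel.reference_genes[:4]}
        with pytest.raises(SampleFailure, match=panel.reference_genes[4]):
            reference_aggregate(refs, panel)

    @pytest.mark.parametrize(
        "gene_cp, ref, expected",
        [(24.0, 24.0, 10.0), (22.0, 24.0, 8.0), (30.0, 24.0, 16.0)],
    )
    def test_centering_formula(self, gene_cp, ref, expected):
        assert normalize_expression(gene_cp, ref) == pytest.approx(expected)

    def test_shift_invariance(self):
        base = normalize_expression(22.3, 24.7)
        assert normalize_expression(23.3, 25.7) == pytest.approx(base)


class TestGdnaQC:
    def test_non_detect_passes(self):
        assert gdna_qc(NON_DETECT, 35.0)

    def test_early_crossing_fails(self):
        assert not gdna_qc(25.0, 35.0)

    def test_exactly_at_threshold_passes(self):
        assert gdna_qc(35.0, 35.0)


class TestPlateQC:
    def _control_plate(self, panel, seed=0):
        from assaykit.simulate import default_control_levels

        levels = default_control_levels(panel)
        return ak.simulate_control_plates(
            1,
            {g: m for g, (m, s) in levels.items()},
            {g: s for g, (m, s) in levels.items()},
            panel,
            seed=seed,
        )[0]

    def test_nominal_controls_pass(self, panel):
        status = plate_qc(self._control_plate(panel), panel)
        assert status.overall_pass
        assert status.messages == []

    def test_detected_negative_well_fails(self, panel):
        plate = self._control_plate(panel)
        neg = plate.select(role="negative")[0]
        plate.wells.remove(neg)
        plate.wells.append(
            WellMeasurement(
                plate_id=neg.plate_id, well_id=neg.well_id, sample_id=neg.sample_id,
                gene=neg.gene, replicate_index=neg.replicate_index, cp=30.0,
                role="negative",
            )
        )
        status = plate_qc(plate, panel)
        assert not status.negative_controls_pass
        assert not status.overall_pass

    def test_gdna_positive_non_detect_fails(self, panel):
        plate = self._control_plate(panel)
        plate.wells = [w for w in plate.wells if w.role != "gdna_positive"] + [
            WellMeasurement(
                plate_id="p", well_id=f"g{i}", sample_id="gdna_pos",
                gene=panel.gdna_assay, replicate_index=i, cp=NON_DETECT,
                role="gdna_positive",
            )
            for i in (1, 2, 3)
        ]
        status = plate_qc(plate, panel)
        assert not status.gdna_pass

    def test_missing_controls_is_structural_error(self, panel):
        plate = self._control_plate(panel)
        plate.wells = [w for w in plate.wells if w.role != "negative"]
        with pytest.raises(MissingControlsError):
            plate_qc(plate, panel)


class TestQuantifySample:
    def test_end_to_end_shift_invariance(self, panel):
        truth = {g: 8.0 + 0.1 * i for i, g in enumerate(panel.cancer_genes)}
        plate = ak.simulate_patient_plate(truth, panel, noise_sd=0.05, seed=9)
        shifted = PlateData(
            wells=[
                WellMeasurement(
                    plate_id=w.plate_id, well_id=w.well_id, sample_id=w.sample_id,
                    gene=w.gene, replicate_index=w.replicate_index,
                    cp=w.cp if not w.detected else float(w.cp) + 1.0, role=w.role,
                )
                for w in plate.wells
            ],
            metadata=plate.metadata,
        )
        a = ak.quantify_sample(plate, panel).normalized
        b = ak.quantify_sample(shifted, panel).normalized
        for g in a:
            assert b[g] == pytest.approx(a[g], abs=1e-9)

    def test_failed_cancer_gene_fails_sample(self, panel):
        truth = {g: 9.0 for g in panel.cancer_genes}
        plate = ak.simulate_patient_plate(truth, panel, seed=0)
        plate.wells = [
            w if w.gene != "KLK2" else WellMeasurement(
                plate_id=w.plate_id, well_id=w.well_id, sample_id=w.sample_id,
                gene=w.gene, replicate_index=w.replicate_index,
                cp=NON_DETECT, role=w.role,
            )
            for w in plate.wells
        ]
        with pytest.raises(SampleFailure, match="KLK2"):
            ak.quantify_sample(plate, panel)

    def test_reference_window_enforced_when_configured(self, panel):
        strict = panel.model_copy(deep=True)
        strict.qc_thresholds.reference_mean_window = (10.0, 20.0)
        truth = {g: 9.0 for g in panel.cancer_genes}
        plate = ak.simulate_patient_plate(truth, panel, seed=0, reference_cp=24.0)
        with pytest.raises(SampleFailure, match="window"):
            ak.quantify_sample(plate, strict)
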