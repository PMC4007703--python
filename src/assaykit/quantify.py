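"""From raw wells to per-gene expression and plate QC.

The quantification chain is: validate each gene's triplicate (at least two
valid wells), aggregate the valid wells to a weighted-mean Cp, average the
five reference genes, and normalize each cancer gene as

    normalized = gene_cp - reference_average + centering_constant

(centering constant 10 Cp by default).  Because normalization subtracts the
reference average, the result is invariant to any constant Cp shift applied
to all wells of a sample — the property that lets the assay absorb variable
RNA inputs.  On this Cp-oriented scale a larger normalized value means a
later crossing, i.e. lower transcript abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import NON_DETECT, PanelConfig, PlateData, WellMeasurement

__all__ = [
    "GeneExpression",
    "QCStatus",
    "SampleQuantification",
    "GeneFailure",
    "SampleFailure",
    "MissingControlsError",
    "validate_wells",
    "aggregate_gene_cp",
    "reference_aggregate",
    "normalize_expression",
    "gdna_qc",
    "plate_qc",
    "quantify_sample",
]


class GeneFailure(RuntimeError):
    """A gene assay produced fewer than the required valid wells."""

    def __init__(self, gene: str, sample_id: str, n_valid: int, required: int):
        self.gene, self.sample_id, self.n_valid = gene, sample_id, n_valid
        super().__init__(
            f"gene {gene!r} for sample {sample_id!r}: {n_valid} valid well(s), "
            f"{required} required"
        )


class SampleFailure(RuntimeError):
    """A sample cannot be quantified (failed reference or cancer gene)."""


class MissingControlsError(RuntimeError):
    """A required control role is absent from the plate."""


@dataclass(frozen=True)
class GeneExpression:
    gene: str
    aggregated_cp: float
    n_valid_wells: int
    normalized: float | None = None  # None for reference genes / partial mode


@dataclass
class QCStatus:
    gdna_pass: bool = True
    negative_controls_pass: bool = True
    positive_control_pass: bool = True
    messages: list[str] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return self.gdna_pass and self.negative_controls_pass and self.positive_control_pass


@dataclass
class SampleQuantification:
    """Quantification output for one sample on one plate."""

    sample_id: str
    expressions: dict[str, GeneExpression]
    reference_aggregate: float
    gdna_pass: bool
    failed_genes: list[str] = field(default_factory=list)

    @property
    def normalized(self) -> dict[str, float]:
        return {
            g: e.normalized
            for g, e in self.expressions.items()
            if e.normalized is not None
        }


def validate_wells(
    wells: Sequence[WellMeasurement],
    min_valid: int = 2,
    raise_on_failure: bool = True,
) -> list[WellMeasurement]:
    """Drop non-detect wells; fail the gene if fewer than ``min_valid``
    remain (triplicates require at least 2 valid wells)."""
    if not wells:
        raise ValueError("no wells supplied")
    genes = {w.gene for w in wells}
    samples = {w.sample_id for w in wells}
    if len(genes) != 1 or len(samples) != 1:
        raise ValueError("validate_wells expects wells for a single gene and sample")
    valid = [w for w in wells if w.detected]
    if len(valid) < min_valid and raise_on_failure:
        raise GeneFailure(genes.pop(), samples.pop(), len(valid), min_valid)
    return valid


def aggregate_gene_cp(
    valid_wells: Sequence[WellMeasurement] | Sequence[float],
    weights: Sequence[float],
) -> float:
    """Weighted mean Cp over the valid wells, weights renormalized over the
    wells actually present.

    Accepts either well objects (weights matched by replicate index) or bare
    Cp values (weights matched positionally).
    """
    if len(valid_wells) < 1:
        raise ValueError("no wells to aggregate")
    if valid_wells and isinstance(valid_wells[0], WellMeasurement):
        cps = np.array([float(w.cp) for w in valid_wells])
        idx = [w.replicate_index - 1 for w in valid_wells]
        if max(idx) >= len(weights):
            raise ValueError("replicate index exceeds configured well_weights")
        w = np.array([weights[i] for i in idx], float)
    else:
        cps = np.asarray(valid_wells, float)
        if len(cps) > len(weights):
            raise ValueError("more wells than configured well_weights")
        w = np.asarray(weights[: len(cps)], float)
    if w.sum() <= 0:
        raise ValueError("weights of present wells sum to zero")
    return float(np.sum(w * cps) / w.sum())


def reference_aggregate(ref_expressions: Mapping[str, float], panel: PanelConfig) -> float:
    """Unweighted mean of the reference genes' aggregated Cps; all
    references must be present."""
    missing = [g for g in panel.reference_genes if g not in ref_expressions]
    if missing:
        raise SampleFailure(f"missing reference gene(s) {missing}")
    vals = [float(ref_expressions[g]) for g in panel.reference_genes]
    return float(np.mean(vals))


def normalize_expression(gene_cp: float, ref_agg: float, centering_constant: float = 10.0) -> float:
    """``(gene_cp - ref_agg) + centering_constant``; shift-invariant in the
    pair (gene_cp, ref_agg)."""
    if not (np.isfinite(gene_cp) and np.isfinite(ref_agg)):
        raise ValueError("inputs must be finite")
    return (float(gene_cp) - float(ref_agg)) + float(centering_constant)


def gdna_qc(gdna_cp, threshold: float) -> bool:
    """Genomic-DNA contamination check on a patient sample: a gDNA-assay
    signal crossing strictly earlier than the threshold fails; NON_DETECT
    (and a crossing at or after the threshold) passes."""
    if gdna_cp is NON_DETECT or gdna_cp is None:
        return True
    return not float(gdna_cp) < threshold


def plate_qc(plate: PlateData, panel: PanelConfig) -> QCStatus:
    """Evaluate the plate's processing controls.

    Negative (no-template) wells must all be NON_DETECT; gDNA-positive wells
    must all detect; the RT-PCR positive pool must yield a valid triplicate
    (>= 2 valid wells) for every gene measured on it.  A missing control role
    raises :class:`MissingControlsError`.
    """
    status = QCStatus()
    thresholds = panel.qc_thresholds

    negatives = plate.select(role="negative")
    if not negatives:
        raise MissingControlsError("no negative-control wells on plate")
    bad = [w for w in negatives if w.detected]
    if bad:
        status.negative_controls_pass = False
        for w in bad:
            status.messages.append(
                f"negative well {w.well_id} detected at Cp {float(w.cp):.2f}"
            )

    gdna_pos = plate.select(role="gdna_positive")
    if not gdna_pos:
        raise MissingControlsError("no gDNA positive-control wells on plate")
    nd = [w for w in gdna_pos if not w.detected]
    if nd:
        status.gdna_pass = False
        status.messages.append(
            f"{len(nd)} gDNA positive-control well(s) failed to detect"
        )

    positives = plate.select(role="rtpcr_positive")
    if not positives:
        raise MissingControlsError("no RT-PCR positive-control wells on plate")
    for gene in sorted({w.gene for w in positives}):
        gene_wells = [w for w in positives if w.gene == gene]
        n_valid = sum(w.detected for w in gene_wells)
        if n_valid < thresholds.min_valid_wells:
            status.positive_control_pass = False
            status.messages.append(
                f"positive control gene {gene}: only {n_valid} valid well(s)"
            )
    return status


def quantify_sample(
    plate: PlateData,
    panel: PanelConfig,
    sample_id: str | None = None,
    roles: tuple[str, ...] = ("patient", "dilution"),
) -> SampleQuantification:
    """Quantify one sample: per-gene aggregated Cp, the reference average,
    normalized expression for the cancer genes, and the sample's gDNA check.

    A failed gene (fewer than 2 valid wells) fails the sample — reference
    genes always, cancer genes unless ``panel.allow_partial``.
    """
    if sample_id is None:
        candidates = sorted(
            {w.sample_id for w in plate.wells if w.role in roles}
        )
        if len(candidates) != 1:
            raise ValueError(f"plate holds samples {candidates}; pass sample_id=")
        sample_id = candidates[0]

    thresholds = panel.qc_thresholds
    aggregated: dict[str, GeneExpression] = {}
    failed: list[str] = []
    for gene in panel.all_genes:
        wells = [
            w for w in plate.select(gene=gene, sample_id=sample_id)
            if w.role in roles
        ]
        if not wells:
            failed.append(gene)
            continue
        try:
            valid = validate_wells(wells, min_valid=thresholds.min_valid_wells)
        except GeneFailure:
            failed.append(gene)
            continue
        aggregated[gene] = GeneExpression(
            gene=gene,
            aggregated_cp=aggregate_gene_cp(valid, panel.well_weights),
            n_valid_wells=len(valid),
        )

    failed_refs = [g for g in failed if g in panel.reference_genes]
    if failed_refs:
        raise SampleFailure(
            f"sample {sample_id!r}: failed reference gene(s) {failed_refs}"
        )
    failed_cancer = [g for g in failed if g in panel.cancer_genes]
    if failed_cancer and not panel.allow_partial:
        raise SampleFailure(
            f"sample {sample_id!r}: failed cancer gene(s) {failed_cancer} "
            "(score requires all 12; set allow_partial for per-gene reporting)"
        )

    ref_agg = reference_aggregate(
        {g: aggregated[g].aggregated_cp for g in panel.reference_genes}, panel
    )
    window = thresholds.reference_mean_window
    if window is not None and not window[0] <= ref_agg <= window[1]:
        raise SampleFailure(
            f"sample {sample_id!r}: reference-gene average {ref_agg:.2f} Cp "
            f"outside acceptance window {window}"
        )

    for gene in panel.cancer_genes:
        if gene in aggregated:
            e = aggregated[gene]
            aggregated[gene] = GeneExpression(
                gene=gene,
                aggregated_cp=e.aggregated_cp,
                n_valid_wells=e.n_valid_wells,
                normalized=normalize_expression(
                    e.aggregated_cp, ref_agg, panel.centering_constant
                ),
            )

    gdna_wells = [
        w for w in plate.select(gene=panel.gdna_assay, sample_id=sample_id)
        if w.role in roles
    ]
    gdna_pass = all(
        gdna_qc(w.cp if w.detected else NON_DETECT, thresholds.gdna_cp)
        for w in gdna_wells
    )

    return SampleQuantification(
        sample_id=sample_id,
        expressions=aggregated,
        reference_aggregate=ref_agg,
        gdna_pass=gdna_pass,
        failed_genes=failed_cancer,
    )
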