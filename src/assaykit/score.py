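"""The multianalyte score: group scores, the unscaled score, and the
clamped 100-unit scale.

Each pathway group score is a linear combination of its genes'
reference-normalized expressions; an optional config-declared piecewise
pre-transform (identity by default) is applied to each group score before
they are combined with the group coefficients and intercept into the
unscaled score, which an affine map then places on the reported [0, 100]
scale with clamping at the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .panel import PanelConfig, PlateData, ScaleParams
from .quantify import plate_qc, quantify_sample

__all__ = [
    "GPSResult",
    "ScoringError",
    "compute_group_scores",
    "compute_gps_unscaled",
    "scale_gps",
    "score_sample",
]


class ScoringError(RuntimeError):
    """A gene or group required by the score is missing."""


@dataclass
class GPSResult:
    sample_id: str
    normalized: dict[str, float]
    group_scores: dict[str, float]
    gps_unscaled: float
    gps: float
    clamped: bool
    qc_pass: bool = True
    qc_messages: list[str] = field(default_factory=list)


def compute_group_scores(
    normalized: Mapping[str, float], panel: PanelConfig
) -> dict[str, float]:
    """Per-group weighted sums of normalized expression (raw, before any
    group pre-transform)."""
    scores: dict[str, float] = {}
    for group, genes in panel.groups.items():
        total = 0.0
        for gene in genes:
            if gene not in normalized:
                raise ScoringError(f"missing normalized expression for gene {gene!r}")
            total += panel.group_coefficients[gene] * float(normalized[gene])
        scores[group] = total
    return scores


def compute_gps_unscaled(
    group_scores: Mapping[str, float], panel: PanelConfig
) -> float:
    """``intercept + sum(coef_g * transform_g(score_g))`` over the groups."""
    total = panel.gps_intercept
    for group in panel.groups:
        if group not in group_scores:
            raise ScoringError(f"missing group score {group!r}")
        total += panel.gps_coefficients[group] * panel.transform(group)(
            float(group_scores[group])
        )
    return float(total)


def scale_gps(gps_unscaled: float, scale_params: ScaleParams) -> tuple[float, bool]:
    """Affine map then clamp to [lower, upper]; returns (score, clamped)."""
    raw = scale_params.offset + scale_params.slope * float(gps_unscaled)
    if raw < scale_params.lower:
        return scale_params.lower, True
    if raw > scale_params.upper:
        return scale_params.upper, True
    return raw, False


def score_sample(
    plate: PlateData,
    panel: PanelConfig,
    sample_id: str | None = None,
    require_controls: bool = False,
) -> GPSResult:
    """Quantify, normalize and score one sample end-to-end.

    Plate controls are evaluated when present (or required); a failing plate
    QC or a sample gDNA-contamination failure raises rather than emitting a
    score.  The result is invariant to a constant Cp shift of every well.
    """
    qc_pass, qc_messages = True, []
    has_controls = any(
        w.role in ("negative", "gdna_positive", "rtpcr_positive") for w in plate.wells
    )
    if require_controls or has_controls:
        status = plate_qc(plate, panel)
        qc_pass, qc_messages = status.overall_pass, status.messages
        if not qc_pass:
            raise ScoringError(f"plate QC failed: {qc_messages}")

    quant = quantify_sample(plate, panel, sample_id=sample_id)
    if not quant.gdna_pass:
        raise ScoringError(
            f"sample {quant.sample_id!r}: genomic-DNA contamination detected"
        )
    normalized = quant.normalized
    group_scores = compute_group_scores(normalized, panel)
    gpsu = compute_gps_unscaled(group_scores, panel)
    gps, clamped = scale_gps(gpsu, panel.scale_params)
    return GPSResult(
        sample_id=quant.sample_id,
        normalized=normalized,
        group_scores=group_scores,
        gps_unscaled=gpsu,
        gps=gps,
        clamped=clamped,
        qc_pass=qc_pass,
        qc_messages=qc_messages,
    )
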