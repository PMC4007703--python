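"""Control-plate summaries and the end-to-end validation report.

``run_full_validation`` executes every validation stage — linearity,
amplification efficiency, inverse-prediction accuracy, LOD/LOQ, precision
and reproducibility, and control-plate monitoring — on simulated study data,
evaluates each pre-specified criterion, and assembles a single report whose
every verdict row carries its threshold, observed value, and outcome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .dilution import DilutionDesign
from .linearity import (
    assess_linearity,
    check_validation_criteria,
    compute_bias,
    compute_efficiency,
    efficiency_confint,
)
from .panel import PanelConfig, PlateData, default_panel, write_report
from .precision import (
    PrecisionStudy,
    check_precision_criteria,
    fit_precision_model,
    fit_reproducibility_model,
)
from .sensitivity import SensitivityResult, check_sensitivity_criteria, estimate_lod, estimate_loq
from .simulate import (
    GeneSimParams,
    PrecisionSimParams,
    default_control_levels,
    default_gene_sim_params,
    simulate_control_plates,
    simulate_dilution_series,
    simulate_precision_study,
)

__all__ = [
    "ControlSummary",
    "ValidationReport",
    "ValidationThresholds",
    "summarize_controls",
    "target_tumor_volume",
    "run_full_validation",
]


@dataclass(frozen=True)
class ControlSummary:
    gene: str
    n: int
    mean: float
    median: float
    sd: float


def summarize_controls(plates: Iterable[PlateData]) -> list[ControlSummary]:
    """Per-gene n/mean/median/SD of the RT-PCR positive-control wells on the
    raw (non-normalized) Cp scale.  Genes with no control wells are omitted
    with a warning."""
    values: dict[str, list[float]] = {}
    genes_seen: set[str] = set()
    for plate in plates:
        for w in plate.select(role="rtpcr_positive"):
            genes_seen.add(w.gene)
            if w.detected:
                values.setdefault(w.gene, []).append(float(w.cp))
    out = []
    for gene in sorted(genes_seen):
        vals = values.get(gene, [])
        if not vals:
            warnings.warn(f"gene {gene}: no detected control wells; omitted")
            continue
        arr = np.asarray(vals)
        out.append(
            ControlSummary(
                gene=gene,
                n=len(arr),
                mean=float(arr.mean()),
                median=float(np.median(arr)),
                sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            )
        )
    return out


def target_tumor_volume(length_mm: float, width_mm: float, depth_mm: float) -> float:
    """Tumor volume of the smallest evaluable biopsy (mm^3): tumor length x
    biopsy core width x sectioned tumor depth."""
    if length_mm <= 0 or width_mm <= 0 or depth_mm <= 0:
        raise ValueError("all dimensions must be positive")
    return length_mm * width_mm * depth_mm


@dataclass
class ValidationThresholds:
    """Pre-specified acceptance criteria (all configurable)."""

    alpha: float = 0.05
    dl_max_cp: float = 1.0
    resid_sd_max_cp: float = 1.5
    efficiency_tolerance_pct: float = 20.0
    bias_max_pct: float = 25.0
    lod_min_cp: float = 35.0
    lod_cap_cp: float = 40.0
    gene_precision_max_cp: float = 0.30
    gps_precision_max: float = 3.0
    control_sd_max_cp: float = 0.5
    nominal_input_ng: float = 20.0


@dataclass
class ValidationReport:
    efficiency: pd.DataFrame
    linearity: pd.DataFrame
    accuracy: pd.DataFrame
    sensitivity: pd.DataFrame
    precision: pd.DataFrame
    reproducibility: pd.DataFrame
    controls: pd.DataFrame
    criteria: pd.DataFrame
    overall_pass: bool
    seed: int
    stage_errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        def recs(df: pd.DataFrame):
            return json.loads(df.to_json(orient="records", double_precision=12))

        return {
            "overall_pass": self.overall_pass,
            "seed": self.seed,
            "efficiency": recs(self.efficiency),
            "linearity": recs(self.linearity),
            "accuracy": recs(self.accuracy),
            "sensitivity": recs(self.sensitivity),
            "precision": recs(self.precision),
            "reproducibility": recs(self.reproducibility),
            "controls": recs(self.controls),
            "criteria": recs(self.criteria),
            "stage_errors": self.stage_errors,
        }

    def write(self, out_dir: str | Path) -> Path:
        """Emit per-table CSVs plus one JSON report; returns the JSON path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in (
            "efficiency", "linearity", "accuracy", "sensitivity",
            "precision", "reproducibility", "controls", "criteria",
        ):
            getattr(self, name).to_csv(out_dir / f"{name}.csv", index=False)
        path = out_dir / "validation_report.json"
        write_report(self.to_dict(), path)
        return path


def run_full_validation(
    panel: PanelConfig | None = None,
    seed: int = 0,
    thresholds: ValidationThresholds | None = None,
    gene_sim_params: Mapping[str, GeneSimParams] | None = None,
    n_control_plates: int = 18,
) -> ValidationReport:
    """Run every analytical-validation stage on simulated study data.

    Deterministic given ``seed`` and inputs.  Per-stage failures are
    recorded in ``stage_errors`` and the report is still emitted.
    """
    panel = panel or default_panel()
    thr = thresholds or ValidationThresholds()
    sim_params = dict(gene_sim_params or default_gene_sim_params(panel))
    stage_errors: dict[str, str] = {}
    criteria_rows: list[dict[str, Any]] = []

    # ---- dilution-series stages: linearity / efficiency / accuracy / LOD-LOQ
    eff_rows, lin_rows, acc_rows = [], [], []
    sens_results: dict[str, SensitivityResult] = {}
    efficiencies: dict[str, float] = {}
    biases: dict[str, pd.DataFrame] = {}
    nominal: dict[str, float] = {}
    for i, gene in enumerate(sorted(sim_params)):
        params = sim_params[gene]
        design = DilutionDesign(start_conc=panel.dilution_start(gene))
        series = simulate_dilution_series(params, design, seed=seed * 1009 + i)
        try:
            lin = assess_linearity(
                series,
                alpha=thr.alpha,
                dl_max=thr.dl_max_cp,
                resid_sd_max=thr.resid_sd_max_cp,
            )
            lin_rows.append(lin.to_row())
            if not lin.valid:
                stage_errors[f"linearity:{gene}"] = "no valid linear range"
                continue
            fit = lin.final_fit
            slope, slope_se = fit.params[1], fit.bse[1]
            eff = compute_efficiency(slope)
            lo, hi = efficiency_confint(slope, slope_se)
            efficiencies[gene] = eff
            eff_rows.append(
                {"gene": gene, "efficiency_pct": eff, "lower_95ci": lo, "upper_95ci": hi}
            )
            retained = series.subset(
                [k for k, lv in enumerate(series.levels) if lv.x in set(lin.retained_levels)]
            )
            bias_tab = compute_bias(retained, fit)
            biases[gene] = bias_tab
            nominal[gene] = thr.nominal_input_ng
            for _, row in bias_tab.iterrows():
                acc_rows.append({"gene": gene, **row.to_dict()})
            lod = estimate_lod(series, cap=thr.lod_cap_cp)
            loq = estimate_loq(
                series, fit, lin.linear_range, y_min=lod.lod_cp
            )
            sens_results[gene] = SensitivityResult(
                gene=gene, lod_cp=lod.lod_cp, loq_cp=loq.loq_cp,
                y_min=lod.lod_cp, capped=lod.capped,
            )
        except Exception as exc:  # stage failure is recorded, not fatal
            stage_errors[f"dilution:{gene}"] = str(exc)

    eff_df = pd.DataFrame(eff_rows)
    lin_df = pd.DataFrame(lin_rows)
    acc_df = pd.DataFrame(acc_rows)
    if efficiencies:
        acc_eff = check_validation_criteria(
            efficiencies, biases, nominal,
            efficiency_tolerance=thr.efficiency_tolerance_pct,
            bias_max_pct=thr.bias_max_pct,
        )
        criteria_rows.append(
            {
                "criterion": "amplification efficiency within median +/- "
                f"{thr.efficiency_tolerance_pct:g} points",
                "threshold": thr.efficiency_tolerance_pct,
                "observed": float(
                    (acc_eff["efficiency_pct"] - acc_eff["efficiency_median_pct"])
                    .abs()
                    .max()
                ),
                "pass": bool(acc_eff["efficiency_pass"].all()),
            }
        )
        bias_cols = ["bias_nominal_pct", "bias_half_pct", "bias_quarter_pct"]
        criteria_rows.append(
            {
                "criterion": "absolute mean percent bias at nominal/half/quarter "
                f"inputs < {thr.bias_max_pct:g}%",
                "threshold": thr.bias_max_pct,
                "observed": float(acc_eff[bias_cols].abs().to_numpy().max()),
                "pass": bool(acc_eff["bias_pass"].all()),
            }
        )
    sens_df = check_sensitivity_criteria(sens_results, lod_min_cp=thr.lod_min_cp)
    if len(sens_df):
        criteria_rows.append(
            {
                "criterion": f"LOD later than Cp {thr.lod_min_cp:g} for every gene",
                "threshold": thr.lod_min_cp,
                "observed": float(sens_df["lod_cp"].min()),
                "pass": bool(sens_df["lod_pass"].all()),
            }
        )
    if len(lin_df):
        criteria_rows.append(
            {
                "criterion": "valid linear range (max |DL| < "
                f"{thr.dl_max_cp:g} Cp) for every gene",
                "threshold": thr.dl_max_cp,
                "observed": float(lin_df["max_abs_dl"].max(skipna=True))
                if lin_df["max_abs_dl"].notna().any()
                else 0.0,
                "pass": bool(lin_df["valid"].all()),
            }
        )

    # ---- precision / reproducibility ---------------------------------
    prec_rows, repro_rows = [], []
    gene_prec_sds: list[float] = []
    gps_prec_sd = gps_repro_sd = np.nan
    rng = np.random.default_rng(seed + 77_001)
    targets = sorted(panel.cancer_genes) + ["GPS"]
    for t_idx, target in enumerate(targets):
        if target == "GPS":
            p = PrecisionSimParams()
        else:
            p = PrecisionSimParams(
                mu=7.0 + 4.0 * (t_idx / max(len(targets) - 1, 1)),
                sigma_alpha=1.0,
                sigma_eps=0.08 + 0.10 * (t_idx % 5) / 4.0,
                lambda_effects=(0.0, 0.05, -0.05),
            )
        study_df = simulate_precision_study(
            p, seed=int(rng.integers(0, 2**31 - 1)), target=target
        )
        study = PrecisionStudy(study_df)
        try:
            prec = fit_precision_model(study)
            repro = fit_reproducibility_model(study)
        except Exception as exc:
            stage_errors[f"precision:{target}"] = str(exc)
            continue
        for res, rows in ((prec, prec_rows), (repro, repro_rows)):
            lo, hi = res.ci_sigma_eps()
            rows.append(
                {
                    "target": target,
                    "sd": res.sigma_eps,
                    "lower_95cl": lo,
                    "upper_95cl": hi,
                    "sigma_alpha": res.sigma_alpha,
                }
            )
        if target == "GPS":
            gps_prec_sd, gps_repro_sd = prec.sigma_eps, repro.sigma_eps
        else:
            gene_prec_sds.append(prec.sigma_eps)
    prec_df = pd.DataFrame(prec_rows)
    repro_df = pd.DataFrame(repro_rows)
    if gene_prec_sds:
        criteria_rows.append(
            {
                "criterion": "per-gene precision SD <= "
                f"{thr.gene_precision_max_cp:g} Cp",
                "threshold": thr.gene_precision_max_cp,
                "observed": float(max(gene_prec_sds)),
                "pass": bool(max(gene_prec_sds) <= thr.gene_precision_max_cp),
            }
        )
    if np.isfinite(gps_prec_sd):
        criteria_rows.append(
            {
                "criterion": f"score precision SD <= {thr.gps_precision_max:g} units",
                "threshold": thr.gps_precision_max,
                "observed": float(gps_prec_sd),
                "pass": bool(gps_prec_sd <= thr.gps_precision_max),
            }
        )

    # ---- control plates ----------------------------------------------
    levels = default_control_levels(panel)
    plates = simulate_control_plates(
        n_control_plates,
        {g: m for g, (m, s) in levels.items()},
        {g: s for g, (m, s) in levels.items()},
        panel,
        seed=seed + 13,
    )
    ctrl = summarize_controls(plates)
    ctrl_df = pd.DataFrame([c.__dict__ for c in ctrl])
    if len(ctrl_df):
        criteria_rows.append(
            {
                "criterion": "positive-control SD <= "
                f"{thr.control_sd_max_cp:g} Cp for every gene",
                "threshold": thr.control_sd_max_cp,
                "observed": float(ctrl_df["sd"].max()),
                "pass": bool((ctrl_df["sd"] <= thr.control_sd_max_cp).all()),
            }
        )

    criteria_df = pd.DataFrame(criteria_rows)
    overall = bool(criteria_df["pass"].all()) and not stage_errors
    return ValidationReport(
        efficiency=eff_df,
        linearity=lin_df,
        accuracy=acc_df,
        sensitivity=sens_df,
        precision=prec_df,
        reproducibility=repro_df,
        controls=ctrl_df,
        criteria=criteria_df,
        overall_pass=overall,
        seed=seed,
        stage_errors=stage_errors,
    )
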