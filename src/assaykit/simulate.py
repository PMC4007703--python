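"""Synthetic qPCR data generators.

Every generator is a pure function of its parameters and a seed, and emits
the same containers the analysis modules consume.  The statistical structure
mirrors the assay-validation study designs:

* dilution series: 14 two-fold levels, 3 independent series x 3 wells per
  level, Gaussian Cp noise with a log-linear variance model
  ``Var(eps) = exp(gamma0 + gamma1 * log2 x)`` (variance grows as the input
  shrinks when ``gamma1 < 0``);
* precision/reproducibility studies: 10 samples x 3 RNA inputs
  (5/10/20 ng) x 3 replicates from the two-level mixed model
  ``Y_ijk = mu + alpha_i + lambda_j + eps_ijk``;
* control plates: one positive-control pool measured in triplicate per gene,
  gDNA-positive wells, and no-template negative wells (always non-detect);
* per-biopsy RNA yields: lognormal, parameterized so the lowest quartile of
  yields in the 0.0225 mm^3 target tumor volume falls in the 19-34 ng band.

Cp values are censored at the 45-cycle run length: a draw beyond the run is
emitted as NON_DETECT, never truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dilution import DilutionDesign, DilutionLevel, DilutionSeries
from .panel import CP_CEILING, NON_DETECT, PanelConfig, PlateData, WellMeasurement

__all__ = [
    "GeneSimParams",
    "DilutionDesign",
    "PrecisionSimParams",
    "DEFAULT_RNA_YIELD_MEANLOG",
    "DEFAULT_RNA_YIELD_SDLOG",
    "simulate_dilution_series",
    "simulate_precision_study",
    "simulate_control_plates",
    "simulate_patient_plate",
    "simulate_rna_yields",
    "default_gene_sim_params",
    "default_control_levels",
]


@dataclass(frozen=True)
class GeneSimParams:
    """True response-curve parameters for one gene assay.

    Mean Cp at concentration x is the polynomial
    ``b0 + b1*L + c2*L^2 + c3*L^3`` in ``L = log2 x``; when ``plateau_cp`` is
    set the signal saturates into background,
    ``Cp(x) = -log2(2^-poly(x) + 2^-plateau_cp)``, so the mean tends to the
    plateau as the concentration vanishes.  ``conc_bias`` multiplies the true
    concentration actually dispensed at every level (1.0 = unbiased);
    ``fault_bias`` applies only at the levels listed in ``fault_levels_ng``
    (matched within 1%), a fault-injection hook for exercising the accuracy
    criteria.
    """

    gene: str = "GENE"
    b0: float = 27.0          # Cp at 1 ng/well
    b1: float = -1.0468       # Cp per log2 ng; ~93.9% amplification efficiency
    c2: float = 0.0
    c3: float = 0.0
    gamma0: float = 2.0 * math.log(0.15)   # noise SD 0.15 Cp at 1 ng
    gamma1: float = -0.15
    plateau_cp: float | None = None
    conc_bias: float = 1.0
    fault_bias: float = 1.0
    fault_levels_ng: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.b1 >= 0:
            raise ValueError("slope b1 must be negative (later Cp at lower input)")
        if self.conc_bias <= 0 or self.fault_bias <= 0:
            raise ValueError("concentration bias factors must be positive")

    def dispensed(self, x: float) -> float:
        """Concentration actually dispensed at nominal level x."""
        out = x * self.conc_bias
        if any(abs(x - f) <= 0.01 * f for f in self.fault_levels_ng):
            out *= self.fault_bias
        return out

    def mean_cp(self, x: np.ndarray | float) -> np.ndarray:
        L = np.log2(np.asarray(x, float))
        poly = self.b0 + self.b1 * L + self.c2 * L**2 + self.c3 * L**3
        if self.plateau_cp is None:
            return poly
        return -np.log2(np.exp2(-poly) + np.exp2(-self.plateau_cp))

    def noise_sd(self, x: np.ndarray | float) -> np.ndarray:
        L = np.log2(np.asarray(x, float))
        return np.sqrt(np.exp(self.gamma0 + self.gamma1 * L))


@dataclass(frozen=True)
class PrecisionSimParams:
    """Truth for a precision/reproducibility study on one target.

    Defaults emulate the reported 100-unit-score regime: between-sample SD
    11.4, residual (precision) SD 1.86, and RNA-input offsets whose pooled
    contribution raises the reproducibility SD to ~2.11.
    """

    mu: float = 35.0
    sigma_alpha: float = 11.4
    sigma_eps: float = 1.86
    lambda_effects: tuple[float, ...] = (0.0, 1.22, -1.22)
    n_samples: int = 10
    inputs: tuple[float, ...] = (5.0, 10.0, 20.0)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.sigma_alpha < 0 or self.sigma_eps < 0:
            raise ValueError("SDs must be nonnegative")
        if len(self.lambda_effects) != len(self.inputs):
            raise ValueError("one lambda per RNA input required")
        if self.n_samples < 1 or self.n_replicates < 1:
            raise ValueError("design sizes must be >= 1")


#: RNA-yield lognormal defaults: median 40 ng per 0.0225 mm^3 of tumor,
#: giving Q1 ~ 26.7 ng (within the observed 19-34 ng lowest quartile) and a
#: mean below 50 ng.
DEFAULT_RNA_YIELD_MEANLOG = math.log(40.0)
DEFAULT_RNA_YIELD_SDLOG = 0.6


def simulate_dilution_series(
    params: GeneSimParams,
    design: DilutionDesign | None = None,
    seed: int = 0,
) -> DilutionSeries:
    """Draw one gene's dilution series under the heteroscedastic model.

    Each of ``design.n_series`` plates contributes ``design.n_wells`` wells
    per level; draws past the 45-cycle run are censored to NON_DETECT and
    counted in ``DilutionLevel.n_nondetect``.
    """
    design = design or DilutionDesign()
    rng = np.random.default_rng(seed)
    levels: list[DilutionLevel] = []
    for x in design.concentrations:
        x_true = params.dispensed(float(x))
        mu = float(params.mean_cp(x_true))
        sd = float(params.noise_sd(x_true))
        cps, plates, nd = [], [], 0
        for s in range(design.n_series):
            draws = mu + sd * rng.standard_normal(design.n_wells)
            for d in draws:
                if d > CP_CEILING:
                    nd += 1
                else:
                    cps.append(float(d))
                    plates.append(f"plate{s + 1}")
        levels.append(DilutionLevel(x=float(x), cps=cps, plate_ids=plates, n_nondetect=nd))
    return DilutionSeries(gene=params.gene, levels=levels)


def simulate_precision_study(
    params: PrecisionSimParams | None = None,
    seed: int = 0,
    target: str = "GPS",
) -> pd.DataFrame:
    """Draw a balanced precision/reproducibility table.

    Returns a tidy frame with columns ``sample_id, rna_input_ng, replicate,
    target, value`` where ``value ~ mu + alpha_i + lambda_j + eps_ijk``.
    """
    params = params or PrecisionSimParams()
    rng = np.random.default_rng(seed)
    alpha = params.sigma_alpha * rng.standard_normal(params.n_samples)
    rows = []
    for i in range(params.n_samples):
        for j, inp in enumerate(params.inputs):
            eps = params.sigma_eps * rng.standard_normal(params.n_replicates)
            for k in range(params.n_replicates):
                rows.append(
                    {
                        "sample_id": f"S{i + 1:02d}",
                        "rna_input_ng": float(inp),
                        "replicate": k + 1,
                        "target": target,
                        "value": float(
                            params.mu + alpha[i] + params.lambda_effects[j] + eps[k]
                        ),
                    }
                )
    return pd.DataFrame(rows)


def default_control_levels(panel: PanelConfig) -> dict[str, tuple[float, float]]:
    """Synthetic positive-control (mean Cp, SD) per gene, spanning the
    19-30 Cp range typical of a pooled tumor control, plus the gDNA assay."""
    out: dict[str, tuple[float, float]] = {}
    genes = panel.all_genes
    for i, gene in enumerate(sorted(genes)):
        mean = 19.5 + 10.0 * i / max(len(genes) - 1, 1)
        sd = 0.18 + 0.02 * (i % 5)
        out[gene] = (round(mean, 2), round(sd, 3))
    out[panel.gdna_assay] = (30.0, 0.25)
    return out


def simulate_control_plates(
    n_plates: int,
    gene_means: Mapping[str, float],
    gene_sds: Mapping[str, float],
    panel: PanelConfig,
    seed: int = 0,
) -> list[PlateData]:
    """Simulate control plates: per plate one positive-control pool measured
    in triplicate for every gene, triplicate gDNA-positive wells, and three
    no-template negative wells (always NON_DETECT)."""
    genes = panel.all_genes
    missing = [g for g in genes + [panel.gdna_assay] if g not in gene_means or g not in gene_sds]
    if missing:
        raise KeyError(f"missing control parameters for gene(s) {missing}")
    rng = np.random.default_rng(seed)
    plates: list[PlateData] = []
    for p in range(n_plates):
        pid = f"ctrl{p + 1:02d}"
        wells: list[WellMeasurement] = []
        for gene in genes:
            draws = gene_means[gene] + gene_sds[gene] * rng.standard_normal(3)
            for r, d in enumerate(draws, start=1):
                wells.append(
                    WellMeasurement(
                        plate_id=pid,
                        well_id=f"P_{gene}_{r}",
                        sample_id="pos_pool",
                        gene=gene,
                        replicate_index=r,
                        cp=float(np.clip(d, 1e-6, CP_CEILING)),
                        role="rtpcr_positive",
                    )
                )
        gdna = panel.gdna_assay
        draws = gene_means[gdna] + gene_sds[gdna] * rng.standard_normal(3)
        for r, d in enumerate(draws, start=1):
            wells.append(
                WellMeasurement(
                    plate_id=pid,
                    well_id=f"G_{r}",
                    sample_id="gdna_pos",
                    gene=gdna,
                    replicate_index=r,
                    cp=float(np.clip(d, 1e-6, CP_CEILING)),
                    role="gdna_positive",
                )
            )
        for r in range(1, 4):
            wells.append(
                WellMeasurement(
                    plate_id=pid,
                    well_id=f"N_{r}",
                    sample_id="ntc",
                    gene=panel.reference_genes[(r - 1) % len(panel.reference_genes)],
                    replicate_index=r,
                    cp=NON_DETECT,
                    role="negative",
                )
            )
        plates.append(PlateData(wells=wells, metadata={"plate_id": pid}))
    return plates


def simulate_patient_plate(
    true_normalized: Mapping[str, float],
    panel: PanelConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "patient1",
    reference_cp: float | Mapping[str, float] = 24.0,
) -> PlateData:
    """Simulate a patient plate whose zero-noise normalized expressions are
    exactly ``true_normalized``.

    ``true_normalized`` maps each of the 12 cancer genes to its target
    reference-normalized expression; reference genes are placed at
    ``reference_cp`` (scalar or per-gene).  Each gene gets triplicate wells
    with iid Gaussian Cp noise, plus gDNA wells that never detect.
    """
    missing = [g for g in panel.cancer_genes if g not in true_normalized]
    if missing:
        raise KeyError(f"true_normalized missing gene(s) {missing}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if isinstance(reference_cp, Mapping):
        ref_cp = {g: float(reference_cp[g]) for g in panel.reference_genes}
    else:
        ref_cp = {g: float(reference_cp) for g in panel.reference_genes}
    ref_mean = float(np.mean(list(ref_cp.values())))
    wells: list[WellMeasurement] = []

    def add(gene: str, true_cp: float) -> None:
        draws = true_cp + noise_sd * rng.standard_normal(3)
        for r, d in enumerate(draws, start=1):
            cp = NON_DETECT if d > CP_CEILING else float(max(d, 1e-6))
            wells.append(
                WellMeasurement(
                    plate_id="sim", well_id=f"{gene}_{r}", sample_id=sample_id,
                    gene=gene, replicate_index=r, cp=cp, role="patient",
                )
            )

    for gene in panel.reference_genes:
        add(gene, ref_cp[gene])
    for gene in panel.cancer_genes:
        add(gene, ref_mean + float(true_normalized[gene]) - panel.centering_constant)
    for r in range(1, 4):
        wells.append(
            WellMeasurement(
                plate_id="sim", well_id=f"gdna_{r}", sample_id=sample_id,
                gene=panel.gdna_assay, replicate_index=r, cp=NON_DETECT,
                role="patient",
            )
        )
    return PlateData(wells=wells, metadata={"plate_id": "sim"})


def simulate_rna_yields(
    n: int,
    meanlog: float = DEFAULT_RNA_YIELD_MEANLOG,
    sdlog: float = DEFAULT_RNA_YIELD_SDLOG,
    seed: int = 0,
) -> np.ndarray:
    """Lognormal RNA yields (ng per 0.0225 mm^3 target tumor volume)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if sdlog < 0:
        raise ValueError("sdlog must be nonnegative")
    rng = np.random.default_rng(seed)
    return np.exp(meanlog + sdlog * rng.standard_normal(n))


def default_gene_sim_params(panel: PanelConfig) -> dict[str, GeneSimParams]:
    """A plausible truth set for all 17 gene assays (synthetic; per-gene
    intercepts spread over 21-30 Cp, efficiencies ~88-100%, a late background
    plateau, and the study's heteroscedastic noise model)."""
    effs = [88.0, 90.0, 92.0, 94.0, 96.0, 98.0, 100.0]
    params: dict[str, GeneSimParams] = {}
    for i, gene in enumerate(sorted(panel.all_genes)):
        eff = effs[i % len(effs)]
        slope = -1.0 / math.log2(1.0 + eff / 100.0)
        params[gene] = GeneSimParams(
            gene=gene,
            b0=21.0 + 9.0 * i / 16.0,
            b1=slope,
            gamma0=2.0 * math.log(0.15),
            gamma1=-0.15,
            plateau_cp=38.0,
        )
    return params
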