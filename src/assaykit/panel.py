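"""Assay panel definition and plate-level Cp measurements.

The panel configuration is the single source of truth for the assay: which
genes are measured, how they are grouped, which genes are references, the
scoring coefficients, and the QC thresholds.  Nothing outside the shipped
default YAML hard-codes gene names.

Cp ("crossing point") values are qPCR cycle numbers; the instrument runs 45
cycles, so a measured Cp lies in (0, 45] and a reaction that never crosses
threshold within the run is recorded as the ``NON_DETECT`` sentinel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "NON_DETECT",
    "CP_CEILING",
    "GROUPS",
    "WELL_ROLES",
    "ConfigurationError",
    "PlateParseError",
    "PanelConfig",
    "ScaleParams",
    "QCThresholds",
    "GroupTransform",
    "WellMeasurement",
    "PlateData",
    "load_panel_config",
    "default_panel",
    "read_plate_csv",
    "write_plate_csv",
    "write_report",
    "read_report",
]

#: qPCR run length in cycles; a Cp cannot exceed this.
CP_CEILING = 45.0

#: The four biological pathway groups of the cancer genes.
GROUPS = ("androgen", "cellular_organization", "proliferation", "stromal")

WELL_ROLES = ("patient", "rtpcr_positive", "gdna_positive", "negative", "dilution")


class _NonDetect:
    """Singleton sentinel: no threshold crossing within the 45-cycle run."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NON_DETECT"

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


NON_DETECT = _NonDetect()


class ConfigurationError(ValueError):
    """Panel configuration is malformed or violates an invariant."""


class PlateParseError(ValueError):
    """A plate CSV row could not be interpreted."""


class ScaleParams(BaseModel):
    """Affine map from the unscaled score to the reported 100-unit scale."""

    model_config = ConfigDict(extra="forbid")

    slope: float = Field(gt=0)
    offset: float
    lower: float = 0.0
    upper: float = 100.0

    @model_validator(mode="after")
    def _ordered(self) -> "ScaleParams":
        if not self.lower < self.upper:
            raise ValueError("scale clamp bounds must satisfy lower < upper")
        return self


class QCThresholds(BaseModel):
    """Quality-control cutoffs, all in Cp units (cycles)."""

    model_config = ConfigDict(extra="forbid")

    gdna_cp: float = 35.0
    cp_ceiling: float = CP_CEILING
    min_valid_wells: int = 2
    # Optional window for the reference-gene average (sample validity);
    # no default bounds are shipped.
    reference_mean_window: tuple[float, float] | None = None

    @model_validator(mode="after")
    def _check(self) -> "QCThresholds":
        if self.min_valid_wells < 1:
            raise ValueError("min_valid_wells must be >= 1")
        w = self.reference_mean_window
        if w is not None and not w[0] < w[1]:
            raise ValueError("reference_mean_window must be ordered")
        return self


class GroupTransform(BaseModel):
    """Optional piecewise pre-transform applied to a group score before the
    unscaled-score combination (identity when absent)."""

    model_config = ConfigDict(extra="forbid")

    kind: str = Field(pattern="^(identity|clip_low|clip_high)$")
    value: float | None = None

    def __call__(self, score: float) -> float:
        if self.kind == "clip_low":
            return max(score, float(self.value))
        if self.kind == "clip_high":
            return min(score, float(self.value))
        return score

    @model_validator(mode="after")
    def _needs_value(self) -> "GroupTransform":
        if self.kind != "identity" and self.value is None:
            raise ValueError(f"transform {self.kind!r} requires a value")
        return self


class PanelConfig(BaseModel):
    """The complete assay definition.

    ``groups`` maps each pathway group to its cancer genes;
    ``group_coefficients`` weight each gene inside its group score;
    ``gps_coefficients`` (one per group) plus ``gps_intercept`` form the
    unscaled score, which ``scale_params`` maps onto [lower, upper].
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "panel"
    groups: dict[str, list[str]]
    reference_genes: list[str]
    gdna_assay: str
    well_weights: list[float] = Field(default_factory=lambda: [1.0, 1.0, 1.0])
    group_coefficients: dict[str, float]
    gps_coefficients: dict[str, float]
    gps_intercept: float = 0.0
    group_transforms: dict[str, GroupTransform] = Field(default_factory=dict)
    scale_params: ScaleParams
    qc_thresholds: QCThresholds = Field(default_factory=QCThresholds)
    centering_constant: float = 10.0
    dilution_start_ng: dict[str, float] = Field(
        default_factory=lambda: {"default": 204.0}
    )
    # When False (default) a failed cancer gene fails the whole sample; when
    # True partial per-gene reporting is allowed (no score).
    allow_partial: bool = False

    # ---- derived views -------------------------------------------------
    @property
    def cancer_genes(self) -> list[str]:
        return [g for genes in self.groups.values() for g in genes]

    @property
    def all_genes(self) -> list[str]:
        """Cancer genes + reference genes (the 17 expression assays)."""
        return self.cancer_genes + list(self.reference_genes)

    def group_of(self, gene: str) -> str:
        for grp, genes in self.groups.items():
            if gene in genes:
                return grp
        raise KeyError(gene)

    def transform(self, group: str) -> GroupTransform:
        return self.group_transforms.get(group, GroupTransform(kind="identity"))

    def dilution_start(self, gene: str) -> float:
        return self.dilution_start_ng.get(gene, self.dilution_start_ng["default"])

    # ---- invariants ----------------------------------------------------
    @model_validator(mode="after")
    def _invariants(self) -> "PanelConfig":
        for grp in self.groups:
            if grp not in GROUPS:
                raise ValueError(f"unknown group {grp!r}; expected one of {GROUPS}")
        seen: dict[str, str] = {}
        for grp, genes in self.groups.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} appears in both {seen[g]!r} and {grp!r}"
                    )
                seen[g] = grp
        dupes = set(seen) & set(self.reference_genes)
        if dupes:
            raise ValueError(f"gene(s) {sorted(dupes)} listed as both cancer and reference")
        if len(set(self.reference_genes)) != len(self.reference_genes):
            raise ValueError("duplicate reference gene")
        if self.gdna_assay in seen or self.gdna_assay in self.reference_genes:
            raise ValueError(f"gdna assay {self.gdna_assay!r} collides with a gene")
        missing = set(self.cancer_genes) - set(self.group_coefficients)
        if missing:
            raise ValueError(f"group_coefficients missing gene(s) {sorted(missing)}")
        if set(self.gps_coefficients) != set(self.groups):
            raise ValueError(
                "gps_coefficients keys must match the group names "
                f"{sorted(self.groups)}, got {sorted(self.gps_coefficients)}"
            )
        for grp in self.group_transforms:
            if grp not in self.groups:
                raise ValueError(f"group_transforms references unknown group {grp!r}")
        if not self.well_weights or any(w < 0 for w in self.well_weights):
            raise ValueError("well_weights must be nonnegative")
        if sum(self.well_weights) <= 0:
            raise ValueError("well_weights must not all be zero")
        if "default" not in self.dilution_start_ng:
            raise ValueError("dilution_start_ng requires a 'default' entry")
        return self


@dataclass(frozen=True, order=True)
class WellMeasurement:
    """One qPCR well: identity plus its Cp (or NON_DETECT)."""

    plate_id: str
    well_id: str
    sample_id: str
    gene: str
    replicate_index: int
    cp: float | _NonDetect
    role: str = "patient"

    def __post_init__(self) -> None:
        if self.role not in WELL_ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if not isinstance(self.cp, _NonDetect):
            cp = float(self.cp)
            if not 0.0 < cp <= CP_CEILING:
                raise ValueError(
                    f"Cp {cp} outside (0, {CP_CEILING}] for well "
                    f"{self.plate_id}/{self.well_id}"
                )

    @property
    def detected(self) -> bool:
        return not isinstance(self.cp, _NonDetect)

    def _sort_key(self):
        cp = float("inf") if not self.detected else float(self.cp)
        return (self.plate_id, self.well_id, self.sample_id, self.gene,
                self.replicate_index, self.role, cp)


@dataclass
class PlateData:
    """A collection of well measurements with plate-run metadata.

    Equality uses set semantics: two plates with the same wells in any order
    compare equal.
    """

    wells: list[WellMeasurement] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateData):
            return NotImplemented
        key = WellMeasurement._sort_key
        return (
            sorted(self.wells, key=key) == sorted(other.wells, key=key)
            and self.metadata == other.metadata
        )

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self) -> Iterator[WellMeasurement]:
        return iter(self.wells)

    def select(
        self,
        gene: str | None = None,
        sample_id: str | None = None,
        role: str | None = None,
    ) -> list[WellMeasurement]:
        out = self.wells
        if gene is not None:
            out = [w for w in out if w.gene == gene]
        if sample_id is not None:
            out = [w for w in out if w.sample_id == sample_id]
        if role is not None:
            out = [w for w in out if w.role == role]
        return out

    @property
    def sample_ids(self) -> list[str]:
        return sorted({w.sample_id for w in self.wells})

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": w.plate_id,
                "well_id": w.well_id,
                "sample_id": w.sample_id,
                "gene": w.gene,
                "replicate": w.replicate_index,
                "role": w.role,
                "cp": "" if not w.detected else w.cp,
            }
            for w in self.wells
        ]
        return pd.DataFrame(
            rows,
            columns=["plate_id", "well_id", "sample_id", "gene", "replicate", "role", "cp"],
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def load_panel_config(path: str | Path) -> PanelConfig:
    """Load and validate a panel configuration from YAML or JSON.

    Raises
    ------
    ConfigurationError
        On parse failure or any invariant violation; the message names the
        offending field or gene.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read panel config {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"panel config {path} is not a mapping")
    try:
        return PanelConfig(**raw)
    except Exception as exc:  # pydantic ValidationError or ValueError
        raise ConfigurationError(f"invalid panel config {path}: {exc}") from exc


def default_panel() -> PanelConfig:
    """The shipped 17-gene prostate panel (12 cancer genes in four pathway
    groups plus 5 reference genes and the gDNA-contamination assay)."""
    from importlib import resources

    with resources.as_file(
        resources.files("assaykit").joinpath("data/panel_gps.yaml")
    ) as p:
        return load_panel_config(p)


_ND_TOKENS = {"", "nd", "non_detect", "nondetect", "na"}


def read_plate_csv(path: str | Path, panel: PanelConfig) -> PlateData:
    """Read a plate CSV (columns ``plate_id,well_id,sample_id,gene,replicate,
    role,cp``) into :class:`PlateData`.

    An empty or ``"ND"`` cp field maps to NON_DETECT.  Genes not in the panel,
    Cp values outside (0, 45], and malformed rows raise
    :class:`PlateParseError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["plate_id", "well_id", "sample_id", "gene", "replicate", "role", "cp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateParseError(f"{path}: missing column(s) {missing}")
    known = set(panel.all_genes) | {panel.gdna_assay}
    wells: list[WellMeasurement] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        gene = row.gene.strip()
        if gene not in known:
            raise PlateParseError(f"{path}:{idx}: unknown gene {gene!r}")
        cp_text = row.cp.strip()
        cp: float | _NonDetect
        if cp_text.lower() in _ND_TOKENS:
            cp = NON_DETECT
        else:
            try:
                cp = float(cp_text)
            except ValueError as exc:
                raise PlateParseError(f"{path}:{idx}: bad cp {cp_text!r}") from exc
        try:
            wells.append(
                WellMeasurement(
                    plate_id=row.plate_id,
                    well_id=row.well_id,
                    sample_id=row.sample_id,
                    gene=gene,
                    replicate_index=int(row.replicate),
                    cp=cp,
                    role=row.role.strip(),
                )
            )
        except ValueError as exc:
            raise PlateParseError(f"{path}:{idx}: {exc}") from exc
    return PlateData(wells=wells)


def write_plate_csv(plate: PlateData, path: str | Path) -> None:
    df = plate.to_dataframe()
    df["cp"] = [
        "ND" if not w.detected else repr(float(w.cp)) for w in plate.wells
    ]
    df.to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, _NonDetect):
        return "ND"
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, BaseModel):
        return _jsonable(obj.model_dump())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(report: Any, path: str | Path) -> None:
    """Write a result record to JSON (``.json``) or a table to CSV (``.csv``).

    JSON output round-trips through :func:`read_report`; dataclasses,
    pydantic models, mappings and DataFrames are serialized to plain types.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if isinstance(report, pd.DataFrame):
            df = report
        else:
            records = _jsonable(report)
            if isinstance(records, Mapping):
                records = [records]
            df = pd.DataFrame(records)
        df.to_csv(path, index=False)
        return
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
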