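"""Dilution-series containers: the substrate for linearity, efficiency,
accuracy and sensitivity statistics.

A series is a ladder of known RNA concentrations (ng per PCR well) with
replicate Cp measurements at each level.  The log scale is base 2 throughout:
one "log unit" is one two-fold dilution step, and one Cp is nominally one
doubling of template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DilutionDesign", "DilutionLevel", "DilutionSeries"]


@dataclass(frozen=True)
class DilutionDesign:
    """A serial-dilution layout: ``n_levels`` concentrations descending from
    ``start_conc`` by ``dilution_factor``, measured on ``n_series``
    independent series (plates) with ``n_wells`` wells per level each."""

    start_conc: float = 204.0
    n_levels: int = 14
    dilution_factor: float = 2.0
    n_series: int = 3
    n_wells: int = 3

    def __post_init__(self) -> None:
        if self.start_conc <= 0:
            raise ValueError("start_conc must be positive")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.n_series < 1 or self.n_wells < 1:
            raise ValueError("n_series and n_wells must be >= 1")

    @property
    def concentrations(self) -> np.ndarray:
        """Concentrations in descending order, ng per well."""
        return self.start_conc / self.dilution_factor ** np.arange(self.n_levels)

    @property
    def replicates_per_level(self) -> int:
        return self.n_series * self.n_wells

    @property
    def fold_range(self) -> float:
        """Concentration span quoted by the "one log unit per level"
        convention: ``dilution_factor ** n_levels`` (a 14-level two-fold
        series is reported as a 2^14 = 16,384-fold range, although its
        endpoints are 2^13 apart)."""
        return self.dilution_factor ** self.n_levels


@dataclass
class DilutionLevel:
    """Replicate Cp measurements at one known concentration."""

    x: float
    cps: list[float] = field(default_factory=list)
    plate_ids: list[str] = field(default_factory=list)
    n_nondetect: int = 0

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("concentration must be positive")
        if self.plate_ids and len(self.plate_ids) != len(self.cps):
            raise ValueError("plate_ids must align with cps")

    @property
    def log2x(self) -> float:
        return math.log2(self.x)

    @property
    def n(self) -> int:
        return len(self.cps)

    @property
    def mean_cp(self) -> float:
        return float(np.mean(self.cps))

    @property
    def sd_cp(self) -> float:
        """Replicate SD around the level mean (model-free)."""
        if len(self.cps) < 2:
            return float("nan")
        return float(np.std(self.cps, ddof=1))


@dataclass
class DilutionSeries:
    """All levels for one gene, strictly descending in concentration."""

    gene: str
    levels: list[DilutionLevel]

    def __post_init__(self) -> None:
        xs = [lv.x for lv in self.levels]
        self.levels = [lv for _, lv in sorted(zip(xs, self.levels), key=lambda t: -t[0])]
        xs = [lv.x for lv in self.levels]
        if len(set(xs)) != len(xs):
            raise ValueError("duplicate concentration level")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (log2 concentration, Cp) well-level arrays."""
        L, y = [], []
        for lv in self.levels:
            L.extend([lv.log2x] * lv.n)
            y.extend(lv.cps)
        return np.asarray(L, float), np.asarray(y, float)

    def subset(self, keep: list[int]) -> "DilutionSeries":
        return DilutionSeries(self.gene, [self.levels[i] for i in sorted(keep)])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lv in self.levels:
            for j, cp in enumerate(lv.cps):
                rows.append(
                    {
                        "gene": self.gene,
                        "x_ng": lv.x,
                        "log2x": lv.log2x,
                        "plate_id": lv.plate_ids[j] if lv.plate_ids else "",
                        "cp": cp,
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "x_ng", "log2x", "plate_id", "cp"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene: str | None = None) -> "DilutionSeries":
        """Inverse of :meth:`to_dataframe` (one gene per call)."""
        if gene is not None:
            df = df[df["gene"] == gene]
        else:
            genes = df["gene"].unique()
            if len(genes) != 1:
                raise ValueError("dataframe holds multiple genes; pass gene=")
            gene = genes[0]
        levels = []
        for x, sub in df.groupby("x_ng"):
            levels.append(
                DilutionLevel(
                    x=float(x),
                    cps=[float(v) for v in sub["cp"]],
                    plate_ids=[str(p) for p in sub["plate_id"]] if "plate_id" in sub else [],
                )
            )
        return cls(gene=str(gene), levels=levels)
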