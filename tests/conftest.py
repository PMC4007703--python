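import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import assaykit as ak
from assaykit.dilution import DilutionLevel, DilutionSeries
from assaykit.panel import PanelConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel() -> PanelConfig:
    """The shipped default 17-gene panel."""
    return ak.default_panel()


@pytest.fixture(scope="session")
def toy_panel() -> PanelConfig:
    """Panel with hand-computable coefficients.

    Group scores: androgen mean of 4 genes, cellular mean of 4, TPX2 alone,
    stromal mean of 3.  Unscaled score = stromal - androgen; scaled score
    = 20 + 10 * unscaled, clamped to [0, 100].
    """
    return PanelConfig(
        name="toy",
        groups={
            "androgen": ["AZGP1", "KLK2", "SRD5A2", "FAM13C"],
            "cellular_organization": ["FLNC", "GSN", "TPM2", "GSTM2"],
            "proliferation": ["TPX2"],
            "stromal": ["BGN", "COL1A1", "SFRP4"],
        },
        reference_genes=["ARF1", "ATP5E", "CLTC", "GPS1", "PGK1"],
        gdna_assay="ARF1_promoter",
        group_coefficients={
            **{g: 0.25 for g in ["AZGP1", "KLK2", "SRD5A2", "FAM13C"]},
            **{g: 0.25 for g in ["FLNC", "GSN", "TPM2", "GSTM2"]},
            "TPX2": 1.0,
            **{g: 1.0 / 3.0 for g in ["BGN", "COL1A1", "SFRP4"]},
        },
        gps_coefficients={
            "androgen": -1.0,
            "cellular_organization": 0.0,
            "proliferation": 0.0,
            "stromal": 1.0,
        },
        gps_intercept=0.0,
        scale_params={"slope": 10.0, "offset": 20.0, "lower": 0.0, "upper": 100.0},
    )


def exact_series(
    b0: float = 27.0,
    b1: float = -1.0,
    n_levels: int = 14,
    start: float = 204.0,
    n_rep: int = 9,
    gene: str = "GENE",
    offsets: dict[int, float] | None = None,
    spreads: dict[int, float] | None = None,
) -> DilutionSeries:
    """Noise-free dilution series with exactly linear mean Cp, optionally
    distorted: ``offsets[i]`` shifts level i's Cp, ``spreads[i]`` fans the
    replicates symmetrically around the level mean."""
    offsets = offsets or {}
    spreads = spreads or {}
    levels = []
    for i in range(n_levels):
        x = start / 2.0**i
        mu = b0 + b1 * np.log2(x) + offsets.get(i, 0.0)
        fan = spreads.get(i, 0.0)
        cps = [mu + fan * (j - (n_rep - 1) / 2.0) for j in range(n_rep)]
        levels.append(DilutionLevel(x=x, cps=cps))
    return DilutionSeries(gene=gene, levels=levels)


@pytest.fixture
def make_exact_series():
    return exact_series
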