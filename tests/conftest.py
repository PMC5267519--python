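import numpy as np
import pytest

from cypind import CompoundRecord, CompoundTruth, PanelSpec


def plateau_truths() -> list[CompoundTruth]:
    """Six inducers whose tested range spans the plateau (low = EC50/50,
    high = 50×EC50), with exposures spread across the calibration curve."""
    params = [
        # name, e_max (fold increase), ec50 µM, slope, cmax_ub µM
        ("cmpd_a", 22.0, 0.36, 1.0, 2.37),
        ("cmpd_b", 23.0, 15.0, 1.5, 7.26),
        ("cmpd_c", 16.0, 5.0, 1.0, 0.249),
        ("cmpd_d", 33.0, 3.3, 2.0, 0.0282),
        ("cmpd_e", 20.0, 3.6, 1.0, 0.0236),
        ("cmpd_f", 28.0, 5.6, 1.0, 0.0201),
    ]
    return [
        CompoundTruth(name=n, e_max=e, ec50=c, slope=b, e_min=0.0,
                      conc_low=c / 50.0, conc_high=c * 50.0, cmax_ub=cm)
        for n, e, c, b, cm in params
    ]


@pytest.fixture
def recovery_spec() -> PanelSpec:
    return PanelSpec(compounds=plateau_truths(), n_lots=1, noise_cv=0.0, seed=7)


@pytest.fixture
def recovery_records(recovery_spec) -> list[CompoundRecord]:
    return [
        CompoundRecord(name=c.name, cmax_ub=c.cmax_ub, substrate_class="midazolam",
                       in_calibration_set=True)
        for c in recovery_spec.compounds
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
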