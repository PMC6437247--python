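import numpy as np
import pytest

import acekin as ak
from acekin.input_function import (
    AnalyticInputParams,
    InputFunctionSet,
    eval_analytic_input,
)
from acekin.tac import SampledCurve, grid_1s


@pytest.fixture(scope="session")
def schedule():
    return ak.default_schedule()


@pytest.fixture(scope="session")
def ysw_preset():
    return ak.get_preset("YS_warm")


@pytest.fixture(scope="session")
def ysw_inputs(ysw_preset):
    """Calibrated younger-subject warm-condition input functions (shared)."""
    return ak.make_aif(ysw_preset)


@pytest.fixture(scope="session")
def ysc_inputs():
    return ak.make_aif(ak.get_preset("YS_cold"))


def bolus_inputs(l3: float = 0.22, total_s: float = 1800.0) -> InputFunctionSet:
    """Metabolite-free bolus input set (Cb == Cp) for closed-form oracles."""
    t = grid_1s(total_s)
    cp = eval_analytic_input(AnalyticInputParams(0.5, 200.0, 4.0, 1.2, 4.0, 0.5, l3), t)
    return InputFunctionSet(
        Cb=SampledCurve(t, cp),
        Cp=SampledCurve(t, cp.copy()),
        Cm=SampledCurve(t, np.zeros_like(cp)),
    )


@pytest.fixture(scope="session")
def clean_inputs():
    return bolus_inputs()
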