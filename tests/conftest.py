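"""Shared fixtures: the model configurations exercised across the suite.

All recurrent-weight sets are the printed model-side values; stimulus
amplitudes for the decision and hysteresis regime tests are the study
configuration documented in docs/methods.md (placed inside the
competition window of the unbiased-stimulus bifurcation diagram, where
the respective attractor structures exist).
"""

import pytest

from wtadyn import ModelParams

# Stimulus amplitude (pA) placing the decision configuration in the
# winner-take-all regime, where the 50 pA activity threshold is reachable.
WTA_AMPLITUDE = 40.0
# Ramp amplitude (pA) for the hysteresis regime: bistable around Coh=0
# at I_w_plus in {120, 100} pA, mono-stable everywhere at 80 pA.
HYSTERESIS_AMPLITUDE = 28.0

DECISION_THRESHOLD = 50.0  # pA on the firing activity


@pytest.fixture(scope="session")
def decision_params() -> ModelParams:
    """Printed decision configuration: I_w_plus=100 pA, I_w_minus=60 pA."""
    return ModelParams(I_w_plus=100.0, I_w_minus=60.0)


@pytest.fixture(scope="session")
def wm_params_200() -> ModelParams:
    """Working-memory configuration with moderate self-excitation."""
    return ModelParams(I_w_plus=200.0, I_w_minus=60.0)


@pytest.fixture(scope="session")
def wm_params_250() -> ModelParams:
    """Working-memory configuration with strong self-excitation."""
    return ModelParams(I_w_plus=250.0, I_w_minus=60.0)


@pytest.fixture(scope="session")
def hysteresis_params() -> ModelParams:
    """Strongest hysteresis configuration (I_w_plus=120 pA)."""
    return ModelParams(I_w_plus=120.0, I_w_minus=60.0)
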