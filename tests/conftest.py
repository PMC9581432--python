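import hypothesis
import pytest
from hypothesis import strategies as st

from exerdyn import ModelParameters, PopulationState

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

rate = st.floats(min_value=0.0, max_value=0.5, allow_nan=False)
positive_count = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


@st.composite
def parameters(draw):
    return ModelParameters(
        **{name: draw(rate) for name in ModelParameters().as_dict()}
    )


@st.composite
def states(draw):
    s = draw(positive_count)
    e1 = draw(positive_count)
    e2 = draw(positive_count)
    hypothesis.assume(s + e1 + e2 > 1e-6)
    return PopulationState(t=0.0, S=s, E1=e1, E2=e2)


@pytest.fixture
def fig3a_params():
    """Persistence scenario parameters: social uptake dominates recidivism."""
    return ModelParameters(
        k1=0.002, r1=0.015, beta1=0.0022, alpha1=0.005, alpha2=0.005
    )


@pytest.fixture
def fig3b_params():
    """Extinction scenario: recidivism raised to beta1 = 0.035."""
    return ModelParameters(
        k1=0.002, r1=0.015, beta1=0.035, alpha1=0.005, alpha2=0.005
    )
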