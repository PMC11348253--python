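import numpy as np
import pytest
from hypothesis import settings

from gmpda.simulate import EventSeries

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def six_events() -> EventSeries:
    """The worked six-event example with prime period 11."""
    return EventSeries(np.array([12, 23, 34, 45, 56, 67]), 67)
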