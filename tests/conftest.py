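"""Shared synthetic fixtures.

Everything is generated programmatically at test time from the package's own
synthetic-recording module; heavier recordings are module/session scoped so
the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleeplfp.core import DELTA, NREM, RIPPLE, SPINDLE
from sleeplfp.synth import EventSpec, SimConfig, generate_recording


@pytest.fixture(scope="session")
def nrem_recording():
    """5 min NonREM at 1 kHz with a dozen of each event kind, plus truth."""
    specs = (
        [EventSpec(kind=RIPPLE) for _ in range(12)]
        + [EventSpec(kind=SPINDLE) for _ in range(8)]
        + [EventSpec(kind=DELTA) for _ in range(10)]
    )
    cfg = SimConfig(
        duration=300.0,
        fs=1000.0,
        state_schedule=[(NREM, 300.0)],
        event_specs=specs,
        seed=11,
    )
    return generate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
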