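import numpy as np
import pytest

from isletwave import synthgen as sg
from isletwave.traceio import SegmentSchedule, Trace


@pytest.fixture(scope="session")
def four_condition_schedule() -> SegmentSchedule:
    return SegmentSchedule.default_four_condition()


@pytest.fixture()
def slow_wave_trace() -> Trace:
    """Noiseless 4-min-period, 50%-duty square wave, 40 min at 6-s frames."""
    return sg.make_trace(sg.WaveSpec(archetype="slow", period=4.0, duty=0.5, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_cohort():
    """Two strains (slow vs fast responders) x 2 sexes x 2 animals x 3 islets."""
    spec = sg.CohortSpec(
        strains=("SLOW", "FAST"),
        sexes=("M", "F"),
        animals_per_group=2,
        islets_per_animal=3,
        archetype_map={
            "SLOW": [sg.WaveSpec("slow", period=4.0, duty=0.5, noise_sd=0.02)] * 3
            + [sg.WaveSpec("silent", noise_sd=0.02)],
            "FAST": [sg.WaveSpec("fast", period=1.0, duty=0.4, noise_sd=0.02)] * 3
            + [sg.WaveSpec("silent", noise_sd=0.02)],
        },
        seed=7,
    )
    return sg.make_cohort(spec)


def constant_trace(level: float, n: int = 400, dt: float = 0.1) -> Trace:
    return Trace("const", np.arange(n) * dt, np.full(n, level))
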