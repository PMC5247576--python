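import numpy as np
import pytest

from electrogenetics import electrochem as ec


@pytest.fixture
def fcn_state():
    """The experimental mediator pool: 3 ml of 5 mM Fcn, fully reduced, 37 C."""
    return ec.ElectrolysisState(volume=3e-3, total_conc=5e-3, frac_ox=0.0,
                                temperature=310.15)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_schedule(rng, n_segments=None, min_dur=60.0, max_dur=900.0,
                    e_lo=-0.4, e_hi=0.6):
    """A random piecewise-constant potential program."""
    n = n_segments or int(rng.integers(2, 6))
    return ec.SignalSchedule([
        (float(rng.uniform(e_lo, e_hi)), float(rng.uniform(min_dur, max_dur)))
        for _ in range(n)
    ])
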