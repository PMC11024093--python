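import numpy as np
import pytest

from calshape import CohortSpec, ParamRanges, TransientParams


@pytest.fixture
def times_52():
    """Post-stimulus frame times for the default acquisition (52 frames, 30 s)."""
    return np.arange(52) * 30.0


@pytest.fixture
def typical_params():
    """A realistic responder: ~150 s decay time, early peak, plateau at c."""
    return TransientParams(tau_decay=1 / 150, tau_delta=0.05, b=1.0, c=0.5)


@pytest.fixture
def small_cohort_spec():
    """Two-geometry cohort small enough for per-cell fitting in tests."""
    return CohortSpec(
        n_cells={"O": 6, "L": 6},
        group_ranges={
            "O": ParamRanges(inv_tau_decay_s=(30.0, 150.0)),
            "L": ParamRanges(inv_tau_decay_s=(200.0, 800.0)),
        },
        concentrations=(3.0,),
        noise_sd=1.0,
        nonresponder_fraction=0.0,
        seed=7,
    )


def sample_params(rng, inv_tau=(15.0, 1500.0), tau_delta=(1e-6, 1e-1),
                  b=(0.1, 1000.0), c=(0.1, 1000.0)):
    """Log-uniform parameter draw within the grid-search ranges."""
    logu = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))  # noqa: E731
    return TransientParams(
        tau_decay=1.0 / logu(*inv_tau),
        tau_delta=logu(*tau_delta),
        b=logu(*b),
        c=logu(*c),
    )
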