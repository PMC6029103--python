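import numpy as np
import pytest

from attachkin import AttachmentSeries, model_nb, presets


@pytest.fixture(scope="session")
def late_exp_params():
    """Later-exponential-phase two-component mixture parameters."""
    return (
        np.array([presets.FAST_FRACTION, presets.SLOW_FRACTION]),
        np.array([presets.ALPHA_FAST, presets.ALPHA_SLOW]),
    )


def make_noiseless_series(fractions, rates, duration=3600.0, dt=3.0, n_total=10**6):
    """Exact mixture curve on a frame grid, rendered as integer-like counts.

    n_total is large enough that rounding to integers perturbs the curve by
    < 1e-6, preserving 'noiseless' for recovery tests.
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    y = model_nb(t, fractions, rates)
    n_bulk = np.round(y * n_total).astype(int)
    return AttachmentSeries(t, n_bulk, n_total - n_bulk, n_total)


@pytest.fixture(scope="session")
def noiseless_series(late_exp_params):
    f, a = late_exp_params
    return make_noiseless_series(f, a)
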