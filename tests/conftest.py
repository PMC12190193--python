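import numpy as np
import pytest

from lensepr.sr import simulate_sr_decay, fit_single


@pytest.fixture(scope="session")
def single_fit_replicates():
    """200 seeded single-exponential fits at 1% noise (T1 = 5 us).

    Shared across covariance-sanity and unbiasedness checks so the fits run
    once per session.
    """
    fits = []
    for ss in np.random.SeedSequence(2024).spawn(200):
        d = simulate_sr_decay(
            [(1.0, 5.0)], t_grid=np.linspace(0, 25, 2048),
            noise_sd=0.01, seed=np.random.default_rng(ss),
        )
        fits.append(fit_single(d))
    return fits
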