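import numpy as np
import pytest

from spliceshift.synthetic import (
    ZERO_NOISE,
    generate_ase_catalog,
    generate_samples,
    generate_truth,
    simulate_peak_table,
)


@pytest.fixture(scope="session")
def zero_noise_screen():
    """A small concordant screen with no technical noise: truth is exactly
    recoverable, so downstream stages can be checked against it."""
    catalog = generate_ase_catalog(24, seed=11)
    truth = generate_truth(
        catalog, prop_null=0.5, discordant_rate=0.0, response_rate=0.6, seed=12
    )
    samples = generate_samples()
    peaks = simulate_peak_table(catalog, truth, samples, noise=ZERO_NOISE, seed=13)
    return catalog, truth, samples, peaks


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
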