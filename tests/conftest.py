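"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from actirhythm import (
    FourierBasis,
    FunctionalPCA,
    fit_curves,
    simulate_cohort,
)
from actirhythm.prep import epoch_means
from actirhythm.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def recovery_cohort():
    """Noise-free cohort under which fPCA recovery is exact (n=500)."""
    return simulate_cohort(GeneratorConfig.exact_recovery(n_participants=500, seed=11))


@pytest.fixture(scope="session")
def recovery_fpca(recovery_cohort):
    """Pipeline prep+fPCA run on the noise-free cohort."""
    profiles = epoch_means(recovery_cohort.minute_records, "overall")
    basis = FourierBasis()
    fits = fit_curves(profiles.means, basis)
    res = FunctionalPCA(fits, basis).fit(n_components=4)
    return res


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-condition cohort (noise, missingness, health outcome), n=200."""
    return simulate_cohort(GeneratorConfig(n_participants=200, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
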