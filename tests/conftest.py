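import numpy as np
import pytest

from nphtest import FixtureSpec, make_fixture

# administrative horizon giving ~40 % censoring for unit-rate exponential times
CENSOR_40 = float(np.log(2.5))


@pytest.fixture
def null_fixture():
    """Factory for identical-arm exponential datasets with ~40 % censoring."""

    def _make(n_per_arm=250, seed=0, censored=True):
        return make_fixture(
            FixtureSpec(
                family="exponential",
                n_per_arm=n_per_arm,
                effect="null",
                rate=1.0,
                censor_horizon=CENSOR_40 if censored else None,
                seed=seed,
            )
        )

    return _make


@pytest.fixture
def ph_fixture():
    """Factory for proportional-hazards datasets with a given hazard ratio."""

    def _make(n_per_arm=250, hr=0.75, seed=0, censored=True):
        return make_fixture(
            FixtureSpec(
                family="exponential",
                n_per_arm=n_per_arm,
                effect="ph",
                hr=hr,
                rate=1.0,
                censor_horizon=CENSOR_40 if censored else None,
                seed=seed,
            )
        )

    return _make


@pytest.fixture
def early_fixture():
    """Factory for early-effect datasets (benefit that dwindles, then reverses)."""

    def _make(n_per_arm=250, seed=0):
        return make_fixture(
            FixtureSpec(
                family="exponential",
                n_per_arm=n_per_arm,
                effect="early",
                rate=1.0,
                hr_early=0.5,
                hr_late=1.1,
                censor_horizon=2.0,
                seed=seed,
            )
        )

    return _make
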