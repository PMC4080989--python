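import numpy as np
import pytest

from atptca.plate import DoseSeries, InhibitionProfile, N_STEPS


@pytest.fixture
def series() -> DoseSeries:
    """Canonical 2 .. 0.0625 uM doubling series (TDC = 1 uM)."""
    return DoseSeries.from_tdc("drugX", 1.0)


def make_profile(inhibition, series=None, condition="drugX", cv=None, n_reps=3):
    """Build an InhibitionProfile directly from six inhibition values (%)."""
    series = series or DoseSeries.from_tdc(condition, 1.0)
    inhibition = tuple(float(x) for x in inhibition)
    cv = tuple(cv) if cv is not None else (0.0,) * N_STEPS
    return InhibitionProfile(
        condition=condition,
        series=series,
        inhibition=inhibition,
        cv=cv,
        n_replicates=(n_reps,) * N_STEPS,
    )


def hill_profile(imax, ec50, slope, series=None, condition="drugX"):
    """Noiseless profile sampled from a Hill curve at the six dilution steps."""
    series = series or DoseSeries.from_tdc(condition, 1.0)
    c = np.asarray(series.concentrations)
    ch = c ** slope
    inh = imax * ch / (ec50 ** slope + ch)
    return make_profile(inh, series=series, condition=condition)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def hill_profile_factory():
    return hill_profile
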