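"""Shared fixtures: simulated nights and fitted models, built once."""

import warnings

import numpy as np
import pytest

import spindlepp as sp


@pytest.fixture(scope="session")
def paper_night():
    """One 8-h paper_default night (hypnogram, SO series, train, covariates)."""
    scen = sp.paper_like_scenario("paper_default")
    return sp.simulate_night(scen, seed=42)


@pytest.fixture(scope="session")
def paper_fit(paper_night):
    """Full stage+phase+interaction+history model fitted on that night."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sp.fit_spec(paper_night.cov, "stage+phase+interaction+history15")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def constant_rate_covariates(duration_s, dt_s, rate_per_s, event_times,
                             stage="N2", so_freq=0.85):
    """Minimal covariate series around an externally generated train."""
    n = int(round(duration_s / dt_s))
    phase = sp.wrap_phase(2 * np.pi * so_freq * (np.arange(n) + 0.5) * dt_s)
    counts = np.zeros(n, dtype=int)
    idx = np.minimum((np.asarray(event_times) // dt_s).astype(int), n - 1)
    np.add.at(counts, idx, 1)
    counts = np.minimum(counts, 1)
    return sp.CovariateSeries(
        dt_s=dt_s,
        stage=np.full(n, stage, dtype=object),
        phase=phase,
        sop=np.full(n, 0.5),
        counts=counts,
        event_times=np.asarray(event_times, dtype=float),
    )
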