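import numpy as np
import pytest

from misinfosim import (
    ModelParams,
    Posterior,
    SynthSpec,
    gen_corpus,
    segment_corpus,
)
from misinfosim.inference import compute_rhat
from misinfosim.model import PARAM_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(20201103)


def make_posterior(params: ModelParams, n: int = 200, jitter: float = 0.0,
                   seed: int = 0) -> Posterior:
    """A synthetic posterior concentrated on known parameters.

    Used where scenario machinery is under test and MCMC would only add
    noise and runtime; jitter (relative) keeps draws inside supports.
    """
    rng = np.random.default_rng(seed)
    base = params.as_array()
    draws = np.tile(base, (4, n, 1)).astype(float)
    if jitter:
        draws *= 1.0 + jitter * rng.standard_normal(draws.shape)
        draws[..., 2] = np.clip(draws[..., 2], 0.0, 1.0)
        draws[..., 3] = np.abs(draws[..., 3])
        draws[..., 4] = np.abs(draws[..., 4])
    post = Posterior(draws=draws)
    post.rhat = {
        name: compute_rhat(draws[:, :, i]) for i, name in enumerate(PARAM_NAMES)
    }
    return post


@pytest.fixture(scope="session")
def small_study():
    """A segmented single-burst corpus with truth-centred posteriors.

    Session-scoped: the corpus is deterministic and read-only in tests.
    Returns (events, posteriors, truth, incidents, registry, offenders).
    """
    spec = SynthSpec(
        n_incidents=8,
        n_accounts=1500,
        accounts_per_incident=150,
        events_per_incident=(1.0,),
        rng_seed=14,
    )
    incidents, registry, offenders, truth = gen_corpus(spec)
    events, _prov = segment_corpus(incidents)
    truth_by_incident = truth.set_index("incident_id")
    posteriors = {}
    for i, ev in enumerate(events):
        row = truth_by_incident.loc[ev.incident_id]
        params = ModelParams(
            alpha=row["alpha"], beta=row["beta"], delta=row["delta"],
            lam=row["lam"], phi=row["phi"],
        )
        posteriors[ev.event_id] = make_posterior(
            params, n=100, jitter=0.03, seed=100 + i
        )
    return events, posteriors, truth, incidents, registry, offenders
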