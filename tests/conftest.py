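import numpy as np
import pandas as pd
import pytest

from usualintake import PseudoPopulation, SyntheticSpec, generate_population


@pytest.fixture(scope="session")
def balanced_survey():
    """2000 persons x 2 recalls generated with an identity-scale model."""
    spec = SyntheticSpec(n_persons=2000, n_recalls=2, lam=1.0, beta0=10.0,
                         sigma2_between=1.0, sigma2_within=2.0, seed=42)
    dataset, truth = generate_population(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def lognormal_survey():
    """1000 persons x 2 recalls on the log scale with known lognormal truth."""
    spec = SyntheticSpec(n_persons=1000, n_recalls=2, lam=0.0, beta0=1.0,
                         sigma2_between=0.25, sigma2_within=0.25, seed=11)
    dataset, truth = generate_population(spec)
    return spec, dataset, truth


def make_pseudo(intakes, weights=None, supplement=None, **covariates) -> PseudoPopulation:
    """Hand-built pseudo-population for small fixtures."""
    intakes = np.asarray(intakes, dtype=float)
    n = intakes.size
    supplement = np.zeros(n) if supplement is None else np.asarray(supplement, dtype=float)
    frame = pd.DataFrame({
        "source_person_id": [f"p{i}" for i in range(n)],
        "weight_share": np.ones(n) if weights is None else np.asarray(weights, dtype=float),
        "usual_food_intake": intakes,
        "supplement_contribution": supplement,
        "total_intake": intakes + supplement,
    })
    for name, values in covariates.items():
        frame[name] = values
    return PseudoPopulation(frame)
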