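import numpy as np
import pandas as pd
import pytest

import cdbiorisk as cb


@pytest.fixture(scope="session")
def samples200():
    return cb.generate_soil_dataset(200, seed=1)


@pytest.fixture(scope="session")
def frame126():
    return cb.prepare_modeling_frame(cb.generate_soil_dataset(126, seed=5))


@pytest.fixture(scope="session")
def forest126(frame126):
    from cdbiorisk.bioaccess import REFERENCE_OPTIMUM

    return cb.rf_grid_fit(frame126,
                          grid={k: [v] for k, v in REFERENCE_OPTIMUM.items()},
                          seed=0)


@pytest.fixture(scope="session")
def point_specs():
    """All-point-mass exposure specs for deterministic Monte Carlo checks."""
    vals = dict(C=1.0, BA=1.0, IngR=100.0, InhR=14.5, EF=350.0, ED=6.0,
                BW=15.0, AT=2190.0, SA=2800.0, AF=0.2, ABF=0.001, PEF=1.36e9)
    return {p: cb.DistributionSpec(p, "point", v) for p, v in vals.items()}


def brute_force_shapley(model, x: pd.Series, background: pd.DataFrame,
                        features) -> np.ndarray:
    """Independent oracle: exact Shapley by enumeration of all coalitions,
    with the interventional value function evaluated through model.predict."""
    import itertools
    from math import factorial

    k = len(features)
    phi = np.zeros(k)

    def value(coalition):
        hybrid = background.copy()
        for f in coalition:
            hybrid[f] = x[f]
        return model.predict(hybrid[list(features)]).mean()

    for i, f in enumerate(features):
        others = [g for g in features if g != f]
        for r in range(k):
            for S in itertools.combinations(others, r):
                w = factorial(r) * factorial(k - r - 1) / factorial(k)
                phi[i] += w * (value(set(S) | {f}) - value(set(S)))
    return phi
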