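import numpy as np
import pandas as pd
import pytest

from frailtypaths.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One medium synthetic cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(n_subjects=4000, seed=11))


@pytest.fixture()
def six_subject_survival():
    """Tiny no-ties survival fixture with one binary covariate."""
    return pd.DataFrame({
        "followup_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 0, 1, 1, 0],
        "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
    })


def weibull_ph_sample(rng, n, beta, shape=1.5, scale=0.1, censor=10.0,
                      p_binary=None):
    """Simulate from a Weibull PH model for parameter-recovery tests."""
    beta = np.asarray(beta, dtype=float)
    p = len(beta)
    X = rng.normal(size=(n, p))
    if p_binary is not None:
        X[:, 0] = rng.binomial(1, p_binary, size=n)
    eta = X @ beta
    T = (-np.log(rng.uniform(size=n)) / (scale * np.exp(eta))) ** (1 / shape)
    t = np.minimum(T, censor)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["followup_time"] = t
    df["event"] = (T <= censor).astype(int)
    return df
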