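import numpy as np
import pandas as pd
import pytest

from envinvar.scm import (
    Cohort,
    ROLE_PREDICTOR,
    ROLE_TARGET,
    ROLE_BINARY_CHILD,
    ROLE_DEMOGRAPHIC,
    build_scm,
    parent_recovery_preset,
    sample_multi_env,
    target_shift_preset,
)


@pytest.fixture(scope="session")
def recovery_scm():
    return build_scm(parent_recovery_preset())


@pytest.fixture(scope="session")
def shift_scm():
    return build_scm(target_shift_preset())


@pytest.fixture(scope="session")
def recovery_train(recovery_scm):
    """Two training environments from the parent-recovery benchmark."""
    return sample_multi_env(recovery_scm, {"e1": 1000, "e2": 1000}, seed=11)


@pytest.fixture()
def toy_cohort():
    """Tiny hand-made cohort: Y = 2*A - B + noise, binary child, demographic."""
    rng = np.random.default_rng(5)
    n = 200
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    y = 2 * a - b + 0.5 * rng.standard_normal(n)
    c = rng.binomial(1, 1 / (1 + np.exp(-(0.5 * y - 0.2)))).astype(float)
    age = rng.normal(30, 6, n)
    df = pd.DataFrame({"A": a, "B": b, "Y": y, "C": c, "AGE": age})
    roles = {
        "A": ROLE_PREDICTOR,
        "B": ROLE_PREDICTOR,
        "Y": ROLE_TARGET,
        "C": ROLE_BINARY_CHILD,
        "AGE": ROLE_DEMOGRAPHIC,
    }
    env = np.where(np.arange(n) < n // 2, "e1", "e2").astype(object)
    return Cohort(df, roles, env)
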