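import numpy as np
import pandas as pd
import pytest

from pyquint import RCTDataset, ScenarioSpec, generate, resolve_control


def make_dataset(n=24, J=2, seed=0, effect_left=1.2, effect_right=-1.2):
    """Small planted-interaction trial used across the unit tests."""
    if effect_left == effect_right == 0:
        pattern = "null"
    elif effect_left * effect_right < 0:
        pattern = "qualitative"
    else:
        pattern = "quantitative"
    spec = ScenarioSpec(
        n=n, J=J, pattern=pattern,
        effect_left=effect_left, effect_right=effect_right, seed=seed,
    )
    return generate(spec)


def random_dataset(rng, n=None, J=None):
    """A fully random small trial (no planted structure beyond noise)."""
    n = n or int(rng.integers(16, 41))
    J = J or int(rng.integers(1, 4))
    X = rng.standard_normal((n, J))
    if J > 1 and rng.random() < 0.5:
        X[:, -1] = (X[:, -1] > 0).astype(float)  # one dichotomous covariate
    t = np.where(rng.random(n) < 0.5, 1, 2)
    # guard: both arms present with at least 2 members each
    t[:2] = 1
    t[2:4] = 2
    y = rng.standard_normal(n) + 0.8 * (t == 1) * np.sign(X[:, 0])
    return RCTDataset(y=y, t=t, X=X, covariate_names=tuple(f"x{j+1}" for j in range(J)))


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def planted_dataset():
    return make_dataset(n=200, J=3, seed=11, effect_left=0.8, effect_right=-0.8)


@pytest.fixture
def raw_table():
    """A raw trial table with missing values and a 3-category treatment."""
    rng = np.random.default_rng(5)
    n = 30
    frame = pd.DataFrame(
        {
            "pre": rng.normal(20, 4, n).round(1),
            "post": rng.normal(16, 5, n).round(1),
            "cond": rng.choice([1, 2, 3], n, p=[0.4, 0.4, 0.2]),
            "age": rng.integers(25, 70, n).astype(float),
            "optimism": rng.integers(5, 30, n).astype(float),
        }
    )
    frame.loc[[3, 7, 12], "age"] = np.nan
    return frame
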