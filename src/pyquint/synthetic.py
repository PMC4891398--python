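"""Synthetic two-arm trials with known subgroup structure.

The generator emulates the input the method expects: n participants
randomized to two arms, J numeric baseline covariates, and a continuous
outcome in which a treatment-by-subgroup interaction of known shape is
planted.  One covariate (``split_var``) defines the true partition at
``split_point``; within each side the arm-1 mean is shifted against arm 2 by
``effect * noise_sd``, so the planted effects are expressed directly on the
Cohen's d scale and translate one-to-one to the ``dmin`` gate.

Patterns:

* ``null`` — no treatment effect anywhere (both effects 0);
* ``quantitative`` — same ranking of the arms on both sides, different
  magnitude;
* ``qualitative`` — the ranking reverses across the threshold (the
  structure the tree method is designed to find).

Defaults plant the canonical benchmark condition: n = 400 split equally
between arms, three standard-normal covariates, a qualitative interaction
of +/- 0.8 SD at the median of the first covariate, unit noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data_model import RCTDataset
from .errors import ValidationError

PATTERNS = ("null", "quantitative", "qualitative")


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth description of a synthetic trial."""

    n: int = 400
    arm_ratio: float = 0.5  # fraction of participants in arm 1
    J: int = 3
    pattern: str = "qualitative"
    split_var: int = 0
    split_point: float = 0.0
    effect_left: float = 0.8
    effect_right: float = -0.8
    noise_sd: float = 1.0
    dichotomous_last: bool = False  # make the last covariate 0/1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError("n must be at least 4")
        if not 0 < self.arm_ratio < 1:
            raise ValidationError("arm_ratio must be strictly between 0 and 1")
        if self.J < 1:
            raise ValidationError("at least one covariate is required")
        if not 0 <= self.split_var < self.J:
            raise ValidationError("split_var out of range")
        if self.pattern not in PATTERNS:
            raise ValidationError(f"pattern must be one of {PATTERNS}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.pattern == "null" and (self.effect_left != 0 or self.effect_right != 0):
            raise ValidationError("null pattern requires both effects to be 0")
        if self.pattern == "qualitative" and not (
            self.effect_left * self.effect_right < 0
        ):
            raise ValidationError(
                "qualitative pattern requires effects of opposite sign"
            )
        if self.pattern == "quantitative" and (
            self.effect_left * self.effect_right < 0
            or (self.effect_left == 0 and self.effect_right == 0)
        ):
            raise ValidationError(
                "quantitative pattern requires same-sign effects, not both zero"
            )

    def null(self) -> "ScenarioSpec":
        """The matching no-effect scenario (same design, zero effects)."""
        from dataclasses import replace

        return replace(self, pattern="null", effect_left=0.0, effect_right=0.0)


def generate(spec: ScenarioSpec) -> RCTDataset:
    """Draw one trial according to ``spec``; reproducible from its seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    X = rng.standard_normal((n, spec.J))
    if spec.dichotomous_last:
        X[:, -1] = (X[:, -1] > 0).astype(float)
    n1 = int(round(spec.arm_ratio * n))
    n1 = min(max(n1, 2), n - 2)
    t = np.full(n, 2)
    t[rng.permutation(n)[:n1]] = 1

    left = X[:, spec.split_var] <= spec.split_point
    effect = np.where(left, spec.effect_left, spec.effect_right)
    # the whole arm-vs-arm shift is carried by arm 1, so within each true
    # subgroup the population Cohen's d equals the planted effect exactly
    y = spec.noise_sd * rng.standard_normal(n)
    y = y + np.where(t == 1, effect * spec.noise_sd, 0.0)

    names = tuple(f"x{j + 1}" for j in range(spec.J))
    return RCTDataset(
        y=y, t=t, X=X, covariate_names=names, treatment_label_map={1: 1, 2: 2}
    )


def generate_table(spec: ScenarioSpec) -> tuple[pd.DataFrame, dict]:
    """Trial as a flat CSV-ready table plus the ground-truth sidecar dict."""
    ds = generate(spec)
    frame = pd.DataFrame({"y": ds.y, "trt": ds.t})
    for j, name in enumerate(ds.covariate_names):
        frame[name] = ds.X[:, j]
    return frame, asdict(spec)


def write_scenario(spec: ScenarioSpec, csv_path, sidecar_path=None) -> None:
    """Write the generated trial to CSV and the spec to a JSON sidecar."""
    frame, truth = generate_table(spec)
    frame.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = str(csv_path) + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump(truth, fh, indent=2)
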