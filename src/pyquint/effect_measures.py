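"""Per-arm summaries, Cohen's d and leaf-level treatment statistics.

Cohen's d is the arm-1 minus arm-2 mean difference divided by the pooled
standard deviation with the usual ``n1 + n2 - 2`` degrees of freedom.  Its
standard error uses the large-sample formula

    se(d) = sqrt((n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2 - 2))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateVarianceError, EmptyArmError

#: labels a leaf can carry: treatment 1 better, treatment 2 better, no clear
#: difference, or not yet assigned
P1, P2, P3 = "P1", "P2", "P3"
UNASSIGNED = "unassigned"

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class ArmSummary:
    """Count, mean and sample SD (``n - 1`` denominator; 0 when n = 1)."""

    n: int
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ArmSummary":
        values = np.asarray(values, dtype=float)
        n = values.size
        if n == 0:
            raise EmptyArmError("cannot summarize an empty arm")
        sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
        return cls(n=int(n), mean=float(np.mean(values)), sd=sd)

    @property
    def ss(self) -> float:
        """Within-arm sum of squared deviations."""
        return (self.n - 1) * self.sd**2


def pooled_sd(a: ArmSummary, b: ArmSummary) -> float:
    if a.n + b.n < 3:
        raise DegenerateVarianceError("pooled SD needs at least 3 observations")
    return math.sqrt((a.ss + b.ss) / (a.n + b.n - 2))


def cohens_d(a: ArmSummary, b: ArmSummary) -> float:
    """Standardized mean difference of arm ``a`` minus arm ``b``."""
    sp = pooled_sd(a, b)
    if sp <= _VAR_EPS * max(1.0, abs(a.mean), abs(b.mean)):
        raise DegenerateVarianceError("pooled SD is zero; d undefined")
    return (a.mean - b.mean) / sp


def se_cohens_d(a: ArmSummary, b: ArmSummary, d: float) -> float:
    """Large-sample standard error of Cohen's d."""
    n, m = a.n, b.n
    if n + m < 3:
        raise DegenerateVarianceError("se(d) needs at least 3 observations")
    return math.sqrt((n + m) / (n * m) + d**2 / (2 * (n + m - 2)))


@dataclass
class LeafStats:
    """Treatment statistics of one leaf (or any row subset).

    ``d`` and ``se_d`` are NaN when the pooled SD is zero (possible with a
    constant outcome in a leaf); the raw mean difference ``diff`` is always
    defined and carries the sign used for class admissibility.
    """

    arm1: ArmSummary
    arm2: ArmSummary
    d: float
    se_d: float
    diff: float
    class_label: str = field(default=UNASSIGNED)

    @property
    def n(self) -> int:
        return self.arm1.n + self.arm2.n

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.d)

    def ci95(self) -> tuple[float, float]:
        """Normal-approximation 95% confidence interval for d."""
        return (self.d - 1.96 * self.se_d, self.d + 1.96 * self.se_d)


def leaf_stats(dataset, member_index) -> LeafStats:
    """Summarize the rows ``member_index`` of ``dataset`` per treatment arm.

    Raises :class:`EmptyArmError` when either arm is absent from the subset.
    """
    member_index = np.asarray(member_index, dtype=int)
    if member_index.size == 0:
        raise EmptyArmError("empty row subset")
    t = dataset.t[member_index]
    y = dataset.y[member_index]
    y1, y2 = y[t == 1], y[t == 2]
    if y1.size == 0 or y2.size == 0:
        raise EmptyArmError("subset does not contain both treatment arms")
    a1 = ArmSummary.from_values(y1)
    a2 = ArmSummary.from_values(y2)
    diff = a1.mean - a2.mean
    try:
        d = cohens_d(a1, a2)
        se = se_cohens_d(a1, a2, d)
    except DegenerateVarianceError:
        d, se = float("nan"), float("nan")
    return LeafStats(arm1=a1, arm2=a2, d=d, se_d=se, diff=diff)
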