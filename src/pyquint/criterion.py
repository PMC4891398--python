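"""The partitioning criterion and the admissible leaf-to-subgroup assignments.

A tree's leaves are assigned to three subgroups: P1 (treatment 1 better),
P2 (treatment 2 better) and the optional P3 ("region of uncertainty").
An assignment is admissible when P1 and P2 are both nonempty and every P1
leaf has a positive arm-1-minus-arm-2 mean difference and every P2 leaf a
negative one.

For an admissible assignment the criterion is

    C = w1 * [ log(1 + |E1|) + log(1 + |E2|) ]          (difference component)
      + w2 * [ log(n_P1)     + log(n_P2) ]              (cardinality component)

where ``E_k`` is the treatment effect of subgroup k — Cohen's d (effect-size
criterion) or the raw mean difference (difference-in-means criterion) of all
its members pooled — and ``n_Pk`` its total member count.  With the default
weights each bracketed component has a maximum of 2, attained at
``|E1| = |E2| = 3`` and ``n_P1 = n_P2 = n/2``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ControlParams, RCTDataset
from .effect_measures import P1, P2, P3, ArmSummary, LeafStats, cohens_d
from .errors import QuintError

#: tolerance used for "higher value of C" comparisons during the search
C_TOL = 1e-10


@dataclass(frozen=True)
class Assignment:
    """One label per leaf, in left-to-right leaf order."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [l for l in self.labels if l not in (P1, P2, P3)]
        if bad:
            raise QuintError(f"unknown class label(s): {bad}")

    def leaves_in(self, label: str) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]


@dataclass(frozen=True)
class CriterionValue:
    """The criterion C and its two weighted components."""

    C: float
    diff_component: float
    card_component: float
    class_effect_1: float
    class_effect_2: float
    n_P1: int
    n_P2: int


def assignment_admissible(stats: Sequence[LeafStats], assignment: Assignment) -> bool:
    """Check the nonempty-class and mean-difference-per-leaf conditions."""
    labels = assignment.labels
    if len(labels) != len(stats):
        return False
    if P1 not in labels or P2 not in labels:
        return False
    for st, lab in zip(stats, labels):
        if lab == P1 and not st.diff > 0:
            return False
        if lab == P2 and not st.diff < 0:
            return False
    return True


def enumerate_admissible_assignments(stats: Sequence[LeafStats]) -> list[Assignment]:
    """All admissible label vectors for the given leaf statistics.

    A leaf with positive mean difference may carry P1 or P3, one with a
    negative difference P2 or P3, and one with a zero difference only P3;
    vectors without both a P1 and a P2 leaf are dropped.  May be empty, in
    which case the candidate tree is inadmissible.
    """
    options = []
    for st in stats:
        if st.diff > 0:
            options.append((P1, P3))
        elif st.diff < 0:
            options.append((P2, P3))
        else:
            options.append((P3,))
    out = []
    for labels in itertools.product(*options):
        if P1 in labels and P2 in labels:
            out.append(Assignment(labels=labels))
    return out


def class_effect(
    dataset: RCTDataset, leaves_in_class: Sequence[np.ndarray], crit: str
) -> float:
    """Treatment effect of a subgroup: its leaves' members pooled into one
    group, then Cohen's d (``effect_size``) or the raw mean difference
    (``difference_in_means``) between the arms of that pooled group."""
    if not leaves_in_class:
        raise QuintError("class has no leaves")
    members = np.concatenate([np.asarray(ix, dtype=int) for ix in leaves_in_class])
    t = dataset.t[members]
    y = dataset.y[members]
    y1, y2 = y[t == 1], y[t == 2]
    a = ArmSummary.from_values(y1)
    b = ArmSummary.from_values(y2)
    if crit == "effect_size":
        return cohens_d(a, b)
    return a.mean - b.mean


def weighted_class_effect(
    dataset: RCTDataset, leaves_in_class: Sequence[np.ndarray], crit: str
) -> float:
    """Size-weighted mean of per-leaf effects — the alternative aggregation
    kept for sensitivity checks only; pooling is the default."""
    from .effect_measures import leaf_stats

    total = 0
    acc = 0.0
    for ix in leaves_in_class:
        st = leaf_stats(dataset, ix)
        val = st.d if crit == "effect_size" else st.diff
        acc += st.n * val
        total += st.n
    return acc / total


def criterion_value(
    dataset: RCTDataset,
    leaves: Sequence[np.ndarray],
    assignment: Assignment,
    control: ControlParams,
) -> CriterionValue:
    """Evaluate C for a tree given as leaf row subsets plus an assignment."""
    from .effect_measures import leaf_stats

    stats = [leaf_stats(dataset, ix) for ix in leaves]
    if not assignment_admissible(stats, assignment):
        raise QuintError("assignment violates the admissibility conditions")

    effect_fn = class_effect if control.pooled_class_effect else weighted_class_effect
    parts = {}
    for label in (P1, P2):
        idx = assignment.leaves_in(label)
        subsets = [leaves[i] for i in idx]
        e = effect_fn(dataset, subsets, control.crit)
        n_k = int(sum(len(np.asarray(s)) for s in subsets))
        parts[label] = (e, n_k)
    e1, n_p1 = parts[P1]
    e2, n_p2 = parts[P2]
    diff_comp = control.w1 * (math.log1p(abs(e1)) + math.log1p(abs(e2)))
    card_comp = control.w2 * (math.log(n_p1) + math.log(n_p2))
    return CriterionValue(
        C=diff_comp + card_comp,
        diff_component=diff_comp,
        card_component=card_comp,
        class_effect_1=e1,
        class_effect_2=e2,
        n_P1=n_p1,
        n_P2=n_p2,
    )
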