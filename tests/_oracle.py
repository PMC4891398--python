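"""Independent brute-force oracle for the split search.

Everything here is computed the slow, obvious way — per-candidate loops,
two-pass means/SDs on the raw rows, full enumeration of the 3^L label
vectors — deliberately sharing no code with the package's vectorized
prefix-sum search, so agreement between the two is informative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

TOL = 1e-10


def _mean(v):
    return sum(v) / len(v)


def _sd(v):
    if len(v) < 2:
        return 0.0
    m = _mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))


def group_stats(ds, idx):
    """(n1, mean1, sd1, n2, mean2, sd2) of a row subset, two-pass arithmetic."""
    y1 = [ds.y[i] for i in idx if ds.t[i] == 1]
    y2 = [ds.y[i] for i in idx if ds.t[i] == 2]
    return (len(y1), _mean(y1) if y1 else float("nan"), _sd(y1),
            len(y2), _mean(y2) if y2 else float("nan"), _sd(y2))


def pooled_d(ds, idx):
    n1, m1, s1, n2, m2, s2 = group_stats(ds, idx)
    ss = (n1 - 1) * s1**2 + (n2 - 1) * s2**2
    if n1 + n2 < 3 or ss <= 0:
        return None
    return (m1 - m2) / math.sqrt(ss / (n1 + n2 - 2))


def mean_diff(ds, idx):
    n1, m1, _, n2, m2, _ = group_stats(ds, idx)
    return m1 - m2


def split_points(x):
    xs = sorted(set(float(v) for v in x))
    return [(a + b) / 2 for a, b in zip(xs, xs[1:])]


def criterion(ds, leaves, labels, control):
    """C evaluated directly from the raw rows; None if inadmissible."""
    if "P1" not in labels or "P2" not in labels:
        return None
    for idx, lab in zip(leaves, labels):
        d = mean_diff(ds, idx)
        if lab == "P1" and not d > 0:
            return None
        if lab == "P2" and not d < 0:
            return None
    total = 0.0
    for lab in ("P1", "P2"):
        members = [i for idx, l in zip(leaves, labels) if l == lab for i in idx]
        if control.crit == "effect_size":
            e = pooled_d(ds, members)
            if e is None:
                return None
        else:
            e = mean_diff(ds, members)
        total += control.w1 * math.log(1 + abs(e))
        total += control.w2 * math.log(len(members))
    return total


@dataclass
class OracleBest:
    node_id: int
    covariate_index: int
    threshold: float
    labels: tuple
    C: float


def oracle_best_split(ds, leaf_nodes, control, current_C=None):
    """Exhaustive scan over (node, covariate, split point, assignment).

    ``leaf_nodes`` is the left-to-right list of (node_id, member row array);
    a single entry means this is the first split, which is additionally
    gated on |d| >= dmin with opposite signs in the two children.
    """
    first = len(leaf_nodes) == 1
    cands = []
    for pos, (node_id, idx) in enumerate(leaf_nodes):
        idx = np.asarray(idx)
        for j in range(ds.J):
            for thr in split_points(ds.X[idx, j]):
                left = idx[ds.X[idx, j] <= thr]
                right = idx[ds.X[idx, j] > thr]
                cl = group_stats(ds, left)
                cr = group_stats(ds, right)
                if (cl[0] < control.a1 or cr[0] < control.a1
                        or cl[3] < control.a2 or cr[3] < control.a2):
                    continue
                dl, dr = pooled_d(ds, left), pooled_d(ds, right)
                if control.crit == "effect_size" or first:
                    if dl is None or dr is None:
                        continue
                if first and not (abs(dl) >= control.dmin
                                  and abs(dr) >= control.dmin and dl * dr < 0):
                    continue
                leaves = (
                    [a for _, a in leaf_nodes[:pos]]
                    + [left, right]
                    + [a for _, a in leaf_nodes[pos + 1:]]
                )
                for labels in itertools.product(("P1", "P2", "P3"), repeat=len(leaves)):
                    c = criterion(ds, leaves, labels, control)
                    if c is not None:
                        cands.append(OracleBest(node_id, j, thr, labels, c))
    if not cands:
        return None
    cmax = max(c.C for c in cands)
    tied = [c for c in cands if c.C >= cmax - TOL]
    best = min(tied, key=lambda c: (c.covariate_index, c.threshold, c.node_id))
    if current_C is not None and not (best.C > current_C + TOL):
        return None
    return best
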