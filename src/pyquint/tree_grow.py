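"""Sequential binary partitioning: grow the nested tree sequence.

Each step performs an exhaustive search over every current leaf as candidate
parent, every covariate, every candidate split point (midpoints between
consecutive distinct values; rows with value <= split point go left), and —
for the resulting tree — every admissible assignment of *all* leaves to the
subgroups P1/P2/P3.  The quadruple maximizing the criterion C is accepted
when it improves on the current C; growth stops when no admissible candidate
improves C or the maximum number of leaves is reached.

Boundary conditions enforced:

1. qualitative-interaction gate (first split only): both child leaves must
   have |Cohen's d| >= dmin with opposite signs, else no tree is grown;
2. every leaf must keep at least a1 arm-1 and a2 arm-2 members;
3. subgroups P1 and P2 must be nonempty;
4. a leaf can be labeled P1 (P2) only if its arm-1 minus arm-2 mean
   difference is positive (negative).

Nodes use the conventional binary numbering: root 1, children of k are
2k and 2k + 1.

The inner scan works on per-arm prefix sums of y and y^2 in covariate order,
so all split points of one (leaf, covariate) pair are evaluated with a few
vector operations; assignments are enumerated over the sign-compatible label
choices only.  The search is deterministic: ties in C (within 1e-10) are
broken toward the lowest covariate index, then the smallest split point,
then the smallest parent node id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .criterion import C_TOL, Assignment, CriterionValue, criterion_value
from .data_model import ControlParams, RCTDataset
from .effect_measures import P1, P2, P3, LeafStats, leaf_stats
from .errors import DataError, QuintError

_SS_EPS = 1e-10


@dataclass(frozen=True)
class SplitRule:
    covariate_index: int
    covariate_name: str
    threshold: float


@dataclass
class Node:
    """A tree node; ``split`` is None for leaves."""

    id: int
    member_index: np.ndarray
    split: SplitRule | None = None
    stats: LeafStats | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class QuintTree:
    """Binary tree plus the current leaf assignment and criterion value."""

    nodes: dict[int, Node]
    assignment: Assignment | None = None
    criterion: CriterionValue | None = None

    def leaf_ids(self) -> list[int]:
        """Leaf node ids in left-to-right order."""
        out: list[int] = []

        def walk(k: int) -> None:
            node = self.nodes[k]
            if node.is_leaf:
                out.append(k)
            else:
                walk(2 * k)
                walk(2 * k + 1)

        walk(1)
        return out

    def leaves(self) -> list[Node]:
        return [self.nodes[k] for k in self.leaf_ids()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    @property
    def n_splits(self) -> int:
        return self.n_leaves - 1

    def labeled_leaf_stats(self) -> list[LeafStats]:
        """Leaf statistics with the class labels of the current assignment."""
        stats = [ln.stats for ln in self.leaves()]
        if self.assignment is None:
            return list(stats)
        return [replace(st, class_label=lab) for st, lab in zip(stats, self.assignment.labels)]

    def route(self, frame: pd.DataFrame) -> np.ndarray:
        """Leaf position (0-based, left-to-right) for each row of ``frame``.

        ``frame`` must contain every covariate the tree splits on; a missing
        value on a needed splitter raises :class:`DataError` for that row.
        """
        needed = {n.split.covariate_name for n in self.nodes.values() if not n.is_leaf}
        for name in needed:
            if name not in frame.columns:
                raise DataError(f"column {name!r} required for routing is absent")
        leaf_order = {k: i for i, k in enumerate(self.leaf_ids())}
        out = np.empty(len(frame), dtype=int)

        def descend(k: int, rows: np.ndarray) -> None:
            node = self.nodes[k]
            if node.is_leaf:
                out[rows] = leaf_order[k]
                return
            vals = frame[node.split.covariate_name].to_numpy(dtype=float)[rows]
            bad = np.isnan(vals)
            if bad.any():
                raise DataError(
                    f"missing value on splitter {node.split.covariate_name!r} "
                    f"for row(s) {frame.index[rows[bad]].tolist()}"
                )
            go_left = vals <= node.split.threshold
            descend(2 * k, rows[go_left])
            descend(2 * k + 1, rows[~go_left])

        descend(1, np.arange(len(frame)))
        return out


@dataclass(frozen=True)
class SplitCandidate:
    """The maximizing (node, covariate, split point, assignment) quadruple."""

    node_id: int
    covariate_index: int
    threshold: float
    labels: tuple[str, ...]
    C: float


@dataclass
class FitSequence:
    """The nested subtree series produced by :func:`grow`.

    ``trees[i]`` has ``i + 2`` leaves; ``fit_info`` has one entry per size
    (apparent C; bias-corrected C and its se are filled by pruning);
    ``split_info`` one entry per accepted split.
    """

    dataset: RCTDataset
    control: ControlParams
    trees: list[QuintTree] = field(default_factory=list)
    fit_info: list[dict] = field(default_factory=list)
    split_info: list[dict] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def grew(self) -> bool:
        return len(self.trees) > 0

    @property
    def final_tree(self) -> QuintTree:
        if not self.trees:
            raise QuintError("no tree was grown")
        return self.trees[-1]

    def tree_of_size(self, n_leaves: int) -> QuintTree:
        for tr in self.trees:
            if tr.n_leaves == n_leaves:
                return tr
        raise QuintError(f"no subtree with {n_leaves} leaves in the sequence")


def candidate_split_points(x: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values of ``x``."""
    xs = np.unique(np.asarray(x, dtype=float))
    if xs.size < 2:
        return np.empty(0)
    return (xs[:-1] + xs[1:]) / 2.0


def split_admissible(left: LeafStats, right: LeafStats, control: ControlParams) -> bool:
    """Minimum per-arm leaf sizes, plus non-degenerate pooled variance under
    the effect-size criterion."""
    counts_ok = (
        left.arm1.n >= control.a1
        and right.arm1.n >= control.a1
        and left.arm2.n >= control.a2
        and right.arm2.n >= control.a2
    )
    if not counts_ok:
        return False
    if control.crit == "effect_size" and (left.degenerate or right.degenerate):
        return False
    return True


def first_split_qualifies(left: LeafStats, right: LeafStats, dmin: float) -> bool:
    """Qualitative-interaction gate: |d| >= dmin in both leaves, opposite
    signs.  Always evaluated on Cohen's d, whatever the criterion."""
    if left.degenerate or right.degenerate:
        return False
    return abs(left.d) >= dmin and abs(right.d) >= dmin and left.d * right.d < 0


def _leaf_suff(dataset: RCTDataset, idx: np.ndarray, y0: np.ndarray) -> tuple:
    """Per-arm (n, sum, sumsq) of centered outcome plus total n and diff."""
    t = dataset.t[idx]
    y = y0[idx]
    m1, m2 = t == 1, t == 2
    n1, n2 = int(m1.sum()), int(m2.sum())
    s1, s2 = float(y[m1].sum()), float(y[m2].sum())
    q1, q2 = float((y[m1] ** 2).sum()), float((y[m2] ** 2).sum())
    diff = s1 / n1 - s2 / n2
    return n1, s1, q1, n2, s2, q2, diff


def best_split(
    dataset: RCTDataset, tree: QuintTree, control: ControlParams
) -> SplitCandidate | None:
    """Exhaustive search for the best admissible next split.

    Returns the maximizing quadruple together with the criterion value of
    the resulting tree, or None when no admissible candidate improves on the
    current tree's C.  When ``tree`` is the bare root this is the first
    split, additionally gated by :func:`first_split_qualifies`.
    """
    leaves = tree.leaves()
    first = len(leaves) == 1
    current_C = tree.criterion.C if tree.criterion is not None else None
    # centering y per dataset removes cancellation error in the prefix-sum
    # variance algebra without changing means differences, SDs or d
    y0 = dataset.y - dataset.y.mean()

    suffs = [_leaf_suff(dataset, ln.member_index, y0) for ln in leaves]
    es = control.crit == "effect_size"
    best: SplitCandidate | None = None

    for pos, parent in enumerate(leaves):
        idx = parent.member_index
        others = [suffs[i] for i in range(len(leaves)) if i != pos]
        # label options for the unchanged leaves, by sign of their mean diff
        other_opts = []
        for (_, _, _, _, _, _, diff) in others:
            if diff > 0:
                other_opts.append((P1, P3))
            elif diff < 0:
                other_opts.append((P2, P3))
            else:
                other_opts.append((P3,))

        pn1, ps1, pq1, pn2, ps2, pq2, _ = suffs[pos]
        t = dataset.t[idx]
        y = y0[idx]
        for j in range(dataset.J):
            x = dataset.X[idx, j]
            order = np.argsort(x, kind="stable")
            xs = x[order]
            cut = np.flatnonzero(xs[:-1] < xs[1:])  # last index of each left block
            if cut.size == 0:
                continue
            thr = (xs[cut] + xs[cut + 1]) / 2.0
            ys, ts = y[order], t[order]
            is1 = ts == 1
            c1n = np.cumsum(is1)[cut].astype(float)
            c1s = np.cumsum(np.where(is1, ys, 0.0))[cut]
            c1q = np.cumsum(np.where(is1, ys * ys, 0.0))[cut]
            cn = cut + 1.0
            c2n = cn - c1n
            c2s = np.cumsum(ys)[cut] - c1s
            c2q = np.cumsum(ys * ys)[cut] - c1q

            ln1, ls1, lq1 = c1n, c1s, c1q
            ln2, ls2, lq2 = c2n, c2s, c2q
            rn1, rs1, rq1 = pn1 - ln1, ps1 - ls1, pq1 - lq1
            rn2, rs2, rq2 = pn2 - ln2, ps2 - ls2, pq2 - lq2

            adm = (
                (ln1 >= control.a1)
                & (rn1 >= control.a1)
                & (ln2 >= control.a2)
                & (rn2 >= control.a2)
            )
            if not adm.any():
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                lm1, lm2 = ls1 / ln1, ls2 / ln2
                rm1, rm2 = rs1 / rn1, rs2 / rn2
                diff_l = lm1 - lm2
                diff_r = rm1 - rm2
                ss_l = (lq1 - ls1 * lm1) + (lq2 - ls2 * lm2)
                ss_r = (rq1 - rs1 * rm1) + (rq2 - rs2 * rm2)
                scale = max(1.0, pq1 + pq2)
                if es or first:
                    adm = adm & (ss_l > _SS_EPS * scale) & (ss_r > _SS_EPS * scale)
                if first:
                    nl, nr = ln1 + ln2, rn1 + rn2
                    d_l = diff_l / np.sqrt(ss_l / (nl - 2))
                    d_r = diff_r / np.sqrt(ss_r / (nr - 2))
                    adm = adm & (
                        (np.abs(d_l) >= control.dmin)
                        & (np.abs(d_r) >= control.dmin)
                        & (d_l * d_r < 0)
                    )
            if not adm.any():
                continue

            for fixed in itertools.product(*other_opts):
                f = {
                    P1: [0.0] * 7,  # n1, s1, q1, n2, s2, q2, ntot
                    P2: [0.0] * 7,
                }
                for lab, (on1, os1, oq1, on2, os2, oq2, _) in zip(fixed, others):
                    if lab in f:
                        acc = f[lab]
                        acc[0] += on1
                        acc[1] += os1
                        acc[2] += oq1
                        acc[3] += on2
                        acc[4] += os2
                        acc[5] += oq2
                        acc[6] += on1 + on2
                for lab_l, lab_r in itertools.product((P1, P2, P3), repeat=2):
                    if f[P1][6] == 0 and P1 not in (lab_l, lab_r):
                        continue
                    if f[P2][6] == 0 and P2 not in (lab_l, lab_r):
                        continue
                    valid = adm.copy()
                    if lab_l == P1:
                        valid &= diff_l > 0
                    elif lab_l == P2:
                        valid &= diff_l < 0
                    if lab_r == P1:
                        valid &= diff_r > 0
                    elif lab_r == P2:
                        valid &= diff_r < 0
                    if not valid.any():
                        continue
                    comp = 0.0
                    card = 0.0
                    ok = valid
                    for lab in (P1, P2):
                        fn1, fs1, fq1, fn2, fs2, fq2, fnt = f[lab]
                        N1 = fn1 + (ln1 if lab_l == lab else 0) + (rn1 if lab_r == lab else 0)
                        S1 = fs1 + (ls1 if lab_l == lab else 0) + (rs1 if lab_r == lab else 0)
                        N2 = fn2 + (ln2 if lab_l == lab else 0) + (rn2 if lab_r == lab else 0)
                        S2 = fs2 + (ls2 if lab_l == lab else 0) + (rs2 if lab_r == lab else 0)
                        NT = fnt + ((ln1 + ln2) if lab_l == lab else 0) + (
                            (rn1 + rn2) if lab_r == lab else 0
                        )
                        with np.errstate(divide="ignore", invalid="ignore"):
                            E = S1 / N1 - S2 / N2
                            if es:
                                Q1 = fq1 + (lq1 if lab_l == lab else 0) + (
                                    rq1 if lab_r == lab else 0
                                )
                                Q2 = fq2 + (lq2 if lab_l == lab else 0) + (
                                    rq2 if lab_r == lab else 0
                                )
                                SS = (Q1 - S1 * S1 / N1) + (Q2 - S2 * S2 / N2)
                                dof = N1 + N2 - 2
                                ok = ok & (dof > 0) & (SS > _SS_EPS * scale)
                                E = E / np.sqrt(SS / np.maximum(dof, 1))
                            comp = comp + np.log1p(np.abs(E))
                            card = card + np.log(np.maximum(NT, 1.0))
                    if not np.any(ok):
                        continue
                    C = control.w1 * comp + control.w2 * card
                    C = np.where(ok, C, -np.inf)
                    i = int(np.argmax(C))
                    c_val = float(C[i])
                    if not np.isfinite(c_val):
                        continue
                    labels = tuple(
                        list(fixed[:pos]) + [lab_l, lab_r] + list(fixed[pos:])
                    )
                    cand = SplitCandidate(
                        node_id=parent.id,
                        covariate_index=j,
                        threshold=float(thr[i]),
                        labels=labels,
                        C=c_val,
                    )
                    best = _prefer(best, cand)

    if best is None:
        return None
    if current_C is not None and not (best.C > current_C + C_TOL):
        return None
    return best


def _prefer(best: SplitCandidate | None, cand: SplitCandidate) -> SplitCandidate:
    if best is None:
        return cand
    if cand.C > best.C + C_TOL:
        return cand
    if cand.C < best.C - C_TOL:
        return best
    key = (cand.covariate_index, cand.threshold, cand.node_id)
    best_key = (best.covariate_index, best.threshold, best.node_id)
    return cand if key < best_key else best


def _apply_split(
    dataset: RCTDataset, tree: QuintTree, cand: SplitCandidate, control: ControlParams
) -> QuintTree:
    parent = tree.nodes[cand.node_id]
    x = dataset.X[parent.member_index, cand.covariate_index]
    go_left = x <= cand.threshold
    left_idx = parent.member_index[go_left]
    right_idx = parent.member_index[~go_left]
    rule = SplitRule(
        covariate_index=cand.covariate_index,
        covariate_name=dataset.covariate_names[cand.covariate_index],
        threshold=cand.threshold,
    )
    nodes = dict(tree.nodes)
    nodes[cand.node_id] = Node(
        id=cand.node_id, member_index=parent.member_index, split=rule, stats=parent.stats
    )
    k = cand.node_id
    nodes[2 * k] = Node(id=2 * k, member_index=left_idx, stats=leaf_stats(dataset, left_idx))
    nodes[2 * k + 1] = Node(
        id=2 * k + 1, member_index=right_idx, stats=leaf_stats(dataset, right_idx)
    )
    new_tree = QuintTree(nodes=nodes)
    assignment = Assignment(labels=cand.labels)
    leaves = [nodes[i].member_index for i in new_tree.leaf_ids()]
    new_tree.assignment = assignment
    new_tree.criterion = criterion_value(dataset, leaves, assignment, control)
    return new_tree


def grow(dataset: RCTDataset, control: ControlParams) -> FitSequence:
    """Grow the full nested tree sequence.

    If no admissible first split passes the qualitative-interaction gate the
    result carries ``stop_reason = "no qualitative interaction"`` and an
    empty tree list — a finding, not an error.
    """
    root_idx = np.arange(dataset.n)
    root = Node(id=1, member_index=root_idx, stats=leaf_stats(dataset, root_idx))
    tree = QuintTree(nodes={1: root})
    fit = FitSequence(dataset=dataset, control=control)

    while True:
        if tree.n_leaves >= control.maxl:
            fit.stop_reason = "maximum number of leaves reached"
            break
        cand = best_split(dataset, tree, control)
        if cand is None:
            fit.stop_reason = (
                "no qualitative interaction"
                if tree.n_leaves == 1
                else "no admissible split improves the criterion"
            )
            break
        prev_leaves = tree.n_leaves
        tree = _apply_split(dataset, tree, cand, control)
        fit.trees.append(tree)
        fit.fit_info.append(
            {
                "size": tree.n_leaves,
                "n_splits": tree.n_splits,
                "apparent_C": tree.criterion.C,
            }
        )
        fit.split_info.append(
            {
                "split": prev_leaves,
                "parent_node": cand.node_id,
                "child_nodes": (2 * cand.node_id, 2 * cand.node_id + 1),
                "covariate": dataset.covariate_names[cand.covariate_index],
                "split_point": cand.threshold,
            }
        )
    return fit


def assign_new(tree: QuintTree, covariate_rows: pd.DataFrame) -> list[tuple[str, str]]:
    """Route new rows down the tree; returns ``(leaf label, class label)``
    per row, with leaves labeled "Leaf 1".."Leaf L" left to right."""
    if tree.assignment is None:
        raise QuintError("tree has no leaf assignment")
    if not isinstance(covariate_rows, pd.DataFrame):
        covariate_rows = pd.DataFrame(covariate_rows)
    pos = tree.route(covariate_rows)
    labels = tree.assignment.labels
    return [(f"Leaf {p + 1}", labels[p]) for p in pos]
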