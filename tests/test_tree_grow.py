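import numpy as np
import pandas as pd
import pytest

from pyquint import (
    ControlParams,
    RCTDataset,
    assign_new,
    best_split,
    candidate_split_points,
    first_split_qualifies,
    grow,
    resolve_control,
    split_admissible,
)
from pyquint.effect_measures import ArmSummary, LeafStats
from pyquint.tree_grow import Node, QuintTree
from pyquint.effect_measures import leaf_stats

from conftest import make_dataset, random_dataset
from _oracle import oracle_best_split


def _leaf(n1, n2, d=0.5, sd=1.0):
    return LeafStats(
        arm1=ArmSummary(n1, d, sd), arm2=ArmSummary(n2, 0.0, sd),
        d=d if sd > 0 else float("nan"), se_d=0.3, diff=d,
    )


def _root_tree(ds):
    idx = np.arange(ds.n)
    return QuintTree(nodes={1: Node(id=1, member_index=idx, stats=leaf_stats(ds, idx))})


class TestCandidateSplitPoints:
    def test_midpoints(self):
        np.testing.assert_allclose(candidate_split_points([1, 2, 3]), [1.5, 2.5])

    def test_dichotomous(self):
        np.testing.assert_allclose(candidate_split_points([0, 1, 0, 1]), [0.5])

    def test_integer_scale_half_points(self):
        pts = candidate_split_points(np.arange(15, 25))
        assert 18.5 in pts  # integer scales split on half-integers

    def test_constant_column_empty(self):
        assert candidate_split_points([2.0, 2.0, 2.0]).size == 0


class TestSplitAdmissible:
    def test_count_below_minimum(self):
        ctl = ControlParams(a1=10, a2=10)
        assert not split_admissible(_leaf(9, 12), _leaf(15, 15), ctl)

    def test_all_counts_ok(self):
        ctl = ControlParams(a1=10, a2=10)
        assert split_admissible(_leaf(10, 10), _leaf(15, 15), ctl)

    def test_constant_outcome_leaf_inadmissible_under_es(self):
        degen = _leaf(10, 10, d=0.0, sd=0.0)
        ctl = ControlParams(a1=5, a2=5, crit="effect_size")
        assert not split_admissible(degen, _leaf(10, 10), ctl)
        ctl_dm = ControlParams(a1=5, a2=5, crit="difference_in_means")
        assert split_admissible(degen, _leaf(10, 10), ctl_dm)


class TestFirstSplitQualifies:
    @pytest.mark.parametrize(
        "dl, dr, dmin, expected",
        [
            (0.45, -0.62, 0.30, True),
            (0.45, 0.62, 0.30, False),  # same sign: no qualitative interaction
            (0.35, -0.35, 0.40, False),  # below the raised threshold
            (0.30, -0.30, 0.30, True),  # boundary read inclusively
        ],
    )
    def test_gate(self, dl, dr, dmin, expected):
        assert first_split_qualifies(_leaf(10, 10, dl), _leaf(10, 10, dr), dmin) is expected


class TestBestSplitAgainstOracle:
    def _ctl(self, ds, dmin):
        return resolve_control(ds, dmin=dmin, bootstrap=False, a1=3, a2=3)

    @pytest.mark.parametrize("seed", range(12))
    def test_first_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng)
        ctl = self._ctl(ds, dmin=0.0 if seed % 2 else 0.30)
        got = best_split(ds, _root_tree(ds), ctl)
        want = oracle_best_split(ds, [(1, np.arange(ds.n))], ctl)
        if want is None:
            assert got is None
            return
        assert got is not None
        assert (got.node_id, got.covariate_index) == (want.node_id, want.covariate_index)
        assert got.threshold == want.threshold
        assert got.labels == want.labels
        assert got.C == pytest.approx(want.C, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_second_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds = random_dataset(rng, n=40)
        ctl = self._ctl(ds, dmin=0.0)
        fit = grow(ds, ctl.with_(maxl=2))
        if not fit.grew:
            pytest.skip("no admissible first split in this draw")
        tree = fit.final_tree
        got = best_split(ds, tree, ctl.with_(maxl=3))
        leaf_nodes = [(k, tree.nodes[k].member_index) for k in tree.leaf_ids()]
        want = oracle_best_split(ds, leaf_nodes, ctl, current_C=tree.criterion.C)
        if want is None:
            assert got is None
            return
        assert got is not None
        assert (got.node_id, got.covariate_index, got.labels) == (
            want.node_id, want.covariate_index, want.labels
        )
        assert got.threshold == want.threshold
        assert got.C == pytest.approx(want.C, abs=1e-9)

    def test_planted_covariate_selected(self):
        ds = make_dataset(n=60, J=3, seed=4)
        ctl = resolve_control(ds, bootstrap=False)
        got = best_split(ds, _root_tree(ds), ctl)
        assert got is not None and got.covariate_index == 0

    def test_all_constant_covariates_yield_none(self):
        ds = make_dataset(n=30, seed=1)
        flat = RCTDataset(
            y=ds.y, t=ds.t, X=np.zeros_like(ds.X), covariate_names=ds.covariate_names
        )
        ctl = resolve_control(flat, bootstrap=False)
        assert best_split(flat, _root_tree(flat), ctl) is None


class TestGrow:
    def test_maxl_caps_tree_size(self, planted_dataset):
        ctl = resolve_control(planted_dataset, maxl=3, bootstrap=False)
        fit = grow(planted_dataset, ctl)
        assert fit.final_tree.n_leaves <= 3

    def test_gate_violation_grows_no_tree(self):
        ds = make_dataset(n=200, seed=2, effect_left=0.2, effect_right=0.2)
        ctl = resolve_control(ds, dmin=0.40, bootstrap=False)
        fit = grow(ds, ctl)
        assert not fit.grew
        assert fit.stop_reason == "no qualitative interaction"

    def test_apparent_c_strictly_increases(self, planted_dataset):
        ctl = resolve_control(planted_dataset, maxl=6, bootstrap=False)
        fit = grow(planted_dataset, ctl)
        cs = [row["apparent_C"] for row in fit.fit_info]
        assert all(b > a for a, b in zip(cs, cs[1:]))

    def test_deterministic(self, planted_dataset):
        ctl = resolve_control(planted_dataset, maxl=5, bootstrap=False)
        a = grow(planted_dataset, ctl)
        b = grow(planted_dataset, ctl)
        assert [t.n_leaves for t in a.trees] == [t.n_leaves for t in b.trees]
        assert a.split_info == b.split_info
        assert [t.assignment.labels for t in a.trees] == [
            t.assignment.labels for t in b.trees
        ]

    def test_trees_nested_and_partition_preserved(self, planted_dataset):
        ds = planted_dataset
        ctl = resolve_control(ds, maxl=6, bootstrap=False)
        fit = grow(ds, ctl)
        for tree in fit.trees:
            members = np.concatenate([n.member_index for n in tree.leaves()])
            assert sorted(members.tolist()) == list(range(ds.n))
        for smaller, larger in zip(fit.trees, fit.trees[1:]):
            assert larger.n_leaves == smaller.n_leaves + 1
            smaller_splits = {
                (k, n.split.covariate_index, n.split.threshold)
                for k, n in smaller.nodes.items() if not n.is_leaf
            }
            larger_splits = {
                (k, n.split.covariate_index, n.split.threshold)
                for k, n in larger.nodes.items() if not n.is_leaf
            }
            assert smaller_splits <= larger_splits

    def test_boundary_conditions_hold_post_hoc(self, planted_dataset):
        ds = planted_dataset
        ctl = resolve_control(ds, maxl=6, bootstrap=False)
        fit = grow(ds, ctl)
        for tree in fit.trees:
            labels = tree.assignment.labels
            assert "P1" in labels and "P2" in labels
            for st, lab in zip(tree.labeled_leaf_stats(), labels):
                assert st.arm1.n >= ctl.a1 and st.arm2.n >= ctl.a2
                if lab == "P1":
                    assert st.diff > 0
                if lab == "P2":
                    assert st.diff < 0
            # gate on the first split of the sequence
            first = fit.trees[0]
            dl, dr = (st.d for st in first.labeled_leaf_stats())
            assert abs(dl) >= ctl.dmin and abs(dr) >= ctl.dmin and dl * dr < 0


class TestAssignNew:
    def test_boundary_value_goes_left_and_training_rows_reproduce(self, planted_dataset):
        ds = planted_dataset
        ctl = resolve_control(ds, maxl=4, bootstrap=False)
        fit = grow(ds, ctl)
        tree = fit.final_tree
        frame = pd.DataFrame(ds.X, columns=list(ds.covariate_names))
        routed = tree.route(frame)
        for i, node in enumerate(tree.leaves()):
            np.testing.assert_array_equal(
                np.flatnonzero(routed == i), np.sort(node.member_index)
            )
        # a row exactly at the root threshold goes left
        root_rule = tree.nodes[1].split
        probe = pd.DataFrame([{c: 0.0 for c in ds.covariate_names}])
        probe[root_rule.covariate_name] = root_rule.threshold
        # drive all other splitters far left so the path is determined
        leaf_label, cls = assign_new(tree, probe)[0]
        assert cls in {"P1", "P2", "P3"}
        assert int(leaf_label.split()[-1]) <= tree.n_leaves

    def test_missing_splitter_raises(self, planted_dataset):
        ds = planted_dataset
        ctl = resolve_control(ds, maxl=2, bootstrap=False)
        tree = grow(ds, ctl).final_tree
        frame = pd.DataFrame(ds.X[:3], columns=list(ds.covariate_names))
        frame.iloc[1, tree.nodes[1].split.covariate_index] = np.nan
        with pytest.raises(Exception):
            assign_new(tree, frame)

    def test_two_leaf_routing(self, planted_dataset):
        ds = planted_dataset
        ctl = resolve_control(ds, maxl=2, bootstrap=False)
        tree = grow(ds, ctl).final_tree
        rule = tree.nodes[1].split
        below = {c: 0.0 for c in ds.covariate_names}
        below[rule.covariate_name] = rule.threshold - 1.0
        above = dict(below, **{rule.covariate_name: rule.threshold + 1.0})
        out = assign_new(tree, pd.DataFrame([below, above]))
        assert out[0][0] == "Leaf 1" and out[1][0] == "Leaf 2"
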