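"""Summaries, serialization and the command-line interface.

``summarize`` assembles the fit / split / leaf information tables of a
grown or pruned tree; ``export_tree`` serializes a tree to JSON (lossless,
re-importable with ``tree_from_dict``) or to Graphviz DOT text in which P1
leaves are green, P2 leaves red and P3 leaves grey, with Cohen's d and its
95% confidence interval printed in each leaf.

The CLI is a thin layer over the library: ``fit`` / ``prune`` / ``summary``
/ ``predict`` / ``simulate``.  Exit codes: 0 ok (including the legitimate
"no tree grown" finding), 1 data or validation error, 2 usage error.
"""

from __future__ import annotations

import dataclasses
import json
import sys

import click
import numpy as np
import pandas as pd

from . import pruning as pruning_mod
from .criterion import Assignment, CriterionValue
from .data_model import (
    ControlParams,
    RCTDataset,
    build_dataset,
    parse_formula,
    read_csv,
    resolve_control,
)
from .effect_measures import LeafStats, ArmSummary
from .errors import QuintError
from .pruning import PrunedFit, prune
from .synthetic import ScenarioSpec, write_scenario
from .tree_grow import FitSequence, Node, QuintTree, SplitRule, assign_new, grow


@dataclasses.dataclass
class SummaryBundle:
    """Header plus the three tables a fitted tree is reported with."""

    header: dict
    fit_info: pd.DataFrame
    split_info: pd.DataFrame
    leaf_info: pd.DataFrame

    def format_text(self) -> str:
        crit_name = {
            "effect_size": "Effect size criterion",
            "difference_in_means": "Difference in means criterion",
        }[self.header["criterion"]]
        lines = [f"Partitioning criterion: {crit_name}"]
        tmap = self.header.get("treatment_label_map") or {}
        for orig, code in tmap.items():
            lines.append(f"Treatment code T={code} corresponds to category {orig!r}")
        lines.append(f"Number of observations used: {self.header['n']}")
        if self.header.get("stop_reason"):
            lines.append(f"Stopped because: {self.header['stop_reason']}")
        for w in self.header.get("warnings", []):
            lines.append(f"Warning: {w}")
        lines += ["", "Fit information:", _round2(self.fit_info).to_string(index=False)]
        lines += ["", "Split information:", _round2(self.split_info).to_string(index=False)]
        lines += ["", "Leaf information:", _round2(self.leaf_info).to_string(index=False)]
        return "\n".join(lines)


def _round2(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(2)
    return out


def summarize(fit: FitSequence | PrunedFit) -> SummaryBundle:
    """Fit / split / leaf information of a grown or pruned tree.

    Displayed numbers are rounded to two decimals by ``format_text``; the
    tables themselves keep full precision.
    """
    if isinstance(fit, PrunedFit):
        seq = fit.sequence
        tree = fit.tree
        info_rows = fit.fit_info
        warnings = list(fit.warnings)
        shown_sizes = {r["size"] for r in info_rows if r["size"] <= fit.selected_size}
    else:
        seq = fit
        tree = seq.final_tree
        info_rows = [
            dict(r, bias_corrected_C=None, se=None) for r in seq.fit_info
        ]
        warnings = []
        shown_sizes = {r["size"] for r in info_rows}

    fit_tbl = pd.DataFrame(
        [
            {
                "split": r["n_splits"],
                "leaves": r["size"],
                "apparent_C": r["apparent_C"],
                "bias_corrected_C": r.get("bias_corrected_C"),
                "se": r.get("se"),
            }
            for r in info_rows
        ]
    )
    split_tbl = pd.DataFrame(
        [
            dict(r, child_nodes=str(r["child_nodes"]))
            for r in seq.split_info
            if r["split"] + 1 in shown_sizes
        ]
    )
    leaf_rows = []
    for i, (node, st) in enumerate(zip(tree.leaves(), tree.labeled_leaf_stats())):
        leaf_rows.append(
            {
                "leaf": f"Leaf {i + 1}",
                "node": node.id,
                "n_T1": st.arm1.n,
                "mean_T1": st.arm1.mean,
                "sd_T1": st.arm1.sd,
                "n_T2": st.arm2.n,
                "mean_T2": st.arm2.mean,
                "sd_T2": st.arm2.sd,
                "d": st.d,
                "se": st.se_d,
                "class": st.class_label,
            }
        )
    header = {
        "criterion": seq.control.crit,
        "treatment_label_map": seq.dataset.treatment_label_map,
        "n": seq.dataset.n,
        "stop_reason": seq.stop_reason,
        "warnings": warnings,
    }
    return SummaryBundle(
        header=header,
        fit_info=fit_tbl,
        split_info=split_tbl,
        leaf_info=pd.DataFrame(leaf_rows),
    )


# ---------------------------------------------------------------------------
# serialization

_LEAF_COLORS = {"P1": "palegreen", "P2": "lightcoral", "P3": "lightgrey"}


def tree_to_dict(tree: QuintTree) -> dict:
    nodes = []
    for k in sorted(tree.nodes):
        node = tree.nodes[k]
        entry: dict = {"id": k, "member_index": node.member_index.tolist()}
        if node.split is not None:
            entry["split"] = dataclasses.asdict(node.split)
        if node.stats is not None:
            entry["stats"] = _stats_to_dict(node.stats)
        nodes.append(entry)
    out = {"nodes": nodes}
    if tree.assignment is not None:
        out["assignment"] = list(tree.assignment.labels)
    if tree.criterion is not None:
        out["criterion"] = dataclasses.asdict(tree.criterion)
    return out


def tree_from_dict(payload: dict) -> QuintTree:
    nodes = {}
    for entry in payload["nodes"]:
        split = SplitRule(**entry["split"]) if "split" in entry else None
        stats = _stats_from_dict(entry["stats"]) if "stats" in entry else None
        nodes[entry["id"]] = Node(
            id=entry["id"],
            member_index=np.asarray(entry["member_index"], dtype=int),
            split=split,
            stats=stats,
        )
    tree = QuintTree(nodes=nodes)
    if "assignment" in payload:
        tree.assignment = Assignment(labels=tuple(payload["assignment"]))
    if "criterion" in payload:
        tree.criterion = CriterionValue(**payload["criterion"])
    return tree


def _stats_to_dict(st: LeafStats) -> dict:
    return {
        "arm1": dataclasses.asdict(st.arm1),
        "arm2": dataclasses.asdict(st.arm2),
        "d": st.d,
        "se_d": st.se_d,
        "diff": st.diff,
        "class_label": st.class_label,
    }


def _stats_from_dict(payload: dict) -> LeafStats:
    return LeafStats(
        arm1=ArmSummary(**payload["arm1"]),
        arm2=ArmSummary(**payload["arm2"]),
        d=payload["d"],
        se_d=payload["se_d"],
        diff=payload["diff"],
        class_label=payload["class_label"],
    )


def export_tree(tree: QuintTree, format: str = "json") -> str:
    """Serialize a tree as JSON (lossless) or Graphviz DOT text."""
    if format == "json":
        return json.dumps(tree_to_dict(tree), indent=2)
    if format == "dot":
        return _to_dot(tree)
    raise QuintError(f"unknown export format {format!r} (expected 'json' or 'dot')")


def _to_dot(tree: QuintTree) -> str:
    labels = tree.assignment.labels if tree.assignment is not None else None
    leaf_order = {k: i for i, k in enumerate(tree.leaf_ids())}
    lines = ["digraph quint_tree {", "  node [fontname=Helvetica];"]
    for k in sorted(tree.nodes):
        node = tree.nodes[k]
        if node.is_leaf:
            i = leaf_order[k]
            st = node.stats
            cls = labels[i] if labels is not None else "unassigned"
            lo, hi = st.ci95()
            label = (
                f"Leaf {i + 1} ({cls})\\nd = {st.d:.2f} "
                f"[{lo:.2f}, {hi:.2f}]\\nn = {st.n}"
            )
            color = _LEAF_COLORS.get(cls, "white")
            lines.append(
                f'  n{k} [shape=box, style=filled, fillcolor="{color}", label="{label}"];'
            )
        else:
            lines.append(f'  n{k} [shape=ellipse, label="{node.split.covariate_name}"];')
            v = node.split.threshold
            lines.append(f'  n{k} -> n{2 * k} [label="<= {v:g}"];')
            lines.append(f'  n{k} -> n{2 * k + 1} [label="> {v:g}"];')
    lines.append("}")
    return "\n".join(lines)


def dataset_to_dict(ds: RCTDataset) -> dict:
    return {
        "y": ds.y.tolist(),
        "t": ds.t.tolist(),
        "X": ds.X.tolist(),
        "covariate_names": list(ds.covariate_names),
        "treatment_label_map": {str(k): v for k, v in ds.treatment_label_map.items()},
    }


def dataset_from_dict(payload: dict) -> RCTDataset:
    return RCTDataset(
        y=np.asarray(payload["y"], dtype=float),
        t=np.asarray(payload["t"], dtype=int),
        X=np.asarray(payload["X"], dtype=float),
        covariate_names=tuple(payload["covariate_names"]),
        treatment_label_map=dict(payload["treatment_label_map"]),
    )


def sequence_to_dict(fit: FitSequence) -> dict:
    return {
        "dataset": dataset_to_dict(fit.dataset),
        "control": dataclasses.asdict(fit.control),
        "trees": [tree_to_dict(t) for t in fit.trees],
        "fit_info": fit.fit_info,
        "split_info": [dict(r, child_nodes=list(r["child_nodes"])) for r in fit.split_info],
        "stop_reason": fit.stop_reason,
    }


def sequence_from_dict(payload: dict) -> FitSequence:
    ds = dataset_from_dict(payload["dataset"])
    control = ControlParams(**payload["control"])
    fit = FitSequence(
        dataset=ds,
        control=control,
        trees=[tree_from_dict(t) for t in payload["trees"]],
        fit_info=payload["fit_info"],
        split_info=[
            dict(r, child_nodes=tuple(r["child_nodes"])) for r in payload["split_info"]
        ],
        stop_reason=payload["stop_reason"],
    )
    return fit


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli() -> None:
    """Qualitative interaction trees for two-arm randomized trials."""


def _handle(fn):
    import functools

    @functools.wraps(fn)
    def wrapper(*args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except QuintError as exc:
            click.echo(f"error: {exc}", err=True)
            sys.exit(1)

    return wrapper


@cli.command()
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--formula", required=True,
              help='Variable roles, e.g. "y ~ trt | x1 + x2". The outcome may be '
                   'a change score "(post - pre)"; construct it so that higher = better.')
@click.option("--arms", default=None, help="Two treatment categories, comma-separated.")
@click.option("--crit", default="es", type=click.Choice(["es", "dm"]))
@click.option("--maxl", default=10, show_default=True)
@click.option("--dmin", default=0.30, show_default=True)
@click.option("--a1", default=None, type=int)
@click.option("--a2", default=None, type=int)
@click.option("--w", default=None, help="Component weights w1,w2 (override defaults).")
@click.option("--boot/--no-boot", "bootstrap", default=True, show_default=True)
@click.option("--B", "n_boot", default=25, show_default=True)
@click.option("--seed", default=None, type=int)
@click.option("--out", "out_path", default=None, type=click.Path())
@_handle
def fit(data_path, formula, arms, crit, maxl, dmin, a1, a2, w, bootstrap, n_boot, seed, out_path):
    """Grow the full tree sequence on a CSV trial table."""
    table = read_csv(data_path)
    spec = parse_formula(formula)
    arm_list = _parse_arms(arms, table, spec) if arms else None
    ds = build_dataset(table, spec, arms=arm_list)
    for orig, code in ds.treatment_label_map.items():
        click.echo(f"Treatment code T={code} corresponds to category {orig!r}")
    click.echo(f"Observations used after listwise deletion: {ds.n}")
    if ds.missingness:
        click.echo(f"Missing values among dropped rows, per variable: {ds.missingness}")
    weights = tuple(float(v) for v in w.split(",")) if w else None
    control = resolve_control(
        ds, crit=crit, w=weights, maxl=maxl, dmin=dmin, a1=a1, a2=a2,
        bootstrap=bootstrap, B=n_boot, seed=seed,
    )
    click.echo(
        f"Control: crit={control.crit}, w=({control.w1:.4f}, {control.w2:.4f}), "
        f"maxl={control.maxl}, dmin={control.dmin}, a1={control.a1}, a2={control.a2}, "
        f"bootstrap={control.bootstrap}, B={control.B}"
    )
    sequence = grow(ds, control)
    if not sequence.grew:
        click.echo(
            "qualitative interaction condition violated; no tree grown "
            "(the data show no admissible first split with |d| >= dmin on both sides)"
        )
    else:
        click.echo(f"Grew {sequence.final_tree.n_splits} split(s); "
                   f"stopped because: {sequence.stop_reason}")
    if out_path:
        with open(out_path, "w") as fh:
            json.dump({"kind": "fit", "sequence": sequence_to_dict(sequence)}, fh)
        click.echo(f"Wrote {out_path}")


def _parse_arms(arms: str, table: pd.DataFrame, spec) -> list:
    raw = [a.strip() for a in arms.split(",")]
    col = table[spec.treatment_name]
    if pd.api.types.is_numeric_dtype(col):
        return [type(col.iloc[0])(float(a)) if float(a) != int(float(a)) else int(float(a))
                for a in raw]
    return raw


@cli.command("prune")
@click.option("--fit", "fit_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", default=None, type=click.Path())
@_handle
def prune_cmd(fit_path, out_path):
    """Bias-correct a stored fit and select the final tree size."""
    with open(fit_path) as fh:
        payload = json.load(fh)
    sequence = sequence_from_dict(payload["sequence"])
    pruned = prune(sequence, sequence.dataset, sequence.control)
    for warning in pruned.warnings:
        click.echo(f"Warning: {warning}")
    click.echo(f"Selected tree size: {pruned.selected_size} leaves")
    if out_path:
        with open(out_path, "w") as fh:
            json.dump(
                {
                    "kind": "pruned",
                    "sequence": sequence_to_dict(sequence),
                    "selected_size": pruned.selected_size,
                    "fit_info": pruned.fit_info,
                    "warnings": pruned.warnings,
                },
                fh,
            )
        click.echo(f"Wrote {out_path}")


def _load_fit(path) -> FitSequence | PrunedFit:
    with open(path) as fh:
        payload = json.load(fh)
    sequence = sequence_from_dict(payload["sequence"])
    if payload.get("kind") == "pruned":
        return PrunedFit(
            sequence=sequence,
            selected_size=payload["selected_size"],
            fit_info=payload["fit_info"],
            warnings=payload.get("warnings", []),
        )
    return sequence


@cli.command()
@click.option("--fit", "fit_path", required=True, type=click.Path(exists=True))
@_handle
def summary(fit_path):
    """Print fit, split and leaf information of a stored (pruned) fit."""
    fit_obj = _load_fit(fit_path)
    click.echo(summarize(fit_obj).format_text())


@cli.command()
@click.option("--fit", "fit_path", required=True, type=click.Path(exists=True))
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@_handle
def predict(fit_path, data_path, out_path):
    """Assign new rows to leaves and subgroups; writes a CSV."""
    fit_obj = _load_fit(fit_path)
    tree = fit_obj.tree if isinstance(fit_obj, PrunedFit) else fit_obj.final_tree
    table = read_csv(data_path)
    routed = assign_new(tree, table)
    out = table.copy()
    out["leaf"] = [leaf for leaf, _ in routed]
    out["subgroup"] = [cls for _, cls in routed]
    out.to_csv(out_path, index=False)
    click.echo(f"Wrote {out_path}")


@cli.command()
@click.option("--n", default=400, show_default=True)
@click.option("--arm-ratio", default=0.5, show_default=True)
@click.option("--j", "n_cov", default=3, show_default=True)
@click.option("--pattern", default="qualitative",
              type=click.Choice(["null", "quantitative", "qualitative"]), show_default=True)
@click.option("--split-var", default=0, show_default=True)
@click.option("--split-point", default=0.0, show_default=True)
@click.option("--effect-left", default=0.8, show_default=True)
@click.option("--effect-right", default=-0.8, show_default=True)
@click.option("--noise-sd", default=1.0, show_default=True)
@click.option("--seed", default=None, type=int)
@click.option("--out", "out_path", required=True, type=click.Path())
@_handle
def simulate(n, arm_ratio, n_cov, pattern, split_var, split_point,
             effect_left, effect_right, noise_sd, seed, out_path):
    """Write a synthetic trial CSV plus a ground-truth JSON sidecar."""
    if pattern == "null":
        effect_left = effect_right = 0.0
    spec = ScenarioSpec(
        n=n, arm_ratio=arm_ratio, J=n_cov, pattern=pattern, split_var=split_var,
        split_point=split_point, effect_left=effect_left, effect_right=effect_right,
        noise_sd=noise_sd, seed=seed,
    )
    write_scenario(spec, out_path)
    click.echo(f"Wrote {out_path} and {out_path}.json")
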