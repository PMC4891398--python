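"""Bootstrap bias correction of the criterion and one-SE tree-size selection.

The apparent criterion of a grown subtree overstates how well it would do on
new data, because the same rows were used both to search the splits and to
evaluate C.  The correction re-runs the whole growing procedure on B
bootstrap samples; for each tree size L, the "optimism" of a bootstrap run
is its training C minus the C of the *frozen* bootstrap tree (fixed splits,
fixed class labels) re-evaluated on the original data.  The mean optimism
over usable bootstrap runs is subtracted from the apparent C, and the final
size is the smallest one whose bias-corrected C is within one standard error
of the maximum.

Bootstrap samples are drawn stratified by treatment arm by default, so arm
sizes (and the feasibility of the per-arm leaf minima) are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .criterion import CriterionValue
from .data_model import ControlParams, RCTDataset
from .effect_measures import leaf_stats
from .errors import EmptyArmError, DegenerateVarianceError, QuintError
from .tree_grow import FitSequence, QuintTree, grow


@dataclass(frozen=True)
class BootstrapRecord:
    """Optimism bookkeeping for one (bootstrap sample, tree size) pair."""

    sample_id: int
    tree_size: int
    train_C: float
    test_C: float | None
    usable: bool

    @property
    def optimism(self) -> float:
        if not self.usable or self.test_C is None:
            raise QuintError("optimism undefined for an unusable record")
        return self.train_C - self.test_C


@dataclass
class PrunedFit:
    """The selected subtree with per-size fit information.

    ``fit_info`` rows carry size, apparent C, bias-corrected C, its se and
    the number of usable bootstrap records; warnings flag sizes whose
    bootstrap support is thin (a sign of tree instability).
    """

    sequence: FitSequence
    selected_size: int
    fit_info: list[dict]
    warnings: list[str] = field(default_factory=list)
    records: list[BootstrapRecord] = field(default_factory=list)

    @property
    def tree(self) -> QuintTree:
        return self.sequence.tree_of_size(self.selected_size)


def draw_bootstrap(
    dataset: RCTDataset, seed: int | None, sample_id: int, *, stratified: bool = True
) -> RCTDataset:
    """Resample n rows with replacement, by default n1 from arm 1 and n2
    from arm 2; reproducible from ``(seed, sample_id)``."""
    entropy = [sample_id] if seed is None else [seed, sample_id]
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    if stratified:
        rows1 = dataset.arm_rows(1)
        rows2 = dataset.arm_rows(2)
        take = np.concatenate(
            [rng.choice(rows1, size=rows1.size, replace=True),
             rng.choice(rows2, size=rows2.size, replace=True)]
        )
    else:
        take = rng.choice(np.arange(dataset.n), size=dataset.n, replace=True)
    return RCTDataset(
        y=dataset.y[take],
        t=dataset.t[take],
        X=dataset.X[take],
        covariate_names=dataset.covariate_names,
        treatment_label_map=dict(dataset.treatment_label_map),
    )


def project_frozen(
    tree: QuintTree, data: RCTDataset, control: ControlParams
) -> CriterionValue | None:
    """Apply a frozen tree (fixed splits and class labels) to other data and
    re-evaluate C there; None ("unusable") when a subgroup no longer has
    both arms represented, or its pooled variance degenerates under the
    effect-size criterion."""
    if tree.assignment is None:
        raise QuintError("tree has no leaf assignment")
    frame = _covariate_frame(data)
    pos = tree.route(frame)
    n_leaves = tree.n_leaves
    leaves = [np.flatnonzero(pos == i) for i in range(n_leaves)]
    labels = tree.assignment.labels
    # classes must keep both arms; empty leaves are fine as long as their
    # class still has members of each arm
    for lab in ("P1", "P2"):
        members = np.concatenate(
            [leaves[i] for i in range(n_leaves) if labels[i] == lab]
            or [np.empty(0, dtype=int)]
        )
        if members.size == 0:
            return None
        t = data.t[members]
        if not ((t == 1).any() and (t == 2).any()):
            return None
    kept = [i for i in range(n_leaves) if len(leaves[i]) > 0]
    try:
        # leaf-level sign conditions are *not* re-checked: labels are frozen
        return _criterion_frozen(
            data, [leaves[i] for i in kept], tuple(labels[i] for i in kept), control
        )
    except (EmptyArmError, DegenerateVarianceError):
        return None


def _criterion_frozen(data, leaves, labels, control) -> CriterionValue:
    """Criterion with fixed labels, bypassing the sign admissibility check."""
    from .criterion import class_effect

    parts = {}
    for lab in ("P1", "P2"):
        subsets = [leaves[i] for i, l in enumerate(labels) if l == lab]
        e = class_effect(data, subsets, control.crit)
        parts[lab] = (e, int(sum(len(s) for s in subsets)))
    e1, n1 = parts["P1"]
    e2, n2 = parts["P2"]
    diff_comp = control.w1 * (math.log1p(abs(e1)) + math.log1p(abs(e2)))
    card_comp = control.w2 * (math.log(n1) + math.log(n2))
    return CriterionValue(
        C=diff_comp + card_comp,
        diff_component=diff_comp,
        card_component=card_comp,
        class_effect_1=e1,
        class_effect_2=e2,
        n_P1=n1,
        n_P2=n2,
    )


def _covariate_frame(data: RCTDataset):
    import pandas as pd

    return pd.DataFrame(data.X, columns=list(data.covariate_names))


def bootstrap_records(
    fit: FitSequence, dataset: RCTDataset, control: ControlParams
) -> tuple[list[BootstrapRecord], int]:
    """Grow a full sequence on each bootstrap sample and record, per tree
    size present in both sequences, the training C and the frozen-tree test
    C on the original data.  Returns the records and the number of bootstrap
    samples in which no tree was grown (failed qualitative-interaction
    gate)."""
    records: list[BootstrapRecord] = []
    n_failed = 0
    for b in range(1, control.B + 1):
        sample = draw_bootstrap(
            dataset, control.seed, b, stratified=control.stratified_bootstrap
        )
        boot_fit = grow(sample, control)
        if not boot_fit.grew:
            n_failed += 1
            continue
        sizes_orig = {row["size"] for row in fit.fit_info}
        for tr, row in zip(boot_fit.trees, boot_fit.fit_info):
            if row["size"] not in sizes_orig:
                continue
            test = project_frozen(tr, dataset, control)
            records.append(
                BootstrapRecord(
                    sample_id=b,
                    tree_size=row["size"],
                    train_C=row["apparent_C"],
                    test_C=None if test is None else test.C,
                    usable=test is not None,
                )
            )
    return records, n_failed


def summarize_records(
    fit_info: list[dict], records: list[BootstrapRecord], *, se_scaled_by_sqrt_b: bool = True
) -> tuple[list[dict], list[str]]:
    """Fill bias-corrected C and its se into per-size fit rows.

    For each size: bias-corrected C = apparent C - mean optimism over usable
    records; se = sd(optimism) / sqrt(#usable) (or the raw sd when
    ``se_scaled_by_sqrt_b`` is off).  Sizes with fewer than two usable
    records are flagged as unstable.
    """
    out = []
    warnings: list[str] = []
    for row in fit_info:
        size = row["size"]
        opts = [r.optimism for r in records if r.tree_size == size and r.usable]
        new = dict(row)
        new["n_usable"] = len(opts)
        if len(opts) == 0:
            new["bias_corrected_C"] = None
            new["se"] = None
            warnings.append(
                f"size {size}: no usable bootstrap record; bias correction unavailable"
            )
        else:
            mean_opt = float(np.mean(opts))
            new["bias_corrected_C"] = row["apparent_C"] - mean_opt
            if len(opts) == 1:
                new["se"] = 0.0
            else:
                sd = float(np.std(opts, ddof=1))
                new["se"] = sd / math.sqrt(len(opts)) if se_scaled_by_sqrt_b else sd
            if len(opts) < 2:
                warnings.append(
                    f"size {size}: only {len(opts)} usable bootstrap record(s); "
                    "the tree may be unstable from this size on"
                )
        out.append(new)
    return out, warnings


def bias_correct(
    fit: FitSequence, dataset: RCTDataset, control: ControlParams
) -> tuple[list[dict], list[str], list[BootstrapRecord]]:
    """Bootstrap bias correction of a grown sequence's criterion values."""
    if not control.bootstrap:
        raise QuintError("bias correction requires control.bootstrap = True")
    if control.B < 2:
        raise QuintError("bias correction requires B >= 2")
    records, n_failed = bootstrap_records(fit, dataset, control)
    warnings: list[str] = []
    if n_failed:
        warnings.append(
            f"{n_failed} of {control.B} bootstrap samples grew no tree "
            "(qualitative-interaction gate failed there)"
        )
    if not records:
        info = [dict(row, bias_corrected_C=None, se=None, n_usable=0) for row in fit.fit_info]
        warnings.append(
            "every bootstrap sample failed the qualitative-interaction gate; "
            "bias correction unavailable, apparent values only"
        )
        return info, warnings, records
    info, w2 = summarize_records(
        fit.fit_info, records, se_scaled_by_sqrt_b=control.se_scaled_by_sqrt_b
    )
    return info, warnings + w2, records


def select_one_se(fit_info: list[dict]) -> int:
    """One-standard-error rule: among sizes with a bias-corrected C, find the
    maximum; return the smallest size whose bias-corrected C is at least
    that maximum minus the se *at the maximizing size*."""
    usable = [row for row in fit_info if row.get("bias_corrected_C") is not None]
    if not usable:
        raise QuintError("no size has a bias-corrected criterion value")
    best = max(usable, key=lambda r: r["bias_corrected_C"])
    band = best["bias_corrected_C"] - (best["se"] or 0.0)
    for row in sorted(usable, key=lambda r: r["size"]):
        if row["bias_corrected_C"] >= band:
            return int(row["size"])
    return int(best["size"])  # unreachable; the max itself is in the band


def prune(fit: FitSequence, dataset: RCTDataset, control: ControlParams) -> PrunedFit:
    """Bias-correct the sequence and select the final tree size.

    A sequence whose full tree already has two leaves is returned as-is
    (nothing to prune).  With the bootstrap disabled, the full tree is kept
    and the fit information stays apparent-only.
    """
    if not fit.grew:
        raise QuintError("cannot prune: no tree was grown")
    full_size = fit.final_tree.n_leaves
    if full_size == 2:
        info = [dict(row, bias_corrected_C=None, se=None, n_usable=0) for row in fit.fit_info]
        return PrunedFit(sequence=fit, selected_size=2, fit_info=info,
                         warnings=["full tree has two leaves; no pruning needed"])
    if not control.bootstrap:
        info = [dict(row, bias_corrected_C=None, se=None, n_usable=0) for row in fit.fit_info]
        return PrunedFit(
            sequence=fit,
            selected_size=full_size,
            fit_info=info,
            warnings=["bootstrap disabled: full tree kept, no bias correction"],
        )
    info, warnings, records = bias_correct(fit, dataset, control)
    if all(row.get("bias_corrected_C") is None for row in info):
        return PrunedFit(
            sequence=fit, selected_size=full_size, fit_info=info,
            warnings=warnings, records=records,
        )
    selected = select_one_se(info)
    return PrunedFit(
        sequence=fit, selected_size=selected, fit_info=info,
        warnings=warnings, records=records,
    )
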