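"""Input handling: role formulas, outcome construction, data cleaning and
tuning-parameter resolution.

The entry point for most users is :func:`build_dataset`, which turns a raw
trial table plus a formula like ``"y ~ trt | x1 + x2"`` into a validated
:class:`RCTDataset`, and :func:`resolve_control`, which fills in the default
tuning parameters of the partitioning criterion.

Conventions pinned here (they matter for reproducing results):

* all logarithms in the default weight formulas are **natural** logs;
* the interquartile range uses the 25th/75th percentiles with linear
  interpolation;
* the per-arm minimum leaf sizes default to ``ceil(0.10 * arm size)``;
* treatment arms are recoded to codes 1 and 2 in ascending order of the
  original category values, and the mapping is kept on the dataset.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormulaError, ValidationError

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")

#: Canonical names of the two partitioning criteria, with accepted aliases.
CRIT_ALIASES = {
    "es": "effect_size",
    "effect_size": "effect_size",
    "dm": "difference_in_means",
    "difference_in_means": "difference_in_means",
}


@dataclass(frozen=True)
class FormulaSpec:
    """Variable roles extracted from a formula string.

    ``outcome_expr`` is either a single column name or a ``(minuend,
    subtrahend)`` pair for a change score; ``covariate_names`` preserves the
    order written in the formula (used for tie-breaking during the split
    search).
    """

    outcome_expr: str | tuple[str, str]
    treatment_name: str
    covariate_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.covariate_names) < 1:
            raise FormulaError("at least one candidate splitting variable is required")
        dupes = {c for c in self.covariate_names if list(self.covariate_names).count(c) > 1}
        if dupes:
            raise FormulaError(f"duplicate covariate name(s): {sorted(dupes)}")
        if self.treatment_name in self.covariate_names:
            raise FormulaError(
                f"treatment variable {self.treatment_name!r} also listed as covariate"
            )
        outcome_cols = (
            {self.outcome_expr} if isinstance(self.outcome_expr, str) else set(self.outcome_expr)
        )
        # NB: the baseline measurement may appear as a covariate under its own
        # name; only the outcome *expression columns as outcome* are excluded.
        if self.treatment_name in outcome_cols:
            raise FormulaError("treatment variable cannot be part of the outcome expression")

    @property
    def outcome_columns(self) -> tuple[str, ...]:
        if isinstance(self.outcome_expr, str):
            return (self.outcome_expr,)
        return tuple(self.outcome_expr)


def parse_formula(text: str) -> FormulaSpec:
    """Parse ``"Y ~ T | X1 + ... + XJ"`` into a :class:`FormulaSpec`.

    The outcome part is a column name or a difference ``A - B`` (optionally
    wrapped as ``(A - B)`` or ``I(A - B)`` in the style of R model formulas),
    evaluated in the written order.  Whether a higher score means a better
    outcome is the caller's responsibility; construct the difference so that
    it does.
    """
    if text.count("~") != 1:
        raise FormulaError(f"formula must contain exactly one '~': {text!r}")
    if text.count("|") != 1:
        raise FormulaError(f"formula must contain exactly one '|': {text!r}")
    outcome_part, rest = text.split("~")
    treatment_part, cov_part = rest.split("|")

    outcome = _parse_outcome(outcome_part.strip())
    treatment = _require_name(treatment_part.strip(), role="treatment")
    covs = tuple(_require_name(tok.strip(), role="covariate") for tok in cov_part.split("+"))
    return FormulaSpec(outcome_expr=outcome, treatment_name=treatment, covariate_names=covs)


def _parse_outcome(token: str) -> str | tuple[str, str]:
    inner = token
    m = re.fullmatch(r"I\s*\((.*)\)", inner) or re.fullmatch(r"\((.*)\)", inner)
    if m:
        inner = m.group(1).strip()
    if "-" in inner:
        left, _, right = inner.partition("-")
        return (
            _require_name(left.strip(), role="outcome"),
            _require_name(right.strip(), role="outcome"),
        )
    return _require_name(inner, role="outcome")


def _require_name(token: str, *, role: str) -> str:
    if not _NAME_RE.fullmatch(token):
        raise FormulaError(f"invalid {role} name: {token!r}")
    return token


def derive_outcome(table: pd.DataFrame, expr: str | tuple[str, str]) -> pd.Series:
    """Evaluate the outcome expression on a table.

    For a pair ``(a, b)`` the result is the element-wise ``a - b`` in that
    order (e.g. baseline minus follow-up so that a larger drop in a symptom
    score is a larger, better outcome).
    """
    cols = (expr,) if isinstance(expr, str) else expr
    for c in cols:
        if c not in table.columns:
            raise DataError(f"outcome column {c!r} not found in data")
        if not pd.api.types.is_numeric_dtype(table[c]):
            raise DataError(f"outcome column {c!r} is not numeric")
    if isinstance(expr, str):
        return table[expr].astype(float)
    return table[expr[0]].astype(float) - table[expr[1]].astype(float)


@dataclass
class RCTDataset:
    """A cleaned two-arm trial: outcome, arm codes in {1, 2}, covariates.

    ``y`` is on the outcome scale with higher = better; ``X`` is an
    ``n x J`` float matrix whose columns are continuous, ordinal or
    dichotomous.  No missing values anywhere.
    """

    y: np.ndarray
    t: np.ndarray
    X: np.ndarray
    covariate_names: tuple[str, ...]
    treatment_label_map: dict = field(default_factory=dict)
    #: per-variable count of missing values among the dropped rows
    missingness: dict = field(default_factory=dict)
    #: original-category -> 0/1 encodings applied to non-numeric covariates
    covariate_value_maps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataError("covariate matrix must be two-dimensional")
        n = self.y.shape[0]
        if self.t.shape[0] != n or self.X.shape[0] != n:
            raise DataError("y, t and X must have the same number of rows")
        if self.X.shape[1] != len(self.covariate_names):
            raise DataError("covariate_names must match the number of X columns")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise DataError("missing values are not allowed after cleaning")
        codes = set(np.unique(self.t))
        if not codes <= {1, 2} or len(codes) != 2:
            raise DataError("treatment codes must be exactly {1, 2}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n1(self) -> int:
        return int(np.sum(self.t == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.t == 2))

    @property
    def J(self) -> int:
        return self.X.shape[1]

    def arm_rows(self, code: int) -> np.ndarray:
        return np.flatnonzero(self.t == code)

    def to_frame(self, outcome_name: str = "y", treatment_name: str = "t") -> pd.DataFrame:
        """Export as a flat table (outcome, original arm labels, covariates)."""
        inverse = {v: k for k, v in self.treatment_label_map.items()}
        frame = pd.DataFrame({outcome_name: self.y})
        frame[treatment_name] = [inverse.get(c, c) for c in self.t]
        for j, name in enumerate(self.covariate_names):
            frame[name] = self.X[:, j]
        return frame


def build_dataset(
    table: pd.DataFrame,
    spec: FormulaSpec,
    arms: Sequence | None = None,
) -> RCTDataset:
    """Clean a raw table into an :class:`RCTDataset`.

    Rows are restricted to the two requested arm categories (``arms`` may be
    omitted when the treatment column is already dichotomous), then listwise
    deletion removes every row with a missing value on the outcome columns,
    the treatment or any covariate.  Arms are recoded to 1 and 2 in ascending
    order of the original categories; the mapping is stored on the dataset.
    """
    for name in (spec.treatment_name, *spec.covariate_names):
        if name not in table.columns:
            raise DataError(f"column {name!r} not found in data")

    treat_raw = table[spec.treatment_name]
    present = pd.unique(treat_raw.dropna())
    if arms is None:
        if len(present) != 2:
            raise DataError(
                f"treatment column has {len(present)} categories; "
                "select two with the arms argument"
            )
        arms = list(present)
    else:
        arms = list(arms)
        if len(arms) != 2 or arms[0] == arms[1]:
            raise DataError("exactly two distinct arm categories must be selected")
        missing_arms = [a for a in arms if a not in set(present)]
        if missing_arms:
            raise DataError(f"arm categories not present in data: {missing_arms}")

    sub = table[treat_raw.isin(arms)].copy()
    y_all = derive_outcome(sub, spec.outcome_expr)

    role_cols = pd.DataFrame({"__y__": y_all})
    role_cols["__t__"] = sub[spec.treatment_name]
    cov_frames = {}
    for name in spec.covariate_names:
        col = sub[name]
        if pd.api.types.is_numeric_dtype(col):
            cov_frames[name] = col.astype(float)
        else:
            cov_frames[name] = col  # encoded after deletion
        role_cols[name] = col
    keep = ~role_cols.isna().any(axis=1)
    missingness = {
        str(c): int(role_cols.loc[~keep, c].isna().sum())
        for c in role_cols.columns
        if role_cols.loc[~keep, c].isna().any()
    }
    missingness = {
        {"__y__": "outcome", "__t__": spec.treatment_name}.get(k, k): v
        for k, v in missingness.items()
    }

    y = y_all[keep].to_numpy(dtype=float)
    t_raw = sub.loc[keep, spec.treatment_name]

    ordered = sorted(arms, key=_category_key)
    label_map = {ordered[0]: 1, ordered[1]: 2}
    t = t_raw.map(label_map).to_numpy(dtype=int)
    n1, n2 = int(np.sum(t == 1)), int(np.sum(t == 2))
    if n1 < 2 or n2 < 2:
        raise DataError(
            f"fewer than 2 usable rows in an arm after listwise deletion (n1={n1}, n2={n2})"
        )

    value_maps: dict = {}
    cols = []
    for name in spec.covariate_names:
        col = sub.loc[keep, name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            continue
        levels = sorted(pd.unique(col), key=_category_key)
        if len(levels) > 2:
            raise DataError(
                f"covariate {name!r} has {len(levels)} non-numeric categories; "
                "only dichotomous categorical covariates are supported"
            )
        mapping = {lev: float(i) for i, lev in enumerate(levels)}
        value_maps[name] = mapping
        cols.append(col.map(mapping).to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(y), 0))

    return RCTDataset(
        y=y,
        t=t,
        X=X,
        covariate_names=spec.covariate_names,
        treatment_label_map=label_map,
        missingness=missingness,
        covariate_value_maps=value_maps,
    )


def _category_key(v):
    """Sort key for arbitrary category labels: numerics first, then strings."""
    try:
        return (0, float(v), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(v))


@dataclass(frozen=True)
class ControlParams:
    """Tuning parameters of the partitioning criterion and the search.

    Defaults (filled by :func:`resolve_control`): effect-size criterion,
    ``maxl=10`` leaves, ``dmin=0.30``, per-arm leaf minima
    ``ceil(0.10 * arm size)``, bootstrap bias correction with ``B=25``
    samples.  ``w1`` scales the difference-in-treatment-outcome component and
    ``w2`` the cardinality component; the defaults equalize the two at a
    maximum of 2 each.
    """

    crit: str = "effect_size"
    w1: float = 1.0 / math.log(1 + 3)
    w2: float = 1.0
    maxl: int = 10
    dmin: float = 0.30
    a1: int = 1
    a2: int = 1
    bootstrap: bool = True
    B: int = 25
    seed: int | None = None
    #: optional variants (see docs): unstratified bootstrap, raw-sd 1-SE band,
    #: size-weighted (instead of pooled) class effects
    stratified_bootstrap: bool = True
    se_scaled_by_sqrt_b: bool = True
    pooled_class_effect: bool = True

    def with_(self, **kwargs) -> "ControlParams":
        return replace(self, **kwargs)


def default_weights(crit: str, y: np.ndarray) -> tuple[float, float]:
    """Default component weights: ``(1/ln(1+3), 1/ln(n/2))`` for the
    effect-size criterion and ``(1/ln(IQR(y)), 1/ln(n/2))`` for the
    difference-in-means criterion.  Natural logarithms throughout."""
    n = len(y)
    if 0.50 * n <= 1:
        raise ValidationError("n too small to form the default cardinality weight")
    w2 = 1.0 / math.log(0.50 * n)
    if crit == "effect_size":
        w1 = 1.0 / math.log(1 + 3)
    else:
        q25, q75 = np.percentile(y, [25, 75])  # linear interpolation
        iqr = float(q75 - q25)
        if iqr <= 1.0:
            raise ValidationError(
                f"IQR(y) = {iqr:.4g} <= 1: the default difference-in-means weight "
                "1/log(IQR) is undefined; pass w explicitly"
            )
        w1 = 1.0 / math.log(iqr)
    return w1, w2


def resolve_control(
    dataset: RCTDataset,
    *,
    crit: str = "es",
    w: tuple[float, float] | None = None,
    maxl: int = 10,
    dmin: float = 0.30,
    a1: int | None = None,
    a2: int | None = None,
    bootstrap: bool = True,
    B: int = 25,
    seed: int | None = None,
    **variants,
) -> ControlParams:
    """Validate user overrides against their allowed ranges and fill defaults.

    The weights are recomputed for the chosen criterion unless ``w`` is given
    explicitly; the leaf minima default to 10% of each arm (rounded up).
    """
    if crit not in CRIT_ALIASES:
        raise ValidationError(f"crit must be one of {sorted(set(CRIT_ALIASES))}; got {crit!r}")
    crit = CRIT_ALIASES[crit]

    if not isinstance(maxl, (int, np.integer)) or not 1 <= maxl <= 50:
        raise ValidationError(f"maxl must be an integer between 1 and 50; got {maxl!r}")
    if not 0 <= dmin <= 3:
        raise ValidationError(f"dmin must be a real between 0 and 3; got {dmin!r}")
    if a1 is None:
        a1 = math.ceil(0.10 * dataset.n1)
    if a2 is None:
        a2 = math.ceil(0.10 * dataset.n2)
    if not isinstance(a1, (int, np.integer)) or not 1 <= a1 <= dataset.n1:
        raise ValidationError(f"a1 must be an integer between 1 and n1={dataset.n1}; got {a1!r}")
    if not isinstance(a2, (int, np.integer)) or not 1 <= a2 <= dataset.n2:
        raise ValidationError(f"a2 must be an integer between 1 and n2={dataset.n2}; got {a2!r}")
    if not isinstance(B, (int, np.integer)) or B < 2:
        raise ValidationError(f"B must be an integer of at least 2; got {B!r}")

    if w is None:
        w1, w2 = default_weights(crit, dataset.y)
    else:
        w1, w2 = float(w[0]), float(w[1])
        if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
            raise ValidationError(
                "weights must be nonnegative reals, at least one of them nonzero"
            )

    return ControlParams(
        crit=crit,
        w1=w1,
        w2=w2,
        maxl=int(maxl),
        dmin=float(dmin),
        a1=int(a1),
        a2=int(a2),
        bootstrap=bool(bootstrap),
        B=int(B),
        seed=seed,
        **variants,
    )


def read_csv(path) -> pd.DataFrame:
    """Read a trial table: header row, missing values as empty field or NA."""
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)
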