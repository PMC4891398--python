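# Methods

This note records the model, the algorithmic conventions and the design
choices behind `pyquint`, at the level of detail a user needs to interpret
its output or reproduce it elsewhere.

## Model and procedure

The data are a two-arm RCT: outcome `y` (numeric, higher = better, possibly
a change score), treatment `t ∈ {1, 2}`, covariates `X` (continuous,
ordinal or dichotomous; categorical variables with more than two levels are
rejected). Listwise deletion is applied over all variables named in the
role formula, arms are recoded to 1/2 in ascending order of the original
categories, and the mapping is reported.

A candidate solution is a binary tree (root 1, children of node *k* are
*2k* and *2k + 1*; rows with splitter ≤ split point go left) together with
an assignment of leaves to subgroups P1/P2/P3. The partitioning criterion
is

    C = w1·[log(1+|E1|) + log(1+|E2|)] + w2·[log nP1 + log nP2]

with natural logarithms. `E_k` is the effect of subgroup k with all its
leaves' members pooled into one group: Cohen's d under the effect-size
criterion, the raw mean difference under the difference-in-means criterion.
Pooling (rather than a size-weighted average of per-leaf effects) is the
default because the subgroup — not the leaf — is the unit whose treatment
effect the criterion rewards; the weighted-average aggregation remains
available behind `ControlParams.pooled_class_effect=False` for sensitivity
checks. The difference-in-means component uses the same `log(1+|E|)` form
so the two criteria coincide in shape and are continuous at E = 0.

Admissibility: P1 and P2 nonempty; a leaf may be labeled P1 (P2) only if
its arm-1 minus arm-2 mean difference is positive (negative); every leaf
keeps at least `a1` arm-1 and `a2` arm-2 members; and the first split must
pass the qualitative-interaction gate: |d| ≥ dmin in both children with
opposite signs (evaluated on Cohen's d under either criterion). The gate is
checked only at the first split; deeper splits are constrained by the
admissibility rules but not re-gated on dmin. `≥` is read inclusively at
exact equality. If the gate fails, no tree is grown and the run reports
"no qualitative interaction" — a finding, not an error.

Growing is greedy and exhaustive: each step scans every (leaf, covariate,
split point, full-tree assignment) quadruple — split points are midpoints
between consecutive distinct values — and accepts the maximizing candidate
iff it improves C by more than 1e-10. Ties within that tolerance are broken
toward the lowest covariate index (formula order), then the smallest split
point, then the smallest parent node id, making the search deterministic.
After every accepted split *all* leaves are re-assigned.

Pruning: B bootstrap samples (drawn with replacement, stratified by arm so
that arm sizes and the feasibility of a1/a2 are preserved; an unstratified
flag exists), each re-grown into its own nested sequence. For each size L
present in both sequences, optimism = bootstrap training C − the C of the
frozen bootstrap tree (splits and class labels fixed) re-evaluated on the
original data; a record is unusable when a frozen subgroup loses an arm
entirely (or its pooled variance degenerates under the effect-size
criterion). Bias-corrected C(L) = apparent C(L) − mean usable optimism(L);
se(L) = sd(optimism)/√(#usable) (a flag exposes the raw-sd variant). Sizes
with fewer than two usable records are flagged as unstable; bootstrap
samples that fail the gate contribute no records and are counted in a
warning. The one-SE rule picks the smallest L with
biasC(L) ≥ max_L biasC − se(argmax); the band uses the se at the argmax
size only. A sequence whose full tree has two leaves is returned unpruned,
and with the bootstrap disabled the full tree is kept with apparent-only
fit information.

## Tuning parameters

| parameter | meaning | default | range |
|---|---|---|---|
| `crit` | effect-size vs difference-in-means criterion | `effect_size` | {es, dm} |
| `w1, w2` | component weights | `1/ln(1+3)` (es) or `1/ln(IQR(y))` (dm); `1/ln(0.5·n)` | ≥ 0, not both 0 |
| `maxl` | maximum number of leaves | 10 | 1–50 |
| `dmin` | minimum \|d\| per child at the first split | 0.30 | 0–3 |
| `a1, a2` | minimum per-arm members per leaf | `ceil(0.10·n_arm)` | 1–n_arm |
| `bootstrap`, `B` | bias correction on/off, number of samples | on, 25 | B ≥ 2 |

The default weights make each criterion component max out at 2: 3 is taken
as a plausible maximum effect size (IQR(y) as a plausible maximum mean
difference), and n/2 as the largest balanced subgroup size. Conventions the
defaults leave open are pinned as: natural log everywhere; IQR as the 75th
minus 25th percentile with linear interpolation (hence the dm default
demands IQR(y) > 1 — pass `w` explicitly for tighter scales); ceiling for
the 10% leaf minima so they are always positive integers. `dmin = 0.30` is
a sensible type-I/type-II balance at n ≈ 400; raise it (e.g. 0.40) for
smaller samples.

## Effect sizes

Cohen's d uses the pooled SD with n₁ + n₂ − 2 degrees of freedom and sample
SDs (n − 1 denominator). Its standard error is the large-sample formula
`sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2−2)))`, and 95% intervals are
d ± 1.96·se. No small-sample (Hedges) correction is applied. For the
reference leaf configuration (11, 1.00, 3.10) vs (7, 3.71, 4.75) this gives
d = −0.7125 and se = 0.4996; se values near 0.5 reported elsewhere for the
same configuration differ slightly depending on the se estimator, which is
why the se formula is documented here explicitly.

## Synthetic data

`ScenarioSpec`/`generate` simulate the intended input: `J` standard-normal
covariates (optionally one dichotomized), exact arm sizes from `arm_ratio`,
and outcome = noise + an arm-1 shift of `effect·noise_sd` whose sign and
size switch at `split_point` on the chosen covariate. Because the whole
shift is carried by arm 1 and there is no prognostic main effect, the
population Cohen's d inside each true subgroup equals the planted effect
exactly. The defaults are the benchmark condition used throughout the
tests: n = 400, equal arms, J = 3, a qualitative ±0.8 SD interaction at the
median of x1, unit noise.

What this generator does **not** emulate: correlated or skewed covariates,
prognostic main effects, heteroscedastic noise, missing data mechanisms, or
multi-way interactions. Passing tests therefore demonstrate correctness of
the algorithmic machinery and its operating characteristics under clean
planted structure, not performance guarantees on messy real trials.

## Numerical choices

The split scan works on per-arm prefix sums of the outcome and its square
in covariate order; the outcome is centered first so the variance algebra
is immune to catastrophic cancellation. A leaf or subgroup whose pooled sum
of squares falls below 1e-10 times the total (scaled) sum of squares is
treated as zero-variance: inadmissible under the effect-size criterion,
allowed under difference-in-means except at the gated first split.
Improvement and tie comparisons use the absolute tolerance 1e-10.
Reported tables round to two decimals for display only.

Problem sizes used by the test suite and acceptance script — 100 recovery
replicates at n = 400, 200 null replicates, 50 pruning replicates at
n = 200 with B = 25, and 50 oracle-comparison trials at n ≤ 40 — were
chosen so the full bootstrap machinery is exercised many times over while a
complete run stays in the tens of seconds; n = 200 for the pruning study is
enough for a ±0.8 SD single split to be found essentially always while
keeping 26 tree sequences per replicate affordable.

## Known limitations

Only two arms; no surrogate splits (rows missing a splitter cannot be
routed); no categorical covariates beyond two levels; no population
re-weighting of the criterion; the greedy search has no lookahead, so a
split that only pays off two levels deeper is missed; and the bootstrap
se of the optimism is an approximation whose two variants (÷√B or raw sd)
can select different sizes when the bias-corrected profile is flat.
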