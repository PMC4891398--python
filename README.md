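# pyquint — qualitative interaction trees for two-arm randomized trials

When a randomized controlled trial (RCT) compares two treatments, the
average effect can hide that one subgroup of participants does better under
treatment 1 while another does better under treatment 2 — a *qualitative*
(disordinal) treatment–subgroup interaction. These interactions are the ones
that matter for personalized treatment assignment, and they are exactly what
`pyquint` searches for. It is aimed at biostatisticians and applied
researchers analyzing RCT data with many candidate baseline moderators and
no strong a priori subgroup hypotheses.

## The method

Given an outcome *Y* (higher = better), a dichotomous treatment *T* ∈ {1, 2}
and baseline covariates *X₁ … X_J*, the method builds a binary tree whose
leaves are assigned to three subgroups: ℘₁ (treatment 1 better), ℘₂
(treatment 2 better) and the optional ℘₃ (no clear difference). A tree with
leaf assignment is scored by the composite partitioning criterion

```
C = w₁ · [ log(1 + |E₁|) + log(1 + |E₂|) ]  +  w₂ · [ log n℘₁ + log n℘₂ ]
```

where *E_k* is the treatment effect of subgroup ℘_k — Cohen's
*d* = (ȳ₁ − ȳ₂)/s_pool of all its members pooled (effect-size criterion) or
the raw mean difference (difference-in-means criterion) — and *n℘ₖ* is the
subgroup's size. The first bracket rewards strong opposite effects, the
second rewards large subgroups; the default weights equalize the two
components at a maximum of 2 each.

Growing is stepwise and exhaustive: at each step, every (leaf, covariate,
split point, leaf-to-subgroup assignment) quadruple is scanned and the one
maximizing C is accepted if it improves C, subject to boundary conditions —
a qualitative-interaction gate on the first split (both child leaves need
|d| ≥ d_min with opposite signs, else **no tree is grown**), per-arm minimum
leaf sizes, nonempty ℘₁ and ℘₂, and sign-consistent leaf labels. Because the
apparent C always increases with tree size, the grown sequence is pruned:
B bootstrap re-fits estimate the optimism of C at every size, the
bias-corrected C = apparent C − mean optimism, and the one-standard-error
rule picks the smallest size within one SE of the best bias-corrected C.

## Worked example

```python
from pyquint import ScenarioSpec, generate, grow, prune, resolve_control, summarize

dataset = generate(ScenarioSpec(seed=2024))        # 400-person synthetic RCT,
control = resolve_control(dataset, B=25, seed=1)   # +0.8/-0.8 SD interaction at
fit = grow(dataset, control)                       # the median of x1
pruned = prune(fit, dataset, control)
print(summarize(pruned).format_text())
```

prints (abridged):

```
Partitioning criterion: Effect size criterion
Number of observations used: 400

Fit information:
 split  leaves  apparent_C  bias_corrected_C   se
     1       2        2.87              2.83 0.02
     2       3        2.91              2.78 0.02
     3       4        2.93              2.76 0.02
     4       5        2.95              2.71 0.03

Split information:
 split  parent_node child_nodes covariate  split_point
     1            1      (2, 3)        x1         -0.0

Leaf information:
  leaf  node  n_T1  mean_T1  sd_T1  n_T2  mean_T2  sd_T2     d   se class
Leaf 1     2   105     0.77   0.92   106    -0.07   1.02  0.86 0.14    P1
Leaf 2     3    95    -0.83   0.96    94    -0.04   1.03 -0.80 0.15    P2
```

The apparent C rises with every split (it always does), but the
bias-corrected C peaks at one split and the one-SE rule keeps the two-leaf
tree — the planted truth. Leaf 1 (x1 ≤ −0.0) shows d = +0.86, so treatment 1
is better there (class P1); Leaf 2 shows d = −0.80, treatment 2 better
(class P2). Each `d` is the standardized mean difference of arm 1 minus
arm 2 inside that leaf, and the recovered split point sits at the planted
threshold (the covariate's median).

The same analysis runs from the shell on any CSV:

```
pyquint fit --data trial.csv --formula "y ~ trt | x1 + x2 + x3" \
            --seed 1 --out fit.json
pyquint prune --fit fit.json --out pruned.json
pyquint summary --fit pruned.json
pyquint predict --fit pruned.json --data new_patients.csv --out assigned.csv
```

The outcome may be a change score written as `"(post - pre)"`; construct it
so that higher values mean better outcomes. See `examples/` for short
narrative scripts covering growing and pruning, treatment assignment, the
d_min gate, and tree export.

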