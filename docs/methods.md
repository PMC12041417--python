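# Methods

This note documents the models, estimators, and design choices behind
`alertgs`, and what its simulation-based tests do and do not demonstrate.

## Gene-wise alerts (ALEC)

For each gene, responses `y` (log2 scale) at strictly increasing condition
values `x0 < x1 < … < cmax` are tested for a dose/time-response shape using
a two-step multiple-contrast procedure:

* **Contrast test.** Each of six candidate families — linear, quadratic,
  exponential, emax, sigEmax, betaMod, in the standard dose-finding
  parameterizations (`alertgs.models`) — contributes an optimal contrast
  `c ∝ nᵢ(μ⁰ᵢ − μ̄_w)` built from its guesstimate mean vector `μ⁰` under
  homoscedastic Gaussian errors. The per-candidate t-statistic uses the
  pooled within-condition variance. Multiplicity over candidates is handled
  by the Monte-Carlo distribution of `max|t|` under the flat Gaussian null
  (20 000 draws, cached per design; the draw seed is a stable digest of the
  design, so all genes measured under one design share one null). The test
  is two-sided so that up- and down-regulated genes are caught by the same
  candidate set. A gene is significant when any candidate's adjusted
  p-value is below alpha (default 0.05). Degenerate inputs: perfectly
  replicated responses give zero residual variance; a contrast is then
  declared infinitely significant if its numerator exceeds numerical dust
  (`1e-9` relative), and zero otherwise.
* **Winner selection.** Significant candidates are fitted by least squares
  (closed-form for linear/quadratic; multi-start bounded Levenberg–
  Marquardt/TRF otherwise, with starts derived from the data range). The
  winner minimizes AIC under a Gaussian likelihood,
  `n·log(RSS/n) + 2(p+1)`; ties break by candidate list order, and
  non-convergent fits are excluded and logged.

The **guesstimates are not from any particular study**: they are shipped
defaults spanning shallow to steep and non-monotone shapes, scaled to the
condition range, and are user-configurable. Only contrast shapes depend on
them, not the fitted models.

The ALEC is found by grid search on `[x0, cmax]` (default step
`(cmax−x0)/10⁴`) for the first crossing of `λ = f(x0, Φ̂) ± log2(1.5)`
(up/down), refined by bisection inside the bracketing grid cell. When both
directions yield an alert, only the minimum is retained with its direction.
Property tests confirm agreement with the analytic inversion for linear and
emax families to within one grid step.

## Preparation of alerts

All N analyzed genes are placed on one axis: correct-direction alerts
unchanged in `(0, cmax]`; missing alerts imputed i.i.d. uniform on
`[cmax+ε, 2cmax−ε]` (default `ε = 0.01·cmax`; any `ε < cmax/2` preserves
the block structure, so the choice is inert for the statistic);
wrong-direction alerts mapped to `3cmax − alert`, which reverses their
order (a gene that reacted early in the wrong direction is pushed to the
far end). Duplicated values — only those — receive additive uniform jitter
(default `1e-9·cmax`); values exactly at `cmax` are jittered downward so no
correct-direction alert leaves the observable window. One pipeline seed
spawns independent substreams for imputation and jitter.

## Running sum, ES, p-values

With set size M, the path over the sorted genes steps `+√((N−M)/M)` at
members and `−√(M/(N−M))` at non-members; `M` member steps and `N−M`
non-member steps cancel exactly, so the path starts and ends at zero. The
ES is the path maximum over prepared alerts `≤ cmax`, floored at zero —
the floor is what produces the zero-inflation that the rectified null model
expects. The argmax alert is reported (smallest on ties).

Permutations are drawn as uniform M-subsets of the gene positions
(equivalent to permuting labels; alert coordinates never move), P = 1000 by
default, via a vectorized partial Fisher–Yates shuffle. Because the path
only rises at member positions, a permutation's ES is computed from its
member positions alone. The same stored permutations serve the global
p-value and the alert estimator, so the two are mutually consistent.

The empirical p-value is the plain tail fraction `#{ESᵢ ≥ ES}/P` — no
`(k+1)/(P+1)` correction, so exact zeros can occur. The smooth alternative
fits `max(0, Gumbel(μ, β))` to the permuted scores by maximum likelihood:
zeros contribute the point mass `F(0) = exp(−exp(μ/β))`, positive values
the Gumbel density; optimization is L-BFGS-B on `(μ, log β)` with analytic
gradients from a moment-based start and a coarse grid fallback. The
resulting p-value `1 − F(ES)` is strictly positive (floored at the smallest
subnormal against underflow) and strictly decreasing. Calibration against
the empirical p-value in the null's central bulk is asserted in tests.

## Group-wise alert

Candidate coordinates are exactly the member genes' correct-direction
alerts `≤ cmax` (imputed and wrong-direction values are not interpretable
alert coordinates). The running sum is evaluated as a right-continuous step
function — value after all genes with prepared alert `≤ a`. The estimate is
the smallest candidate where at most 5% of permutations reach the original
path's height. The scan has a member-coordinate selection effect (the
original path just stepped up where it is evaluated), so it is only applied
to sets that already passed the global test; ungated it would flag roughly
half of random sets, gated it claims alerts for well under 10% of random
sets (asserted in tests).

## Decorrelation

**LocMin** keeps a set iff its p-value is strictly smaller than all
parents' and children's. Neighbors are resolved *transitively* through sets
that were filtered out (e.g. below the 10-gene minimum), so the hierarchy
is not artificially broken. The rule is evaluated in a single simultaneous
pass against the original p-value map — order-invariant, hence
reproducible; exact ties drop both sides (measure-zero with smooth
p-values). **elim** is the comparison baseline: genes with alert at or
below a cutoff (default 20) are "significant", sets are Fisher-tested
children-first (reverse topological order, ties by id), and genes of
significant sets are removed from all ancestors before those are tested.
Plain BH-FDR is available as an off-by-default alternative.

## Simulation framework

The generator emulates the structure of a 48-week time-course study:
alerts live on `[3, 48]` weeks, group alerts are integers in `{5..46}`,
meaningful gene alerts follow `4·Beta(2,2) + g − 2` (support `[g−2, g+2]`,
mean `g`, variance 0.8), background alerts are Uniform(3, 48) on a fraction
`r` of genes, and a background candidate replaces a meaningful alert only
when strictly smaller. Counts round up: `⌈x·|group|⌉` meaningful genes per
group, `⌈r·N⌉` background genes. The independent regime draws per group
from currently unalerted members in draw order; the iterative regime
processes groups by increasing `g` and samples from all members, earlier
groups keeping priority. Each picked group uses its own RNG substream keyed
by draw order, which makes the two regimes coincide seed-for-seed on
disjoint collections — a tested invariant.

The synthetic collection is a layered random DAG: Pareto-weighted gene
sampling for leaf sets (heavy per-gene multi-annotation tail), parents as
unions of 2–4 children plus a few extra genes, at least two parents per
non-root node (GO groups typically have several parents and/or children;
without this the hierarchy is too sparse for neighborhood-based
decorrelation to behave like it does on GO), and extra cross-level edges at
a configurable rate, followed by an upward membership closure that
guarantees child ⊆ parent.

**What the simulations do not show.** The generator reproduces overlap,
hierarchy, and alert geometry, not expression-level noise, correlated
errors within pathways, annotation bias of real GO releases, or the
model-fitting stage (alerts are simulated directly). Passing tests
demonstrate calibration and recovery of the set-level inference given
alerts, not end-to-end performance on RNA-seq counts.

## Problem sizes used in tests and the acceptance script

The simulation checks run at a reduced scale chosen as a deliberate
trade-off: a synthetic collection of ~600 sets over 5000 genes, 20 runs per
scenario, P = 1000 permutations (the study-scale default). The null
calibration check counts runs whose LocMin-significant total stays below 5%
of sets; the recovery check (iterative regime, n = 10 groups, x = 0.3,
r = 0.1) counts meaningful groups found directly or via a direct
parent/child among LocMin-significant sets and pools the signed alert
errors, whose median is expected to be ≤ 0: the estimator scans member
alerts from below and stops at the first permutation-beating coordinate,
which systematically favors the early tail of a group's alert window —
underestimation rather than overestimation, the conservative direction for
hazard assessment.

## Known limitations

* The MCP adjustment is Monte-Carlo, not exact multivariate-t quadrature;
  adjusted p-values carry O(1/√20000) granularity.
* The rectified-Gumbel fit needs at least one positive permuted score; a
  set whose permutation null is all zeros falls back to the empirical
  p-value.
* LocMin is all-or-nothing per neighborhood; two truly reacting
  parent/child sets cannot both be reported.
* The group-wise alert has no confidence interval.
* The weighted (per-gene) enrichment-score variant is not implemented.
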