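# Methods

## The score

For a subset S of fingerprint bits and a binary activity label Y over n
compounds, the package scores S by normalized mutual information

AIC_Y(S) = I(X_S; Y) / H(Y),

where X_S is the joint pattern of the bits in S (an element of {0,1}^|S|),
I is Shannon mutual information in bits, and H(Y) is the label entropy.
All probabilities are maximum-likelihood relative frequencies over the
dataset — no pseudocounts. Two consequences of the ML choice are relied
on throughout:

* **Monotonicity.** For empirical distributions, adding a bit can never
  decrease I(X_S; Y), so greedy trajectories are non-decreasing and need
  no backtracking.
* **Saturation.** Once the observed patterns separate the two classes,
  the score is exactly 1 and every further candidate ties. Selection is
  kept deterministic by breaking ties on higher singleton score, then
  lower bit id. A Laplace-smoothing option was considered and rejected:
  it would break exact monotonicity and the score definition contains no
  smoothing.

ML estimation also means the score is biased upward at small n (patterns
that happen to separate classes by chance score highly). The package
does not correct for this; the saturation index in each
`SelectionResult` makes it visible, and the evaluation harness exists
precisely to check selections against held-out predictions.

Implementation: patterns are keyed by compact integer codes updated
incrementally (code ← 2·code + bit, re-factorized each step), so one
score evaluation is O(n) regardless of subset size; candidate scoring is
vectorized over bits in chunks. `brute_force_aic` is an independent
oracle that enumerates all 2^N patterns explicitly and must agree with
the fast path to 1e-10; the agreement is asserted over every subset of
size ≤ 8 of a random 50×12 matrix.

## Greedy selection

AIC-MAX is forward greedy selection: k steps, each adding the candidate
bit maximizing the group score. Forward greedy is the canonical reading
of incrementally maximizing a group score and costs O(k·B) score
evaluations for B bits; non-greedy search (beam, annealing) is out of
scope. The default k = 100 bits per task is the package's standard
reduced-representation size for receptor-ligand sets. For several tasks
the group score is the *unweighted* arithmetic mean of per-task scores —
per-task sample sizes deliberately do not weight the mean, so a small
ligand set counts as much as a large one; a weighted variant can be
composed from `aic_score` directly if wanted. Degenerate tasks (one
label class) are rejected loudly rather than scored 0, because a silent
0 would let a broken task pull the average down unnoticed.

## Activity labelling

Potencies (Ki or equivalent, nM) are thresholded: active iff Ki ≤ 100 nM,
inactive iff Ki > 1000 nM, the gap in between discarded. The inclusive
boundary on the active side and the strict one at 1000 nM keep the two
sets disjoint. Replicate measurements of a compound–target pair are
collapsed by median before thresholding (robust, order-independent).
Both thresholds are parameters.

## Selectivity tasks

A pair task labels actives of target A as 1 and actives of target B as 0.
Compounds active at both have no well-defined selectivity label and are
excluded (counted per pair); inactives play no role. Unordered pairs are
computed once — by the label-flip symmetry of the score, orientation
changes nothing. Per-target summaries: union (selected in ≥ 1 pair) and
core (selected in every non-skipped pair). Degenerate pairs (< 2
compounds on a side after exclusion) are recorded as skipped so one bad
pair cannot abort a sweep.

## Evaluation harness

Each task is scored by stratified k-fold cross-validation (default 10
folds, reduced with a warning when the smaller class is too small);
out-of-fold predictions are pooled into a single confusion matrix and
summarized once by MCC. MCC's degenerate-denominator case returns 0 with
a logged warning (the common convention). The default learner is a
random forest (500 trees, √B features per split, fixed seed) behind a
fit/predict adapter; a deterministic parity stub exercises the harness
under a known null. Whether MCC should come from CV or a held-out split
is a genuine design fork; CV was chosen and is declared in the report
metadata.

Paired per-task MCCs are compared by a Wilcoxon signed-rank test,
one-sided with alternative "reduced ≥ raw" (matching the question the
reduction is meant to answer). Differences inside ±0.005 count as "no
change" and are excluded; zeros are dropped; |differences| get average
ranks on ties. The null tail is exact for n ≤ 25 — the distribution of
the positive-rank sum is built by convolution over doubled ranks,
equivalent to enumerating all 2^n sign assignments and valid under
ties — and a tie-corrected normal approximation with continuity
correction beyond. The exact path is cross-checked in tests against an
explicit sign-enumeration oracle and against scipy's exact method in the
tie-free regime.

## Synthetic data

The generator emulates exactly the statistical structure the score
reacts to, and nothing else — no molecules, no chemistry, no
inter-bit correlation beyond what is planted:

* labels first (exact class sizes), then bits conditional on class, so
  every planted bit's population score is available in closed form and
  recorded in the manifest;
* planted bits: Bernoulli(p_active | y=1, p_inactive | y=0);
* XOR pairs: one bit uniform, the partner set to bit ⊕ label — parity
  equals the label on every row while each bit is marginally uniform
  (singleton information 0, pair information 1). This construction keeps
  the declared class balance intact;
* duplicates copy their source column exactly; noise bits are
  label-independent Bernoulli(p_noise).

Seeding is hierarchical — (global seed, target, role, bit id) — so
adding bits or targets never perturbs existing columns. Defaults
(300 compounds per class, noise occurrence 0.1) describe a mid-sized
receptor-ligand task. The pairwise-suite generator gives each target
characteristic bits at 0.8 occurrence in its own actives and 0.2
elsewhere: each such bit discriminates its target from every other
target, so recovery into the core-bit set is the designed outcome.

What passing on synthetic data does **not** show: real fingerprint bits
are heavily correlated (substructure containment), class-conditional
independence does not hold, and real actives/inactives ratios are far
from balanced. Results on planted data validate the machinery, not the
chemistry.

## Problem sizes in the standard verification run

The test suite and `scripts/acceptance.py` use: oracle agreement on all
3 796 subsets of size ≤ 8 of one 50×12 matrix; closed-form convergence
at n = 10⁵; core-bit recovery over 20 seeded 4-target suites (300
actives per target, effect 0.6, k = 15); type-I control over 500
ten-task null suites (n = 60, parity stub, 5-fold CV); noise dilution
over 20 tasks (200 per class, 10 planted bits at 0.75/0.25 plus 2000
noise bits, 64-tree forest, 5-fold CV). These sizes are large enough
that the stochastic checks are stable across seeds while a full run
stays around a minute on a single core.

## Known limitations

* KRFP reproduction is best-effort: SMARTS matching follows RDKit's
  aromaticity model and may differ bit-for-bit from other toolkits; the
  bundled 4860-key dictionary is a synthetic stand-in (size and format
  only), with `load_smarts_keys` for a real key file.
* The ML score's small-sample optimism (above) means selections on very
  small ligand sets saturate early; inspect `saturated_at`.
* Constant bit columns are retained (they carry score 0 by construction)
  rather than pruned, so bit indices always align with the input.
* Only binary features and binary labels are supported; continuous
  descriptors and multi-way selectivity labels are out of scope.
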