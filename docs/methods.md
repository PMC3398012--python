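# Methods

This note records the models, conventions and numerical choices behind
`molconnect`, and what the synthetic-data tests do and do not establish.

## Molecular graphs and descriptor conventions

Molecules are hydrogen-suppressed labelled graphs: heavy atoms carry an
element symbol, an attached-hydrogen count and a formal charge; bonds carry
a conventional order (1, 2, 3, or 1.5 for aromatic) and a ring flag.
Multi-fragment inputs (salt/solvate SMILES with `.`) are rejected rather
than silently picking a fragment. 3-D geometry, stereochemistry and
tautomerism are out of scope.

Conventions that the descriptor literature leaves to the implementer:

* **Adjacency/distance matrices** treat every bond, aromatic included, as
  an edge of weight 1; the 1.5 conventional order enters only where bond
  orders are summed. Distances are unweighted shortest-path bond counts.
* **Valence degrees** follow Kier–Hall: δv = Zv − h + q for period-2
  elements and (Zv − h + q)/(Z − Zv − 1) for heavier ones (Zv valence
  electrons, Z atomic number, h attached hydrogens, q formal charge),
  computed as exact rationals. The supported element set is the organic
  subset (B, C, N, O, F, Si, P, S, Cl, Br, I); anything else raises an
  error naming the atom — descriptors never return silent NaN.
* **Rotatable bonds (RBN)**: acyclic single bonds with both endpoints of
  degree ≥ 2; amide C–N bonds are excluded by default (configurable), the
  dominant convention.
* **Constant-descriptor removal** uses sample variance ≤ 1e-12 as the
  float-safe meaning of "no change across molecules"; the boundary value
  is removed (≤ convention).
* The **extended tier** contains descriptors whose published definitions
  are contested or scattered; the definitions used here are documented
  choices, not claims about any other software's output: TIE is the sum of
  Kier–Hall E-states S = I + ΔI with I = ((2/L)²δv + 1)/δ and
  ΔI_i = Σ_j (I_i − I_j)/(d_ij + 1)²; MAXDN is the maximal negative ΔI
  (Gramatica's electrotopological negative variation); Jhete applies the
  Balaban formula to the Barysz electronegativity- and bond-order-weighted
  distance matrix; TI1 = 4·QW/n² and TI2 = 4/(n·λ₂) are Laplacian-spectrum
  indices built on the quasi-Wiener sum and the algebraic connectivity.
  RAM is the ramification index Σ max(0, δᵢ − 2). Core-tier results never
  depend on these.
* Eigensolves use `numpy.linalg.eigvalsh`; eigenvalues below 1e-9 in
  magnitude are clamped to zero (a connected graph must show exactly one
  zero Laplacian eigenvalue).

## Curation and labelling

Multi-report molecules collapse to the mean activity value; a group is
excluded when its value range exceeds a discrepancy limit. "Large
discrepancy" is not a number anywhere in the source conventions, so the
defaults — 20 percentage points for %F/%FA, 1.0 log unit for log *P*app —
are explicit, configurable package choices. Label thresholds are
%F ≥ 80, %FA ≥ 70, log *P*app ≤ −4 for the positive class, boundary
included. Class balancing down-samples the majority class uniformly
without replacement, seeded.

## PLS-DA, VIP and the permutation test

The two-class response is coded {0, 1} and centred; X is autoscaled to
unit *sample* variance (ddof = 1, the SIMCA convention). Components are
extracted by NIPALS PLS1 with deflation of both X and y; the component
count is chosen by cross-validated Q² over 7-fold venetian blinds
(interleaved index folds), accepting another component while ΔQ² ≥ 0.01 up
to `max_components` (default 10). VIP uses unit-norm X-weights and
per-component explained Y-variance, so ΣVIP² = p holds identically; the
selection threshold VIP ≥ 1 keeps descriptors that contribute more than
the mean squared importance.

The permutation test refits each permuted model at the component count
selected on the observed data (no CV inside permutations), so the
statistic is computed identically under the null — this is what makes the
p-value exact, p = (1 + #{perm ≥ obs})/(1 + n_perm). The module-level
default statistic is R²Y; the *pipeline* default is Q², for a measured
reason: with p ≈ n a single PLS component fits ~0.3 R²Y on random labels,
so R²Y has essentially no power there, while Q² is ≤ 0 under the null and
detects the planted separation at p ≤ 0.01. Both are available via
`statistic=`.

## Classifier bench and the reference model

The reference classifier is logistic regression with a ridge estimator:
minimise NLL + λ‖β‖² with the intercept unpenalised, by damped Newton
iteration to gradient norm ≤ 1e-8 (λ default 1e-8, the conventional
near-unpenalised setting). Cross-validation is repeated stratified k-fold
(default 10 × 10) with features standardised inside each training fold
only. Accuracy and precision are reported in percent from pooled per-fold
confusion counts; precision is *not applicable* (not zero) when a fold
predicts no positives. The bake-off menu ships seven built-ins (ridge
logistic, 1-NN, 3-NN, Gaussian naive Bayes, decision tree, random forest,
MLP — the latter six via scikit-learn) and accepts any object with
fit/predict semantics; ranking is by mean accuracy with deterministic
name tie-breaks.

## CFS

Merit uses Pearson correlations of standardised features against the ±1
class vector (an optional discretised mode was considered and rejected:
Pearson admits closed-form oracle tests). Best-first forward search over
add-one expansions stops after 5 consecutive non-improving expansions;
ties break by feature name. For p ≤ 12 the search provably matches
exhaustive enumeration in the test suite. One caution from the algebra:
duplicating an *above-average-relevance* in-set feature can raise merit
(the relevance mean rises faster than the redundancy penalty), so "adding
redundant features lowers merit" holds only for at-or-below-average
features; the tests state the property in that form.

## Robustness score

`score_from_counts` is exact arithmetic: score = 10·m/n, significant at
≥ 5. `small_set_score` draws `n_sets` resamples of `set_size` molecules
uniformly *with replacement* (unstratified; single-class draws are redrawn
and logged), cross-validates each (10-fold by default) with the reference
classifier, and counts resamples whose accuracy reaches the full-data
reference accuracy. "Reaches" means ≥, the only reading under which a
majority of noisy 100-molecule resamples can qualify at realistic
accuracy levels.

## Synthetic study generator

`gen_two_endpoint_study` emulates the study design end-to-end: p = 198
usable descriptor columns, of which a block of 47 is informative for both
endpoints, plus 2 descriptors unique to the first endpoint and 3 unique to
the second; 300 molecules per endpoint. The common block is exchangeably
correlated (ρ = 0.3) through one Gaussian factor — mimicking the strong
collinearity of topological descriptor panels — and all other columns are
independent standard normals. Labels are drawn through a logistic link on
the standardised sum of the endpoint's informative columns scaled to
`effect_sd` (default 1.5) plus N(0, noise_sd²) label noise (default 0.5).
The third endpoint is driven by the common block alone. A Monte-Carlo
Bayes-accuracy bound for this label model is provided and upper-bounds any
classifier's CV accuracy in the tests.

What passing tests on this generator show: the selection machinery
(PLS-DA/VIP) recovers a planted, collinear informative block near-perfectly
at effect 1.5 SD and n = 300; intersecting two endpoints' selections
recovers the shared block (Jaccard ≥ 0.8); the permutation test is
calibrated; combining the common set beats any single descriptor at the
joint endpoint's full size (n = 969). What they do *not* show: anything
about real molecules — real descriptor distributions are non-Gaussian,
heavy-tailed and nonlinearly informative, and real activity labels carry
structured measurement error.

One documented limitation: in this linear-Gaussian world the CFS subset is
*sufficient* — the claim that reducing the VIP set must lower accuracy
does not reproduce. Any planted design whose 47 descriptors are all
individually recoverable by VIP at n = 300 is necessarily so redundant
that a 15–25-descriptor CFS subset predicts within estimation noise of the
full set (verified against an independent holdout, and across factor
structures, mixed effect signs and suppressor-style designs). The
irreducibility seen on real data reflects heterogeneous, non-Gaussian
information content that this generator intentionally does not model; the
corresponding acceptance test is kept failing rather than weakened.

## Pipeline

Stages run in order: inputs (synthetic study or curated CSVs) →
constant-descriptor removal → balancing → PLS-DA + VIP + permutation test
per endpoint → classifier bake-off → intersection → joint-endpoint
evaluation (combined + per-descriptor) → CFS check → robustness score →
ANOVA → connectivity map (SIF + GraphML). Every threshold is a config key
with its conventional default (80/70/−4 labels, VIP ≥ 1, permutation
α = 0.01, ANOVA α = 0.05, 1000 × 100 resamples, score ≥ 5, 10 × 10 CV).
The global seed fans out to per-stage seeds through
`numpy.random.SeedSequence`, so re-running a config is bit-reproducible
(report checksums are asserted in the tests). Test and example configs
scale the simulation sizes down (fewer resamples, 2 × 10 CV) to keep runs
in seconds; the statistical conventions are unchanged by that scaling.

## Known limitations

* Descriptor values follow the formulas documented here; no claim of
  bit-parity with any commercial descriptor software is made, and the
  identity of any particular historical 247-descriptor panel is not
  reconstructable.
* PLS-DA is strictly two-class; multi-class endpoints are out of scope.
* The CFS search is heuristic beyond p ≈ 20 (exhaustive equivalence is
  only asserted for p ≤ 12).
* `small_set_score` at its full default (1000 resamples × 10-fold CV) is
  the slowest stage by far; scale `n_sets` down for exploration.
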