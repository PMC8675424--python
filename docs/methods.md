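# Methods

## Data model

A dataset is a subjects × features matrix `X` (no missing values — rows with
any missing feature are dropped at load time and counted, never imputed),
a binary diagnosis `y` (1 = case), and a site label per subject. The 150
default feature columns follow the Desikan parcellation: mean cortical
thickness and surface area for 34 bilateral cortical parcels (68 + 68) plus
7 bilateral subcortical volumes (14). Feature order in the input file is
canonical; every downstream mask indexes that order.

Sites are categorized from their class counts with one tunable,
`min_per_class` (default 5): *balanced* sites have at least that many of
each class, *case-only* / *control-only* sites have none of one class, and
sites with some of each class but fewer than `min_per_class` are
*mixed-small*. The default of 5 reflects that a leave-site-out fold needs
several members of each class for its AUC to be estimable with tolerable
variance. Mixed-small sites remain in every training pool but are never
used as evaluation folds — a conservative choice that avoids high-variance
fold scores without discarding data. The three dataset variants are nested:
`base` (balanced + mixed-small), `base_plus_cases` (adds case-only), `full`
(adds control-only).

## Synthetic multi-site generator

For subject *i* at site *s*, feature *j*:

    x_ij = a_sj + c_s * (delta_j * y_i * 1[j in J] + eps_ij + (L u_i)_j)

- `a_sj ~ N(0, site_offset_sd²)` — additive per-(site, feature) offset, the
  first-order model of scanner/sample shifts. Default SD 1.0: site effects
  comparable in magnitude to within-site subject variability, the regime in
  which site confounding is a live threat.
- `log c_s ~ N(0, site_scale_sd²)` — per-site multiplicative gain; default
  SD 0.1 (≈10% gain differences), a modest second-order scanner effect.
- `eps_ij ~ N(0, noise_sd²)`, default 1 — the within-class unit.
- `delta_j` — planted diagnosis effect in within-class SD units on signal
  set `J`; labels are assigned by the site plan, not by a latent liability
  model, because the confound under study is compositional.
- optional rank-`r` loadings `L` (entries `N(0, 1/r)`) induce feature
  correlation; off by default since the evaluation questions do not depend
  on it.

Randomness is keyed per site: the per-site stream seeds from
(master seed, CRC32(site id)), so adding or removing a site never perturbs
another site's draws, and one integer seed reproduces everything bit-exactly.

The consortium-style plan has margins matched to a large multi-site
addiction study — 24 training sites (5 balanced, 3 case-only, 16
control-only; 692 cases / 960 controls) and 3 balanced test sites
(146 / 236) — with per-site sizes a documented package constant (balanced
sites 60–260 subjects, control-only 14–120) since only the margins, not the
per-site counts, are published for the study this layout emulates. `scale`
shrinks every nonzero cell proportionally with a floor of 2, preserving all
site categories. Experiments in the tests and acceptance script run at
scale 0.25 (413 training subjects), which keeps the full workflow within
desk-scale runtimes while leaving each balanced site with enough subjects
for stable fold AUCs.

What the generator does *not* emulate: realistic ROI covariance atlases,
age/sex structure, site-specific noise scales, and non-Gaussian artefacts.
Passing tests therefore demonstrate that the machinery behaves correctly
under compositional site confounding with additive/multiplicative site
effects — not that any particular real dataset contains a recoverable
4-feature signal.

## Cross-validation schemes

- **Random repeated k-fold** (default 50 repeats × 3 folds) stratifies on
  diagnosis only. Site is deliberately ignored: this scheme *is* the object
  of study. All R·k fold AUCs are retained; the reported ±SD is the sample
  SD across those fold scores.
- **Leave-one-site-out** uses the balanced sites as folds. Each fold trains
  on *all* other subjects of the supplied variant — including imbalanced
  sites — and scores the held-out site; the summary is the unweighted mean
  over fold sites (not subject-weighted pooling).

AUC is computed with the rank-based Mann–Whitney equivalence (ties ½); a
brute-force pair-count oracle in the tests pins the implementation exactly.

## Classifiers

Three families, one wrapper: z-score standardization learned from the
training rows of the call, nested hyperparameter selection by inner
stratified CV (default 3 folds) on mean AUC, refit on all supplied rows.
Ties in the inner criterion break toward stronger regularization.
Standardization is computed once per `fit()` call from the training rows;
the inner selection folds reuse those statistics. This is leakage-safe with
respect to any outer validation data (the leakage that matters for the CV
comparison); recomputing statistics inside every inner fold would change
selected hyperparameters only marginally at these sample sizes.

- *ridge_logistic*: L2 logistic regression; strength grid of 13 log-spaced
  values in C ∈ [1e-4, 1e4], evaluated via a warm-started regularization
  path. With candidates ascending in C, argmax-first implements the
  strong-regularization tie-break.
- *elasticnet_logistic*: elastic-net penalized logistic loss; random search
  (default 100 draws) with `l1_ratio ~ U(0,1)`, `C` log-uniform on
  [1e-4, 1e4]. The contract is the penalized objective; the solver (SAGA)
  is an implementation detail.
- *svm_rbf*: RBF-kernel SVM; random search over `C` log-uniform [1e-4, 1e4]
  and `gamma` log-uniform [1e-6, 1e1].

Scores always mean "higher = more case-like". Zero-variance columns
standardize to zeros with a warning rather than erroring, so degenerate
folds fail soft. No probability calibration: every metric here is
rank-based.

## Evolutionary feature search

Individuals are nonempty binary masks. Fitness is the LOSO mean AUC of a
*fixed-strength* ridge (C = 1) on the masked columns — quick to train, and
the exploratory grid shows classifier choice moves performance only
marginally, so the search spends its budget on masks, not hyperparameters.
Fitness evaluation pre-standardizes each LOSO fold once at full width
(masking standardized columns equals standardizing masked columns) and fits
a damped-Newton minimizer of the identical penalized objective; agreement
with the generic path is asserted in tests. Results are memoized by
(dataset fingerprint, mask).

Per island: initialize P masks with per-bit inclusion probability
`init_prob` (default 0.1 — sparse starts make the sparsity objective
meaningful); each generation, P−1 offspring are bred by size-2 tournament
(lexicographic: fitness, then smaller size, then younger age), uniform
crossover with probability 0.5, per-bit mutation at rate 2/p, plus one
random newcomer at age 0; survival takes P from parents∪offspring∪newcomer
by NSGA-style nondominated sorting on (fitness↑, size↓, age↓). Offspring
inherit their lineage's age; only newcomers reset it — the age–fitness
Pareto mechanism that keeps fresh lineages alive next to entrenched elites.
Islands (default 3) evolve independently from island-specific substreams
and are merged only at output: the result is the top-`k_top` (default 200)
unique masks ever evaluated, ranked by (fitness desc, size asc,
lexicographic mask) — a total order, so equal seeds reproduce results
exactly.

Two presets package the search-variant grids: `six_variant_preset` — six
variants crossing population size, generation count and initialization
density (the sparsity-pressure knob), mirroring a six-way search-design
grid; and `compact_preset` — two variants (init densities 0.05 and 0.2) at
P = 60, G = 40, 3 islands, the desk-scale default. Averaging importances
across even two variants matters: a single run can entrench a correlated
hitchhiker feature in all of its top subsets (observed in development),
while variant averaging washes such features out of the top ranks.

Crossover is included but can be disabled (`crossover_rate=0`); mutation
alone is the minimal operator set the search design names.

## Importance and selection

Within a variant, each retained subset S contributes `fit(S)/|S|` to every
member feature; the per-feature totals divide by `Σ_S fit(S)/|S|` — the
unique linear normalization with the endpoints "in all retained sets → 1,
in none → 0". (The raw totals satisfy `Σ_f raw(f) = Σ_S fit(S)`, asserted as
a property test.) The final ranking averages variants with equal weight.
Selection takes features with mean importance ≥ τ; τ defaults to 0.8, and a
top-k sweep (k = 2..15) quantifies sensitivity to that choice. If nothing
reaches τ the pipeline falls back to the top 4 by importance with a
prominent warning.

## Final evaluation and posthoc checks

The final model is a nested-tuned ridge (not the GA's fixed-C ridge) on the
selected features, trained on all training subjects and scored once on the
pooled test-site subjects (a single AUC, not per-site scores). Posthoc:
all-features ridge and SVM on the full / no-extra-controls / balanced-only
training variants, the top-k sweep, and paired AUC comparisons.

Paired AUC comparison uses DeLong's covariance estimator for correlated
ROC curves, two-sided. At 30 or fewer subjects the asymptotic normal
approximation is poor (development measurements: p-value errors up to 0.2
at n = 8 against an exact-null permutation reference), so `delong_compare`
switches to a paired permutation test (per-subject swap of the two models'
scores, |ΔAUC| statistic, 50,000 vectorized permutations, add-one
estimate) below that boundary.

## Numerical and degenerate-input conventions

- Fold SDs use ddof = 1; a single fold reports SD 0.
- LOSO folds lacking a class raise an error naming the site.
- All-zero masks after mutation are repaired by setting one uniform bit.
- The Newton solver damps steps by backtracking on the penalized objective
  (separable folds would otherwise diverge) and stops at gradient
  max-norm < 1e-8·n or 50 iterations.
- Seeds: every stochastic component (generator, CV shuffles, searches,
  permutation tests) derives from explicit integer seeds via
  `numpy.random.SeedSequence`; nothing reads global RNG state.

## Known limitations

- The six-variant preset is an interpretation of a search-design grid whose
  exact composition is not published; it is labelled a preset, not a
  reproduction.
- The importance normalization resolves an ambiguity in the published
  description by the unique form consistent with its stated endpoints.
- τ = 0.8 is adopted as the default threshold; the original threshold
  selection procedure ("further internal nested validation") is unspecified,
  so this package provides the sweep utility instead of an automatic
  chooser.
- Covariates (age, sex) are not modelled; site harmonization (e.g.,
  location/scale adjustment per site) is deliberately out of scope — the
  point of the workflow is evaluation and selection that tolerate site
  effects, not their removal.
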