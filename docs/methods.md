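# Methods

## Problem setting

logBB = log10(C_brain / C_blood) summarizes how readily a compound crosses
the blood–brain barrier; experimentally curated collections span roughly
−2.69 to 1.7, and the conventional qualitative boundary is logBB ≥ −1 for
"permeable". The toolkit fits a regression model mapping computed molecular
descriptors to logBB, then optionally reads the model out as a classifier
at that boundary. This document records the modeling conventions, the
defaults and why they were chosen, and what the synthetic fixtures do and
do not establish.

## Similarity curation

Fingerprints are Morgan/circular, radius 2, hashed to 1024 bits — the open
equivalent of ECFP4. Different fingerprint generators produce different bit
assignments, so similarity values are generator-specific; all decisions in
one run use one generator, which is what the curation logic requires.
Tanimoto similarity is N_c / (N_a + N_b − N_c); for two all-zero
fingerprints (no heavy-atom environments hashed, essentially impossible for
real molecules) the 0/0 case is defined as 0 and the compound is flagged.

Deduplication is a greedy leader pass in input order: a compound is kept
iff its similarity to every previously kept compound is ≤ 0.85. The
comparison is strict (> discards, = keeps). Which member of a similar pair
to keep is genuinely open; keeping the earlier record makes the pass
deterministic for a fixed input order and idempotent (re-curating the kept
set discards nothing). The same cutoff screens an external test set against
the training set, removing leakage from near-duplicates.

## Descriptors

Descriptors come from RDKit's descriptor set (~210 2D descriptors;
`Descriptors3D` adds conformer-based ones when requested). 3D descriptors
require an embedded conformer; ETKDG embedding with a fixed seed makes them
deterministic, and an embedding failure yields NaN rather than a silent
zero. NaN and ±inf are treated identically at pruning time: a column with
any such entry anywhere in the dataset is dropped, because one unusable
entry makes the column unusable for fitting. Pruning is idempotent.

Standardization uses per-column training-set mean and sample (ddof = 1)
standard deviation; zero-variance columns are dropped with a warning before
scaling. Held-out rows are always transformed with training statistics. By
default the scaler is refit inside each CV fold — scaling the full matrix
before splitting leaks held-out information into the transform — and a
`prescale` flag restores global pre-scaling where protocol compatibility
matters. Pearson correlations are invariant to affine scaling, so the
feature-selection stage is unaffected by this choice.

## Correlation-based feature selection

Both redundancy (feature–feature) and relevance (feature–target) use the
absolute Pearson correlation: a strongly negative correlation is just as
redundant, and just as informative, as a positive one. The filter ranks
descriptors by descending |r(x, y)| (ties broken lexicographically by name
for determinism) and keeps a descriptor iff its |r| with every already-kept
descriptor is ≤ the threshold. Visiting in relevance order guarantees
globally, not just pairwise, that whenever two redundant features clash the
more target-correlated one survives. Constant columns are excluded up front
(their correlation is undefined).

The threshold is selected by sweeping 0.1–0.9 in steps of 0.1 and
cross-validating one learner on each resulting feature set. The same fold
partition (one seed) is reused across thresholds so the comparison is
paired; ties break toward the smaller feature set, preferring parsimony.
Feature count is non-decreasing in the threshold by construction (a looser
threshold only relaxes constraints).

## Learners and cross-validation

The eight learners run through scikit-learn (plus the LightGBM and XGBoost
scikit-learn wrappers) with a uniform seeded, single-threaded
configuration. The neural network defaults to one hidden layer of
min(64, n_features) units. Hyperparameter grids live in a shipped TOML file
(`logbbpred/data/default_grids.toml`) and are fully user-overridable; grid
search enumerates the Cartesian product in deterministic order (sorted
parameter names), scores each point by mean CV R² on shared folds, keeps
the first point on ties, and refits the winner on all data.

Cross-validation is a shuffled k-fold split (default k = 10) from a single
integer seed recorded in every CV record. R² is the conventional
coefficient of determination about the mean of the observed values; MSE is
the plain mean squared error. Fold metrics are averaged arithmetically.

## Classification metrics

Binarization at logBB ≥ −1 (the boundary value itself is permeable) feeds a
confusion table with "permeable" as the positive class. Sensitivity,
specificity, accuracy, PPV, NPV and MCC follow the standard definitions;
any metric with a zero denominator is reported as absent together with the
reason, never coerced to 0, so degenerate evaluation sets cannot look
spuriously perfect. MCC is algebraically the Pearson correlation of the two
binary label vectors, which the tests exploit as an independent oracle.

## Synthetic fixtures

`make_smiles_series` emits homologous alkane/alcohol series (adjacent
members similar well above 0.85) and a mixed pool including small diverse
molecules (cross-pairs well below 0.85), giving curation both discard and
keep cases. The chemistry is deliberately trivial: descriptor validity and
pipeline bookkeeping are under test, not pharmacology.

`make_regression_dataset` draws signal features z_i ~ N(0, 1), clones each
as ρ·z_i + √(1−ρ²)·ε (clone–generator correlation exactly ρ, clone–clone
ρ²), adds unrelated noise features, and sets y = Σ β_i z_i + N(0, σ).
Because the signals are independent and unit-variance, var(y) = |β|² + σ²
and the out-of-sample R² of any correctly specified model is bounded by the
analytic ceiling 1 − σ²/var(y); `noise_sd_for_ceiling` inverts that
relation. The truth record carries block membership, coefficients and the
ceiling, so tests can assert block recovery by the correlation filter and
ceiling recovery by linear regression (the acceptance checks use n = 2000,
5 seeds, ceiling 0.6, tolerance ±0.05 — sampling and estimation noise at
that n sit comfortably inside the band). An optional affine rescaling maps
y into the empirical logBB envelope [−2.69, 1.7] (R² is affine-invariant)
so binarization tests populate both classes.

What the fixtures do **not** emulate: real descriptor distributions (heavy
tails, discreteness, structural missingness), nonlinear
structure–activity relationships, activity cliffs, or assay noise that
varies by compound. Passing tests therefore demonstrate correctness of the
machinery and its statistical contracts, not predictive performance on
experimental logBB data — for that, the pipeline must be run on a real
curated dataset.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately modest sizes — hundreds to a
few thousand synthetic compounds, 10-fold CV, 5 seeds for Monte-Carlo
claims — chosen so each statistical assertion has enough power for its
tolerance while the whole suite stays quick to iterate on. Tolerances:
exact arithmetic identities at 1e-12, scaler round-trips at 1e-9,
noiseless-model recovery at 1e-6, Monte-Carlo recoveries at ±0.05.

Degenerate inputs are errors, not silent defaults: constant vectors for
Pearson/R², empty grids, k outside [2, n], unknown learners, and missing
feature columns at prediction time all raise named exceptions.

## Known limitations

- Fingerprint bit assignments are generator-specific; similarity values are
  not comparable across fingerprint software, only within a run.
- The pipeline trains on compounds that all carry observed logBB; it does
  not impute missing targets.
- Leader-pass deduplication depends on input order (documented and
  deterministic, but a different ordering can keep a different
  representative of a similar cluster).
- Applicability-domain estimation beyond the similarity screen is out of
  scope, as are consensus ensembles across learners.
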