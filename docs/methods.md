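# Methods

This note documents the models, algorithms and numerical choices behind
`qsar_garf`, in the order the pipeline runs them.

## Data model

A `DescriptorMatrix` is a compounds × descriptors real matrix with unique,
ordered row and column names; values must be finite at load time (molecular
descriptor generators emit complete tables, so missing values are treated
as input errors, not imputed). An `ActivityVector` holds molar pIC₅₀ =
−log₁₀(IC₅₀) per compound; a `QSARDataset` is their inner join plus a
per-compound split label in {train, test, unassigned}.

The packaged benchmark (`data/table3_fbpase.csv`) is a transcription of a
published 190-compound FBPase-inhibitor table: observed pIC₅₀ in
[3.60, 8.00], predictions of a GA-RF and a pure-RF model, and train/test
membership (126/64). The loader re-validates all three constraints on every
call, so a corrupted transcription fails loudly. The table carries no
out-of-bag prediction column, so the cross-validated coefficient r²_cv
cannot be recomputed from it and is reported as NaN in fixture-derived
reports; all other statistics reproduce the published values at their
printed precision.

## Descriptor filters

Three filters run in a fixed order; each output column set is a subsequence
of the input and the composition is idempotent.

1. **Sparse-zero** (`zero_fraction`, default 0.85): a descriptor is removed
   iff its fraction of exact zeros strictly exceeds the cutoff.
2. **Near-zero variance** (`freq_ratio_cutoff` 19 ≙ 95/5,
   `unique_percent_cutoff` 10): constants are always removed; otherwise a
   descriptor is removed iff the ratio of its most-frequent to
   second-most-frequent value count exceeds the cutoff *and* the percentage
   of distinct values is below the cutoff. This is the standard
   frequency-ratio/unique-percent rule used in QSAR preprocessing; the
   defaults are the conventional ones and both are configurable.
3. **Correlation** (`corr_cutoff`, default 0.75): while any descriptor pair
   has |Pearson r| above the cutoff, locate the worst pair and drop the
   member with the larger mean absolute correlation to all surviving
   descriptors; ties drop the later column in input order. The greedy rule
   is deterministic and order-stable, and the post-condition
   max |r| ≤ cutoff is asserted on every run. Correlation is computed on
   raw (unstandardized) values; zero-variance columns must be removed first
   (the near-zero-variance filter guarantees this in the pipeline order)
   and are an error here.

## SOM splitting

A small Kohonen map (6 × 6 = 36 units) probes the descriptor space.
Descriptors are standardized to zero mean / unit variance *for the map
only* — distance-based placement needs comparable scales, whereas the
forests later use raw values (tree splits are monotone-invariant).
Training is classic online SOM: 500 presentations per unit by default, the
winner is the nearest codebook vector (Euclidean), and all units move
toward the presented compound under a Gaussian neighborhood whose radius
decays linearly from max(rows, cols)/2 to 1 while the learning rate decays
from 0.5 to 0.01. The codebook is initialized from randomly drawn data
rows. Everything is driven by one seeded generator, so training is
reproducible.

The split rule enforces the two properties a rational split must have
(test compounds near training compounds; joint coverage of the occupied
map): the test quota per occupied unit is proportional to unit occupancy,
rounded by largest remainder to hit the requested test size exactly, under
the constraint that every unit retains at least one training compound
(singleton units contribute nothing). Within a unit the quota is sampled
uniformly; changing the seed changes only this within-unit sampling, never
the quotas. If the coverage constraint makes the requested test size
unreachable, the split raises rather than silently shrinking the test set.

## Random forest and OOB machinery

Trees are unpruned CART regression trees (scikit-learn
`DecisionTreeRegressor`); the bagging loop is implemented in the package
because the analyses need per-tree bootstrap bookkeeping:

* each tree trains on a bootstrap resample (n draws with replacement);
  `mtry` descriptors are sampled as split candidates at each node (default
  ⌊p/3⌋, the regression convention, and the value the benchmark's footnote
  implies: 13 of 40 and 36 of 108);
* a node with at most `min_node_size` = 5 compounds is not split further,
  matching the reference R implementation's `nodesize = 5` semantics
  (leaves may be smaller);
* the OOB prediction for compound i averages only trees whose bootstrap
  excluded i. With ntree ≥ 100 every compound has an OOB value with
  overwhelming probability; compounds without one are flagged and make
  OOB-based statistics raise rather than silently default;
* `%IncMSE` permutation importance: per tree, the OOB MSE after permuting
  one descriptor minus the tree's baseline OOB MSE, averaged over trees and
  divided by its standard error (the raw mean if the spread is zero);
* `IncNodePurity`: the total decrease in node sum-of-squares attributed to
  splits on a descriptor — the regression analogue of "mean decrease
  Gini" (Gini impurity is undefined for regression, so the label denotes
  node-impurity decrease here);
* the tree-count convergence experiment fits one forest at the largest
  requested size and evaluates prefixes, so the trajectory at the maximum
  coincides exactly with a directly fitted forest of that size and seed.

The node-size interpretation was cross-checked against R's `randomForest`
on identical data (external r² 0.42 here vs 0.436 there on the same split
and descriptor mask).

## Genetic algorithm

Chromosomes are binary masks over the descriptor columns with a hard
non-empty invariant (an all-zero mask produced by crossover or mutation is
repaired by setting one random bit). Defaults follow the classic GA-toolbox
pipeline: population 50, 200 generations (fixed-generation termination),
generation gap 0.9 (45 offspring), double-point crossover with probability
0.7, and bit-flip mutation at 0.7/p — the toolbox default for binary
strings, the only defensible reading of an otherwise unstated "default"
rate. Selection is linear ranking (selective pressure 2.0) realized by
stochastic universal sampling; ranking rather than raw-fitness proportional
selection because the fitness is an error to be minimized. Tied fitnesses
share averaged ranks, so a degenerate population is sampled uniformly.
Reinsertion is elitist: offspring replace the worst 90 % of the old
population, the best 10 % survive, making the best-ever fitness monotone
non-increasing — a hard invariant of the implementation.

Fitness is the OOB MSE of a forest (default 100 trees inside the GA, for
speed; the convergence experiment shows 100 suffices) fitted on the masked
training descriptors. The forest seed is derived from the GA seed and a
CRC-32 hash of the mask, and evaluations are memoized, so fitness is a
deterministic function of the mask: the search cannot be misled by forest
sampling noise between evaluations of the same mask, and identical
(dataset, config) runs are bit-identical.

## Validation battery

With y the observed and ŷ the predicted activities:

* r²_ncv and r²_ts — squared Pearson correlation (training resp. test);
* r²_cv = 1 − Σ(y−ŷ)²/Σ(y−ȳ_tr)² over the training set with OOB
  predictions (PRESS form);
* r²_pred = 1 − PRESS/SD over the test set, where SD sums squared
  deviations of the test observations from the *training* mean ȳ_tr;
* k = Σ y·ŷ / Σ ŷ² — least-squares slope through the origin, observed
  regressed on predicted; r²_o = 1 − Σ(y−kŷ)²/Σ(y−ȳ_test)², the
  through-origin determination coefficient with the test-set observed mean
  in the denominator (the Golbraikh–Tropsha convention; fixture
  recomputation confirms it reproduces the published values);
* r²_m = r²_ts·(1 − √(r²_ts − r²_o)), Roy's modified metric; it equals
  r²_ts when the two fits agree and approaches 0 as they diverge. A
  numerically negative difference within 1e−9 is clamped silently; larger
  negative differences clamp with a warning;
* the Tropsha gate applies the four criteria with strict inequalities:
  r²_pred > 0.5, r²_ts > 0.6, (r²_ts−r²_o)/r²_ts < 0.1, 0.85 ≤ k ≤ 1.15.

Y-randomization refits the supplied modelling procedure on label-permuted
training activities (a fresh permutation and seed per round; 500 rounds by
default, scaled down in tests), scoring training statistics against the
permuted labels and test statistics against the true test activities. A
model with real prediction power shows collapsing r² values and inflated
RMSE under this null.

## Synthetic data

The generator emulates the statistical structure of real descriptor
tables so every stage has an analytic answer key: k informative columns
~ N(0,1) drive a linear activity y = intercept + Xβ + ε with
ε ~ N(0, σ²); decoys are pure noise, near-duplicates of informative
columns at a chosen population correlation, zero-inflated sparse columns
with an *exact* zero count (so the sparse filter's decision is
deterministic), and constants. Column positions are shuffled. With
independent informative columns the population R² is
Σβ²/(Σβ² + σ²) — analytic, so acceptance bounds need no reference fit.

Default study conditions: 150 compounds, 100 descriptors, 10 informative
with unit coefficients, σ = √2.5 (population R² = 0.8), intercept 6.0 (a
pIC₅₀-like scale — a zero-mean response would make the through-origin slope
k meaningless), 10 sparse columns at zero fraction 0.95, 10 correlated
near-duplicates at r = 0.9, 3 constants. Ground-truth recall counts a
correlated near-duplicate as recovering its informative partner — the
standard accounting for redundant feature groups, where either member
carries the signal; a strict per-column recall is also provided.

What the generator does *not* emulate: real descriptor distributions
(integer counts, heavy tails), nonlinear structure–activity landscapes, and
activity cliffs. Passing tests therefore demonstrate that the machinery
behaves correctly under a known linear signal, not that GA-RF is the best
model for any particular chemistry.

A second generator produces Gaussian blobs whose adjacent centroids sit a
specified distance apart along the main diagonal — on every axis, so the
separation survives the SOM's per-descriptor standardization — for testing
map organization and split coverage.

### Scale of the behavioural checks

The acceptance suite runs the GA-recovery check at population 30 / 30
generations / 100-tree fitness over 10 seeds on the default conditions
(about a minute per seed on one core), and the Y-randomization collapse at
20 rounds. The collapse demonstration premises a strongly predictive
unpermuted model; on the diffuse default signal (R² = 0.8 spread over 10
equal coefficients) a random forest attains external r² of only ≈ 0.3–0.6
— confirmed against R's `randomForest` on identical data, an information
limit of the method on diffuse additive signals, not an implementation
artifact — so that demonstration uses a concentrated variant: 3 informative
descriptors with β = 2 and σ = √3, the same population R² = 0.8.

## Degenerate inputs and tie-breaks

* Pearson r² is NaN (reported as missing, never an exception) when either
  vector is constant; PRESS-based statistics raise on a zero denominator.
* BMU ties resolve to the lowest unit index; correlation-filter ties drop
  the later column; reinsertion ties survive oldest-first; all RNG streams
  are `numpy` `default_rng` seeded from the configuration.
* The final model's mtry defaults to ⌊p_selected/3⌋; an explicit override
  exists for tuning sweeps.
* CLI exit codes: 0 success, 2 validation-invariant failure (Tropsha gate
  fails on `validate`/`run`), 3 input error.

## Known limitations

* The original 777-descriptor matrix behind the published benchmark is not
  distributable, so end-to-end selection on the real data (the 40-descriptor
  subset, the published r²_cv = 0.67, the published tuning medians) is out
  of reach; the packaged table supports the validation battery only, and the
  behavioural properties are established on synthetic ground truth instead.
* The SOM uses a fixed rectangular topology and linear schedules; it is a
  splitting device, not a general-purpose SOM library.
* Y-randomization with the full GA inside each round is supported through
  the procedure interface but is computationally heavy; the default
  procedure refits the forest on the already-selected mask, which is the
  conventional compromise.
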