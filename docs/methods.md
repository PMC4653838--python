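# Methods

## The integration model

The package treats each omics data type as a patient × feature matrix
X⁽ᵏ⁾ on a shared patient set. Instead of merging raw features, it maps
every data type into the space of patient–patient correlations: P⁽ᵏ⁾
(Pearson) and S⁽ᵏ⁾ (Spearman with midranks) between patient rows. These
matrices are dimensionless, bounded in [−1, 1] and — for Spearman —
invariant under any strictly increasing transform of the measurements, so
data types measured on arbitrary scales become commensurable. The
column-wise stack Y = [P⁽¹⁾ S⁽¹⁾ … P⁽ᴷ⁾ S⁽ᴷ⁾] is the extracted feature
matrix; the integrated similarity Z is the Pearson correlation of the
rows of Y. Two patients are similar when their correlation profiles to
all patients, across all data types, agree. There is no weight, kernel
bandwidth or other tunable parameter anywhere in the pipeline.

Assumptions worth keeping in mind: all data types must cover the same
patients (the loaders take the intersection and re-sort; patients missing
from any data type are dropped — the method itself has no missing-data
story); each data type needs at least two features and three patients for
row-wise correlation to be meaningful; and a patient with a constant
feature row has no defined correlation to anyone — such pairs are
assigned similarity 0 with a warning, keeping the matrices well formed.

Numerical choices: correlations are computed on full rows (no column
standardization — Step III centers and scales internally, which keeps the
parameter-free property), symmetrized, clipped to [−1, 1], and the
diagonal is forced to 1. Symmetry and diagonal assertions use a 1e−10
tolerance. Blocks are stacked in the supplied data-type order with P
before S; Step III is invariant to column order, so this affects only
bookkeeping.

## The simulation scenarios

Five generators isolate individual failure modes of integration. All
default to 100 patients (two planted classes of 50) × 100 variables,
block amplitude 1; class-1 patients are elevated on the first half of
the variables, class-2 on the second half.

- **sd1 (scale conflicts).** One prototype D0 = blocks + standard-normal
  noise on every entry; observed as T1 = D0^q and T2 = q^D0 elementwise.
  Noise is added *before* the transforms — this is the crux of the
  scenario, because the heavy-tailed powers destroy Pearson structure
  while rank structure partially survives. q defaults to 20, the value
  used throughout the reference benchmark; q must be an integer (negative
  noisy entries under fractional powers would be complex) and q = 1
  degenerates (1^x is constant), which triggers a warning.
- **sd2 (noise types).** Clean prototype; T1 adds Normal(0, q), T2 adds
  Uniform(0, q) noise.
- **sd3 (noise sizes).** Normal noise with two different standard
  deviations, default (0.5, 2.0); equal values are rejected.
- **sd4 (incomplete relationships).** Each data type defines only one
  class's block; the other patients are all-zero rows. Only the union of
  both data types determines the full bipartition.
- **sd5 (conflicting relationships).** The first data type plants the
  standard bipartition; the second plants an offset one (outer 30+30
  patients vs middle 40), mirrored in the same block style so both carry
  equal signal. The 4-class truth (sizes 30/20/20/30) is the common
  refinement of the two bipartitions.

The noise scale q of sd2/sd4/sd5 is a free parameter of the study design;
the default is 1.0 and the directional tests sweep q ∈ {0.5, 1, 2} to
show the orderings are not an artifact of one setting.

A **realistic** augmentation doubles the second class (fresh prototype
rows and fresh noise), appends 50 unclassified patients whose features
are pure standard-normal noise, and pads each data type with 10× as many
uninformative standard-normal features as informative ones (200 patients
× 1100 variables in the default design). Unclassified patients take part
in every representation but are excluded from label-dependent scoring.
All generators are bit-deterministic functions of their spec (seed
included); per-source noise streams are spawned from the master seed.

What the generators do *not* emulate: realistic omics marginals
(beta-values, counts), feature correlation structure, batch effects,
missingness, or survival times. Passing benchmarks here demonstrates
robustness to the isolated failure modes, not performance on any
particular real cohort.

## The evaluation metrics

- **Pairwise similarity.** Mean Pearson correlation between patient
  pairs, split into within-class and between-class averages (diagonal
  excluded). For the raw baselines the correlations are computed from the
  (concatenated) data rows; for the integrative variants the patient-pair
  Pearson correlation in the extracted feature space *is* Z, so the
  metric averages Z's entries directly. A Gaussian-kernel analogue uses
  exp(−d²/2σ²) on Euclidean distances of the representation rows with σ =
  median off-diagonal distance (a fixed bandwidth is accepted as an
  option; if all points coincide the similarity is defined as 1 with a
  warning).
- **Class discovery.** k-means with many random initializations (default
  1000; the benchmark runs use 100), keeping the partition with the
  minimal total point-to-centroid squared distance, scored by normalized
  mutual information against the planted truth. NMI uses the sqrt
  normalization I(A;B)/√(H(A)H(B)) (max-normalization available); when a
  partition has zero entropy the value is 1 for identical partitions and
  0 otherwise. k = 2 for sd1–sd4, k = 4 for sd5.
- **Class prediction.** Leave-one-out cross-validated random-forest
  accuracy (√p features per split, per-fold derived seeds). The default
  forest has 100 trees; the benchmark and acceptance runs use 50, where
  LOO accuracy on ~100-patient cohorts has long plateaued — this keeps a
  full benchmark repeat within seconds on one CPU.
- **Cluster-number selection** (for unlabeled data): for each k in 2..10
  the full cohort is clustered and compared, via NMI on shared patients,
  with clusterings of random 80% subsamples; the most reproducible k wins
  (ties favour the smaller k). Subsampling is what makes the score
  discriminative — with fixed data, best-of-many-restarts k-means is
  effectively deterministic at every k, so repeated full-data runs would
  call every k perfectly stable.

The benchmark runner repeats a scenario (default 100 repeats; the
acceptance runs use 20), scores each requested method and reports
mean ± sd per metric, with every report embedding the configuration that
produced it.

For iBFE the features handed to k-means and the classifier are the rows
of Z (the final integrated representation); for the baselines they are
the raw (concatenated) columns. The single-data-type baselines are
evaluated on their raw matrices; evaluating them in their own
correlation space is a defensible alternative reading of "the features
each method constructs", and would change their scores — the choice is
deliberate and fixed here.

## Survival analysis

Subtype prognosis uses the Kaplan–Meier product-limit estimator per
cluster and a two-group log-rank test of each cluster against all
remaining patients (chi-square reference, 1 df). Censorings tied with
events at the same time are treated as occurring after them, the
standard product-limit convention. P-values are reported uncorrected,
one test per cluster, mirroring per-cluster reporting practice; readers
comparing many clusters should adjust accordingly. No Cox modelling,
covariate adjustment or competing-risks handling is attempted.

## Problem sizes of the shipped analyses

The test suite and `scripts/acceptance.py` run the sd1 benchmark with 20
repeats, 100 k-means restarts and 50-tree forests, and the directional
sweeps with 4 repeats per setting — sizes chosen so a full run of either
finishes in minutes on a single CPU while keeping the Monte-Carlo error
of every reported mean well inside the tolerances being checked (the
repeat-to-repeat sd of each metric is at most a few hundredths).

## Known limitations

- The integrated similarity is transductive: adding a patient changes
  everyone's features, so there is no out-of-sample mapping.
- Z is M × M; the method extracts at most M features per correlation
  kind, which is a compression for omics-scale feature counts but not
  for tiny cohorts.
- Two reference values of the original scale-conflict comparison (the
  single-data-type classification accuracy and the integrated
  within-class correlation level) are not recovered by this
  implementation under the stated generative settings; the discrepancy
  is stable across seeds and interpretation variants we tested and is
  documented where those checks run. All qualitative orderings, and the
  remaining reference values, reproduce.
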