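# Methods

## The classification model

Each patient contributes a whole-lesion set of ADC voxel values (units
10⁻⁶ mm²/s throughout; readers convert from 10⁻³ mm²/s when a file declares
it). Values are binned on a shared grid of half-open intervals
`[origin + m·w, origin + (m+1)·w)`, default `origin = 0`, width `w = 100`,
40 bins covering 0–4000. The upper limit is a package choice: free-water ADC
is ≈ 3000, so 4000 leaves margin; the edge convention (boundary value goes
to the right-hand bin) is likewise fixed here because exact tests require
one. Both are configuration, not constants. Values above the grid are
clamped into the last bin with a warning by default — rare hot voxels should
not abort a pipeline — while `overflow_policy="error"` is available and used
in tests to catch fixture mistakes.

For each tumor class t ∈ {PA, WT, MT}, the reference distribution is the
pooled empirical PMF of all voxels of that class's patients:

    p_{t,m} = (Σ_i O_m(i) + α) / (Σ_i N(i) + α·M)

with M bins and α Laplace pseudo-counts per bin (default α = 0.5). Pooling
is by voxel, not by patient: a patient with twice the voxels influences the
reference twice as much, which is exactly what "pooling the data" means and
what the chi-square expected counts presuppose. Smoothing keeps every
statistic finite; with α = 0 the raw empirical PMF is used and a bin with
zero expected but positive observed count yields an infinite statistic
(deterministically ordered after all finite values; two infinities tie).

Classification computes `T_t(i) = Σ_m (O_m(i) − N(i)p_{t,m})² / (N(i)p_{t,m})`
per candidate class and takes the argmin. Exact ties are broken by the fixed
class order PA < WT < MT and flagged; the tie rule exists purely for
reproducible cross-validation, real-valued statistics essentially never tie.

## The mean-ADC comparator

The comparator reduces each lesion to its mean ADC and applies two
thresholds, MT-vs-PA and MT-vs-WT, each fitted by maximizing the Youden
index J = sensitivity + specificity − 1 over candidate cuts at the midpoints
between consecutive distinct observed means (±∞ sentinels included) and both
orientations (MT below or above the cut). Midpoints realize every achievable
confusion matrix, so the search is exhaustive without being continuous.
Orientation is learned rather than assumed: the expected ordering (PA high,
WT low, MT between) holds on average, but small resampled training sets can
invert it, and a learned orientation keeps every CV fold well-defined. Ties
in J break toward the smaller cut, then toward "MT if ≤".

Two pairwise thresholds do not by themselves define a three-class rule. The
rule used here is the minimal one consistent with the band structure
(WT below, PA above, MT between): a patient is MT iff both thresholds vote
MT; otherwise the benign class whose threshold vetoed MT decides; if both
veto, the class whose threshold the mean clears by the larger margin wins
(ties to PA). This combination rule is this package's own construction and
is only used where a three-way mean-based decision is required (CV metrics);
pairwise evaluations always use the single relevant threshold.

## Evaluation

Apparent (resubstitution) performance fits references and thresholds on the
full cohort and classifies the same patients. Pairwise sensitivity and
specificity treat MT as positive; MT-vs-PA and MT-vs-WT restrict both the
candidate set and the evaluated patients to the pair (their own
two-candidate decisions — this is what lets MT-vs-PA and MT-vs-WT
sensitivities differ), while MT-vs-benign uses the three-way rule over all
patients.

Predictive performance uses three schemes, all pooling held-out predictions
into one confusion matrix (micro-averaging; stable with a 21-patient
class — a macro switch averaging per-repeat metrics exists for repeated CV):

- **LOOCV** — deterministic; each patient classified by models fitted
  without them. An in-loop assertion verifies the held-out id is absent from
  every fitted reference's source set.
- **Repeated stratified k-fold** (default k = 10, 1000 repeats) — each
  class's shuffled patients are dealt round-robin over the folds, so
  per-class fold counts differ by at most one and no fold can empty a class
  that has ≥ k patients; with k = n the scheme reduces exactly to LOOCV.
  A fold that would still empty a training class (possible only for a
  singleton class) is skipped and counted in the report diagnostics.
- **Stratified bootstrap** (default 1000 iterations) — within each class,
  as many draws with replacement as the class has patients (so the training
  multiset never loses a class); evaluation is on the out-of-bag patients,
  the honest analogue of a test set. Iterations with an empty out-of-bag set
  are skipped and counted.

Metrics: total accuracy (trace/total), per-class precision and true-positive
rate, and the pooled benign row (PA and WT merged). A precision whose
denominator is zero is reported as null, never 0 — "never predicted" is
different information than "always wrong". Every report embeds the
configuration that produced it (binning, α, k, repeats, seed), and identical
seeds give byte-identical serialized reports.

## The synthetic cohort generator

The generator emulates the study conditions: 73 patients, 30 PA / 22 WT /
21 MT, per-patient voxel counts uniform on [50, 5000] (the lower bound is
the smallest eligible lesion, ~1 cm³ at 2×2×5 mm voxels). Each class is a
finite mixture of truncated-at-zero normals on the ADC scale:

| class | components (weight, location, scale) | mixture mean | skew |
|-------|--------------------------------------|--------------|------|
| WT | (1.00, 850, 120) | 850 | ~0 |
| MT | (0.80, 950, 150), (0.20, 1900, 300) | 1140 | + |
| PA | (0.85, 1950, 200), (0.15, 1250, 250) | 1845 | − |

Mixtures were chosen over a skew-normal parameterization because the
skewness of these lesions is mechanistically a two-population story (dense
cellularity plus necrosis for MT), which a mixture encodes directly, and
because mixture moments have closed forms the tests use as oracles. The
numeric locations and scales are this package's own invention — no
published per-class voxel summaries exist to calibrate against — and are
plain configuration. All components sit ≥ 5 standard deviations above zero,
so the zero-truncation (implemented by redrawing negative values within
their component) perturbs the closed-form moments negligibly.

`overlap_factor` f ∈ [0, 1] interpolates every class toward one common
truncated normal at the grand mean (scale 300): each component keeps weight
w(1−f) and moves a fraction f of the way in location and scale, while a
shared component of weight f absorbs the rest. At f = 0 the defaults are
untouched; at f = 1 the three class distributions coincide exactly, giving a
chance-level control for any classifier built on them.

Voxels are i.i.d. within a patient; no spatial correlation is simulated.
Every downstream computation is histogram-based, so spatial structure would
be invisible to it. The map/mask synthesis (`generate_map_and_mask`) places
a patient's values under a deterministic ellipsoid-like mask in a background
of parenchyma-like draws (N(1100, 150) truncated at zero) purely to exercise
the NIfTI ingestion path; extraction recovers the values exactly.

**What passing tests do and do not show.** The default cohort's classes are
cleanly separated, so perfect recovery there demonstrates pipeline
correctness (no leakage, correct pooling, correct decision rules), not
clinical performance; real cohorts overlap and their accuracy depends on
that overlap, which `overlap_factor` can emulate but not calibrate. The
generator also omits scanner noise, intra-lesion spatial structure, and
inter-patient heterogeneity of the class-conditional distributions (every
patient of a class shares one mixture), all of which would lower real-world
performance relative to the synthetic figures.

## Numerical choices and degenerate inputs

- PMFs are renormalized after smoothing to absorb sub-ulp rounding; the
  normalization invariant is enforced at 1e-12.
- Masks must be exactly {0, 1}; anything else is rejected rather than
  thresholded, so segmentation errors surface.
- Chi-square with mismatched binning schemes, empty classes after exclusion,
  fewer than two candidate classes, and empty voxel lists are all validation
  errors, not silent coercions.
- Problem sizes in the distributed tests and acceptance script: the full
  73-patient cohort for LOOCV and the chance-level control, 1000
  repeats/iterations for repeated CV and bootstrap in the acceptance script,
  and small cohorts (6–7 patients) where a hand-unrolled oracle is the
  point. These sizes keep a full run in tens of seconds on one CPU while
  exercising every code path at the study's stated scale.

## Known limitations

- The three-way mean-ADC combination rule is a construction of this package
  (only the two pairwise thresholds are standard); alternative combinations
  could shift the mean-method CV numbers.
- The chi-square statistic is used as a raw discrepancy score; no
  degrees-of-freedom calibration or p-values are attached, and none are
  needed for the argmin rule.
- Parametric reference models and likelihood-based scoring are out of scope.
- Bootstrap evaluation is out-of-bag; optimism-style corrections evaluating
  on the full sample are not implemented.
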