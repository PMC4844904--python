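# Methods

## Model and procedure

The framework assumes a balanced case/control voice study in which each
subject contributes exactly one recording per vocal test and every
recording is described by the same fixed feature panel. Its central
modelling assumption is that class signal is *test-localised*: a few
speaking exercises separate PD from control speech well, most do not,
and a recording's informativeness depends on which exercise produced it.
The pipeline therefore (1) splits the recording table into one
subjects × features matrix per test, (2) z-scores each matrix
column-wise, (3) screens each test's features by the correlation filter,
(4) trains one classifier per surviving test on its own selected
features, evaluated by leave-one-out (LOO) over subjects, and (5) fuses
the per-test predictions by unweighted majority vote.

Because every subject has exactly one row in each per-test matrix, plain
LOO never splits a subject across train and test — the property that
makes per-test modelling attractive compared with pooled designs, where
leave-one-subject-out bookkeeping is needed.

The correlation filter treats each feature against the binary label:
Pearson's r (equivalently the point-biserial correlation) with a
two-sided p-value from the Student-t transform t = r·√((n−2)/(1−r²)),
df = n−2. Selection uses strict inequality p < α. Two-sided testing is
used because dysphonia features can shift in either direction.

Unsuccessful tests (no feature with p < α) are resolved by policy:
**MCFS** assigns them the `fallback_k` features most frequently selected
across all tests — frequencies are always computed from the data at
hand, never hard-coded — with ties broken deterministically by lower
feature index; **A-MCFS** omits them from the ensemble. A vote tie
(possible when an even number of tests votes) is resolved toward PD:
in a screening setting a false negative is the costlier error.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | two-sided selection threshold per (test, feature) |
| `fallback_k` | 4 | MCFS fallback feature count |
| k-NN `k` | 1/3/5/7 | Euclidean neighbours; odd, so votes cannot tie |
| SVM `C` | 1 | penalty, both kernels |
| RBF `sigma` | 3 | K(u,v) = exp(−‖u−v‖²/(2σ²)), i.e. gamma = 1/(2σ²) ≈ 0.056 |
| `fold_safe` | off | re-fit normalisation *and* selection per LOO fold |

"Discriminant analysis" is linear discriminant analysis with pooled
covariance. s-LOO summary codes follow the numbering 1 mean, 2 median,
3 trimmed mean (25% removed), 4 SD, 5 mean absolute deviation, 6
interquartile range; the canonical pairings are (1–4), (2–5), (3–6) and
(all). "25% removed" is read as 12.5% from each tail (configurable via
`trim_fraction`); "mean absolute deviation" is deviation about the
mean, not the median-based MAD.

## Validation protocols and leakage

The default ("faithful") protocol fits the z-score transform and the
feature selection once on all subjects before cross-validation. This
reproduces the historical protocol this framework is defined by, but it
leaks the held-out subject into scaling and selection; on pure-noise
inputs the spuriously selected features genuinely separate the full
sample, so faithful-mode accuracy on null data is strongly optimistic.
`fold_safe=True` removes the leak completely: for each held-out subject
the normalisation, the per-test selection and the MCFS/A-MCFS plan are
all re-fit on the remaining subjects only.

Leakage-free operation exposes a second, opposite bias that users should
expect: with one subject held out, every training fold is 19-vs-20
imbalanced, so each per-test LOO classifier tilts slightly toward the
majority training class — the class the held-out subject does *not*
belong to. Majority voting over ~k independent such voters amplifies a
per-voter bias ε to roughly √(2k/π)·ε, so on pure-noise tables the
fold-safe framework scores systematically *below* 50% (the acceptance
suite measures this directly). This is a property of majority-vote LOO
on balanced nulls, not an implementation artefact; the per-test and
pooled-LOSO oracles in the test suite confirm fold handling by
exhaustive enumeration.

## Synthetic data

The generator emulates the study geometry: `n_subjects` balanced
subjects, `n_tests` × `n_features` per subject, features within a test
drawn from a multivariate Gaussian with exchangeable correlation
`feature_corr` (default 0.3 — real jitter/shimmer families are strongly
inter-correlated and a common factor is the simplest structure exposing
that to the selector). Informative tests add `effect`·`noise_sd`
(default 1.5 SD on features 1–4 of tests 4, 6, 7) to the PD class mean.
One seeded `numpy` generator drives all randomness; identical seeds give
bit-identical tables.

What the generator does **not** emulate: the marginal shapes of real
acoustic features (log-normal jitter, zero-inflated voice-break counts),
cross-test correlation within a subject, label noise, or severity
gradation (UPDRS). Passing tests on synthetic data therefore demonstrate
the machinery — separation, selection calibration, voting, the
superiority of per-test modelling when signal is test-localised — not
clinical performance on real recordings.

## Numerical choices and degenerate inputs

- Constant feature columns: z-scoring maps them to zeros (with a logged
  warning) rather than erroring; the correlation filter skips them
  (never selected).
- Sample (n−1) standard deviations everywhere.
- MCC with a zero factor in the denominator is defined as 0 (logged).
  Reports round percentages to 2 decimals and MCC to 4; machine-readable
  output keeps full precision.
- k-NN neighbour-distance ties follow training-row order; training-row
  permutation invariance of predictions is property-tested for all
  families.
- Linear discriminant analysis falls back to a pooled-covariance
  decision with a tiny ridge (1e-9 scale) when the within-class scatter
  is identically zero (e.g. a feature equal to the label), where the
  standard solver is undefined.
- The RBF kernel at σ = 3 is calibrated for the low-dimensional selected
  feature subsets (1–6 columns). On high-dimensional z-scored inputs
  (pooled LOSO at 26 columns, s-LOO summary vectors at 156) pairwise
  distances grow with dimension and the kernel collapses toward zero,
  degrading the SVM to majority-class prediction; baselines at those
  dimensionalities are more meaningfully run with the linear kernel.
- The headerless train-file dialect does not record vocal-test identity;
  `test_id` 1..26 is assigned by row order within each subject block.
  This ordering assumption is documented at the reader and holds for the
  public train file, whose 26 recordings per subject are stored in test
  order.

## Problem sizes

Monte-Carlo checks in the test suite and the acceptance script use 10–50
seeds at the native study size (40 × 26 × 26); these sizes give
Monte-Carlo standard errors around 1 percentage point on accuracy means,
adequate for the qualitative claims being tested.

## Known limitations

- The faithful protocol's selection leakage (above) means its absolute
  accuracies are optimistic; comparisons *between* schemes run under the
  same protocol remain meaningful.
- Majority voting weights all surviving tests equally; a test that
  barely passed the filter votes with the same weight as a strongly
  informative one.
- The framework assumes every subject completed every test; missing
  recordings are rejected at parse time rather than handled.
- With 26 features per test and n = 40, the 5% filter admits ≈1.3
  spurious features per noise test, so A-MCFS typically retains several
  uninformative voters; the vote, not the filter, suppresses them.
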