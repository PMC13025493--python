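# Methods

This note records the quantitative conventions the package implements, the
synthetic phantom model, and the known limits of both.

## Ensemble aggregation

An ensemble prediction is K ≥ 2 member probability maps on one pixel grid
with one pixel spacing. The consensus mask is the pixel-wise mean map
thresholded **strictly** above 0.5; a mean of exactly 0.5 is background. The
same strict rule produces per-member masks when per-member areas are needed.

Monte-Carlo dropout ensembles arrive as T ≥ 2 stochastic passes over F
models. Aggregation is two-stage: fold-wise mean over passes first, then the
mean across folds. With equal pass counts per fold this equals the grand
mean; the two-stage form is kept because it defines the "members" whose
spread the epistemic metrics measure.

## Uncertainty metrics

For mean map p̄ and members p_k, with H₂ the base-2 binary entropy and the
convention 0·log 0 = 0:

| metric | definition |
|---|---|
| `avg_probability` | mean over pixels of max(p̄, 1−p̄) |
| `avg_probability_sm` | mean of p̄ over consensus pixels only |
| `avg_calibrated_probability` | `avg_probability` after Platt calibration |
| `cov_pixelwise` | mean over eligible pixels (p̄ > 10⁻⁶) of SD_k(p_k)/p̄ |
| `cov_sma` | sample SD / mean of per-member mask pixel counts |
| `avg_variance` | mean over pixels of the population variance across members |
| `avg_variance_sm` | same, over consensus pixels only |
| `avg_entropy` | mean over pixels of H₂(p̄) |
| `expected_entropy` | mean over members and pixels of H₂(p_k) |

Pixel-wise spread uses the **population** (1/K) variance — the K members are
the whole ensemble, not a sample. Per-member areas use the **sample** (n−1)
CoV. Undefined values (empty consensus region, no calibration model, zero
mean area) are NaN in memory and the explicit marker `NA` in CSV output,
never 0. By Jensen's inequality `avg_entropy ≥ expected_entropy`; their gap
is the mutual-information-style disagreement term, and both entropies
coincide exactly when members agree.

Platt calibration fits p ↦ σ(a·logit(p) + b), a ≥ 0, by logistic regression
(effectively unregularized, C = 10⁶) on probability/label pairs, with
probabilities clipped to [10⁻⁷, 1−10⁻⁷] before the logit.

Uncertainty–error association is the Pearson correlation with the exact
two-sided t transform p-value, t = r·√((n−2)/(1−r²)). Interpretation bands on
|r|: (0, 0.3] weak, (0.3, 0.5] moderate, (0.5, 0.7] strong, (0.7, 1) very
strong, exactly 1 perfect (values within 10⁻¹² of 1 are snapped — exactly
collinear data should not be demoted by floating-point roundoff).

## Quantification

SMA (cm²) = pixel count × row spacing (mm) × column spacing (mm) / 100;
SMI = SMA / height² with height restricted to (0.5, 2.5) m. Percent
difference is (measured − reference)/reference × 100, reference > 0. The
six-month weight loss uses the weight record closest to 182 days before the
reference date, within ±45 days. The cachexia label follows the Fearon rule
with strict inequalities — loss > 5% at BMI ≥ 20, or loss > 2% at BMI < 20 —
and is undefined (None), not false, when BMI is missing.

## Agreement

From confusion counts (tp, fp, fn): Dice = 200·tp/(2tp+fp+fn),
Jaccard = 100·tp/(tp+fp+fn), related by D = 2J/(1+J); both undefined when
both masks are empty. Signed area difference = (fp − fn)/(tp + fn) × 100,
which equals the SMA percent difference — the overlap scores and the area
difference are all functions of the same three counts. Bland–Altman:
differences d = comparator − reference, bias = mean(d), limits of agreement
= bias ± 1.96 × sample SD(d).

## Triage

A case is flagged iff its uncertainty metric is **strictly** above the
threshold; a case is high-error iff |SMA % difference| is strictly above the
cutoff (default 2.5%). Sensitivity and specificity are NaN, not 0, when their
denominator is empty. Quantile thresholds use the nearest-rank convention
(the ⌈q·n⌉-th order statistic), so the threshold is always an observed value
and at most (1−q)·n cases sit strictly above it. Threshold selection
policies: `max_youden` (maximize sensitivity + specificity − 1),
`sensitivity_floor` (smallest threshold meeting the floor; an infeasible
floor raises an error naming the best achievable), `review_budget`
(smallest threshold whose flagged fraction fits the budget — flag as many
cases as the budget allows), and `quantile`. Ties break toward the lower
threshold, i.e. toward sending more cases to review.

## DICOM and L3 selection

A slice is axial when |(row × col)·ẑ| > 0.9 — invariant to in-plane rotation,
admitting mild gantry tilt while excluding sagittal/coronal planes. Slices
group by (study, series, frame of reference, acquisition number, slice
thickness, spacing between slices) and sort by patient-z; duplicate positions
are kept and reported, never silently dropped. HU = slope·raw + intercept.
The L3 level comes from an external anatomical label volume in which L3
carries label 29: the longest contiguous run of labeled slices wins (ties
toward the inferior run), and the selected slice is the floor midpoint of
that run (`mid`) or its last slice (`end`). Reimplementing the anatomical
labeling itself is out of scope — it is a file-based pluggable input.

## Synthetic phantom model

Patient CTs and trained segmentation weights cannot ship with the package,
so end-to-end behaviour is exercised on parametric phantoms: an elliptical
fat-density body containing two paraspinal ellipses, two psoas ellipses, an
anterior abdominal-wall annulus sector and a bone disc, with Gaussian HU
noise. The default totals ≈5,800 muscle pixels at 1.5 mm spacing on a
256×256 grid (≈130 cm², a typical adult L3 SMA) and scales with grid area.
Rendered masks are guaranteed within 5% of the requested component areas;
overlapping or out-of-body components are rejected with a diagnostic.

Simulated ensemble members derive from the reference mask through three
separable knobs: `boundary_sigma` blurs the indicator into a shared boundary
probability ramp (aleatoric-like), `member_jitter` warps each member by an
independent smooth displacement field with the given RMS amplitude
(epistemic: members disagree on the boundary), and `label_noise` flips
isolated probabilities. With all knobs at zero every member equals the mask
indicator exactly.

Corruptions emulate out-of-distribution scans (`severity` 0 is the identity):
`streak_artifact` adds, inside Gaussian-profiled bands, a shared logit-space
bias (shifting the consensus and hence the measured area) plus
member-specific logit noise (inflating disagreement) — accuracy degrades and
uncertainty rises together, which is precisely the coupling the triage rule
exploits; `field_truncation` zeroes a lateral strip; `blur` and
`intensity_shift` act as named.

**What the phantoms are not:** they do not model CT physics, anatomy beyond
coarse L3 topology, inter-patient texture, or a real segmentation network's
failure modes. They validate the arithmetic and the qualitative
uncertainty–error coupling, not clinical accuracy. Published per-image
benchmark rows (bundled as plain data in `musclequant.benchmarks`) anchor the
summary-statistics, overlap-identity and triage arithmetic against a real
clinical evaluation.

## Numerical choices and open decisions

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; cohort generation draws per-case child seeds below 2³¹.
- Median: midpoint interpolation.
- Logit clipping: 10⁻⁶ inside the corruption model, 10⁻⁷ in calibration.
- The nearest-rank quantile, strict comparisons, entropy base 2 and the
  population/sample variance split above are deliberate, tested conventions;
  changing any of them changes reported metrics.
- The review-budget policy prefers the smallest feasible threshold (flag the
  most cases the budget allows); a workload-minimizing variant would prefer
  the largest.
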