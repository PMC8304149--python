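# Methods

## Scope

`octriage` implements an automated diagnosis pipeline for oral optical
coherence tomography (OCT) B-scans, of the kind used to triage suspicious
oral lesions at the point of care: frame quality gating, mirror-pair
segmentation of raw device frames, a scalar attenuation ("algorithm") score
with published class bands, an embedding + linear-classifier cascade with
per-site aggregation and ROC cut-offs, a three-test triage decision tree,
and diagnostic-accuracy arithmetic with exact binomial intervals. Because
the clinical image data behind such devices is not publicly deposited, the
package ships a synthetic B-scan simulator that reproduces the statistical
structure every stage assumes, so the whole pipeline is testable end to end.

## The forward model (synthetic B-scans)

A B-scan is rows = depth (pixel pitch 7.0 µm), columns = lateral position
(15.0 µm), intensities in [0, 1]. The mean image is layered:

* air gap above a gently undulating surface row (background 0.02);
* optional bright keratin cap (dorsal tongue);
* epithelium starting at intensity 0.85 and decaying as
  `exp(−2 µ_epi ∆z)` with depth ∆z in µm;
* a 2-px bright basement-membrane line whose brightness scales with a
  contrast parameter in [0, 1] (0 = destroyed, as in carcinoma);
* stroma continuing the decay with its own coefficient µ_stroma.

The mean image is multiplied by unit-mean gamma speckle (shape 9 by
default, i.e. ≈33 % multiplicative noise; shapes ≥ 10⁶ are treated as the
noise-free limit) and clipped to [0, 1]. Dorsal-tongue frames additionally
carry vertical shadow stripes (papillae shadowing). No refraction,
polarization, or wave optics: this is the minimal model supporting every
measurement the pipeline makes.

In the noiseless single-layer limit the column log-intensity is exactly
linear with slope `−2 µ_epi · 7.0 · log10(e)` per pixel on the log10 scale
(`SLOPE_PER_MU ≈ 6.0801` per µm⁻¹); the test suite verifies recovery of
this closed form to 1e-6.

### Class profiles and calibration

Each of the six diagnosis classes maps to one sampling profile. The
attenuation means are set so the ideal decay slope equals the published
class score means — carcinoma −0.0651 (µ ≈ 0.0107 µm⁻¹ ≈ 10.7 cm⁻¹·10),
dysplasia −0.0828 (µ ≈ 0.0136), normal/benign −0.0943 (µ ≈ 0.0155) — which
places the attenuation coefficients in the 10–16 mm⁻¹ range reported for
oral mucosa. Basement-membrane contrast weakens with grade (0.65 normal →
0.35 severe dysplasia → 0 carcinoma) and epithelial thickness grows with
it. Site factors impose the anatomical thickness ordering (floor of mouth
0.60 < ventral tongue 0.80 < … < buccal 1.25, relative to the class mean).

The between-site spread of the sampled attenuation corresponds to ≈0.0025
score units. This is deliberately far below the ±0.012–0.015 dispersions
printed for patient cohorts: that dispersion is patient-level heterogeneity
(habits, ulceration, chromophores) the simulator does not emulate, and
band-level classification of per-site scores would be impossible under it
(the normal-class mean lies 0.0025 from its band edge). Consequently,
passing tests demonstrate that the *pipeline arithmetic* recovers what the
generator encodes — not that real lesions separate this cleanly.

A one-time script (`scripts/calibrate.py`) runs the canonical
simulate → gate → split → score protocol and fits the affine map from raw
median slope to the published score scale; the committed constants are
gain 1.014234, offset 0.001289 (i.e. the raw slope is already on-scale and
calibration corrects residual window/edge effects of order 1e-3).

### Quality drift

Frame quality degrades linearly with acquisition order: Gaussian blur sigma
0.03 px per frame index and additive noise sd (0.03/1500) per index. These
magnitudes are tuned to the detection scale of the quality model — dropout
probability rises smoothly from ≈15 % at index 0 to 100 % by index ~11,
reproducing a study-like "poor-quality images removed, quality worsening
with acquisition order" regime that the ADF/KPSS stationarity checks can
see. They are perceptually subtle; the synthetic world's statistics are far
tighter than clinical imagery, so detectable degradation is numerically
small.

## Quality gating (NIQE-style)

The no-reference score follows the natural-scene-statistics recipe:
mean-subtracted contrast-normalized (MSCN) coefficients with
Gaussian-weighted local moments (window scale 7/6, stabilizer C = 1/255);
a symmetric generalized Gaussian fit (moment-ratio inversion, shape grid
0.05–10) of the MSCN field plus asymmetric fits of its four orientation
products; 18 features × 2 scales on 96-px patches (sharp patches only for
the corpus, threshold 0.75 of the peak patch contrast); a multivariate
Gaussian corpus model; and the Mahalanobis-type distance with pooled
covariance pseudo-inverse as the score. Inputs are min-max normalized
first, making the score exactly invariant to global intensity scale and
offset.

The pristine corpus is 60 drift-free simulator frames spanning classes and
sites (no external model download). The default gate is the 97.5th
percentile of the corpus self-scores. Because frames of one site share a
tissue model, gating is correlated within site: a small fraction of sites
(~5–7 %) lose all frames and are flagged rather than scored.

Stationarity of the acquisition-order quality series uses ADF (unit-root
null, lag order by AIC) and KPSS (level-stationarity null, default
bandwidth) from statsmodels. The clinical series behind the published
p-values is unavailable; the tests exercise the two tests' complementary
behavior on constructed series.

## Mirror-pair segmentation

Raw device frames stack the B-scan, a 3-row bright separator, and a
vertically mirrored copy. Frames are min-max normalized and smoothed
(σ = 1 px) for matching only; halves are extracted from the raw frame so
intensity measurements stay exact. The template pair is the surface band
(18 rows above to 30 rows below the nominal surface) of a noiseless,
flat-surface simulator frame — full halves decorrelate across classes
because deep rows are speckle-dominated, and the surface band is the
feature all classes share. Matching is zero-normalized cross-correlation
(`skimage.feature.match_template`; a brute-force double loop is the test
oracle), searched within ±16 rows of the geometrically expected placement.
A frame is rejected when the weaker of the two peaks falls below 0.6: valid
frames score ≥ 0.75 and pure-noise frames ≤ 0.03, so the threshold
separates cleanly.

## The attenuation score

Per A-line, the surface is the peak of the depth-directed
derivative-of-Gaussian response (σ = 2 px axially, lateral smoothing
σ = 4 px to suppress speckle); the epithelial lower boundary is the
strongest sub-surface rising edge — the basement-membrane line — accepted
only when it reaches 30 % of the column's peak response, so carcinoma
(destroyed membrane) yields no boundary. Bottom rows (≈8 px) are excluded
from edge candidates: the tissue surface cannot sit at the scan edge, and a
one-row-off split can leave the separator line there.

The score is `gain × median_columns(slope) + offset`, where each column's
slope is the least-squares fit of `log10(max(I, 1e-4))` against depth over
`[surface + 5, min(surface + 40, boundary − 1))`, with one pass of robust
outlier rejection (3.5 robust sigmas, MAD floor 0.02) that removes
undetected membrane rows and noise-floor pixels. The 40-px (280 µm) window
stays inside the device's 0.2–1 mm penetration; longer windows would
average the log floor into the steeper (normal) classes and compress the
scale nonlinearly. The 5-px start offset skips the surface transition rows.
Thickness = median(boundary − surface) × 7.0 µm where boundaries exist.

Band classification uses the published ranges with each shared endpoint
assigned to the more-negative (less severe) band; −0.0580 itself is out of
range. Frames out of range are excluded from site means; a site with no
in-range frame is flagged for review rather than forced into a class
(ulcerated/benign lesions violate the layered-decay assumption in
practice). Site score = arithmetic mean of frame scores.

## Embeddings and the cascade

The embedding stage is an interface: any pure, deterministic
image → fixed-length vector map registers as a backend (external pretrained
CNN activations plug in as adapters; none are bundled). The default
backend (dim 71) concatenates a 4×4 grid of patch mean/sd, the quadratic
shape of the column-mean log-intensity depth profile, 8-bin oriented
gradient histograms over quadrants, and the MSCN AGGD parameters. Each
coordinate carries a documented flag for invariance to small intensity
offsets. Features are computed on the normalized/smoothed upper scan and,
by default, also on the un-mirrored lower copy (two rows per frame).

Each cascade stage is a linear hinge-loss (max-margin) classifier
(`LinearSVC`, C = 1) on standardized features. Stage populations: Test 1
carcinoma vs all; Test 2 dysplasia (any grade) vs normal/benign; Test 3
moderate/severe vs mild/normal/benign. Splits are **by site**, stratified
by stage label, 70/30 train/cv with largest-remainder allocation — frames
of one site are near-duplicates, so site-level splitting is deliberately
stricter than dividing individual images. Frame decision values average
into a site score; the operating cut-off maximizes Youden's J over
midpoint thresholds on the cv sites (ties → higher sensitivity, then the
smaller threshold). The decision tree routes sites sequentially (positive
Test 1 → refer for biopsy as carcinoma; negative Test 2 → routine
monitoring; Test 3 splits high-grade referral from low-grade surveillance),
and stages after a decisive call are not evaluated. Combined sensitivity
counts a site as detected when any stage flags it (configurable to
stage-only).

## Diagnostic metrics

Sensitivity, specificity, PPV, NPV and accuracy derive from raw confusion
counts; metrics with zero denominators are reported absent, never 0.
Intervals are Clopper–Pearson exact (inverse-Beta form) — the convention of
the diagnostic-accuracy software this field uses, and the one consistent
with the printed (82–98) interval for 51/55. Percents round half-up.
ROC/AUC go through scikit-learn (ties as simultaneous steps, trapezoidal
AUC), with the Mann–Whitney concordance identity as the independent oracle
in tests. The sample-size routine is the standard two-sided
normal-approximation one-sample proportion formula; under the stated design
(null 0.85, alternative 0.91, α = 0.05, power 80 %) it yields 246, and no
standard formula reproduces the printed 207 — the printed enrollment 249 is
reproducible only as ceil(207 × 1.2) dropout inflation, which
`inflate_for_dropout` implements.

## Problem sizes and numerical choices

Calibration and acceptance cohorts use 60 sites per diagnosis class with
3–5 frames per site (≥ 50 sites per score group survive gating); the
quality-model corpus seed (42) and template seed (0) are fixed constants of
the method, while the cohort seed is the run's randomness. The AGGD shape
grid is 0.05–10 in steps of 0.001. Degenerate inputs raise typed errors
(constant images, single-class labels, identical scores, empty sites)
rather than returning silent defaults.

## Known limitations

* The score formula is a declared stand-in: the upstream publications never
  print the original arithmetic, only the score ranges. The median
  log-decay slope is calibrated to those ranges and reproduces their
  ordering, not their derivation.
* The simulator omits patient-level heterogeneity, motion, refraction and
  ulceration; cascade performance on it (≈99–100 %) is an upper bound that
  demonstrates pipeline correctness, not clinical accuracy.
* The quality gate encodes only the automatic criterion; the physician
  review used alongside it in practice has no counterpart here.
* Dorsal-tongue shadowing is emulated, but the published dorsal-tongue
  false-positive rates depend on real tissue architecture and are treated
  as printed-count arithmetic only.
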