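# Methods

`octneed` implements a complete, synthetic-data-backed analogue of a
treatment-need prediction analysis for neovascular age-related macular
degeneration (nAMD) under an anti-VEGF treat-and-extend (T&E) regimen:
from SD-OCT volumes at Weeks 8 and 16 of therapy, predict how much
treatment a patient will need later — the first adequate injection
interval, the injection frequency in each study year, and the final
interval after two years.  The raw clinical trial images such analyses
are built on are not publicly available, so the package pairs the
analysis machinery with a generative cohort model whose ground truth is
known exactly; every statistical claim the test suite makes is a claim
about this synthetic system, made precise below.

## Cohort simulation

Each patient carries a latent disease activity `A ~ LogNormal(mu, sigma)`
(defaults `mu = 2.5`, `sigma = 1.1`, nanolitre scale) and a compartment
split `f ~ Beta(2, 2)` dividing activity between intraretinal fluid
(IRF) and subretinal fluid (SRF).  Fluid at calendar week `w`, with the
last injection at week `w0`, is

```
IRF(w) = A · f · (1 − exp(−r (w − w0))) · ε_w,
SRF(w) = A · (1 − f) · g · (1 − exp(−r (w − w0))) · ε'_w,
```

with rebound rate `r = 0.15 / week`, SRF gain `g = 2.5` (subretinal
pools are anatomically larger than cystoid spaces), and multiplicative
lognormal visit noise `ε` with `sigma = 0.35`.  The noise multipliers
are pre-drawn per calendar week when the patient is created, so the
trajectory is a deterministic, monotone function of `A` — this makes
the monotonicity property (more activity ⇒ fewer extensions, more
injections) exact rather than statistical, at the cost of assuming the
measurement noise field is a property of the patient-week rather than
of the visit.

Treatment follows the T&E protocol: three loading injections at weeks
0, 4, 8, then an injection at every visit with the interval adjusted in
2-week steps within [8, 16] weeks.  The anatomic decision rule at each
interval-adjustment visit (Visit 4 onward) is

* **shorten** if IRF ≥ 6.0 nL or the SRF dome height ≥ 50 µm,
* **maintain** if SRF ≥ 16 nL but below 50 µm in height,
* **extend** otherwise.

SRF height is tied to volume through a half-ellipsoid dome of aspect
ratio 10 (lateral semi-axis = 10 × height), under which 16 nL ≈ 42 µm
and 50 µm ≈ 26 nL — the maintain band is therefore the 16–26 nL range.
The defaults were chosen once to give endpoint label fractions of
roughly 40–55% and a strong positive association between Week-16 fluid
load and the short-interval label (point-biserial r ≈ 0.74), i.e. a
cohort in which the prediction task is well-posed but not trivial.

## Scan rendering

The renderer turns a fluid state into a B-scan stack with exact
voxel-level ground truth.  Retinal boundary surfaces (ILM, IPL, OPL,
photoreceptor band, RPE, Bruch's membrane) are low-order polynomials in
the two en-face coordinates with bounded random tilt/curvature and a
Gaussian foveal depression; tissue classes receive fixed reflectivities
and the image is degraded with multiplicative lognormal speckle
(σ = 0.22 by default) and an optional gamma.  IRF is rendered as 1–3
hypo-reflective ellipsoids strictly between ILM and OPL; SRF as a
hypo-reflective dome that lifts the neurosensory retina off the RPE.
Pocket extents are discretized by an exact-count rule: voxels are
admitted innermost-first (by normalized ellipsoid radius, within the
anatomically admissible compartment) until the voxel count matches the
requested volume, which pins every mask volume to the requested
nanolitres within half a voxel.  Drusen, pigment-epithelial detachment,
vessel shadows and motion artifacts are not modelled; no implemented
criterion uses them, but their absence is one reason the stand-in
segmenter scores far better here than any method would on clinical
scans.

## Preprocessing

The chain mirrors standard B-scan preprocessing: resample to a
reference pitch (7 µm axial, 26.25 µm lateral) and fix the en-face
field of view at 3.36 mm (128 columns); keep the 28 B-scans around the
central one; crop rows to the retina (extreme ILM/BM rows ± 220 µm,
then rounded to exactly 128 rows when the image allows, which makes the
later per-B-scan resize an identity and keeps thin masks lossless);
CLAHE per B-scan (clip limit 0.01, 8 × 8 tiles); flatten Bruch's
membrane to row 90 of 128 by integer per-column shifts; resize to
128 × 128 and crop to 52 rows × 72 columns.  The crop window is
asymmetric — 48 rows above the flattened membrane, 4 below — because
the retina lies almost entirely above Bruch's membrane; a crop centred
on the membrane would discard the inner retina.  Masks and layer
curves are co-transformed; label resampling is mass-conserving (linear
interpolation, then keep the top-k voxels with k chosen so the label's
physical volume is preserved), because nearest-neighbour resampling
loses one-voxel-thick structures such as a flat dome's rim.

## Biomarker quantification

Volumes are voxel counts times the voxel volume (1 nL = 10⁶ µm³); SRF
height is the longest contiguous SRF run along any A-scan times the
axial pitch (disjoint runs do not add).  Presence thresholds default to
6.0 nL (IRF) and 16 nL (SRF), compared inclusively; thresholds can be
re-calibrated against reference grades at the equal error rate — the
candidate midpoint between consecutive sorted unique values minimizing
|FPR − FNR|, ties toward the lower threshold.  Grader agreement is a
2 × 2 confusion matrix with the reference rater as truth, reported as
sensitivity, specificity and balanced accuracy; the package ships the
published ARIES study-site/AI vs reading-center counts, recovered from
a delimiter-less transcription by exhaustive digit-split search and
cross-checked by the exact agreement of the reading-center marginals
between the two SRF-height tables.

The stand-in segmenter (hypo-reflective voxels below 0.45 × the median
intra-retinal intensity, restricted to the anatomically admissible
compartment, components under 20 voxels dropped) exists to close the
pipeline on synthetic data; its contract is geometric overlap with the
renderer's ground truth (Dice ≥ 0.8; in practice ≈ 1.0 because the
phantom's fluid is cleanly hypo-reflective).  Its in-plane smoothing is
deliberately small (σ = 0.4 px): stronger smoothing blurs one-voxel
dome rims into the adjacent bright bands and systematically undercounts
SRF.  Nothing about this component is a claim about clinical
segmentation performance.

## Labels

* First interval (Visit 7, extrapolated to Visit 4): fewer than 3
  extension decisions at Visits 4–7 ⇒ *short* (< 12 weeks), else
  *long* (≥ 12 weeks).  Maintain and shorten both count as
  non-extensions.
* Yearly need: *high* means ≥ 8 injections in weeks [0, 52) or ≥ 5 in
  weeks [52, 104); year boundaries at 52 weeks partition the horizon.
* Final interval: last assigned interval < 12 weeks ⇒ *short*.

Year labels are only defined when follow-up covers the window (the
next scheduled visit would fall beyond it).  Experiments use the study
arms the original analyses used: the first-interval and Year-1
endpoints use the early-start arm only; Year-2 and final-interval pool
both arms.

## Predictors

**Fluid-feature logistic regression.**  Eight features per patient —
IRF volume, SRF volume and SRF height at Weeks 8 and 16, plus the two
week-16 − week-8 volume changes — signed-log1p-transformed and
standardized with training-set moments, fitted by L2-penalized binomial
maximum likelihood (λ = 1 by default, inverse-frequency class weights
in cross-validation).  Standard errors come from the inverse of the
penalized observed information.  Constant features are dropped with a
warning; an all-constant design degrades to an intercept-only model so
that ablation experiments score exactly at chance.  A one-hidden-layer
variant sits behind `hidden_units` for the non-linear reading of the
method; the plain sigmoid model is the default and the one evaluated.

**Volumetric network.**  A twin 3-D convolutional encoder with shared
weights processes the Week-8 and Week-16 model inputs: average-pool
stem (2 × 4 × 4), two 3³ convolutions (8 and 16 channels by default)
with ReLU and a 2³ max-pool between them, global average pooling, and a
16-unit dense head on the concatenated pair embedding producing one
logit.  Training is Adam (lr 3 × 10⁻³), weighted cross-entropy,
mini-batches of 32, early stopping on validation loss with patience 10,
at most 60 epochs.  The implementation is pure numpy with hand-written
backpropagation, which buys bit-level reproducibility: a fixed seed
gives an identical weight hash on re-run.  Transfer learning
re-initializes the head, warms it up for 12 epochs with the encoder
frozen at the full learning rate, then fine-tunes all layers at 0.3 ×
the learning rate; the head warm-up is what lets a low-learning-rate
fine-tune escape its random head before early stopping triggers.  The
source task emulating the pre-existing model is fluid persistence (any
IRF or SRF presence) at Week 16 on a separate synthetic cohort.

## Evaluation

Cross-validation is at patient level: k = 5 rotating test folds (20%),
the remainder split 64%/16% into training and validation, stratified by
label when class counts allow, repeated (default 5 ×) with independent
partition seeds.  AUC is the trapezoidal area under the ROC over all
score thresholds (equal to normalized Mann–Whitney pair counting, ties
half); the reported AUC is the mean ± SD over repeats of the per-repeat
pooled-test-score AUC.  The operating point is the equal error rate:
the FNR = FPR crossing found by linear interpolation along the ROC;
sensitivity, specificity and the accuracy recomputed from raw scores at
that threshold are reported together with group counts.

## Scaled-down study sizes

The automated checks run the transfer-learning contrast with a reduced
network (6/12 channels, 12-unit head, ≤ 40 epochs), a 200–250 patient
source cohort, target draws of n = 100 patients split 64/16/20, and
3–5 paired seeds; the fluid-feature benchmark uses 150–200 patient
cohorts measured through the full render → segment → quantify path.
These sizes keep a full run on one CPU core in minutes while leaving
the qualitative contrasts (transfer ≥ scratch; benchmark AUC well above
chance; permutation null at 0.5) statistically unambiguous on the
synthetic cohort.

## What passing tests do and do not show

The synthetic system shares the real analysis' structure — fluid
dynamics drive protocol decisions, scans measure fluid with noise,
labels derive from decisions — but its images are far cleaner than
clinical SD-OCT and its decision rule is exactly the rule the labels
are built from.  Passing tests therefore validate the machinery
(geometry, quantification, calibration, cross-validation, training
dynamics, determinism) and the internal consistency of the analysis,
not clinical performance; the published clinical AUCs are not
reproducible without the trial images, and no number produced here
should be compared to them except the grader-agreement table, which is
computed from published counts.
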