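# Methods

`csarray` implements the chemometric stack of a four-channel colorimetric
sensor array for organic-acid analysis in distilled spirits: ΔRGB
fingerprint construction, DUPLEX set splitting, particle-swarm-tuned
variable-weighted LS-SVM quantitation, PLSDA classification, and OCPLS
one-class authentication. Because raw laboratory RGB readings for such
arrays are essentially never published, the package ships a synthetic
sensor-response generator that reproduces the *statistical structure* of
the laboratory studies; all tests and the acceptance script run on it.
This note records the models, the defaults and why, and what the
synthetic studies do and do not demonstrate.

## The measurement model

A sample is measured as the mean RGB color of four sensor wells
(channels S1–S4, one reducing-agent chemistry each), giving an
m × 4 × 3 matrix. The feature vector is the signed difference
response − control, flattened channel-major to 12 columns
(S1_R … S4_B) and used unamplified; the 0–255 rescaled
color-difference diagram is display-only. ROI means are computed over
the inclusive pixel-center disk of 25 px diameter by default; means are
real-valued (no rounding). Whether source pixels are gamma-encoded sRGB
is not modeled — the pipeline operates on stored pixel values as-is.

## Synthetic data generator

**Single analyte.** The expected ΔRGB response of analyte *A* at
concentration *c* (mmol/L) is a per-feature Hill curve
r_k(c) = a_k · c^{s_k} / (K_k^{s_k} + c^{s_k}), with amplitude vector
*a* (signed color units), half-saturation *K* (mmol/L) and exponent *s*
allowed to vary per feature. The Hill form is monotone, bounded by the
gamut, and linear at low concentration. Replicate noise is i.i.d.
additive Gaussian per feature (`NoiseSpec`), and every generator is a
pure function of its parameters plus a seed.

**The built-in library.** Nine fingerprints named for the acids the
array targets (benzoic, lactic, acetic, butyric, isobutyric, valeric,
isovaleric, hexanoic, octanoic). Values are arbitrary but frozen. They
were drawn once under an explicit design rule: amplitudes 80–100 color
units with pairwise-distinct sign patterns, and *channel
specialization* — per acid, two channels cover the low range
(K ∈ [0.8, 2] mmol/L, s ∈ [0.4, 0.6]) and two the high range
(K ∈ [8, 16] mmol/L, s ∈ [1.0, 1.5]) — with each draw accepted only if
the closed-form single-sample information bound
σ_rel(c) = σ_noise / ‖(a_k s_k u_k(1−u_k))_k‖ (u_k the saturation
fraction) stays below 15% at 0.001 mmol/L and below 0.7% at 10 mmol/L
under replicate noise of 0.5% of the maximum amplitude. The rule encodes
the qualitative requirement that a fingerprint remain informative over
the full four-decade calibration range: one shared saturation constant
cannot discriminate both the lowest and the highest decade at once.

**Mixtures.** The base expectation of a mixture is the sum of the
single-analyte responses. Pure additivity, however, confines a 5 × 5
composition grid to a low-rank smooth manifold on which dummy-code
least-squares/PLS argmax provably masks interior classes (we measured
~50% accuracy noise-free for any Hill parameterization). Real co-existing
acids interact — they compete for one chromogenic reagent and shift the
system pH jointly — and perfect linear discrimination of 25 mixture
classes from 12 features is only possible when such composition-specific
chemistry departs from additivity. The generator therefore adds a
deterministic interaction offset per composition: a pseudo-random unit
direction keyed by (interaction seed, composition) with magnitude 0.6 ×
the mean single-component response norm, applied only when at least two
components are present, with the total clipped to ±255. Replicates of a
composition share the offset (it is systematic chemistry, not noise),
identical seeds reproduce it bit-for-bit, and a single-component
"mixture" reduces exactly to that component's response.

**Class populations and blends.** Multi-class spirit populations draw
pairwise-distinct centroids uniformly in ±100 color units with Gaussian
within-class scatter; adulteration blends are convex combinations
(1−f)·pure + f·adulterant with f the adulterant volume share (a 1:9
genuine:adulterant blend is f = 0.9).

**Noise defaults (the study conditions).** Calibration series use
10 concentrations (0.001–10 mmol/L), 24 replicates, and replicate sd =
0.5% of the fingerprint's maximum amplitude. Classification studies set
replicate sd = d_min / 40, where d_min is the smallest pairwise
class-centroid distance. The 40 comes from a margin argument: fitted
dummy-code argmax boundaries carry margins of roughly 0.13 × d_min, so
d_min/σ = 40 leaves ≥ 5σ decision margins and hence zero expected errors
across ~600 draws. (Nearest-centroid separability alone would need far
less; the binding constraint is the indicator-regression margin.)
The interaction strength 0.6 was fixed by the same margin diagnostic.

## DUPLEX splitting

Classical DUPLEX alternates farthest-point assignment between two
subsets; the calibration protocol needs three (train/monitor/predict =
0.5/0.25/0.25, i.e. 120/60/60 at m = 240). The generalization: subset
target sizes come from largest-remainder rounding; each subset is seeded
in turn with the mutually farthest unassigned pair (Euclidean distance on
autoscaled features); thereafter the subset furthest below its target
receives the unassigned point with maximal minimum distance to its
members. All ties break to the lowest index, so the split is a pure
function of the feature matrix. Splitting is done in feature space (the
protocol's alternative — concentration space — is not stated anywhere we
know of). A practical consequence worth remembering when reading the
figures of merit: DUPLEX sends extreme points to the training set, so
prediction samples are interpolative and slightly flattering.

## PSO-VWLS-SVM quantitation

The calibration model is an LS-SVM with the variable-weighted radial
kernel K(x, z) = exp(−Σ_k w_k (x_k − z_k)² / σ²), w_k ∈ [0, 1]. Fitting
solves the dual bordered system [[0, 1ᵀ], [1, K + I/γ]] (b; α) = (0; y)
by one dense solve; a singular system raises rather than falling back to
a pseudo-inverse. Features are autoscaled on training statistics.
Because the calibration spans four decades, targets are log10-transformed
by default (flag `log_target`), then standardized; predictions are
back-transformed.

The weight vector and the two hyperparameters are tuned by global-best
PSO (position = (w₁…w₁₂, ln σ², ln γ); 100 particles, 100 iterations,
constriction coefficients 0.729/1.494/1.494; box: w ∈ [0,1],
σ² ∈ [10⁻⁶, 10⁶], γ ∈ [10⁻², 10⁸]). The objective is the monitoring-set
RMSE in concentration units — the fit anchors the low decades through the
log-scale targets while the objective disciplines the top decade, which
dominates absolute error. Non-finite objective values count as +∞; the
global-best trace is non-increasing by construction and ties keep the
first-found position.

Figures of merit follow analytical convention: per-sample recovery
(predicted/true × 100, samples with zero truth excluded), squared Pearson
correlation r², RMSEP, and LOD/LOQ = 3σ/10σ of the model-predicted
concentration over ≥3 blank replicates, converted to g/L with bundled
molar masses. RMSEP is reported in mmol/L on the original scale.

## PLSDA classification

Classes are one-hot (dummy) coded in first-appearance order. PLS2 is the
classical NIPALS bilinear decomposition with X-only deflation on
autoscaled features and centered dummies; rotations R = W(PᵀW)⁻¹ give
direct coefficients for any leading subset of components, and at full
rank the fit equals multivariate least squares on [1, X] (tested against
that oracle). The latent-variable count minimizes the leave-one-out
misclassification count under the argmax rule, with a parsimony
tie-break (smallest count attaining the minimum). Argmax ties go to the
lowest class index and are logged. Metrics are accuracy and one-vs-rest
sensitivity/specificity per class with macro averages, all in percent.

## OCPLS authentication

The genuine class alone is modeled by PLS1 of a unit target on the
*uncentered* feature matrix (NIPALS, y-deflating). Complexity is chosen
by Monte Carlo cross-validation (100 random 80/20 splits by default,
mean squared validation residual of the unit target, one-standard-error
parsimony rule). Two diagnostics summarize a query: the score distance
SD = √(Σ_a (t_a − t̄_a)²/var_a) over the A retained components (scores
centered at the training score mean so the χ² calibration below is
coherent; components with zero training variance are skipped with a
warning), and the absolute central residual ACR = |r − mean training r|
of the unit target. Thresholds at confidence 97.5% (configurable):
SD limit = √(χ²_{A, 0.975}); ACR limit = mean + z₀.₉₇₅ · sd of the
training ACR under a normal approximation. The four-way category table —
regular / good leverage / class outlier / bad leverage — is exhaustive
and exclusive, and only regular points are called genuine. Note the
joint nominal coverage of the two ~97.5% gates is ~93–95%, not 97.5%;
the coverage test is anchored accordingly.

## Orchestration and reproducibility

`run_quantify`, `run_classify`, `run_authenticate` (and the `csarray`
CLI over YAML configs) wire the studies end to end and write run records
(JSON report + generator metadata + diagnostics CSV + SD/ACR plot)
sufficient to regenerate outputs bit-identically: every stochastic step
is seeded, and generator metadata alone reproduces each dataset exactly.
The numbered scripts under `analysis/` are thin narrative drivers over
the same functions.

## Problem sizes

The standard studies are deliberately desk-scale: 240-sample calibrations
(nine of them for the envelope summary), a 600-sample 25-class grid, a
288-sample 12-class population, 120 blend queries, and 2000-draw coverage
simulations. A full nine-acid envelope run takes on the order of a minute
on one CPU; the classification and authentication studies run in seconds.

## What passing tests show — and what they do not

The synthetic generator reproduces the *structure* of the laboratory
studies (sample counts, concentration designs, replicate layout,
class-separation regimes), not their chemistry. Passing the envelope
tests demonstrates that the algorithms are implemented correctly and
recover the published performance figures *under conditions engineered
to match the published separability*; it does not validate the sensor
chemistry, nor predict performance on real plates with drift,
illumination error, or non-Gaussian replicate scatter, none of which the
generator models. Real-data figures (the published LOD/LOQ table, RMSEP
range, and the specific selected LV counts 9/8/5) depend on unpublished
raw data and are out of scope.

## Known limitations

* The mixture interaction offset is a statistical stand-in for unmodeled
  interaction chemistry; its magnitude is a free parameter, chosen by
  the margin rule above rather than fitted to any measurement.
* Quantitation is single-analyte; simultaneous multi-analyte calibration
  is explicitly not attempted.
* OCPLS "small/big" thresholds follow one standard convention; published
  work rarely prints its exact threshold rule, and other conventions
  (robust centers, jackknife variances) would shift borderline verdicts.
* The ROI extractor assumes axis-aligned plates and constant
  illumination; there is no white-balance or flat-field correction.
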