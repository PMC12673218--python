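# Methods

`eegexplain` asks a single question of a trained EEG decoder: *do the
features it learned look like the EEG signal it was trained on?*  The
package provides every stage needed to pose that question reproducibly —
a synthetic data generator with planted ground truth, compact CNN decoders
under a leakage-free cross-validation protocol, gradient attributions, an
interpretability score with group statistics, and a surface-Laplacian view
of the resulting topographies.

## Synthetic epoched EEG

Real multi-participant ERP datasets are rarely shareable, and even when
they are, they carry no ground truth about *where* class information lives.
The generator therefore emulates a stimulus-locked paradigm in which the
truth is planted:

* **Evoked components.** Each component is a Gaussian bump in time
  (`peak_latency`, `temporal_width` = Gaussian sd, both in seconds) times a
  fixed per-channel pattern with unit maximum (microvolts via `amplitude`).
  A Gaussian is the simplest unimodal surrogate for an ERP deflection;
  oscillatory or multiphasic morphology is deliberately out of scope.
* **Background activity.** Gaussian noise shaped to `1/f^alpha`
  (`noise_spectral_exponent`, default 1) *inside the 1–40 Hz band* and zero
  outside, mirroring the bandpass normally applied to scalp EEG.  The
  output standard deviation equals `noise_sd` exactly in expectation
  (Parseval-normalised filter).
* **Variability.** Per-trial latency jitter (`latency_jitter_sd`, clipped
  so the peak stays inside the epoch), and per-participant multiplicative
  amplitude factors ~ N(1, `participant_amplitude_sd`) plus additive
  per-channel topography perturbations ~ N(0, `participant_topography_sd`
  × max|pattern|), drawn once per participant.  This is the smallest
  hierarchy that makes subject-wise cross-validation meaningful.
* **Referencing.** Every trial is re-referenced to the common average, as
  scalp EEG pipelines do.  A consequence worth remembering: the channel sum
  of the planted signal is exactly zero afterwards (see *Known
  limitations*).
* **Montage.** 32 electrodes by default, on a Fibonacci lattice over the
  upper unit hemisphere with coarse scalp-region labels.  Real cap
  coordinates are unnecessary for any of the math; only unit-sphere
  positions matter (for the spherical-spline Laplacian).

Two presets define the study conditions: a 3-class "visual" design (one
component per class at 0.15 s over distinct 6-channel groups; classes
differ by topography) and a 2-class "pre/post" design in which the `pre`
class is stimulation-free.  Default scale is 8 participants with 50
(3-class) or 100 (2-class) trials per class per participant at 256 Hz over
0–0.75 s (192 samples).  `noise_sd` defaults to 9 µV against 3 µV
components: with these values the compact CNN decodes the 3-class design at
≈0.55 held-out and the time-resolved logistic baseline peaks at ≈0.54 —
the range such decoders reach on comparable real recordings — rather than
at an unrealistically easy SNR.  `ground_truth_mask` exposes the planted
support (|pattern| > 0.5, time within one width of the peak) for recovery
checks.

What passing tests on this generator do **not** show: robustness to
artifacts (ocular, muscle), non-phase-locked oscillatory activity, realistic
channel covariance, or drifting electrode impedances.  Conclusions about
real recordings require real recordings.

## Decoders and protocol

Three estimator families (scikit-learn interface: `fit`, `predict`,
`predict_proba`, `get_params`):

* **`EEGNetClassifier`** — temporal convolution (kernel 16 samples, shared
  across electrodes), depthwise spatial convolution spanning the full
  electrode axis (depth multiplier 2), separable temporal convolution
  (kernel 64), batch-norm + ELU after the spatial and separable stages,
  average pooling (8) and a softmax head.  No batch norm sits between the
  first two convolutions: the depthwise spatial filter immediately follows
  the temporal one, and normalising the large pre-reduction tensor adds
  cost without benefit.  The printed source convention of a "dropout rate"
  of 4 is not a valid rate; the default here is 0.25, configurable.
* **`ResidualCNNClassifier`** — an initial temporal convolution plus four
  identity-shortcut blocks of two temporal convolutions each (16→32
  filters, widening and pooling mid-stack), global average pooling, softmax
  head.  This is a deliberately reduced residual network: deep image-scale
  variants both exceed workstation budgets and are known to pass zero
  gradients to their deepest layers; the early/intermediate/late layer
  roles are preserved and remain addressable for attribution.
* **`PointwiseLogisticDecoder`** — one multinomial logistic regression per
  time point (L2, strength 1.0 — no regularisation value is canonical, so
  the scikit-learn default is kept), reporting the accuracy time course
  and its maximum (taken over the fold-mean curve).

Training minimises categorical cross-entropy by mini-batch gradient descent
(batch 64).  Family defaults: SGD with learning rate 1e-4, momentum 0.5,
staircase exponential decay 0.94 (applied every 10 epochs — the decay
period is a free choice; no canonical value exists) for the compact CNN;
Adam at 1e-3 for the residual CNN; early stopping when validation loss has
not decreased for 25 consecutive epochs, with weights restored to the best
epoch.  Inputs are divided by the training set's global standard deviation.
At the trial counts the simulator produces (hundreds per fold rather than
thousands), SGD at 1e-4 needs several hundred epochs to move; the
demonstration and test runs therefore pass an explicit Adam configuration
(1e-3, 15–35 epochs) and say so — this is a problem-size choice, not a
change of the family defaults.

**Splits are participant-wise**: all trials of a participant fall into
exactly one of train (81%), validation (10%), test (9%) within each of 5
folds (set sizes `round(fraction × N)`, at least 1 for validation and test,
remainder to train; the held-out window rotates across folds).
Disjointness is asserted at training time, not assumed.  The engine behind
the CNNs is a small explicit forward/backward layer stack on numpy arrays
(FFT-based temporal convolutions); its gradients are verified against
central finite differences in the test suite.

## Attribution

* **Saliency** — the gradient of the pre-softmax score of the target class
  with respect to the input, one signed channels × samples map per trial.
  The pre-softmax logit (not the softmax output) is differentiated by
  default — the standard and numerically stabler choice; `score="softmax"`
  switches to the probability.
* **Grad-CAM** — at a named convolution, each feature map is weighted by
  its globally average-pooled gradient (1/Z Σᵢⱼ ∂S/∂A), maps are summed and
  rectified.  Feature-map grids are resampled to the input grid by linear
  interpolation along time and nearest-neighbour/broadcast along channels.
  A layer whose gradients vanish for every requested trial yields an
  all-zero map flagged `dead_layer`, not an error.

The target class for backpropagation is the trial's true class; since only
correctly predicted trials are attributed, this equals the predicted class.
Group maps average trial maps **per condition** in a fixed hierarchy —
trials, then participants, then folds — with absolute values taken of
saliency at aggregation (the per-trial sign pattern is informative, the
group map's is not; where exactly to rectify is a convention, and
rectify-at-aggregation is the one used here).  By default trials from all
participants are fed to each fold's decoder for feature extraction, with a
switch to restrict to held-out participants.

Layer presets: `early`/`intermediate`/`late` map to convolutions 1/2/3 for
the compact CNN; for the residual family, early/intermediate are the first
two convolutions and `late` is the deepest convolution that still receives
nonzero gradients on a probe trial.

## Interpretability score and statistics

For each participant, the attribution map is compared to the absolute
amplitude of that participant's mean EEG over *the same correctly predicted
trials* (keeping both operands on identical trial sets; an all-trials
switch exists).  At each time point, the Pearson correlation across
channels between |EEG| and the (nonnegative) feature map gives the
interpretability time course.  Samples where either vector is constant
across channels are undefined and excluded — notably, Grad-CAM maps from
channel-collapsed layers (the compact CNN's 2nd and 3rd convolutions) are
channel-constant after broadcasting, so their correlation is undefined by
construction and those layers drop out of the score tables.  Per-condition
time courses are averaged per participant before group statistics.

Group inference: two-sided one-sample Wilcoxon signed-rank versus zero at
each sample, Benjamini–Hochberg FDR across samples.  Zero differences are
discarded; p-values are exact for n ≤ 25 (sign-flip enumeration via dynamic
programming over doubled midranks, so ties are handled exactly) and use a
continuity-corrected normal approximation above; z is always reported from
the normal form.  Per-participant maximum scores and their latencies (ties
→ earliest) feed paired Wilcoxon contrasts between methods, layers and
decoder families.

Topographies can be sharpened with a spherical-spline surface Laplacian
(current source density; regularisation `lambda2` = 1e-5, spline
`stiffness` = 4.7), computed by MNE-Python on the montage's unit-sphere
coordinates scaled to a 9.5 cm head.

## Numerical choices and degenerate inputs

* Cross-entropy clamps probabilities at machine epsilon and warns when the
  true class receives exactly zero mass.
* A participant/condition cell with no correct trials is dropped from that
  condition's hierarchy with a log warning; a condition with no correct
  trials anywhere raises.
* An all-undefined correlation time course (flat feature map) excludes the
  participant from max-score statistics with a warning.
* Finite-difference oracle points that straddle a ReLU kink (detected by a
  two-epsilon consistency check) are skipped — the secant, not the
  gradient, is invalid there.
* Identical pipeline configuration and seed reproduce byte-identical
  `results.json` (asserted in the tests).

## Known limitations

* **Early-layer Grad-CAM needs large trial counts.**  After common-average
  referencing the planted signal sums to zero across channels, so the
  first-order term of the expected rectified cam cancels in the
  channel-summed time marginal; what remains is a second-order (≈0.5% at
  the default SNR) elevation that only dominates sampling noise at several
  thousand correct trials — more than the default desk-scale runs produce.
  Moreover the *sign* of the planted channels' deviation equals the sign of
  the spatial-DC component of the learned depthwise filters, which
  common-average-referenced data leaves unconstrained, making the top-channel
  set of an early-layer cam a per-fold coin flip.  On noise-free trials the
  early-layer cam localises the plant cleanly (argmax within 0.01–0.02 s,
  full channel overlap), and the per-feature-map oracle confirms the
  implementation, so this is a property of the method at desk scale, not a
  defect of the code.  Saliency does not suffer from it (its gradient is
  channel-resolved before any pooling) and recovers the plant reliably.
* The generator's trial count and participant pool are an order of
  magnitude below the recordings that motivated the pipeline; absolute
  interpretability scores here are not comparable to values obtained on
  real data.
* Wilcoxon exactness is per time point; no cluster-based correction across
  time is provided.
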