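# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
world does and does not establish.

## Encoding model

Each simulated channel's firing rate in a 20-ms bin is linear in the intended
velocity of the two hands plus a direction-independent laterality code:

    f = b0 + b_rx d_rx + b_ry d_ry + b_lx d_lx + b_ly d_ly + b_lat c_lat

with `c_lat = +1` for unimanual right movement and `-1` for unimanual left.
The laterality code is defined by the task only for unimanual movement; we
use `+1` for bimanual bins (bimanual population activity most closely
resembles unimanual-right activity in the top principal components) and `0`
for no-movement bins.  Both conventions are configurable
(`SimPopulation.bimanual_c_lat`).

Nonlinearity with respect to the decoded variables enters through context
dependence: the coefficient vectors may differ between the unimanual and
bimanual contexts (suppression = reduced column norm; decorrelation = rotated
column), and through the laterality term itself, which no linear decoder of
velocity can exploit.

### Population sampling

Coefficients are drawn i.i.d. standard normal per channel and rescaled so
each directional column has a requested norm (default: unit per-channel RMS
tuning, i.e. column norm `sqrt(n_channels)` Hz per unit velocity; the real
magnitudes are not published, and the absolute scale is immaterial because
noise is calibrated functionally, see below).  Left-hand columns are built by
mixing the right column with an independent draw,
`v_l = rho * v_r + sqrt(1 - rho^2) * w`, then rescaling; the realized sample
correlation is therefore approximate (tolerance ±0.05 at 192 channels).  An
`exact_correlation` mode orthogonalizes the mixture and enforces the centered
correlation exactly; parameter-recovery tests use it so that estimator error
is not confounded with construction error.

Bimanual columns are the unimanual columns scaled by per-hand suppression
factors (defaults 1.0 right, 0.66 left) and, by default, re-mixed with an
independent draw to hit a target unimanual-to-bimanual correlation per hand
(defaults 0.85 right, 0.45 left), mirroring the published structure.

The laterality column norm is `lat_scale` times the mean of the four
directional column norms — the published variance decomposition shows
laterality tuning comparable to or larger than directional tuning, so
`lat_scale = 1` makes the laterality dimension as large as a typical
directional one.

Baselines are uniform on [5, 50] Hz, a realistic range for multiunit
threshold-crossing rates.  Rates are expected values in Hz; a count view is
rate × 0.02 s.

## Noise model and functional SNR

I.i.d. Gaussian noise with one shared standard deviation is added per bin and
channel, and negative rates are clipped to zero.  The noise level is set
functionally: a cross-validated linear decoder predicts the point-at-target
unit vector, the decode is regressed on the intention
(`decoded = D @ pointing + eps`), and

    fSNR = ((D11 + D22) / 2) / mean residual SD.

`calibrate_sigma` bisects sigma (geometrically, since fSNR ~ 1/sigma) until
the mean fSNR across hands matches the target; the same standard-normal draw
is reused at every candidate sigma so the objective is smooth and monotone.
With a single shared sigma the two hands cannot be matched independently, so
the objective is the across-hand mean.  The real dataset's fSNR is not
published; we adopt **fSNR = 1.5 per hand** as the stated noise level of all
synthetic experiments (a mid-range value for clinically recorded
threshold-crossing decoding: clearly decodable single bins, far from
noiseless).  Clipping at zero is a genuine nonlinearity of the generator: it
attenuates low-baseline channels slightly and differentially across contexts;
estimator tests therefore quote recovered values against realized, not just
programmed, population structure where the distinction matters.

## Sessions and kinematics

Two generators are provided.  `generate_unimanual_dataset` emulates the
movement-window-only decoding datasets: 400-ms trials (20 bins), each with a
uniformly random unit velocity inside one of 8 direction wedges, balanced
within ±1 trial per wedge per hand.  `generate_session` emulates the
delayed-movement calibration task: per trial a 1–2-s delay (uniform), a 1–2-s
move epoch, and 1 s of idle; during the move epoch (after a 200-ms reaction
lag) the encoded intention is the unit cursor-to-target vector, constant per
trial.  The velocity *targets* stored for recurrent-decoder training are
saturated profiles: zero during the reaction time, maximum speed until the
remaining distance falls below 15% of the total, then a linear taper to zero
(the published taper is schematic; the 15% fraction is configurable).  The
minimum-jerk profile (fifth-order polynomial position, peak speed
1.875 × distance / duration) describes the open-loop cursor motion itself.
Both discrete profiles are derived from exact position differences so they
displace the cursor by exactly the trial distance.

## Cross-validated tuning statistics

Encoding fits are fold-wise ordinary least squares (no ridge, per the source
analyses; collinearity triggers a condition-number warning) on stacked 20-ms
bins in a 300–700-ms window after the go cue, with block-wise mean removal
first (synthetic sessions form a single block by default).  Folds are
assigned at trial level, stratified by context and direction wedge — bins
within a trial are strongly dependent, so bin-level folds would leak.
Unimanual fits drop the inactive hand's columns.

Because each fold is fitted on disjoint trials, fold estimates carry
independent noise, and the average *cross-fold* inner product of a
coefficient column is an unbiased estimator of its squared norm (the naive
pooled squared norm is biased upward by tr(Sigma)/k).  Correlations between
columns of two fits use mean-centered vectors, cross-fold products in the
numerator, and cross-validated norms in the denominator.  At high noise these
estimators can legitimately return negative squared norms or correlations
outside [-1, 1]; values are passed through unclipped, with signed square
roots for magnitudes.  Tuning strength per hand is the mean of the x- and
y-column magnitudes; the suppression ratio is bimanual over unimanual
strength.  Session-level estimates are noisy at 40 trials per type; headline
statistics average over block-set replicates, as in the published analysis.

## dPCA marginalized variance

Unimanual trials are organized into a (channel × laterality × direction ×
time) trial-averaged tensor; direction uses the four quadrants (half-open
intervals [0°, 90°), … — the tie rule is ours) to match the ANOVA grouping.
After per-channel grand-mean centering, the additive marginalizations are:
time (mean over laterality and direction), laterality and direction (partial
averages minus the time course; each absorbs its interaction with time), and
the laterality × direction interaction (residual).  Cross-validation splits
each cell's trials in half, marginalizes each half, element-wise multiplies
and sums — an unbiased variance estimate that can be slightly negative under
noise; negative components are floored at zero for the reported fractions and
kept signed in `cv_variance`.  Fractions are reproducible within ±0.03–0.05
across split seeds at the default synthetic scale.

## Electrode tuning

Per electrode and context, trial-mean rates in the analysis window are
grouped by the relevant hand's direction quadrant (bimanual grouping for one
hand ignores the other hand).  A one-way ANOVA p-value below 1e-5 marks the
electrode strongly tuned, and FVAF = SS_dir / SS_total quantifies strength
(undefined, reported missing, at zero total variance).

## Laterality removal

The encoding model is refitted with the laterality predictor; the pooled
laterality column is normalized and the projection of the (mean-centered)
rates onto it subtracted.  Because orthogonal projection commutes with OLS on
the same design, refitting on the output returns laterality coefficients that
are zero to floating-point precision; linear directional decoding is
unaffected (the removed dimension is direction-independent), while nonlinear
decoders lose their means of telling the hands apart.

## Decoders

*Ridge*: the penalty is chosen from a log grid by maximizing mean held-out
Pearson r across the four outputs, with trial-level folds balanced across
unimanual right/left time steps; the final model is refitted on all data.

*Feed-forward network*: one densely connected hidden layer (512 rectifier
units; the nonlinearity is not published, rectifier is our default) mapping a
single bin to four velocities, implemented with scikit-learn's multilayer
perceptron — no deep-learning framework is assumed anywhere.  Optimizer
settings (Adam, learning rate 0.05, batch 512, ≤300 epochs, patience 100)
were tuned once for desk-scale convergence: with small learning rates the
network stalls in its linear regime and never learns the gating nonlinearity
that distinguishes it from ridge.

*Recurrent decoder*: a single-layer gated recurrent unit network (512 units
at full scale, 128 at desk scale) with a trainable day-specific affine input
transform (identity/zero initialized; synthetic experiments use one day), a
linear velocity head (4 outputs) and a softmax context head.  We use four
softmax classes (unimanual right, unimanual left, bimanual, no movement); the
published diagram shows three context signals with an implicit null, and the
four-class reading is ours.  Per-bin gating is by context argmax with no
hysteresis (optional exponential smoothing of the probabilities is off by
default): a cursor's velocity is zeroed unless its context class is engaged.
The loss is squared error over velocities plus cross-entropy over context
(weights 1:1, configurable — the published weighting is not stated) plus L2
weight decay.  Training is full backpropagation through time with Adam and
gradient-norm clipping, implemented in numpy and verified against finite
differences.  Optional input augmentations: i.i.d. Gaussian input noise, and
"mean drift" — a per-channel offset composed of a constant draw plus a slow
random walk across the snippet (the published augmentation of this name is
not defined; this is our reading).  Inference is strictly one 20-ms bin per
step; batch decoding and step-wise decoding are bit-identical.

## Training-data alteration

The labeled stream (inputs, velocity + context targets, and a per-bin
condition label: movement type × per-hand direction quadrant, with
unimanual-right-delay / unimanual-left-delay / bimanual-delay / rest
subtypes of no-movement) is cut into clips starting at random bins with raw
durations uniform in 0.2–0.8 of the snippet length — the duration bound
applies to the raw clip *before* dilation (the published text does not say;
this is our documented reading).  Each clip is resampled by a factor drawn
uniformly from [0.5, 2]: continuous channels and velocity targets by linear
interpolation with endpoints preserved, context classes by nearest neighbor
(interpolating class ids is meaningless).  Dilation does not rescale velocity
magnitudes — values are interpolated, not differentiated.  Clips are appended
until the 500-bin (10-s) snippet is full, the last clip truncated; a
candidate clip is rejected and redrawn if it would push any condition's share
of assembled bins more than 10% (absolute, configurable) above its target
share (uniform over movement types, subdivided uniformly over directions).
During the first snippet's worth of bins the share denominator is floored at
one snippet length so that tiny totals do not reject everything.  Clips may
span trial boundaries (the method's purpose is to fracture structure); a
flag forbids it.  Every snippet records its clip provenance (start, raw
length, factor, bins used) and can be replayed bit-exactly.  Train and
validation snippets are built from trial-level disjoint pools split in
advance.

## Closed-loop simulation

A simulated user stands in for the participant: per 20-ms step it forms a
unit point-at-target intention for each cursor it attends (all active cursors
for the simultaneous strategy; the cursor farther from its target, with a
3-bin switching hysteresis, for the sequential strategy), zero within the
200-ms reaction time of trial start or when the cursor is inside its target.
The intention is encoded through the simulated population with
context-appropriate coefficients and calibrated noise.  Optional angular
intention jitter is available (default 0; the raw-vs-altered ordering was
verified insensitive to it up to 0.6 rad).

Task mechanics follow the online protocol: workspace [-1, 1]², target radius
0.15 and distance 0.7 (geometry not fully published; ours, configurable),
dwell 500 ms, timeout 10 s.  Both cursors must sit in their targets
simultaneously; the dwell timer resets whenever any required cursor exits.
In unimanual trials the inactive cursor's target is its start position, so a
jittery decoder can fail a unimanual trial by drifting the wrong cursor.
Error assistance attenuates the velocity component orthogonal to the
cursor-to-target line by (1 - a); push assistance adds a target-directed
vector of magnitude (b × decoded speed); lock mode freezes the inactive
cursor.  Decoded velocity maps to workspace units through a configurable
output gain, mirroring the published online gain sweeps.  The decoder runs
*continuously across trials* (as deployed in real time); a flag restores
per-trial state resets.  Angular error is measured on the decoded,
pre-assistance velocity against the cursor-to-target direction over the
300–500-ms window (the published measurement is ambiguous between decoded
velocity and cursor displacement; we use decoded velocity and note it).
Cursor jitter is the mean decoded speed of a cursor during the other
cursor's active bins divided by its own active bins' mean speed.

## Experiments

The decoding sweep evaluates ridge and the feed-forward network on matched
datasets and folds per (rho, lat_scale) cell — grid values are our choice
(the published figure does not print them); defaults
rho ∈ {0, 0.25, 0.5, 0.75, 0.9, 1.0}, lat_scale ∈ {0, 0.25, 0.5, 1.0}.  Per
cell: sample a 192-channel population (no bimanual tuning changes — the sweep
concerns unimanual decoding), generate 2000 trials per hand, calibrate noise
to fSNR 1.5 (on a 400-trial/hand matched dataset for speed; fSNR depends on
the population and sigma, not the dataset length), mean-remove and
standardize, and evaluate on a held-out 20% of trials balanced by type.

The augmentation comparison trains two identical recurrent decoders on the
same delayed-movement source session — one on consecutive unaltered
("stereotyped") snippets, one on dilated/shuffled balanced snippets — and
evaluates both offline (held-out stereotyped stream) and in the simulated
closed loop.  The session and the closed-loop task include unimanual *and*
bimanual trials, as in the online protocol.  This matters: the stereotyped
decoder's online failure concentrates in bimanual trials, where one cursor
reaches its target before the other and the remaining movement is a
bimanual-to-unimanual context transition that never occurs in delay/move/idle
training blocks.  Desk-scale defaults (64 channels, 40 trials/type, 5-s
snippets, 128 units, 1000 Adam steps) fit the comparison in ~2.5 minutes on
one CPU; full scale restores 512 units and 10-s snippets.

## What the synthetic world does not establish

The generator produces linear-plus-laterality tuning with stationary i.i.d.
Gaussian noise.  It has no spiking statistics, no electrode-array geometry or
correlated noise, no neural adaptation or drift within a session, no
open-loop versus closed-loop tuning changes, and its simulated user is far
more stereotyped than a person.  Green tests establish that the estimators
recover what the generator programmed and that the decoding and
generalization *patterns* reproduce under the stated statistical structure —
not that the effect sizes match the published human data.  The published
real-data statistics (e.g. 34%/12% suppression, 39% laterality fraction) are
recomputable only from the deposited recordings via `reanalyze_deposited`,
which never downloads data and is exercised in tests only for its error
contract and report schema.

## Numerical conventions

Random state: every public entry point takes a seed; child generators are
derived per trial/noise/augmentation draw so results are bit-reproducible.
Degenerate inputs: constant predictions yield NaN Pearson r (reported
missing); zero total variance yields NaN FVAF; rank-deficient OLS designs
raise; fSNR of an exact fit is +inf.  Direction quadrants use half-open
angular intervals.  Negative cross-validated variances are floored only in
reported fractions.  HDF5 stores rates as float32; statistics on round-tripped
sessions match to ~1e-3 relative.
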