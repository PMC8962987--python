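# Methods

`emglabel` implements sensor-free continuous labeling for proportional,
simultaneous surface-EMG (sEMG) control, together with a complete synthetic
study harness that exercises the method end to end: signal generation,
time-domain feature extraction, a supervised acquisition protocol, five
labeling strategies, Gaussian-process velocity decoding, closed-loop 2D
cursor tasks and the rank-based statistics used to compare strategies.

## The labeling method

The premise: during a simple cue-guided training procedure, the EMG feature
stream itself already encodes the intensity of the muscle contraction, so
continuous regression targets can be computed from it directly — no force
sensor, data glove or tracked visual stimulus, and no synchronization
mismatch between signal and label, because both come from the same stream.

Per electrode *e* and per 150-sample sliding window, the four Hudgins
time-domain features are computed: mean absolute value (MAV), waveform
length (WL), zero crossings (ZC) and slope-sign changes (SSC).  With 8
electrodes this gives a 32-element frame per 1 kHz time step.  For each cued
direction *dir*, the label chain is:

1. **Electrode sum** — per feature *f*,
   `x_f,dir[i] = Σ_e x_e,f,dir[i]`, reducing 32 features to 4 streams while
   keeping each electrode's proportional influence.
2. **Per-feature normalization** —
   `x'_f,dir[i] = (x_f,dir[i] − x_min,f) / (max(x_f,dir) − x_min,f)`, where
   `x_min,f` is the mean of the electrode-summed feature over the recorded
   rest state and the maximum is taken over the direction's training data.
   The features have different units; this puts them on equal footing.
   Frames quieter than the rest mean are clipped to 0 (the label domain has
   no negative intensity), and the maximum is pooled over the repetitions
   used for training (a per-repetition variant is available via
   `per_repetition_norm`).
3. **Combination** — the four normalized streams are summed and divided by
   the maximum of that sum over the direction's training data, so every
   direction attains label 1 exactly once.  The direction's sign (± on the
   x- or y-DoF) is applied afterwards; the other DoF is labeled 0.

Five strategies assemble training sets from these labels.  Each takes 2000
of the 3000 active samples available per direction and repetition:

| strategy | label kind | samples used |
|---|---|---|
| A | binary (±1)  | first 2000 active (rising transient included) |
| B | continuous   | first 2000 active (rising transient included) |
| C | binary (±1)  | active samples 1001–3000 (steady state only) |
| D | continuous   | active samples 1001–3000 (steady state only) |
| E | continuous   | first 1500 active + 500 trailing frames through the falling flank |

The composition of strategy E's trailing block is an open design point; the
package anchors it at the end of activation — the last above-threshold frame
of the post-quota decay — so the block spans the late plateau and the entire
falling flank, and its labels decay toward 0 through the same equations (no
artificial ramp is imposed).  The 1500/500 split is configurable
(`rising_count`).

## Acquisition protocol

A state machine mirrors the supervised training procedure: one direction is
cued at a time; feature frames whose activity signal exceeds the threshold
count toward a 3000-sample quota; after the quota, the subject must rest for
1000 *consecutive* sub-threshold frames before the next cue; the sweep over
the four directions (+x, −x, +y, −y) is repeated four times and the last
three repetitions form the training set.  Counting from the threshold
crossing makes the bookkeeping invariant to reaction time.  A single active
frame during the dwell restarts the dwell counter (consecutive means
consecutive); real data might need a tolerance here.

**Activity signal and threshold.** The activity signal is the sum of the
per-channel MAVs — the simplest scalar monotone in overall contraction
intensity.  The threshold is the rest-activity mean plus `threshold_k`
standard deviations of the rest activity.  The default is `k = 4`: at a
1 kHz frame rate the activity signal is a smooth 150-sample moving average,
and a 3-sd threshold leaves rare above-threshold rest excursions (every few
tens of seconds) that break the strict consecutive dwell; 4 sd keeps the
onset latency negligible (the envelope crosses it a few milliseconds into a
ramp) while making the dwell reliable.  Both the rule and `k` are config.

**ZC/SSC deadband.** ZC and SSC counts are gated by an amplitude deadband,
default 0.02 V (about twice the synthetic baseline noise).  This is not
cosmetic: on a Gaussian baseline a zero deadband makes ZC/SSC invariant to
amplitude scaling, so after per-feature min-max normalization those two
streams would be pure noise spanning [0, 1] and would blur the labels (we
measured steady-state label spreads an order of magnitude too wide).  With
the deadband, crossing counts grow monotonically with contraction level, as
they do in practice, and all four features carry intensity information.

## Synthetic EMG model

Interference-pattern sEMG is emulated as zero-mean Gaussian noise whose
standard deviation is amplitude-modulated by an activation envelope, plus a
per-channel DC offset — the standard surrogate when real recordings are
unavailable.  Key parameters (defaults in parentheses):

- 8 channels at 1 kHz; rest noise sd 0.01 V; burst amplitude 0.5 V at full
  recruitment (inside a ±5 V acquisition range).
- Envelope: piecewise linear rest → rise (400 ms) → plateau → fall (400 ms),
  smoothstep optional.  The plateau holds `steady_level` (0.8 of full
  recruitment), jittered per burst by 5 % relative sd — operators are asked
  for a comfortable, not a calibrated, contraction level.
- Direction × channel mixing weights: each direction drives two dominant
  channels (weight 1) with 5 % cross-talk elsewhere, mimicking an
  agonist-pair electrode placement.
- Sessions hold the plateau ~0.6 s beyond the active-sample quota and rest
  about twice the dwell requirement between cues (humans pause longer than
  the sample-exact minimum; this also makes the strict dwell robust to rare
  rest excursions).

What the generator does **not** model: motor-unit physiology and spectral
changes with force, fatigue, electrode shift and drift, movement artifacts,
cross-talk dynamics.  Passing tests therefore demonstrate the *mechanics* of
the pipeline and the *direction* of strategy effects under clean conditions,
not performance on real sEMG.

The closed-loop simulated operator aims from cursor to target and eases off
linearly inside a 120 px slow-down radius (this is what enables fine
motion), with a 150 ms reaction delay, ~6° directional noise and 5 %
intensity noise per 20 ms control tick.  Intended direction and intensity
drive the same noise model as training, with non-cardinal directions mixing
the two relevant cardinal weight rows.

## Decoder

One Gaussian-process regressor per DoF maps the 32-feature frame to a
velocity command in [−1, 1] (posterior mean, clipped).  Kernel: constant ×
RBF plus a white-noise term, on standardized features, hyperparameters by
L-BFGS marginal-likelihood ascent.  Training rows beyond a budget are
uniformly subsampled for the cubic-cost GP (class default 2000 rows; the
test suite and acceptance script run at 250–400 rows, which already recovers
a known monotone feature-to-label map with held-out RMSE well below 0.05).
Rest frames labeled (0, 0) — as many as one direction's segment — are
included so the decoder returns to zero at rest.  Constant labels on a DoF
degrade gracefully to a mean-only model with a warning.

## Tasks and measures

**Aiming task (AT).** Target circle (radius 40 px — reported target sizes
vary widely across cursor studies; this is a package default) at 400 px along a cardinal
axis; cursor starts at the center and integrates command × 600 px/s at a
50 Hz tick with zero-order hold; success requires 500 ms continuous dwell in
the circle within a 10 s timeout.  One experiment is five sequences of all
four directions in random order (20 trials).  Measures: success,
completion/gross/fine motion time (gross ends at first target contact),
path efficiency (straight-line distance over traveled path, gross section),
average and maximum speed (gross section), overshoots (defined here as exits from the circle after first contact,
before success).

**Tracking task (TT).** The target moves at 100 px/s along one DoF, center
→ +400 → −400 → center: 1600 px of travel with exactly two turns.  Measures: time-averaged cursor-target
distance and average cursor travel speed.

**Statistics.** Per-subject means per strategy (failures excluded from time
measures) feed a tie-corrected Kruskal–Wallis test; post hoc, pairwise
Wilcoxon *signed-rank* tests (the design is within-subject; a rank-sum
variant would ignore the pairing) with Bonferroni correction, effect size
r = |Z|/√N with N the total observations of the pair, zero differences
dropped before ranking.  Values more than twice their group mean (computed
inclusively) are flagged as outliers and removed.

## Numerical choices and degenerate inputs

- Features are computed on causal (trailing) windows with step 1, matching
  an online 1 kHz system; frame *i* is aligned with raw sample *i* + 149.
  The acquisition hardware's fixed transport delay is not modeled; it is
  identical during training and use and cancels.
- ZC requires a strict sign change (a zero sample never crosses); SSC
  requires strictly opposite neighboring slopes.
- Noiseless rest (activity sd 0) gets a tiny positive threshold margin so
  the threshold stays strictly above the rest mean.
- Degenerate label normalization (feature maximum ≤ rest mean) and an
  all-zero combined stream are rejected with diagnostics rather than
  producing NaNs.
- All randomness flows from explicitly passed `numpy` generators; fixed
  seeds make every stage bit-reproducible, including the closed-loop
  experiments.

## Scale of the shipped experiments

Unit tests run a reduced protocol (600-sample quota, 150-frame dwell, two
sweeps) for speed; the acceptance checks and `scripts/acceptance.py` run the
full protocol (3000/1000/4 sweeps, ~116 s of 8-channel signal per session),
train A/B decoders at a 400-row GP budget and evaluate 4 simulated subjects
× 20 aiming + 10 tracking trials per strategy, plus bookkeeping runs at 10
subjects.  These sizes are the package's chosen experiment scale; all are
parameters.

## Known limitations

- The synthetic amplitude-modulated-noise model cannot show that the method
  works on real sEMG — only that the pipeline is faithful and that the
  strategy contrasts (label spread with/without transients; binary labels
  saturating commands, costing path efficiency) emerge from the mechanism.
- The simulated operator has no learning, fatigue or biomechanics; success
  rates in closed loop are near ceiling, unlike human studies.
- Strategy E's rising/falling split and the target-circle radius are
  assumptions exposed as parameters, not reproduced constants.
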