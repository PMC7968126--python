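# Methods

This note documents the models behind `exogait`: what the synthetic
gait generator emulates, how the biofeedback, assistance, outcome, and
statistics modules are defined, which parameters matter, and where the
design was genuinely open.

## The synthetic treadmill session

The generator stands in for a motion-capture laboratory: a participant
walks on an instrumented treadmill at a fixed belt speed `v` while
five synchronized systems record — footplate force-sensitive resistors
(FSR) and exoskeleton torque at 100 Hz, marker trajectories at 120 Hz,
vertical ground reaction force (GRF) at 980 Hz, and surface EMG at
1926 Hz — all sharing a trigger at `t = 0`.

**Foot-contact sequence.** Contacts alternate strictly left/right.
The interval ending at a side's contact is drawn from a normal
distribution with mean `mean_step_length / v` (the treadmill
constraint) and coefficient of variation `step_time_cv` (default
0.04, a typical pediatric-gait variability level), truncated at 25%
of the mean to keep intervals positive. Toe-off follows at 60% of the
stride (a standard stance fraction for walking). The stored ground
truth defines the true length of step *n* as `v · (t_n − t_{n−1})` —
exactly, for every step, regardless of variability. Sensor noise
never touches the truth record.

**Heel kinematics.** During stance a heel rides the belt backwards at
`−v`; during swing it follows the unique quintic with belt-matched
velocity and zero acceleration at both ends. Landing positions are
solved so that the left–right heel separation at each contact equals
the true step length exactly. A consequence used throughout: during
double support both heels translate together, so their separation is
constant there, and reading the separation at the first marker frame
at/after a heel strike is exact in the noiseless limit. Marker noise
is i.i.d. Gaussian, default sd 2 mm (typical optical-capture
precision).

**FSR and GRF waveforms.** The FSR is a trapezoid between a 0.1 V
swing baseline and a 3.0 V stance plateau, with a 30 ms linear rise
*centred on* the contact instant and a 30 ms fall centred on toe-off;
the mid-amplitude crossing is therefore an unbiased timing marker.
Contact jitter (`contact_jitter_sd_s`) shifts each FSR edge
independently, emulating footplate sensing error relative to the
optical reference; Gaussian voltage noise (default 0.02 V) is added
on top. The GRF is a body-weight-scaled trapezoid with a 5 ms onset
ramp starting at contact (so a 20 N threshold is crossed within one
980 Hz sample for all cohort masses) and a mild double-bump
modulation.

**Joint kinetics and EMG.** Angles and extensor-positive moments are
smooth per-cycle templates (sums of Gaussians / sinusoids in stride
phase): the biological ankle plantarflexor moment peaks in late
stance (default 1.0 Nm/kg), knee and hip extensor moments peak early
stance (0.5 + 0.015·crouch and 0.6 Nm/kg), and all moments are
exactly zero through swing, which makes phase-gating assertions
exact. `crouch_offset_deg` (default 15°) shifts hip and knee angles
toward flexion. EMG is 20–450 Hz band-limited Gaussian noise
amplitude-modulated by stance-phased envelopes (soleus burst in late
stance, vastus lateralis at loading response) over a configurable
noise floor; the true envelope is stored for validation.

**Condition sets.** `make_condition_set` produces `baseline` (zero
device torque), `assist`, and `bf_assist` at the same speed, 120 s
each with the final 20 s flagged as the analysis window. The
biofeedback response is emulated, not simulated: `bf_assist` lengthens
mean steps by a configured factor (default 1.14, the scale of
reported step-length biofeedback responses in CP) and reduces crouch
by 4°. Human adaptation, learning curves, and engagement effects are
deliberately out of scope — passing tests show the *pipeline* is
correct, not that people behave this way.

## Event detection

A two-state stance/swing machine per side: contact at the upward
threshold crossing, toe-off at the downward one. Crossing times are
refined by causal linear interpolation between the bracketing
samples, so timing error is set by the signal model rather than the
sampling period. A temporal debounce cancels transition pairs
bounding phases shorter than `min_phase_s` (default 100 ms, the
shortest plausible phase at these speeds); raising the window can
only remove events. The FSR threshold defaults to the midpoint of the
per-trial 5th/95th percentile voltages; the force threshold defaults
to the 20 N lab convention. The real-time feedback path uses only FSR
events; force-plate events are the offline measurement reference —
mirroring the device-versus-laboratory split. Degenerate inputs are
rejected with diagnostics: a side that never unloads, and thresholds
inside the noise floor (median detected phase < 50 ms ⇒ "chatter").

## Biofeedback session

Estimates use consecutive contacts of the merged two-sided stream, so
each interval spans one step; the first contact yields no estimate.
The interface state refreshes every `update_every_strides` (default
2) completed strides; each side's displayed value is the mean of its
last `window_steps` (default 2) estimates; a refresh scores one point
when the mean of the most recent left and right estimates *strictly*
exceeds the target (`baseline × 1.10`). Two readings of "average of
the last two steps" exist — one-per-side versus last-two-regardless-
of-side; they coincide for alternating gait, and the one-per-side
reading is implemented because it matches the per-side display.
Scoring is +1 per successful refresh. Display positions are
normalized by twice the target (bar mid-screen); they are cosmetic
but logged. With contact jitter sd σ, an estimate differences two
noisy times, so its error sd converges to `√2·v·σ`; this closed form
is verified at n = 1000 steps.

## Assistance model

Stance torque is `gain × (estimated biological ankle moment)`, the
gain fitted per trial so the realized peak equals
`pf_peak_target_nmkg × mass` (default 0.22 Nm/kg). Whether a real
controller fixes this gain a priori or tunes it per participant is an
open design point; the auto-fit is the declared choice here. Swing
torque is the constant dorsiflexion set-point (`df_setpoint_nmkg`,
default 0.05, valid range 0.02–0.11), stored negative under the
plantarflexion-positive sign convention. Transitions blend linearly
over 50 ms centred on each contact/toe-off to avoid discontinuities;
outside those ramps the phase gating is exact. The footplate-based
ankle-moment estimator of the physical device is replaced by the
trial's known moment template — the proportional law, not the
estimator, is the modeled contribution. For powered trials the stored
kinetics represent what inverse dynamics would measure (muscle +
device); `decompose_biological` subtracts the device torque pointwise
(after linear-interpolation resampling from 100 Hz to the 120 Hz
kinetics grid), and biological power subtracts torque × angular
velocity, so moment and power conservation hold at machine precision
by construction.

## Outcomes

Sign conventions: extensor/plantarflexor moments positive; hip/knee
extension and ankle plantarflexion angles positive. "Peak knee
extension" is reported as the stance maximum of the extension-positive
angle (equivalently, minimum flexion) — the natural reading for
crouched gait, where extension beyond neutral may never occur.
Angular velocity differentiates the angle after a 4th-order zero-phase
Butterworth low-pass at 6 Hz (noise would otherwise dominate the
derivative). Stance-average positive power is the trapezoidal integral
of `max(P, 0)` over the half-open stance window `[contact, toe_off)`,
with interpolated window endpoints, divided by stance time; the summed
variant adds per-joint averages (hip + knee + ankle, plus the device
as a fourth component in the total variant). Outcomes are computed
per cycle (consecutive same-side force-plate contacts inside the
analysis window), averaged within each limb, then across limbs;
kinetics are divided by body mass exactly once; fewer than three
complete cycles per limb rejects the window. Zero-phase IIR filtering
leaves edge transients within a few seconds of the record boundaries,
so exactness comparisons use interior windows.

## EMG

The linear envelope is 4th-order zero-phase Butterworth band-pass
15–380 Hz → full-wave rectification → 4th-order zero-phase Butterworth
low-pass 7 Hz (Butterworth order and zero-phase application are
declared choices; only the cutoffs are fixed by the procedure being
modeled). Envelopes are normalized by the peak from the zero-torque
reference trial processed identically. Stance iEMG divides the
trapezoidal integral of the normalized envelope over stance by the
stance duration — "divided by the period" read as the stance time, so
the quantity is a phase-mean.

## Statistics

RMSE% uses the participant's mean measured step length as denominator
(the percent basis is otherwise underdetermined). Pooled Pearson R is
computed over all participants' steps pooled rather than averaging
per-participant coefficients (flagged as a choice; both are defensible
with few participants). The normality gate is the Lilliefors-corrected
Kolmogorov–Smirnov test on paired differences — the correction is
required because the null parameters are estimated from the sample;
with fewer than 4 pairs the gate is inapplicable and the t branch is
used with a note. The Wilcoxon fallback uses Pratt zero-handling with
the exact distribution when n ≤ 25 and no zeros. Identical conditions
return p = 1 by convention. No multiple-comparison correction is
applied, consistent with an exploratory feasibility design. A known
calibration limit, measured by Monte Carlo: at n = 7 and α = 0.05 the
gate's power against Cauchy-distributed differences is ≈ 0.43 (as it
is for Shapiro–Wilk), so heavy-tailed data route to Wilcoxon in under
half of replicates at this sample size; the t branch's type-I error
remains nominal (≈ 0.05).

## Problem sizes and determinism

Default trials are 120 s with a 20 s analysis window; test and
acceptance runs use 10–60 s trials (and a 560 s trial for the
n = 1000 noise-propagation check), sizes chosen to give stable
statistics at interactive runtimes. Every random quantity flows from
a single `numpy` generator seeded per trial; identical configs and
seeds reproduce byte-identical serialized bundles (`%.17g` float
formatting and round-trip parsing guarantee exact text round-trips).

## Known limitations

Sagittal-plane only: no step width or mediolateral kinematics. No
musculoskeletal modeling — joint kinetics enter as analytic templates,
not inverse dynamics from markers and forces. No motor/transmission
dynamics or cable mechanics in the device model. The generator's
behavioral "response" to biofeedback is a configured effect size, so
group-level condition contrasts validate the analysis chain, not human
behavior. Missed or double foot contacts are not simulated by
default.
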