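# Methods

`propriosnn` models how an insect's nervous system reads out joint
posture and movement from arrays of proprioceptive hairs.  This note
documents the model, its numerical treatment, the choices made where
the design was genuinely open, and what the bundled synthetic data can
and cannot show.

## Model

### Hair fields and range fractionation

A joint's angle θ is sensed by a **hair plate**: two opposing rows of
`N_h` cuticular hairs.  Hair *i* of a field is deflected only inside
its receptive field `[θ_rf0_i, θ_rf90_i]`; within it the deflection
φ grows linearly from 0° to 90°, outside it saturates.  Receptive
fields are uniform in width `(θ_max − θ_min)/N_h`, tile the field's
range exactly (the outer hairs' edges are pinned to the field bounds),
and adjacent fields share a configurable overlap `θ_ol` (default
0.1°).  A *positively* oriented hair engages as θ rises; a *negatively*
oriented hair is fully deflected at low θ and releases as θ rises.
The two fields of a plate cover the halves of the joint's working
range below and above the **resting angle** (its midpoint), with a
small inter-field overlap `θ_olhf = θ_ol` so that the innermost hair
of each field retains a little deflection at rest.

For velocity encoding the plate is **extended**: both fields span the
full working range with `N_h` hairs each (default 50 per field, 100
per plate), so receptive-field transitions occur in both movement
directions anywhere in the range.  Only the 25 hairs per field whose
receptive fields lie in that field's original half-range stay wired to
the position interneurons; the supplementary hairs serve the velocity
pathway alone.

### Afferents: adaptive exponential integrate-and-fire

Each hair drives one mechanosensory afferent with current
`I = gain · φ` (gain default 50 pA/°, admissible 10–150 pA/°).  The
afferent is an AdEx neuron,

    C dV/dt = I − g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) − w
    τ_w dw/dt = a (V − E_L) − w

with a spike recorded whenever V > V_T, followed by V → E_L and
w → w + b.  Defaults: C = 200 pF, g_L = 2 nS, E_L = −70 mV,
Δ_T = 2 mV, V_T = −50 mV, a = 2 nS, τ_w = 50 ms, b = 264 pA.  The
adaptation current w produces the phasic-tonic signature: a burst at
deflection onset decaying to a tonic plateau `f_ss` (≈257 Hz for a
fully deflected hair at the default gain).  `b` is dimensionally a
current increment (it adds to w, which enters the voltage equation as
a current), hence pA.  τ_w = 50 ms is deliberately shorter than the
~600 ms that best fits slow biological adaptation: a long time
constant suppresses the afferent after rapid movement reversals and
degrades downstream velocity encoding.

### Interneurons: leaky integrate-and-fire

Interneurons are LIF units: a presynaptic spike adds its weight ω to
V, V decays toward E_L with time constant τ, and V > V_T emits a spike
and resets.  Per joint there are four:

* **Position INs** (τ = 120 ms, ω = 1 mV): `pos+` integrates every
  spike from the position-wired hairs of the positively oriented
  field, `pos−` from the negatively oriented field.  Their long τ
  turns afferent spike counts into a rate proportional to how far the
  joint sits from rest on either side.
* **Velocity INs**: each hair's afferent train first passes a
  per-hair **high-pass LIF** (τ = 5 ms, ω = 10.4 mV — see below),
  which fires only while its input rate exceeds a cutoff `f_c`;
  surviving spikes from all hairs of a field converge on an
  **integrator LIF** whose weight (25 mV) exceeds the threshold gap
  V_T − E_L = 20 mV, so it relays every input spike.  Because `f_c`
  is tuned just above the tonic plateau `f_ss`, only the phasic burst
  fired while θ crosses a hair's receptive field survives — the
  population rate of `vel+`/`vel−` then tracks angular speed in the
  rising/falling direction.

The model is deterministic throughout: identical inputs give
bit-identical spike trains.

## Numerics

All state equations are advanced by backward differences on a fixed
grid (default dt = 0.25 ms): linear terms are implicit; the AdEx
exponential is evaluated at the previous step's voltage, keeping each
update a linear solve, with its argument clamped at
`(V − V_T)/Δ_T ≤ 20`.  Spikes trigger on the strict test V > V_T
evaluated after the update, so the clamp shapes only the discarded
overshoot, never spike timing.  Voltage divergence beyond a hard
ceiling raises an error rather than propagating NaNs.

Two discrete-grid effects matter downstream:

* **ISI alternation.**  Under constant drive the equilibrium
  inter-spike interval is generally not a multiple of dt, so the
  discrete train alternates between the two bracketing step counts
  (15/16 steps at full deflection).  Tonic rates are therefore
  measured as spike count over a trailing window, and the adaptation
  ("ISIs never shorten") invariant holds up to one step of jitter.
* **High-pass cutoff vs. alternation.**  A periodic train of ISI `n`
  steps drives the high-pass LIF's voltage envelope to
  `ω / (1 − ρ^n)`, ρ = 1/(1 + dt/τ); the cutoff `f_c` is the rate of
  the largest `n` for which this exceeds the threshold gap.  An
  *alternating* 15/16 train, however, reaches a higher two-cycle
  envelope than the strictly periodic train at the same mean rate, so
  the weight must be calibrated against the afferent's *actual*
  equilibrium train.  With this integrator the calibration
  (`calibrate_cutoff`: raise ω until `f_c` sits just above `f_ss`,
  requiring zero output for the tonic train and at least one output
  spike for the phasic burst of a 50 °/s receptive-field crossing)
  selects ω = 10.4 mV on a 0.2 mV grid, giving f_c = 266.7 Hz against
  f_ss ≈ 257 Hz.  An afferent only ~4 % cooler (ISIs alternating
  16/17) would tolerate 10.8 mV; the shipped default is the value the
  calibration actually selects for the shipped afferent, because with
  10.8 mV the saturated hairs of an extended plate leak ≈40 Hz each
  through the filter, destroying stationarity silence and direction
  selectivity.

Rate estimation is a convention, not part of the model.  Two
estimators are provided: `isi_holdover` (1/ISI held over each
interval; used for position decoding and for peak rates, where the
peak is 1/min ISI) and a centred `boxcar` count (default 50 ms; used
for velocity decoding, whose combined signal is otherwise dominated by
stair-stepping).  Peak afferent rates quoted anywhere in the package
are reciprocal minimum ISIs.

## Stimuli and synthetic data

* **Ramp-and-hold batteries** characterise the afferent: deflection
  0 → 37° at 980, 604, 352, 188 or 96 °/s, and deflection at
  240.4 °/s to 60, 46, 34, 23 or 15°, each with a 500 ms hold
  (configurable; the steady state is read from the trailing 100 ms of
  the hold, and results are insensitive to hold length beyond
  adaptation settling).
* **Constant-velocity sweeps** are triangular waves over the working
  range, preceded by a 500 ms settle hold.  The per-speed output rate
  is measured over the central 60 % of each constant-velocity phase,
  excluding the post-reversal carryover (residual adaptation lets an
  IN fire briefly after a direction change, bounded by ~3 τ_w) and
  the range edges where the extended fields saturate.
* **Synthetic gait traces** stand in for 200 Hz motion-capture
  recordings of flat walking: a ~1 Hz fundamental with 2nd/3rd
  harmonics at relative amplitudes (1, 0.3, 0.1) and random phases,
  plus Gaussian noise low-passed at 5 Hz (SD 1°), soft-clipped (tanh)
  into the joint's working range.  They reproduce bounded quasi-
  periodic stepping with smooth reversals and plateau asymmetries,
  but not the trial-to-trial variability, step-class structure,
  inter-joint coupling or measurement noise of real kinematics —
  decoding scores on synthetic traces are therefore upper bounds on
  what identical settings achieve on experimental data (synthetic
  traces are smoother, so MSE is lower and classifier accuracy higher
  than the ~0.03 / ~0.09 / 0.914 expected on recorded walking).

## Evaluation

* **Afferent fit (MAE)**: over the ten ramp trials,
  `(1/20) Σ (|Δx_ss| + |Δx_max|)` between model and reference peak and
  steady-state rates, in Hz.  An 8×8 grid search over gain
  (10–150 pA/°) and b (50–350 pA) reports the full MAE surface and all
  argmin cells; ties are broken lexicographically by default or by a
  seeded random choice.  The bundled reference table is a clearly
  marked synthetic stand-in (`data/reference_rates_synthetic.csv`);
  MAE against it is illustrative only.
* **Decoding (MSE)**: the antagonistic rates are combined as
  `znorm(r+ − r−)` and compared with the z-normalised stimulus (joint
  angle for position; central-difference angular velocity, low-passed
  at 10 Hz, for velocity), averaged over every time step, joint and
  trial with equal weight.  Velocity decoding lags the stimulus by
  ~0.025 s (the phasic peak trails maximum hair deflection); an
  optional lag shift trims the overlap and removes this bias.
* **Direction classification**: velocity-IN spikes are scored against
  the sign of dθ/dt at the spike time (TP/FP for `vel+` on
  rising/falling, FN/TN for `vel−`), with samples below 1e−6 °/ms
  excluded as direction-undefined; TPR, TNR and ACC = (TPR+TNR)/2.
  Empty denominators yield NaN, never a silent 0.
* **Rate–velocity linearity**: ordinary least squares of mean IN rate
  on sweep speed; the slope (Hz per °/s = spikes per degree) is ~1.8
  with r² ≈ 0.99 for the default network over 50–400 °/s.

## Degenerate inputs and edge rules

Zero-variance series cannot be z-normalised and raise an error; a
decoder that never spikes is scored against a flat z-line in grid
searches.  Joint angles outside a field's range are legal (hairs
saturate).  Presynaptic events landing in one step sum their weights.
Event times are binned to the nearest step; spike times are reported
at the end of the step that crossed threshold.

## Known limitations

Hair geometry is idealised: uniform lengths, equal spacing, strictly
linear hair-angle/joint-angle coupling, no two-dimensional multi-hair
overlap.  There is no noise model, no refractory period, and no
chordotonal-specific afferent (the femur-tibia joint reuses the hair
plate model on the grounds that its encoder shares range fractionation
and phasic-tonic dynamics).  Velocity interneurons are strictly
direction-selective by construction and carry a short post-reversal
carryover; position interneurons overshoot at abrupt angle changes
(the afferent's phasic peak leaks into the position rate, and grows
with ω).  Quantities tied to the afferent's absolute discrete firing
rate (tonic plateau, peak rates, the calibrated high-pass weight) are
sensitive at the few-percent level to the integration scheme and grid.
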