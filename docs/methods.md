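# Methods

## The model

`cvinfer` implements a lumped-parameter model of the systemic circulation
written entirely in terms of measurable pressures. The circulation is a
closed loop: a one-chamber heart pumping at rate Hr with stroke volume
SV ≈ C_a·P_p, a compliant arterial compartment (compliance C_a), a lumped
peripheral resistance R, and a compliant venous compartment (C_v) whose
unstressed volume is recruited by autonomic activation. Eliminating the
(unmeasurable) volumes through the compliance relations leaves two coupled
ODEs for the mean arterial and venous pressures:

    C_a·dP_a/dt = C_a·Hr·P_p − (P_a − P_v)/R
    C_a·dP_a/dt + C_v·dP_v/dt − ΔV_v0·dS_tot/dt = I_ex

where ΔV_v0 is the span of recruitable unstressed venous volume and I_ex
is the external volume current (negative during bleeding or capillary
leak, positive during fluid administration).

Three control layers close the loop:

* **Baroreflex** S_b = 1 − σ(k_b·(P_a − P_set)) with fixed gain
  k_b = 0.1838 mmHg⁻¹: a negative-feedback response to deviations of
  arterial pressure from the set point P_set.
* **Independent autonomic drive** S(t), pressure-independent (arousal,
  drugs, pain), modeled per analysis segment as linear in time and clipped
  to [0, 1].
* **Total activation** S_tot = σ(3.3·(S_b + S − 1)), which drives heart
  rate Hr = Hr_min + (Hr_max − Hr_min)·S_tot, contractility
  K̃ = K̃_min + (K̃_max − K̃_min)·S_tot, venous recruitment and (together
  with the non-autonomic modulation M_SVR ∈ [−1, 1]) the peripheral
  resistance R = R_min + (R_max − R_min)·σ(3.3·(S_tot + M_SVR)).

The pulse pressure follows from the contractility chain with the venous
pressure standing in for the end-diastolic filling pressure:
P_p = K̃(S_tot)·P_v/(P_a − P_v). This approximation degrades when P_v
approaches P_a (e.g. pulmonary hypertension); the code enforces a minimal
gap of 0.5 mmHg and raises a regime error beyond it rather than
extrapolate.

### Scaled parameterization

From pressure data alone C_a is not identifiable, so the estimator works
in scaled coordinates: C̃_v = C_v/C_a, ΔṼ_v0 = ΔV_v0/C_a (mmHg),
Ĩ_ex = I_ex/C_a (mmHg/s), R̃ = α_RC·C_a·R (s, where α_RC absorbs the
unknown pulse-contour calibration), and the relative contractility K̃
(mmHg), which never decomposes into its physical factors. Fifteen scaled
parameters are estimated per segment; forward simulation uses the physical
parameterization and converts exactly (`PhysicalParameters.to_scaled`).

## Forward simulation

Fixed-step RK4 (default dt = 0.1 s) on the two pressure ODEs.
dS_tot/dt is evaluated analytically by the chain rule through both
sigmoids — the arterial equation does not involve dP_v/dt, so the venous
equation can use the freshly computed dP_a/dt explicitly. Numerical
bookkeeping: the stressed-volume functional C_a·P_a + C_v·P_v − ΔV_v0·S_tot
must change exactly by ∫I_ex dt; at dt = 0.1 the residual is ≤ 2·10⁻⁴
relative (dominated by the first seconds, where the printed off-equilibrium
initial state (48, 4) mmHg relaxes quickly), and ≤ 10⁻⁵ at dt = 0.05. The
accuracy-sensitive checks therefore integrate at dt = 0.05; 0.1 remains the
default for speed. Trajectories are aborted with explicit errors on
pressure blow-up (> 500 mmHg) or regime collapse (P_a − P_v below the gap).

Reference parameter set (a neonate-like artificial patient, used by all
simulations unless overridden): P_set = 50 mmHg, Hr 100–180 bpm,
K̃ 200–800 mmHg, R 0.8–1.8 mmHg·s/ml, C_a = 0.45 ml/mmHg, C_v = 10 ml/mmHg,
ΔV_v0 = 65 ml, S = 0.2, initial pressures 48/4 mmHg.

### Scenario library

Drive schedules are piecewise-linear with range clipping. Magnitudes are
not dictated by the physiology alone, so they were fixed once at values
that keep the observables inside the validity thresholds of the
extraction pipeline:

* `hypovolemic` — I_ex ramps to −0.05 ml/s within a minute and holds for
  the 15-min withdrawal (≈ 13% of a 3.5-kg neonate's blood volume), then
  stops.
* `distributive` — M_SVR declines linearly 0 → −0.5 over 15 min.
* `combined` — both schedules superposed.
* `fight_or_flight` — S steps 0.2 → 0.8 over two minutes, mid-record.
* `control` — all drives constant.

## Synthetic waveforms

The waveform generator renders an observable envelope into 125 Hz
beat-resolved traces: each beat rises from diastolic to systolic level as
a raised half-cosine over 30% of the cycle (systolic ejection), then
decays exponentially with time constant R·C_a toward an asymptote chosen
for continuity. The systolic level solves, per beat and in closed form,
the constraint that the beat mean equal P_a given range P_p and decay
constant τ — so beat rate, per-beat mean, range and decay constant all
carry recoverable ground truth. The venous channel adds small cardiac and
respiratory oscillations to the P_v envelope.

This morphology is deliberately synthetic: no dicrotic notch, no
respiratory pulse-pressure variation, no wave propagation. It emulates
exactly the envelope statistics the feature extractor measures, which is
what a round-trip test needs; fidelity on real catheter waveforms is a
separate question the synthetic fixtures cannot answer. Injected
artifacts (spikes, flat-line dropouts, baseline wander at Poisson rates)
emulate movement/flush corruption for robustness tests, with a
ground-truth mask.

## Feature extraction

1. **Beat detection** — diastolic troughs via prominence-gated local
   minima (prominence ≥ 25% of the robust pulse amplitude, refractory
   0.2 s). Heart rate is the reciprocal beat period; pulse pressure the
   per-beat max − min.
2. **RC estimation** — over each diastolic run-off (systolic peak to next
   onset, trimming two samples at each corner) the linearized exponential
   P[i+1] = c + b·P[i] is fitted by least squares; b = exp(−Δt/τ) is
   invariant to the unknown decay asymptote, which the arterial channel
   alone cannot supply. Fits with R² < 0.5 or non-decaying run-offs are
   flagged and imputed from neighbouring beats. RC is identified only up
   to the global scale the estimator fits as α_RC.
3. **Outlier clamping** — points outside local median ± 3 scaled MAD
   (20-s window) are set to the violated threshold, not removed. When the
   local MAD is zero an epsilon floor (0.5 mmHg for pressures, 1 bpm for
   heart rate) keeps genuinely constant stretches untouched.
4. **Resampling** — mean pressures are 10-s moving averages of the raw
   channels; all five channels are linearly interpolated onto the uniform
   10 Hz grid. A configurable low-pass stage defaults to pass-through:
   the observables are already minute-scale envelopes and any hard
   cutoff above the 5 Hz Nyquist of the grid is vacuous.
5. **Validity** — a 300-s segment is analysed only if every sample
   satisfies 20 < P_a < 250 mmHg, 0 < P_v < 25 mmHg, RC > 0,
   30 < Hr < 250 min⁻¹ and P_p > 10 mmHg; the first violated criterion is
   reported.

Round-trip accuracy on artifact-free synthetic records: pressures and
heart rate within 2%, pulse pressure within 5%, RC within 15% (up to the
global scale), verified in the acceptance tests.

## Inverse estimation

`ShockStateModel(obs, meta).fit(n_starts, seed)` estimates the fifteen
parameters independently on overlapping 300-s windows (100-s stride; a
25-min record gives 12 windows, starts 0…1100 s — a trailing window that
ends flush with the record is dropped unless it is the only one).

**Objective.** For each window, residuals link the parameters to the
data: heart rate (f_H), scaled resistance (f_R), pulse pressure (f_P),
the venous volume balance (f_I) and the arterial flow balance (f_a, with
heart rate in beats/s so the units are mmHg/s). S_b is computed from the
*measured* arterial pressure; S and M_SVR are linear in segment-local
time. The objective is the left-Riemann time integral of the weighted
squared residuals, each normalized by a segment-level scale (means of
Hr, RC, P_p, Hr·P_p; the bound of Ĩ_ex for f_I) with weights
w_H = 1, w_R = w_P = w_I = 0.2, w_a = 10, plus a memory penalty
β·Σ exp(−(t−t̄)/τ)·(θ̂(t̄)−θ)²/B² (β = 0.1, τ = 500 s, B the upper bound)
over the slowly-varying parameters {C̃_v, ΔṼ_v0, P_set, Hr_max, Hr_min,
R̃_max, R̃_min}. The decaying exponential weights *recent* estimates most;
a growing exponential would let the oldest segment dominate without
bound.

**Derivative channels.** Ṗ_a and Ṗ_v are Savitzky–Golay first
derivatives (30-s window, order 2) computed once on the full series;
Ṡ_tot follows analytically by the chain rule. The smoothing defines the
timescale on which the flow-balance residuals are meaningful; transients
faster than the window (e.g. the integration start-up transient of the
artificial patients) are invisible to it, which is why the recovery
experiments discard a 120-s settle-in.

**Bounds.** Search boxes come from age-bracketed pediatric reference
ranges for P_set, Hr_min, Hr_max, fixed physiological ranges for the
rest, and per-kg blood volume anchors for the volume parameters
(ΔṼ_v0 ∈ [0.1·V_b/C_max, 0.3·V_b/C_min], |Ĩ_ex| ≤ 0.25·V_b/(3600·C_min),
with V_b = 100 ml/kg up to 3 months of age, else 75, and compliance per kg
C ∈ [0.02, 0.15] ml/(mmHg·kg)); body weight cancels in the scaled
coordinates, so the boxes depend on age only. α_RC, absent from the
reference ranges, spans [0.1, 10]. As data accumulate the extremal
parameters tighten monotonically: the upper bound of Hr_min falls to the
smallest observed heart rate, the lower bound of Hr_max rises to the
largest, and likewise for R̃_min/R̃_max through RC.

**Optimization.** Parameters are mapped to the unit box and minimized
with L-BFGS-B using the analytic gradient of the objective (assembled by
the chain rule through the three sigmoids; verified against finite
differences in the tests). Multi-start: a pool of 20·n_starts uniform
random points (n_starts = 5 by default) plus the previous segment's
optimum is screened by objective value and the best n_starts are
polished; the lowest objective wins. The screening step exists because
a start with a far-off set point saturates the baroreflex sigmoid and
leaves the local solver on a flat plateau. All randomness derives from
one master seed via per-segment spawned streams, so fits are exactly
reproducible.

**Outputs.** Per-segment estimates, a centred 5-segment moving average
("smoothed trace"), and the derived shock indices: Ī_ex = Ĩ_ex/ΔṼ_v0
(per minute; negative = ongoing volume loss), M_SVR at the segment
midpoint (negative = non-autonomic vasodilation), and K̃_max (low =
cardiogenic component). `summary()` prints record-level means with
standard errors. `reconstruct(i)` rebuilds Hr, RC and P_p from θ̂ and the
measured pressures (through S_tot, consistently with the pulse-pressure
relation) and reports Pearson correlations against the measured channels;
constant channels yield NaN with a flag. Fast fluctuations are not
reproduced by construction — S and M_SVR are linear within a segment.

## Recovery experiments (study conditions)

The canned experiments in `cvinfer.experiments` fix, once: artificial
neonate patients (age 14 d, 3.5 kg) generated with the reference
parameter set under each scenario; a 120-s settle-in before a 25-min
analysed record (insult beginning at the analysed window's start and
evolving over 15 min); noiseless 10 Hz observables taken directly from
the simulator; 5 restarts per segment. Under these conditions every
seeded realization recovers the sign of the defining index (negative
Ī_ex for hypovolemic, negative M_SVR for distributive, both for
combined), the control patient's Ī_ex stays within ±0.005 min⁻¹ of zero,
and pooled reconstruction correlations exceed 0.95. The reproduction
script (`scripts/acceptance.py`) reruns these at 3 estimation seeds per
patient to stay within a few minutes of runtime.

Note the reference simulation values P_set = 50 mmHg and Hr_min = 100 bpm
do not jointly fit inside any single age bracket (the neonatal Hr_min
range is [110, 130] bpm), so Hr_min's truth lies outside its search box.
The recovery targets do not involve Hr_min itself; its misfit is absorbed
by S_tot and Hr_max.

## Known limitations

* One chamber, no pulmonary circulation, no ventilation coupling or
  pericardial mechanics; the P_p relation degrades at high venous
  pressures.
* M_SVR's *level* is weakly identified within a single segment (it trades
  against R̃_min/R̃_max through a saturating sigmoid); identification
  rests on the cross-segment memory penalty, data-driven bound
  tightening, and averaging across segments. Control records, where RC
  is constant, leave M_SVR essentially unidentified — only the volume
  index is meaningful there.
* The synthetic waveform morphology constrains only envelope statistics;
  beat detection and RC extraction are not validated against real
  catheter recordings.
* Parameter magnitudes (e.g. ΔṼ_v0, C̃_v) carry residual degeneracy; the
  shock indices are ratios and trends chosen to be robust to it, but
  absolute parameter values should be read with care.
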