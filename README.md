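# cvinfer

Mechanistic cardiovascular modelling and shock-state inference from
bedside blood-pressure waveforms.

Critically-ill patients in intensive care are continuously monitored
through arterial and central-venous catheters, yet the quantities that
define a shock state — ongoing blood-volume loss, maladaptive
vasodilation, failing contractility — are hidden: they cannot be measured
directly at the bedside. `cvinfer` implements a lumped-parameter model of
the circulation written purely in terms of measurable pressures,

    C_a·Ṗ_a = C_a·Hr·P_p − (P_a − P_v)/R
    C_a·Ṗ_a + C_v·Ṗ_v − ΔV_v0·Ṡ_tot = I_ex

with baroreflex and independent autonomic control driving heart rate,
contractility, venous recruitment and peripheral resistance through
shared sigmoid activations. On top of the model sit:

* a **forward simulator** of shock scenarios (hypovolemic, distributive,
  combined, fight-or-flight) with full hidden-state traces;
* a **synthetic waveform generator** producing beat-resolved 125 Hz
  arterial/venous traces from any observable envelope;
* a **feature-extraction pipeline** turning raw waveforms into the five
  10 Hz observables (mean arterial and venous pressure, heart rate,
  pulse pressure, and RC — resistance × arterial compliance, known up to
  a pulse-contour scale);
* an **inverse estimator** that infers the fifteen hidden physiological
  parameters per 300-s window by constrained multi-start optimization
  and reports clinically interpretable shock indices: the volume-loss
  rate Ī_ex (min⁻¹), the non-autonomic resistance modulation M_SVR, and
  the maximal relative contractility K̃_max.

It is written for researchers in computational physiology and critical
care who want a transparent, fully testable implementation — every stage
runs on synthetic data with known ground truth.

## Worked example

Simulate a bleeding neonate, estimate the hidden parameters from the
simulated observables, and read off the shock indices:

```python
import cvinfer as cv

trace = cv.simulate(scenario="hypovolemic")      # 25-min record
obs = trace.observables()                        # five channels at 10 Hz

meta = cv.PatientMeta(age_years=14 / 365, weight_kg=3.5)
model = cv.ShockStateModel(obs, meta)
res = model.fit(n_starts=5, seed=1)
print(res.summary())
```

which prints (abridged):

```
                    Shock-state inverse model
==================================================================
Patient age: 0.04 y   weight: 3.5 kg
Windows: 12 (12 valid/estimated)   restarts: 5   seed: 1
Objective (median over segments): 0.001873
------------------------------------------------------------------
Shock indices (mean +/- SE over segments):
  volume-loss rate  I_ex  -0.0507 +/- 0.0089 1/min
  SVR modulation    M_SVR +0.1104 +/- 0.0395
  max contractility K_max 738.8 +/- 21.9 mmHg
------------------------------------------------------------------
Median parameter estimates:
  p_set                 52.15   bounds [42, 73]
  ...
  k_max_rel             695.5   bounds [333.3, 1e+04]
==================================================================
```

The negative volume-loss rate identifies the hypovolemic state: the
patient loses intravascular volume at about 5% of the recruitable venous
reserve per minute (the generating simulation withdrew 0.05 ml/s over
15 min). M_SVR near zero correctly reports no major vasodilatory
component, and the recovered maximal contractility (≈ 740 mmHg) sits
near the generating value of 800 mmHg.

The same analysis runs from raw waveforms — synthesize them first if you
have no recordings:

```python
rec = cv.synthesize_waveforms(obs, seed=0)       # 125 Hz, beat-resolved
model = cv.ShockStateModel.from_waveforms(rec, meta)
```

or from the shell:

```
cvinfer simulate --scenario hypovolemic --out trace.csv
cvinfer synth    --trace trace.csv --out wave.csv --seed 1
cvinfer extract  --waveform wave.csv --out obs.csv
cvinfer estimate --observables obs.csv --age-years 0.04 --weight-kg 3.5 \
                 --seed 1 --out estimates.csv
cvinfer report   --estimates estimates.csv --out indices.csv
```

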