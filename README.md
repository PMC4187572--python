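# musclebold

Quantitative muscle BOLD fMRI analysis: dual-echo R2\* relaxometry of
exercising calf muscle, block-design cycle averaging, mono-exponential
recovery fitting, and repeated-measures visit statistics — together with a
synthetic dual-echo EPI generator so the whole pipeline is testable without
any scanner data.

## The problem

Skeletal-muscle functional MRI tracks tissue oxygenation during exercise
through the effective transverse relaxation rate R2\* = 1/T2\*:
deoxyhemoglobin is paramagnetic, so lower oxygenation means faster signal
decay and higher R2\*. A dual-gradient-echo EPI sequence acquires two
echoes (TE₁, TE₂) per time point; under monoexponential decay
S(TE) = S₀·e^(−TE·R2\*), the two-point estimate

```
R2* = ln(S(TE₁) / S(TE₂)) / (TE₂ − TE₁)
```

is exact and immune to coil gain. During a block-design plantar-flexion
paradigm (baseline, then cycles of contraction + recovery), the ROI-mean
R2\* time course of a muscle rises during exercise and relaxes back
afterwards. After normalising to the resting baseline B₀
(p(t) = (R2\*(t) − B₀)/B₀ × 100) and averaging the final cycles, the
post-exercise portion is fitted with

```
y(t) = plateau + (peak − plateau) · e^(−t/τ)
```

giving the two headline metrics per muscle and run:

- **maximal change** — the peak amplitude of the cycle-averaged
  percent-change time course (% of baseline R2\*), an index of oxygen
  utilisation;
- **recovery change** — peak minus the fitted end-of-recovery value
  (also reported normalised by the peak), an index of re-oxygenation.

A statistics layer compares these metrics across repeated visits
(paired t tests, one-way repeated-measures ANOVA, Kolmogorov–Smirnov
normality checks) and correlates between-visit changes with blood-pressure
changes, including the cohort screening rule (MVC within 200–700 N, IPAQ
≤ 10,000 MET-min) and blood-pressure aggregation (mean of readings 2–3).

## Worked example

```python
from musclebold.pipeline import run_synthetic

res = run_synthetic("fast", seed=3, snr=50.0, muscles=("soleus", "gastrocnemius"))
print(res.metrics[["muscle", "maximal_change", "recovery_change", "tau"]].round(3))
```

```
       muscle  maximal_change  recovery_change     tau
       soleus           5.355            2.623  36.425
gastrocnemius           6.164            3.038  36.523
```

The `fast` preset simulates a 40×40-matrix calf phantom (TR 3 s,
TE 21/60 ms, 60 s baseline + 4 × (90 s exercise + 120 s recovery), 300
volumes) with a soleus amplitude of 5.12 % and gastrocnemius 6.04 %
injected, plus Rician noise at SNR 50. The estimates above recover those
amplitudes to within the noise of a single run (the injected soleus truth
implies a recovery change of 2.433 %); on noiseless data the recovery is
exact to fit tolerance. The `examples/` directory has one short script per
capability (simulation, R2\* mapping, ROI metrics, parameter recovery,
visit statistics), and a thin CLI mirrors the stages:

```bash
musclebold simulate --preset fast --seed 1 --out data/
musclebold metrics --preset fast data/ out/
musclebold stats out/metrics.csv statsout/
```

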