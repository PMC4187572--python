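"""Seeded parameter-recovery study at a published group-mean effect size.

Injects a known maximal change, re-estimates it through the whole pipeline
across several noise realisations, and compares the mean estimate with the
injected value. Raw-max peak detection on a noisy series is slightly
positively biased; the bias shrinks with ROI size and peak sharpness.
"""

from musclebold.pipeline import amplitude_recovery_study

AMPLITUDE = 5.12   # soleus 15% MVC control-visit group mean, % of baseline R2*

df = amplitude_recovery_study("soleus", AMPLITUDE, seeds=range(1, 6),
                              preset_name="fast", snr=50.0)
print(df[["seed", "maximal_change", "recovery_change", "tau"]].round(3).to_string(index=False))
print(f"\nmean estimated maximal change: {df['maximal_change'].mean():.3f}"
      f"  (injected {AMPLITUDE})")
print("Each row is an independent Rician-noise realisation at SNR 50 on the")
print("reduced 40x40 preset; scripts/acceptance.py runs 20 seeds per amplitude.")
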