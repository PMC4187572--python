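"""Generate a synthetic dual-echo calf dataset and inspect the signal model.

The phantom contains soleus and medial/lateral gastrocnemius rectangles on a
background compartment; muscles carry an exercise-locked R2* excursion.
"""

import numpy as np

from musclebold import DEFAULT_TRUTH, NoiseSpec, generate_dual_echo, get_preset, sigma_for_snr

preset = get_preset("fast")   # 40x40 matrix, 10 slices, 300 frames at TR=3 s
noise = NoiseSpec("rician", sigma_for_snr(50.0, preset.tissues, preset.acq), seed=1)
series, truth = generate_dual_echo(preset.acq, preset.paradigm, preset.tissues,
                                   DEFAULT_TRUTH, noise)

print("ground truth per tissue:")
print(truth.to_string(index=False))

# a soleus voxel at rest: S(TE) = s0 * exp(-TE * R2*) -> 532.6 / 165.3 (+ noise)
x, y = 15, 27
print(f"\nsoleus voxel ({x},{y}) frame 0: echo1={series.echo1[x, y, 4, 0]:.1f}, "
      f"echo2={series.echo2[x, y, 4, 0]:.1f}")
print(f"noiseless prediction:           echo1={1000*np.exp(-0.021*30):.1f}, "
      f"echo2={1000*np.exp(-0.060*30):.1f}")
print("\nThe dual-echo log-ratio ln(S1/S2)/(TE2-TE1) recovers R2* ~ 30 1/s at rest;")
print("during exercise R2* rises by up to the injected amplitude (% of baseline).")
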