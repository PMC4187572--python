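"""Smooth a dual-echo series and map it to R2*: the oxygenation proxy.

On noiseless data the two-point estimate inverts the generator exactly;
with Rician noise, ROI averaging brings it back within a fraction of 1%.
"""

import numpy as np

from musclebold import (
    DEFAULT_TRUTH,
    NoiseSpec,
    SmoothingKernel,
    generate_dual_echo,
    get_preset,
    r2star_series,
    sigma_for_snr,
    smooth_4d,
)

preset = get_preset("fast")

# noiseless: algebraic identity
series, _ = generate_dual_echo(preset.acq, preset.paradigm, preset.tissues, DEFAULT_TRUTH)
r2s = r2star_series(series)
print(f"noiseless soleus voxel at rest: R2* = {r2s.values[15, 27, 4, 0]:.10f} 1/s (truth 30)")

# noisy + smoothed (3x3x6 mm FWHM, the study kernel)
noise = NoiseSpec("rician", sigma_for_snr(50.0, preset.tissues, preset.acq), seed=2)
series_n, _ = generate_dual_echo(preset.acq, preset.paradigm, preset.tissues,
                                 DEFAULT_TRUTH, noise)
smoothed = smooth_4d(series_n, SmoothingKernel(3.0, 3.0, 6.0))
r2s_n = r2star_series(smoothed)
roi = preset.roi("soleus").voxel_slices(preset.acq)
baseline_mean = r2s_n.values[roi][..., 5:10].mean()
print(f"SNR-50 ROI-mean baseline R2*:   {baseline_mean:.3f} 1/s "
      f"({abs(baseline_mean-30)/30*100:.2f}% from truth)")
print(f"valid voxels: {r2s_n.mask.sum()} / {r2s_n.mask.size}")
print("\nHigher R2* means more deoxyhemoglobin, i.e. lower tissue oxygenation.")
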