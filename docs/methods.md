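# Methods

## Signal model and R2* estimation

Magnitude dual-echo EPI signal is modelled as monoexponential transverse
decay, S(TE, t) = S₀·exp(−TE·R2\*(t)). With two echoes the effective
relaxation rate has the unique closed-form solution
R2\* = ln(S₁/S₂)/(TE₂−TE₁); this two-point log-ratio is the only estimator
consistent with a two-echo monoexponential acquisition, is exact on
noiseless data, and is invariant to any common scaling of both echoes.
The logarithm needs strictly positive inputs: voxels whose signal falls
below ε = 10⁻⁶ × the median signal in **any** frame are masked invalid for
the whole run, so every surviving time course is hole-free. No T2/T2\*
decomposition or field-map correction is attempted; R2\* is used directly
as the (inverse) oxygenation index.

## Timing conventions

Frames are timestamped at acquisition onset, t = i·TR; all paradigm phases
are half-open intervals [start, end) on these onset times. With the default
protocol (TR 3 s; 60 s baseline; four cycles of 90 s exercise + 120 s
recovery) every block boundary falls exactly on a frame boundary: 20
baseline frames, then 30 exercise + 40 recovery frames per cycle. Frames
beyond the paradigm are labelled `post` and ignored. Slice timing within a
TR is ignored.

## ROI analysis chain

ROIs are axis-aligned rectangles replicated over the middle six of ten
slices (0-based slices 2–7, the only symmetric choice): medial
gastrocnemius 32×6, lateral 16×6, soleus 25×6 voxels per slice at the full
80×80 matrix, with medial+lateral adjacent so their union forms the 48×6
combined gastrocnemius ROI. The chain is:

1. per-frame mean R2\* over the ROI's valid voxels;
2. baseline B₀ = mean over frames whose onset lies in [15 s, 30 s) —
   frames 5–9 at TR 3 s (the endpoint convention is a config constant);
3. percent change p(t) = (R2\* − B₀)/B₀ × 100, using the single run
   baseline for all cycles;
4. cycle average: elementwise mean of p(t) over the final three of four
   cycles, aligned at cycle start; the first cycle is discarded to avoid
   carry-over effects.

The combined-ROI mean equals the voxel-count-weighted (32:16) mean of the
sub-muscle means by construction; this is regression-tested.

## Recovery fit and metrics

The recovery-phase frames of the cycle average (t re-zeroed at the
exercise→recovery boundary) are fitted by nonlinear least squares with
y(t) = plateau + (peak − plateau)·e^(−t/τ). Initialisation is
deterministic: peak₀ = first recovery frame, plateau₀ = mean of the final
15 s, τ₀ = 30 s; τ is bounded to (0.1, 600] s. A flat segment is flagged
degenerate (amplitude 0, τ undefined) and a τ landing within 1 % of a bound
marks the fit unconverged; flags propagate into the metrics table rather
than being silently replaced.

Maximal change is the maximum of the cycle-averaged series. The trough is
the fitted model value at the end of the 120 s recovery window (fitting
precedes extraction; a raw-minimum variant is available via
`trough="raw"`). Recovery change = maximal change − trough, reported both
in percent-of-baseline units (default) and divided by the peak
(`recovery_change_normalized`). Both are reported because group tables in
this literature are ambiguous about whether "normalised by peak amplitude"
means the divided form; the magnitudes printed alongside peaks are usually
consistent with the *unnormalised* difference, so that is the default.
Signed values are preserved (a trough above baseline gives a small or
negative recovery change).

## Synthetic data generator

The generator emulates a calf cross-section: rectangular soleus and
medial/lateral gastrocnemius compartments (R2\* 30 s⁻¹, S₀ 1000) on a
background (R2\* 25 s⁻¹, S₀ 500; values are fixed arbitrary constants with
a 2:1 S₀ contrast). Muscle rectangles extend one to three voxels beyond
their ROIs and span all slices, mirroring conservative ROI placement inside
a muscle boundary, so spatial smoothing does not mix background signal into
ROI means. Each muscle carries an injected percent-change profile:

- baseline: 0;
- exercise: linear ramp to the peak amplitude A at the exercise→recovery
  boundary. The true on-exercise shape is not identifiable from published
  figures; a ramp is the simplest shape with an unambiguous peak, and the
  profile function is pluggable;
- recovery: (A − D) + D·e^(−t_rec/τ), where D is the amount recovered
  within the window as τ→0.

Cycle 1 ramps from 0; every later cycle ramps from the previous recovery's
end value, which makes cycles 2–4 exactly periodic — so the final-three-
cycle average equals the steady-state cycle and the noiseless pipeline
returns A exactly (the package's primary oracle, tested to ≤0.1 %
relative).

Defaults: amplitudes 5.12 % (soleus) and 6.04 % (gastrocnemius sub-ROIs) —
the control-visit 15 % MVC group means — with D = A/2 and τ = 40 s. τ is
not published; 40 s places the time constant comfortably inside the 120 s
fitted window while leaving a visible plateau deficit. Noise is Rician,
√((S+n₁)² + n₂²) with iid Gaussian n₁, n₂ of standard deviation σ; the SNR
parameter is defined on the baseline echo-1 muscle signal
(σ = S₀·e^(−TE₁·R2\*)/SNR, so SNR 50 → σ ≈ 10.65). For σ ≪ S the Rician
mean exceeds S by ≈ σ²/2S; at SNR ≥ 50 this bias is below fit tolerance
for the headline metrics (it also largely cancels in the baseline
normalisation). Generation is bit-reproducible per seed, and NIfTI output
is float64 without scaling so files round-trip exactly.

Two presets exist: `study` (80×80 matrix, 2.5 mm in-plane) and `fast`
(40×40, 5 mm in-plane) with all rectangles scaled by half in-plane for
quick simulation studies. The generator does **not** model motion, EPI
distortion, vessels/adipose inclusions, blood-flow/volume compartments or
any mechanistic BOLD biophysics — passing tests demonstrate correctness of
the analysis chain under the stated signal model, not robustness to those
real-data effects. Motion correction is out of scope; inputs are assumed
motion-free or pre-corrected.

## Preprocessing

Spatial Gaussian smoothing with per-axis FWHM 3×3×6 mm (σ = FWHM/(2√(2 ln 2))
voxels), applied to the raw echo images before the log-ratio (the only
order consistent with a downstream per-voxel Bloch-equation computation),
one 3D volume at a time (σ = 0 on the time axis), with reflective
boundaries to preserve kernel mass. Smoothing of near-uniform ROI interiors
leaves ROI means essentially unchanged (<5 % effect on metrics at default
geometry, regression-tested).

## Statistics

Screening: eligible iff 200 N ≤ MVC ≤ 700 N (boundaries inclusive — values
"outside the range" are excluded, so endpoints are inside) and IPAQ ≤
10,000 MET-min. Blood pressure: mean of the second and third of three
readings. Normality uses the classical one-sample Kolmogorov–Smirnov test
against a normal with the sample's mean/SD, mirroring common statistical-
package output; since estimating parameters makes classical KS
conservative, a Lilliefors-corrected variant is available. Paired t tests
are classical (df = n−1); the one-way repeated-measures ANOVA is computed
via statsmodels' AnovaRM and unit-tested against a hand sum-of-squares
decomposition, with F = t² verified for the two-visit case. Pearson
correlations report two-tailed p via t = r√(n−2)/√(1−r²). Between-visit
correlation analysis pairs subjects present at both visits (complete-case,
n reported per cell; cells with <3 pairs are skipped) over a grid of
workload × muscle × metric × visit-pair × BP component. No multiple-testing
correction is applied (α = 0.05 per test, as is conventional in this
literature); outputs state this.

## Problem sizes and determinism

Simulation studies in the test and acceptance suites use the `fast` preset
(40×40×10×300 voxels per echo), 20 seeds per condition, at SNR 50 — about
one second per run. Statistical calibration uses 10,000 null replicates at
n = 9. All randomness flows through explicitly seeded NumPy generators.

## Known limitations

- **Peak-detection bias.** Maximal change is the raw maximum of the noisy
  cycle-averaged series, so it inherits the positive bias of a maximum
  statistic: E[max(curve + noise)] > max(curve), largest when the peak is
  flat relative to the per-frame noise. At SNR 50 on the `fast` preset the
  across-seed mean overestimates small amplitudes by ≈0.2 pp (soleus
  2.55 % injection) and large/sharper ones by ≲0.15 pp; the bias shrinks
  with ROI size (gastrocnemius ≈0.06 pp) and vanishes without noise. A
  fit-based peak would be nearly unbiased but is not the conventional
  definition of this metric.
- Two-echo estimation cannot separate T2 from T2′ contributions; R2\* is
  reported as-is.
- ROI geometry is static across frames and visits; no registration, vessel
  exclusion (beyond the validity mask) or interactive drawing.
- The exercise-phase profile shape in the generator is an assumption
  (linear ramp); only the peak and recovery segments are anchored to the
  analysis contract.
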