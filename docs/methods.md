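# Methods

## The model

`hpmrf` simulates metabolite-specific imaging of hyperpolarized
[1-¹³C]pyruvate and its conversion to [1-¹³C]lactate with a one-way
two-pool Bloch-McConnell system. Writing the transverse magnetization of
each pool as a complex number m = Mx + iMy and the longitudinal component as
z, the free evolution between RF pulses is

    dm_P/dt = (−1/T2P − kPL − 2πi f_P) m_P
    dm_L/dt = kPL m_P + (−1/T2L − 2πi f_L) m_L
    dz_P/dt = (−1/T1P − kPL) z_P + u(t)
    dz_L/dt = kPL z_P − z_L/T1L

where kPL (s⁻¹) is the apparent pyruvate→lactate conversion rate, f_X is
each pool's precession frequency (chemical shift + bulk B0 error +
per-isochromat off-resonance), and u(t) is the bolus input rate. Exchange
acts on all three components of each pool, so transverse coherences carry
exchanged magnetization — this matters for balanced SSFP, whose signal is
built from refocused coherences. Longitudinal relaxation drives z toward
zero, not toward thermal equilibrium: hyperpolarized magnetization is
non-renewable.

Because both 2×2 subsystems are lower triangular with constant coefficients
between events, the propagator over any interval is an elementwise
closed-form matrix exponential, and the bolus (inhomogeneous) term has an
exact integral for a piecewise-constant rate. The whole engine is therefore
exact per interval and fully vectorized over parameter batches and
isochromats; there is no ODE solver tolerance anywhere. The propagator is
verified in the test suite against `scipy.linalg.expm` on the full 6×6
generator and against a fine-step forward-Euler integration including the
bolus.

### Bolus input

u(t) is a gamma-variate: u(t) ∝ (t − t_arr)^(α−1) · exp(−(t − t_arr)/β),
with shape α = 2 and the scale β set so that 99% of the input falls within
the bolus duration. Defaults: arrival −4 s (the bolus begins 4 s before
imaging, reflecting the calibration delay after bolus detection), duration
12 s, total input 1. All signals are expressed in units of this
relaxation-free total bolus signal, so a Monte Carlo noise SD σ is directly
a fraction of the total bolus magnetization. While the bolus is active the
inhomogeneous term is integrated with 10 ms sub-steps (piecewise-constant
rate at the sub-step midpoint); the residual discretization error is below
10⁻⁶ of the signal scale.

### Intravoxel off-resonance (linewidth)

B0 inhomogeneity within a voxel is modeled as a Lorentzian distribution of
off-resonance frequencies with configurable FWHM (default 5 Hz), truncated
at ±3 FWHM and sampled at 101 equal-probability-mass quantiles (isochromats);
the odd count guarantees an on-resonance isochromat, and the voxel signal is
the isochromat mean. A Gaussian alternative is config-selectable; the
distribution family is a modeling choice, not a measured property.

### RF and spectral selectivity

RF pulses are instantaneous rotations applied to the target metabolite only
(ideal spectral selectivity; the multiband pulse profiles of the real
sequences are not modeled). The rotation axis phase is ramped at the target
pool's nominal frequency (the pulse is resonant with that pool) and the
recorded signal is demodulated at the same frequency, so each metabolite is
effectively observed in its own rotating frame while exchange between the
two frames stays exact. A B1 calibration error scales every flip angle; a
bulk B0 error shifts both pools' precession but not the transmit/receive
frequencies.

## Experiment designs

Three interleaved pyruvate/lactate designs are built by
`sequences.build_schedule`:

| design | pyruvate | lactate | temporal res |
|---|---|---|---|
| `mrf_sigmoid` | 3D bSSFP, sigmoid flip 5°→80° (midpoint 20 s), TR 15.6 ms | 3D bSSFP 60°, TR 15.3 ms | 4.1 s |
| `mrf_constant` | 3D bSSFP, constant 30°, TR 15.6 ms | same | 4.1 s |
| `hybridgre` | 2D multi-slice spoiled GRE 10°, TR 1 s, 22 ms readout | same | 4.6 s |

The sigmoid flip angle α(t) = α_min + (α_max − α_min)/(1 + e^(20 − t)) is
evaluated per excitation at absolute time since acquisition start. Each
bSSFP block contains 128 total excitations: a 10-pulse sin² catalyzation
ramp scaled to the first imaging tip, 107 imaging excitations with exact
0°/180° phase alternation, a mirrored 10-pulse de-catalyzation ramp scaled
to the last imaging tip, and a final half-angle tip-back that returns the
magnetization to the longitudinal axis between blocks. (128 *imaging*
excitations plus ramps would not fit inside the 2.05 s half-period of the
4.1 s temporal resolution; counting preparation pulses in the block total is
the only reading consistent with non-overlapping blocks.) Pyruvate blocks
start each interleave period and lactate blocks sit at the half-period
offset; a 60 s window gives 15 samples per metabolite for the MRF designs
and 13 for the hybrid design (periods = round(duration / resolution)).

### What one fingerprint sample is

Each acquisition block contributes one complex sample: the total (k-space
center) signal of that block's acquisition, i.e. the sum over all imaging
excitations of the echo at TE = TR/2 demodulated by the excitation's RF
phase. For the 2D multi-slice GRE block — one excitation per 21 mm slice
sub-volume, 16 slices covering the same 33.6 cm slab as the 3D
acquisitions — the single echo is weighted by the 16 slices. This
"volume-DC" convention makes the per-sample amplitude proportional to the
total signal the sequence collects per time point, which is what a fixed
per-sample noise σ must be compared against; it reproduces the published
Monte Carlo precision of all three designs, including the bSSFP designs'
SNR-efficiency advantage over the hybrid. Sampling the single
center-of-k-space echo instead (`sample_mode="center_echo"`) is available
but under-weights the echo train by two orders of magnitude and is not used
by the analyses.

## Dictionary and estimators

A dictionary holds one fingerprint per kPL value on the grid 0–0.1 s⁻¹ in
steps of 10⁻⁴ (1001 entries), all other parameters fixed at the nominal
values (T1 = 30/25 s, T2 = 0.5/1 s for pyruvate/lactate, shifts 0/392 Hz,
bolus −4 s/12 s, LW 5 Hz). Entries are unit-L2-normalized over the full
concatenated complex vector; raw norms are retained so amplitude-true
signals can be reconstructed. Generation is deterministic, and dictionaries
cache to HDF5 keyed by a content hash of their spec.

Template matching maximizes |⟨signal, entry⟩| over entries (conjugate-linear
inner product), which is invariant to any nonzero complex scaling of the
signal; ties break toward lower kPL. Noise-free, the estimation error is
bounded by the grid step.

`direct_fit` is the conventional comparator: bounded nonlinear least squares
over kPL alone, fitting |signal| to |model(kPL)|, multi-started from
{0.005, 0.02, 0.06} s⁻¹. To keep a fit to ~microseconds the magnitude model
is pre-tabulated on the dense dictionary grid and evaluated through a cubic
spline; the fingerprint is smooth in kPL (adjacent grid entries differ by
≪1% in norm), so the surrogate's interpolation error is far below the fit's
statistical error. The magnitude residual is the source of this estimator's
low-kPL bias: the expected magnitude of a noisy complex sample exceeds the
clean magnitude (noise floor), pushing fitted kPL upward where lactate is
small.

## Monte Carlo evaluation

For each (kPL, σ) cell, i.i.d. Gaussian noise of SD σ per real/imaginary
channel (total-bolus units) is added to the raw fingerprint and each
replicate is re-matched against the full dictionary. Noise streams are
counter-based — every (entry, σ) pair spawns an independent generator from
the master seed — so results are reproducible and independent of execution
order or subsetting. Summaries report mean, SD, percent bias and
CV = 100·SD/mean relative to the true kPL.

The pooled accuracy fractions ("runs with bias < 1%", "grid points with
mean bias < 0.1%") use thresholds expressed as percentages of the
dictionary's kPL span (i.e. absolute errors of 10⁻³ and 10⁻⁴ s⁻¹). A
truth-relative 1% band would be narrower than one grid step over most of
the low-kPL grid and is not consistent with the per-point CVs these same
runs produce; the span-relative reading is.

## Sensitivity analysis

Noise-free fingerprints at kPL = 0.02 s⁻¹ are simulated with one nuisance
parameter swept over 21 equally spaced values and matched against the
nominal dictionary; the signed error (fitted − true) is reported. Sweep
ranges: T1 pyruvate 20–40 s, T1 lactate 15–30 s, T2 pyruvate 0.3–0.7 s, T2
lactate 0.6–1.4 s, B1 scale 0.8–1.2, B0 ±15 Hz, linewidth 0.2–9.8 Hz. Where
a stated step size disagrees with the 21-value test-set size, the endpoints
are honored and 21 values used. The bolus sweep ranges are not constrained
by any published value; this package uses arrival −8–0 s and duration
6–18 s (both symmetric about the nominal, spans comparable to the
relaxation-time sweeps), fixed once as part of the study conditions.

## Synthetic dynamic images

The digital phantom emulates interleaved dynamic metabolite volumes of a
small-animal kidney experiment: ellipsoid "kidney" ROIs with elevated kPL
(defaults 0.02 and 0.05 s⁻¹) on a zero-conversion background, every voxel
following the forward model at its local kPL with shared bolus/field
parameters, plus independent complex Gaussian noise per voxel, channel and
frame. It does not emulate perfusion or flow, partial-volume effects,
spatially varying B0/B1 fields, coil sensitivity, or reconstruction
artifacts — so phantom-based tests demonstrate estimator correctness under
the model's own assumptions, not robustness to every property of real data.

The voxel-wise chain mirrors the in vivo processing: SNR masks from peak
pyruvate magnitude over noise SD (threshold 5 by default; the threshold is
a config choice), template matching per masked voxel, AUC images (magnitude
sum over time) and lactate/pyruvate AUC ratios, dynamic AUC SNR
(|cumulative complex sum| / real-channel noise SD) with series aligned by
whole-frame shifts matching mean lactate time-to-peak, TTP as
argmax-of-magnitude, and Pearson + Bland-Altman (mean difference ±1.96 SD)
map comparisons.

## Numerical choices and degenerate inputs

- Propagator denominators (rate differences) below 10⁻¹² switch to their
  analytic limits; T1 = T2 = ∞ is valid input (rates become zero).
- Matching rejects all-zero signals; AUC ratios and TTP mark zero-signal
  voxels as no-data rather than dividing by zero.
- Zero linewidth or a single isochromat collapses the off-resonance
  distribution to a delta at zero, and equals the many-isochromat limit as
  LW → 0.
- `direct_fit` flags (rather than raises on) non-convergence of all starts.

## Problem sizes used by the shipped analyses

The acceptance script runs the published-point Monte Carlo at the full
n = 10 000 replication; the pooled grid fractions and the SD-reduction
comparison run on a 101-point (respectively 71-point) grid subsample at
n = 1000 per cell, and the direct-fit comparison uses 21 grid points at
n = 100 — sizes chosen so the whole recomputation finishes in a few minutes
on one CPU while keeping each statistic's sampling error well inside its
comparison band (the one exception, the max-of-noisy-means direct-fit
statistic, is noisy at any feasible n because the reference evaluation used
n = 100 itself).

## Known limitations

- Encode ordering, per-excitation k-space weighting and reconstruction are
  abstracted into the volume-DC sample; design comparisons that hinge on
  intra-block signal history (e.g. which design is most sensitive to bolus
  timing) are sensitive to this abstraction.
- The gamma bolus shape (α = 2) and the acquisition window (60 s) are
  config-exposed defaults, not measured values.
- Nuisance parameters (relaxation times, bolus timing, field terms) are
  fixed during estimation; only kPL is fitted. Mismatch biases are
  quantified by the sensitivity module rather than estimated away.
- No alanine/bicarbonate/pyruvate-hydrate pools and no perfusion
  compartment.
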