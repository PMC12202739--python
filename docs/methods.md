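# Methods

## The sequence and its signal model

`qrfthermo` models a continuous balanced steady-state-free-precession
acquisition with a constant low flip angle α (default 10°) and an RF
excitation phase that grows quadratically with the TR index,
φ[n] = c·n² degrees (default c = 4.2 deg/TR², TR = 10 ms, TE = 1.8 ms).
Sampling a quadratic phase at the TR period is equivalent to a linear
frequency modulation: the sequence's effective resonance frequency is the
centered finite difference of φ[n],

    f[n] = c·n / (180·TR)  Hz,

wrapped into the unaliased band [−1/(2TR), +1/(2TR)) — ±50 Hz at the
default TR — with period N = 180/c ≈ 42.9 TRs.  Each time the sweep passes
an isochromat's off-resonance frequency, that isochromat emits a signal
peak, so the timing of peaks over a window of a few seconds encodes the
voxel's frequency.  The low flip angle deliberately desensitizes the
timecourse to T1 and T2 so that frequency (and hence temperature) is the
dominant contrast.

Temperature couples to frequency through the proton-resonance-frequency
shift, Δf = γ̄·α_PRF·ΔT·B0 with γ̄ = 42.577 MHz/T and α_PRF = −0.01 ppm/°C
(−1.277 Hz/°C at 3 T; a 25 °C hot spot shifts by −32 Hz).  The unaliased
frequency band maps to a temperature ambiguity period of
(1/TR)/(γ̄|α_PRF|B0) ≈ 78.3 °C.

## Bloch simulation and the dictionary

Atoms are simulated by per-TR propagation of the magnetization 3-vector:
instantaneous rotation by α about a transverse axis at angle φ[n]
(relaxation during RF neglected), then free precession at 2π·f0 with
exponential T1/T2 relaxation split into a TE segment (the complex
transverse magnetization is sampled there) and a TR−TE segment.  Balanced
gradients are idealized (zero net moment per TR); magnetization starts at
thermal equilibrium, and analyses discard the first 220-TR window to
remove the transient approach to the pseudo steady state.

Two conventions worth stating:

- **Receiver phase.** The excitation phase φ[n] is retained in the
  received signal (no per-TR demodulation).  Data simulation and the
  dictionary share the convention, so matching — which uses inner-product
  magnitudes — is invariant to it.
- **Frequency aliasing.** Atoms at f0 and f0 + 1/TR are identical up to a
  fixed phase factor exp(i2π·TE/TR) contributed by the TE precession
  segment; all magnitude and matching quantities are exactly 1/TR-periodic.

Intravoxel frequency dispersion ("linewidth") is modeled as a Gaussian
frequency distribution, realized as a circular convolution along the dense
dictionary frequency axis (exact, because atoms are periodic in f0).  The
linewidth parameter is interpreted as the Gaussian FWHM by default; a
`fwhm=False` switch treats it as the standard deviation instead, since
either reading of "Gaussian linewidth" is defensible.  The default grid
holds 4096 frequencies over [−50, +50) Hz, 17 linewidths from 1 to 49 Hz
and two T1/T2 pairs (250/10 ms, 1250/50 ms); precision studies use a fine
8192-point frequency axis (temperature step ≈ 0.0095 °C at 3 T) with a
single 1 Hz linewidth and the phantom's own T1/T2, the configuration a
uniform phantom calls for.

A known behavior: an atom's signal peak lags the sweep crossing of its
frequency by roughly the T2 memory of the sequence (~3 TRs at T2 = 70 ms,
≤2 TRs at T2 = 10 ms).  This lag is common to data and dictionary and
cancels in matching.

## Acquisition model

Spatial encoding uses an Archimedean spiral with constant radial velocity
(radially uniform sampling), 6 ms readout at 2 µs dwell (3000 samples),
twelve interleaves rotated by 2π/12 and played in linear order
(TR n → interleaf n mod 12), reaching the grid Nyquist radius; twelve
consecutive TRs cover k-space once.  No gradient-hardware (slew/amplitude)
constraints are modeled.  Density compensation weights are analytic
annulus areas with each interleaf treated as standalone coverage — the
per-TR sliding-window convention, under which a single-interleaf gridding
frame is object-scale and the 12-frame average approximates the
band-limited object.

The NUFFT is Kaiser–Bessel gridding: 2× oversampled FFT, width-8
interpolation kernel with the Beatty β, analytic deapodization, and a
precomputed sparse interpolation matrix per interleaf.  The adjoint is the
exact conjugate transpose of the forward operator (sparse transpose +
inverse FFT), so adjoint identities hold to machine precision while the
forward approximates the exact non-uniform DFT to ~1e-7.  All transforms
are unitarily normalized so noise propagates with unit gain between
k-space and image domains.

**Noise calibration.**  The target SNR (default 112) is defined in the
2DFT comparator image as mean in-mask magnitude divided by the *complex*
noise standard deviation (each real component receives σ/√2).  This
convention is fixed by a closed-form argument: the phase-difference
temperature std of the comparator is √2·(σ/√2)/A / (2π·γ̄|α_PRF|·TE·B0) =
0.0927 °C at SNR 112, TE 12 ms and 3 T, matching the reference value the
comparator is supposed to produce, whereas the per-component convention
gives 0.131 °C.  Spiral per-sample noise is the same σ scaled by
√(dwell_2DFT/dwell_qRF) = √12.5 to account for the bandwidth difference;
2DFT noise is added in the image domain (equivalent to k-space under the
unitary FFT).

## Reconstruction

Data are partitioned into windows (default 220 TRs = 2.2 s,
nonoverlapping; 110/330-TR and overlapping windows supported).  Per
window:

- **Gridding**: density-compensated adjoint NUFFT per TR, coil-combined
  with conjugate sensitivities.
- **Subspace CG**: the window's unit-norm dictionary atoms are SVD-
  compressed to k = 15 temporal basis vectors; CGLS (conjugate gradients
  on the normal equations, zero-initialized, no regularization or
  preconditioning) solves for the coefficient maps of the linear model
  coefficients → basis expansion → coil weighting → NUFFT.  A fixed 10
  iterations is used; the residual is monotone but full convergence is
  slow because the center-dense spiral makes the normal equations
  ill-conditioned (relative residual ~1e-3 after 400 iterations even on
  exactly subspace-consistent data).  Reconstruction quality at 10
  iterations is what matters and is validated directly.  The operator is
  applied in the basis domain (FFTs act on the k coefficient maps, not the
  220 per-TR images), which is algebraically identical and ~20× faster.

Matching is exhaustive: each voxel timecourse is assigned the dictionary
entry maximizing |⟨atom, signal⟩|/‖signal‖ over unit-norm window atoms
(ties → lowest grid index; zero-signal voxels are masked out with inner
product 0).  The large-dictionary matmul runs in complex64; inner-product
gaps between adjacent atoms are ~1e-3, far above float32 resolution, so
the argmax is unaffected.

## Temperature maps

A window's matched frequency map Δf(x) and mean image combine into a
synthesized GRE image |I_mean(x)|·exp(i·2π·TR·Δf(x)); the sequence TR (not
TE) sets the phase scale because it determines where frequency aliasing
occurs.  Temperature change is the phase difference against a baseline,
ΔT = Δθ/(2π·γ̄·α_PRF·T·B0) with T = TR (qRF-MRF) or TE (2DFT).  Taken
literally with Δθ = dynamic−baseline and α_PRF < 0 this yields
heating-negative values; the `sign_convention` flag (default
`heating_positive`, equivalent to a conjugate receiver demodulation) is
applied identically to both paths so comparisons are convention-free.

The multibaseline + referenceless estimator combines a nonnegatively
weighted baseline library, a low-order polynomial background phase
(2D monomials fitted over currently-cold voxels, magnitude-weighted) and a
sparse heat phase (soft-threshold support detection, unshrunk values on
the support), alternated to a fixed tolerance.  The full published
algorithm this emulates has additional internals that are not reproduced
here; this simplified scheme is a documented stand-in, validated on
constructed ground truth (background polynomial + hot spot), and the
Monte-Carlo precision numbers use plain single-baseline subtraction and do
not depend on it.  As with any referenceless estimator, a spatially
uniform temperature change is absorbed into the background term — the
heat-phase map is identifiable only for localized (sparse) heating.

## Monte-Carlo precision studies

The precision harness follows a fixed recipe: a uniform disc phantom
(64-voxel diameter on a 128×128 grid; T1 = 825 ms, T2 = 70 ms,
T2* = 46 ms, 0 Hz frequency), a 660-TR acquisition whose first 220 TRs are
discarded and whose second and third 220-TR windows serve as baseline and
"heated" windows — both at 0 Hz, deliberately: precision is a pure noise
property and no hot spot belongs in this study.  The signal is the 0 Hz
entry of the matching dictionary replicated across the disc; noisy spiral
k-space is drawn per realization; each window is reconstructed, matched
against the fine dictionary, and single-baseline-subtracted.  The
per-voxel std across realizations is pooled as √(mean per-voxel variance)
over the mask (the per-voxel map and the mean-of-std scalar are also
reported).  The 2DFT comparator scales the disc by the spoiled-GRE
steady-state amplitude at the Ernst angle (11.6° for T1 = 825 ms,
TR = 17 ms) and adds image-domain noise at the target SNR.

Replicate counts used by the acceptance script — 25 realizations for the
gridding cells, 50 for the 2DFT comparator, 15 for the subspace-CG cell —
keep the Monte-Carlo error of a pooled std a few percent (the pool
averages thousands of voxels per realization) while the CG cell, whose
reconstruction dominates compute, runs at the smallest count.

## What the synthetic data does and does not emulate

The generator reproduces the simulation conditions of the study the
package models: uniform or Gaussian-hot-spot phantoms, ideal coils
(uniform single coil by default; smooth synthetic multi-coil maps
available), exact trajectories, and white complex Gaussian noise.  It does
not emulate k-space trajectory errors, B0 drift or eddy currents,
respiration or motion, fat signal, or coupling of T1/T2 to temperature —
the error sources that dominate real scans.  Passing precision tests
therefore demonstrates the noise-limited behavior of the method, not its
robustness to those confounds.

## Numerical choices and known limitations

- Noiseless end-to-end recovery is exact (within one dictionary grid step
  everywhere) for frequency-homogeneous objects on fully sampled data.
  With 12× per-TR undersampling, deterministic aliasing modulates voxel
  timecourses (a 12-TR-periodic factor) and PSF side-lobe mixing biases
  voxels on steep frequency gradients by a few fine-grid steps (~1–4% of a
  25 °C hot-spot shift near its flanks; the peak voxel itself is accurate
  to <1%).  These biases are identical across noise realizations and
  cancel in through-time standard deviations.
- The within-window ramp study: a linear temperature rise across a window
  produces an inner-product spectrum with a near-flat top centered on the
  window-mean temperature.  The half-max interval center is the stable
  peak statistic; the raw argmax wanders ~±1.5 °C along the plateau.
- Dynamic-heating (FUS-style) scenarios Bloch-simulate each voxel with its
  time-varying PRF frequency; Gaussian linewidth broadening is not applied
  on this path (a stationary-frequency construct), which against the 1 Hz
  dictionary linewidth is a negligible, symmetric mismatch.
- The hot-spot FWHM (default 16 voxels) and the FUS focus geometry
  (anisotropic Gaussian, 8×24-voxel FWHM) are package choices — plausible
  for a focused-ultrasound focus at 2 mm resolution — as no reference
  values exist for them.
- Heating leaves T1/T2 unchanged by default (the precision studies assume
  this); `make_fus_scenario` operates on frequency only.
- CGLS divergence (residual growth over three consecutive iterations)
  triggers a warning and returns the best iterate; in practice the
  residual is monotone.
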