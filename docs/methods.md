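# Methods

This note documents the models implemented in `twodes`, the synthetic-data
generator that exercises them, the numerical choices, and the limits of what
the recovery tests demonstrate.

## Data model

A 2DES measurement enters the pipeline as a real 3D array over
(excitation ω₁, emission ω₃, population time t₂) — the purely absorptive
representation.  Both frequency axes are uniform wavenumber grids (cm⁻¹);
t₂ is a uniform femtosecond grid.  Complex rephasing/non-rephasing signals,
phasing, and t₁/t₃ interferogram processing are upstream of this package and
out of scope.  The speed of light is fixed once as c = 2.99792458×10⁻⁵ cm/fs;
the transform-limited Gaussian time–bandwidth product is K = 2 ln2/π
(intensity FWHM convention), which maps a 10 fs pulse to a 1472 cm⁻¹
spectral FWHM.

## Global kinetic fitting (2D-DAS)

The population kinetics are modeled as shared exponentials with per-pixel
amplitudes.  Fitting uses **variable projection**: for any trial decay
constants the amplitude maps are the exact linear least-squares solution, so
the nonlinear search runs only over the τₖ.  Implementation details:

* τ is parameterized as log₁₀τ with bounds 20 fs – 50 ps (positivity and
  conditioning); the projected sum of squared residuals is evaluated through
  the normal equations with a QR fallback near degeneracy.
* Multistart: `n_starts` (default 8) log-spaced τ tuples spanning the
  bounds, each refined by Nelder–Mead (xatol 10⁻⁵ in log₁₀τ ≈ 0.002 % in τ).
  The reported minimum is chosen by lowest SSR with ties broken toward the
  smaller fast constant, so the result does not depend on start order.
* The fit window excludes t₂ < 10 fs by default (pulse-overlap artifacts).
* DAS are reported with τ ascending; fitted constants ≥ 1000 fs are labeled
  “>1 ps” (a 1 ps window does not constrain them further), with the numeric
  value retained in machine-readable output.

**Offset column.**  A free per-pixel constant is supported but disabled by
default.  Over a 1 ps window, a constant is nearly collinear with a >1 ps
exponential (sampled correlation ≈ 0.97): including both inflates the
amplitude-map variance about fourfold at 1 % noise and destabilizes the slow
constant, while the slowest exponential already captures any quasi-static
background.  Enable `include_offset` only when the model contains no slow
component of its own.

**Unweighted least squares** is used throughout; no pixel weighting scheme
is imposed on the data.

## Center line slope

The CLS window defaults to the t₂ = 0 peak center ± 1.2 × FWHM per axis
(FWHM measured on the axis cuts through the peak).  Within the window, each
excitation column whose maximum exceeds 20 % of the windowed slice maximum
contributes its emission-axis maximum, refined by a 3-point parabola (an
intensity-centroid option exists for flat-topped or noisy peaks).  The CLS
is the weighted (by column maximum) least-squares slope of those centers
versus ω₁; for a bivariate Gaussian this equals ρ·σ₃/σ₁ exactly, which the
test suite verifies over a (ρ, σ-ratio) grid to 0.01.  CLS is computed along
excitation columns (emission center vs excitation) — the common convention.
The CLS(t₂) trace is fitted with a·exp(−t₂/τ) + b by multistart nonlinear
least squares; traces whose decay amplitude is indistinguishable from the
scatter (|a| ≤ max(0.02, 3·rmse)) are flagged `tau_identifiable = False`,
with b carrying the level — the signature of frozen spectral diffusion in a
low-temperature glass.

## Fourier spectra of coherences

Residues (data minus fitted kinetics, on the fit window) are normalized on
the raw dataset maximum, Hann-windowed along t₂, zero-padded fourfold
(≈ 8.3 cm⁻¹ bins for a 1 ps window at 7.5 fs steps) and Fourier transformed
per pixel.  The aggregation over pixels is the **root mean square** of the
magnitude spectra.  Rationale: aggregation must act per pixel (anti-phased
beats would cancel in the mean trace), and RMS aggregates beat *power*
(Parseval-consistent).  Under a plain mean of magnitudes, the incoherent
noise floor adds quasi-linearly to every bin and fills the valleys between
neighbouring modes, masking weak beating components; in quadrature the floor
is flat and genuine beat power stands out.  Peak picking selects local
maxima with prominence ≥ 10 % of the spectrum maximum above 100 cm⁻¹,
refined by 3-point parabolas.  **Beating intensities should be compared via
peak prominence** (amplitude above the incoherent background), not raw bin
amplitude, which contains the noise floor; this is how the temperature
quenching of low-frequency modes is quantified in the tests.

## Synthetic data generator

The generator emulates the structure of measured chlorophyll-b Q-band 2DES
stacks on the default grid ω ∈ [13 800, 17 600] cm⁻¹ (96 points) and t₂ from
0 to 1000 fs in 7.5 fs steps, with four presets:

* `rt_kinetic` — bi-exponential kinetics, τ = 150 fs and 3 ps (standing for
  “>1 ps”): a fast DAS with decay on the diagonal Q_y(0,0) peak
  (15 390 cm⁻¹) and rise on flanking off-diagonal lobes (peak rounding by
  spectral diffusion); a slow DAS with the diagonal peak, a vibronic cross
  peak at (16 000, 15 250) cm⁻¹ and a negative excited-state absorption at
  (15 410, 14 350) cm⁻¹; nine damped beat modes at 200, 296, 380, 450, 530,
  770, 926, 1120, 1260 cm⁻¹ (amplitude 3 % of the signal maximum, 600 fs
  damping) localized on the diagonal band; 1 % i.i.d. Gaussian noise.
* `k77_kinetic` — the 77 K analogue: τ = 60 fs and 3 ps; the fast DAS decays
  on the (narrower, more elongated) diagonal peak at 15 580 cm⁻¹ and rises
  at emission ≈ 15 000 cm⁻¹ with excitation maxima near 16 000 and
  17 000 cm⁻¹ (vibrational energy redistribution); beat modes below
  700 cm⁻¹ quenched to one fifth of their RT amplitude.
* `rt_lineshape` / `k77_lineshape` — a single bivariate-Gaussian peak whose
  excitation–emission correlation follows
  ρ(t₂) = ρ∞ + (ρ₀ − ρ∞)·exp(−t₂/τ_sd) with ρ₀ = 0.85 and, at RT,
  ρ∞ = 0.05, τ_sd = 150 fs; at 77 K the correlation is frozen (ρ₀ = ρ∞),
  reproducing the absence of spectral diffusion in a glass.

Feature widths, lobe amplitudes, beat amplitudes/damping and the noise level
are not measured quantities; they were chosen once to mimic the qualitative
morphology and signal-to-noise of such measurements, with two constraints
found necessary for the generator to fulfil its role as a recovery target:

* **Beat phases are pairwise decorrelated** (a deterministic golden-ratio
  sequence).  Distinct vibrational coherences carry unrelated phases; had
  all nine modes been launched in phase, they would synthesize a coherent
  packet near t₂ = 0 whose slowly decaying envelope mimics an extra kinetic
  component and corrupts the bi-exponential fit (the slow constant collapses
  to ≈ 0.8 ps).
* **The slow-DAS diagonal width is 240 cm⁻¹**: with a broader diagonal
  (σ = 300 cm⁻¹ at ρ = 0.5) the below-diagonal cross peak would sit entirely
  on the diagonal feature's flank and cease to exist as a local maximum,
  contrary to the distinct cross peak the preset is meant to show.  The
  coherence beat profile keeps the broader σ = 300 cm⁻¹ band.

What the recovery tests do **not** show: the generator uses Gaussian
features and i.i.d. Gaussian noise, so passing tests demonstrate correctness
of the algorithms under the stated statistical model, not robustness to
correlated (1/f, scatter) noise, non-Gaussian lineshapes, phasing errors or
pump-intensity drifts present in real measurements.

## Feature location

Extrema are located as the extremal pixel followed by independent 3-point
parabolic interpolation per axis (offsets clamped to ±half a pixel; skipped
at grid edges).  When a search region is a mask that cuts through a stronger
feature outside it (e.g. “below the diagonal”), the region's raw maximum is
a spurious boundary shoulder; the `local_only` option restricts the search
to genuine local extrema of the full map and should be used for reading off
feature coordinates in masked regions.

## Determinism and problem sizes

All randomness flows through a single integer seed per dataset
(`numpy.random.default_rng`); identical preset + seed gives bit-identical
cubes, reports and containers.  The default problem size (96×96×134 ≈ 1.2 M
voxels) fits comfortably in memory and a full pipeline pass (generate, fit,
CLS, FSC) takes a few seconds on one CPU; the multi-seed robustness test
uses a 24×24 spatial grid, which leaves the shared-constant estimation
problem unchanged while keeping the sweep quick.

## Known limitations

* No target analysis (compartmental kinetic schemes) and no error bars on
  fitted constants beyond multi-seed dispersion.
* CLS assumes a single dominant diagonal peak inside the window; overlapping
  peaks bias the column centers.
* The FSC does not separate ground- from excited-state coherences and does
  not model finite pulse bandwidth filtering of beat amplitudes.
* The ">1 ps" label reflects the scan-window limit, not a measured constant.
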