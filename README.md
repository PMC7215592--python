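# twodes

Analysis toolkit for two-dimensional electronic spectroscopy (2DES) of
molecular chromophores, built around the workflow used to characterize the
sub-picosecond relaxation of chlorophyll-type pigments: multi-exponential
**global fitting** into 2D decay-associated spectra (2D-DAS), **center line
slope** (CLS) analysis of spectral diffusion, and **Fourier spectra of
coherences** (FSC) of the oscillating residues.  A synthetic-data generator
reproduces the statistical structure of measured 2DES stacks so every stage
of the pipeline can be validated by parameter recovery.

## Who this is for

Ultrafast spectroscopists who already have phased, purely absorptive 2D
frequency–frequency maps ω₁ × ω₃ (excitation × emission, cm⁻¹) as a function
of the population time t₂ (fs), and want the population kinetics, the
frequency–frequency correlation decay, and the vibrational coherence content
extracted with one consistent set of conventions.

## The models

**Global fit (variable projection).**  Every pixel shares the decay
constants:

```
S(ω₁, ω₃, t₂) = Σₖ Aₖ(ω₁, ω₃) · exp(−t₂/τₖ)   (+ optional offset A₀)
```

The τₖ are optimized (multistart + Nelder–Mead in log τ), while the linear
amplitude maps Aₖ — the 2D-DAS — are solved exactly per pixel by least
squares.  A positive DAS amplitude marks a decaying signal, a negative one a
rising signal; the DAS morphology therefore reads out where population goes.
Early population times (default t₂ < 10 fs) are excluded because of
pulse-overlap artifacts; constants ≥ 1 ps are reported as “>1 ps”, since a
1 ps scan cannot pin them down further.

**CLS.**  For each t₂ slice, the emission-frequency position of the maximum
in every excitation column of a window around the diagonal peak is refined
by parabolic interpolation; the weighted slope of those centers versus ω₁ is
the CLS.  For a bivariate-Gaussian peak, CLS = ρ·σ₃/σ₁, so the CLS decay
CLS(t₂) = a·exp(−t₂/τ) + b tracks the frequency–frequency correlation
function; τ is the spectral-diffusion constant.

**FSC.**  After subtracting the fitted kinetics, each pixel's residue trace
is Hann-windowed, zero-padded (4×) and Fourier transformed; the per-pixel
magnitude spectra are aggregated (RMS over pixels by default) into a single
beat-amplitude spectrum whose peaks mark vibrational coherence frequencies.

## Worked example

```python
import twodes as td

ds = td.generate(td.get_preset("rt_kinetic"))       # synthetic RT dataset
result = td.fit_global(ds)                          # bi-exponential VARPRO
print(result.summary())
```

```
Global kinetic fit (variable projection)
  dataset: rt_kinetic (RT)
  components: 2  |  offset: no  |  fit window: t2 >= 10 fs (132 points)
  total SSR over 9216 pixels: 498.669
  component tau = 151.5 fs  [152 fs]
    DAS max +0.891 at (15385, 15394) cm^-1; min -0.385 at (15116, 15731) cm^-1
  component tau = 3065.6 fs  [>1 ps]
    DAS max +0.999 at (15398, 15393) cm^-1; min -0.298 at (15412, 14344) cm^-1
```

The fast constant recovers the 150 fs spectral-diffusion component encoded
in the preset (here 151.5 fs from 1 % noise); the slow component is reported
as “>1 ps”.  Its DAS shows the excited-state absorption as a negative
feature at (15 412, 14 344) cm⁻¹ — the preset encodes (15 410, 14 350).

```python
resid = td.residues(ds, result)
print(td.pick_peaks(td.compute_fsc(resid)).summary())
```

```
FSC peaks (frequency / amplitude / prominence):
     198.9 cm^-1   0.09052   0.02124
     296.0 cm^-1   0.08976   0.01499
     377.9 cm^-1   0.09009   0.01569
     451.4 cm^-1   0.09   0.01632
     531.7 cm^-1   0.09004   0.01918
     770.5 cm^-1   0.09023   0.02081
     925.5 cm^-1   0.09082   0.02146
    1119.1 cm^-1   0.09032   0.0206
    1259.7 cm^-1   0.09024   0.01951
```

All nine vibrational modes injected by the preset (200 … 1260 cm⁻¹) are
recovered within a few cm⁻¹.  The spectral-diffusion preset closes the loop
on the CLS stage:

```python
ls = td.generate(td.get_preset("rt_lineshape"))
print(td.fit_cls_exponential(td.cls_trace(ls)).summary())
```

```
CLS exponential fit: slope(t2) = a*exp(-t2/tau) + b
  tau  = 155.9 fs (spectral diffusion)
  a    = +0.7908
  b    = +0.0439
  rmse = 0.02647 over 134 points
```

## Command line

```
twodes simulate --preset rt_kinetic -o rt.h5     # write the HDF5 container
twodes fit -i rt.h5                              # global fit -> /fit group
twodes cls -i rt.h5                              # CLS trace + exponential fit
twodes fsc -i rt.h5 && twodes peaks -i rt.h5     # coherence spectrum + peaks
twodes report -i rt.h5                           # human-readable summary
```

The container layout (`/axes`, `/data/cube`, `/meta`, optional `/fit`,
`/cls`, `/coherence`) and the CSV dialects are documented in
`src/twodes/io.py`; run configurations (YAML/JSON) validate against
`twodes.io.RUN_CONFIG_SCHEMA`.

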