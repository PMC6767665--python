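# Methods

This note documents the forward model, the reconstruction algorithm, the
synthetic phantoms, the numerical conventions, and the design choices that
were genuinely open — in enough detail that every number the package prints
can be traced to a decision recorded here.

## Forward model

The two interferometer channels share one spectrometer.  With a reference
path offset of +d (channel 1) and −d (channel 2) depth bins, the combined
object is represented as one complex full-range vector u of length N:
channel-1 bin j at index j, channel-2 bin j at index (N−j) mod N.  The
detected spectrum is

    f_i = 2R · Re[ e^{iφ_i} (F u)_i ],

with F the unnormalised DFT and R the reference-arm amplitude.  Index 0 is
the shared zero-path/DC bin of both channels; physical phantoms leave it
empty, and the channel demultiplexer reports it in both channels by
convention.

**Amplitude normalisation.** With the default R = 1/2 a unit reflector at
bin m produces exactly f_i = cos(2πmi/N), and the matched-phase inverse
transform with gain 1/R returns the input amplitude.  The whole pipeline —
synthesis, undersampling with N/M rescale, TCDE — is therefore amplitude
preserving, which makes amplitude-recovery checks meaningful.  Under the
unnormalised DFT, Σ|Fu|² = N·Σ|u|² exactly (asserted in the tests).

**Dispersion phase.** φ(ω) = a₂(ω−ω₀)² + a₃(ω−ω₀)³, expanded in the
angular-optical-frequency detuning with a₂ in s² and a₃ in s³.  Quoted
coefficient magnitudes such as a₂ = 7680×10⁻³⁰ are bare numbers whose units
are conventionally left implicit; only the s²-on-angular-frequency reading
(i.e. 7680 fs², group-delay-dispersion scale) produces the observed
order-10-radian band-edge phase, so that interpretation is fixed here and
exposed in the config.  Expanding in ω rather than k is equivalent up to
factors of c and matches the fs² convention.  c = 2.99792458×10⁸ m/s.

**Grids.** The native simulation grid is linear in wavenumber, which makes
the DFT relation exact.  Wavelength-linear spectrometer data are supported
via cubic-spline resampling onto a uniform-k axis with the same endpoints
and pixel count (idempotent on already-uniform input).  The default
spectrometer is 790 nm centre, 40 nm full bandwidth, 0.05 nm resolution,
960 pixels; the depth-bin size is L/(N/2) with L = λ₀²/(4δλ) the one-sided
maximum depth (6.5 µm at the defaults).

**Omitted physics.** DC and autocorrelation terms are off by default (real
systems subtract the reference DC; an `include_autocorrelation` flag adds a
stylised |sample|² + DC pedestal for stress tests).  Fringe washout,
spectrometer roll-off, pixel crosstalk and polarisation are not modelled.

## TCDE reconstruction

Each iteration t on the spectral residual r (initially f_u):

1. zero-fill r to length N (adjoint of the sampling matrix) and apply the
   compensated inverse DFT with gain 1/R;
2. multiply by N/M — zero filling attenuates coherent peaks by M/N in
   expectation, so this rescale restores unbiased peak amplitudes;
3. threshold the magnitude: iteration 1 at α·max|u| (default α = 0.2,
   separating the strong reflections), iterations ≥ 2 at β times the robust
   noise scale 1.4826·MAD(|u|) (default β = 3.0).  Neither rule is forced by
   the physics; both are exposed in `ReconConfig`;
4. extract circular local maxima above threshold together with their ±w
   neighbouring bins (default w = 1), at most `max_components` peaks
   (default 12) per iteration;
5. resolve conjugates: a candidate peak m is dropped when the magnitude
   within ±`conj_window` bins (default 3) of its mirror bin N−m exceeds its
   own.  The window matters: a dispersion-broadened conjugate image spans
   tens of bins, so comparing only the exact mirror bin would let its side
   lobes through as spurious components.  Exact ties break toward the lower
   bin index (deterministic);
6. re-estimate the new components' complex amplitudes by least squares
   against r restricted to the sampled pixels (a real design matrix with
   Re/Im columns per bin), and subtract their re-synthesised spectrum from
   r.  Because the subtraction is an orthogonal projection, the residual
   energy is non-increasing — an invariant the tests assert on every input.

After the configured iterations (default 2: a strong pass and a weak pass;
optionally auto-extended while the relative residual-energy drop exceeds
`extend_threshold`, capped by `max_iterations`), two closing steps run:

- **Joint debias refit.**  All extracted bins are refit together against the
  original f_u.  The per-iteration fits are overcomplete (peaks plus
  neighbours) and partially absorb the weak components' spectral content
  before those are ever extracted, biasing their amplitudes low — at 20%
  sampling the weak mirror of the two-mirror phantom came back ≈40% low
  without this step.  The refit runs only while 2K real unknowns ≤
  `final_refit_max_load`·M (default 0.8): past that point the least squares
  is no longer meaningfully overdetermined and would overfit noise.
- **Prune.**  Components whose final magnitude falls below
  `prune_fraction` (default 10⁻³) of the largest are dropped; these are
  neighbour/side-lobe bins the least squares zeroed out numerically.

If iteration 1 finds no component the result is returned flagged `empty`
rather than raising — an all-zero spectrum is a legitimate input.

## Phantoms and what they do (not) emulate

- `sparse_reflectors` / `mirror_phantom`: discrete specular reflectors, the
  structure TCDE assumes.  The canonical three-reflector signal (bins
  200/250/580, amplitudes 3/1/0.1 on 1024 bins) and the two-mirror
  dual-channel phantom are packaged in `demos`.
- `layered_phantom`: layers of configurable width with exponential
  attenuation and circular complex Gaussian speckle — the standard
  fully-developed-speckle model for tissue texture.  An optional Gaussian
  `confocal_window` emulates the confocal gate as a pure amplitude envelope
  (never amplifying).
- `two_channel_scene` splits an object between the channels: mode 1
  laterally (adjacent halves, same depth range), mode 2 axially (upper and
  deeper halves, optional lateral offset between the channels).

The two-mirror phantom adds Gaussian detection noise of σ = 0.19 counts for
a unit-amplitude strong mirror, placing the channel-1 full-sampling A-scan
SNR near 45 dB — the scale implied by a ~103 dB-sensitivity bench system
measuring a −56 dB reflector.  The weak mirror is 10× smaller.  "Recovery"
in the rate sweep means a component within ±1 bin of the truth with
amplitude within 30%.

What passing these tests shows: the operator algebra, amplitude calibration,
conjugate suppression and the qualitative sampling-rate thresholds.  What
they do not show: performance on dense (non-sparse) tissue, sensitivity
roll-off, motion, speckle decorrelation between channels, or spectrometer
calibration error — real-data effects outside the simulation.

## Design calculator

Closed forms: axial resolution (2ln2/π)·λ₀²/Δλ; one-sided depth λ₀²/(4δλ);
lateral resolution 4λ₀f/(πD); depth of focus 2π·Δx²/λ₀.  Tissue values
divide by group indices 1.452 (axial) and 1.45 (depth), each reverse-solved
from the quoted air/tissue pairs.  The 4.0 mm beam diameter and the DOF
convention are likewise reverse-engineered from the quoted spot sizes and
DOFs (they reproduce both focal lengths' values consistently); the report
derives DOF from the spot size as quoted to 0.01 µm so the two table entries
stay mutually consistent, and the 21.8 mm maximum scan width is a
pass-through configuration value (scan geometry, not derivable from the
optics).  Quoted table values appear truncated, not rounded, at two
decimals; tests therefore allow one unit in the last printed digit.

## Stitching and SNR conventions

Channel 2's depth axis is flipped on demux so both channels report depth
increasing into the sample.  Mode-1 stitching concatenates laterally with a
zero-filled, provenance-tagged dead-zone gap.  Mode-2 stitching shifts the
deep image laterally (the instrument offset is a user parameter), keeps the
common columns, and blends any seam overlap by maximum — robust to the lower
channel-2 signal level; with zero overlap the stitched depth extent is
exactly twice the single-channel extent.  A-scan SNR is
20·log₁₀(peak / std of a noise window of ≥8 bins excluding the peak), with
+inf as the zero-noise sentinel.

## Problem sizes and runtime

All packaged studies run on one CPU in seconds: the three-reflector study on
N = 1024 with 20–24 sampling masks, the mirror rate sweep on N = 960 with
50 seeds per rate, and the mode-2 B-scan demonstrations on N = 256–512 with
8–16 A-lines.  Randomness is routed exclusively through explicit seeds
(`numpy.random.default_rng` / `SeedSequence`), so every result in the README
reproduces bit for bit.

## Known limitations

- Per-bin speckle is uncorrelated; no axial point-spread convolution is
  applied to phantom profiles (reflectors are ideal single bins).
- The iteration-2 threshold (β·MAD) is global; strongly non-stationary
  artifact floors (e.g. a huge broadened conjugate next to a weak signal)
  are handled by the conjugate window, not by local thresholding.
- Amplitude re-estimation assumes the extracted support contains the truth;
  at very low sampling rates (≲5–10%) spurious peaks enter the model and
  recovery degrades — which is precisely the regime the rate-sweep study
  quantifies.
- The channel-2 window shares bin 0 (zero path/DC) with channel 1; phantoms
  with signal exactly at zero path are ambiguous by construction.
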