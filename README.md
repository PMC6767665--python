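# dcoct — dual-channel single-spectrometer SD-OCT with compressive dispersion encoding

`dcoct` simulates and reconstructs **dual-channel spectral-domain optical
coherence tomography (SD-OCT)** in which both interferometer channels share a
single spectrometer.  It is aimed at OCT researchers who want to study — in
silico, with full control of every parameter — how a pre-introduced reference
path offset, deliberate dispersion encoding, and random spectral
undersampling interact when one line camera must carry two depth channels.

## The model

A reference path offset of ±d separates the channels in depth space: after
reconstruction channel 1 occupies depths [0, 2d] and channel 2 occupies
[−2d, 0].  Writing the combined full-range complex backscatter profile as
u ∈ ℂᴺ (negative depths stored at index N−j under the DFT wraparound
convention), the detected real spectrum is

    f = 2R · Re[ Φ Ψ u ],          Φ = diag(e^{iφ}),  Ψ = DFT,

where R is the reference-arm amplitude and φ(ω) = a₂(ω−ω₀)² + a₃(ω−ω₀)³ a
large, deliberately introduced dispersion phase.  Because f is real, every
depth m has a conjugate ghost at N−m; compensating the known φ numerically
leaves true peaks sharp while ghosts keep a doubled chirp 2φ and are
broadened and suppressed — **dispersion encoding (DE)** gives full-range
imaging from one real spectrum.

Randomly keeping only M of the N spectrometer pixels (a sampling matrix T,
rate M/N) relaxes the spectrometer resolution the dual-channel offset would
otherwise demand.  The **two-step compressive dispersion-encoding (TCDE)**
algorithm recovers the sparse depth profile from f_u = 2R·Re[TΦΨu]: each
iteration zero-fills the spectral residual, applies the compensated inverse
DFT with an N/M amplitude rescale, extracts the strongest peaks (first pass:
a fraction α of the global peak; later passes: β robust noise sigmas) with
their ±1 neighbouring bins, resolves each conjugate pair toward the larger
magnitude, re-estimates amplitudes by least squares on the sampled pixels,
and subtracts the re-synthesised spectrum — removing the components'
conjugate images and aliasing artifacts so weaker reflectors surface in the
next pass.

The package also contains the closed-form design calculator for such a
system (axial/lateral resolution, maximum depth, depth of focus), phantom
generators (sparse reflectors, mirrors, layered speckle tissue), channel
demultiplexing, B-scan assembly and the two stitching modes (mode 1 doubles
imaging speed, mode 2 doubles imaging depth).

## Worked example

The canonical demonstration: a sparse depth signal with reflectors at bins
200, 250 and 580 of amplitudes 3, 1 and 0.1, dispersed with
a₂ = 7680×10⁻³⁰ s², a₃ = 376×10⁻⁴⁵ s³ on a 790 nm / 40 nm, 1024-pixel grid,
then reconstructed from **half** of the spectral pixels:

```python
from dcoct import demos

out = demos.run_fig3(rate=0.5, seed=0)
print(out["recovered"])
```

```
{200: 3.000000000000008, 250: 1.0000000000000009, 580: 0.09999999999999662}
```

All three reflectors — including the one 30× weaker than the strongest —
come back at their true amplitudes; the first TCDE iteration captures bins
200/250, the second surfaces bin 580 after the strong components' conjugate
and aliasing artifacts have been subtracted.  The same scenario is available
from the shell:

```bash
dcoct demo fig3 --rate 0.5 --seed 0 --out out/fig3
dcoct design-report
```

The design report prints the analytic system table:

```
Dual-channel SD-OCT design report
---------------------------------------------
Axial resolution (air/tissue)         6.88 / 4.74 um
Max imaging depth (air/tissue)        3.12 x 2 / 2.15 x 2 mm
Lateral resolution (mode 1)           7.54 um
Depth of focus (mode 1)               452.16 um
Lateral resolution (mode 2)           3.77 um
Depth of focus (mode 2)               113.04 um
Max imaging width                     21.8 mm
```

How low can the sampling rate go?  On a noisy two-mirror phantom with a 10:1
amplitude ratio (`dcoct demo rate-sweep --seed 0 --out out/sweep`, 50 seeds
per rate), recovery probability per channel is

| rate | strong mirror | weak mirror |
|------|---------------|-------------|
| 0.05 | 0.00          | 0.02        |
| 0.10 | 1.00          | 0.00        |
| 0.20 | 1.00          | 0.54        |
| 0.50 | 1.00          | 0.90        |
| 1.00 | 1.00          | 1.00        |

Both mirrors survive 20% sampling in a majority of trials, the weak mirror
drowns in aliasing artifacts at 10%, and at 5% even the strong mirror can no
longer be reconstructed — the practical floor depends on signal strength
relative to the noise and aliasing floor.

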