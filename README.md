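# dsli — diffuse spectral localization imaging of microcavity probes

Optical microscopy fails a few hundred micrometers into biological
tissue: scattering randomizes photon directions within one transport
length l\* = 1/(μ<sub>a</sub> + μ<sub>s</sub>(1−g)), and images of
anything deeper blur into a diffuse glow.  Dye-doped polystyrene
microspheres (~15 μm) offer a way through: each bead is a
whispering-gallery-mode (WGM) resonator whose emission spectrum is a comb
of narrow lines (Q ≈ 7000) at wavelengths set by its diameter and the
refractive index of its surroundings.  Scattering blurs *where* light
arrives, but not *at which wavelength* — so each bead keeps a spectral
fingerprint that survives arbitrarily strong diffusion.

`dsli` implements the full analysis chain for this kind of experiment,
plus the simulation machinery to calibrate and test it:

- **`dsli.wgm`** — exact characteristic-equation solver for TE/TM
  eigenwavelengths of bare and multilayer (coated) spheres; retrieval of
  diameter and external refractive index by fitting a measured comb, with
  a free-spectral-range (FSR) fallback when too few lines are available.
- **`dsli.unmix`** — fluorescence-background removal, Lorentzian peak
  detection, and comb unmixing: candidate FSR values from peak pairs are
  propagated across the spectrum (1/λ̃ = 1/λᵢ + N·FSR) and scored by how
  many observed peaks they reproduce; same-FSR groups at offset phases
  are merged as the TE/TM pair of one cavity; missing teeth are filled in.
- **`dsli.hsi`** — hyperspectral cubes (ENVI and HDF5), per-resonance
  intensity maps, 2D Gaussian localization, surface-footprint widths, and
  depth from a monotone width↔depth calibration curve.
- **`dsli.mc`** — photon-packet Monte Carlo (Henyey–Greenstein or
  Mie-tabulated phase function, Fresnel boundaries), Mie optics for
  phantom design, depth-calibration curves, integrating-sphere R/T and
  inverse optical-property estimation.
- **`dsli.synth`** — ground-truthed synthetic scenes: bead populations
  (mean 15 μm, CV 14%), exact per-bead mode combs, depth-dependent diffuse
  footprints, dye background and shot noise, with a complete truth
  manifest.
- **`dsli.pipeline`** — end-to-end orchestration producing one record per
  microcavity (x, y, z, diameter, external index, environment class), and
  the downstream readouts: in-cell vs out-of-cell classification
  (1.37 vs 1.34), same-cell inference (Δn < 0.003), diameter-tag tracking,
  and functionalized-sensor (pH / temperature) comb-shift readout.

A `dsli` command-line tool wraps the common operations
(`simulate`, `unmix`, `localize`, `mc-calibrate`, `run`, `track`,
`sense`, `capacity`).

## Worked example

Render a synthetic three-bead scene under a scattering layer and run the
full chain on it:

```python
import numpy as np
from dsli import synth, pipeline

scene = synth.make_scene(n_beads=3, field_um=240, depth_um=150, seed=5)
x = np.arange(0, 241, 5.0)
cube, truth = synth.render_cube(scene, x, x, window_nm=(505, 535), seed=5)
for r in pipeline.run_dsli(cube):
    print(f"x={r.x_um:6.1f} y={r.y_um:6.1f} d={r.diameter_um:.4f} um "
          f"n_ext={r.n_external:.4f} ({r.environment}, {r.n_peaks} peaks)")
```

prints (one line per identified microcavity):

```
x=  44.4 y= 203.9 d=14.4784 um n_ext=1.3402 (out_of_cell, 15 peaks)
x= 171.9 y= 171.9 d=13.3159 um n_ext=1.3404 (out_of_cell, 13 peaks)
x=  44.8 y= 100.5 d=12.2188 um n_ext=1.3411 (out_of_cell, 11 peaks)
```

The generator's truth for this seed is beads of 14.4784, 13.3159 and
12.2188 μm at (44.2, 203.9), (171.2, 171.7) and (45.1, 100.4) —
diameters recovered to well under a nanometer and positions to ~1 μm
even though the rendered footprints are ~80 μm wide and overlap.

Solve a single bead's modes directly:

```python
from dsli import wgm
params = wgm.SphereParams(diameter=15.0, n_internal=1.59, n_external=1.34)
modes = wgm.find_modes(params, window=(500, 540))
fsr, dlam = wgm.fsr_estimate(15.0, 1.59, 520.0)   # 0.01335 1/um, 3.61 nm
```

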