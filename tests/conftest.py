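"""Shared fixtures: exactly solved mode sets and small rendered scenes.

The expensive objects (mode solves, rendered cubes, pipeline runs) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

from dsli import synth, wgm


@pytest.fixture(scope="session")
def modes_15um():
    """All modes of the reference 15 um bead in water-like surroundings."""
    params = wgm.SphereParams(15.0, 1.59, 1.34)
    return params, wgm.find_modes(params, (500.0, 540.0), max_radial_order=2)


@pytest.fixture(scope="session")
def modes_13um():
    """Mode set of the 13.0189 um / n_ext 1.37 bead used in fit round trips."""
    params = wgm.SphereParams(13.0189, 1.59, 1.37)
    return params, wgm.find_modes(params, (500.0, 540.0), max_radial_order=2)


@pytest.fixture(scope="session")
def noiseless_fit(modes_13um):
    """Round-trip fit of the noiseless 13.0189 um comb (shared, ~20 s)."""
    _, modes = modes_13um
    return wgm.fit_size_index(list(modes.wavelengths()), 1.59)


def make_comb(nu0, fsr, window=(500.0, 540.0)):
    """Perfect comb wavelengths (nm) with spacing ``fsr`` (1/um) in window."""
    nu_lo, nu_hi = 1e3 / window[1], 1e3 / window[0]
    n = np.arange(int(np.ceil((nu_lo - nu0) / fsr)),
                  int(np.floor((nu_hi - nu0) / fsr)) + 1)
    return np.sort(1e3 / (nu0 + n * fsr))


@pytest.fixture(scope="session")
def two_comb_peaks():
    """Two interleaved perfect combs with known FSRs and memberships."""
    from dsli.unmix import Peak

    fsr1, fsr2 = 0.0130, 0.0138
    lam1 = make_comb(1e3 / 520.0, fsr1)[:8]
    lam2 = make_comb(1e3 / 521.3, fsr2)[:8]
    peaks = [Peak(w, 0.074, 100.0, 1000.0) for w in np.sort(
        np.concatenate([lam1, lam2]))]
    labels = ["a" if min(abs(lam1 - p.wavelength_nm)) <
              min(abs(lam2 - p.wavelength_nm)) else "b" for p in peaks]
    return peaks, labels, fsr1, fsr2


@pytest.fixture(scope="session")
def rendered_scene():
    """A 3-bead scene rendered to a cube with Poisson noise (shared)."""
    scene = synth.make_scene(n_beads=3, field_um=240, depth_um=150, seed=5)
    x = np.arange(0.0, 241.0, 5.0)
    cube, manifest = synth.render_cube(scene, x, x, window_nm=(505.0, 535.0),
                                       seed=5)
    return scene, cube, manifest


@pytest.fixture(scope="session")
def pipeline_records(rendered_scene):
    from dsli import pipeline

    _, cube, _ = rendered_scene
    return pipeline.run_dsli(cube)
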