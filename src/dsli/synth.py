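"""Ground-truthed synthetic scenes and hyperspectral cubes.

Emulates what the optical setup records from dye-doped polystyrene beads
(mean diameter 15 um, coefficient of variation 14%, index 1.59) under or
inside a scattering layer: each bead contributes a comb of Lorentzian
whispering-gallery lines at its exactly computed mode wavelengths,
spatially weighted by its depth-dependent diffuse surface footprint, on
top of a smooth shared dye-emission background, with Poisson shot noise.
Every rendered quantity is recorded in a manifest so that detection,
unmixing, localization and fitting can be scored against absolute truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import wgm
from .hsi import CalibrationCurve, HyperspectralCube
from .mc import McGeometry, OpticalMedium, run_mc

__all__ = [
    "BeadPopulation",
    "SceneBead",
    "Scene",
    "GroundTruthManifest",
    "ENVIRONMENT_INDEX_MODELS",
    "sample_population",
    "pair_indistinguishability_probability",
    "capacity_estimate",
    "make_scene",
    "render_cube",
    "dye_emission",
]

#: per-environment external-index models: (mean, standard deviation).
#: Growth medium is stable (well within 0.002 RIU); cytoplasm is centered
#: near 1.37 with cell-to-cell spread; interstitial fluid in tissue sits
#: between the two.
ENVIRONMENT_INDEX_MODELS: dict[str, tuple[float, float]] = {
    "medium": (1.340, 0.001),
    "cytoplasm": (1.370, 0.007),
    "interstitial": (1.350, 0.003),
}


@dataclass
class BeadPopulation:
    """Diameters and surroundings of a sampled bead batch."""

    diameters_um: np.ndarray
    n_external: np.ndarray
    environments: list[str]
    n_internal: float = 1.59
    seed: int = 0


@dataclass
class SceneBead:
    x_um: float
    y_um: float
    depth_um: float
    diameter_um: float
    n_external: float
    environment: str = "medium"
    q_factor: float = 7000.0
    brightness: float = 1.0


@dataclass
class Scene:
    beads: list[SceneBead]
    medium: OpticalMedium
    geometry: str = "slab_overlayer"  # how the scattering layer sits
    n_internal: float = 1.59


@dataclass
class GroundTruthManifest:
    """Everything the renderer put into a cube, bead by bead."""

    beads: list[dict] = field(default_factory=list)
    window_nm: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=1, default=float)
        if path is not None:
            with open(path, "w") as f:
                f.write(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(beads=d["beads"], window_nm=tuple(d["window_nm"]),
                   seed=d["seed"])

    def all_mode_wavelengths(self, bead_index: int | None = None) -> np.ndarray:
        lam = [m["wavelength_nm"] for k, b in enumerate(self.beads)
               for m in b["modes"]
               if bead_index is None or k == bead_index]
        return np.asarray(sorted(lam))


# ---------------------------------------------------------------------------
# population statistics


def sample_population(
    n: int,
    mean_um: float = 15.0,
    cv: float = 0.14,
    seed: int = 0,
    environment: str = "medium",
    n_internal: float = 1.59,
) -> BeadPopulation:
    """Draw a bead batch: Gaussian diameters, environment-specific index.

    Diameters are normal with the given mean and coefficient of variation,
    truncated at zero (redrawn); the external index of each bead is drawn
    from the environment's model in :data:`ENVIRONMENT_INDEX_MODELS`
    (pass ``environment="mixed:medium,cytoplasm"``-style lists elsewhere by
    sampling twice).  Reproducible from the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    d = rng.normal(mean_um, cv * mean_um, n)
    while np.any(d <= 0):  # truncate the (negligible) non-physical tail
        bad = d <= 0
        d[bad] = rng.normal(mean_um, cv * mean_um, bad.sum())
    mu_n, sd_n = ENVIRONMENT_INDEX_MODELS[environment]
    n_ext = rng.normal(mu_n, sd_n, n)
    return BeadPopulation(
        diameters_um=d, n_external=n_ext, environments=[environment] * n,
        n_internal=n_internal, seed=seed)


def pair_indistinguishability_probability(
    mean_um: float = 15.0,
    cv: float = 0.14,
    threshold_um: float = 0.003,
) -> float:
    """P(|D1 - D2| < t) for two independent beads of one batch.

    Two beads are spectrally indistinguishable when their diameters agree
    within the comb resolution (~3 nm); for D ~ N(mean, (cv*mean)^2) the
    difference is N(0, 2 sigma^2), giving the closed form erf(t / (2 sigma)).
    """
    if threshold_um < 0:
        raise ValueError("threshold must be >= 0")
    sigma = cv * mean_um
    if sigma == 0:
        return 1.0
    return math.erf(threshold_um / (2.0 * sigma))


def capacity_estimate(
    scan_area_mm2: float = 9.0,
    spot_diameter_um: float = 200.0,
    beads_per_spot: float = 5.0,
) -> float:
    """Maximum number of resolvable beads over a scan area.

    The diffuse collection spot covers ``pi (d/2)^2``; each spot position
    yields ``beads_per_spot`` reliably identified beads, so the capacity is
    their product ratio, rounded to two significant figures.
    """
    if min(scan_area_mm2, spot_diameter_um, beads_per_spot) <= 0:
        raise ValueError("all inputs must be positive")
    spot_area_mm2 = math.pi * (0.5 * spot_diameter_um * 1e-3) ** 2
    raw = scan_area_mm2 / spot_area_mm2 * beads_per_spot
    if raw <= 0:
        return 0.0
    mag = 10.0 ** (math.floor(math.log10(raw)) - 1)
    return float(round(raw / mag) * mag)


# ---------------------------------------------------------------------------
# scenes


def make_scene(
    n_beads: int,
    field_um: float = 320.0,
    depth_um: float | tuple[float, float] = 200.0,
    medium: OpticalMedium | None = None,
    geometry: str = "slab_overlayer",
    environment: str = "medium",
    mean_um: float = 15.0,
    cv: float = 0.14,
    min_diameter_gap_um: float = 0.05,
    seed: int = 0,
) -> Scene:
    """Random scene of beads in a square field at the given depth(s).

    Bead diameters are resampled until all pairwise gaps exceed
    ``min_diameter_gap_um`` (default 50 nm: comfortably distinguishable
    combs); pass 0 to allow collisions, or place beads manually for
    designed fixtures.  ``depth_um`` may be a single depth or a (lo, hi)
    range sampled uniformly.
    """
    rng = np.random.default_rng(seed)
    medium = medium or OpticalMedium(63.0, 0.2, 0.87, 1.41)
    for attempt in range(200):
        pop = sample_population(n_beads, mean_um, cv, seed + 7919 * attempt,
                                environment)
        gaps = np.abs(np.subtract.outer(pop.diameters_um, pop.diameters_um))
        np.fill_diagonal(gaps, np.inf)
        if min_diameter_gap_um <= 0 or gaps.min() >= min_diameter_gap_um:
            break
    else:
        raise RuntimeError("could not sample well-separated diameters")
    lo = 0.15 * field_um
    hi = 0.85 * field_um
    beads = []
    for k in range(n_beads):
        if isinstance(depth_um, (tuple, list)):
            z = float(rng.uniform(depth_um[0], depth_um[1]))
        else:
            z = float(depth_um)
        beads.append(SceneBead(
            x_um=float(rng.uniform(lo, hi)), y_um=float(rng.uniform(lo, hi)),
            depth_um=z, diameter_um=float(pop.diameters_um[k]),
            n_external=float(pop.n_external[k]), environment=environment,
            q_factor=float(rng.uniform(5000, 10000)),
            brightness=float(rng.uniform(0.6, 1.0))))
    return Scene(beads=beads, medium=medium, geometry=geometry)


# ---------------------------------------------------------------------------
# rendering


def dye_emission(wavelength_nm: np.ndarray, center_nm: float = 515.0,
                 width_nm: float = 25.0) -> np.ndarray:
    """Smooth normalized emission profile of the doping dye."""
    return np.exp(-0.5 * ((wavelength_nm - center_nm) / width_nm) ** 2)


def _footprint(bead: SceneBead, scene: Scene, x_um, y_um, psf: str,
               calibration: CalibrationCurve | None, seed: int) -> np.ndarray:
    X, Y = np.meshgrid(x_um, y_um)
    if psf == "mc":
        lstar = 1e3 / (scene.medium.mua_per_mm
                       + scene.medium.mus_per_mm * (1 - scene.medium.g))
        if scene.geometry == "slab_overlayer":
            geo = McGeometry("slab_overlayer", thickness_um=bead.depth_um,
                             source_depth_um=bead.depth_um)
        else:
            geo = McGeometry("embedded",
                             thickness_um=bead.depth_um + 4 * lstar,
                             source_depth_um=bead.depth_um)
        res = run_mc(scene.medium, geo, n_photons=100_000, seed=seed,
                     map_half_um=max(300.0, 3 * bead.depth_um))
        m = res.surface_map
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (m.y_um, m.x_um), m.data, bounds_error=False, fill_value=0.0)
        fp = interp(np.stack([(Y - bead.y_um).ravel(),
                              (X - bead.x_um).ravel()], axis=-1))
        fp = fp.reshape(X.shape)
        peak = res.surface_map.data.max()
        fp = fp / peak if peak > 0 else fp
    else:
        if calibration is not None:
            from .hsi import PchipInterpolator  # shared import path

            sig = float(PchipInterpolator(
                calibration.depth_um, calibration.width_um)(
                    np.clip(bead.depth_um, calibration.depth_um[0],
                            calibration.depth_um[-1])))
        else:
            # diffusive spreading scale: footprint sigma grows roughly
            # linearly with depth once past one transport length
            sig = max(6.0, 0.55 * bead.depth_um)
        r2 = (X - bead.x_um) ** 2 + (Y - bead.y_um) ** 2
        fp = np.exp(-0.5 * r2 / sig**2)
    if fp.max() <= 0:
        raise ValueError(f"bead at ({bead.x_um}, {bead.y_um}) renders no light")
    # unit peak: ``peak_counts`` is the per-pixel amplitude at the footprint
    # center, the quantity exposure time actually controls
    return fp


def render_cube(
    scene: Scene,
    x_um: np.ndarray | None = None,
    y_um: np.ndarray | None = None,
    window_nm: tuple[float, float] = (500.0, 540.0),
    spectral_step_nm: float = 0.023,
    peak_counts: float = 3000.0,
    background_ratio: float = 1.0,
    noise: str = "poisson",
    psf: str = "gaussian",
    calibration: CalibrationCurve | None = None,
    max_radial_order: int = 1,
    seed: int = 0,
) -> tuple[HyperspectralCube, GroundTruthManifest]:
    """Render a scene into a hyperspectral cube plus its truth manifest.

    Each bead's comb is computed exactly from the characteristic equation,
    broadened to Lorentzians at the bead's Q factor, scaled by per-tooth
    amplitudes following the dye emission envelope, and spread over the
    field by the bead's surface footprint (Monte Carlo map or Gaussian
    approximation).  ``peak_counts`` sets the brightest tooth's amplitude
    in the summed spectrum (counts); ``background_ratio`` scales the
    shared smooth dye background relative to that amplitude.  ``noise``
    is "poisson" or "none".
    """
    rng = np.random.default_rng(seed)
    if x_um is None:
        x_um = np.arange(0.0, 321.0, 5.0)
    if y_um is None:
        y_um = np.arange(0.0, 321.0, 5.0)
    lam = np.arange(window_nm[0], window_nm[1] + spectral_step_nm / 2,
                    spectral_step_nm)
    cube = np.zeros((len(y_um), len(x_um), len(lam)), dtype=float)
    manifest = GroundTruthManifest(window_nm=window_nm, seed=seed)
    envelope = dye_emission(lam)
    bg_spatial = np.zeros((len(y_um), len(x_um)))
    for k, bead in enumerate(scene.beads):
        params = wgm.SphereParams(bead.diameter_um, scene.n_internal,
                                  bead.n_external)
        modes = wgm.find_modes(params, window_nm, max_radial_order)
        entry = {
            "x_um": bead.x_um, "y_um": bead.y_um, "depth_um": bead.depth_um,
            "diameter_um": bead.diameter_um, "n_external": bead.n_external,
            "environment": bead.environment, "q_factor": bead.q_factor,
            "brightness": bead.brightness, "modes": [], "rendered": True,
        }
        if len(modes) == 0:
            entry["rendered"] = False
            manifest.beads.append(entry)
            continue
        fp = _footprint(bead, scene, x_um, y_um, psf, calibration,
                        seed + 911 * k)
        spectrum = np.zeros_like(lam)
        for mode_id, w in modes.modes:
            fwhm = w / bead.q_factor
            amp = (bead.brightness * peak_counts
                   * float(np.interp(w, lam, envelope))
                   * rng.uniform(0.55, 1.0))
            spectrum += amp * (0.5 * fwhm) ** 2 / ((lam - w) ** 2
                                                   + (0.5 * fwhm) ** 2)
            entry["modes"].append({
                "polarization": mode_id.polarization.value,
                "angular_order": mode_id.angular_order,
                "radial_order": mode_id.radial_order,
                "wavelength_nm": w, "fwhm_nm": fwhm, "amplitude": amp})
        cube += fp[:, :, None] * spectrum[None, None, :]
        bg_spatial += bead.brightness * fp
        manifest.beads.append(entry)
    # shared smooth dye background (same spectral shape for every bead)
    cube += (background_ratio * peak_counts
             * bg_spatial[:, :, None] * envelope[None, None, :])
    if noise == "poisson":
        cube = rng.poisson(np.clip(cube, 0, None)).astype(float)
    elif noise != "none":
        raise ValueError("noise must be 'poisson' or 'none'")
    return HyperspectralCube(x_um, y_um, lam, cube), manifest
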