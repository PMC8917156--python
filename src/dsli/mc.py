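"""Photon-transport Monte Carlo, Mie optics and depth calibration.

The scattering media here (microsphere-loaded silicone phantoms, skin,
brain) are described by a scattering coefficient mu_s, absorption
coefficient mu_a, scattering anisotropy g (mean cosine of the
single-scattering angle) and refractive index n.  Photon packets are
propagated with exponential free paths, weight absorption with survival
roulette, Henyey-Greenstein or Mie-tabulated scattering, and Fresnel
reflection/refraction at the index-mismatched top and bottom surfaces —
the standard tissue-optics random walk.

Two source geometries matter for depth calibration: an isotropic point
emitter (a fluorescent microcavity) below a finite scattering slab with
nothing but transparent polymer beneath it ("slab_overlayer"), and the
same emitter embedded inside the medium, where light scattered below the
source can return ("embedded") — the embedded footprint at the surface is
systematically wider.  A collimated pencil beam onto a free-standing slab
reproduces the integrating-sphere transmittance/reflectance measurement
used to verify (or, run in reverse, estimate) the medium's optical
properties.

Lengths are um internally; mu_s and mu_a are specified in 1/mm as is
conventional, and converted on use.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .hsi import CalibrationCurve, IntensityMap, surface_width

log = logging.getLogger(__name__)

__all__ = [
    "OpticalMedium",
    "McGeometry",
    "McResult",
    "MieScatterer",
    "transport_length",
    "mie_single_particle",
    "mie_phase_table",
    "medium_from_particles",
    "sample_scatter_angle",
    "run_mc",
    "build_calibration",
    "integrating_sphere_rt",
    "invert_optical_properties",
    "CalibrationCurve",
]


@dataclass
class OpticalMedium:
    """Scattering/absorption description of a phantom or tissue layer."""

    mus_per_mm: float
    mua_per_mm: float = 0.2  # weakly absorbing unless stated otherwise
    g: float = 0.87
    n: float = 1.41
    phase_function: str = "hg"  # "hg" | "mie"
    # tabulated cumulative phase function (cos theta grid, CDF) for "mie"
    phase_table: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.mus_per_mm < 0 or self.mua_per_mm < 0:
            raise ValueError("mu_s and mu_a must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError("g must be in (-1, 1)")
        if self.phase_function not in ("hg", "mie"):
            raise ValueError("phase function must be 'hg' or 'mie'")
        if self.phase_function == "mie" and self.phase_table is None:
            raise ValueError("'mie' phase function needs a phase_table")


def transport_length(medium: OpticalMedium) -> tuple[float, float]:
    """Transport length l* and scattering mean free path ls, in um.

    l* = 1/(mu_a + mu_s (1 - g)) is the depth over which the photon
    direction fully randomizes — the depth limit of ballistic imaging;
    ls = 1/mu_s is the mean distance between scattering events.
    """
    denom = medium.mua_per_mm + medium.mus_per_mm * (1.0 - medium.g)
    if denom <= 0:
        raise ValueError("non-scattering, non-absorbing medium: l* infinite")
    l_star = 1e3 / denom
    ls = 1e3 / medium.mus_per_mm if medium.mus_per_mm > 0 else math.inf
    return l_star, ls


@dataclass
class McGeometry:
    """Simulation geometry: a laterally infinite layer, z down from the top.

    ``slab_overlayer``: scattering only between the source and the
    detector; the source sits at ``source_depth_um`` (the slab's bottom
    face) and anything crossing the bottom boundary is lost into the
    transparent mounting polymer.  ``embedded``: the medium continues to
    ``thickness_um`` below the top, so light scattered beneath the source
    can return.  The detection surface is the top plane.
    """

    configuration: str = "slab_overlayer"
    thickness_um: float = 200.0
    source_depth_um: float = 200.0
    n_above: float = 1.0  # air above the sample
    n_below: float = 1.34  # glass/fluoropolymer mounting layer
    collection_na: float | None = None  # None: tally every exiting photon

    def __post_init__(self) -> None:
        if self.configuration not in ("slab_overlayer", "embedded"):
            raise ValueError("configuration must be 'slab_overlayer' or 'embedded'")
        if not 0 <= self.source_depth_um <= self.thickness_um:
            raise ValueError("source depth must lie inside the medium")
        if self.collection_na is not None and not 0 < self.collection_na < 1:
            raise ValueError("NA must be in (0, 1)")


@dataclass
class McResult:
    """Tallies of one Monte Carlo run (all fractions of launched weight)."""

    surface_map: IntensityMap  # fluence exiting the top surface
    exit_top: float
    exit_bottom: float
    absorbed: float
    ballistic_bottom: float  # bottom exits with zero scattering events
    overflow: float  # exited top outside the tallied map extent
    n_photons: int
    seed: int
    geometry: str = ""

    @property
    def energy_budget(self) -> float:
        return self.exit_top + self.exit_bottom + self.absorbed


# ---------------------------------------------------------------------------
# Mie theory


@dataclass
class MieScatterer:
    """A dilute suspension of identical dielectric spheres."""

    diameter_um: float
    n_sphere: float
    n_medium: float
    number_density_per_mm3: float = 0.0
    wavelength_nm: float = 532.0

    def __post_init__(self) -> None:
        if min(self.diameter_um, self.n_sphere, self.n_medium,
               self.wavelength_nm) <= 0:
            raise ValueError("all Mie parameters must be positive")

    @property
    def size_parameter(self) -> float:
        return (math.pi * self.diameter_um * self.n_medium
                / (self.wavelength_nm * 1e-3))


def _mie_coefficients(m: float, x: float):
    """Mie a_n, b_n for a real relative index m and size parameter x."""
    nmax = int(x + 4.05 * x ** (1.0 / 3.0) + 2)
    mx = m * x
    nmx = max(nmax, int(abs(mx))) + 16
    D = np.zeros(nmx + 1)
    for k in range(nmx, 0, -1):  # downward logarithmic-derivative recurrence
        D[k - 1] = k / mx - 1.0 / (D[k] + k / mx)
    n = np.arange(1, nmax + 1)
    psi = np.zeros(nmax + 1)
    chi = np.zeros(nmax + 1)
    psi_m1, chi_m1 = math.cos(x), -math.sin(x)  # order -1
    psi[0], chi[0] = math.sin(x), math.cos(x)  # order 0
    for k in range(1, nmax + 1):
        psi[k] = (2 * k - 1) / x * psi[k - 1] - psi_m1
        chi[k] = (2 * k - 1) / x * chi[k - 1] - chi_m1
        psi_m1, chi_m1 = psi[k - 1], chi[k - 1]
    xi = psi - 1j * chi
    Dn = D[1:nmax + 1]
    da = Dn / m + n / x
    db = Dn * m + n / x
    a = (da * psi[1:] - psi[:-1]) / (da * xi[1:] - xi[:-1])
    b = (db * psi[1:] - psi[:-1]) / (db * xi[1:] - xi[:-1])
    return a, b


def mie_single_particle(sc: MieScatterer) -> tuple[float, float]:
    """Scattering cross-section (um^2) and anisotropy g of one sphere.

    Standard Mie series with the Wiscombe truncation rule; ``g`` is the
    intensity-weighted mean cosine of the scattering angle.  In the
    Rayleigh limit (size parameter -> 0) g -> 0.
    """
    x = sc.size_parameter
    m = sc.n_sphere / sc.n_medium
    a, b = _mie_coefficients(m, x)
    n = np.arange(1, len(a) + 1)
    qsca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    asy = 0.0
    asy += np.sum(n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
                  * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])))
    asy += np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b)))
    g = 4.0 / (x**2 * qsca) * asy
    radius = 0.5 * sc.diameter_um
    return float(qsca * math.pi * radius**2), float(g)


def mie_phase_table(sc: MieScatterer, n_angles: int = 2000):
    """Tabulated cumulative phase function ``(cos_theta, cdf)``.

    The unpolarized angular intensity (|S1|^2+|S2|^2)/2 is integrated over
    angle to build an inverse-CDF sampling table; its mean cosine matches
    the series ``g`` from :func:`mie_single_particle` to the quadrature
    accuracy.
    """
    x = sc.size_parameter
    m = sc.n_sphere / sc.n_medium
    a, b = _mie_coefficients(m, x)
    nmax = len(a)
    mu = np.cos(np.linspace(math.pi, 0.0, n_angles))  # ascending cos
    pi_n = np.zeros((nmax, n_angles))
    tau_n = np.zeros((nmax, n_angles))
    pi_n[0] = 1.0
    tau_n[0] = mu
    if nmax > 1:
        pi_n[1] = 3.0 * mu
        tau_n[1] = 2.0 * mu * pi_n[1] - 3.0 * pi_n[0]
    for k in range(2, nmax):
        n_ = k + 1
        pi_n[k] = ((2 * n_ - 1) * mu * pi_n[k - 1] - n_ * pi_n[k - 2]) / (n_ - 1)
        tau_n[k] = n_ * mu * pi_n[k] - (n_ + 1) * pi_n[k - 1]
    n = np.arange(1, nmax + 1)[:, None]
    coef = (2 * n + 1) / (n * (n + 1))
    S1 = np.sum(coef * (a[:, None] * pi_n + b[:, None] * tau_n), axis=0)
    S2 = np.sum(coef * (a[:, None] * tau_n + b[:, None] * pi_n), axis=0)
    p = 0.5 * (np.abs(S1) ** 2 + np.abs(S2) ** 2)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(mu))])
    cdf /= cdf[-1]
    return mu, cdf


def medium_from_particles(sc: MieScatterer, mua_per_mm: float = 0.2,
                          phase_function: str = "hg") -> OpticalMedium:
    """Bulk optical properties of a dilute sphere suspension.

    mu_s is number density times the single-particle scattering
    cross-section (independent scattering); g comes from the Mie series.
    Above ~10% volume fraction dependent scattering makes this estimate
    unreliable and a warning is raised.
    """
    sigma_um2, g = mie_single_particle(sc)
    mus_per_mm = sc.number_density_per_mm3 * sigma_um2 * 1e-6  # um^2/mm^3 -> 1/mm
    vol_frac = (sc.number_density_per_mm3
                * (math.pi / 6.0) * (sc.diameter_um * 1e-3) ** 3)
    if vol_frac > 0.10:
        warnings.warn(
            f"volume fraction {vol_frac:.2f} > 0.1: independent-scattering "
            "assumption is questionable", stacklevel=2)
    table = mie_phase_table(sc) if phase_function == "mie" else None
    return OpticalMedium(mus_per_mm=mus_per_mm, mua_per_mm=mua_per_mm, g=g,
                         n=sc.n_medium, phase_function=phase_function,
                         phase_table=table)


def sample_scatter_angle(medium: OpticalMedium, rng: np.random.Generator,
                         size: int = 1) -> np.ndarray:
    """Sample cos(theta) from the medium's single-scattering phase function.

    Henyey-Greenstein uses the closed-form inverse CDF; a Mie-tabulated
    medium is sampled by inverse-CDF interpolation of its table.
    """
    u = rng.random(size)
    if medium.phase_function == "mie":
        mu, cdf = medium.phase_table
        return np.interp(u, cdf, mu)
    g = medium.g
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - t * t) / (2.0 * g)


# ---------------------------------------------------------------------------
# transport kernel


@njit(cache=True)
def _fresnel_r(ci, n1, n2):
    if ci > 0.9999999:
        r = (n1 - n2) / (n1 + n2)
        return r * r
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 / n2 * si
    if st >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st * st)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport(n_photons, seed, mus, mua, g, use_table, tab_mu, tab_cdf,
               n_med, n_above, n_below, thickness, src_z, pencil,
               transparent_below, map_half, nbins, na_cos, w_thresh, w_survive):
    """Photon-packet random walk in a laterally infinite layer.

    Returns (surface map, exit_top, exit_bottom, absorbed, ballistic,
    overflow_top).  All lengths um, mus/mua per um.  ``na_cos`` < 1 limits
    the top-surface tally to exit angles inside the collection cone
    (cosine in air above); the total ``exit_top`` is always tallied.
    """
    np.random.seed(seed)
    smap = np.zeros((nbins, nbins))
    bin_um = 2.0 * map_half / nbins
    exit_top = 0.0
    exit_bottom = 0.0
    absorbed = 0.0
    ballistic = 0.0
    overflow = 0.0
    mut = mus + mua
    albedo = mus / mut if mut > 0 else 1.0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = src_z
        w = 1.0
        nscat = 0
        if pencil == 1:
            ux = 0.0
            uy = 0.0
            uz = 1.0
            r0 = _fresnel_r(1.0, n_above, n_med)
            if np.random.random() < r0:
                exit_top += w  # specular reflection at entry
                continue
            z = 0.0
        else:
            cz = 2.0 * np.random.random() - 1.0
            sz = math.sqrt(max(0.0, 1.0 - cz * cz))
            ph = 2.0 * math.pi * np.random.random()
            ux = sz * math.cos(ph)
            uy = sz * math.sin(ph)
            uz = cz
        alive = True
        while alive:
            if mut > 0.0:
                s = -math.log(np.random.random() + 1e-300) / mut
            else:
                s = 1.0e12
            while s > 0.0:
                if uz > 1e-12:
                    d_b = (thickness - z) / uz
                    top = False
                elif uz < -1e-12:
                    d_b = -z / uz
                    top = True
                else:
                    d_b = 1.0e13
                    top = False
                if s < d_b:
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    s = 0.0
                    break
                # move to the boundary
                x += d_b * ux
                y += d_b * uy
                z = 0.0 if top else thickness
                s -= d_b
                ci = abs(uz)
                n_out = n_above if top else n_below
                if (not top) and transparent_below:
                    # transparent mounting below the slab: photon leaves
                    exit_bottom += w
                    if nscat == 0:
                        ballistic += w
                    alive = False
                    break
                refl = _fresnel_r(ci, n_med, n_out)
                if np.random.random() < refl:
                    uz = -uz
                    z = min(max(z, 1e-9), thickness - 1e-9)
                    continue
                if top:
                    exit_top += w
                    # exit angle in the medium -> cone test in the outside
                    st_out = n_med / n_out * math.sqrt(max(0.0, 1.0 - ci * ci))
                    ct_out = math.sqrt(max(0.0, 1.0 - st_out * st_out))
                    if ct_out >= na_cos:
                        ix = int((x + map_half) / bin_um)
                        iy = int((y + map_half) / bin_um)
                        if 0 <= ix < nbins and 0 <= iy < nbins:
                            smap[iy, ix] += w
                        else:
                            overflow += w
                    else:
                        overflow += w
                else:
                    exit_bottom += w
                    if nscat == 0:
                        ballistic += w
                alive = False
                break
            if not alive:
                break
            # interaction: absorb part of the weight, then scatter
            absorbed += w * (1.0 - albedo)
            w *= albedo
            nscat += 1
            if w < w_thresh:
                if np.random.random() < w_survive:
                    w /= w_survive
                else:
                    absorbed += w
                    alive = False
                    break
            if use_table == 1:
                u = np.random.random()
                k = np.searchsorted(tab_cdf, u)
                if k <= 0:
                    ct = tab_mu[0]
                elif k >= len(tab_mu):
                    ct = tab_mu[-1]
                else:
                    f = (u - tab_cdf[k - 1]) / (tab_cdf[k] - tab_cdf[k - 1] + 1e-300)
                    ct = tab_mu[k - 1] + f * (tab_mu[k] - tab_mu[k - 1])
            else:
                u = np.random.random()
                if abs(g) < 1e-8:
                    ct = 2.0 * u - 1.0
                else:
                    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                    ct = (1.0 + g * g - t * t) / (2.0 * g)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            ph = 2.0 * math.pi * np.random.random()
            cp = math.cos(ph)
            sp = math.sin(ph)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz >= 0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz_n = -st * cp * den + uz * ct
                ux, uy, uz = ux_n, uy_n, uz_n
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
    return smap, exit_top, exit_bottom, absorbed, ballistic, overflow


def run_mc(
    medium: OpticalMedium,
    geometry: McGeometry,
    n_photons: int = 100_000,
    seed: int = 1,
    map_half_um: float | None = None,
    map_bin_um: float = 5.0,
    source: str = "isotropic",
    roulette_threshold: float = 1e-4,
    roulette_survive: float = 0.1,
) -> McResult:
    """Run the photon-packet Monte Carlo and tally the surface footprint.

    The default source is an isotropic point emitter at the geometry's
    source depth (a fluorescent microcavity); ``source="pencil"`` launches
    a collimated beam into the top surface instead (integrating-sphere
    configuration).  Identical seed and settings give identical tallies.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if source not in ("isotropic", "pencil"):
        raise ValueError("source must be 'isotropic' or 'pencil'")
    if map_half_um is None:
        map_half_um = max(300.0, 3.0 * geometry.source_depth_um)
    nbins = max(2, int(round(2 * map_half_um / map_bin_um)))
    use_table = 1 if medium.phase_function == "mie" else 0
    if use_table:
        tab_mu, tab_cdf = medium.phase_table
        tab_mu = np.ascontiguousarray(tab_mu, dtype=np.float64)
        tab_cdf = np.ascontiguousarray(tab_cdf, dtype=np.float64)
    else:
        tab_mu = np.zeros(2)
        tab_cdf = np.array([0.0, 1.0])
    na_cos = math.sqrt(max(0.0, 1.0 - geometry.collection_na**2)) \
        if geometry.collection_na else -1.0
    smap, etop, ebot, absd, ball, over = _transport(
        int(n_photons), int(seed) & 0x7FFFFFFF,
        medium.mus_per_mm * 1e-3, medium.mua_per_mm * 1e-3, medium.g,
        use_table, tab_mu, tab_cdf,
        medium.n, geometry.n_above, geometry.n_below,
        float(geometry.thickness_um), float(geometry.source_depth_um),
        1 if source == "pencil" else 0,
        geometry.configuration == "slab_overlayer",
        float(map_half_um), nbins, na_cos,
        roulette_threshold, roulette_survive)
    centers = -map_half_um + map_bin_um * (np.arange(nbins) + 0.5)
    inv = 1.0 / n_photons
    return McResult(
        surface_map=IntensityMap(centers, centers, smap * inv),
        exit_top=etop * inv, exit_bottom=ebot * inv, absorbed=absd * inv,
        ballistic_bottom=ball * inv, overflow=over * inv,
        n_photons=int(n_photons), seed=int(seed),
        geometry=geometry.configuration)


# ---------------------------------------------------------------------------
# depth calibration


def build_calibration(
    medium: OpticalMedium,
    depths_um,
    geometry: str = "slab_overlayer",
    n_photons: int = 200_000,
    seed: int = 1,
    metric: str = "sigma",
    embedded_margin_lstar: float = 4.0,
    n_above: float = 1.0,
    n_below: float = 1.34,
    map_half_um: float | None = None,
) -> CalibrationCurve:
    """Simulated (depth, surface-footprint width) calibration curve.

    One Monte Carlo run per depth; the footprint width is measured with
    :func:`dsli.hsi.surface_width` using the same metric the curve will be
    queried with.  Widths must come out strictly increasing with depth —
    if they do not, the photon budget is too small for the depth grid.
    """
    depths = sorted(float(d) for d in depths_um)
    if len(depths) < 3:
        raise ValueError("need at least 3 calibration depths")
    l_star, _ = transport_length(medium)
    if map_half_um is None:
        # one common extent for all knots: the width metric must see the
        # same truncation at every depth
        map_half_um = max(300.0, 3.0 * depths[-1])
    widths = []
    for k, depth in enumerate(depths):
        if geometry == "slab_overlayer":
            geo = McGeometry("slab_overlayer", thickness_um=depth,
                             source_depth_um=depth,
                             n_above=n_above, n_below=n_below)
        else:
            geo = McGeometry("embedded",
                             thickness_um=depth + embedded_margin_lstar * l_star,
                             source_depth_um=depth,
                             n_above=n_above, n_below=n_below)
        res = run_mc(medium, geo, n_photons=n_photons, seed=seed + 1000 * k,
                     map_half_um=map_half_um)
        widths.append(surface_width(res.surface_map, metric=metric))
    if np.any(np.diff(widths) <= 0):
        raise ValueError(
            "footprint widths not strictly increasing with depth; "
            "increase n_photons or thin out the depth grid")
    return CalibrationCurve(
        depth_um=np.array(depths), width_um=np.array(widths),
        metric=metric, geometry=geometry,
        medium_summary=(f"mus={medium.mus_per_mm}/mm mua={medium.mua_per_mm}/mm "
                        f"g={medium.g} n={medium.n}"))


# ---------------------------------------------------------------------------
# integrating sphere


def integrating_sphere_rt(
    medium: OpticalMedium,
    thickness_um: float,
    n_photons: int = 100_000,
    seed: int = 1,
) -> tuple[float, float]:
    """Total transmittance and reflectance of a free-standing slab.

    Collimated normal-incidence beam, Fresnel boundaries against air on
    both faces (the slab is placed on an integrating-sphere port).
    Returns ``(T, R)``; R includes the specular component, so in the
    thin-slab limit T -> 1 - specular and R -> specular.
    """
    geo = McGeometry("embedded", thickness_um=thickness_um,
                     source_depth_um=0.0, n_above=1.0, n_below=1.0)
    res = run_mc(medium, geo, n_photons=n_photons, seed=seed,
                 source="pencil", map_half_um=300.0)
    return res.exit_bottom, res.exit_top


def invert_optical_properties(
    r_measured: float,
    t_measured: float,
    thickness_um: float,
    mus_range_per_mm: tuple[float, float] = (20.0, 120.0),
    g_range: tuple[float, float] = (0.5, 0.98),
    mua_per_mm: float = 0.2,
    n: float = 1.4,
    n_photons: int = 20_000,
    seed: int = 1,
    n_grid: tuple[int, int] = (11, 9),
):
    """Estimate (mu_s, g) from measured integrating-sphere R and T.

    Runs the forward simulation over a (mu_s, g) grid and minimizes the
    squared mismatch of (R, T).  Because R and T constrain essentially
    mu_s(1-g) plus one weaker combination, the residual surface often has
    a valley; the full goodness map is returned so the caller can see it.

    Returns ``(mus, g, residual_map, status)`` with status "ok" or
    "boundary" when the optimum lies on the search-range edge (range too
    narrow).
    """
    if not (0 < r_measured < 1 and 0 < t_measured < 1):
        raise ValueError("R and T must be in (0, 1)")
    mus_vals = np.linspace(*mus_range_per_mm, n_grid[0])
    g_vals = np.linspace(*g_range, n_grid[1])
    resid = np.empty((n_grid[0], n_grid[1]))
    for i, mus in enumerate(mus_vals):
        for j, g in enumerate(g_vals):
            med = OpticalMedium(mus_per_mm=mus, mua_per_mm=mua_per_mm,
                                g=g, n=n)
            t_sim, r_sim = integrating_sphere_rt(
                med, thickness_um, n_photons=n_photons,
                seed=seed + 37 * i + j)
            resid[i, j] = (r_sim - r_measured) ** 2 + (t_sim - t_measured) ** 2
    i0, j0 = np.unravel_index(np.argmin(resid), resid.shape)
    status = "ok"
    if i0 in (0, n_grid[0] - 1) or j0 in (0, n_grid[1] - 1):
        status = "boundary"
        log.warning("inversion optimum on search-range boundary")
    return float(mus_vals[i0]), float(g_vals[j0]), resid, status
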