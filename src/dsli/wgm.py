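"""Whispering-gallery-mode eigenwavelengths of dielectric microspheres.

A dye-doped polystyrene bead of diameter ``d`` supports optical resonances
(whispering-gallery modes, WGMs) whose vacuum wavelengths are set by three
numbers only: the diameter, the internal refractive index and the refractive
index of the surroundings.  Matching the electromagnetic boundary conditions
on the sphere surface yields one characteristic equation per polarization
(TE / TM) and angular order ``l``; its roots in wavelength are the modes,
indexed by radial order ``q`` (q = 1 is the outermost, highest-Q family).

For the high-Q modes relevant here the outgoing spherical Hankel function is
replaced by the spherical Neumann function, which turns the complex
eigenfrequency problem into a real root search — the standard approximation
for narrow resonances.  Radial orders are assigned by counting roots downward
in wavelength from the angular-momentum cutoff (internal size parameter
``x = l + 1/2``), above which no confined mode exists.

All wavelengths are vacuum wavelengths in nm; diameters and radii in um.
Conversion from air wavelengths, if an instrument reports them, is the
caller's responsibility.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.interpolate import CubicSpline
from scipy.special import ai_zeros, spherical_jn, spherical_yn

log = logging.getLogger(__name__)

__all__ = [
    "Polarization",
    "SphereParams",
    "LayeredSphereParams",
    "ModeId",
    "ModeSet",
    "WgmFitResult",
    "characteristic_residual",
    "find_modes",
    "find_modes_layered",
    "fsr_estimate",
    "fit_size_index",
    "size_from_fsr",
]

# negatives of the first Airy-function zeros, used in the asymptotic
# estimate of where the q-th radial mode sits relative to the cutoff
_AIRY_ZEROS = -ai_zeros(8)[0]  # 2.338, 4.088, 5.521, ...


class Polarization(str, Enum):
    TE = "TE"
    TM = "TM"


@dataclass(frozen=True)
class SphereParams:
    """Geometry and indices of a bare microsphere resonator."""

    diameter: float  # um
    n_internal: float
    n_external: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.n_external < 1.0 or self.n_internal < 1.0:
            raise ValueError("refractive indices must be >= 1")
        if self.n_internal <= self.n_external:
            warnings.warn(
                "n_internal <= n_external: no confined whispering-gallery "
                "modes exist for this sphere",
                stacklevel=2,
            )


@dataclass(frozen=True)
class LayeredSphereParams:
    """A spherically symmetric multilayer resonator (core + coatings).

    ``layer_radii`` are the interface radii in um, strictly increasing, the
    last one being the outer surface of the outermost coating.
    ``layer_indices`` has one more entry than ``layer_radii``: the core index,
    one index per coating, and finally the index of the surroundings.
    """

    layer_radii: tuple[float, ...]
    layer_indices: tuple[float, ...]

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.layer_radii)
        indices = tuple(float(n) for n in self.layer_indices)
        object.__setattr__(self, "layer_radii", radii)
        object.__setattr__(self, "layer_indices", indices)
        if len(indices) != len(radii) + 1:
            raise ValueError("need one more index than there are interfaces")
        if any(r <= 0 for r in radii) or any(np.diff(radii) <= 0):
            raise ValueError("layer radii must be positive and strictly increasing")
        if any(n < 1.0 for n in indices):
            raise ValueError("refractive indices must be >= 1")

    @property
    def outer_diameter(self) -> float:
        return 2.0 * self.layer_radii[-1]


@dataclass(frozen=True, order=True)
class ModeId:
    polarization: Polarization
    angular_order: int
    radial_order: int

    def __post_init__(self) -> None:
        if self.angular_order < 1 or self.radial_order < 1:
            raise ValueError("angular and radial orders must be >= 1")


@dataclass
class ModeSet:
    """Mode wavelengths of one resonator inside a spectral window."""

    params: SphereParams | LayeredSphereParams
    modes: list[tuple[ModeId, float]] = field(default_factory=list)

    def wavelengths(self, polarization: Polarization | None = None) -> np.ndarray:
        lam = [w for m, w in self.modes
               if polarization is None or m.polarization == polarization]
        return np.asarray(sorted(lam))

    def __len__(self) -> int:
        return len(self.modes)


@dataclass
class WgmFitResult:
    diameter: float  # um
    n_external: float
    residual: float  # mean absolute wavelength mismatch, nm
    matched_modes: list[tuple[float, ModeId]]  # (peak wavelength nm, mode)
    status: str = "ok"  # "ok" | "underdetermined"
    diameter_sigma: float = float("nan")  # um
    n_external_sigma: float = float("nan")


# ---------------------------------------------------------------------------
# characteristic equation


def _riccati(l: int | np.ndarray, z: np.ndarray):
    """Riccati-Bessel psi = z j_l(z), chi = -z y_l(z) and derivatives."""
    jl = spherical_jn(l, z)
    jlp = spherical_jn(l, z, derivative=True)
    yl = spherical_yn(l, z)
    ylp = spherical_yn(l, z, derivative=True)
    psi = z * jl
    psip = jl + z * jlp
    chi = -z * yl
    chip = -(yl + z * ylp)
    return psi, psip, chi, chip


def characteristic_residual(
    params: SphereParams,
    polarization: Polarization,
    angular_order: int,
    wavelength_nm: float | np.ndarray,
):
    """Boundary-condition mismatch of a bare sphere at the given wavelength.

    Returned in a cross-multiplied, normalized form that is free of poles:
    sign changes in wavelength are the eigenmodes.  Vectorized over
    ``wavelength_nm``.

    Raises :class:`FloatingPointError` if the special functions overflow
    (very large angular order far below cutoff) rather than returning NaN.
    """
    lam_um = np.asarray(wavelength_nm, dtype=float) * 1e-3
    if np.any(lam_um <= 0):
        raise ValueError("wavelength must be positive")
    x1 = math.pi * params.diameter * params.n_internal / lam_um
    x2 = math.pi * params.diameter * params.n_external / lam_um
    l = int(angular_order)
    psi, psip, _, _ = _riccati(l, x1)
    _, _, chi, chip = _riccati(l, x2)
    if polarization == Polarization.TE:
        t1 = params.n_internal * psip * chi
        t2 = params.n_external * psi * chip
    else:
        t1 = params.n_external * psip * chi
        t2 = params.n_internal * psi * chip
    res = (t1 - t2) / (np.abs(t1) + np.abs(t2) + 1e-300)
    if not np.all(np.isfinite(res)):
        raise FloatingPointError(
            f"characteristic equation unevaluable for l={l} "
            "(special-function overflow)"
        )
    return res


def _layered_residual(
    params: LayeredSphereParams,
    polarization: Polarization,
    angular_order: int,
    wavelength_nm: float | np.ndarray,
):
    """Transfer-matrix residual for a multilayer sphere (vectorized).

    The field in each layer is b*psi + c*chi in that layer's optical
    coordinate; coefficients are propagated outward by matching the
    tangential fields at every interface.  A confined mode has no psi
    (standing regular) component outside, so the residual is the outer
    b coefficient, normalized.
    """
    lam_um = np.atleast_1d(np.asarray(wavelength_nm, dtype=float)) * 1e-3
    l = int(angular_order)
    k = 2.0 * math.pi / lam_um  # 1/um
    te = polarization == Polarization.TE

    b = np.ones_like(lam_um)
    c = np.zeros_like(lam_um)
    indices = params.layer_indices
    for i, r in enumerate(params.layer_radii):
        n_in, n_out = indices[i], indices[i + 1]
        eta_in = n_in if te else 1.0 / n_in
        eta_out = n_out if te else 1.0 / n_out
        psi_i, psip_i, chi_i, chip_i = _riccati(l, n_in * k * r)
        F = b * psi_i + c * chi_i
        G = eta_in * (b * psip_i + c * chip_i)
        psi_o, psip_o, chi_o, chip_o = _riccati(l, n_out * k * r)
        # solve [[psi_o, chi_o], [eta_out psip_o, eta_out chip_o]] @ (b,c) = (F,G)
        det = eta_out * (psi_o * chip_o - chi_o * psip_o)  # = -eta_out
        b = (F * eta_out * chip_o - G * chi_o) / det
        c = (G * psi_o - F * eta_out * psip_o) / det
        norm = np.maximum(np.abs(b), np.abs(c))
        norm = np.where(norm > 0, norm, 1.0)
        b, c = b / norm, c / norm
    res = b / (np.hypot(b, c) + 1e-300)
    if not np.all(np.isfinite(res)):
        raise FloatingPointError(
            f"layered characteristic equation unevaluable for l={l}"
        )
    if np.isscalar(wavelength_nm):
        return float(res[0])
    return res


# ---------------------------------------------------------------------------
# mode finding


def _residual_fn(params, polarization, l):
    if isinstance(params, LayeredSphereParams):
        return lambda lam: _layered_residual(params, polarization, l, lam)
    return lambda lam: characteristic_residual(params, polarization, l, lam)


def _scan_params(params):
    """Upper and lower bounds on the mode scale ``pi * d * n`` (um).

    The upper bound (outer diameter, highest guiding index) sets where the
    downward scan must start so no root is missed above it; the lower bound
    (core diameter, lowest guiding index) decides when scanning smaller
    angular orders can safely stop.
    """
    if isinstance(params, LayeredSphereParams):
        inner = params.layer_indices[:-1]
        hi = math.pi * params.outer_diameter * max(inner)
        lo = math.pi * 2.0 * params.layer_radii[0] * min(inner)
        return hi, lo
    s = math.pi * params.diameter * params.n_internal
    return s, s


def _roots_for_l(params, polarization, l, lam_min, max_radial_order,
                 grid_step=0.05, xtol=1e-7):
    """Roots (descending wavelength) for one angular order, labelled q=1.. .

    Scans downward from the cutoff wavelength so the root count equals the
    radial order; stops once ``max_radial_order`` roots are found.
    """
    scale_hi, _ = _scan_params(params)
    nu = l + 0.5
    lam_cut = 1e3 * scale_hi / nu  # nm, x = nu
    if lam_cut <= lam_min:
        return []
    f = _residual_fn(params, polarization, l)
    roots: list[float] = []
    lo_limit = lam_min - 1e-9
    hi = lam_cut
    # scan in chunks so we can stop early once enough roots are found
    chunk = 400
    grid_hi = hi
    while grid_hi > lo_limit and len(roots) < max_radial_order:
        grid = grid_hi - grid_step * np.arange(chunk + 1)
        grid = grid[grid >= lo_limit - grid_step]
        if len(grid) < 2:
            break
        vals = f(grid)
        sign = np.sign(vals)
        flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        for i in flips:
            r = optimize.brentq(f, grid[i + 1], grid[i], xtol=xtol)
            roots.append(float(r))
            if len(roots) >= max_radial_order:
                break
        grid_hi = grid[-1]
    return roots


def find_modes(
    params: SphereParams,
    window: tuple[float, float],
    max_radial_order: int = 2,
    grid_step: float = 0.05,
) -> ModeSet:
    """All TE and TM eigenwavelengths inside ``window`` (nm), labelled.

    ``grid_step`` is the bracketing resolution in nm; 0.05 nm is safe for the
    ~3.6 nm free spectral range of a 15 um bead and each bracketed root is
    polished to well below 1e-6 nm.
    """
    lam_min, lam_max = float(window[0]), float(window[1])
    if lam_min >= lam_max:
        raise ValueError("window must be (min, max) with min < max")
    if max_radial_order < 1:
        raise ValueError("max_radial_order must be >= 1")
    modes: list[tuple[ModeId, float]] = []
    if isinstance(params, SphereParams) and params.n_internal <= params.n_external:
        log.info("index-matched or inverted sphere: no confined modes")
        return ModeSet(params=params, modes=[])
    scale_hi, scale_lo = _scan_params(params)
    scale_hi, scale_lo = 1e3 * scale_hi, 1e3 * scale_lo  # lam_nm = scale / x
    l_max = int(scale_hi / lam_min) + 2
    airy = _AIRY_ZEROS[min(max_radial_order, len(_AIRY_ZEROS)) - 1]
    for pol in (Polarization.TE, Polarization.TM):
        for l in range(l_max, 0, -1):
            nu = l + 0.5
            # asymptotic location of the deepest requested radial order;
            # once it rises above the window, smaller l only move further up
            x_deep = nu + 2.0 ** (-1.0 / 3.0) * airy * nu ** (1.0 / 3.0)
            if scale_lo / x_deep > lam_max + 5.0:
                break
            roots = _roots_for_l(params, pol, l, lam_min, max_radial_order,
                                 grid_step=grid_step)
            for q, lam in enumerate(roots, start=1):
                if lam_min <= lam <= lam_max:
                    modes.append((ModeId(pol, l, q), lam))
    modes.sort(key=lambda t: t[1])
    if not modes:
        log.info("no confined modes in window %s for %s", window, params)
    return ModeSet(params=params, modes=modes)


def find_modes_layered(
    params: LayeredSphereParams,
    window: tuple[float, float],
    max_radial_order: int = 2,
    grid_step: float = 0.05,
) -> ModeSet:
    """Eigenwavelengths of a coated (multilayer) sphere inside ``window``."""
    if not isinstance(params, LayeredSphereParams):
        raise TypeError("params must be LayeredSphereParams")
    return find_modes(params, window, max_radial_order, grid_step)


# ---------------------------------------------------------------------------
# free spectral range


def fsr_estimate(diameter: float, n_internal: float, wavelength_nm: float):
    """Analytic free-spectral-range estimate of a sphere comb.

    Returns ``(fsr_per_um, dlam_nm)``: the mode spacing in 1/lambda (1/um),
    which is wavelength-independent at this order, and the local wavelength
    spacing ``dlam = lambda^2 / (pi n d)`` in nm.
    """
    if diameter <= 0 or n_internal <= 0 or wavelength_nm <= 0:
        raise ValueError("all inputs must be positive")
    fsr = 1.0 / (math.pi * n_internal * diameter)  # 1/um
    lam_um = wavelength_nm * 1e-3
    dlam_nm = 1e3 * lam_um**2 * fsr
    return fsr, dlam_nm


def _peak_wavelengths(peaks: Sequence) -> np.ndarray:
    lam = [p.wavelength_nm if hasattr(p, "wavelength_nm") else float(p)
           for p in peaks]
    return np.asarray(sorted(lam), dtype=float)


def _comb_fsr(lam_nm: np.ndarray) -> float:
    """Robust comb spacing in 1/lambda (1/um) from possibly gappy teeth."""
    inv = np.sort(1.0 / (lam_nm * 1e-3))
    spacings = np.diff(inv)
    spacings = spacings[spacings > 0]
    base = spacings.min()
    mult = np.maximum(1, np.round(spacings / base).astype(int))
    return float(np.median(spacings / mult))


def comb_fsr_mixed(
    lam_nm: Sequence[float],
    fsr_range: tuple[float, float] = (0.010, 0.018),
    kernel_width: float = 1.5e-4,
) -> float:
    """Comb spacing (1/um) of a multi-family comb (TE+TM, several q).

    All sub-combs of one sphere share the free spectral range but differ in
    phase, so adjacent-spacing statistics fail; instead, every pairwise
    1/lambda difference is scored against integer multiples of a candidate
    spacing.  Matches are weighted by the inverse multiple so that
    sub-harmonics (F/2 matches everything with doubled multiples) do not
    win, and the best candidate is refined by least squares over the
    matched differences.
    """
    lam = _peak_wavelengths(lam_nm)
    if len(lam) < 3:
        raise ValueError("need at least 3 peaks")
    nu = np.sort(1.0 / (lam * 1e-3))
    d = (nu[None, :] - nu[:, None])[np.triu_indices(len(nu), 1)]
    d = d[d < 14 * fsr_range[1]]
    n_grid = max(200, int(4 * (fsr_range[1] - fsr_range[0]) / kernel_width))
    Fs = np.linspace(fsr_range[0], fsr_range[1], n_grid)
    m = np.maximum(1, np.round(d[:, None] / Fs[None, :]))
    r = np.abs(d[:, None] - m * Fs[None, :])
    score = np.sum(np.exp(-((r / kernel_width) ** 2)) / m, axis=0)
    F0 = float(Fs[np.argmax(score)])
    for _ in range(3):
        mm = np.maximum(1, np.round(d / F0))
        keep = np.abs(d - mm * F0) < 3 * kernel_width
        if keep.sum() < 2:
            break
        F0 = float(np.sum(d[keep] * mm[keep]) / np.sum(mm[keep] ** 2))
    return F0


def _invert_fsr(fsr: float, n_internal: float, lam_mean_nm: float,
                radial_order: int = 1, n_external_guess: float = 1.35,
                exact: bool = True) -> float:
    """Diameter (um) whose comb spacing at ``lam_mean_nm`` equals ``fsr``."""
    c3 = 2.0 ** (-1.0 / 3.0) * _AIRY_ZEROS[radial_order - 1] / 3.0
    d = 1.0 / (math.pi * n_internal * fsr)  # zeroth-order seed
    for _ in range(3):
        nu = math.pi * d * n_internal / (lam_mean_nm * 1e-3)
        d = (1.0 + c3 * nu ** (-2.0 / 3.0)) / (math.pi * n_internal * fsr)
    if not exact:
        return d
    try:
        for _ in range(3):
            f_model = _model_fsr(d, n_internal, lam_mean_nm, radial_order,
                                 min(n_external_guess, n_internal - 0.01))
            d *= f_model / fsr
            if abs(f_model / fsr - 1.0) < 1e-7:
                break
    except (RuntimeError, FloatingPointError):
        log.warning("exact FSR refinement failed; analytic inversion kept")
    return d


def _model_fsr(d, n_internal, lam_center_nm, radial_order, n_external):
    """Exact comb spacing in 1/lambda (1/um) near ``lam_center_nm``."""
    half = 2.5e3 * lam_center_nm**2 * 1e-6 / (math.pi * n_internal * d)
    ms = find_modes(SphereParams(d, n_internal, n_external),
                    (lam_center_nm - half, lam_center_nm + half),
                    max_radial_order=radial_order)
    lam = sorted(w for m, w in ms.modes
                 if m.polarization == Polarization.TE
                 and m.radial_order == radial_order)
    if len(lam) < 2:
        raise RuntimeError("could not bracket two adjacent modes")
    inv = 1.0 / (np.asarray(lam) * 1e-3)
    return float(np.mean(-np.diff(inv)))


def size_from_fsr(
    peaks: Sequence,
    n_internal: float,
    radial_order: int = 1,
    n_external_guess: float = 1.35,
) -> tuple[float, float]:
    """Diameter (um) and its uncertainty from the comb spacing alone.

    Inverts the observed 1/lambda spacing through the sphere dispersion
    relation: an analytic seed (with the leading Airy-expansion curvature
    correction — without it the naive d = 1/(pi n FSR) is biased by ~2% at
    these size parameters) is refined against the spacing of exactly
    computed modes.  The comb is assumed single-polarization at the given
    radial order (TE is used for the model; the TE/TM spacing difference is
    ~5e-4 relative).  The spacing itself is almost independent of the
    external index, so only a rough guess of it is needed.  Missing teeth
    are tolerated by dividing each adjacent spacing by its nearest integer
    multiple of the smallest one.
    """
    lam = _peak_wavelengths(peaks)
    if len(lam) < 2:
        raise ValueError("need at least 2 peaks of the same comb")
    fsr = _comb_fsr(lam)
    d = _invert_fsr(fsr, n_internal, float(np.mean(lam)), radial_order,
                    n_external_guess)
    # uncertainty: spacing scatter propagated, floored at the 6 nm scale
    # that FSR-only sizing supports with a handful of teeth
    inv = np.sort(1.0 / (lam * 1e-3))
    spac = np.diff(inv)
    mult = np.maximum(1, np.round(spac / spac.min()).astype(int))
    rel = float(np.std(spac / mult) / fsr) / max(1, len(lam) - 1) ** 0.5
    sigma = max(d * rel, 0.006 / max(1, len(lam) - 1) ** 0.5)
    if len(lam) == 2:
        sigma = max(sigma, 0.006)
    return d, sigma


# ---------------------------------------------------------------------------
# size + external index fitting


def _greedy_assign(peaks_nm: np.ndarray, modes_nm: np.ndarray,
                   penalty_nm: float = 5.0):
    """One-to-one nearest assignment of peaks to modes, smallest gaps first.

    Returns (mean absolute mismatch in nm, list of (peak index, mode index)),
    unmatched peaks contributing ``penalty_nm`` each.
    """
    if len(modes_nm) == 0:
        return penalty_nm, []
    diff = np.abs(peaks_nm[:, None] - modes_nm[None, :])
    order = np.argsort(diff, axis=None, kind="stable")
    used_p = np.zeros(len(peaks_nm), bool)
    used_m = np.zeros(len(modes_nm), bool)
    pairs = []
    total = 0.0
    for flat in order:
        i, j = divmod(int(flat), len(modes_nm))
        if used_p[i] or used_m[j]:
            continue
        used_p[i] = used_m[j] = True
        pairs.append((i, j))
        total += diff[i, j]
        if used_p.all() or used_m.all():
            break
    n_unmatched = int((~used_p).sum())
    total += n_unmatched * penalty_nm
    return total / len(peaks_nm), pairs


def _mode_table(d_ref, n_internal, n_grid, window, max_radial_order):
    """Per-(pol, l, q) cubic splines of mode wavelength vs external index.

    Exploits exact scale invariance: at fixed indices every mode wavelength
    is proportional to the diameter, so one reference-diameter table covers
    the whole diameter search range.
    """
    per_n = []
    for n_ext in n_grid:
        ms = find_modes(SphereParams(d_ref, n_internal, n_ext), window,
                        max_radial_order)
        per_n.append(dict((m, w) for m, w in ms.modes))
    common = set(per_n[0])
    for dd in per_n[1:]:
        common &= set(dd)
    labels = sorted(common)
    table = np.array([[dd[m] for m in labels] for dd in per_n])  # (n, label)
    splines = CubicSpline(n_grid, table, axis=0)
    return labels, splines


def _polish_modes(params, labels, lam_guess, half_nm=0.8, iters=48):
    """Exact mode wavelengths near predicted positions, vectorized bisection.

    Returns an array aligned with ``labels``; NaN where no sign change was
    bracketed (label drifted out of validity).
    """
    out = np.full(len(labels), np.nan)
    for pol in (Polarization.TE, Polarization.TM):
        idx = [k for k, m in enumerate(labels) if m.polarization == pol]
        if not idx:
            continue
        ls = np.array([labels[k].angular_order for k in idx])
        lo = np.array([lam_guess[k] for k in idx]) - half_nm
        hi = lo + 2 * half_nm
        if isinstance(params, LayeredSphereParams):
            def f(lam, ls=ls, pol=pol):
                return np.array([
                    _layered_residual(params, pol, l, w)
                    for l, w in zip(ls, lam)])
        else:
            def f(lam, ls=ls, pol=pol):
                lam_um = lam * 1e-3
                x1 = math.pi * params.diameter * params.n_internal / lam_um
                x2 = math.pi * params.diameter * params.n_external / lam_um
                psi, psip, _, _ = _riccati(ls, x1)
                _, _, chi, chip = _riccati(ls, x2)
                if pol == Polarization.TE:
                    t1 = params.n_internal * psip * chi
                    t2 = params.n_external * psi * chip
                else:
                    t1 = params.n_external * psip * chi
                    t2 = params.n_internal * psi * chip
                return (t1 - t2) / (np.abs(t1) + np.abs(t2) + 1e-300)

        flo, fhi = f(lo), f(hi)
        ok = flo * fhi < 0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            fm = f(mid)
            left = flo * fm <= 0
            hi = np.where(left, mid, hi)
            fhi = np.where(left, fm, fhi)
            lo = np.where(left, lo, mid)
            flo = np.where(left, flo, fm)
        res = 0.5 * (lo + hi)
        res[~ok] = np.nan
        for k, v in zip(idx, res):
            out[k] = v
    return out


def fit_size_index(
    peaks: Sequence,
    n_internal: float,
    d_range: tuple[float, float] = (12.0, 18.0),
    n_ext_range: tuple[float, float] = (1.33, 1.40),
    max_radial_order: int = 2,
    coarse_dd_um: float = 0.005,
    coarse_dn: float = 5e-4,
    n_table_points: int = 13,
    min_peaks: int = 4,
) -> WgmFitResult:
    """Retrieve diameter and external index from a measured peak comb.

    The internal index must be known; the remaining two parameters are found
    by overlapping the measured peaks with theoretical mode positions over a
    (diameter, external index) search region.  The search is seeded by
    FSR-only sizing (which pins the diameter to ~0.1% and thereby excludes
    the comb-aliasing local minima one whole tooth away), scanned on a coarse
    grid through a scale-invariant mode-position table, and polished against
    the exact characteristic equation.

    Fewer than ``min_peaks`` peaks cannot constrain both parameters; the
    result then falls back to FSR-only sizing with status "underdetermined".
    """
    lam = _peak_wavelengths(peaks)
    if len(lam) < 2:
        raise ValueError("need at least 2 peaks")
    # seed the diameter from the comb spacing of the full (mixed TE/TM,
    # multi-q) comb; this pins d well inside one tooth of the comb-aliasing
    # ambiguity (one tooth ~ 0.8% of d)
    fsr_lo = 1.0 / (math.pi * n_internal * d_range[1]) * 0.95
    fsr_hi = 1.0 / (math.pi * n_internal * d_range[0]) * 1.1
    if len(lam) >= 3:
        fsr0 = comb_fsr_mixed(lam, (fsr_lo, fsr_hi))
    else:
        fsr0 = _comb_fsr(lam)
    d_fsr = _invert_fsr(fsr0, n_internal, float(np.mean(lam)))
    d_sig = 0.006 / max(1, len(lam) - 1) ** 0.5
    if len(lam) < min_peaks:
        return WgmFitResult(
            diameter=d_fsr, n_external=float("nan"), residual=float("nan"),
            matched_modes=[], status="underdetermined",
            diameter_sigma=max(d_sig, 0.006))

    d_center = min(max(d_fsr, d_range[0]), d_range[1])
    d_lo = max(d_range[0], d_center - 0.03)
    d_hi = min(d_range[1], d_center + 0.03)
    d_ref = 0.5 * (d_lo + d_hi)
    span = lam[-1] - lam[0]
    pad = 2.5 + span * (d_hi / d_lo - 1.0)
    window = (lam[0] - pad, lam[-1] + pad)
    n_grid = np.linspace(n_ext_range[0], n_ext_range[1], n_table_points)
    labels, splines = _mode_table(d_ref, n_internal, n_grid, window,
                                  max_radial_order)
    if not labels:
        return WgmFitResult(d_fsr, float("nan"), float("nan"), [],
                            status="underdetermined", diameter_sigma=d_sig)

    def table_metric(d, n_ext):
        modes = splines(n_ext) * (d / d_ref)
        m, _ = _greedy_assign(lam, modes)
        return m

    ds = np.arange(d_lo, d_hi + coarse_dd_um / 2, coarse_dd_um)
    ns = np.arange(n_ext_range[0], n_ext_range[1] + coarse_dn / 2, coarse_dn)
    best = (np.inf, d_ref, float(ns[0]))
    for n_ext in ns:
        modes_ref = splines(float(n_ext))
        for d in ds:
            m, _ = _greedy_assign(lam, modes_ref * (d / d_ref))
            if m < best[0]:
                best = (m, float(d), float(n_ext))
    # local refinement on the interpolated landscape
    res = optimize.minimize(
        lambda p: table_metric(p[0], p[1]), x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400})
    d_opt, n_opt = float(res.x[0]), float(res.x[1])
    n_opt = min(max(n_opt, n_ext_range[0]), n_ext_range[1])

    # fix the mode assignment at the table optimum, then polish against the
    # exact characteristic equation
    modes_opt = splines(n_opt) * (d_opt / d_ref)
    _, pairs = _greedy_assign(lam, modes_opt)
    fit_labels = [labels[j] for _, j in pairs]
    fit_peaks = np.array([lam[i] for i, _ in pairs])

    def exact_metric(p):
        d, n_ext = p
        if d <= 0 or n_ext <= 1.0 or n_ext >= n_internal:
            return 1e3
        sp = SphereParams(d, n_internal, n_ext)
        guess = splines(min(max(n_ext, n_grid[0]), n_grid[-1])) * (d / d_ref)
        guess = np.array([guess[labels.index(m)] for m in fit_labels])
        exact = _polish_modes(sp, fit_labels, guess)
        bad = np.isnan(exact)
        vals = np.abs(fit_peaks - exact)
        vals[bad] = 5.0
        return float(np.mean(vals))

    res2 = optimize.minimize(
        exact_metric, x0=[d_opt, n_opt], method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 160})
    d_fin, n_fin = float(res2.x[0]), float(res2.x[1])
    resid = float(res2.fun)
    matched = [(float(w), m) for w, m in zip(fit_peaks, fit_labels)]
    status = "ok"
    if resid > 0.1:  # nm: worse than a linewidth -> the fit is not trusted
        status = "underdetermined"
    return WgmFitResult(
        diameter=d_fin, n_external=n_fin, residual=resid,
        matched_modes=matched, status=status,
        diameter_sigma=d_sig)
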