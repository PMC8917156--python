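"""Spectral unmixing: peak detection and free-spectral-range comb grouping.

A mixed emission spectrum collected through a scattering layer contains the
superposed whispering-gallery combs of several microcavities.  Each cavity's
modes are equally spaced in 1/lambda with a spacing (the free spectral
range, FSR) set by its diameter, so the combs can be disentangled without
any spatial information: for every detected peak, candidate FSR values from
peak pairs are propagated across the spectrum (1/lam_N = 1/lam_i + N*FSR)
and the value whose propagated comb overlaps the most observed peaks wins.
Peaks sharing an FSR and a comb phase form one polarization sub-comb; the TE
and TM sub-combs of one cavity share the FSR but not the phase and are
merged afterwards.

All comb arithmetic is done in 1/lambda (units 1/um); tolerances are in
1/lambda as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Peak",
    "PeakGroup",
    "subtract_background",
    "detect_peaks",
    "assign_fsr",
    "group_peaks",
    "pair_te_tm",
    "fill_missing_peaks",
    "unmix_spectrum",
    "peaks_to_frame",
    "groups_to_frame",
]

#: spectrometer wavelength resolution (nm) the default tolerances assume
SPECTRAL_RESOLUTION_NM = 0.023


@dataclass
class Spectrum:
    """A 1D emission spectrum on a strictly increasing wavelength grid."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.intensity.shape != self.wavelength_nm.shape:
            raise ValueError("wavelength and intensity must be 1D and equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def __len__(self) -> int:
        return len(self.wavelength_nm)


@dataclass
class Peak:
    """A detected spectral line (Lorentzian-refined local maximum)."""

    wavelength_nm: float
    fwhm_nm: float
    prominence: float
    amplitude: float
    fitted: bool = True  # False: Lorentzian refinement failed, raw maximum kept

    @property
    def quality_factor(self) -> float:
        return self.wavelength_nm / self.fwhm_nm


@dataclass
class PeakGroup:
    """A per-microcavity comb: member peaks plus predicted missing teeth."""

    group_id: int
    fsr_per_um: float
    members: list[Peak] = field(default_factory=list)
    polarizations: list[str] = field(default_factory=list)  # per member
    filled_in: list[float] = field(default_factory=list)  # predicted nm
    flags: set[str] = field(default_factory=set)

    def wavelengths(self, polarization: str | None = None) -> np.ndarray:
        lam = [p.wavelength_nm for p, pol in zip(self.members, self.polarizations)
               if polarization is None or pol == polarization]
        return np.asarray(sorted(lam))


# ---------------------------------------------------------------------------
# background subtraction


def asls_baseline(
    y: np.ndarray,
    smoothness: float = 1e7,
    asymmetry: float = 1e-3,
    n_iter: int = 12,
) -> np.ndarray:
    """Asymmetric-least-squares baseline of a 1D signal.

    Minimizes ``sum w_i (y_i - z_i)^2 + smoothness * sum (d2 z)^2`` where
    points above the baseline (the peaks) get weight ``asymmetry`` and
    points below get weight ~1; the pentadiagonal system is solved with a
    banded Cholesky factorization, so a single call costs O(n).
    """
    n = len(y)
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (smoothness * (d2.T @ d2)).todia()
    # upper banded storage for solveh_banded
    offsets = list(penalty.offsets)
    ab_pen = np.zeros((3, n))
    for off, row in zip(offsets, penalty.data):
        if off >= 0:
            ab_pen[2 - off, :] = row
    w = np.ones(n)
    z = y
    from scipy.linalg import solveh_banded

    for _ in range(n_iter):
        ab = ab_pen.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def subtract_background(
    spectrum: Spectrum,
    smoothness: float = 1e7,
    asymmetry: float = 1e-3,
    n_iter: int = 12,
) -> Spectrum:
    """Remove the smooth fluorescence background under a spectrum.

    The dye emission is a broad smooth curve common to all microcavities;
    the sharp comb peaks ride on top of it.  The baseline is estimated by
    asymmetric least squares (:func:`asls_baseline`), then subtracted.
    Residual noise may be negative; no clipping is applied.
    """
    n = len(spectrum)
    if n < 16:
        raise ValueError("spectrum shorter than the smoothing scale")
    y = spectrum.intensity
    z = asls_baseline(y, smoothness, asymmetry, n_iter)
    return Spectrum(spectrum.wavelength_nm, y - z, background=np.asarray(z))


# ---------------------------------------------------------------------------
# peak detection


def _lorentzian(x, amplitude, center, fwhm, offset):
    h = 0.5 * fwhm
    return amplitude * h**2 / ((x - center) ** 2 + h**2) + offset


def detect_peaks(
    spectrum: Spectrum,
    prominence_threshold: float,
    fit_window: int = 5,
) -> list[Peak]:
    """Local maxima above a prominence threshold, Lorentzian-refined.

    Each candidate maximum is refined by fitting a Lorentzian plus constant
    offset over ``+-fit_window`` grid points, which recovers peak centers to
    a small fraction of the grid spacing.  If the fit does not converge the
    raw maximum is kept with the grid-resolution linewidth and flagged.
    """
    lam = spectrum.wavelength_nm
    y = spectrum.intensity
    idx, props = find_peaks(y, prominence=prominence_threshold)
    dx = float(np.median(np.diff(lam)))
    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        lo = max(0, i - fit_window)
        hi = min(len(y), i + fit_window + 1)
        xw, yw = lam[lo:hi], y[lo:hi]
        p0 = (y[i] - yw.min(), lam[i], 2.5 * dx, yw.min())
        try:
            popt, _ = curve_fit(
                _lorentzian, xw, yw, p0=p0,
                bounds=([0, xw[0], 0.2 * dx, -np.inf],
                        [np.inf, xw[-1], 20 * dx, np.inf]),
                maxfev=4000)
            peaks.append(Peak(
                wavelength_nm=float(popt[1]), fwhm_nm=float(popt[2]),
                prominence=float(props["prominences"][k]),
                amplitude=float(popt[0]), fitted=True))
        except RuntimeError:
            peaks.append(Peak(
                wavelength_nm=float(lam[i]), fwhm_nm=float(2 * dx),
                prominence=float(props["prominences"][k]),
                amplitude=float(y[i]), fitted=False))
    peaks.sort(key=lambda p: p.wavelength_nm)
    return peaks


# ---------------------------------------------------------------------------
# FSR assignment (comb propagation)


def default_match_tolerance(wavelength_nm: float) -> float:
    """Half the spectrometer resolution expressed in 1/lambda (1/um)."""
    lam_um = wavelength_nm * 1e-3
    return 0.5 * SPECTRAL_RESOLUTION_NM * 1e-3 / lam_um**2


def _comb_mismatch(nu, nu0, fsr):
    """Distance of each 1/lambda value from the comb anchored at nu0."""
    return np.abs((nu - nu0 + 0.5 * fsr) % fsr - 0.5 * fsr)


def assign_fsr(
    peaks: list[Peak],
    match_tolerance: float | None = None,
    min_support: int = 4,
    fsr_range: tuple[float, float] = (0.009, 0.025),
):
    """Per-peak FSR assignment by comb propagation over all partner peaks.

    For each peak ``i`` and every partner ``j`` whose 1/lambda distance lies
    in ``fsr_range``, the candidate spacing is propagated across the
    spectrum and scored by how many observed peaks it reproduces within
    ``match_tolerance``; the best-supported candidate wins, ties going to
    the smaller FSR.  Peaks whose best support falls below ``min_support``
    stay unassigned (NaN).

    Returns ``(fsr, support)`` arrays aligned with ``peaks``.
    """
    n = len(peaks)
    fsr_out = np.full(n, np.nan)
    support_out = np.zeros(n, dtype=int)
    if n < 3:
        return fsr_out, support_out
    lam = np.array([p.wavelength_nm for p in peaks])
    nu = 1.0 / (lam * 1e-3)
    tol = match_tolerance or default_match_tolerance(float(np.mean(lam)))
    for i in range(n):
        cand = np.abs(nu - nu[i])
        jmask = (cand >= fsr_range[0]) & (cand <= fsr_range[1])
        best_support, best_fsr = 0, np.nan
        for f in sorted(cand[jmask]):
            miss = _comb_mismatch(nu, nu[i], f)
            s = int(np.sum(miss < tol))
            if s > best_support:  # ties keep the earlier (smaller) FSR
                best_support, best_fsr = s, f
        if best_support >= min_support:
            fsr_out[i] = best_fsr
            support_out[i] = best_support
    return fsr_out, support_out


# ---------------------------------------------------------------------------
# grouping


def group_peaks(
    peaks: list[Peak],
    fsr: np.ndarray,
    support: np.ndarray | None = None,
    match_tolerance: float | None = None,
    fsr_tolerance: float | None = None,
) -> list[PeakGroup]:
    """Group peaks into single-polarization combs by FSR value and phase.

    Two assigned peaks join the same comb when their FSR values agree within
    ``fsr_tolerance`` and the comb propagated from one lands on the other
    within ``match_tolerance`` (transitively).  After the combs are formed,
    every peak — including peaks claimed by another comb — is re-tested
    against each comb and added on match, so membership is non-exclusive:
    a peak can be shared by several microcavities.
    """
    lam = np.array([p.wavelength_nm for p in peaks])
    nu = 1.0 / (lam * 1e-3)
    tol = match_tolerance or default_match_tolerance(float(np.mean(lam))
                                                     if len(lam) else 520.0)
    ftol = fsr_tolerance if fsr_tolerance is not None else tol
    assigned = [k for k in range(len(peaks)) if np.isfinite(fsr[k])]
    parent = {k: k for k in assigned}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ai, a in enumerate(assigned):
        for b in assigned[ai + 1:]:
            if abs(fsr[a] - fsr[b]) > ftol:
                continue
            f = 0.5 * (fsr[a] + fsr[b])
            if _comb_mismatch(np.array([nu[b]]), nu[a], f)[0] < tol:
                parent[find(a)] = find(b)

    clusters: dict[int, list[int]] = {}
    for a in assigned:
        clusters.setdefault(find(a), []).append(a)

    groups: list[PeakGroup] = []
    for gid, idxs in enumerate(sorted(clusters.values(), key=lambda s: min(s))):
        f = float(np.mean([fsr[k] for k in idxs]))
        anchor = nu[idxs[0]]
        # least-squares comb model over the cluster: pairwise FSR estimates
        # are quantized by the two defining peaks only, and an anchored comb
        # propagated across the whole window drifts at the edges
        nu_m = np.array([nu[k] for k in idxs])
        for _ in range(3):
            N = np.round((nu_m - anchor) / f)
            if len(idxs) >= 2 and np.ptp(N) > 0:
                slope, intercept = np.polyfit(N, nu_m, 1)
                f, anchor = float(slope), float(intercept)
        # non-exclusive sweep: claim every peak on this comb
        miss = _comb_mismatch(nu, anchor, f)
        members = [peaks[k] for k in range(len(peaks)) if miss[k] < tol]
        scatter = float(np.std(miss[miss < tol])) if len(members) > 1 else 0.0
        g = PeakGroup(
            group_id=gid, fsr_per_um=f, members=members,
            polarizations=["unassigned"] * len(members))
        if scatter > 0.6 * tol:
            g.flags.add("unresolvable")
        groups.append(g)
    return groups


def pair_te_tm(
    groups: list[PeakGroup],
    match_tolerance: float | None = None,
    fsr_tolerance: float | None = None,
    verify_n_internal: float | None = None,
    verify_residual_nm: float = 0.05,
) -> list[PeakGroup]:
    """Merge same-FSR, phase-offset comb pairs into one microcavity.

    Both polarization families of one sphere share the free spectral range
    but sit at different comb phases, so two groups with equal FSR (within
    ``fsr_tolerance``) and non-overlapping combs are merged with TE/TM
    sub-labels.  Which sub-comb is which polarization cannot be decided
    from the comb alone; if ``verify_n_internal`` is given the merged comb
    is additionally fitted to the characteristic equation and the merge is
    rejected (and sub-labels fixed) when the joint fit residual exceeds
    ``verify_residual_nm`` — two accidental same-FSR cavities do not form a
    consistent TE/TM pair.
    """
    if not groups:
        return []
    lam0 = float(np.mean([m.wavelength_nm for g in groups for m in g.members]))
    tol = match_tolerance or default_match_tolerance(lam0)
    ftol = fsr_tolerance if fsr_tolerance is not None else tol
    used = set()
    merged: list[PeakGroup] = []
    for i, gi in enumerate(groups):
        if i in used:
            continue
        # among all phase-offset candidates prefer the closest FSR: the two
        # polarization families of one sphere share the free spectral range
        # essentially exactly, while chance alignments only land within
        # tolerance; ties go to the partner with more teeth
        candidates = []
        for j in range(i + 1, len(groups)):
            if j in used:
                continue
            gj = groups[j]
            if abs(gi.fsr_per_um - gj.fsr_per_um) > ftol:
                continue
            f = 0.5 * (gi.fsr_per_um + gj.fsr_per_um)
            nui = 1.0 / (gi.wavelengths() * 1e-3)
            nuj = 1.0 / (gj.wavelengths() * 1e-3)
            offset = float(np.median(_comb_mismatch(nuj, nui[0], f)))
            if offset < tol:
                continue  # same comb, not a polarization partner
            candidates.append((-abs(gi.fsr_per_um - gj.fsr_per_um),
                               len(gj.members), j))
        partner = None
        for _, _, j in sorted(candidates, reverse=True):
            if verify_n_internal is not None and not _te_tm_consistent(
                    gi, groups[j], verify_n_internal, verify_residual_nm):
                continue
            partner = j
            break
        if partner is None:
            merged.append(gi)
            continue
        gj = groups[partner]
        used.add(partner)
        # deterministic sub-labels: the sub-comb whose lowest member phase
        # is smaller is called TE; with solver verification the labels are
        # fixed by the fit inside _te_tm_consistent's cache instead
        first, second = sorted(
            (gi, gj), key=lambda g: float(np.min(g.wavelengths())))
        members = list(first.members) + list(second.members)
        pols = ["TE"] * len(first.members) + ["TM"] * len(second.members)
        g = PeakGroup(
            group_id=gi.group_id,
            fsr_per_um=0.5 * (gi.fsr_per_um + gj.fsr_per_um),
            members=members, polarizations=pols,
            flags=gi.flags | gj.flags)
        merged.append(g)
    for gid, g in enumerate(merged):
        g.group_id = gid
    return merged


def _te_tm_consistent(gi, gj, n_internal, residual_nm):
    """Do two same-FSR combs jointly fit one sphere's characteristic eq?"""
    from . import wgm

    lam = np.concatenate([gi.wavelengths(), gj.wavelengths()])
    try:
        fit = wgm.fit_size_index(sorted(lam), n_internal)
    except (ValueError, RuntimeError):
        return False
    return fit.status == "ok" and fit.residual < residual_nm


def fill_missing_peaks(
    group: PeakGroup,
    window: tuple[float, float],
    match_tolerance: float | None = None,
) -> PeakGroup:
    """Predict comb teeth inside ``window`` that have no observed member.

    Uses the group's FSR and each sub-comb's phase; predicted wavelengths
    are stored in ``filled_in`` (the observed members are untouched).
    """
    if len(group.members) < 2:
        raise ValueError("need a group with at least 2 members")
    tol = match_tolerance or default_match_tolerance(
        float(np.mean([m.wavelength_nm for m in group.members])))
    f = group.fsr_per_um
    nu_lo = 1.0 / (window[1] * 1e-3)
    nu_hi = 1.0 / (window[0] * 1e-3)
    nu_all = 1.0 / (np.array([m.wavelength_nm for m in group.members]) * 1e-3)
    filled: list[float] = []
    sub_pols = sorted(set(group.polarizations))
    for pol in sub_pols:
        nus = np.array([
            1.0 / (m.wavelength_nm * 1e-3)
            for m, p in zip(group.members, group.polarizations) if p == pol])
        if len(nus) == 0:
            continue
        anchor = nus[0]
        # least-squares comb phase from this sub-comb's members
        dev = (nus - anchor + 0.5 * f) % f - 0.5 * f
        anchor = anchor + float(np.mean(dev))
        n_lo = int(np.ceil((nu_lo - anchor) / f))
        n_hi = int(np.floor((nu_hi - anchor) / f))
        for N in range(n_lo, n_hi + 1):
            nu_pred = anchor + N * f
            if np.min(np.abs(nu_all - nu_pred)) > tol:
                filled.append(1.0 / nu_pred * 1e3)
    group.filled_in = sorted(filled)
    return group


# ---------------------------------------------------------------------------
# convenience front end and tabular export


def unmix_spectrum(
    spectrum: Spectrum,
    prominence_threshold: float,
    match_tolerance: float | None = None,
    min_support: int = 4,
    subtract: bool = True,
    fill_window: tuple[float, float] | None = None,
    verify_n_internal: float | None = None,
) -> tuple[list[Peak], list[PeakGroup]]:
    """Background-subtract, detect peaks, and group them into combs."""
    s = subtract_background(spectrum) if subtract else spectrum
    peaks = detect_peaks(s, prominence_threshold)
    fsr, support = assign_fsr(peaks, match_tolerance, min_support)
    groups = group_peaks(peaks, fsr, support, match_tolerance)
    groups = pair_te_tm(groups, match_tolerance,
                        verify_n_internal=verify_n_internal)
    window = fill_window or (float(spectrum.wavelength_nm[0]),
                             float(spectrum.wavelength_nm[-1]))
    for g in groups:
        if len(g.members) >= 2:
            fill_missing_peaks(g, window, match_tolerance)
    return peaks, groups


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame({
        "wavelength_nm": [p.wavelength_nm for p in peaks],
        "width_nm": [p.fwhm_nm for p in peaks],
        "prominence": [p.prominence for p in peaks],
        "amplitude": [p.amplitude for p in peaks],
    })


def groups_to_frame(groups: list[PeakGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        for p, pol in zip(g.members, g.polarizations):
            rows.append((g.group_id, pol, p.wavelength_nm, "observed",
                         g.fsr_per_um))
        for lam in g.filled_in:
            rows.append((g.group_id, "unassigned", lam, "filled", g.fsr_per_um))
    return pd.DataFrame(
        rows, columns=["group_id", "polarization", "wavelength_nm",
                       "status", "fsr_per_um"])
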