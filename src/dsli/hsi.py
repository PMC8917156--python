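"""Hyperspectral-cube handling and spectral localization.

A pushbroom hyperspectral scan records a full emission spectrum in every
image pixel, giving an (y, x, lambda) cube.  Displaying the cube at one
microcavity's resonance wavelength isolates that cavity's diffuse light
footprint on the sample surface; a 2D Gaussian fit of the footprint gives
its lateral position, and the footprint width — which grows monotonically
with source depth in a scattering medium — gives its depth through a
calibration curve.

Conventions: pixel centers, x right / y down, origin at the first pixel;
all lengths in um, wavelengths in nm.  Cube data axes are ordered
(y, x, wavelength).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import PchipInterpolator

from .unmix import Spectrum, asls_baseline

log = logging.getLogger(__name__)

__all__ = [
    "HyperspectralCube",
    "IntensityMap",
    "Localization2D",
    "CalibrationCurve",
    "read_cube",
    "write_cube",
    "write_map",
    "subtract_background_cube",
    "spectral_sum",
    "slice_at_peak",
    "fit_gaussian2d",
    "localize_microcavity",
    "surface_width",
    "depth_from_width",
    "bin_cube",
]


@dataclass
class HyperspectralCube:
    """(y, x, lambda) intensity data on uniform spatial axes."""

    x_um: np.ndarray
    y_um: np.ndarray
    wavelength_nm: np.ndarray
    data: np.ndarray  # shape (ny, nx, nl)

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.data = np.asarray(self.data)
        for name, ax in (("x_um", self.x_um), ("y_um", self.y_um),
                         ("wavelength_nm", self.wavelength_nm)):
            if ax.ndim != 1 or (len(ax) > 1 and np.any(np.diff(ax) <= 0)):
                raise ValueError(f"{name} must be 1D strictly increasing")
        if self.data.shape != (len(self.y_um), len(self.x_um),
                               len(self.wavelength_nm)):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with axes "
                f"({len(self.y_um)}, {len(self.x_um)}, {len(self.wavelength_nm)})")

    @property
    def pixel_pitch_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0]) if len(self.x_um) > 1 else 1.0


@dataclass
class IntensityMap:
    """A 2D image extracted from a cube over one wavelength band."""

    x_um: np.ndarray
    y_um: np.ndarray
    data: np.ndarray  # (ny, nx)
    band_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.y_um), len(self.x_um)):
            raise ValueError("map shape inconsistent with axes")


@dataclass
class Localization2D:
    """Result of fitting a 2D Gaussian to a diffuse light footprint."""

    x0_um: float
    y0_um: float
    sigma_x_um: float
    sigma_y_um: float
    theta_rad: float
    amplitude: float
    offset: float
    residual: float  # rms residual / fitted amplitude
    status: str = "ok"  # "ok" | "poor" | "centroid-fallback"
    per_peak: list["Localization2D"] = field(default_factory=list)
    scatter_um: float = float("nan")  # spread of per-peak centers
    n_peaks_used: int = 1


@dataclass
class CalibrationCurve:
    """Monotone (depth, surface-footprint width) relation of a medium.

    Built from simulated or measured footprints at known depths; queried
    with the same width metric it was built with.
    """

    depth_um: np.ndarray
    width_um: np.ndarray
    metric: str = "sigma"
    geometry: str = "slab_overlayer"
    medium_summary: str = ""

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.width_um = np.asarray(self.width_um, dtype=float)
        if len(self.depth_um) != len(self.width_um) or len(self.depth_um) < 2:
            raise ValueError("need >= 2 (depth, width) knots of equal length")
        order = np.argsort(self.depth_um)
        self.depth_um = self.depth_um[order]
        self.width_um = self.width_um[order]
        if np.any(np.diff(self.width_um) <= 0):
            raise ValueError("widths must be strictly increasing with depth")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_um": self.depth_um,
                             "width_um": self.width_um})


# ---------------------------------------------------------------------------
# I/O

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_cube(cube: HyperspectralCube, path: str | Path,
               format: str = "hdf5", interleave: str = "bsq") -> None:
    """Write a cube as HDF5 (``/cube`` + ``/axes/*``) or ENVI (.hdr + raw).

    The round trip is lossless (bit-exact for integer counts).  ENVI files
    store the wavelength list and pixel pitch in the header; BSQ and BIL
    interleaves are supported.
    """
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=cube.data)
            g = f.create_group("axes")
            g.create_dataset("x_um", data=cube.x_um)
            g.create_dataset("y_um", data=cube.y_um)
            g.create_dataset("wavelength_nm", data=cube.wavelength_nm)
        return
    if format != "envi":
        raise ValueError(f"unknown format {format!r}")
    ny, nx, nl = cube.data.shape
    dtype = cube.data.dtype
    if dtype not in _ENVI_CODES:
        dtype = np.dtype(np.float64)
    code = _ENVI_CODES[np.dtype(dtype)]
    if interleave == "bsq":  # (bands, lines, samples)
        arr = np.ascontiguousarray(np.moveaxis(cube.data.astype(dtype), 2, 0))
    elif interleave == "bil":  # (lines, bands, samples)
        arr = np.ascontiguousarray(np.moveaxis(cube.data.astype(dtype), 2, 1))
    else:
        raise ValueError("interleave must be 'bsq' or 'bil'")
    raw = path.with_suffix(".raw")
    arr.tofile(raw)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelength_nm)
    pitch_x = cube.x_um[1] - cube.x_um[0] if nx > 1 else 1.0
    pitch_y = cube.y_um[1] - cube.y_um[0] if ny > 1 else 1.0
    hdr = path.with_suffix(".hdr")
    hdr.write_text(
        "ENVI\n"
        f"samples = {nx}\nlines = {ny}\nbands = {nl}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {code}\ninterleave = {interleave}\n"
        f"byte order = {0 if arr.dtype.byteorder in ('<', '=', '|') else 1}\n"
        f"pixel size = {{{pitch_x:.6f}, {pitch_y:.6f}}}\n"
        f"wavelength units = nm\nwavelength = {{{wl}}}\n")


def _parse_envi_header(text: str) -> dict:
    # collapse {...} blocks spanning lines, then parse key = value
    fields: dict[str, str] = {}
    buf = ""
    key = None
    for line in text.splitlines():
        if key is None:
            if "=" not in line:
                continue
            k, v = line.split("=", 1)
            k, v = k.strip().lower(), v.strip()
            if v.startswith("{") and "}" not in v:
                key, buf = k, v
            else:
                fields[k] = v
        else:
            buf += " " + line.strip()
            if "}" in buf:
                fields[key] = buf
                key = None
    return fields


def read_cube(path: str | Path, format: str | None = None) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube` (HDF5 or ENVI)."""
    path = Path(path)
    if format is None:
        format = "envi" if path.suffix.lower() in (".hdr", ".raw") else "hdf5"
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "cube" not in f:
                raise ValueError("HDF5 file has no /cube dataset")
            for ax in ("x_um", "y_um", "wavelength_nm"):
                if f"axes/{ax}" not in f:
                    raise ValueError(f"HDF5 file missing /axes/{ax}")
            return HyperspectralCube(
                x_um=f["axes/x_um"][:], y_um=f["axes/y_um"][:],
                wavelength_nm=f["axes/wavelength_nm"][:], data=f["cube"][:])
    hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    fields = _parse_envi_header(hdr.read_text())
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"ENVI header missing field {req!r}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing field 'wavelength'")
    nx, ny, nl = (int(fields[k]) for k in ("samples", "lines", "bands"))
    dtype = _ENVI_DTYPES[int(fields["data type"])]
    arr = np.fromfile(path.with_suffix(".raw"), dtype=dtype)
    if arr.size != nx * ny * nl:
        raise ValueError(
            f"raw file has {arr.size} values, header implies {nx * ny * nl}")
    inter = fields["interleave"].lower()
    if inter == "bsq":
        data = np.moveaxis(arr.reshape(nl, ny, nx), 0, 2)
    elif inter == "bil":
        data = np.moveaxis(arr.reshape(ny, nl, nx), 1, 2)
    else:
        raise ValueError(f"unsupported interleave {inter!r}")
    wl = np.array([float(v) for v in
                   fields["wavelength"].strip("{} ").split(",")])
    pitch = fields.get("pixel size", "{1, 1}").strip("{} ").split(",")
    px, py = float(pitch[0]), float(pitch[1])
    return HyperspectralCube(
        x_um=np.arange(nx) * px, y_um=np.arange(ny) * py,
        wavelength_nm=wl, data=data)


# ---------------------------------------------------------------------------
# spectral operations


def write_map(m: IntensityMap, path: str | Path) -> None:
    """Export an intensity map as 16-bit TIFF plus a CSV twin.

    The TIFF is scaled to the full 16-bit range (metadata records the
    scale); the CSV keeps the raw values with the coordinate axes.
    """
    import tifffile

    path = Path(path)
    data = m.data.astype(float)
    lo, hi = float(data.min()), float(data.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(
        path.with_suffix(".tif"),
        ((data - lo) * scale).astype(np.uint16),
        metadata={"scale": scale, "offset": lo,
                  "band_nm": list(m.band_nm)})
    df = pd.DataFrame(data, index=m.y_um, columns=m.x_um)
    df.to_csv(path.with_suffix(".csv"))


def subtract_background_cube(cube: HyperspectralCube,
                             smoothness: float = 1e7,
                             asymmetry: float = 1e-3,
                             n_iter: int = 6) -> HyperspectralCube:
    """Per-pixel fluorescence-background subtraction over a whole cube.

    Applies the same asymmetric-least-squares baseline as
    :func:`dsli.unmix.subtract_background` to every pixel spectrum.
    """
    ny, nx, nl = cube.data.shape
    out = np.empty((ny, nx, nl), dtype=float)
    flat = cube.data.reshape(-1, nl)
    outf = out.reshape(-1, nl)
    for i in range(flat.shape[0]):
        y = flat[i].astype(float)
        if y.any():
            outf[i] = y - asls_baseline(y, smoothness, asymmetry, n_iter)
        else:
            outf[i] = 0.0
    return HyperspectralCube(cube.x_um, cube.y_um, cube.wavelength_nm, out)


def spectral_sum(cube: HyperspectralCube,
                 region: np.ndarray | None = None) -> Spectrum:
    """Sum of the pixel spectra over a region (default: the whole field).

    The cube is expected to be background-subtracted already (see
    :func:`subtract_background_cube`); the sum is then the superposition of
    all microcavity combs reaching the detector within the region.
    """
    if region is None:
        region = np.ones(cube.data.shape[:2], dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != cube.data.shape[:2]:
        raise ValueError("region mask shape must match the field")
    if not region.any():
        raise ValueError("empty region")
    total = cube.data[region].sum(axis=0)
    return Spectrum(cube.wavelength_nm, total.astype(float))


def slice_at_peak(cube: HyperspectralCube, center_nm: float,
                  bandwidth_nm: float, sideband: bool = True,
                  avoid_nm=None) -> IntensityMap:
    """Intensity map integrated over a band centered on one spectral peak.

    With the band on one microcavity's resonance, only that microcavity
    contributes and the map is its diffuse surface footprint.  The cube is
    expected to be background-subtracted; with ``sideband`` (default) the
    average of two flanking off-resonance bands is additionally subtracted,
    removing any residual smooth background so the map is unbiased by the
    other emitters' light distributions.  If two cavities share the peak
    wavelength the footprints superpose; comb grouping decides attribution.
    """
    lam = cube.wavelength_nm
    lo, hi = center_nm - bandwidth_nm / 2, center_nm + bandwidth_nm / 2
    if lo < lam[0] or hi > lam[-1]:
        raise ValueError(f"band [{lo:.3f}, {hi:.3f}] nm outside the "
                         f"wavelength grid [{lam[0]:.3f}, {lam[-1]:.3f}] nm")
    sel = (lam >= lo) & (lam <= hi)
    if not sel.any():
        sel[np.argmin(np.abs(lam - center_nm))] = True
    data = cube.data[:, :, sel].sum(axis=2)
    if sideband:
        # several flanking off-resonance bands, combined by a per-pixel
        # median so a band accidentally covering another cavity's comb
        # tooth does not contaminate the estimate; bands overlapping any
        # known peak (``avoid_nm``) are skipped outright
        n_in = int(sel.sum())
        avoid = np.asarray(avoid_nm, dtype=float) if avoid_nm is not None \
            else np.empty(0)
        side_maps = []
        for off in (-8.5, -7.0, -5.5, -4.0, -2.5, 2.5, 4.0, 5.5, 7.0, 8.5):
            c = center_nm + off * bandwidth_nm
            if len(avoid) and np.min(np.abs(avoid - c)) < 1.5 * bandwidth_nm:
                continue
            ssel = (lam >= c - bandwidth_nm / 2) & (lam <= c + bandwidth_nm / 2)
            if ssel.any():
                side_maps.append(cube.data[:, :, ssel].sum(axis=2)
                                 / ssel.sum())
            if len(side_maps) == 6:
                break
        if side_maps:
            data = data - n_in * np.median(side_maps, axis=0)
    return IntensityMap(cube.x_um, cube.y_um, data, band_nm=(lo, hi))


def bin_cube(cube: HyperspectralCube, factor_xy: int = 2,
             factor_lambda: int = 2) -> HyperspectralCube:
    """Integer binning (summation) in space and wavelength.

    Emulates the fast-scan acquisition mode in which the camera bins
    2x2 spatially and 2x spectrally; trailing rows/columns that do not
    fill a bin are dropped.
    """
    ny, nx, nl = cube.data.shape
    my, mx, ml = (ny // factor_xy) * factor_xy, (nx // factor_xy) * factor_xy, \
        (nl // factor_lambda) * factor_lambda
    d = cube.data[:my, :mx, :ml].reshape(
        my // factor_xy, factor_xy, mx // factor_xy, factor_xy,
        ml // factor_lambda, factor_lambda).sum(axis=(1, 3, 5))
    x = cube.x_um[:mx].reshape(-1, factor_xy).mean(axis=1)
    y = cube.y_um[:my].reshape(-1, factor_xy).mean(axis=1)
    wl = cube.wavelength_nm[:ml].reshape(-1, factor_lambda).mean(axis=1)
    return HyperspectralCube(x, y, wl, d)


# ---------------------------------------------------------------------------
# 2D localization


def _gauss2d(coords, amplitude, x0, y0, sx, sy, theta, offset):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return amplitude * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + offset


def _moments(m: IntensityMap):
    z = m.data - np.percentile(m.data, 10)
    z = np.clip(z, 0, None)
    tot = z.sum()
    if tot <= 0:
        raise ValueError("flat or empty map")
    X, Y = np.meshgrid(m.x_um, m.y_um)
    x0 = float((X * z).sum() / tot)
    y0 = float((Y * z).sum() / tot)
    sx = float(np.sqrt(((X - x0) ** 2 * z).sum() / tot))
    sy = float(np.sqrt(((Y - y0) ** 2 * z).sum() / tot))
    return x0, y0, max(sx, 1e-3), max(sy, 1e-3), float(z.max())


def fit_gaussian2d(m: IntensityMap, residual_threshold: float = 0.2,
                   fit_offset: bool = True) -> Localization2D:
    """Least-squares 2D Gaussian (with offset) fit of a footprint map.

    Initialized from the intensity centroid and second moments.  The fit
    quality is the rms residual relative to the rms of the fitted blob
    itself (model minus offset); when it exceeds ``residual_threshold`` —
    e.g. two comparable blobs in one map — the fit is flagged "poor"
    rather than silently returning a meaningless midpoint.
    Non-convergence falls back to the centroid.

    On a map whose baseline is known to be zero (background- and
    sideband-subtracted slices), fix ``fit_offset=False``: a free offset is
    nearly degenerate with the width on a footprint wider than the field
    and lets noise pull the center.
    """
    x0, y0, sx, sy, amp = _moments(m)
    X, Y = np.meshgrid(m.x_um, m.y_um)
    coords = (X.ravel(), Y.ravel())
    z = m.data.ravel().astype(float)
    off_hi = np.inf if fit_offset else 1e-12
    off_lo = -np.inf if fit_offset else -1e-12
    off0 = float(np.percentile(z, 10)) if fit_offset else 0.0
    p0 = (amp, x0, y0, sx, sy, 0.0, off0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d, coords, z, p0=p0,
            bounds=([0, m.x_um[0] - 5 * sx, m.y_um[0] - 5 * sy,
                     1e-3, 1e-3, -np.pi, off_lo],
                    [np.inf, m.x_um[-1] + 5 * sx, m.y_um[-1] + 5 * sy,
                     np.inf, np.inf, np.pi, off_hi]),
            maxfev=5000)
    except RuntimeError:
        return Localization2D(x0, y0, sx, sy, 0.0, amp, 0.0,
                              residual=float("inf"),
                              status="centroid-fallback")
    model = _gauss2d(coords, *popt)
    resid = z - model
    blob_rms = float(np.sqrt(np.mean((model - popt[6]) ** 2)))
    rel = float(np.sqrt(np.mean(resid**2)) / max(blob_rms, 1e-30))
    status = "ok" if rel <= residual_threshold else "poor"
    return Localization2D(
        x0_um=float(popt[1]), y0_um=float(popt[2]),
        sigma_x_um=abs(float(popt[3])), sigma_y_um=abs(float(popt[4])),
        theta_rad=float(popt[5]), amplitude=float(popt[0]),
        offset=float(popt[6]), residual=rel, status=status)


def localize_microcavity(cube: HyperspectralCube, group,
                         bandwidth_nm: float | None = None,
                         avoid_nm=None) -> Localization2D:
    """Localize one microcavity from all of its comb peaks.

    Fits the footprint at every observed peak wavelength of the group and
    combines the centers by amplitude-weighted averaging; the scatter of
    the per-peak centers is reported as the localization uncertainty.
    Averaging over the typically 15-20 available peaks beats any
    single-peak fit because the per-peak noise is independent.
    """
    if bandwidth_nm is None:
        dl = float(np.median(np.diff(cube.wavelength_nm)))
        bandwidth_nm = 3 * dl
    wavelengths = [p.wavelength_nm for p in getattr(group, "members", group)]
    if not wavelengths:
        raise ValueError("group has no observed peaks")
    fits: list[Localization2D] = []
    for lam in wavelengths:
        try:
            fits.append(fit_gaussian2d(
                slice_at_peak(cube, lam, bandwidth_nm, avoid_nm=avoid_nm),
                fit_offset=False))
        except ValueError:
            continue
    fits = [f for f in fits if f.status in ("ok", "poor")]
    if not fits:
        raise ValueError("no per-peak footprint could be fitted")
    xs = np.array([f.x0_um for f in fits])
    ys = np.array([f.y0_um for f in fits])
    if len(fits) >= 4:
        # robustify against the occasional contaminated slice (a comb tooth
        # shared with another microcavity superposes both footprints)
        mx, my = np.median(xs), np.median(ys)
        r = np.hypot(xs - mx, ys - my)
        mad = 1.4826 * np.median(r) + 1e-9
        keep = r <= max(5.0 * mad, 1.0)
        if keep.sum() >= 3:
            fits = [f for f, k in zip(fits, keep) if k]
            xs, ys = xs[keep], ys[keep]
    w = np.array([f.amplitude for f in fits])
    w = w / w.sum()
    x0 = float(w @ xs)
    y0 = float(w @ ys)
    scatter = float(np.sqrt(w @ ((xs - x0) ** 2 + (ys - y0) ** 2)))
    best = fits[int(np.argmax([f.amplitude for f in fits]))]
    return Localization2D(
        x0_um=x0, y0_um=y0,
        sigma_x_um=float(w @ [f.sigma_x_um for f in fits]),
        sigma_y_um=float(w @ [f.sigma_y_um for f in fits]),
        theta_rad=best.theta_rad, amplitude=float(np.max(w * len(w))),
        offset=best.offset,
        residual=float(np.mean([f.residual for f in fits])),
        status="ok", per_peak=fits, scatter_um=scatter,
        n_peaks_used=len(fits))


# ---------------------------------------------------------------------------
# footprint width and depth


def _gauss1d(x, a, x0, s, c):
    return a * np.exp(-0.5 * ((x - x0) / s) ** 2) + c


def surface_width(m: IntensityMap, metric: str = "sigma",
                  n_directions: int = 4) -> float:
    """Width of a diffuse surface footprint, averaged over directions.

    Extracts 1D profiles through the footprint center along
    ``n_directions`` equally spaced directions (default 0/45/90/135
    degrees), fits a Gaussian to each and averages the widths.  ``metric``
    is "sigma" (Gaussian sigma), "fwhm", or "gauss2d" (mean sigma of an
    offset-free 2D Gaussian model fit — immune to the field truncation of
    an off-center footprint, which pads and inflates the 1D profiles); a
    calibration curve must be queried with the same metric it was built
    with.  Invariant under intensity rescaling.
    """
    if metric not in ("sigma", "fwhm", "gauss2d"):
        raise ValueError("metric must be 'sigma', 'fwhm' or 'gauss2d'")
    if not np.any(m.data != m.data.ravel()[0]):
        raise ValueError("flat map has no width")
    if metric == "gauss2d":
        loc = fit_gaussian2d(m, fit_offset=False)
        if loc.status == "centroid-fallback":
            raise ValueError("2D width fit did not converge")
        return 0.5 * (loc.sigma_x_um + loc.sigma_y_um)
    x0, y0, sx, sy, _ = _moments(m)
    pitch_x = m.x_um[1] - m.x_um[0]
    pitch_y = m.y_um[1] - m.y_um[0]
    ny, nx = m.data.shape
    half = 0.5 * min((nx - 1) * pitch_x, (ny - 1) * pitch_y)
    t = np.linspace(-half, half, 2 * max(nx, ny))
    widths = []
    for k in range(n_directions):
        ang = np.pi * k / n_directions
        xs = x0 + t * np.cos(ang)
        ys = y0 + t * np.sin(ang)
        ix = (xs - m.x_um[0]) / pitch_x
        iy = (ys - m.y_um[0]) / pitch_y
        prof = ndimage.map_coordinates(m.data.astype(float), [iy, ix],
                                       order=1, mode="nearest")
        span = prof.max() - prof.min()
        try:
            # bounded fit: on a truncated, noisy profile an unconstrained
            # width/offset pair can run away together
            popt, _ = optimize.curve_fit(
                _gauss1d, t, prof,
                p0=(span, 0.0, min(0.5 * (sx + sy), half), prof.min()),
                bounds=([0.0, -0.5 * half, 0.1 * abs(t[1] - t[0]),
                         -0.5 * span - abs(prof.min())],
                        [4.0 * span, 0.5 * half, 2.0 * half,
                         prof.max()]),
                maxfev=4000)
            widths.append(abs(float(popt[2])))
        except (RuntimeError, ValueError):
            continue
    if not widths:
        raise ValueError("no direction profile could be fitted")
    w = float(np.mean(widths))
    return w * (2.0 * np.sqrt(2.0 * np.log(2.0)) if metric == "fwhm" else 1.0)


def depth_from_width(width_um: float, calibration: CalibrationCurve) -> float:
    """Depth below the surface from the footprint width (um).

    Shape-preserving monotone (PCHIP) interpolation of the calibration
    knots; queries outside the calibrated range are clamped with a
    warning.  A wider footprint never maps to a shallower depth.
    """
    w = calibration.width_um
    if width_um <= w[0] or width_um >= w[-1]:
        warnings.warn(
            f"width {width_um:.1f} um outside calibrated range "
            f"[{w[0]:.1f}, {w[-1]:.1f}]; clamping", stacklevel=2)
        width_um = min(max(width_um, w[0]), w[-1])
    interp = PchipInterpolator(w, calibration.depth_um)
    return float(interp(width_um))
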