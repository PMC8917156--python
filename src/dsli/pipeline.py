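"""End-to-end DSLI orchestration and downstream interpretation.

Ties the stages together: background subtraction over the cube, summed
spectrum, peak detection and comb unmixing, per-comb spatial localization,
depth from the footprint width, diameter / external-index retrieval, and
environment classification — producing one record per identified
microcavity.  On top of the records sit the biological readouts: is a bead
inside a cell (cytoplasm index ~1.37 vs growth medium ~1.34), are two
beads likely in the same cell (index difference below ~0.003), frame-to-
frame tracking by diameter tags, and functionalized-sensor readout from
rigid comb shifts (pH, temperature).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import hsi, unmix, wgm

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "MicrocavityRecord",
    "SensorCalibration",
    "TrackLink",
    "run_dsli",
    "classify_environment",
    "same_cell_probability",
    "track_records",
    "peak_shift_series",
    "records_to_frame",
]


@dataclass
class PipelineConfig:
    """Tunable settings of the end-to-end run (all overridable)."""

    n_internal: float = 1.59
    prominence: float | None = None  # None: 6 x robust noise of the sum
    bandwidth_nm: float | None = None  # None: 3 spectral samples
    d_range: tuple[float, float] = (8.0, 22.0)  # population mean +- >3 sigma
    n_ext_range: tuple[float, float] = (1.32, 1.41)
    min_peaks_full_fit: int = 6
    min_peaks_record: int = 6  # the "good spectrum" gate for emitting a record
    # a genuine comb owns teeth no other comb claims; chance alignments and
    # harmonics of a denser comb are built almost entirely of shared teeth
    min_exclusive_peaks: int = 4
    # peaks broader than this quality factor carry too little wavelength
    # precision and overlap their neighbours; they never enter the combs
    min_quality_factor: float = 2000.0
    match_tolerance: float | None = None
    min_support: int = 4
    max_radial_order: int = 2
    calibration: hsi.CalibrationCurve | None = None
    class_centers: dict = field(default_factory=lambda: {
        "out_of_cell": 1.340, "in_cell": 1.370})
    class_sigma: float = 0.007
    dead_band: float = 0.002


@dataclass
class MicrocavityRecord:
    """One identified microcavity: position, size, surroundings."""

    record_id: int
    x_um: float
    y_um: float
    z_um: float
    diameter_um: float
    diameter_sigma_um: float
    n_external: float
    n_external_sigma: float
    environment: str  # in_cell | out_of_cell | undetermined
    n_peaks: int
    flags: set = field(default_factory=set)
    group_id: int = -1
    fsr_per_um: float = float("nan")
    scatter_um: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.n_external):
            self.environment = "undetermined"


@dataclass
class SensorCalibration:
    """Linear map from a comb shift (nm) to a physical quantity.

    ``quantity(shift) = reference_value + (shift - reference_shift) /
    sensitivity_nm_per_unit``.  For a pH-responsive hydrogel coating the
    sensitivity is negative (swelling at high pH blue-shifts the comb);
    for a thermo-responsive coating it is ~0.044 nm/degC around 37 degC.
    """

    quantity: str  # "pH" | "temperature" | "raw-shift"
    sensitivity_nm_per_unit: float = 1.0
    reference_value: float = 0.0
    reference_shift_nm: float = 0.0
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.quantity != "raw-shift" and self.sensitivity_nm_per_unit == 0:
            raise ValueError("sensitivity must be nonzero")

    def apply(self, shift_nm: float) -> float:
        if self.quantity == "raw-shift":
            return shift_nm
        val = (self.reference_value
               + (shift_nm - self.reference_shift_nm)
               / self.sensitivity_nm_per_unit)
        if self.valid_range is not None:
            lo, hi = self.valid_range
            if not lo <= val <= hi:
                log.warning("calibrated %s=%.3f outside validity range",
                            self.quantity, val)
        return val


@dataclass
class TrackLink:
    id_a: int
    id_b: int
    diameter_diff_nm: float
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# end-to-end run


def _auto_prominence(spectrum: unmix.Spectrum) -> float:
    resid = np.diff(spectrum.intensity)
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid))) / np.sqrt(2)
    return 6.0 * max(sigma, 1e-12)


def run_dsli(cube: hsi.HyperspectralCube,
             config: PipelineConfig | None = None,
             subtracted: bool = False) -> list[MicrocavityRecord]:
    """Run the full DSLI chain on one hyperspectral cube.

    Stages: per-pixel background subtraction -> summed spectrum -> peak
    detection -> FSR unmixing into per-microcavity combs -> per-comb
    spatial localization at its own peak wavelengths -> depth from the
    footprint width (when a calibration curve is configured) -> diameter
    and external index from the characteristic-equation fit, falling back
    to FSR-only sizing for combs with too few teeth -> environment
    classification.  Stage failures degrade to flagged partial records
    rather than aborting the run.
    """
    cfg = config or PipelineConfig()
    if not subtracted:
        log.info("background-subtracting %s cube", cube.data.shape)
        cube = hsi.subtract_background_cube(cube)
    total = hsi.spectral_sum(cube)
    prominence = cfg.prominence or _auto_prominence(total)
    peaks = unmix.detect_peaks(total, prominence)
    n_raw = len(peaks)
    peaks = [p for p in peaks
             if p.quality_factor >= cfg.min_quality_factor and p.fitted]
    log.info("detected %d peaks above prominence %.1f (%d sharp enough)",
             n_raw, prominence, len(peaks))
    fsr, support = unmix.assign_fsr(peaks, cfg.match_tolerance, cfg.min_support)
    groups = unmix.group_peaks(peaks, fsr, support, cfg.match_tolerance)
    groups = unmix.pair_te_tm(groups, cfg.match_tolerance)
    window = (float(cube.wavelength_nm[0]), float(cube.wavelength_nm[-1]))
    for g in groups:
        if len(g.members) >= 2:
            unmix.fill_missing_peaks(g, window, cfg.match_tolerance)
    log.info("unmixed %d microcavity combs", len(groups))

    # accept combs largest-first; each must own enough teeth that no
    # already-accepted comb claims, which rejects chance alignments and
    # harmonics (their teeth all belong to a denser parent comb) without
    # penalizing the parent itself
    order = sorted(range(len(groups)), key=lambda k: -len(groups[k].members))
    taken: set[int] = set()
    accepted: set[int] = set()
    claim_counts: dict[int, int] = {}
    for gg in groups:
        for p in gg.members:
            claim_counts[id(p)] = claim_counts.get(id(p), 0) + 1
    for k in order:
        g = groups[k]
        novel = [p for p in g.members if id(p) not in taken]
        if (len(g.members) >= cfg.min_peaks_record
                and len(novel) >= cfg.min_exclusive_peaks):
            accepted.add(k)
            taken.update(id(p) for p in g.members)
        else:
            log.info("group %d: %d teeth / %d unclaimed, below the record "
                     "gate", g.group_id, len(g.members), len(novel))

    records: list[MicrocavityRecord] = []
    for k in sorted(accepted):
        g = groups[k]
        flags = set(g.flags)
        # --- spatial localization from this comb's own wavelengths;
        # teeth claimed by several combs carry superposed footprints, so
        # prefer the peaks exclusive to this microcavity
        exclusive = [p for p in g.members if claim_counts[id(p)] == 1]
        loc_members = exclusive if len(exclusive) >= 3 else g.members
        if len(exclusive) < len(g.members):
            flags.add("shared-peaks")
        all_peak_nm = [p.wavelength_nm for p in peaks]
        try:
            loc = hsi.localize_microcavity(cube, loc_members,
                                           cfg.bandwidth_nm,
                                           avoid_nm=all_peak_nm)
        except ValueError:
            log.warning("group %d: localization failed", g.group_id)
            continue
        # --- depth from footprint width, measured with the same metric
        # (surface_width) the calibration curve was built with
        z = float("nan")
        if cfg.calibration is not None:
            if cfg.calibration.metric == "gauss2d":
                # the per-peak localization fits already measure this
                # width for every comb tooth; the median over them is far
                # less noisy than any single slice
                widths = [0.5 * (f.sigma_x_um + f.sigma_y_um)
                          for f in loc.per_peak]
            else:
                widths = []
                strongest = sorted(g.members, key=lambda p: -p.amplitude)[:5]
                for p in strongest:
                    try:
                        m = hsi.slice_at_peak(
                            cube, p.wavelength_nm,
                            cfg.bandwidth_nm
                            or 3 * float(np.median(np.diff(cube.wavelength_nm))),
                            avoid_nm=all_peak_nm)
                        widths.append(hsi.surface_width(
                            m, metric=cfg.calibration.metric))
                    except (ValueError, RuntimeError):
                        continue
            if widths:
                try:
                    z = hsi.depth_from_width(float(np.median(widths)),
                                             cfg.calibration)
                except ValueError:
                    flags.add("no-depth")
            else:
                flags.add("no-depth")
        # --- sizing ladder: full fit -> FSR-only -> drop
        lam = sorted(m.wavelength_nm for m in g.members)
        d = d_sig = n_ext = n_sig = float("nan")
        if len(lam) >= cfg.min_peaks_full_fit:
            try:
                fit = wgm.fit_size_index(
                    lam, cfg.n_internal, cfg.d_range, cfg.n_ext_range,
                    max_radial_order=cfg.max_radial_order)
            except (ValueError, RuntimeError, FloatingPointError):
                fit = None
                flags.add("fit-failed")
            if fit is not None and fit.status == "ok":
                d, d_sig = fit.diameter, max(fit.residual * 1e-3, 1e-5)
                n_ext, n_sig = fit.n_external, cfg.class_sigma / 10
            elif fit is not None:
                d, d_sig = fit.diameter, fit.diameter_sigma
                flags.add("size-only")
        else:
            flags.add("size-only")
        if np.isnan(d):
            try:
                d = wgm._invert_fsr(g.fsr_per_um, cfg.n_internal,
                                    float(np.mean(lam)))
                d_sig = 0.006  # FSR-only sizing class accuracy
            except Exception:
                flags.add("unsized")
        env, _conf = classify_environment(
            n_ext, cfg.class_centers, cfg.class_sigma, cfg.dead_band)
        records.append(MicrocavityRecord(
            record_id=len(records), x_um=loc.x0_um, y_um=loc.y0_um, z_um=z,
            diameter_um=d, diameter_sigma_um=d_sig,
            n_external=n_ext, n_external_sigma=n_sig,
            environment=env, n_peaks=len(g.members), flags=flags,
            group_id=g.group_id, fsr_per_um=g.fsr_per_um,
            scatter_um=loc.scatter_um))
    return records


# ---------------------------------------------------------------------------
# interpretation


def classify_environment(
    n_external: float,
    class_centers: dict | None = None,
    class_sigma: float = 0.007,
    dead_band: float = 0.002,
) -> tuple[str, float]:
    """Classify a bead's surroundings from its external refractive index.

    Nearest class center wins (defaults: growth medium 1.34 vs cytoplasm
    1.37); indices within ``dead_band`` of the midpoint boundary — the
    stability scale of the medium itself — return "undetermined".  The
    confidence is the distance from the boundary in units of the class
    spread.
    """
    centers = class_centers or {"out_of_cell": 1.340, "in_cell": 1.370}
    if not np.isfinite(n_external):
        return "undetermined", 0.0
    names = sorted(centers, key=lambda k: centers[k])
    vals = [centers[k] for k in names]
    # nearest-center classification with a dead band at each boundary
    k = int(np.argmin([abs(n_external - v) for v in vals]))
    for b in range(len(vals) - 1):
        boundary = 0.5 * (vals[b] + vals[b + 1])
        if abs(n_external - boundary) < dead_band:
            return "undetermined", abs(n_external - boundary) / class_sigma
    conf = abs(n_external - vals[k]) / class_sigma
    boundary_dist = min(abs(n_external - 0.5 * (vals[b] + vals[b + 1]))
                        for b in range(len(vals) - 1))
    return names[k], boundary_dist / class_sigma


def same_cell_probability(
    a: MicrocavityRecord | float,
    b: MicrocavityRecord | float,
    threshold: float = 0.003,
    within_cell_sigma: float = 0.007,
) -> tuple[bool, float]:
    """Are two in-cell beads plausibly inside the same cell?

    Beads sharing a cell see the same cytoplasm, so their measured external
    indices agree within measurement noise (typically below 0.003), while
    two beads in separate cells draw independent indices from the
    cell-to-cell distribution N(mu, sigma^2).  Returns ``(candidate,
    p_same)`` where ``candidate`` flags |dn| < threshold and ``p_same`` is
    one minus the chance that a separate-cell pair lands at least this
    close: 1 - erf(|dn| / (2 sigma)).
    """
    import math

    na = a.n_external if hasattr(a, "n_external") else float(a)
    nb = b.n_external if hasattr(b, "n_external") else float(b)
    if not (np.isfinite(na) and np.isfinite(nb)):
        raise ValueError("both records need a measured external index")
    dn = abs(na - nb)
    p_chance = math.erf(dn / (2.0 * within_cell_sigma))
    return dn < threshold, 1.0 - p_chance


def track_records(
    frames: list[list[MicrocavityRecord]],
    tag_tolerance_nm: float = 3.0,
    ambiguity_factor: float = 2.0,
) -> list[list[TrackLink]]:
    """Link records across consecutive frames by their diameter tags.

    The bead diameter is a persistent fingerprint (repeatability ~0.6 nm,
    population spacing ~ tens of nm), so frame-to-frame identity is an
    optimal one-to-one assignment minimizing total |diameter difference|,
    with links above ``tag_tolerance_nm`` forbidden.  A link is flagged
    ambiguous when a competing partner lies within ``ambiguity_factor``
    times its own mismatch + the tolerance — two beads closer than the tag
    resolution cannot be told apart.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    all_links: list[list[TrackLink]] = []
    BIG = 1e6
    for fa, fb in zip(frames[:-1], frames[1:]):
        da = np.array([r.diameter_um for r in fa])
        db = np.array([r.diameter_um for r in fb])
        cost = np.abs(da[:, None] - db[None, :]) * 1e3  # nm
        cost_masked = np.where(cost <= tag_tolerance_nm, cost, BIG)
        rows, cols = linear_sum_assignment(cost_masked)
        links = []
        for i, j in zip(rows, cols):
            if cost_masked[i, j] >= BIG:
                continue
            competitors = np.sum(cost[i, :] <= tag_tolerance_nm) - 1
            links.append(TrackLink(
                id_a=fa[i].record_id, id_b=fb[j].record_id,
                diameter_diff_nm=float(cost[i, j]),
                ambiguous=competitors > 0))
        all_links.append(links)
    return all_links


def peak_shift_series(
    series: list[np.ndarray],
    reference: int = 0,
    max_pair_gap_nm: float = 1.8,
    calibration: SensorCalibration | None = None,
):
    """Rigid comb shift of one microcavity across conditions or time.

    ``series`` holds the comb's peak wavelengths (nm) per condition; teeth
    are paired with the reference condition by nearest wavelength (within
    ``max_pair_gap_nm``, about half a free spectral range) and the shift is
    the mean over paired teeth, with standard-error uncertainty.  With a
    calibration attached, the shifts are also mapped to the physical
    quantity.  Returns a DataFrame with columns shift_nm, shift_sigma_nm,
    n_teeth (and quantity when calibrated).
    """
    ref = np.sort(np.asarray(series[reference], dtype=float))
    if len(ref) == 0:
        raise ValueError("reference condition has no peaks")
    rows = []
    for k, lam in enumerate(series):
        lam = np.sort(np.asarray(lam, dtype=float))
        deltas = []
        for w in lam:
            j = int(np.argmin(np.abs(ref - w)))
            if abs(ref[j] - w) <= max_pair_gap_nm:
                deltas.append(w - ref[j])
        if not deltas:
            raise ValueError(
                f"condition {k}: no comb teeth pair with the reference "
                f"within {max_pair_gap_nm} nm")
        deltas = np.asarray(deltas)
        shift = float(np.mean(deltas))
        sigma = float(np.std(deltas, ddof=1) / np.sqrt(len(deltas))) \
            if len(deltas) > 1 else float("nan")
        row = {"condition": k, "shift_nm": shift, "shift_sigma_nm": sigma,
               "n_teeth": len(deltas)}
        if calibration is not None:
            row[calibration.quantity] = calibration.apply(shift)
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_frame(records: list[MicrocavityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["flags"] = ";".join(sorted(d["flags"]))
        rows.append(d)
    return pd.DataFrame(rows)
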