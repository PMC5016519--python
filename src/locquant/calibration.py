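"""Blink calibration: from repeated localizations to molecular densities.

A fluorophore blinks several times during an acquisition, so one
molecule produces several localizations.  On a diluted reference sample
(< 20 localizations/um^2, where single fluorophores are isolated) the
repeated localizations of one molecule can be grouped into *tracks*
across the whole image stack.  Sweeping the tracking radius from 1 to
160 nm yields a saturation curve of mean track length versus radius; the
plateau (read at 50 nm) is the *conversion factor*: the average number
of localizations per detected fluorophore.  Localization densities
divided by this factor give detected molecular densities.

Aligning the members of each track (length >= 3) to the track's center
of mass pools the localization errors; the spread of the pooled offsets,
corrected for the shrinkage introduced by subtracting each track's own
centroid, estimates the experimental localization precision sigma_x,
sigma_y.

Grouping uses a deterministic greedy frame-ordered centroid linkage: the
calibration statistic depends only on the tracking radius and on the
temporal gap allowance (the whole stack, by default), not on a tracker's
motion model, and the linkage is validated against ground truth on
synthetic scenes.

The statsmodels-style entry point is :class:`BlinkCalibrationModel`,
whose :meth:`~BlinkCalibrationModel.fit` returns a
:class:`BlinkCalibrationResults` carrying the estimates, their standard
errors, and a ``summary()`` table.  The individual pipeline operations
are also exposed as plain functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .io import LocalizationTable, EmptyInputError

__all__ = [
    "TrackSet",
    "CalibrationCurve",
    "BlinkCalibration",
    "AlignedOffsets",
    "MolecularDensity",
    "group_localizations",
    "radius_sweep",
    "estimate_conversion_factor",
    "align_tracks",
    "estimate_precision",
    "molecular_density",
    "BlinkCalibrationModel",
    "BlinkCalibrationResults",
    "DEFAULT_RADII",
    "DEFAULT_PLATEAU_RADIUS",
]

#: tracking-radius sweep grid, nm
DEFAULT_RADII = tuple(range(1, 161))
#: radius at which the saturation level is read, nm
DEFAULT_PLATEAU_RADIUS = 50.0


@dataclass
class TrackSet:
    """Partition of table rows into per-fluorophore tracks."""

    tracks: list  # list of np.ndarray row indices (original table order)
    radius: float  # nm
    max_gap: Optional[int]  # frames; None = whole stack

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def track_lengths(self) -> np.ndarray:
        return np.array([len(t) for t in self.tracks], dtype=np.int64)

    @property
    def mean_track_length(self) -> float:
        lengths = self.track_lengths
        return float(lengths.mean()) if lengths.size else float("nan")

    def labels(self, n_rows: int) -> np.ndarray:
        """Per-row track index."""
        lab = np.full(n_rows, -1, dtype=np.int64)
        for k, idx in enumerate(self.tracks):
            lab[idx] = k
        return lab


def group_localizations(table: LocalizationTable, radius: float,
                        max_gap: Optional[int] = None) -> TrackSet:
    """Greedy frame-ordered centroid linkage of localizations into tracks.

    Localizations are processed in frame order (stable within a frame).
    Each joins the nearest open track whose *running centroid* lies
    within ``radius`` and whose last frame is within ``max_gap`` frames;
    ties go to the lowest track index; otherwise it opens a new track.
    ``max_gap=None`` allows gaps spanning the whole stack.  With radius
    0 only exactly coincident localizations merge.
    """
    if radius < 0:
        raise ValueError("tracking radius must be >= 0")
    n = table.n
    if n == 0:
        return TrackSet([], radius, max_gap)
    order = np.argsort(table.frame, kind="stable")
    xy = table.xy[order]
    frames = table.frame[order]

    centroids = np.empty((n, 2))
    counts = np.zeros(n, dtype=np.int64)
    last_frame = np.empty(n, dtype=np.int64)
    members: list[list[int]] = []
    n_tracks = 0

    for i in range(n):
        p = xy[i]
        f = frames[i]
        joined = -1
        if n_tracks:
            diff = centroids[:n_tracks] - p
            dist2 = diff[:, 0] ** 2 + diff[:, 1] ** 2
            ok = dist2 <= radius * radius
            if max_gap is not None:
                ok &= (f - last_frame[:n_tracks]) <= max_gap
            if ok.any():
                cand = np.where(ok)[0]
                joined = int(cand[np.argmin(dist2[cand])])  # argmin → lowest index on ties
        if joined >= 0:
            c = counts[joined]
            centroids[joined] = (centroids[joined] * c + p) / (c + 1)
            counts[joined] = c + 1
            last_frame[joined] = f
            members[joined].append(int(order[i]))
        else:
            centroids[n_tracks] = p
            counts[n_tracks] = 1
            last_frame[n_tracks] = f
            members.append([int(order[i])])
            n_tracks += 1

    tracks = [np.array(m, dtype=np.int64) for m in members]
    return TrackSet(tracks, radius, max_gap)


@dataclass
class CalibrationCurve:
    """Mean track length versus tracking radius (the saturation curve)."""

    radii: np.ndarray  # nm
    mean_track_length: np.ndarray  # localizations/track
    se_track_length: np.ndarray  # SE of the mean, same units
    n_tracks: np.ndarray

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.radii, self.mean_track_length, yerr=self.se_track_length,
                    fmt="-", **kwargs)
        ax.set_xlabel("tracking radius (nm)")
        ax.set_ylabel("mean track length (localizations)")
        return ax


def _curve_from_length_lists(radii: np.ndarray,
                             lengths_per_radius: list[np.ndarray]) -> CalibrationCurve:
    means = np.empty(len(radii))
    ses = np.empty(len(radii))
    ntr = np.empty(len(radii), dtype=np.int64)
    for k, lengths in enumerate(lengths_per_radius):
        means[k] = lengths.mean()
        ses[k] = (lengths.std(ddof=1) / math.sqrt(lengths.size)
                  if lengths.size > 1 else 0.0)
        ntr[k] = lengths.size
    return CalibrationCurve(radii, means, ses, ntr)


def radius_sweep(table: LocalizationTable,
                 radii: Optional[Sequence[float]] = None,
                 max_gap: Optional[int] = None) -> CalibrationCurve:
    """Group at every radius of the sweep grid (default 1..160 nm)."""
    if table.n == 0:
        raise EmptyInputError("cannot sweep an empty table")
    radii_arr = np.asarray(DEFAULT_RADII if radii is None else radii, dtype=float)
    if radii_arr.size == 0 or np.any(radii_arr <= 0) or np.any(np.diff(radii_arr) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    lengths = [group_localizations(table, r, max_gap).track_lengths for r in radii_arr]
    return _curve_from_length_lists(radii_arr, lengths)


def estimate_conversion_factor(curve: CalibrationCurve,
                               plateau_radius: float = DEFAULT_PLATEAU_RADIUS,
                               method: str = "at_radius",
                               window: tuple[float, float] = (40.0, 80.0),
                               ) -> tuple[float, float]:
    """Saturation level of the sweep curve: localizations per fluorophore.

    ``method="at_radius"`` (default) reads the curve at the fixed plateau
    radius; ``method="window_mean"`` averages the curve (and its SEs)
    over ``window`` as a plateau fit.
    """
    if method == "window_mean":
        lo, hi = window
        sel = (curve.radii >= lo) & (curve.radii <= hi)
        if not sel.any():
            raise ValueError(f"no sweep radii inside window [{lo}, {hi}] nm")
        return float(curve.mean_track_length[sel].mean()), float(curve.se_track_length[sel].mean())
    if method != "at_radius":
        raise ValueError(f"unknown method {method!r}")
    hit = np.isclose(curve.radii, plateau_radius)
    if not hit.any():
        raise ValueError(
            f"plateau radius {plateau_radius} nm not in sweep grid "
            f"[{curve.radii.min():g}..{curve.radii.max():g}]")
    k = int(np.argmax(hit))
    return float(curve.mean_track_length[k]), float(curve.se_track_length[k])


@dataclass
class AlignedOffsets:
    """Pooled (dx, dy) of track members relative to their track centroid.

    ``track_length`` holds, for every offset, the length of the track it
    came from -- needed for the shrinkage correction: deviations from a
    track's own sample centroid have variance sigma^2 (L-1)/L.
    """

    dx: np.ndarray  # nm
    dy: np.ndarray  # nm
    track_length: np.ndarray  # per offset
    n_tracks: int

    @property
    def n(self) -> int:
        return self.dx.size


def align_tracks(tracks: TrackSet, table: LocalizationTable,
                 min_length: int = 3) -> AlignedOffsets:
    """Subtract each qualifying track's center of mass from its members.

    Tracks shorter than ``min_length`` (default 3, i.e. length > 2) are
    excluded.  Offsets have zero mean per track by construction.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    dx_parts, dy_parts, len_parts = [], [], []
    n_used = 0
    x, y = table.x, table.y
    for idx in tracks.tracks:
        if idx.size < min_length:
            continue
        dx_parts.append(x[idx] - x[idx].mean())
        dy_parts.append(y[idx] - y[idx].mean())
        len_parts.append(np.full(idx.size, idx.size, dtype=np.int64))
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no tracks of length >= {min_length}")
    return AlignedOffsets(np.concatenate(dx_parts), np.concatenate(dy_parts),
                          np.concatenate(len_parts), n_used)


def _gauss_sigma_histogram(values: np.ndarray, bin_width: float) -> float:
    """Least-squares Gaussian fit to a histogram of the offset marginal."""
    from scipy.optimize import curve_fit

    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(xv, amp, mu, sigma):
        return amp * np.exp(-((xv - mu) ** 2) / (2.0 * sigma ** 2))

    sd0 = max(values.std(), bin_width)
    popt, _ = curve_fit(gauss, centers, counts,
                        p0=(counts.max() or 1.0, values.mean(), sd0))
    return abs(float(popt[2]))


def estimate_precision(offsets: Union[AlignedOffsets, np.ndarray],
                       method: str = "analytic",
                       bin_width: float = 2.0) -> tuple[float, float]:
    """Localization precision (sigma_x, sigma_y) from aligned offsets.

    ``method="analytic"`` (default) is the shrinkage-corrected pooled
    standard deviation: sigma^2 = sum(d^2) / sum_t (L_t - 1), which
    undoes the per-track centroid subtraction exactly and involves no
    binning.  ``method="histogram"`` least-squares fits a Gauss function
    to the marginal histograms (bin width 2 nm), for parity with how
    such distributions are usually displayed; no shrinkage correction is
    applied there.  A plain (n, 2) array may be passed instead of
    :class:`AlignedOffsets`, in which case the offsets are treated as
    direct draws (no shrinkage).
    """
    if isinstance(offsets, AlignedOffsets):
        dx, dy = offsets.dx, offsets.dy
        # sum over tracks of (L-1), expressed per offset
        dof = float(np.sum(1.0 - 1.0 / offsets.track_length))
    else:
        arr = np.asarray(offsets, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected an (n, 2) offset array")
        dx, dy = arr[:, 0], arr[:, 1]
        dof = float(dx.size - 1)
    if dx.size < 10:
        raise ValueError("need at least 10 offsets to estimate the precision")
    if method == "analytic":
        if dof <= 0:
            raise ValueError("no degrees of freedom left for the variance estimate")
        if not isinstance(offsets, AlignedOffsets):
            dx = dx - dx.mean()
            dy = dy - dy.mean()
        return (float(math.sqrt(np.sum(dx ** 2) / dof)),
                float(math.sqrt(np.sum(dy ** 2) / dof)))
    if method == "histogram":
        if np.ptp(dx) == 0 and np.ptp(dy) == 0:
            return 0.0, 0.0
        return (_gauss_sigma_histogram(dx, bin_width),
                _gauss_sigma_histogram(dy, bin_width))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class MolecularDensity:
    """Detected molecular density: localization density / conversion factor."""

    value: float  # fluorophores per um^2
    rounded: int
    se: Optional[float] = None

    def __str__(self) -> str:
        if self.se is None:
            return f"{self.rounded} fluorophores/µm² ({self.value:.2f})"
        return f"{self.rounded} ± {self.se:.0f} fluorophores/µm² ({self.value:.2f})"


def molecular_density(localization_density: float, conversion_factor: float,
                      density_se: Optional[float] = None,
                      conversion_se: Optional[float] = None) -> MolecularDensity:
    """Convert a localization density into a detected molecular density.

    Optional first-order propagation of independent standard errors:
    se = value * sqrt((se_rho/rho)^2 + (se_c/c)^2).
    """
    if conversion_factor <= 0:
        raise ValueError("conversion_factor must be > 0")
    if localization_density < 0:
        raise ValueError("localization_density must be >= 0")
    value = localization_density / conversion_factor
    se = None
    if density_se is not None and conversion_se is not None and localization_density > 0:
        se = value * math.sqrt((density_se / localization_density) ** 2
                               + (conversion_se / conversion_factor) ** 2)
    return MolecularDensity(value=value, rounded=int(round(value)), se=se)


@dataclass
class BlinkCalibration:
    """The calibration constants: conversion factor and precision."""

    conversion_factor: float  # localizations per fluorophore
    conversion_se: float
    sigma_x: float  # nm
    sigma_y: float  # nm


class BlinkCalibrationModel:
    """Blink calibration fitted to one or more diluted reference scenes.

    Parameters
    ----------
    tables : LocalizationTable or sequence thereof
        Diluted reference sample(s) (< 20 localizations/um^2 so that
        fluorophores are isolated).  Several scenes are pooled: track
        statistics are combined across them at every radius.
    radii : sequence of float, optional
        Tracking-radius sweep grid in nm; default 1..160.
    plateau_radius : float
        Radius at which the saturation level is read, default 50 nm.
    max_gap : int, optional
        Maximal temporal gap inside a track; default spans the stack.
    min_track_length : int
        Minimal track length entering the precision alignment (3, i.e.
        tracks with length > 2).
    precision_method : {"analytic", "histogram"}
        Estimator for sigma_x/sigma_y, see :func:`estimate_precision`.
    """

    def __init__(self, tables, radii: Optional[Sequence[float]] = None,
                 plateau_radius: float = DEFAULT_PLATEAU_RADIUS,
                 max_gap: Optional[int] = None, min_track_length: int = 3,
                 precision_method: str = "analytic"):
        if isinstance(tables, LocalizationTable):
            tables = [tables]
        self.tables = list(tables)
        if not self.tables or all(t.n == 0 for t in self.tables):
            raise EmptyInputError("calibration needs at least one non-empty table")
        self.radii = np.asarray(DEFAULT_RADII if radii is None else radii, dtype=float)
        self.plateau_radius = float(plateau_radius)
        self.max_gap = max_gap
        self.min_track_length = int(min_track_length)
        self.precision_method = precision_method

    def fit(self) -> "BlinkCalibrationResults":
        lengths_per_radius = [[] for _ in self.radii]
        plateau_tracksets = []
        for t in self.tables:
            if t.n == 0:
                continue
            for k, r in enumerate(self.radii):
                ts = group_localizations(t, float(r), self.max_gap)
                lengths_per_radius[k].append(ts.track_lengths)
                if np.isclose(r, self.plateau_radius):
                    plateau_tracksets.append((ts, t))
        pooled = [np.concatenate(ls) for ls in lengths_per_radius]
        curve = _curve_from_length_lists(self.radii, pooled)
        factor, factor_se = estimate_conversion_factor(curve, self.plateau_radius)
        if not plateau_tracksets:
            raise ValueError(
                f"plateau radius {self.plateau_radius} nm not in sweep grid")
        dx, dy, tl = [], [], []
        n_tracks_aligned = 0
        for ts, t in plateau_tracksets:
            try:
                off = align_tracks(ts, t, self.min_track_length)
            except ValueError:
                continue
            dx.append(off.dx)
            dy.append(off.dy)
            tl.append(off.track_length)
            n_tracks_aligned += off.n_tracks
        if not dx:
            raise ValueError("no tracks long enough for precision alignment")
        offsets = AlignedOffsets(np.concatenate(dx), np.concatenate(dy),
                                 np.concatenate(tl), n_tracks_aligned)
        sigma_x, sigma_y = estimate_precision(offsets, method=self.precision_method)
        return BlinkCalibrationResults(
            model=self, curve=curve, offsets=offsets,
            calibration=BlinkCalibration(factor, factor_se, sigma_x, sigma_y),
            n_tracks_at_plateau=int(curve.n_tracks[np.argmax(np.isclose(self.radii, self.plateau_radius))]),
        )


@dataclass
class BlinkCalibrationResults:
    """Fitted calibration: estimates, uncertainties, and diagnostics."""

    model: BlinkCalibrationModel
    curve: CalibrationCurve
    offsets: AlignedOffsets
    calibration: BlinkCalibration
    n_tracks_at_plateau: int

    @property
    def conversion_factor(self) -> float:
        return self.calibration.conversion_factor

    @property
    def conversion_se(self) -> float:
        return self.calibration.conversion_se

    @property
    def sigma_x(self) -> float:
        return self.calibration.sigma_x

    @property
    def sigma_y(self) -> float:
        return self.calibration.sigma_y

    def molecular_density(self, localization_density: float,
                          density_se: Optional[float] = None) -> MolecularDensity:
        """Table-style row: density / conversion factor, with propagated SE."""
        return molecular_density(localization_density, self.conversion_factor,
                                 density_se, self.conversion_se)

    def summary(self) -> str:
        n_loc = sum(t.n for t in self.model.tables)
        lines = [
            "Blink calibration",
            "=" * 45,
            f"scenes pooled:            {len(self.model.tables)}",
            f"localizations:            {n_loc}",
            f"tracks at plateau radius: {self.n_tracks_at_plateau}"
            f"  (r = {self.model.plateau_radius:g} nm)",
            "-" * 45,
            f"conversion factor:  {self.conversion_factor:6.2f}"
            f" ± {self.conversion_se:.2f}  loc/fluorophore",
            f"sigma_x:            {self.sigma_x:6.2f}  nm",
            f"sigma_y:            {self.sigma_y:6.2f}  nm",
            f"aligned offsets:    {self.offsets.n}"
            f"  (from {self.offsets.n_tracks} tracks, length >= "
            f"{self.model.min_track_length})",
            "=" * 45,
        ]
        return "\n".join(lines)

    def plot_curve(self, ax=None, **kwargs):
        ax = self.curve.plot(ax=ax, **kwargs)
        ax.axhline(self.conversion_factor, ls="--", color="gray", lw=0.8)
        ax.axvline(self.model.plateau_radius, ls=":", color="gray", lw=0.8)
        return ax
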