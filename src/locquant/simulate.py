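"""Seeded point-process generators for localization data.

These emulate the statistical structure of single-molecule localization
experiments on a plasma membrane, and serve both as the null models for
the Ripley analysis and as ground-truth scenes for parameter-recovery
tests:

* complete spatial randomness (homogeneous Poisson process);
* Neyman-Scott clusters: Poisson parents, each spawning a Poisson number
  of Gaussian-scattered offspring -- the standard model of
  blinking-induced self-clustering (on average ~5 localizations per
  fluorophore scattered with the localization precision, ~8 nm);
* frame-resolved blinking fluorophores (the diluted reference-sample
  regime used for calibration);
* two-fold overlapping membranes (superposed layers);
* vesicle-like dense discs, the classic 2D-projection artifact.

Every generator takes an integer seed (or a ``numpy.random.Generator``)
and is bit-reproducible for a given seed.  All returned coordinates lie
inside the stated region: parents of clustered processes are sampled in
a window buffered by five offspring sigmas and offspring falling outside
the observation window are clipped away, which avoids artificial edge
depletion of clusters while keeping the output strictly windowed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .io import LocalizationTable, Region

__all__ = [
    "NeymanScottParams",
    "BlinkSceneTruth",
    "simulate_csr",
    "simulate_neyman_scott",
    "simulate_blinking_scene",
    "simulate_double_membrane",
    "simulate_vesicle_field",
    "DEFAULT_N_FRAMES",
]

#: default acquisition stack length (frames)
DEFAULT_N_FRAMES = 20_000

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def conditional_poisson_mean(mu: float) -> float:
    """Mean of a Poisson(mu) conditioned on being >= 1: mu / (1 - e^-mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0 for the conditioned distribution")
    return mu / -np.expm1(-mu)


def _truncated_poisson(rng: np.random.Generator, mu: float, size: int) -> np.ndarray:
    """Poisson(mu) conditioned >= 1, by resampling zeros."""
    if mu <= 0:
        raise ValueError("offspring mean must be > 0 when conditioning on detection")
    counts = rng.poisson(mu, size=size)
    zeros = counts == 0
    while zeros.any():
        counts[zeros] = rng.poisson(mu, size=int(zeros.sum()))
        zeros = counts == 0
    return counts


@dataclass
class NeymanScottParams:
    """Parameters of the blinking-cluster (Neyman-Scott) process.

    ``offspring_mean`` is the Poisson parameter of the per-parent
    localization count (experimentally ~5 blinks per fluorophore);
    ``offspring_sigma`` is the isotropic Gaussian scatter of offspring
    around their parent, i.e. the localization precision (~8 nm).  With
    ``condition_on_detection`` the count is conditioned on >= 1 -- an
    undetected fluorophore contributes no localizations -- which shifts
    the realized mean to mu/(1-e^-mu) (about +0.7 % at mu = 5).
    """

    parent_intensity: float  # parents per um^2
    offspring_mean: float = 5.0
    offspring_sigma: float = 8.0  # nm
    condition_on_detection: bool = True

    def __post_init__(self) -> None:
        if self.parent_intensity < 0:
            raise ValueError("parent_intensity must be >= 0")
        if self.offspring_mean < 0:
            raise ValueError("offspring_mean must be >= 0")
        if self.offspring_sigma < 0:
            raise ValueError("offspring_sigma must be >= 0")

    @property
    def mean_offspring_realized(self) -> float:
        """Expected localizations per retained parent under the conditioning rule."""
        if self.condition_on_detection:
            return conditional_poisson_mean(self.offspring_mean)
        return self.offspring_mean

    @classmethod
    def from_localization_density(cls, localization_density: float,
                                  offspring_mean: float = 5.0,
                                  offspring_sigma: float = 8.0,
                                  condition_on_detection: bool = True) -> "NeymanScottParams":
        """Choose the parent intensity so the *localization* density matches.

        This is the matching mode used when equating simulations to the
        measured localization density of an experiment: parent intensity
        = target density / expected localizations per parent.
        """
        if localization_density < 0:
            raise ValueError("localization_density must be >= 0")
        per_parent = (conditional_poisson_mean(offspring_mean)
                      if condition_on_detection else offspring_mean)
        return cls(parent_intensity=localization_density / per_parent,
                   offspring_mean=offspring_mean,
                   offspring_sigma=offspring_sigma,
                   condition_on_detection=condition_on_detection)


@dataclass
class BlinkSceneTruth:
    """Ground truth of a simulated blinking scene.

    ``positions`` holds the (x, y) of each retained fluorophore (or
    cluster parent) in nm; ``assignments[k]`` are the row indices of the
    emitted table that belong to fluorophore ``k``.  Every table row is
    assigned to exactly one fluorophore.  Fluorophores whose
    localizations were all clipped away at the window edge are dropped
    (``n_dropped`` records how many), so each retained fluorophore has
    at least one row when counts are conditioned on detection.
    """

    positions: np.ndarray  # (F, 2) nm
    assignments: list = field(default_factory=list)
    n_dropped: int = 0

    @property
    def n_fluorophores(self) -> int:
        return len(self.assignments)

    def labels(self, n_rows: int) -> np.ndarray:
        """Per-row fluorophore index, -1 where unassigned (never for valid truth)."""
        lab = np.full(n_rows, -1, dtype=np.int64)
        for k, idx in enumerate(self.assignments):
            lab[np.asarray(idx, dtype=np.int64)] = k
        return lab


def _uniform_points(rng, count: int, region: Region) -> np.ndarray:
    pts = np.empty((count, 2))
    pts[:, 0] = rng.uniform(region.x_min, region.x_max, size=count)
    pts[:, 1] = rng.uniform(region.y_min, region.y_max, size=count)
    return pts


def simulate_csr(intensity: float, region: Region, seed: SeedLike,
                 n_frames: int = DEFAULT_N_FRAMES) -> LocalizationTable:
    """Homogeneous Poisson field: complete spatial randomness.

    ``intensity`` is in localizations per um^2; the realized count is
    Poisson(intensity * area) with positions i.i.d. uniform in the
    region and frames i.i.d. uniform over the stack.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    rng = _rng(seed)
    count = int(rng.poisson(intensity * region.area_um2()))
    pts = _uniform_points(rng, count, region)
    frames = rng.integers(0, n_frames, size=count)
    return LocalizationTable.from_arrays(pts[:, 0], pts[:, 1], frames)


def _scatter_offspring(rng, parents: np.ndarray, counts: np.ndarray,
                       sigma: float, region: Region):
    """Gaussian offspring around parents, clipped to region.

    Returns (points, parent_positions_retained, assignments, n_dropped).
    """
    total = int(counts.sum())
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, sigma, size=(total, 2)) if sigma > 0 else centers.copy()
    inside = region.contains(pts[:, 0], pts[:, 1])
    parent_of = np.repeat(np.arange(len(parents)), counts)[inside]
    pts = pts[inside]
    assignments = []
    positions = []
    row = np.arange(len(pts))
    n_dropped = 0
    for k in range(len(parents)):
        idx = row[parent_of == k]
        if idx.size == 0:
            n_dropped += 1
            continue
        positions.append(parents[k])
        assignments.append(idx)
    positions_arr = (np.array(positions) if positions else np.empty((0, 2)))
    # re-label assignments against the retained ordering (rows unchanged)
    return pts, positions_arr, assignments, n_dropped


def simulate_neyman_scott(params: NeymanScottParams, region: Region,
                          seed: SeedLike) -> tuple[LocalizationTable, BlinkSceneTruth]:
    """Neyman-Scott clustered field modelling fluorophore blinking.

    Parents are Poisson over the region buffered by 5 * offspring_sigma;
    each parent spawns a Poisson(offspring_mean) number of offspring
    (conditioned >= 1 when ``condition_on_detection``), Gaussian
    scattered with ``offspring_sigma``; offspring outside the window are
    clipped.  The process is purely spatial, so frame indices are 0;
    use :func:`simulate_blinking_scene` when temporal structure matters.
    """
    rng = _rng(seed)
    buffer = 5.0 * params.offspring_sigma
    parent_region = region.buffered(buffer)
    n_parents = int(rng.poisson(params.parent_intensity * parent_region.area_um2()))
    parents = _uniform_points(rng, n_parents, parent_region)
    if n_parents == 0:
        return LocalizationTable.empty(), BlinkSceneTruth(np.empty((0, 2)), [])
    if params.condition_on_detection:
        counts = _truncated_poisson(rng, params.offspring_mean, n_parents)
    else:
        counts = rng.poisson(params.offspring_mean, size=n_parents)
    pts, positions, assignments, n_dropped = _scatter_offspring(
        rng, parents, counts, params.offspring_sigma, region)
    table = LocalizationTable.from_arrays(pts[:, 0], pts[:, 1], 0)
    return table, BlinkSceneTruth(positions, assignments, n_dropped)


def simulate_blinking_scene(fluorophore_density: float, blink_mean: float = 5.0,
                            precision_sigma: float = 8.0,
                            n_frames: int = DEFAULT_N_FRAMES,
                            region: Region = None, seed: SeedLike = None,
                            ) -> tuple[LocalizationTable, BlinkSceneTruth]:
    """Diluted reference sample: isolated blinking fluorophores with frames.

    Fluorophores are uniform in the region at ``fluorophore_density``
    per um^2; each yields a Poisson(``blink_mean``) number of
    localizations conditioned on >= 1, Gaussian-scattered with the
    localization precision ``precision_sigma``.  Frame indices are drawn
    uniformly without replacement over the stack (with replacement, and
    a warning, in the degenerate case of more blinks than frames).
    Blinking here is temporally uniform, not bursty -- sufficient for a
    grouping stage whose temporal gap allowance spans the whole stack.
    """
    if fluorophore_density < 0:
        raise ValueError("fluorophore_density must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if region is None:
        raise ValueError("region is required")
    rng = _rng(seed)
    n_fluor = int(rng.poisson(fluorophore_density * region.area_um2()))
    fluors = _uniform_points(rng, n_fluor, region)
    if n_fluor == 0:
        return LocalizationTable.empty(), BlinkSceneTruth(np.empty((0, 2)), [])
    counts = _truncated_poisson(rng, blink_mean, n_fluor)
    if (counts > n_frames).any():
        warnings.warn("blink count exceeds stack length for some fluorophore(s); "
                      "frames sampled with replacement there", stacklevel=2)
    pts, positions, assignments, n_dropped = _scatter_offspring(
        rng, fluors, counts, precision_sigma, region)
    # frames per retained localization, grouped per fluorophore
    frames = np.zeros(len(pts), dtype=np.int64)
    for idx in assignments:
        k = idx.size
        if k <= n_frames:
            frames[idx] = rng.choice(n_frames, size=k, replace=False)
        else:
            frames[idx] = rng.integers(0, n_frames, size=k)
    table = LocalizationTable.from_arrays(pts[:, 0], pts[:, 1], frames)
    return table, BlinkSceneTruth(positions, assignments, n_dropped)


def simulate_double_membrane(single_intensity: float, region: Region,
                             seed: SeedLike,
                             n_frames: int = DEFAULT_N_FRAMES) -> LocalizationTable:
    """Two independently sampled CSR layers of equal intensity, superposed.

    Models the two-fold membrane of a lamellipodium projected into 2D:
    the expected localization density is exactly twice the single-layer
    density.
    """
    rng = _rng(seed)
    layers = [simulate_csr(single_intensity, region, rng, n_frames) for _ in range(2)]
    data = pd.concat([t.data for t in layers], ignore_index=True)
    return LocalizationTable(data, validate=False)


def simulate_vesicle_field(background_intensity: float, vesicle_count: int,
                           vesicle_radius: float, vesicle_loc_count: int,
                           region: Region, seed: SeedLike,
                           n_frames: int = DEFAULT_N_FRAMES) -> LocalizationTable:
    """CSR background plus dense uniform discs: the vesicle projection artifact.

    Each of ``vesicle_count`` discs of radius ``vesicle_radius`` (nm)
    contains exactly ``vesicle_loc_count`` uniformly placed
    localizations.  Disc centers are uniform over the region shrunk by
    one radius so every disc lies fully inside the window and the
    deterministic part of the count is exact.
    """
    if vesicle_radius <= 0:
        raise ValueError("vesicle_radius must be > 0")
    if vesicle_count < 0 or vesicle_loc_count < 0:
        raise ValueError("vesicle counts must be >= 0")
    rng = _rng(seed)
    background = simulate_csr(background_intensity, region, rng, n_frames)
    parts = [background.data]
    if vesicle_count > 0 and vesicle_loc_count > 0:
        center_region = region.buffered(-vesicle_radius)
        centers = _uniform_points(rng, vesicle_count, center_region)
        total = vesicle_count * vesicle_loc_count
        r = vesicle_radius * np.sqrt(rng.uniform(size=total))
        theta = rng.uniform(0.0, 2 * np.pi, size=total)
        base = np.repeat(centers, vesicle_loc_count, axis=0)
        pts = base + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        frames = rng.integers(0, n_frames, size=total)
        parts.append(LocalizationTable.from_arrays(pts[:, 0], pts[:, 1], frames).data)
    data = pd.concat(parts, ignore_index=True)
    return LocalizationTable(data, validate=False)
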