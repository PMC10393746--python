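"""Per-region point-pattern statistics.

Four families of statistics over marked point patterns in a rectangular
window:

* non-spatial: normalized counts and densities;
* local: median (and MAD of) nearest-neighbour distances, spatial score;
* radius-based: empty-space F, nearest-neighbour G, Ripley K and L, each
  standardized against a closed-form baseline using a Monte-Carlo null
  matched to the observed window and counts;
* global: a 5x5-block inhomogeneity chi-squared and all-pairs distance
  medians.

Raw estimators are plain empirical means without edge correction; the
matched-window null absorbs edge effects during standardization.
Undefined statistics (insufficient counts) are returned as ``nan`` rather
than raised, so region-level extraction always completes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .io import RegionPattern, Window

__all__ = [
    "normalized_count",
    "cell_density",
    "nearest_distance_set",
    "local_distance_stats",
    "spatial_score_stats",
    "empty_space_F_raw",
    "nearest_neighbor_G_raw",
    "ripley_K_raw",
    "ripley_L_raw",
    "theoretical_baseline",
    "standardize_statistic",
    "chi_squared_inhomogeneity",
    "global_distance_stats",
    "null_sigma_mc",
    "NullCalibrator",
    "NullModel",
    "make_grid",
    "median_abs_deviation",
]

STAR = "*"  # pseudo type: all cells whose mark set does not include type i


# ---------------------------------------------------------------------------
# small helpers

def median_abs_deviation(values: np.ndarray, constant: float = 1.0) -> float:
    """Median of absolute deviations from the median.

    ``constant`` defaults to 1 (no normal-consistency scaling); pass 1.4826
    to match the common R default.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    return float(constant * np.median(np.abs(v - med)))


def _nn_dists(pts_i: np.ndarray, pts_j: np.ndarray, same: bool) -> np.ndarray:
    """Distance from each point of ``pts_i`` to the nearest point of ``pts_j``.

    ``same=True`` means the two arrays are the same set of cells and the
    cell itself is excluded (nearest *other* cell).
    """
    d = cdist(pts_i, pts_j)
    if same:
        np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _as_radii(r) -> np.ndarray:
    return np.atleast_1d(np.asarray(r, dtype=float))


# ---------------------------------------------------------------------------
# non-spatial

def normalized_count(pattern: RegionPattern, type_i: str) -> float:
    """Fraction of all cells in the region carrying mark ``type_i``."""
    if pattern.n_total == 0:
        return float("nan")
    return pattern.count(type_i) / pattern.n_total


def cell_density(pattern: RegionPattern, type_i: str) -> float:
    """Cells of ``type_i`` per square micrometer of window area."""
    return pattern.count(type_i) / pattern.window.area


# ---------------------------------------------------------------------------
# local

def nearest_distance_set(
    pattern: RegionPattern, type_i: str, type_j: str
) -> np.ndarray | None:
    """Per type-i cell, distance to the nearest type-j cell (None if undefined).

    For ``type_i == type_j`` the nearest *other* cell of the type is used, so
    at least two cells are required.
    """
    same = type_i == type_j
    pts_i = pattern.points(type_i)
    pts_j = pts_i if same else pattern.points(type_j)
    if len(pts_i) < (2 if same else 1) or len(pts_j) < 1:
        return None
    return _nn_dists(pts_i, pts_j, same)


def local_distance_stats(
    pattern: RegionPattern, type_i: str, type_j: str, mad_constant: float = 1.0
) -> tuple[float, float]:
    """(median, MAD) of nearest type-i -> type-j distances; (nan, nan) if undefined."""
    d = nearest_distance_set(pattern, type_i, type_j)
    if d is None:
        return float("nan"), float("nan")
    return float(np.median(d)), median_abs_deviation(d, mad_constant)


def spatial_scores(
    pattern: RegionPattern,
    tumor: str = "Tumor",
    tcell: str = "Tcell",
    macrophage: str = "Macrophage",
) -> np.ndarray | None:
    """Per tumor cell: d(tumor -> nearest T cell) / d(that T cell -> nearest macrophage).

    Tumor cells whose reference T cell coincides with a macrophage
    (zero denominator) are excluded.  Returns None when any of the three
    types is absent or every score is excluded.
    """
    pts_tum = pattern.points(tumor)
    pts_t = pattern.points(tcell)
    pts_m = pattern.points(macrophage)
    if len(pts_tum) == 0 or len(pts_t) == 0 or len(pts_m) == 0:
        return None
    d_tt = cdist(pts_tum, pts_t)
    nearest_t = d_tt.argmin(axis=1)
    d1 = d_tt[np.arange(len(pts_tum)), nearest_t]
    d_tm = _nn_dists(pts_t, pts_m, same=False)
    d2 = d_tm[nearest_t]
    ok = d2 > 0
    if not ok.any():
        return None
    return d1[ok] / d2[ok]


def spatial_score_stats(
    pattern: RegionPattern, mad_constant: float = 1.0, **roles
) -> tuple[float, float]:
    """(median, MAD) of spatial scores; (nan, nan) when undefined."""
    s = spatial_scores(pattern, **roles)
    if s is None:
        return float("nan"), float("nan")
    return float(np.median(s)), median_abs_deviation(s, mad_constant)


# ---------------------------------------------------------------------------
# radius-based raw estimators (array kernels + pattern-facing wrappers)

def make_grid(window: Window, shape: tuple[int, int] = (100, 100)) -> np.ndarray:
    """Cell-centred lattice of evenly spaced points spanning the window."""
    nx, ny = shape
    if nx < 1 or ny < 1:
        raise ValueError("grid must have at least one point per axis")
    xs = window.xmin + (np.arange(nx) + 0.5) * window.width / nx
    ys = window.ymin + (np.arange(ny) + 0.5) * window.height / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _f_raw(grid: np.ndarray, pts_i: np.ndarray, radii: np.ndarray) -> np.ndarray:
    nd = cKDTree(pts_i).query(grid)[0]
    return (nd[:, None] <= radii[None, :]).mean(axis=0)


def _g_raw(
    pts_i: np.ndarray, pts_j: np.ndarray, radii: np.ndarray, same: bool
) -> np.ndarray:
    nd = _nn_dists(pts_i, pts_j, same)
    return (nd[:, None] <= radii[None, :]).mean(axis=0)


def _k_raw(
    pts_i: np.ndarray,
    pts_j: np.ndarray,
    radii: np.ndarray,
    area: float,
    same: bool,
) -> np.ndarray:
    d = cdist(pts_i, pts_j)
    if same:
        np.fill_diagonal(d, np.inf)
    # number of j-cells strictly closer than r, averaged over i-cells
    mean_counts = (d[:, :, None] < radii[None, None, :]).sum(axis=1).mean(axis=0)
    lam_j = len(pts_j) / area
    return mean_counts / lam_j


def empty_space_F_raw(
    pattern: RegionPattern,
    type_i: str,
    r,
    grid_shape: tuple[int, int] = (100, 100),
):
    """Fraction of grid points within distance r of a type-i cell."""
    pts = pattern.points(type_i)
    radii = _as_radii(r)
    if len(pts) == 0:
        out = np.full(radii.shape, np.nan)
    else:
        grid = make_grid(pattern.window, grid_shape)
        out = _f_raw(grid, pts, radii)
    return float(out[0]) if np.isscalar(r) else out


def _pair_points(pattern: RegionPattern, type_i: str, type_j: str):
    """Resolve (pts_i, pts_j, same) handling the "*" pseudo-type for j."""
    pts_i = pattern.points(type_i)
    if type_j == STAR:
        return pts_i, pattern.points_not(type_i), False
    same = type_i == type_j
    pts_j = pts_i if same else pattern.points(type_j)
    return pts_i, pts_j, same


def nearest_neighbor_G_raw(pattern: RegionPattern, type_i: str, type_j: str, r):
    """Fraction of type-i cells with a type-j cell within distance r."""
    pts_i, pts_j, same = _pair_points(pattern, type_i, type_j)
    radii = _as_radii(r)
    if len(pts_i) < (2 if same else 1) or len(pts_j) < 1:
        out = np.full(radii.shape, np.nan)
    else:
        out = _g_raw(pts_i, pts_j, radii, same)
    return float(out[0]) if np.isscalar(r) else out


def ripley_K_raw(pattern: RegionPattern, type_i: str, type_j: str, r):
    """Density-normalized mean number of type-j cells within distance r of type-i cells."""
    pts_i, pts_j, same = _pair_points(pattern, type_i, type_j)
    radii = _as_radii(r)
    if len(pts_i) < 1 or len(pts_j) < 1:
        out = np.full(radii.shape, np.nan)
    else:
        out = _k_raw(pts_i, pts_j, radii, pattern.window.area, same)
    return float(out[0]) if np.isscalar(r) else out


def ripley_L_raw(pattern: RegionPattern, type_i: str, type_j: str, r):
    """Variance-stabilized K: L = sqrt(K / pi)."""
    k = ripley_K_raw(pattern, type_i, type_j, r)
    if np.isscalar(k):
        return float(np.sqrt(k / math.pi))
    return np.sqrt(k / math.pi)


# ---------------------------------------------------------------------------
# baselines and standardization

@dataclass(frozen=True)
class TheoreticalBaseline:
    name: str
    value: float
    intensity: float | None
    radius: float


def theoretical_baseline(
    name: Literal["F", "G", "K", "L"], lam: float | None, r: float
) -> TheoreticalBaseline:
    """Closed-form expectation under a homogeneous Poisson process.

    F and G need the relevant intensity (of type i resp. type j); K and L
    are intensity-free (pi r^2 and r).
    """
    if name in ("F", "G"):
        if lam is None or lam < 0:
            raise ValueError(f"{name} baseline needs a non-negative intensity")
        value = 1.0 - math.exp(-lam * math.pi * r * r)
    elif name == "K":
        value = math.pi * r * r
    elif name == "L":
        value = float(r)
    else:
        raise ValueError(f"unknown statistic {name!r}")
    return TheoreticalBaseline(name=name, value=value, intensity=lam, radius=r)


def standardize_statistic(raw: float, baseline: float, sigma: float) -> float:
    """z = (raw - baseline) / sigma; nan when sigma is zero/undefined."""
    if not np.isfinite(raw) or not np.isfinite(sigma) or sigma <= 0:
        return float("nan")
    return (raw - baseline) / sigma


# ---------------------------------------------------------------------------
# global

def chi_squared_inhomogeneity(pattern: RegionPattern, type_i: str) -> float:
    """Sum over a 5x5 partition of (block density - overall density)^2 / density."""
    pts = pattern.points(type_i)
    if len(pts) == 0:
        return float("nan")
    w = pattern.window
    counts, _, _ = np.histogram2d(
        pts[:, 0],
        pts[:, 1],
        bins=5,
        range=[[w.xmin, w.xmax], [w.ymin, w.ymax]],
    )
    block_area = w.area / 25.0
    lam = len(pts) / w.area
    lam_blocks = counts / block_area
    return float(((lam_blocks - lam) ** 2 / lam).sum())


def global_distance_stats(
    pattern: RegionPattern, type_i: str, type_j: str, mad_constant: float = 1.0
) -> tuple[float, float]:
    """(median, MAD) over all pairwise type-i x type-j distances.

    For i == j the zero diagonal is excluded.
    """
    same = type_i == type_j
    pts_i = pattern.points(type_i)
    pts_j = pts_i if same else pattern.points(type_j)
    if len(pts_i) < (2 if same else 1) or len(pts_j) < 1:
        return float("nan"), float("nan")
    d = cdist(pts_i, pts_j)
    if same:
        n = len(pts_i)
        vals = d[~np.eye(n, dtype=bool)]
    else:
        vals = d.ravel()
    return float(np.median(vals)), median_abs_deviation(vals, mad_constant)


# ---------------------------------------------------------------------------
# Monte-Carlo null calibration

@dataclass(frozen=True)
class NullModel:
    """Null mean and standard deviation of a raw statistic at each radius.

    Calibrated by placing the observed numbers of points uniformly at random
    in the observed window (binomial process), recomputing the raw statistic
    ``n_null`` times.
    """

    statistic: str
    radii: tuple[float, ...]
    mean: np.ndarray
    sigma: np.ndarray
    n_null: int
    unreliable: bool = False

    def at(self, r: float) -> tuple[float, float]:
        idx = self.radii.index(r)
        return float(self.mean[idx]), float(self.sigma[idx])


def _uniform_points(rng: np.random.Generator, n: int, window: Window) -> np.ndarray:
    pts = rng.random((n, 2))
    pts[:, 0] = window.xmin + pts[:, 0] * window.width
    pts[:, 1] = window.ymin + pts[:, 1] * window.height
    return pts


_STAT_TAG = {"F": 0, "G": 1, "K": 2, "L": 3}


def null_sigma_mc(
    window: Window,
    n_i: int,
    n_j: int | None,
    statistic: Literal["F", "G", "K", "L"],
    radii,
    n_null: int = 199,
    seed: int = 0,
    grid_shape: tuple[int, int] = (100, 100),
    same: bool = False,
) -> NullModel:
    """Monte-Carlo null (mean, sigma per radius) for one raw statistic.

    Deterministic given ``seed``; the replicate stream depends only on the
    statistic family, the counts and the seed, so equal configurations share
    identical nulls.
    """
    if n_null < 2:
        raise ValueError("n_null must be at least 2")
    radii = _as_radii(radii)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            (seed, _STAT_TAG[statistic], n_i, 0 if n_j is None else n_j + 1, int(same))
        )
    )
    area = window.area
    grid = make_grid(window, grid_shape) if statistic == "F" else None
    reps = np.full((n_null, len(radii)), np.nan)
    for b in range(n_null):
        pts_i = _uniform_points(rng, n_i, window)
        if statistic == "F":
            if n_i >= 1:
                reps[b] = _f_raw(grid, pts_i, radii)
            continue
        if same:
            pts_j = pts_i
        else:
            pts_j = _uniform_points(rng, n_j, window)
        if len(pts_i) < (2 if same else 1) or len(pts_j) < 1:
            continue
        if statistic == "G":
            reps[b] = _g_raw(pts_i, pts_j, radii, same)
        else:
            k = _k_raw(pts_i, pts_j, radii, area, same)
            reps[b] = np.sqrt(k / math.pi) if statistic == "L" else k
    defined = np.isfinite(reps).all(axis=1)
    unreliable = defined.mean() < 0.5
    good = reps[defined]
    if len(good) < 2:
        mean = np.full(len(radii), np.nan)
        sigma = np.full(len(radii), np.nan)
        unreliable = True
    else:
        mean = good.mean(axis=0)
        sigma = good.std(axis=0, ddof=1)
    return NullModel(
        statistic=statistic,
        radii=tuple(float(r) for r in radii),
        mean=mean,
        sigma=sigma,
        n_null=n_null,
        unreliable=unreliable,
    )


class NullCalibrator:
    """Caches Monte-Carlo nulls per (statistic, counts) for one window.

    G, K and L nulls for the same (n_i, n_j) share the simulated point
    placements: each replicate places the points once and evaluates all
    three statistics, so calibrating one of them fills the cache for all.
    """

    def __init__(
        self,
        window: Window,
        radii,
        n_null: int = 199,
        seed: int = 0,
        grid_shape: tuple[int, int] = (100, 100),
    ) -> None:
        self.window = window
        self.radii = _as_radii(radii)
        self.n_null = n_null
        self.seed = seed
        self.grid_shape = grid_shape
        self._grid = None
        self._cache: dict[tuple, NullModel] = {}

    def _grid_points(self) -> np.ndarray:
        if self._grid is None:
            self._grid = make_grid(self.window, self.grid_shape)
        return self._grid

    def f_null(self, n_i: int) -> NullModel:
        key = ("F", n_i)
        if key not in self._cache:
            self._cache[key] = null_sigma_mc(
                self.window,
                n_i,
                None,
                "F",
                self.radii,
                n_null=self.n_null,
                seed=self.seed,
                grid_shape=self.grid_shape,
            )
        return self._cache[key]

    def gkl_null(self, n_i: int, n_j: int, same: bool) -> dict[str, NullModel]:
        """Joint null for G, K and L with shared replicate placements."""
        base_key = ("GKL", n_i, n_j, same)
        if base_key not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence((self.seed, 9, n_i, n_j, int(same)))
            )
            nr = len(self.radii)
            g_reps = np.full((self.n_null, nr), np.nan)
            k_reps = np.full((self.n_null, nr), np.nan)
            area = self.window.area
            for b in range(self.n_null):
                pts_i = _uniform_points(rng, n_i, self.window)
                pts_j = pts_i if same else _uniform_points(rng, n_j, self.window)
                if len(pts_i) < (2 if same else 1) or len(pts_j) < 1:
                    continue
                g_reps[b] = _g_raw(pts_i, pts_j, self.radii, same)
                k_reps[b] = _k_raw(pts_i, pts_j, self.radii, area, same)
            out = {}
            for name, reps in (
                ("G", g_reps),
                ("K", k_reps),
                ("L", np.sqrt(np.maximum(k_reps, 0.0) / math.pi)),
            ):
                defined = np.isfinite(reps).all(axis=1)
                good = reps[defined]
                unreliable = defined.mean() < 0.5 or len(good) < 2
                if len(good) < 2:
                    mean = np.full(nr, np.nan)
                    sigma = np.full(nr, np.nan)
                else:
                    mean = good.mean(axis=0)
                    sigma = good.std(axis=0, ddof=1)
                out[name] = NullModel(
                    statistic=name,
                    radii=tuple(float(r) for r in self.radii),
                    mean=mean,
                    sigma=sigma,
                    n_null=self.n_null,
                    unreliable=unreliable,
                )
            self._cache[base_key] = out
        return self._cache[base_key]
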