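"""Feature schema, per-region extraction and patient-level matrices.

The schema per region:

* per analysis type: normalized count, density, chi-squared inhomogeneity,
  standardized F at each radius, and standardized G/K/L against "*" (all
  cells of a different type) at each radius;
* median spatial score and its MAD (when the hierarchy defines the tumor /
  T-cell / macrophage roles);
* per configured ordered type pair: median and MAD of nearest-neighbour
  distances, standardized G/K/L at each radius;
* per unordered pair: median and MAD of all pairwise distances.

Undefined statistics propagate as NaN.  Region features are averaged per
patient and region class ignoring NaN, features observed in at most half of
the patients are dropped, and the rest are median-imputed.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import spatial
from .io import CellTypeHierarchy, RegionPattern

#: Radius-based statistic families; each is evaluated at every radius.
RADIUS_STATISTICS: tuple[str, ...] = ("F", "G", "K", "L")

#: Default evaluation radii in micrometers (first three "small", rest "large").
DEFAULT_RADII: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 75.0, 100.0)

SMALL_RADII: tuple[float, ...] = (5.0, 10.0, 25.0)
LARGE_RADII: tuple[float, ...] = (50.0, 75.0, 100.0)

_PAIR_STATS = {"G", "K", "L", "MMD", "MADMD", "MD", "MADD"}
_RADIUS_STATS = set(RADIUS_STATISTICS)


@dataclass(frozen=True)
class FeatureKey:
    """One named statistic for one type (or pair, or radius)."""

    statistic: str
    type_i: str | None = None
    type_j: str | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if (self.radius is not None) != (self.statistic in _RADIUS_STATS):
            raise ValueError(
                f"radius must be present iff statistic is radius-based: {self}"
            )
        if self.type_j is not None and self.statistic not in _PAIR_STATS:
            raise ValueError(f"type_j only valid for pairwise statistics: {self}")

    def render(self) -> str:
        r = "" if self.radius is None else format(self.radius, "g")
        return "|".join(
            [self.statistic, self.type_i or "", self.type_j or "", r]
        )

    @classmethod
    def parse(cls, text: str) -> "FeatureKey":
        stat, ti, tj, r = text.split("|")
        return cls(
            statistic=stat,
            type_i=ti or None,
            type_j=tj or None,
            radius=float(r) if r else None,
        )


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for region-level feature extraction."""

    radii: tuple[float, ...] = DEFAULT_RADII
    n_null: int = 199
    grid_shape: tuple[int, int] = (100, 100)
    seed: int = 0
    center: str = "theoretical"  # or "null_mean"
    mad_constant: float = 1.0
    score_roles: tuple[str, str, str] = ("Tumor", "Tcell", "Macrophage")

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if len(r) == 0 or (np.diff(r) <= 0).any() or (r <= 0).any():
            raise ValueError("radii must be positive and strictly increasing")
        if self.center not in ("theoretical", "null_mean"):
            raise ValueError(f"unknown centering {self.center!r}")

    def hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def unordered_pairs(
    pair_list: Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Distinct unordered pairs in first-appearance order."""
    seen: set[frozenset[str]] = set()
    out = []
    for a, b in pair_list:
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            out.append((a, b))
    return out


def include_spatial_score(
    hierarchy: CellTypeHierarchy, config: FeatureConfig
) -> bool:
    return set(config.score_roles) <= set(hierarchy.types)


def region_feature_schema(
    hierarchy: CellTypeHierarchy, config: FeatureConfig = FeatureConfig()
) -> list[FeatureKey]:
    """Deterministic ordered list of the features one region emits."""
    keys: list[FeatureKey] = []
    radii = config.radii
    for t in hierarchy.types:
        keys.append(FeatureKey("normalized_count", t))
        keys.append(FeatureKey("density", t))
        keys.append(FeatureKey("chi2", t))
        for r in radii:
            keys.append(FeatureKey("F", t, radius=r))
        for stat in ("G", "K", "L"):
            for r in radii:
                keys.append(FeatureKey(stat, t, spatial.STAR, radius=r))
    if include_spatial_score(hierarchy, config):
        keys.append(FeatureKey("MSS"))
        keys.append(FeatureKey("MADSS"))
    for ti, tj in hierarchy.pair_list:
        keys.append(FeatureKey("MMD", ti, tj))
        keys.append(FeatureKey("MADMD", ti, tj))
        for stat in ("G", "K", "L"):
            for r in radii:
                keys.append(FeatureKey(stat, ti, tj, radius=r))
    for ti, tj in unordered_pairs(hierarchy.pair_list):
        keys.append(FeatureKey("MD", ti, tj))
        keys.append(FeatureKey("MADD", ti, tj))
    return keys


def _standardized_gkl(
    pattern: RegionPattern,
    calib: spatial.NullCalibrator,
    type_i: str,
    type_j: str,
    config: FeatureConfig,
) -> dict[str, np.ndarray]:
    """Standardized G/K/L values at all radii for one (ordered) pair."""
    radii = np.asarray(config.radii)
    pts_i, pts_j, same = spatial._pair_points(pattern, type_i, type_j)
    n_i, n_j = len(pts_i), len(pts_j)
    nan = np.full(len(radii), np.nan)
    if n_i < (2 if same else 1) or n_j < 1:
        return {"G": nan, "K": nan.copy(), "L": nan.copy()}
    area = pattern.window.area
    lam_j = n_j / area
    raw = {
        "G": spatial._g_raw(pts_i, pts_j, radii, same),
        "K": spatial._k_raw(pts_i, pts_j, radii, area, same),
    }
    raw["L"] = np.sqrt(raw["K"] / np.pi)
    nulls = calib.gkl_null(n_i, n_j, same)
    out: dict[str, np.ndarray] = {}
    for stat in ("G", "K", "L"):
        theo = np.array(
            [spatial.theoretical_baseline(stat, lam_j, r).value for r in radii]
        )
        center = nulls[stat].mean if config.center == "null_mean" else theo
        out[stat] = np.array(
            [
                spatial.standardize_statistic(raw[stat][k], center[k], nulls[stat].sigma[k])
                for k in range(len(radii))
            ]
        )
    return out


def extract_region_features(
    pattern: RegionPattern,
    hierarchy: CellTypeHierarchy,
    config: FeatureConfig = FeatureConfig(),
    calibrator: spatial.NullCalibrator | None = None,
) -> dict[FeatureKey, float]:
    """Compute every schema feature for one region (NaN for undefined)."""
    schema = region_feature_schema(hierarchy, config)
    values: dict[FeatureKey, float] = {k: float("nan") for k in schema}
    if pattern.n_total == 0:
        return values
    calib = calibrator or spatial.NullCalibrator(
        pattern.window,
        config.radii,
        n_null=config.n_null,
        seed=config.seed,
        grid_shape=config.grid_shape,
    )
    radii = np.asarray(config.radii)
    area = pattern.window.area

    for t in hierarchy.types:
        n_t = pattern.count(t)
        values[FeatureKey("normalized_count", t)] = spatial.normalized_count(pattern, t)
        values[FeatureKey("density", t)] = spatial.cell_density(pattern, t)
        values[FeatureKey("chi2", t)] = spatial.chi_squared_inhomogeneity(pattern, t)
        if n_t >= 1:
            raw_f = spatial.empty_space_F_raw(pattern, t, radii, config.grid_shape)
            null_f = calib.f_null(n_t)
            lam_t = n_t / area
            for k, r in enumerate(radii):
                theo = spatial.theoretical_baseline("F", lam_t, r).value
                center = null_f.mean[k] if config.center == "null_mean" else theo
                values[FeatureKey("F", t, radius=float(r))] = spatial.standardize_statistic(
                    raw_f[k], center, null_f.sigma[k]
                )
        star = _standardized_gkl(pattern, calib, t, spatial.STAR, config)
        for stat in ("G", "K", "L"):
            for k, r in enumerate(radii):
                values[FeatureKey(stat, t, spatial.STAR, radius=float(r))] = float(
                    star[stat][k]
                )

    if include_spatial_score(hierarchy, config):
        tumor, tcell, mac = config.score_roles
        mss, madss = spatial.spatial_score_stats(
            pattern,
            config.mad_constant,
            tumor=tumor,
            tcell=tcell,
            macrophage=mac,
        )
        values[FeatureKey("MSS")] = mss
        values[FeatureKey("MADSS")] = madss

    for ti, tj in hierarchy.pair_list:
        mmd, madmd = spatial.local_distance_stats(pattern, ti, tj, config.mad_constant)
        values[FeatureKey("MMD", ti, tj)] = mmd
        values[FeatureKey("MADMD", ti, tj)] = madmd
        z = _standardized_gkl(pattern, calib, ti, tj, config)
        for stat in ("G", "K", "L"):
            for k, r in enumerate(radii):
                values[FeatureKey(stat, ti, tj, radius=float(r))] = float(z[stat][k])

    for ti, tj in unordered_pairs(hierarchy.pair_list):
        md, madd = spatial.global_distance_stats(pattern, ti, tj, config.mad_constant)
        values[FeatureKey("MD", ti, tj)] = md
        values[FeatureKey("MADD", ti, tj)] = madd
    return values


# ---------------------------------------------------------------------------
# patient-level matrices

@dataclass
class PatientFeatureMatrix:
    """Patients x features for one region class; NaN marks missing."""

    values: pd.DataFrame  # index: patient ids, columns: rendered FeatureKeys
    region_class: str
    n_regions: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    imputed: bool = False

    @property
    def keys(self) -> list[FeatureKey]:
        return [FeatureKey.parse(c) for c in self.values.columns]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path: str | Path, region_class: str = "tumor") -> "PatientFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        df.index = df.index.astype(str)
        return cls(values=df, region_class=region_class)


class EmptyMatrixError(ValueError):
    """Raised when missingness filtering removes every feature."""


def aggregate_patient_features(
    region_values: Iterable[tuple[str, str, dict[FeatureKey, float]]],
    patients: Sequence[str] | None = None,
) -> dict[str, PatientFeatureMatrix]:
    """Average region features per patient, separately per region class.

    Parameters
    ----------
    region_values
        Iterable of ``(patient_id, region_class, features)`` triples, one per
        region.  Missing (NaN) region values are ignored in the average; a
        feature missing in every region of a patient stays missing.
    patients
        Optional full patient list; patients with no region of some class get
        an all-missing row in that class's matrix.
    """
    rows: dict[str, list[tuple[str, dict[FeatureKey, float]]]] = {}
    for patient_id, region_class, feats in region_values:
        rows.setdefault(region_class, []).append((patient_id, feats))
    all_patients = list(patients) if patients is not None else sorted(
        {p for entries in rows.values() for p, _ in entries}
    )
    out: dict[str, PatientFeatureMatrix] = {}
    for region_class, entries in sorted(rows.items()):
        columns = [k.render() for k in entries[0][1]]
        df = pd.DataFrame(
            [[feats[k] for k in entries[0][1]] for _, feats in entries],
            columns=columns,
            index=[p for p, _ in entries],
        )
        grouped = df.groupby(level=0).mean()  # skipna by default
        n_regions = df.groupby(level=0).size()
        grouped = grouped.reindex(all_patients)
        out[region_class] = PatientFeatureMatrix(
            values=grouped,
            region_class=region_class,
            n_regions=n_regions.reindex(all_patients, fill_value=0),
        )
    return out


def filter_and_impute(matrix: PatientFeatureMatrix) -> PatientFeatureMatrix:
    """Drop features observed in <= 50% of patients, median-impute the rest."""
    df = matrix.values
    if len(df) < 2:
        raise ValueError("need at least 2 patients to filter and impute")
    n = len(df)
    observed = df.notna().sum(axis=0)
    keep = observed > n / 2
    if not keep.any():
        raise EmptyMatrixError(
            f"all {df.shape[1]} features observed in <= 50% of {n} patients"
        )
    kept = df.loc[:, keep]
    medians = kept.median(axis=0, skipna=True)
    dense = kept.fillna(medians)
    return replace(matrix, values=dense, imputed=True)


def missingness_report(matrix: PatientFeatureMatrix) -> dict:
    df = matrix.values
    return {
        "region_class": matrix.region_class,
        "n_patients": int(df.shape[0]),
        "n_features": int(df.shape[1]),
        "n_missing": int(df.isna().sum().sum()),
        "fraction_missing": float(df.isna().mean().mean()) if df.size else 0.0,
    }


def select_features(
    matrix: PatientFeatureMatrix, statistics: Sequence[str]
) -> PatientFeatureMatrix:
    """Sub-matrix restricted to the given statistic families."""
    stats = set(statistics)
    cols = [c for c in matrix.values.columns if FeatureKey.parse(c).statistic in stats]
    return replace(matrix, values=matrix.values[cols])


def group_keys_by(
    keys: Sequence[FeatureKey], by: str = "statistic"
) -> dict[str, list[int]]:
    """Column-index groups for joint importance, keyed by statistic or pair."""
    groups: dict[str, list[int]] = {}
    for idx, k in enumerate(keys):
        if by == "statistic":
            name = k.statistic
        elif by == "pair":
            name = "|".join(sorted(filter(None, (k.type_i, k.type_j)))) or k.statistic
        else:
            raise ValueError(f"unknown grouping {by!r}")
        groups.setdefault(name, []).append(idx)
    return groups
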