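"""Synthetic marked point patterns and cohorts with known structure.

Generators produce :class:`~spatialtme.io.RegionPattern` objects directly
(identity marks: one type per cell) and can serialize cohorts to the same
CSV dialect the reader consumes.  Expected per-type counts are preserved by
every structural variant, so two groups that differ only in spatial
structure have matched count features by construction.

Point placement rules:

* cluster offspring falling outside the window are re-drawn (not clipped)
  until inside, which preserves counts at the cost of a slight shrinkage of
  the effective cluster spread near edges;
* repulsion thinning re-draws candidate points until the target count is
  reached, erroring out if the admissible area is essentially empty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    CellRecord,
    CellTypeHierarchy,
    RegionPattern,
    ValidationError,
    Window,
    write_cell_table,
)

__all__ = [
    "CSRType",
    "ClusteredType",
    "InhibitedType",
    "AttractionPair",
    "RepulsionPair",
    "SimulationSpec",
    "SyntheticPatient",
    "SyntheticCohort",
    "simulate_region",
    "simulate_csr",
    "simulate_clustered",
    "simulate_cross_pair",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CSRType:
    """Homogeneous Poisson points of one type."""

    name: str
    intensity: float  # points per square micrometer

    @property
    def type_names(self) -> tuple[str, ...]:
        return (self.name,)

    def expected_intensities(self) -> dict[str, float]:
        return {self.name: self.intensity}


@dataclass(frozen=True)
class ClusteredType:
    """Thomas-type cluster process: Poisson parents, Gaussian offspring.

    Marginal intensity is ``parent_intensity * mean_offspring``.
    """

    name: str
    parent_intensity: float
    mean_offspring: float
    sigma: float  # offspring displacement sd, micrometers

    @property
    def type_names(self) -> tuple[str, ...]:
        return (self.name,)

    def expected_intensities(self) -> dict[str, float]:
        return {self.name: self.parent_intensity * self.mean_offspring}


@dataclass(frozen=True)
class InhibitedType:
    """Hard-core process: uniform points kept at least ``hard_core`` apart.

    Simple sequential inhibition: candidates are drawn uniformly and
    accepted only if no accepted point lies closer than ``hard_core``.
    The target count is Poisson(intensity * area), so expected counts match
    the CSR process with the same intensity (errors out when the packing is
    infeasible).
    """

    name: str
    intensity: float
    hard_core: float  # micrometers

    @property
    def type_names(self) -> tuple[str, ...]:
        return (self.name,)

    def expected_intensities(self) -> dict[str, float]:
        return {self.name: self.intensity}


@dataclass(frozen=True)
class AttractionPair:
    """Two types sharing cluster parents for a fraction of the second type.

    Type A is a Thomas process; type B points come from the same parents
    with probability ``shared_fraction`` and are uniform otherwise.
    """

    name_a: str
    name_b: str
    parent_intensity: float
    mean_offspring_a: float
    mean_offspring_b: float
    sigma: float
    shared_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValidationError("shared_fraction must be in [0, 1]")

    @property
    def type_names(self) -> tuple[str, ...]:
        return (self.name_a, self.name_b)

    def expected_intensities(self) -> dict[str, float]:
        return {
            self.name_a: self.parent_intensity * self.mean_offspring_a,
            self.name_b: self.parent_intensity * self.mean_offspring_b,
        }


@dataclass(frozen=True)
class RepulsionPair:
    """Type A uniform; type B excluded within ``exclusion`` of any A point."""

    name_a: str
    name_b: str
    intensity_a: float
    intensity_b: float
    exclusion: float  # micrometers

    @property
    def type_names(self) -> tuple[str, ...]:
        return (self.name_a, self.name_b)

    def expected_intensities(self) -> dict[str, float]:
        return {self.name_a: self.intensity_a, self.name_b: self.intensity_b}


Component = CSRType | ClusteredType | InhibitedType | AttractionPair | RepulsionPair


@dataclass(frozen=True)
class SimulationSpec:
    """Window plus one structural component per type (or pair of types)."""

    window: Window
    components: tuple[Component, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for comp in self.components:
            for name in comp.type_names:
                if name in seen:
                    raise ValidationError(
                        f"type {name!r} appears in more than one component"
                    )
                seen.add(name)

    @property
    def type_names(self) -> tuple[str, ...]:
        return tuple(n for c in self.components for n in c.type_names)

    def expected_intensities(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in self.components:
            out.update(c.expected_intensities())
        return out


def _uniform(rng: np.random.Generator, n: int, w: Window) -> np.ndarray:
    pts = rng.random((n, 2))
    pts[:, 0] = w.xmin + pts[:, 0] * w.width
    pts[:, 1] = w.ymin + pts[:, 1] * w.height
    return pts


def _offspring(
    rng: np.random.Generator, parents: np.ndarray, counts: np.ndarray,
    sigma: float, w: Window,
) -> np.ndarray:
    """Gaussian-displaced offspring, re-drawn until inside the window."""
    out = []
    for parent, k in zip(parents, counts):
        for _ in range(int(k)):
            for _attempt in range(1000):
                p = parent + rng.normal(0.0, sigma, size=2)
                if w.contains(p[0], p[1]):
                    out.append(p)
                    break
            else:  # pragma: no cover - pathological sigma >> window
                out.append(np.clip(parent, (w.xmin, w.ymin), (w.xmax, w.ymax)))
    return np.array(out, dtype=float).reshape(len(out), 2)


def _simulate_component(
    comp: Component, w: Window, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    area = w.area
    if isinstance(comp, CSRType):
        n = rng.poisson(comp.intensity * area)
        return {comp.name: _uniform(rng, n, w)}
    if isinstance(comp, ClusteredType):
        n_parents = rng.poisson(comp.parent_intensity * area)
        parents = _uniform(rng, n_parents, w)
        counts = rng.poisson(comp.mean_offspring, size=n_parents)
        return {comp.name: _offspring(rng, parents, counts, comp.sigma, w)}
    if isinstance(comp, InhibitedType):
        n = rng.poisson(comp.intensity * area)
        accepted: list[np.ndarray] = []
        attempts = 0
        while len(accepted) < n:
            attempts += 1
            if attempts > 1000 * max(n, 1):
                raise ValidationError(
                    f"hard core {comp.hard_core} um cannot pack {n} points "
                    f"into the window"
                )
            cand = _uniform(rng, 1, w)[0]
            if all(np.hypot(*(cand - p)) >= comp.hard_core for p in accepted):
                accepted.append(cand)
        return {comp.name: np.array(accepted).reshape(len(accepted), 2)}
    if isinstance(comp, AttractionPair):
        n_parents = rng.poisson(comp.parent_intensity * area)
        parents = _uniform(rng, n_parents, w)
        counts_a = rng.poisson(comp.mean_offspring_a, size=n_parents)
        pts_a = _offspring(rng, parents, counts_a, comp.sigma, w)
        lam_b = comp.parent_intensity * comp.mean_offspring_b
        # shared part: Thomas on the same parents; rest: uniform, so the
        # marginal intensity stays lam_b for any shared_fraction
        counts_b = rng.poisson(
            comp.mean_offspring_b * comp.shared_fraction, size=n_parents
        )
        pts_b_shared = _offspring(rng, parents, counts_b, comp.sigma, w)
        n_free = rng.poisson(lam_b * (1.0 - comp.shared_fraction) * area)
        pts_b = np.vstack([pts_b_shared, _uniform(rng, n_free, w)])
        return {comp.name_a: pts_a, comp.name_b: pts_b}
    if isinstance(comp, RepulsionPair):
        n_a = rng.poisson(comp.intensity_a * area)
        pts_a = _uniform(rng, n_a, w)
        n_b = rng.poisson(comp.intensity_b * area)
        accepted: list[np.ndarray] = []
        tries = 0
        from scipy.spatial import cKDTree

        tree = cKDTree(pts_a) if n_a else None
        while len(accepted) < n_b:
            tries += 1
            if tries > 200:
                raise ValidationError(
                    "repulsion exclusion leaves almost no admissible area"
                )
            cand = _uniform(rng, max(n_b, 16), w)
            if tree is not None:
                d = tree.query(cand)[0]
                cand = cand[d >= comp.exclusion]
            accepted.extend(cand)
        pts_b = np.array(accepted[:n_b]).reshape(n_b, 2)
        return {comp.name_a: pts_a, comp.name_b: pts_b}
    raise TypeError(f"unknown component {comp!r}")


def _build_pattern(
    points: dict[str, np.ndarray],
    spec: SimulationSpec,
    region_id: str,
    region_class: str,
    patient_id: str,
) -> RegionPattern:
    cells: list[CellRecord] = []
    marks: list[frozenset[str]] = []
    for name in spec.type_names:
        for x, y in points.get(name, np.empty((0, 2))):
            cells.append(
                CellRecord(
                    x=float(x),
                    y=float(y),
                    phenotype=name,
                    region_id=region_id,
                    region_class=region_class,
                    patient_id=patient_id,
                )
            )
            marks.append(frozenset({name}))
    return RegionPattern(
        window=spec.window,
        cells=cells,
        marks=marks,
        region_id=region_id,
        region_class=region_class,
        patient_id=patient_id,
        types=spec.type_names,
    )


def simulate_region(
    spec: SimulationSpec,
    seed: int | None = None,
    region_id: str = "r0",
    region_class: str = "tumor",
    patient_id: str = "p0",
) -> RegionPattern:
    """Draw one region pattern from a simulation spec (deterministic per seed)."""
    if spec.window.area <= 0:  # Window already enforces this, belt and braces
        raise ValidationError("zero-area window")
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    points: dict[str, np.ndarray] = {}
    for comp in spec.components:
        points.update(_simulate_component(comp, spec.window, rng))
    return _build_pattern(points, spec, region_id, region_class, patient_id)


def simulate_csr(spec: SimulationSpec, seed: int | None = None, **kw) -> RegionPattern:
    """Homogeneous Poisson pattern; every component must be CSR."""
    if not all(isinstance(c, CSRType) for c in spec.components):
        raise ValidationError("simulate_csr requires CSR components only")
    return simulate_region(spec, seed, **kw)


def simulate_clustered(spec: SimulationSpec, seed: int | None = None, **kw) -> RegionPattern:
    """Thomas-type clustered pattern; at least one clustered component."""
    if not any(isinstance(c, ClusteredType) for c in spec.components):
        raise ValidationError("simulate_clustered requires a clustered component")
    return simulate_region(spec, seed, **kw)


def simulate_cross_pair(spec: SimulationSpec, seed: int | None = None, **kw) -> RegionPattern:
    """Cross-type attraction or repulsion pattern."""
    if not any(isinstance(c, (AttractionPair, RepulsionPair)) for c in spec.components):
        raise ValidationError("simulate_cross_pair requires a cross-pair component")
    return simulate_region(spec, seed, **kw)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SyntheticPatient:
    patient_id: str
    group: str
    regions: list[RegionPattern]
    time_months: float
    event: bool


@dataclass
class SyntheticCohort:
    patients: list[SyntheticPatient]
    effect: dict = field(default_factory=dict)

    @property
    def hierarchy(self) -> CellTypeHierarchy:
        types = self.patients[0].regions[0].types
        return CellTypeHierarchy.identity(types)

    def survival_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "time_months": [p.time_months for p in self.patients],
                "event": [int(p.event) for p in self.patients],
            }
        )

    def region_records(self) -> list[CellRecord]:
        return [c for p in self.patients for reg in p.regions for c in reg.cells]

    def write(self, out_dir: str | Path) -> None:
        """Write cells.csv, survival.tsv, hierarchy.yaml and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cell_table(self.region_records(), out / "cells.csv")
        self.survival_frame().to_csv(out / "survival.tsv", sep="\t", index=False)
        self.hierarchy.to_yaml(out / "hierarchy.yaml")
        truth = {
            "groups": {p.patient_id: p.group for p in self.patients},
            "effect": self.effect,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def simulate_cohort(
    n_patients: int,
    regions_per_patient: int,
    spec_a: SimulationSpec,
    spec_b: SimulationSpec,
    hazard_ratio: float,
    seed: int = 0,
    baseline_hazard: float = math.log(2) / 24.0,
    followup_months: float = 60.0,
    group_fraction: float = 0.5,
    require_matched_counts: bool = True,
) -> SyntheticCohort:
    """Two-group cohort with group-specific spatial structure and survival.

    Group ``A`` patients draw regions from ``spec_a`` with exponential
    hazard ``baseline_hazard``; group ``B`` from ``spec_b`` with hazard
    ``baseline_hazard * hazard_ratio``.  Follow-up is administratively
    censored at ``followup_months``.
    """
    if n_patients < 4:
        raise ValidationError("need at least 4 patients")
    if hazard_ratio <= 0:
        raise ValidationError("hazard_ratio must be positive")
    n_a = int(round(n_patients * group_fraction))
    n_b = n_patients - n_a
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least 2 patients")
    if require_matched_counts:
        ia, ib = spec_a.expected_intensities(), spec_b.expected_intensities()
        if set(ia) != set(ib) or any(
            not math.isclose(ia[t], ib[t], rel_tol=1e-9) for t in ia
        ):
            raise ValidationError(
                f"per-type intensities differ between groups: {ia} vs {ib}"
            )
    rng = np.random.default_rng(seed)
    patients: list[SyntheticPatient] = []
    for idx in range(n_patients):
        group = "A" if idx < n_a else "B"
        spec = spec_a if group == "A" else spec_b
        hazard = baseline_hazard * (1.0 if group == "A" else hazard_ratio)
        regions = [
            simulate_region(
                spec,
                seed=int(rng.integers(0, 2**31 - 1)),
                region_id=f"r{j}",
                region_class="tumor",
                patient_id=f"p{idx:03d}",
            )
            for j in range(regions_per_patient)
        ]
        t = float(rng.exponential(1.0 / hazard))
        event = t <= followup_months
        patients.append(
            SyntheticPatient(
                patient_id=f"p{idx:03d}",
                group=group,
                regions=regions,
                time_months=min(t, followup_months),
                event=event,
            )
        )
    effect = {
        "hazard_ratio": hazard_ratio,
        "group_sizes": {"A": n_a, "B": n_b},
        "spec_a": repr(spec_a.components),
        "spec_b": repr(spec_b.components),
    }
    return SyntheticCohort(patients=patients, effect=effect)
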