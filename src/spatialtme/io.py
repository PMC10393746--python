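"""Reading, validation and marking of per-region single-cell tables.

A *region* is one rectangular imaged field holding a marked point pattern:
cells with micrometer coordinates and a phenotype label.  Raw phenotype
labels are expanded into (possibly multiple) analysis cell-type marks via a
configurable hierarchy, e.g. a ``CD3+CD8+PD-1+`` cell is simultaneously a
``Tcell``, a ``CD8+ Tcell`` and a ``CD3+CD8+PD1+ Tcell``.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class CellTableError(ValueError):
    """Base class for cell-table problems."""


class ConfigError(CellTableError):
    """A required column or configuration entry is missing."""


class ParseError(CellTableError):
    """A cell row could not be converted (e.g. non-numeric coordinate)."""


class ValidationError(CellTableError):
    """Row content violates the domain contract (labels, geometry)."""


#: Closed set of raw phenotype labels produced by the upstream phenotyping step.
RAW_PHENOTYPES: tuple[str, ...] = (
    "PAX5+PD-L1-",
    "PAX5+PD-L1+",
    "CD163+PD-L1-",
    "CD163+PD-L1+",
    "CD3+CD8-PD-1-",
    "CD3+CD8+PD-1-",
    "CD3+CD8-PD-1+",
    "CD3+CD8+PD-1+",
    "other PD-L1+",
    "other",
)

#: Default column-name mapping for delimited cell tables.
DEFAULT_COLUMNS: dict[str, str] = {
    "x": "x",
    "y": "y",
    "phenotype": "phenotype",
    "region_id": "region_id",
    "region_class": "region_class",
    "patient_id": "patient_id",
}

REGION_CLASSES = ("tumor", "border")


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: coordinates in micrometers plus identifiers."""

    x: float
    y: float
    phenotype: str
    region_id: str
    region_class: str
    patient_id: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(
                f"non-finite coordinate ({self.x}, {self.y}) for cell in "
                f"region {self.region_id!r}"
            )


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window (micrometers)."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValidationError(
                f"degenerate window [{self.xmin}, {self.xmax}] x "
                f"[{self.ymin}, {self.ymax}]: both sides must have positive length"
            )

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax


# The three lineages and their nested sub-types.  Order defines column order
# throughout the package.
_LINEAGES: dict[str, tuple[str, ...]] = {
    "Macrophage": ("Macrophage", "PDL1- Macrophage", "PDL1+ Macrophage"),
    "Tcell": (
        "Tcell",
        "CD8- Tcell",
        "CD8+ Tcell",
        "CD3+CD8-PD1- Tcell",
        "CD3+CD8-PD1+ Tcell",
        "CD3+CD8+PD1- Tcell",
        "CD3+CD8+PD1+ Tcell",
    ),
    "Tumor": ("Tumor", "PDL1- Tumor", "PDL1+ Tumor"),
}

#: The 13 analysis cell types (coarse plus fine), in canonical order.
ANALYSIS_TYPES: tuple[str, ...] = tuple(
    t for lineage in _LINEAGES.values() for t in lineage
)

_DEFAULT_TYPE_MAP: dict[str, frozenset[str]] = {
    "PAX5+PD-L1-": frozenset({"Tumor", "PDL1- Tumor"}),
    "PAX5+PD-L1+": frozenset({"Tumor", "PDL1+ Tumor"}),
    "CD163+PD-L1-": frozenset({"Macrophage", "PDL1- Macrophage"}),
    "CD163+PD-L1+": frozenset({"Macrophage", "PDL1+ Macrophage"}),
    "CD3+CD8-PD-1-": frozenset({"Tcell", "CD8- Tcell", "CD3+CD8-PD1- Tcell"}),
    "CD3+CD8+PD-1-": frozenset({"Tcell", "CD8+ Tcell", "CD3+CD8+PD1- Tcell"}),
    "CD3+CD8-PD-1+": frozenset({"Tcell", "CD8- Tcell", "CD3+CD8-PD1+ Tcell"}),
    "CD3+CD8+PD-1+": frozenset({"Tcell", "CD8+ Tcell", "CD3+CD8+PD1+ Tcell"}),
    "other PD-L1+": frozenset(),
    "other": frozenset(),
}


def _default_pair_list(types: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Self pairs plus all cross-lineage pairs, in canonical order.

    Within-lineage pairs of nested types (e.g. Tcell vs CD8+ Tcell) are
    excluded because a cell can carry both marks, which makes nearest-other
    distances degenerate.  The list is a documented default and fully
    user-overridable.
    """
    lineage_of: dict[str, str] = {}
    for lineage, members in _LINEAGES.items():
        for t in members:
            lineage_of[t] = lineage
    pairs: list[tuple[str, str]] = [(t, t) for t in types]
    for a_idx, a in enumerate(types):
        for b in types[a_idx + 1 :]:
            if lineage_of.get(a) != lineage_of.get(b):
                pairs.append((a, b))
    return tuple(pairs)


@dataclass(frozen=True)
class CellTypeHierarchy:
    """Mapping from raw phenotype labels to analysis-type mark sets.

    Parameters
    ----------
    type_map
        Raw phenotype -> set of analysis types (may be empty, e.g. "other").
    types
        Ordered tuple of all analysis types; defines schema order.
    pair_list
        Ordered cell-type pairs to evaluate for pairwise statistics;
        self-pairs allowed.
    """

    type_map: Mapping[str, frozenset[str]]
    types: tuple[str, ...]
    pair_list: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        known = set(self.types)
        for pheno, marks in self.type_map.items():
            extra = set(marks) - known
            if extra:
                raise ConfigError(
                    f"phenotype {pheno!r} maps to unknown types {sorted(extra)}"
                )
        seen: set[tuple[str, str]] = set()
        for pair in self.pair_list:
            if pair in seen:
                raise ConfigError(f"pair {pair} listed twice")
            seen.add(pair)
            for t in pair:
                if t not in known:
                    raise ConfigError(f"pair {pair} references unknown type {t!r}")

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return tuple(self.type_map)

    def marks_for(self, phenotype: str) -> frozenset[str]:
        try:
            return self.type_map[phenotype]
        except KeyError:
            raise ValidationError(f"unknown phenotype label {phenotype!r}") from None

    @classmethod
    def default(cls) -> "CellTypeHierarchy":
        return cls(
            type_map=dict(_DEFAULT_TYPE_MAP),
            types=ANALYSIS_TYPES,
            pair_list=_default_pair_list(ANALYSIS_TYPES),
        )

    @classmethod
    def identity(
        cls,
        types: Sequence[str],
        pair_list: Sequence[tuple[str, str]] | None = None,
        include_self_pairs: bool = True,
    ) -> "CellTypeHierarchy":
        """Hierarchy where each phenotype label is its own analysis type."""
        types = tuple(types)
        if pair_list is None:
            pairs: list[tuple[str, str]] = []
            if include_self_pairs:
                pairs.extend((t, t) for t in types)
            for i, a in enumerate(types):
                for b in types[i + 1 :]:
                    pairs.append((a, b))
            pair_list = pairs
        return cls(
            type_map={t: frozenset({t}) for t in types},
            types=types,
            pair_list=tuple(tuple(p) for p in pair_list),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CellTypeHierarchy":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            types = tuple(raw["types"])
            type_map = {
                str(k): frozenset(v or []) for k, v in raw["type_map"].items()
            }
            pair_list = tuple((str(a), str(b)) for a, b in raw["pairs"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed hierarchy file {path}: {exc}") from exc
        return cls(type_map=type_map, types=types, pair_list=pair_list)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "types": list(self.types),
            "type_map": {k: sorted(v) for k, v in self.type_map.items()},
            "pairs": [list(p) for p in self.pair_list],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class RegionPattern:
    """A marked point pattern inside a rectangular observation window."""

    window: Window
    cells: list[CellRecord]
    marks: list[frozenset[str]]
    region_id: str
    region_class: str
    patient_id: str
    types: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.marks):
            raise ValidationError("cells and marks length mismatch")
        self._coords = np.array(
            [(c.x, c.y) for c in self.cells], dtype=float
        ).reshape(len(self.cells), 2)

    @property
    def n_total(self) -> int:
        """All cells in the region, including unmarked ('other') ones."""
        return len(self.cells)

    def count(self, type_name: str) -> int:
        return sum(1 for m in self.marks if type_name in m)

    @property
    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in self.types}
        for m in self.marks:
            for t in m:
                if t in out:
                    out[t] += 1
                else:
                    out[t] = out.get(t, 0) + 1
        return out

    def points(self, type_name: str) -> np.ndarray:
        """(n, 2) coordinates of cells carrying mark ``type_name``."""
        idx = [i for i, m in enumerate(self.marks) if type_name in m]
        return self._coords[idx]

    def points_not(self, type_name: str) -> np.ndarray:
        """Coordinates of all cells *without* mark ``type_name`` (incl. unmarked)."""
        idx = [i for i, m in enumerate(self.marks) if type_name not in m]
        return self._coords[idx]

    @property
    def coords(self) -> np.ndarray:
        return self._coords


def infer_window(cells: Sequence[CellRecord], padding: float = 0.0) -> Window:
    """Bounding rectangle of the cell coordinates expanded by ``padding``."""
    if not cells:
        raise ValidationError("cannot infer a window from an empty cell list")
    xs = np.array([c.x for c in cells])
    ys = np.array([c.y for c in cells])
    return Window(
        xmin=float(xs.min() - padding),
        xmax=float(xs.max() + padding),
        ymin=float(ys.min() - padding),
        ymax=float(ys.max() + padding),
    )


def build_hierarchy_marks(
    cells: Sequence[CellRecord],
    hierarchy: CellTypeHierarchy,
    window: Window,
) -> RegionPattern:
    """Attach hierarchy mark sets to cells and assemble a :class:`RegionPattern`."""
    if not cells:
        raise ValidationError("cannot build a pattern from an empty cell list")
    ids = {(c.region_id, c.region_class, c.patient_id) for c in cells}
    if len(ids) != 1:
        raise ValidationError(
            f"cells span multiple regions/patients: {sorted(ids)}"
        )
    for idx, c in enumerate(cells):
        if not window.contains(c.x, c.y):
            raise ValidationError(
                f"cell {idx} at ({c.x}, {c.y}) lies outside the window"
            )
    marks = [hierarchy.marks_for(c.phenotype) for c in cells]
    region_id, region_class, patient_id = next(iter(ids))
    return RegionPattern(
        window=window,
        cells=list(cells),
        marks=marks,
        region_id=region_id,
        region_class=region_class,
        patient_id=patient_id,
        types=hierarchy.types,
    )


def parse_cell_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
    phenotypes: Iterable[str] | None = RAW_PHENOTYPES,
) -> list[CellRecord]:
    """Parse a delimited cell table into :class:`CellRecord` rows.

    Parameters
    ----------
    columns
        Mapping from canonical field name (``x``, ``y``, ``phenotype``,
        ``region_id``, ``region_class``, ``patient_id``) to the header name
        used in the file.  Defaults to the identity mapping.
    phenotypes
        Closed set of accepted phenotype labels, or ``None`` to accept any.

    Row order is preserved; no rows are dropped silently.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [v for v in colmap.values() if v not in header]
        if missing:
            raise ConfigError(
                f"{path.name}: missing required column(s) {missing}; header is {header}"
            )
        rows = list(reader)

    allowed = set(phenotypes) if phenotypes is not None else None
    records: list[CellRecord] = []
    bad_labels: set[str] = set()
    for lineno, row in enumerate(rows, start=2):  # header is line 1
        try:
            x = float(row[colmap["x"]])
            y = float(row[colmap["y"]])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path.name}: non-numeric coordinate on line {lineno}: "
                f"x={row[colmap['x']]!r} y={row[colmap['y']]!r}"
            ) from None
        pheno = row[colmap["phenotype"]]
        if allowed is not None and pheno not in allowed:
            bad_labels.add(pheno)
            continue
        records.append(
            CellRecord(
                x=x,
                y=y,
                phenotype=pheno,
                region_id=row[colmap["region_id"]],
                region_class=row[colmap["region_class"]],
                patient_id=row[colmap["patient_id"]],
            )
        )
    if bad_labels:
        raise ValidationError(
            f"{path.name}: unknown phenotype label(s) {sorted(bad_labels)}"
        )
    return records


def write_cell_table(
    records: Sequence[CellRecord],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Serialize cell records in the exact dialect :func:`parse_cell_table` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(DEFAULT_COLUMNS))
        for c in records:
            writer.writerow(
                [repr(c.x), repr(c.y), c.phenotype, c.region_id, c.region_class, c.patient_id]
            )


def group_regions(
    records: Sequence[CellRecord],
    hierarchy: CellTypeHierarchy,
    window: Window | None = None,
    padding: float = 0.0,
) -> list[RegionPattern]:
    """Split records by (patient, region) and build one pattern per region.

    If ``window`` is None the bounding box (plus ``padding``) of each region's
    cells is used.
    """
    by_region: dict[tuple[str, str], list[CellRecord]] = {}
    for c in records:
        by_region.setdefault((c.patient_id, c.region_id), []).append(c)
    patterns = []
    for key in sorted(by_region):
        cells = by_region[key]
        win = window if window is not None else infer_window(cells, padding)
        patterns.append(build_hierarchy_marks(cells, hierarchy, win))
    return patterns
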