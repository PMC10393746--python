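"""End-to-end orchestration: cell tables -> feature matrices -> analyses."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import survival as surv
from . import unsupervised as unsup
from .features import (
    FeatureConfig,
    PatientFeatureMatrix,
    aggregate_patient_features,
    extract_region_features,
    filter_and_impute,
    missingness_report,
)
from .io import CellTypeHierarchy, group_regions, parse_cell_table

log = logging.getLogger("spatialtme")


@dataclass
class RunConfig:
    """Paths plus knobs for a full pipeline run."""

    cells: str
    out_dir: str
    hierarchy: str | None = None  # YAML path; None -> default 13-type hierarchy
    survival: str | None = None
    radii: tuple[float, ...] = feat.DEFAULT_RADII
    n_null: int = 199
    grid: tuple[int, int] = (100, 100)
    seed: int = 0
    center: str = "theoretical"
    mad_constant: float = 1.0
    padding: float = 0.0
    k_min: int = 2
    k_max: int = 5
    nmf_runs: int = 20
    nmf_iter: int = 2000
    n_trees: int = 100_000
    efs_cutoff: float = 12.0
    only: tuple[str, ...] = ("cluster", "classify", "survival")
    phenotypes_open: bool = False  # accept any phenotype label in the tables

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            radii=tuple(float(r) for r in self.radii),
            n_null=self.n_null,
            grid_shape=tuple(self.grid),
            seed=self.seed,
            center=self.center,
            mad_constant=self.mad_constant,
        )

    def hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def load_hierarchy(self) -> CellTypeHierarchy:
        if self.hierarchy:
            return CellTypeHierarchy.from_yaml(self.hierarchy)
        return CellTypeHierarchy.default()


def run_extract(config: RunConfig) -> dict[str, PatientFeatureMatrix]:
    """Parse cell tables, extract region features, write patient matrices."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hierarchy = config.load_hierarchy()
    fcfg = config.feature_config()
    cells_path = Path(config.cells)
    paths = (
        sorted(cells_path.glob("*.csv")) if cells_path.is_dir() else [cells_path]
    )
    if not paths:
        raise FileNotFoundError(f"no cell tables found under {cells_path}")
    phenos = None if config.phenotypes_open else hierarchy.phenotypes
    records = []
    for p in paths:
        records.extend(parse_cell_table(p, phenotypes=phenos))
    if not records:
        raise FileNotFoundError(f"no parsable cell rows under {cells_path}")
    patterns = group_regions(records, hierarchy, padding=config.padding)
    patients = sorted({p.patient_id for p in patterns})
    region_values = []
    for pattern in patterns:
        t0 = time.perf_counter()
        values = extract_region_features(pattern, hierarchy, fcfg)
        n_missing = sum(1 for v in values.values() if not np.isfinite(v))
        log.info(
            "region %s/%s (%s): %d cells, %d/%d missing, %.2fs",
            pattern.patient_id,
            pattern.region_id,
            pattern.region_class,
            pattern.n_total,
            n_missing,
            len(values),
            time.perf_counter() - t0,
        )
        region_values.append((pattern.patient_id, pattern.region_class, values))
    matrices = aggregate_patient_features(region_values, patients=patients)
    sidecar = {"config_hash": config.hash(), "classes": {}}
    for region_class, matrix in matrices.items():
        sidecar["classes"][region_class] = missingness_report(matrix)
        matrix.to_tsv(out / f"features_{region_class}_raw.tsv")
        try:
            dense = filter_and_impute(matrix)
        except (feat.EmptyMatrixError, ValueError) as exc:
            log.warning("skipping %s matrix: %s", region_class, exc)
            continue
        dense.to_tsv(out / f"features_{region_class}.tsv")
        matrices[region_class] = dense
    (out / "features_meta.json").write_text(json.dumps(sidecar, indent=2))
    return matrices


def run_cluster(config: RunConfig, matrix: PatientFeatureMatrix) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    V = unsup.nonnegative_scale(matrix.values).T  # features x patients
    results = {}
    labels_df = pd.DataFrame(index=matrix.values.index)
    for k in range(config.k_min, config.k_max + 1):
        res = unsup.consensus_cluster(
            V,
            k,
            n_runs=config.nmf_runs,
            n_iter=config.nmf_iter,
            seed=config.seed,
        )
        labels_df[f"k{k}"] = res.labels
        pd.DataFrame(
            res.consensus, index=matrix.values.index, columns=matrix.values.index
        ).to_csv(out / f"consensus_k{k}.tsv", sep="\t")
        columns = list(matrix.values.columns)
        results[k] = {
            "cophenetic": res.cophenetic,
            "top_features": {
                str(c + 1): [columns[i] for i in idx]
                for c, idx in res.top_features.items()
            },
        }
    labels_df.to_csv(out / "cluster_labels.tsv", sep="\t", index_label="patient_id")
    (out / "cluster_report.json").write_text(json.dumps(results, indent=2))
    return results


def run_classify(
    config: RunConfig,
    matrix: PatientFeatureMatrix,
    records: list[surv.SurvivalRecord],
) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_all = surv.dichotomize_outcome(records, cutoff=config.efs_cutoff)
    ids = list(matrix.values.index)
    missing = sorted(set(ids) - set(labels_all))
    if missing:
        raise ValueError(f"patients missing from the survival table: {missing}")
    used = [pid for pid in ids if labels_all[pid] != surv.EXCLUDED]
    log.info(
        "classification uses %d/%d patients (%d censored before %.0f months)",
        len(used),
        len(ids),
        len(ids) - len(used),
        config.efs_cutoff,
    )
    X = matrix.values.loc[used]
    y = [labels_all[pid] for pid in used]
    rf = surv.rf_oob_classify(X, y, n_trees=config.n_trees, seed=config.seed)
    keys = matrix.keys
    stat_groups = feat.group_keys_by(keys, by="statistic")
    group_imp = surv.group_permutation_importance(
        rf, X, y, stat_groups, seed=config.seed
    )
    report = {
        "oob_auc": rf.oob_auc,
        "n_patients": len(used),
        "n_excluded": len(ids) - len(used),
        "settings": rf.settings,
        "group_importance": group_imp,
    }
    (out / "rf_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_survival(
    config: RunConfig,
    groups: dict[str, str],
    records: list[surv.SurvivalRecord],
) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = surv.km_logrank(groups, records)
    km_rows = []
    for g, curve in res["curves"].items():
        for t, s in curve.itertuples():
            km_rows.append({"group": g, "time": t, "survival": s})
    pd.DataFrame(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
    report = {
        "statistic": res["statistic"],
        "p_value": res["p_value"],
        "at_risk": res["at_risk"],
        "groups": res["groups"],
    }
    (out / "logrank_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_analyze(config: RunConfig) -> dict:
    """Clustering, classification and survival on an extracted tumor matrix."""
    out = Path(config.out_dir)
    matrix_path = out / "features_tumor.tsv"
    if not matrix_path.exists():
        raise FileNotFoundError(f"feature matrix not found: {matrix_path}")
    matrix = PatientFeatureMatrix.from_tsv(matrix_path, region_class="tumor")
    results: dict = {}
    if "cluster" in config.only:
        results["cluster"] = run_cluster(config, matrix)
    if config.survival and ("classify" in config.only or "survival" in config.only):
        records = surv.read_survival_table(config.survival)
        ids = set(matrix.values.index)
        known = {r.patient_id for r in records}
        unmatched = sorted(ids - known)
        if unmatched:
            raise ValueError(
                f"patients without survival records: {unmatched}"
            )
        if "classify" in config.only:
            results["classify"] = run_classify(config, matrix, records)
        if "survival" in config.only and "cluster" in results:
            labels = pd.read_csv(
                out / "cluster_labels.tsv", sep="\t", index_col="patient_id"
            )
            col = f"k{config.k_min}"
            groups = {str(pid): str(v) for pid, v in labels[col].items()}
            results["survival"] = run_survival(config, groups, records)
    (out / "analysis_report.json").write_text(
        json.dumps({k: v for k, v in results.items() if k != "cluster"} | {
            "cluster": results.get("cluster"),
            "config_hash": config.hash(),
        }, indent=2, default=str)
    )
    return results


def run_all(config: RunConfig) -> dict:
    run_extract(config)
    return run_analyze(config)
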