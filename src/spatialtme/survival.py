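"""Outcome dichotomization, OOB random forest, permutation importance, KM/log-rank.

The forest is a hand-rolled bagging ensemble over scikit-learn decision
trees so that out-of-bag membership stays explicit: a patient's OOB
probability only ever uses trees whose bootstrap sample excluded them, and
(joint) permutation importance re-scores the *same* trees on
column-permuted data.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SurvivalRecord",
    "dichotomize_outcome",
    "RFResult",
    "rf_oob_classify",
    "group_permutation_importance",
    "signed_feature_direction",
    "km_logrank",
    "rank_auc",
]

POOR, GOOD, EXCLUDED = "poor", "good", "excluded"


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValueError(
                f"non-positive follow-up time for {self.patient_id}: {self.time_months}"
            )


def read_survival_table(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(str(r.patient_id), float(r.time_months), bool(int(r.event)))
        for r in df.itertuples()
    ]


def dichotomize_outcome(
    records: Sequence[SurvivalRecord], cutoff: float = 12.0
) -> dict[str, str]:
    """Label patients poor/good/excluded by event status at ``cutoff`` months.

    Event before the cutoff -> poor; event-free follow-up past the cutoff ->
    good; censored before the cutoff -> excluded (outcome undetermined).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels: dict[str, str] = {}
    for rec in records:
        if rec.event and rec.time_months < cutoff:
            labels[rec.patient_id] = POOR
        elif rec.time_months >= cutoff:
            labels[rec.patient_id] = GOOD
        else:
            labels[rec.patient_id] = EXCLUDED
    return labels


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic with midranks for ties."""
    y = np.asarray(y_true, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class RFResult:
    oob_proba: np.ndarray  # P(positive class) per patient
    oob_auc: float
    trees: list[DecisionTreeClassifier] = field(repr=False, default_factory=list)
    inbag: list[np.ndarray] = field(repr=False, default_factory=list)
    classes: tuple[str, str] = (GOOD, POOR)
    settings: dict = field(default_factory=dict)


def _oob_proba(
    trees: Sequence[DecisionTreeClassifier],
    inbag: Sequence[np.ndarray],
    X: np.ndarray,
) -> np.ndarray:
    """Mean positive-class probability per row over trees OOB for that row."""
    n = X.shape[0]
    votes = np.zeros(n)
    counts = np.zeros(n)
    for tree, bag in zip(trees, inbag):
        oob = np.ones(n, dtype=bool)
        oob[bag] = False
        if not oob.any():
            continue
        proba = tree.predict_proba(X[oob])
        pos_col = int(np.argmax(tree.classes_ == 1)) if 1 in tree.classes_ else None
        votes[oob] += proba[:, pos_col] if pos_col is not None else 0.0
        counts[oob] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, votes / np.maximum(counts, 1), np.nan)


def rf_oob_classify(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    n_trees: int = 100_000,
    mtry: int | None = None,
    node_size: int = 1,
    seed: int = 0,
) -> RFResult:
    """Random forest with out-of-bag AUC for a poor/good outcome.

    ``mtry`` defaults to floor(sqrt(p)); ``node_size`` is the minimum leaf
    size.  The positive class is ``poor``.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values; impute first")
    y = np.array([1 if lab == POOR else 0 for lab in labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n, p = X.shape
    mtry = mtry or max(1, int(np.sqrt(p)))
    rng = np.random.default_rng(seed)
    trees: list[DecisionTreeClassifier] = []
    inbag: list[np.ndarray] = []
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    for t in range(n_trees):
        bag = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            min_samples_leaf=node_size,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X[bag], y[bag])
        trees.append(tree)
        inbag.append(bag)
    proba = _oob_proba(trees, inbag, X)
    ok = ~np.isnan(proba)
    auc = rank_auc(y[ok], proba[ok])
    return RFResult(
        oob_proba=proba,
        oob_auc=auc,
        trees=trees,
        inbag=inbag,
        settings={
            "n_trees": n_trees,
            "mtry": mtry,
            "node_size": node_size,
            "seed": seed,
        },
    )


def group_permutation_importance(
    rf: RFResult,
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    groups: Mapping[str, Sequence[int]],
    n_perm: int = 10,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Mean OOB-AUC drop when each group's columns are jointly permuted.

    All columns of a group share the same row permutation per replicate, so
    within-group structure is preserved while the group's relation to the
    outcome is destroyed.  Singleton groups give per-feature importance.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.array([1 if lab == POOR else 0 for lab in labels], dtype=int)
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, float]] = {}
    base = rf.oob_auc
    for name, cols in groups.items():
        cols = np.asarray(list(cols), dtype=int)
        if cols.size == 0:
            raise ValueError(f"group {name!r} is empty")
        drops = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, cols] = X[perm][:, cols]
            proba = _oob_proba(rf.trees, rf.inbag, Xp)
            ok = ~np.isnan(proba)
            drops[b] = base - rank_auc(y[ok], proba[ok])
        out[name] = {
            "importance": float(drops.mean()),
            "se": float(drops.std(ddof=1) / np.sqrt(n_perm)) if n_perm > 1 else 0.0,
        }
    return out


def signed_feature_direction(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    importance: Mapping[str, float] | Sequence[float],
) -> np.ndarray:
    """Importance signed by the poor-vs-good mean difference per feature."""
    X = np.asarray(matrix, dtype=float)
    y = np.array([1 if lab == POOR else 0 for lab in labels], dtype=bool)
    if not y.any() or y.all():
        raise ValueError("both outcome classes must be present")
    diff = X[y].mean(axis=0) - X[~y].mean(axis=0)
    sign = np.sign(diff)
    if isinstance(importance, Mapping):
        imp = np.array([importance[k] for k in importance])
    else:
        imp = np.asarray(list(importance), dtype=float)
    return sign * imp


def km_logrank(
    groups: Mapping[str, str],
    records: Sequence[SurvivalRecord],
    at_times: Sequence[float] = (0, 12, 24, 36, 48, 60),
) -> dict:
    """Kaplan-Meier curves per group plus the log-rank test.

    ``groups`` maps patient id -> group label; patients without a label are
    ignored.  Returns survival functions, the chi-squared statistic, its
    p-value, and a number-at-risk table at ``at_times``.
    """
    recs = [r for r in records if r.patient_id in groups]
    if not recs:
        raise ValueError("no records match the provided group labels")
    labels = sorted({groups[r.patient_id] for r in recs})
    if len(labels) < 2:
        raise ValueError(f"need >= 2 groups, got {labels}")
    by_group = {g: [r for r in recs if groups[r.patient_id] == g] for g in labels}
    for g, rs in by_group.items():
        if not rs:
            raise ValueError(f"group {g!r} has no records")
    curves = {}
    at_risk = {}
    for g, rs in by_group.items():
        kmf = KaplanMeierFitter()
        kmf.fit(
            [r.time_months for r in rs],
            [int(r.event) for r in rs],
            label=str(g),
        )
        curves[g] = kmf.survival_function_
        at_risk[g] = {
            float(t): int(sum(1 for r in rs if r.time_months >= t)) for t in at_times
        }
    df = pd.DataFrame(
        {
            "time": [r.time_months for r in recs],
            "event": [int(r.event) for r in recs],
            "group": [groups[r.patient_id] for r in recs],
        }
    )
    profiles = {
        g: tuple(sorted((r.time_months, r.event) for r in rs))
        for g, rs in by_group.items()
    }
    if len(set(profiles.values())) == 1:
        # identical groups: the statistic is exactly 0 but the chi2 machinery
        # can return nan from 0/0 variance terms
        statistic, p = 0.0, 1.0
    else:
        res = multivariate_logrank_test(df["time"], df["group"], df["event"])
        statistic, p = float(res.test_statistic), float(res.p_value)
    return {
        "curves": curves,
        "statistic": statistic,
        "p_value": p,
        "at_risk": at_risk,
        "groups": labels,
    }
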