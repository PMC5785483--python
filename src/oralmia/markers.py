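"""Diagnostic marker selection and the composite microbial index (MIA).

The workflow mirrors the analysis stages: a random forest ranks OTUs by
impurity-decrease importance, stratified k-fold cross-validation picks the
smallest marker count minimizing classification error, and a simple composite
index

    MIA = mean(abundance of disease-enriched markers)
        - mean(abundance of control-enriched markers)

is scored per sample.  Candidate panels are enumerated over the (m, n) prefix
grid of the two direction-ranked marker lists (an exhaustive power-set mode
exists for small marker sets, as an oracle), each panel evaluated by ROC/AUC
with a Youden-index cut-off.

The index's abundance scale defaults to raw per-sample read counts; a
relative-abundance mode is available via ``scale="relative"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .difftax import relative_abundance
from .io_tables import OtuTable, ValidationError

__all__ = [
    "MarkerEntry",
    "MarkerRanking",
    "CvCurve",
    "RocCurve",
    "MiaPanel",
    "rf_rank",
    "cv_error_curve",
    "mia_score",
    "mia_scores",
    "roc",
    "youden_cutoff",
    "enumerate_panels",
    "best_panel",
    "classify",
    "split_evaluate",
]

#: Fixed forest hyperparameters (trees, sqrt(p) features per split).
N_ESTIMATORS = 500


@dataclass(frozen=True)
class MarkerEntry:
    otu_id: str
    importance: float
    direction: str | None  # None when the group means are exactly equal


@dataclass
class MarkerRanking:
    """Importance-ordered markers with enrichment directions."""

    entries: list[MarkerEntry]
    n_top: int

    def __post_init__(self) -> None:
        imp = [e.importance for e in self.entries]
        if any(b > a for a, b in zip(imp, imp[1:])):
            raise ValidationError("entries must be in descending importance order")
        if self.n_top > len(self.entries):
            raise ValidationError("n_top exceeds ranking length")

    @property
    def otu_ids(self) -> list[str]:
        return [e.otu_id for e in self.entries]

    def enriched(self, direction: str) -> list[str]:
        """Markers of one direction, in importance order."""
        return [e.otu_id for e in self.entries if e.direction == direction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def rf_rank(
    table: OtuTable,
    labels,
    n_top: int = 60,
    seed: int = 0,
    directions: Mapping[str, str] | None = None,
    n_estimators: int = N_ESTIMATORS,
) -> MarkerRanking:
    """Rank OTUs by random-forest variable importance.

    The forest is trained on per-sample relative abundances with the fixed
    hyperparameters (``n_estimators`` trees, sqrt(p) features per split).
    Enrichment directions come from ``directions`` (e.g. a differential
    screen) when given, otherwise from the sign of the group mean
    relative-abundance difference; ties in the mean leave direction ``None``.
    """
    labels = np.asarray(list(labels))
    if len(labels) != table.n_samples:
        raise ValidationError("label count does not match table samples")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need samples from at least 2 classes")
    if counts.min() < 2:
        raise ValidationError("need >= 2 samples per class")
    rel = relative_abundance(table)
    x = rel.to_numpy(dtype=float).T  # samples x otus
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed
    )
    forest.fit(x, labels)
    importance = forest.feature_importances_
    order = np.argsort(-importance, kind="mergesort")[:n_top]
    asd_mean = rel.loc[:, labels == "ASD"].mean(axis=1)
    ctrl_mean = rel.loc[:, labels == "control"].mean(axis=1)
    entries = []
    for i in order:
        otu = table.otu_ids[i]
        if directions is not None and otu in directions:
            direction = directions[otu]
        else:
            diff = float(asd_mean.iloc[i] - ctrl_mean.iloc[i])
            direction = (
                None if diff == 0 else ("ASD-enriched" if diff > 0 else "control-enriched")
            )
        entries.append(MarkerEntry(otu, float(importance[i]), direction))
    return MarkerRanking(entries, n_top=len(entries))


@dataclass
class CvCurve:
    """Cross-validated classification error as a function of marker count."""

    ks: list[int]
    errors: list[float]
    selected_k: int
    selected_error: float


def cv_error_curve(
    table: OtuTable,
    labels,
    ranking: MarkerRanking,
    folds: int = 10,
    trials: int = 10,
    seed: int = 0,
    n_estimators: int = N_ESTIMATORS,
    k_grid: Sequence[int] | None = None,
) -> CvCurve:
    """Stratified k-fold error for forests on the top-k markers, k = 1..n_top.

    Errors are averaged over folds x trials (each trial reshuffles the fold
    assignment deterministically from ``seed``).  ``selected_k`` is the
    smallest k attaining the minimum mean error.
    """
    labels = np.asarray(list(labels))
    rel = relative_abundance(table)
    ks = list(k_grid) if k_grid is not None else list(range(1, ranking.n_top + 1))
    if not ks or min(ks) < 1 or max(ks) > ranking.n_top:
        raise ValidationError("k_grid must lie within 1..n_top")
    ordered = ranking.otu_ids
    errors = []
    for k in ks:
        x = rel.loc[ordered[:k]].to_numpy(dtype=float).T
        fold_errors = []
        for trial in range(trials):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + trial)
            for train_idx, test_idx in skf.split(x, labels):
                forest = RandomForestClassifier(
                    n_estimators=n_estimators,
                    max_features="sqrt",
                    random_state=seed + trial,
                )
                forest.fit(x[train_idx], labels[train_idx])
                predictions = forest.predict(x[test_idx])
                fold_errors.append(float(np.mean(predictions != labels[test_idx])))
        errors.append(float(np.mean(fold_errors)))
    best = int(np.argmin(errors))  # first (smallest k) minimum
    return CvCurve(ks, errors, selected_k=ks[best], selected_error=errors[best])


# ---------------------------------------------------------------------------
# MIA index
# ---------------------------------------------------------------------------


@dataclass
class MiaPanel:
    """A candidate marker panel with its per-sample scores and ROC summary."""

    asd_otus: tuple[str, ...]
    control_otus: tuple[str, ...]
    scores: pd.Series | None = None
    roc: "RocCurve | None" = None
    auc: float | None = None
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    def __post_init__(self) -> None:
        if len(self.asd_otus) + len(self.control_otus) < 1:
            raise ValidationError("panel must contain at least one marker")

    @property
    def name(self) -> str:
        return f"AS{len(self.asd_otus)}HS{len(self.control_otus)}"


def mia_score(sample_abundances: Mapping[str, float], panel: MiaPanel) -> float:
    """Composite index for one sample.

    Mean abundance over the disease-enriched markers minus the mean over the
    control-enriched markers; an empty side contributes 0.
    """
    for otu in (*panel.asd_otus, *panel.control_otus):
        if otu not in sample_abundances:
            raise ValidationError(f"OTU {otu!r} absent from sample abundances")
    pos = (
        sum(float(sample_abundances[o]) for o in panel.asd_otus) / len(panel.asd_otus)
        if panel.asd_otus
        else 0.0
    )
    neg = (
        sum(float(sample_abundances[o]) for o in panel.control_otus)
        / len(panel.control_otus)
        if panel.control_otus
        else 0.0
    )
    return pos - neg


def mia_scores(table: OtuTable, panel: MiaPanel, scale: str = "counts") -> pd.Series:
    """Per-sample MIA over a whole table (``scale``: "counts" or "relative")."""
    if scale not in ("counts", "relative"):
        raise ValidationError(f"unknown abundance scale {scale!r}")
    missing = [
        o for o in (*panel.asd_otus, *panel.control_otus) if o not in set(table.otu_ids)
    ]
    if missing:
        raise ValidationError(f"OTUs absent from table: {missing}")
    data = (
        relative_abundance(table)
        if scale == "relative"
        else table.to_frame().astype(float)
    )
    pos = (
        data.loc[list(panel.asd_otus)].mean(axis=0)
        if panel.asd_otus
        else pd.Series(0.0, index=table.sample_ids)
    )
    neg = (
        data.loc[list(panel.control_otus)].mean(axis=0)
        if panel.control_otus
        else pd.Series(0.0, index=table.sample_ids)
    )
    return (pos - neg).rename("mia")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """ROC curve under the strict decision rule ``score > threshold``."""

    thresholds: np.ndarray  # descending; +/-inf sentinels included
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc(scores, labels, positive: str = "ASD") -> RocCurve:
    """ROC curve with thresholds at the unique scores.

    AUC by the trapezoid rule, so tied positive/negative scores contribute
    half credit (equivalently AUC = Mann-Whitney U / (n_pos * n_neg)).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(list(labels))
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("need at least one sample in each class")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    tpr = np.array([np.mean(pos > t) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
                    for t in thresholds])
    fpr = np.array([np.mean(neg > t) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
                    for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, tpr, fpr, auc)


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity - 1.

    Ties break toward higher sensitivity, then smaller absolute cutoff.
    Returns ``(cutoff, sensitivity, specificity)``.
    """
    finite = np.isfinite(curve.thresholds)
    thresholds = curve.thresholds[finite]
    sens = curve.tpr[finite]
    spec = 1.0 - curve.fpr[finite]
    if len(thresholds) == 0:
        raise ValidationError("ROC curve has no finite thresholds")
    youden = sens + spec - 1.0
    best = None
    for t, se, sp, j in zip(thresholds, sens, spec, youden):
        key = (j, se, -abs(t))
        if best is None or key > best[0]:
            best = (key, float(t), float(se), float(sp))
    return best[1], best[2], best[3]


def classify(scores, cutoff: float, positive: str = "ASD", negative: str = "control"):
    """Label samples: ``positive`` iff score strictly exceeds the cutoff."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > cutoff, positive, negative)


# ---------------------------------------------------------------------------
# Panel enumeration
# ---------------------------------------------------------------------------

POWERSET_LIMIT = 16


def _evaluate_panel(
    panel: MiaPanel, table: OtuTable, labels, scale: str, positive: str
) -> MiaPanel:
    scores = mia_scores(table, panel, scale=scale)
    curve = roc(scores.to_numpy(), labels, positive=positive)
    cutoff, sens, spec = youden_cutoff(curve)
    panel.scores = scores
    panel.roc = curve
    panel.auc = curve.auc
    panel.cutoff = cutoff
    panel.sensitivity = sens
    panel.specificity = spec
    return panel


def enumerate_panels(
    ranking: MarkerRanking,
    table: OtuTable,
    labels,
    mode: str = "grid",
    scale: str = "counts",
    positive: str = "ASD",
) -> list[MiaPanel]:
    """Evaluate candidate panels built from the direction-ranked marker lists.

    ``mode="grid"``: all (m, n) prefix pairs of the disease-enriched and
    control-enriched lists with ``0 <= m <= M``, ``0 <= n <= N``,
    ``m + n >= 1`` — (M+1)(N+1)-1 panels.  ``mode="powerset"``: every subset
    (refused when M + N > 16).  Panels are returned sorted by descending AUC
    (ties: fewer markers first).
    """
    asd_list = ranking.enriched("ASD-enriched")
    ctrl_list = ranking.enriched("control-enriched")
    if not asd_list and not ctrl_list:
        raise ValidationError("ranking has no directed markers")
    labels = np.asarray(list(labels))
    panels: list[MiaPanel] = []
    if mode == "grid":
        for m in range(len(asd_list) + 1):
            for n in range(len(ctrl_list) + 1):
                if m + n == 0:
                    continue
                panels.append(MiaPanel(tuple(asd_list[:m]), tuple(ctrl_list[:n])))
    elif mode == "powerset":
        total = len(asd_list) + len(ctrl_list)
        if total > POWERSET_LIMIT:
            raise ValidationError(
                f"powerset mode limited to {POWERSET_LIMIT} markers, got {total}"
            )
        for r_a in range(len(asd_list) + 1):
            for subset_a in itertools.combinations(asd_list, r_a):
                for r_c in range(len(ctrl_list) + 1):
                    for subset_c in itertools.combinations(ctrl_list, r_c):
                        if len(subset_a) + len(subset_c) == 0:
                            continue
                        panels.append(MiaPanel(tuple(subset_a), tuple(subset_c)))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    panels = [_evaluate_panel(p, table, labels, scale, positive) for p in panels]
    panels.sort(key=lambda p: (-p.auc, len(p.asd_otus) + len(p.control_otus)))
    return panels


def best_panel(panels: list[MiaPanel]) -> MiaPanel:
    """Maximum-AUC panel; AUC ties resolved toward fewer markers."""
    if not panels:
        raise ValidationError("no panels to choose from")
    return min(panels, key=lambda p: (-p.auc, len(p.asd_otus) + len(p.control_otus)))


def split_evaluate(
    table: OtuTable,
    labels,
    n_top: int = 20,
    test_fraction: float = 0.5,
    seed: int = 0,
    scale: str = "counts",
    mode: str = "grid",
    n_estimators: int = N_ESTIMATORS,
) -> dict:
    """Honest train/test evaluation: rank markers, pick the panel and cutoff
    on the training half only, then score the held-out half.

    Returns train/test AUC plus held-out sensitivity/specificity at the
    train-chosen cutoff.
    """
    labels = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_mask[rng.choice(idx, size=n_test, replace=False)] = True
    train_ids = [s for s, t in zip(table.sample_ids, test_mask) if not t]
    test_ids = [s for s, t in zip(table.sample_ids, test_mask) if t]
    train_table = table.select_samples(train_ids)
    test_table = table.select_samples(test_ids)
    train_labels = labels[~test_mask]
    test_labels = labels[test_mask]

    ranking = rf_rank(train_table, train_labels, n_top=n_top, seed=seed,
                      n_estimators=n_estimators)
    panels = enumerate_panels(ranking, train_table, train_labels, mode=mode, scale=scale)
    chosen = best_panel(panels)
    test_scores = mia_scores(test_table, chosen, scale=scale)
    test_curve = roc(test_scores.to_numpy(), test_labels)
    predictions = classify(test_scores.to_numpy(), chosen.cutoff)
    pos = test_labels == "ASD"
    return {
        "panel": chosen,
        "train_auc": chosen.auc,
        "test_auc": test_curve.auc,
        "cutoff": chosen.cutoff,
        "test_sensitivity": float(np.mean(predictions[pos] == "ASD")) if pos.any() else float("nan"),
        "test_specificity": float(np.mean(predictions[~pos] == "control")) if (~pos).any() else float("nan"),
    }
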