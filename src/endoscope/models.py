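"""Prognostic modeling: mRMR ranking, cross-validated AUROC, step-up panels.

Feature selection ranks genes by minimum-redundancy-maximum-relevance:
relevance is the one-way ANOVA F statistic of a gene against the binary
outcome (z-scored over the candidate pool once, at the start), redundancy
the mean absolute Pearson correlation with already-selected genes, and the
greedy criterion their difference.

Panels are sized by a step-up search over the ranked list under repeated
stratified k-fold cross-validated AUROC of an L2-penalized logistic model
(features standardized on the training fold only), choosing the smallest
panel within one standard error of the best mean AUROC.

Fold assignment is derived from a stable hash of (patient id, seed,
repeat), so fold membership is invariant to row order and comparable
across models evaluated on the same patients with the same seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUROC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def mrmr_rank(X: pd.DataFrame, y: pd.Series, m: int = 50, candidates=None) -> pd.DataFrame:
    """Greedy mRMR ranking of up to ``m`` genes.

    Parameters
    ----------
    X
        Patients x genes expression (VST scale), indexed by patient id.
    y
        Binary outcome aligned to X's index.
    candidates
        Subset of X's columns to rank (default: all columns).

    Returns a DataFrame with columns gene_id, score, relevance_z, rank.
    """
    if candidates is None:
        candidates = list(X.columns)
    candidates = [c for c in candidates if c in X.columns]
    if len(candidates) < 1:
        raise ValueError("at least one candidate gene required")
    y_arr = np.asarray(y.loc[X.index]).astype(int)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("both outcome classes required")

    sub = X[candidates]
    sd = sub.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("mrmr_rank: dropping %d constant candidate(s)", len(constant))
        candidates = [c for c in candidates if c not in set(constant)]
        sub = X[candidates]
    arr = sub.to_numpy(dtype=float)
    n_cand = len(candidates)

    relevance, _ = f_classif(arr, y_arr)
    relevance = np.nan_to_num(relevance, nan=0.0)
    rel_sd = relevance.std()
    rel_z = (relevance - relevance.mean()) / rel_sd if rel_sd > 0 else np.zeros(n_cand)

    corr_abs = np.abs(np.corrcoef(arr, rowvar=False))
    if n_cand == 1:
        corr_abs = np.ones((1, 1))
    corr_abs = np.nan_to_num(corr_abs, nan=1.0)

    order = sorted(range(n_cand), key=lambda i: (-relevance[i], candidates[i]))
    selected = [order[0]]
    scores = {order[0]: float(rel_z[order[0]])}
    remaining = set(range(n_cand)) - set(selected)
    while remaining and len(selected) < min(m, n_cand):
        redundancy = corr_abs[np.ix_(sorted(remaining), selected)].mean(axis=1)
        rem_sorted = sorted(remaining)
        cand_scores = rel_z[rem_sorted] - redundancy
        best = min(
            range(len(rem_sorted)),
            key=lambda i: (-cand_scores[i], candidates[rem_sorted[i]]),
        )
        pick = rem_sorted[best]
        selected.append(pick)
        scores[pick] = float(cand_scores[best])
        remaining.discard(pick)

    return pd.DataFrame(
        {
            "gene_id": [candidates[i] for i in selected],
            "score": [scores[i] for i in selected],
            "relevance_z": rel_z[selected],
            "rank": np.arange(1, len(selected) + 1),
        }
    )


def _fold_of(patient_id, seed: int, repeat: int, digest_bytes: int = 8) -> int:
    payload = f"{patient_id}|{seed}|{repeat}".encode()
    return int.from_bytes(hashlib.blake2b(payload, digest_size=digest_bytes).digest(), "big")


def fold_assignments(patient_ids, y: np.ndarray, folds: int, repeats: int, seed: int):
    """Stratified fold labels per repeat, keyed by patient id.

    Within each class, patients are ordered by a stable hash of
    (patient id, seed, repeat) and dealt into folds round-robin, so the
    assignment is invariant to input row order.
    """
    ids = list(patient_ids)
    assignments = np.empty((repeats, len(ids)), dtype=int)
    for rep in range(repeats):
        for cls in np.unique(y):
            members = [i for i in range(len(ids)) if y[i] == cls]
            members.sort(key=lambda i: _fold_of(ids[i], seed, rep))
            for pos, i in enumerate(members):
                assignments[rep, i] = pos % folds
    return assignments


def cv_auroc(
    X: pd.DataFrame,
    y: pd.Series,
    features,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Repeated stratified k-fold AUROC of an L2 logistic model.

    Per fold: standardize on the training split, fit
    LogisticRegression(C=1, max_iter=1000), score the held-out split by
    AUROC.  Returns (mean, sd, fold_scores) over repeats x folds.
    """
    features = list(features)
    y_arr = np.asarray(y.loc[X.index]).astype(int)
    counts = np.bincount(y_arr, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} members; needs >= {folds} for stratification"
        )
    arr = X[features].to_numpy(dtype=float)
    assignments = fold_assignments(X.index, y_arr, folds, repeats, seed)

    scores = []
    for rep in range(repeats):
        for fold in range(folds):
            test = assignments[rep] == fold
            train = ~test
            scaler = StandardScaler().fit(arr[train])
            model = LogisticRegression(C=1.0, max_iter=1000)
            model.fit(scaler.transform(arr[train]), y_arr[train])
            prob = model.predict_proba(scaler.transform(arr[test]))[:, 1]
            scores.append(auroc(prob, y_arr[test]))
    fold_scores = np.asarray(scores)
    return float(fold_scores.mean()), float(fold_scores.std()), fold_scores


def stepup_select(
    X: pd.DataFrame,
    y: pd.Series,
    ranked,
    max_n: int = 50,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Step-up panel sizing over a ranked gene list.

    Evaluates cv_auroc on the first n ranked genes for n = 1..max_n and
    returns the smallest n whose mean AUROC is within one standard error
    (sd at the best n over sqrt(repeats*folds)) of the best mean, plus the
    whole performance curve.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked gene list is empty")
    limit = min(max_n, len(ranked))
    rows = []
    for n in range(1, limit + 1):
        mean, sd, _ = cv_auroc(X, y, ranked[:n], repeats, folds, seed)
        rows.append((n, mean, sd))
    curve = pd.DataFrame(rows, columns=["n_features", "auroc_mean", "auroc_sd"])
    best_idx = int(curve["auroc_mean"].idxmax())
    threshold = curve.loc[best_idx, "auroc_mean"] - curve.loc[best_idx, "auroc_sd"] / np.sqrt(
        repeats * folds
    )
    n_star = int(curve.loc[curve["auroc_mean"] >= threshold, "n_features"].iloc[0])
    return n_star, curve


@dataclass
class ModelReport:
    feature_set: list[str]
    n_features: int
    auroc_mean: float
    auroc_sd: float
    fold_scores: np.ndarray
    group: str = "full cohort"
    seed: int = 0
    comparator_auroc_mean: float | None = None
    comparator_auroc_sd: float | None = None
    n_patients: int = 0
    stepup_curve: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "feature_set": list(self.feature_set),
            "n_features": self.n_features,
            "auroc_mean": self.auroc_mean,
            "auroc_sd": self.auroc_sd,
            "comparator_auroc_mean": self.comparator_auroc_mean,
            "comparator_auroc_sd": self.comparator_auroc_sd,
            "n_patients": self.n_patients,
            "seed": self.seed,
            "fold_scores": [float(v) for v in self.fold_scores],
        }


def compare_with_clinical_score(
    X: pd.DataFrame,
    y: pd.Series,
    features,
    clinical: pd.Series,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> ModelReport:
    """Gene panel vs single-feature clinical-score model, same folds.

    The comparison is restricted to patients with a clinical score; both
    models use identical hash-derived fold assignments (same seed).
    """
    matched = X.index.intersection(clinical.dropna().index)
    if len(matched) < 2 * folds:
        raise ValueError("matched subset too small for stratified cross-validation")
    Xm = X.loc[matched]
    ym = y.loc[matched]
    gene_mean, gene_sd, fold_scores = cv_auroc(Xm, ym, features, repeats, folds, seed)
    clin_df = pd.DataFrame({"clinical_score": clinical.loc[matched]})
    clin_mean, clin_sd, _ = cv_auroc(clin_df, ym, ["clinical_score"], repeats, folds, seed)
    return ModelReport(
        feature_set=list(features),
        n_features=len(list(features)),
        auroc_mean=gene_mean,
        auroc_sd=gene_sd,
        fold_scores=fold_scores,
        seed=seed,
        comparator_auroc_mean=clin_mean,
        comparator_auroc_sd=clin_sd,
        n_patients=len(matched),
    )


def stratified_models(
    X: pd.DataFrame,
    y: pd.Series,
    groups,
    ranked50,
    max_n: int = 50,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> tuple[list[ModelReport], list[str]]:
    """Per-group step-up panels restricted to the top-50 mRMR candidates.

    Each group's model is selected and evaluated on that group's exclusive
    members only.  Groups whose minority outcome class is smaller than the
    fold count are skipped with a logged reason.  Returns the per-group
    reports and the union of selected features.
    """
    ranked50 = list(ranked50)
    reports: list[ModelReport] = []
    union: list[str] = []
    for gid in groups.groups:
        members = [p for p in groups.exclusive_members(gid) if p in X.index]
        yg = y.loc[members].dropna().astype(int)
        members = list(yg.index)
        counts = np.bincount(yg.to_numpy(), minlength=2)
        if counts.min() < folds:
            logger.info(
                "stratified_models: skipping group %s (minority class %d < %d folds)",
                gid, int(counts.min()), folds,
            )
            continue
        Xg = X.loc[members]
        # re-rank the shared candidate pool within the group, then size the panel
        group_ranked = mrmr_rank(Xg, yg, m=len(ranked50), candidates=ranked50)[
            "gene_id"
        ].tolist()
        n_star, curve = stepup_select(Xg, yg, group_ranked, max_n, repeats, folds, seed)
        panel = group_ranked[:n_star]
        mean, sd, fold_scores = cv_auroc(Xg, yg, panel, repeats, folds, seed)
        reports.append(
            ModelReport(
                feature_set=panel,
                n_features=n_star,
                auroc_mean=mean,
                auroc_sd=sd,
                fold_scores=fold_scores,
                group=gid,
                seed=seed,
                n_patients=len(members),
                stepup_curve=curve,
            )
        )
        for gene in panel:
            if gene not in union:
                union.append(gene)
    if not reports:
        raise ValueError("all groups skipped; no stratified model fitted")
    return reports, union
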