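"""Differential expression and clinical-feature comparisons.

Per-gene Welch two-sample t-tests on variance-stabilized expression with
Benjamini-Hochberg adjustment.  Because the VST scale is log2-like, the
difference of group means is reported directly as the log2 fold change
(L2FC), with the convention positive = higher in non-survivors.

Between-group contrasts use only patients exclusive to a single group:
patients attributable to multiple groups are removed before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, df, two-sided p).

    t = (mean a - mean b) / sqrt(va/na + vb/nb) with sample variances and
    Welch-Satterthwaite degrees of freedom.  A zero pooled standard error
    (both samples constant) yields t = 0, p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        logger.warning("welch_test: zero pooled standard error; returning t=0, p=1")
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_table(expr, labels: pd.Series, sort_by: str = "p_adjusted") -> pd.DataFrame:
    """Per-gene Welch test of class 1 (died) vs class 0 (survived).

    Parameters
    ----------
    expr
        ExpressionMatrix (VST scale).
    labels
        Binary per-patient series indexed by patient id; patients missing
        from the index of ``labels`` (or with NA) are dropped.
    sort_by
        "p_adjusted" or "p_value"; ties broken by |l2fc| descending then
        gene id, so the table is deterministic under patient permutation.
    """
    if sort_by not in ("p_adjusted", "p_value"):
        raise ValueError("sort_by must be 'p_adjusted' or 'p_value'")
    labels = labels.dropna()
    common = expr.patient_ids.intersection(labels.index)
    labels = labels.loc[common].astype(int)
    x = expr.values[common]
    a_ids = labels.index[labels == 1]  # died
    b_ids = labels.index[labels == 0]  # survived
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each outcome class needs at least 2 patients")

    a = x[a_ids].to_numpy(dtype=float)
    b = x[b_ids].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (ma - mb) / np.sqrt(se2))
        df = np.where(
            zero,
            na + nb - 2,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
        )
    p = np.where(zero, 1.0, np.minimum(2.0 * stats.t.sf(np.abs(t), df), 1.0))
    if zero.any():
        logger.warning("de_table: %d constant gene(s) set to t=0, p=1", int(zero.sum()))

    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "l2fc": ma - mb,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
            "n_group_a": na,
            "n_group_b": nb,
        }
    )
    table = table.sort_values(
        [sort_by, "l2fc", "gene_id"],
        ascending=[True, False, True],
        key=lambda c: c.abs() if c.name == "l2fc" else c,
        kind="stable",
    ).reset_index(drop=True)
    return table


def _resolve_union(groups, spec_part) -> set:
    """Union of exclusive members for a group id or '+'-joined union."""
    ids = spec_part.split("+") if isinstance(spec_part, str) else list(spec_part)
    members: set = set()
    for gid in ids:
        gid = gid.strip()
        if gid not in groups.groups:
            raise KeyError(f"unknown group id: {gid}")
        members |= set(groups.exclusive_members(gid))
    return members


def contrast_between_groups(expr, groups, pair, sort_by: str = "p_adjusted") -> pd.DataFrame:
    """DE table between two groups (or '+'-joined unions like 't1+t2+t3'),
    using only patients exclusive to a single group."""
    side_a = _resolve_union(groups, pair[0])
    side_b = _resolve_union(groups, pair[1])
    side_a &= set(expr.patient_ids)
    side_b &= set(expr.patient_ids)
    if len(side_a) < 2 or len(side_b) < 2:
        raise ValueError(f"exclusive membership too small for contrast {pair}")
    labels = pd.Series(
        [1] * len(side_a) + [0] * len(side_b), index=sorted(side_a) + sorted(side_b)
    )
    return de_table(expr, labels, sort_by=sort_by)


@dataclass
class ClinicalComparison:
    feature: str
    anova_p: float
    group_n: dict[str, int]
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)
    # pairwise rows: (side_a, side_b, mean difference, p)


def clinical_compare(
    cohort: pd.DataFrame,
    groups,
    features=None,
    pairs=None,
    min_per_group: int = 2,
) -> list[ClinicalComparison]:
    """One-way ANOVA across groups plus pairwise Welch tests per feature.

    Features are numeric cohort columns (non-numeric ones are skipped with
    a log entry) restricted to those with data for at least
    ``min_per_group`` patients in every group compared.  Pair sides may be
    unions joined by '+', in which case the groups are merged before
    testing.  Only exclusive group members are used.
    """
    if features is None:
        features = [c for c in cohort.columns if c not in ("site", "sex")]
    group_ids = list(groups.groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(group_ids) for b in group_ids[i + 1 :]]

    out: list[ClinicalComparison] = []
    for feat in features:
        if not pd.api.types.is_numeric_dtype(cohort[feat]):
            logger.info("clinical_compare: skipping non-numeric feature %r", feat)
            continue
        col = cohort[feat].dropna()
        samples, ns = [], {}
        for gid in group_ids:
            members = [p for p in groups.exclusive_members(gid) if p in col.index]
            samples.append(col.loc[members].to_numpy(dtype=float))
            ns[gid] = len(members)
        if any(n < min_per_group for n in ns.values()):
            logger.info("clinical_compare: feature %r excluded (group with <%d obs)",
                        feat, min_per_group)
            continue
        anova_p = float(stats.f_oneway(*samples).pvalue)
        rows = []
        for side_a, side_b in pairs:
            try:
                a_ids = _resolve_union(groups, side_a)
                b_ids = _resolve_union(groups, side_b)
            except KeyError:
                continue
            a = col.loc[[p for p in a_ids if p in col.index]].to_numpy(dtype=float)
            b = col.loc[[p for p in b_ids if p in col.index]].to_numpy(dtype=float)
            if a.size < min_per_group or b.size < min_per_group:
                continue
            _, _, p = welch_test(a, b)
            rows.append((str(side_a), str(side_b), float(a.mean() - b.mean()), p))
        out.append(ClinicalComparison(feat, anova_p, ns, rows))
    return out
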