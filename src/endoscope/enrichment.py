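"""Preranked gene-set enrichment with a gene-permutation null.

Genes are ranked by log2 fold change in decreasing order; the enrichment
score of a set is the signed maximum deviation of a weighted
Kolmogorov-Smirnov-style running sum (hits weighted by |stat|^p, misses by
a constant decrement).  Normalized scores and p-values come from random
same-size gene draws from the ranked list: gene permutation, not phenotype
permutation, because the ranking statistic is a precomputed fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .de import bh_adjust


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("gene set names must be unique")
        for s in self.sets:
            if not s.genes:
                raise ValueError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([s.name, s.description] + sorted(s.genes)) for s in collection.sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def rank_genes(de: pd.DataFrame, mode: str = "all") -> list[tuple[str, float]]:
    """Ranked (gene, l2fc) list in decreasing l2fc order, gene-id tiebreak.

    mode="significant_only" keeps genes with p_adjusted <= 0.05 (inclusive)
    before ranking, the convention for between-group contrasts;
    mode="all" keeps everything (within-group contrasts).
    """
    if mode not in ("all", "significant_only"):
        raise ValueError("mode must be 'all' or 'significant_only'")
    table = de
    if mode == "significant_only":
        table = table[table["p_adjusted"] <= 0.05]
    if table.empty:
        raise ValueError("no genes left to rank")
    ordered = table.sort_values(["l2fc", "gene_id"], ascending=[False, True], kind="stable")
    return list(zip(ordered["gene_id"], ordered["l2fc"].astype(float)))


def _es_from_hits(abs_stats: np.ndarray, hit_mask: np.ndarray, weight_p: float):
    """Running sum and signed extremum for one hit configuration."""
    n = abs_stats.size
    n_hits = int(hit_mask.sum())
    weights = abs_stats**weight_p
    hit_norm = weights[hit_mask].sum()
    if hit_norm == 0:  # all hit stats zero: fall back to unweighted steps
        increments = np.where(hit_mask, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit_mask, weights / hit_norm, 0.0)
    decrement = 1.0 / (n - n_hits)
    steps = increments - np.where(hit_mask, 0.0, decrement)
    running = np.cumsum(steps)
    extremum = int(np.argmax(np.abs(running)))
    return float(running[extremum]), running, extremum


def enrichment_score(ranked, gene_set, weight_p: float = 1.0):
    """Weighted running-sum enrichment score of a gene set.

    Returns (es, running_sum, leading_edge).  The leading edge contains the
    hit genes at or before the extremum for a positive score, and at or
    after it for a negative score.
    """
    genes = [g for g, _ in ranked]
    stats = np.asarray([s for _, s in ranked], dtype=float)
    members = set(gene_set.genes if hasattr(gene_set, "genes") else gene_set)
    hit_mask = np.asarray([g in members for g in genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    es, running, extremum = _es_from_hits(np.abs(stats), hit_mask, weight_p)
    if es >= 0:
        leading = [g for i, g in enumerate(genes) if hit_mask[i] and i <= extremum]
    else:
        leading = [g for i, g in enumerate(genes) if hit_mask[i] and i >= extremum]
    return es, running, leading


def _null_es(
    abs_stats: np.ndarray, set_size: int, n_perm: int, weight_p: float, rng
) -> np.ndarray:
    """Null enrichment scores from random same-size gene draws, vectorized.

    For sorted hit positions p_1 < ... < p_m the running sum just after and
    just before each hit is a closed form in the cumulative hit weights and
    the miss decrement, so the extremum can be taken over those 2m
    candidate points without walking the whole list.
    """
    n = abs_stats.size
    m = set_size
    weights = abs_stats**weight_p
    decrement = 1.0 / (n - m)
    positions = np.empty((n_perm, m), dtype=np.int64)
    for i in range(n_perm):
        positions[i] = rng.choice(n, size=m, replace=False)
    positions.sort(axis=1)
    w = weights[positions]  # (n_perm, m)
    norm = w.sum(axis=1, keepdims=True)
    safe = norm[:, 0] > 0
    cum = np.cumsum(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gains = cum / norm
    idx = np.arange(m)[None, :]
    misses_before = positions - idx  # misses strictly before hit i
    after = gains - misses_before * decrement
    before = np.where(idx > 0, np.roll(gains, 1, axis=1), 0.0) - misses_before * decrement
    candidates = np.concatenate([after, before], axis=1)
    pick = np.argmax(np.abs(candidates), axis=1)
    out = candidates[np.arange(n_perm), pick]
    if not safe.all():  # degenerate all-zero-weight draws: unweighted steps
        for i in np.flatnonzero(~safe):
            mask = np.zeros(n, dtype=bool)
            mask[positions[i]] = True
            out[i], _, _ = _es_from_hits(abs_stats, mask, 0.0)
    return out


def gsea_preranked(
    ranked,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    p_cutoff: float = 1.0,
    weight_p: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection with a gene-permutation null.

    Per set: null ES from ``n_perm`` random same-size draws; NES = ES over
    the mean |null ES| of matching sign; p = add-one estimator over
    sign-matched nulls; BH across retained sets; rows with p > p_cutoff
    dropped.  Deterministic given the seed.
    """
    genes = [g for g, _ in ranked]
    abs_stats = np.abs(np.asarray([s for _, s in ranked], dtype=float))
    gene_index = set(genes)

    eligible = []
    for gene_set in collection.sets:
        overlap = gene_set.genes & gene_index
        if min_size <= len(overlap) <= max_size and len(overlap) < len(genes):
            eligible.append((gene_set, overlap))
    if not eligible:
        raise ValueError("no gene set within the size limits overlaps the ranked list")

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for gene_set, overlap in eligible:
        es, _, leading = enrichment_score(ranked, overlap, weight_p)
        size = len(overlap)
        if size not in null_cache:
            null_cache[size] = _null_es(abs_stats, size, n_perm, weight_p, rng)
        null = null_cache[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes, p = np.sign(es) * np.inf, 1.0 / (1.0 + n_perm)
        else:
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else 0.0
            p = (1.0 + (np.abs(same_sign) >= abs(es)).sum()) / (1.0 + same_sign.size)
        rows.append(
            {
                "set_name": gene_set.name,
                "es": es,
                "nes": float(nes),
                "p_value": float(p),
                "leading_edge": ",".join(leading),
                "set_size_used": size,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table = table[table["p_value"] <= p_cutoff].reset_index(drop=True)
    return table.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
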