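"""Independent brute-force oracles shared across the suite.

Each implementation is deliberately naive (explicit loops, step-by-step
enumeration) and independent of the package's vectorized code paths.
"""

import numpy as np


def brute_force_bh(p):
    """Step-up adjustment by direct enumeration: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        q[idx] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0
        )
    return q


def brute_force_auroc(scores, labels):
    """All-pairs enumeration with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (len(pos) * len(neg))


def brute_force_es(ranked, gene_set, weight_p=1.0):
    """Exhaustive running-sum walk for the weighted enrichment score."""
    genes = [g for g, _ in ranked]
    stats = [abs(s) for _, s in ranked]
    hits = [g in gene_set for g in genes]
    n, n_hits = len(genes), sum(hits)
    norm = sum(s**weight_p for s, h in zip(stats, hits) if h)
    value, best = 0.0, 0.0
    for g, s, h in zip(genes, stats, hits):
        if h:
            value += (s**weight_p / norm) if norm > 0 else 1.0 / n_hits
        else:
            value -= 1.0 / (n - n_hits)
        if abs(value) > abs(best):
            best = value
    return best
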