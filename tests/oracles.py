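"""Independent reference implementations used only as test oracles.

Each is deliberately naive (double loops, dense matrices, exhaustive
enumeration) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def brute_force_consensus(de, preds_a, preds_b, catalog, min_a=60.0, min_b=0.8):
    """All (miRNA, gene) pairs passing both predictors, by exhaustive search."""
    pairs = set()
    for record in de:
        for reg in catalog:
            names = {reg.symbol} | set(reg.aliases)
            a_scores = [
                p.raw_score
                for p in preds_a
                if p.mirna_id == record.mirna_id and p.gene_symbol in names
            ]
            b_scores = [
                p.raw_score
                for p in preds_b
                if p.mirna_id == record.mirna_id and p.gene_symbol in names
            ]
            if not a_scores or not b_scores:
                continue
            if max(a_scores) >= min_a and max(b_scores) >= min_b:
                pairs.add((record.mirna_id, reg.symbol))
    return pairs


def hypergeometric_tail_by_enumeration(n_universe, n_annotated, n_drawn, k_min):
    """P[overlap >= k_min] by counting every possible draw (universe <= 12)."""
    total = comb(n_universe, n_drawn)
    favourable = 0
    universe = range(n_universe)
    annotated = set(range(n_annotated))
    for draw in combinations(universe, n_drawn):
        if len(annotated.intersection(draw)) >= k_min:
            favourable += 1
    return favourable / total


def reference_mcl(adjacency, inflation, expansion=2, max_iter=200, tol=1e-8):
    """Minimal dense MCL; returns the cluster partition as frozensets of indices.

    Self-loops are set to each node's maximum incident weight, clusters are
    read off attractor rows and overlapping clusters merged — the textbook
    reading, independent of the package implementation.
    """
    adj = np.array(adjacency, dtype=float)
    n = adj.shape[0]
    loops = adj.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(adj, loops)
    m = adj / adj.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion) ** inflation
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() <= tol:
            break
    clusters = []
    for i in range(n):
        if m[i, i] > 1e-6:
            clusters.append(frozenset(np.nonzero(m[i] > 1e-6)[0]) | {i})
    merged = []
    for cluster in clusters:
        overlapping = [c for c in merged if c & cluster]
        for c in overlapping:
            merged.remove(c)
            cluster = cluster | c
        merged.append(cluster)
    return set(map(frozenset, merged))
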