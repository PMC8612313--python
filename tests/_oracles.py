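"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results with the slowest, most literal
formulation available so they share no code path with the implementation.
"""
from itertools import combinations

import numpy as np


def naive_agglomerate(dist, lam, linkage="average"):
    """O(n^3) agglomeration on a square distance matrix, cut at lam.

    Maintains explicit member lists; cluster-pair distances are recomputed
    from the original matrix each round (mean / max / min over all cross
    pairs). Merging continues while the smallest pair distance is <= lam.
    Returns labels canonicalized by first document occurrence.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    reducer = {"average": np.mean, "complete": np.max, "single": np.min}[linkage]
    while len(clusters) > 1:
        best, best_pair = None, None
        for a, b in combinations(range(len(clusters)), 2):
            d = reducer([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best:
                best, best_pair = d, (a, b)
        if best > lam:
            break
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=np.int64)
    for cid, members in enumerate(clusters):
        for i in members:
            labels[i] = cid
    return canonical(labels)


def canonical(labels):
    """Relabel to first-occurrence order so partitions compare directly."""
    mapping = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(np.asarray(labels).tolist()):
        out[i] = mapping.setdefault(lab, len(mapping))
    return out


def same_partition(a, b):
    return np.array_equal(canonical(a), canonical(b))


def pairwise_prf_brute(pred, gold):
    """Pair-by-pair enumeration of precision/recall/F."""
    n = len(pred)
    tp = fp = fn = 0
    for i, j in combinations(range(n), 2):
        in_pred = pred[i] == pred[j]
        in_gold = gold[i] == gold[j]
        tp += in_pred and in_gold
        fp += in_pred and not in_gold
        fn += in_gold and not in_pred
    p = tp / (tp + fp) if tp + fp else (1.0 if tp + fn == 0 else 0.0)
    r = tp / (tp + fn) if tp + fn else (1.0 if tp + fp == 0 else 0.0)
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def random_distance_matrix(rng, n):
    """Symmetric zero-diagonal matrix with continuous entries (ties a.s. absent)."""
    m = rng.uniform(0.0, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
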