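"""Scoring a predicted clustering against a gold clustering.

The comparison metric is pairwise co-membership: over all unordered document
pairs, a true positive is a pair grouped together in both clusterings;
precision measures errors the prediction introduces into groups and recall
measures how completely the gold groups are recovered. Label values carry no
meaning, so both sides are compared purely through the partition they induce.
The fidelity benchmark replays the hybrid algorithm at several train portions
against pure HAC on the same corpus as gold standard, which is the protocol
used to validate that subsampling does not degrade the grouping.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.cluster import pair_confusion_matrix

from .cluster_engine import ClusterParams, Labeling, hac_cluster, hybrid_cluster
from .corpus_io import TokenizedDoc
from .similarity import distance_matrix

__all__ = ["PRFScore", "pairwise_prf", "fidelity_benchmark"]


@dataclass(frozen=True)
class PRFScore:
    precision: float
    recall: float
    f_score: float


def _as_labels(labeling, doc_index=None) -> tuple[np.ndarray, tuple]:
    if isinstance(labeling, Labeling):
        return labeling.labels.copy(), labeling.doc_index
    arr = np.asarray(labeling, dtype=np.int64).copy()
    return arr, doc_index if doc_index is not None else tuple(range(len(arr)))


def _resolve_sentinels(labels: np.ndarray) -> np.ndarray:
    """Treat any remaining −1 documents as distinct singleton groups."""
    out = labels.copy()
    neg = np.flatnonzero(out == -1)
    if neg.size:
        start = out.max() + 1 if out.size else 0
        out[neg] = np.arange(start, start + neg.size)
    return out


def _f(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def pairwise_prf(pred, gold) -> PRFScore:
    """Pairwise precision/recall/F of ``pred`` against ``gold``.

    Zero-denominator conventions: with no co-clustered pair on the predicted
    side, precision is 1 when the gold side has none either (nothing to get
    wrong) and 0 otherwise; recall mirrors the rule on the gold side.
    """
    pred_labels, pred_index = _as_labels(pred)
    gold_labels, gold_index = _as_labels(gold)
    if len(pred_labels) != len(gold_labels):
        raise ValueError("pred and gold must label the same documents")
    if isinstance(pred, Labeling) and isinstance(gold, Labeling) and pred_index != gold_index:
        raise ValueError("pred and gold document ids disagree")
    if len(pred_labels) == 0:
        return PRFScore(1.0, 1.0, 1.0)
    pred_labels = _resolve_sentinels(pred_labels)
    gold_labels = _resolve_sentinels(gold_labels)
    C = pair_confusion_matrix(gold_labels, pred_labels)  # ordered-pair counts
    tp = C[1, 1] / 2
    fp = C[0, 1] / 2
    fn = C[1, 0] / 2
    precision = tp / (tp + fp) if tp + fp > 0 else (1.0 if tp + fn == 0 else 0.0)
    recall = tp / (tp + fn) if tp + fn > 0 else (1.0 if tp + fp == 0 else 0.0)
    return PRFScore(float(precision), float(recall), _f(float(precision), float(recall)))


def fidelity_benchmark(
    docs: Sequence[TokenizedDoc],
    u_values: Iterable[float],
    n_reps: int = 5,
    params: ClusterParams | None = None,
    seed: int = 0,
    gold: Labeling | None = None,
) -> pd.DataFrame:
    """Mean ± 95% CI of P/R/F of the hybrid algorithm per train portion u.

    Gold standard is pure threshold HAC on the same corpus (computed once
    unless supplied). Each repetition uses a distinct seed derived from the
    master seed; the returned table also records wall-clock seconds per run,
    which are hardware-dependent and provided for orientation only.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    params = params or ClusterParams()
    if gold is None:
        gold = hac_cluster(
            distance_matrix(docs, normalizer=params.normalizer),
            params.lambda_threshold,
            params.linkage,
        )
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for u in u_values:
        scores, times = [], []
        for rep_seed in rep_seeds.tolist():
            run_params = replace(params, train_portion_u=float(u), seed=int(rep_seed))
            t0 = time.perf_counter()
            pred = hybrid_cluster(docs, run_params)
            times.append(time.perf_counter() - t0)
            scores.append(pairwise_prf(pred, gold))
        rows.append(_summarize(u, scores, times, n_reps))
    return pd.DataFrame(rows)


def _summarize(u, scores, times, n_reps):
    row = {"u": float(u), "n_reps": n_reps}
    for name in ("precision", "recall", "f_score"):
        vals = np.array([getattr(s, name) for s in scores])
        mean = vals.mean()
        # 95% normal-approximation interval for the mean
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        row[f"{name}_mean"] = float(mean)
        row[f"{name}_ci_low"] = float(mean - half)
        row[f"{name}_ci_high"] = float(mean + half)
    row["runtime_mean_s"] = float(np.mean(times))
    row["runtime_sd_s"] = float(np.std(times, ddof=1))
    return row
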