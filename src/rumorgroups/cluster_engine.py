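"""Threshold hierarchical clustering and the hybrid HAC+KNN grouping algorithm.

Pure threshold HAC merges clusters bottom-up until every inter-cluster
linkage distance exceeds λ, so the number of rumor groups is data-driven.
Because HAC is quadratic, the hybrid algorithm clusters only a random train
portion ``u`` of the corpus exactly, propagates the sample labels to the rest
with a k-nearest-neighbor classifier over the same set-overlap distance, and
then re-clusters everything that stayed unassigned (sample singletons plus
abstaining predictions) in a second HAC pass with fresh, non-colliding label
ids. With ``u = 1`` the hybrid degenerates to pure HAC.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .corpus_io import TokenizedDoc
from .similarity import DistanceMatrix, cross_distance_matrix, distance_matrix

__all__ = ["ClusterParams", "Labeling", "hac_cluster", "hybrid_cluster", "group_table", "knn_predict"]

OUTLIER = -1  # reserved sentinel: unassigned / sample singleton
_LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the hybrid algorithm.

    lambda_threshold: HAC stopping distance λ in (0, 1]; 0.6 groups messages
        sharing a clear majority of their tokens.
    train_portion_u: fraction of the corpus clustered exactly by HAC.
    knn_k: neighbors consulted during label propagation.
    linkage: average (default), complete or single; all three operate on the
        precomputed distance matrix.
    """

    lambda_threshold: float = 0.6
    train_portion_u: float = 0.6
    knn_k: int = 5
    linkage: str = "average"
    normalizer: str = "max"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lambda_threshold <= 1.0:
            raise ValueError("lambda_threshold must be in (0, 1]")
        if not 0.0 < self.train_portion_u <= 1.0:
            raise ValueError("train_portion_u must be in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")


@dataclass(frozen=True)
class Labeling:
    """Per-document integer group labels.

    ``labels[i]`` is the group id of document i; −1 is the reserved
    unassigned sentinel and never survives a full hybrid run. ``pass_`` marks
    whether a document was labeled in the first (sample HAC + KNN) or second
    (re-clustering) pass; pure HAC marks everything as pass 1.
    """

    labels: np.ndarray
    doc_index: tuple[str, ...]
    pass_: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if len(labels) != len(self.doc_index):
            raise ValueError("labels and doc_index must align")
        if self.pass_ is None:
            object.__setattr__(self, "pass_", np.ones(len(labels), dtype=np.int8))
        else:
            object.__setattr__(self, "pass_", np.asarray(self.pass_, dtype=np.int8))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(set(self.labels[self.labels >= 0].tolist()))

    def group_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"message_id": self.doc_index, "group_id": self.labels, "pass": self.pass_}
        )


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive ids in order of first appearance (label values
    carry no meaning; this makes runs comparable)."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels.tolist()):
        out[i] = mapping.setdefault(lab, len(mapping))
    return out


def hac_cluster(
    matrix: DistanceMatrix,
    lambda_threshold: float = 0.6,
    linkage: str = "average",
) -> Labeling:
    """Agglomerative clustering on a precomputed matrix, cut at λ.

    Merging proceeds while the smallest inter-cluster linkage distance is
    ≤ λ and stops when every remaining pair of clusters is farther apart.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    n = matrix.n_docs
    if n == 0:
        return Labeling(labels=np.empty(0, dtype=np.int64), doc_index=())
    if n == 1:
        return Labeling(labels=np.zeros(1, dtype=np.int64), doc_index=matrix.doc_index)
    Z = scipy_linkage(matrix.condensed(), method=linkage)
    flat = fcluster(Z, t=lambda_threshold, criterion="distance")
    return Labeling(labels=_canonical(flat.astype(np.int64)), doc_index=matrix.doc_index)


def knn_predict(
    train_dist: np.ndarray,
    train_labels: np.ndarray,
    k: int,
    vote_reach: float = 1.0,
) -> np.ndarray:
    """Propagate training labels to holdout rows of a rectangular distance
    matrix (holdout × train) by majority vote over the k nearest neighbors.

    A neighbor farther than ``vote_reach`` carries no vote: the clustering
    threshold λ is the algorithm's own definition of how far group membership
    reaches, and propagating a label across a distance HAC would refuse to
    merge is inconsistent with that geometry (at the default reach of 1.0
    only zero-overlap neighbors are muted). A query with no neighbor within
    reach is predicted −1 (unassigned) and handled by the second clustering
    pass. Vote ties break toward the smallest label id.
    """
    n_hold, n_train = train_dist.shape
    k = min(k, n_train)
    preds = np.empty(n_hold, dtype=np.int64)
    # argpartition + stable argsort of the k candidates keeps neighbor choice
    # deterministic under ties (lowest train index wins)
    for i in range(n_hold):
        row = train_dist[i]
        if k < n_train:
            cand = np.argpartition(row, k - 1)[:k]
            cand = cand[np.lexsort((cand, row[cand]))]
        else:
            cand = np.lexsort((np.arange(n_train), row))[:k]
        in_reach = (row[cand] <= vote_reach) & (row[cand] < 1.0)  # 1.0 = no shared token
        votes = train_labels[cand[in_reach]]
        if votes.size == 0:
            preds[i] = OUTLIER
            continue
        vals, counts = np.unique(votes, return_counts=True)
        preds[i] = vals[np.argmax(counts)]  # np.unique sorts: ties → smallest
    return preds


def hybrid_cluster(docs: Sequence[TokenizedDoc], params: ClusterParams) -> Labeling:
    """The full hybrid grouping algorithm.

    1. sample ⌊u·n⌋ documents uniformly without replacement (seeded);
    2–3. distance matrix + threshold HAC on the sample;
    4. demote sample singleton clusters to the −1 sentinel;
    5. train the KNN classifier on the sample labels (including −1) and
       predict the holdout;
    6. combine sample and holdout labels;
    7–9. gather every −1 document, re-run threshold HAC on that subset and
       merge back with label ids offset past all first-pass ids. Documents
       that remain singletons in the second pass keep their own fresh id.
    """
    n = len(docs)
    if n == 0:
        return Labeling(labels=np.empty(0, dtype=np.int64), doc_index=())
    n_train = math.floor(params.train_portion_u * n)
    if n_train < 2:
        raise ValueError(
            f"train portion u={params.train_portion_u} of {n} docs yields "
            f"{n_train} training documents; need at least 2"
        )
    rng = np.random.default_rng(params.seed)
    train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
    hold_mask = np.ones(n, dtype=bool)
    hold_mask[train_idx] = False
    hold_idx = np.flatnonzero(hold_mask)

    train_docs = [docs[i] for i in train_idx]
    train_matrix = distance_matrix(train_docs, normalizer=params.normalizer)
    L_u = hac_cluster(train_matrix, params.lambda_threshold, params.linkage).labels

    # step 4: singleton clusters become the outlier sentinel
    vals, counts = np.unique(L_u, return_counts=True)
    singleton_labels = set(vals[counts == 1].tolist())
    L_u_prime = np.where(np.isin(L_u, list(singleton_labels)), OUTLIER, L_u)

    labels = np.full(n, OUTLIER, dtype=np.int64)
    labels[train_idx] = L_u_prime

    if hold_idx.size:
        if (L_u_prime != OUTLIER).any():
            hold_docs = [docs[i] for i in hold_idx]
            dist = cross_distance_matrix(hold_docs, train_docs, normalizer=params.normalizer)
            labels[hold_idx] = knn_predict(
                dist, L_u_prime, params.knn_k, vote_reach=params.lambda_threshold
            )
        # else: degenerate sample without any non-singleton cluster — skip the
        # classifier and let the second pass cluster everything

    # steps 7–9: second HAC pass over the unassigned pool
    out_idx = np.flatnonzero(labels == OUTLIER)
    passes = np.ones(n, dtype=np.int8)
    if out_idx.size:
        offset = labels.max() + 1 if (labels >= 0).any() else 0
        if out_idx.size == 1:
            labels[out_idx] = offset
        else:
            out_docs = [docs[i] for i in out_idx]
            out_matrix = distance_matrix(out_docs, normalizer=params.normalizer)
            L_o = hac_cluster(out_matrix, params.lambda_threshold, params.linkage).labels
            labels[out_idx] = L_o + offset
        passes[out_idx] = 2

    return Labeling(
        labels=labels,
        doc_index=tuple(d.message_id for d in docs),
        pass_=passes,
    )


def group_table(labeling: Labeling, docs: Optional[Sequence[TokenizedDoc]] = None) -> pd.DataFrame:
    """Per-group summary: size, member ids and an exemplar message.

    The exemplar is the longest member (most tokens; ties toward the smallest
    message id); when no documents are supplied it is the smallest member id.
    Rows are sorted by size descending, ties by smallest member id.
    """
    if (labeling.labels == OUTLIER).any():
        raise ValueError("labeling is not complete: outlier sentinel present")
    by_id = {d.message_id: d for d in docs} if docs is not None else {}
    rows = []
    members: dict[int, list[str]] = {}
    for mid, lab in zip(labeling.doc_index, labeling.labels.tolist()):
        members.setdefault(lab, []).append(mid)
    for lab, ids in members.items():
        if by_id:
            exemplar = min(ids, key=lambda m: (-by_id[m].n_tokens, m))
        else:
            exemplar = min(ids)
        rows.append(
            {"group_id": lab, "size": len(ids), "member_ids": sorted(ids), "exemplar": exemplar}
        )
    frame = pd.DataFrame(rows, columns=["group_id", "size", "member_ids", "exemplar"])
    if frame.empty:
        return frame
    frame["_tie"] = [min(ids) for ids in frame["member_ids"]]
    frame = frame.sort_values(["size", "_tie"], ascending=[False, True]).drop(columns="_tie")
    return frame.reset_index(drop=True)
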