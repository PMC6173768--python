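"""Consensus clustering of the samples x regions call matrix.

Samples are repeatedly subsampled (default 80% of the cohort, 500
repetitions), each subsample is clustered by Ward-linkage hierarchical
clustering on Euclidean distances over the five-level codes and cut at k
clusters, and the consensus matrix records, for every sample pair, the
fraction of co-subsampled repetitions in which the pair co-clustered.  Final
labels come from Ward clustering of (1 - consensus) cut at k.  Cluster
numbers are then canonicalized by copy-number load so that cluster 1 is the
most copy-number-stable group and cluster k the most unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .profiles import LoadSummary
from .recurrence import CallMatrix

__all__ = ["ConsensusResult", "consensus_cluster", "canonicalize_labels",
           "reclustering_agreement"]


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusResult:
    consensus_matrix: pd.DataFrame  # samples x samples, co-clustering frequency
    labels: pd.Series               # per-sample cluster in 1..k
    k: int
    n_reps: int
    subsample_fraction: float
    seed: int | None


def _ward_cut(X: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(call_matrix: CallMatrix | pd.DataFrame, k: int = 3,
                      frac: float = 0.8, reps: int = 500,
                      seed: int | None = None) -> ConsensusResult:
    """Subsampled hierarchical-Ward consensus clustering.

    Each repetition draws ``ceil(frac * n)`` samples without replacement,
    Ward-links them on Euclidean distance over the feature codes and cuts at
    ``k``; consensus(i, j) = co-cluster count / co-sample count.  Final labels
    are obtained by Ward linkage on (1 - consensus).
    """
    codes = call_matrix.codes if isinstance(call_matrix, CallMatrix) else call_matrix
    X = codes.to_numpy(dtype=float)
    n, p = X.shape
    if n < k:
        raise ConsensusError(f"need at least k={k} samples, got {n}")
    if p < 2:
        raise ConsensusError("need at least 2 features")
    if np.all(X == X[0]):
        raise ConsensusError("no variation: feature matrix is constant")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(frac * n))
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.permutation(n)[:m]
        labels = _ward_cut(X[idx], k)
        same = labels[:, None] == labels[None, :]
        ix = np.ix_(idx, idx)
        co_cluster[ix] += same
        co_sample[ix] += 1
    never = (co_sample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(f"{int(never.sum()) // 2} sample pairs were never "
                      "co-subsampled; their consensus is set to 0")
    consensus = np.divide(co_cluster, co_sample,
                          out=np.zeros_like(co_cluster), where=co_sample > 0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    final = fcluster(linkage(squareform(D, checks=False), method="ward"),
                     t=k, criterion="maxclust")
    ids = list(codes.index)
    return ConsensusResult(
        consensus_matrix=pd.DataFrame(consensus, index=ids, columns=ids),
        labels=pd.Series(final, index=ids, name="cluster"),
        k=k, n_reps=reps, subsample_fraction=frac, seed=seed)


def canonicalize_labels(labels: pd.Series,
                        load_summaries: dict[str, LoadSummary] | pd.DataFrame) -> pd.Series:
    """Renumber clusters 1..k by ascending median altered genome fraction.

    Ties on the median fraction are broken by ascending median breakpoint
    count, then by the smaller original label, so canonical labels are a pure
    function of the partition and the load summaries.
    """
    if isinstance(load_summaries, dict):
        loads = pd.DataFrame({
            "altered_fraction": {s: l.altered_fraction for s, l in load_summaries.items()},
            "n_breakpoints": {s: l.n_breakpoints for s, l in load_summaries.items()},
        })
    else:
        loads = load_summaries
    loads = loads.loc[labels.index]
    keys = []
    for lab in sorted(labels.unique()):
        members = labels.index[labels == lab]
        keys.append((float(loads.loc[members, "altered_fraction"].median()),
                     float(loads.loc[members, "n_breakpoints"].median()),
                     lab))
    mapping = {old: new + 1 for new, (_, _, old) in enumerate(sorted(keys))}
    return labels.map(mapping).rename(labels.name)


def reclustering_agreement(labels_full: pd.Series,
                           labels_subset: pd.Series) -> dict:
    """Concordance of two labelings after optimal (Hungarian) label matching.

    ``labels_subset``'s sample ids must be a subset of ``labels_full``'s.
    Returns the agreement fraction over the shared samples, the matched
    cross-tabulation (rows = full-cohort labels, columns = remapped subset
    labels) and the label mapping applied to the subset.
    """
    shared = labels_subset.index.intersection(labels_full.index)
    if len(shared) == 0:
        raise ConsensusError("no shared samples between the two labelings")
    a = labels_full.loc[shared]
    b = labels_subset.loc[shared]
    la = np.array(sorted(a.unique()))
    lb = np.array(sorted(b.unique()))
    counts = np.zeros((la.size, lb.size), dtype=int)
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            counts[i, j] = int(((a == x) & (b == y)).sum())
    rows, cols = linear_sum_assignment(-counts)
    mapping = {lb[j]: la[i] for i, j in zip(rows, cols)}
    # unmatched subset labels (if any) keep themselves
    for y in lb:
        mapping.setdefault(y, y)
    b_mapped = b.map(mapping)
    agreement = float((a == b_mapped).mean())
    crosstab = pd.crosstab(a, b_mapped, rownames=["full"], colnames=["subset"])
    return {"agreement": agreement, "crosstab": crosstab, "mapping": mapping}
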