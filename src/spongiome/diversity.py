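"""Rarefaction, alpha diversity, beta diversity, and sample dendrograms.

Shannon entropy is reported in bits (log base 2). Weighted UniFrac is
computed by a single postorder accumulation of per-branch descendant
proportions, raw form ``sum_b l_b * |p_Ab - p_Bb|``; the normalized
variant divides by ``sum_b l_b * (p_Ab + p_Bb)``. Faith's PD includes
the branches connecting the spanning subtree to the root.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from spongiome.data import (
    DistanceMatrix,
    FeatureTable,
    InputError,
    ParameterError,
)

logger = logging.getLogger(__name__)

BETA_METRICS = ("weighted_unifrac", "jaccard", "bray_curtis")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every column without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped. A sample
    whose total equals ``depth`` is kept unchanged. Deterministic per seed.
    """
    if depth <= 0:
        raise ParameterError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep_ids, cols = [], []
    for j, sid in enumerate(table.sample_ids):
        total = int(sums[j])
        if total < depth:
            continue
        keep_ids.append(sid)
        col = table.counts[:, j]
        if total == depth:
            cols.append(col.copy())
        else:
            # multivariate hypergeometric subsample
            cols.append(rng.multivariate_hypergeometric(col, depth))
    if not keep_ids:
        raise ParameterError(f"no sample reaches rarefaction depth {depth}")
    dropped = len(table.sample_ids) - len(keep_ids)
    if dropped:
        logger.info("rarefy: dropped %d sample(s) below depth %d", dropped, depth)
    return FeatureTable(np.column_stack(cols), table.feature_ids, keep_ids)


# ---------------------------------------------------------------------------
# tree -> branch matrix
# ---------------------------------------------------------------------------

def _branch_proportions(tree: TreeNode, table: FeatureTable):
    """Per-branch descendant-proportion matrix via one postorder pass.

    Returns ``(lengths, P)`` where ``lengths`` has one entry per branch
    (every non-root node with a length) and ``P[b, j]`` is the fraction
    of sample j's reads descending branch b.
    """
    feature_index = {f: i for i, f in enumerate(table.feature_ids)}
    tips = [t.name for t in tree.tips()]
    missing = set(table.feature_ids) - set(tips)
    if missing:
        raise InputError(
            f"{len(missing)} feature(s) missing from tree: {sorted(missing)[:10]}"
        )
    rel = table.relative_abundance()
    n_samples = rel.shape[1]
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = feature_index.get(node.name)
            vec = rel[i, :].astype(float) if i is not None else np.zeros(n_samples)
        else:
            vec = np.zeros(n_samples)
            for child in node.children:
                vec = vec + partial.pop(id(child))
        partial[id(node)] = vec
        if node.parent is not None and node.length is not None:
            lengths.append(float(node.length))
            rows.append(vec)
    if not rows:
        raise InputError("tree has no branch lengths")
    return np.asarray(lengths), np.vstack(rows)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(
    table: FeatureTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Shannon (bits), Pielou's evenness, observed features, Faith's PD.

    Pielou is null when a sample has <= 1 observed feature; all metrics
    are null for empty (zero-total) samples. ``faith_pd`` requires a tree.
    """
    sums = table.sample_sums().astype(float)
    rel = table.relative_abundance()
    records = []
    branch_presence = None
    lengths = None
    if tree is not None:
        lengths, P = _branch_proportions(tree, table)
        branch_presence = P > 0
    for j, sid in enumerate(table.sample_ids):
        if sums[j] == 0:
            logger.warning("sample %s has zero total; alpha metrics null", sid)
            records.append({"sample_id": sid, "shannon": np.nan,
                            "pielou": np.nan, "observed": 0,
                            "faith_pd": np.nan})
            continue
        p = rel[:, j]
        nz = p[p > 0]
        shannon = float(-(nz * np.log2(nz)).sum())
        observed = int((table.counts[:, j] > 0).sum())
        pielou = shannon / np.log2(observed) if observed > 1 else np.nan
        row = {"sample_id": sid, "shannon": shannon, "pielou": pielou,
               "observed": observed}
        if branch_presence is not None:
            row["faith_pd"] = float(lengths[branch_presence[:, j]].sum())
        else:
            row["faith_pd"] = np.nan
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def _pairwise_weighted_unifrac(lengths, P, normalized: bool) -> np.ndarray:
    n = P.shape[1]
    out = np.zeros((n, n))
    for a in range(n):
        diff = np.abs(P[:, a:a + 1] - P[:, a + 1:])          # branches x rest
        num = (lengths[:, None] * diff).sum(axis=0)
        if normalized:
            den = (lengths[:, None] * (P[:, a:a + 1] + P[:, a + 1:])).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(den > 0, num / den, 0.0)
        else:
            vals = num
        out[a, a + 1:] = vals
        out[a + 1:, a] = vals
    return out


def beta_diversity(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized: bool = False,
) -> DistanceMatrix:
    """Pairwise dissimilarity matrix for one of the supported metrics."""
    if metric not in BETA_METRICS:
        raise ParameterError(f"unknown metric {metric!r}; valid: {BETA_METRICS}")
    n = len(table.sample_ids)
    if metric == "weighted_unifrac":
        if tree is None:
            raise InputError("weighted_unifrac requires a tree")
        lengths, P = _branch_proportions(tree, table)
        values = _pairwise_weighted_unifrac(lengths, P, normalized)
    elif metric == "jaccard":
        pres = table.presence().astype(np.int64)
        inter = pres.T @ pres
        sizes = pres.sum(axis=0)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / union, 1.0)
        values = 1.0 - sim
        np.fill_diagonal(values, 0.0)
    else:  # bray_curtis
        rel = table.relative_abundance()
        values = np.zeros((n, n))
        for a in range(n):
            num = np.abs(rel[:, a:a + 1] - rel[:, a + 1:]).sum(axis=0)
            den = (rel[:, a:a + 1] + rel[:, a + 1:]).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(den > 0, num / den, 0.0)
            values[a, a + 1:] = vals
            values[a + 1:, a] = vals
    return DistanceMatrix(table.sample_ids, values)


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------

_LINKAGES = {"upgma": "average", "complete": "complete"}


def cluster_dendrogram(dist: DistanceMatrix, linkage: str = "upgma"):
    """Agglomerative merge tree over samples.

    Returns ``(newick, leaf_order)`` where ``leaf_order`` is the
    dendrogram's left-to-right leaf sequence (for heatmap sorting).
    """
    if linkage not in _LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}; valid: upgma, complete")
    if len(dist) < 2:
        raise InputError("need at least 2 items to cluster")
    condensed = squareform(dist.values, checks=False)
    Z = hierarchy.linkage(condensed, method=_LINKAGES[linkage])
    order = [dist.ids[i] for i in hierarchy.leaves_list(Z)]
    newick = _linkage_to_newick(Z, dist.ids)
    return newick, order


def linkage_matrix(dist: DistanceMatrix, linkage: str = "upgma") -> np.ndarray:
    if linkage not in _LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}")
    condensed = squareform(dist.values, checks=False)
    return hierarchy.linkage(condensed, method=_LINKAGES[linkage])


def _linkage_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}
    reps: dict[int, str] = {i: ids[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        reps[n + k] = f"({reps.pop(a)}:{la:.10g},{reps.pop(b)}:{lb:.10g})"
        heights[n + k] = h
    return reps[n + len(Z) - 1] + ";"
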