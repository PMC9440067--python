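"""Location similarity, bipartite Zi-Pi, correlation modules, indicators.

Location networks are built from presence vectors pooled per location;
module roles use within-module degree z-scores and participation
coefficients. Weighted correlation modules follow the usual soft-power /
topological-overlap / eigenprofile recipe with a static tree cut.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats as sps

from spongiome.data import (
    DistanceMatrix,
    FeatureTable,
    InputError,
    ParameterError,
    SampleMetadata,
)
from spongiome.diversity import linkage_matrix
from spongiome.stats import bh_adjust, kruskal_wallis

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# location similarity network
# ---------------------------------------------------------------------------

@dataclass
class LocationNetwork:
    locations: list[str]
    similarity: pd.DataFrame       # Jaccard similarity, unit diagonal
    heatmap_order: list[str]       # complete-linkage leaf order
    betweenness: dict[str, float]
    graph: nx.Graph
    per_location_richness: dict[str, int]


def pooled_presence(
    table: FeatureTable, metadata: SampleMetadata, sample_type: str = "sponge"
) -> tuple[list[str], np.ndarray]:
    """Presence vector per location over samples of the given type."""
    frame = metadata.frame
    mask = frame["sample_type"] == sample_type
    locs: dict[str, list[str]] = {}
    for sid, loc in frame.loc[mask, "location_id"].items():
        if pd.isna(loc):
            continue
        locs.setdefault(str(loc), []).append(str(sid))
    sample_idx = {s: j for j, s in enumerate(table.sample_ids)}
    names, vectors = [], []
    for loc in sorted(locs):
        cols = [sample_idx[s] for s in locs[loc] if s in sample_idx]
        if not cols:
            logger.warning("location %s has no usable samples; excluded", loc)
            continue
        names.append(loc)
        vectors.append(table.presence()[:, cols].any(axis=1))
    if len(names) < 2:
        raise InputError("need >= 2 locations with samples")
    return names, np.column_stack(vectors)  # features x locations


def location_similarity_network(
    table: FeatureTable, metadata: SampleMetadata
) -> LocationNetwork:
    """Jaccard similarity network between locations with betweenness.

    Heatmap order comes from complete-linkage clustering of Jaccard
    distances; betweenness centrality runs on the complete weighted
    graph with edge length = Jaccard distance.
    """
    names, pres = pooled_presence(table, metadata)
    P = pres.astype(np.int64)
    inter = P.T @ P
    sizes = P.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    np.fill_diagonal(sim, 1.0)
    dist = DistanceMatrix(names, 1.0 - sim)
    Z = linkage_matrix(dist, "complete")
    order = [names[i] for i in hierarchy.leaves_list(Z)]
    G = nx.Graph()
    G.add_nodes_from(names)
    for i, j in itertools.combinations(range(len(names)), 2):
        G.add_edge(names[i], names[j],
                   weight=float(sim[i, j]), length=float(1.0 - sim[i, j]))
    btw = nx.betweenness_centrality(G, weight="length", normalized=True)
    richness = {loc: int(sizes[i]) for i, loc in enumerate(names)}
    return LocationNetwork(
        locations=names,
        similarity=pd.DataFrame(sim, index=names, columns=names),
        heatmap_order=order,
        betweenness={k: float(v) for k, v in btw.items()},
        graph=G,
        per_location_richness=richness,
    )


# ---------------------------------------------------------------------------
# bipartite Zi-Pi
# ---------------------------------------------------------------------------

@dataclass
class ModuleRoles:
    modules: dict[str, int]
    within_module_degree_z: dict[str, float]
    participation: dict[str, float]
    projection: nx.Graph


def bipartite_module_degrees(
    table: FeatureTable, metadata: SampleMetadata
) -> ModuleRoles:
    """Zi-Pi roles of locations in the location projection of the
    location-ASV bipartite presence graph.

    Locations project to a weighted graph (shared-ASV counts); modules
    come from greedy modularity maximization; z is the within-module
    degree standardized inside each module and P the participation
    coefficient over modules.
    """
    names, pres = pooled_presence(table, metadata)
    P = pres.astype(np.int64)
    shared = P.T @ P                 # locations x locations shared ASV counts
    G = nx.Graph()
    G.add_nodes_from(names)
    for i, j in itertools.combinations(range(len(names)), 2):
        w = int(shared[i, j])
        if w > 0:
            G.add_edge(names[i], names[j], weight=w)
    communities = nx.community.greedy_modularity_communities(G, weight="weight")
    module_of = {}
    for m, com in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for node in com:
            module_of[node] = m
    k_in_module: dict[str, dict[int, float]] = {}
    for node in G.nodes:
        km: dict[int, float] = {}
        for nb in G.neighbors(node):
            m = module_of[nb]
            km[m] = km.get(m, 0.0) + G[node][nb]["weight"]
        k_in_module[node] = km
    z_scores: dict[str, float] = {}
    for m in set(module_of.values()):
        members = [n for n in G.nodes if module_of[n] == m]
        kin = np.array([k_in_module[n].get(m, 0.0) for n in members])
        mu, sd = kin.mean(), kin.std()
        for n, k in zip(members, kin):
            z_scores[n] = float((k - mu) / sd) if sd > 0 else 0.0
    participation: dict[str, float] = {}
    for node in G.nodes:
        k_total = sum(k_in_module[node].values())
        if k_total == 0:
            participation[node] = 0.0
            continue
        participation[node] = float(
            1.0 - sum((k / k_total) ** 2 for k in k_in_module[node].values())
        )
    return ModuleRoles(module_of, z_scores, participation, G)


# ---------------------------------------------------------------------------
# weighted correlation modules
# ---------------------------------------------------------------------------

@dataclass
class CorrelationModules:
    taxon_module: dict[str, int]            # -1 = unassigned
    module_eigenprofile: dict[int, np.ndarray]
    kme: dict[str, float]
    module_trait_correlation: pd.DataFrame  # modules x traits
    beta: int
    hub_taxa: dict[int, list[str]] = field(default_factory=dict)


def _pick_soft_power(corr_abs: np.ndarray) -> int:
    """Smallest beta in {2,4,...,12} with scale-free fit R2 >= 0.8, else 6."""
    for beta in (2, 4, 6, 8, 10, 12):
        adj = corr_abs ** beta
        k = adj.sum(axis=1) - 1.0     # exclude self
        k = k[k > 0]
        if len(k) < 10:
            continue
        hist, edges = np.histogram(k, bins=10)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        if keep.sum() < 3:
            continue
        x = np.log10(centers[keep])
        y = np.log10(hist[keep] / hist.sum())
        r = np.corrcoef(x, y)[0, 1]
        if r ** 2 >= 0.8 and r < 0:
            return beta
    return 6


def weighted_correlation_modules(
    rel_table: pd.DataFrame,
    traits: pd.DataFrame,
    beta: int | None = None,
    cut_height: float = 0.75,
    min_module_size: int = 10,
    kme_threshold: float = 0.8,
) -> CorrelationModules:
    """Correlation modules of taxa and their trait associations.

    ``rel_table`` is samples x taxa relative abundances (already
    filtered to sufficiently prevalent taxa); ``traits`` is samples x
    trait values (nutrients, oxygen). Unsigned adjacency ``|r|^beta``,
    topological overlap, average-linkage clustering of 1-TOM, static
    tree cut, module eigenprofile = first principal component, kME =
    correlation of each taxon with its own module's eigenprofile.
    """
    if rel_table.shape[1] < 20 or rel_table.shape[0] < 10:
        raise InputError("need >= 20 taxa and >= 10 samples")
    X = rel_table.astype(float)
    sd = X.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        logger.warning("dropping %d constant taxon profile(s)", len(const))
        X = X.drop(columns=const)
    taxa = list(X.columns)
    mat = X.to_numpy()
    corr = np.corrcoef(mat, rowvar=False)
    corr_abs = np.abs(corr)
    if beta is None:
        beta = _pick_soft_power(corr_abs)
    A = corr_abs ** beta
    np.fill_diagonal(A, 1.0)
    tom = _topological_overlap(A)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    taxon_module: dict[str, int] = {}
    module_ids = []
    for m in sorted(set(labels)):
        members = [i for i, L in enumerate(labels) if L == m]
        if len(members) < min_module_size:
            for i in members:
                taxon_module[taxa[i]] = -1
            continue
        mid = len(module_ids)
        module_ids.append((mid, members))
        for i in members:
            taxon_module[taxa[i]] = mid
    eigenprofiles: dict[int, np.ndarray] = {}
    kme: dict[str, float] = {}
    hub_taxa: dict[int, list[str]] = {}
    for mid, members in module_ids:
        sub = mat[:, members]
        zs = (sub - sub.mean(axis=0)) / np.where(sub.std(axis=0) > 0,
                                                 sub.std(axis=0), 1.0)
        U, S, Vt = np.linalg.svd(zs, full_matrices=False)
        e = U[:, 0] * S[0]
        # orient the eigenprofile with the average taxon
        if np.corrcoef(e, zs.mean(axis=1))[0, 1] < 0:
            e = -e
        eigenprofiles[mid] = e
        hubs = []
        for i in members:
            k = float(np.corrcoef(mat[:, i], e)[0, 1])
            kme[taxa[i]] = k
            if k > kme_threshold:
                hubs.append(taxa[i])
        hub_taxa[mid] = sorted(hubs)
    trait_rows = []
    for mid, _ in module_ids:
        row = {}
        for t in traits.columns:
            tv = traits[t].to_numpy(dtype=float)
            row[t] = float(np.corrcoef(eigenprofiles[mid], tv)[0, 1]) \
                if np.std(tv) > 0 else np.nan
        trait_rows.append(row)
    mt = pd.DataFrame(trait_rows, index=[mid for mid, _ in module_ids])
    return CorrelationModules(
        taxon_module=taxon_module,
        module_eigenprofile=eigenprofiles,
        kme=kme,
        module_trait_correlation=mt,
        beta=int(beta),
        hub_taxa=hub_taxa,
    )


def _topological_overlap(A: np.ndarray) -> np.ndarray:
    """Unsigned TOM: (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    n = A.shape[0]
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    L = Ad @ Ad
    k = Ad.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + Ad) / (kmin + 1.0 - Ad)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# indicator taxa (simplified LEfSe-style)
# ---------------------------------------------------------------------------

@dataclass
class IndicatorResult:
    group: str
    taxon: str
    effect_size: float  # log10 LDA-style effect
    kw_p: float
    kw_adjusted_p: float


def indicator_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    group_column: str = "sample_type",
    alpha: float = 0.05,
    n_bootstrap: int = 30,
    seed: int = 0,
) -> list[IndicatorResult]:
    """Group-enriched taxa: Kruskal-Wallis screen then a bootstrap
    one-vs-rest discriminant effect size on log10-scaled class means."""
    labels = metadata.column(group_column)
    groups = sorted(set(str(g) for g in labels.dropna()))
    counts = {g: int((labels.astype(str) == g).sum()) for g in groups}
    usable = [g for g in groups if counts[g] >= 3]
    for g in groups:
        if g not in usable:
            logger.warning("indicator_taxa: group %s has n=%d < 3; excluded",
                           g, counts[g])
    if len(usable) < 2:
        raise ParameterError("need >= 2 groups with n >= 3")
    keep_samples = [s for s in table.sample_ids
                    if str(labels.get(s)) in usable]
    sub = table.select_samples(keep_samples)
    rel = sub.relative_abundance()
    lab = np.asarray([str(labels[s]) for s in keep_samples])
    rng = np.random.default_rng(seed)
    # screen
    pvals, keep_idx = [], []
    for i in range(rel.shape[0]):
        vals = rel[i, :]
        if np.all(vals == vals[0]):
            continue
        _, p = kruskal_wallis(vals, lab)
        pvals.append(p)
        keep_idx.append(i)
    if not keep_idx:
        return []
    adj = bh_adjust(np.asarray(pvals))
    results: list[IndicatorResult] = []
    for (i, p, ap) in zip(keep_idx, pvals, adj):
        if ap > alpha:  # BH-adjusted screen keeps the familywise null clean
            continue
        vals = rel[i, :]
        # bootstrap one-vs-rest difference of log-scaled class means
        best_group = max(usable, key=lambda g: vals[lab == g].mean())
        effs = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(vals), size=len(vals))
            v, L = vals[idx], lab[idx]
            in_g = v[L == best_group]
            out_g = v[L != best_group]
            if len(in_g) == 0 or len(out_g) == 0:
                continue
            eps = 1e-6
            effs.append(np.log10(in_g.mean() + eps) - np.log10(out_g.mean() + eps))
        if not effs:
            continue
        results.append(IndicatorResult(
            group=best_group,
            taxon=sub.feature_ids[i],
            effect_size=float(np.mean(effs)),
            kw_p=float(p),
            kw_adjusted_p=float(ap),
        ))
    results.sort(key=lambda r: (r.group, -r.effect_size))
    return results
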