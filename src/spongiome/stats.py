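"""Permutation and ordination statistics from first principles.

Dunn's rank test with tie correction, PERMANOVA via Gower-centered
inner products, Mantel permutation correlation, environmental PCA, VIF
pruning, redundancy analysis with adjusted R-squared, and up-to-four-set
variation partitioning by inclusion-exclusion over union models.

Permutation p-values use the add-one rule ``(1 + hits) / (1 + n_perm)``.
Pairwise families are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from spongiome.data import DistanceMatrix, InputError, ParameterError

logger = logging.getLogger(__name__)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_rev, i in enumerate(order[::-1]):
        k = m - rank_rev
        running = min(running, p[i] * m / k)
        adj[i] = running
    return np.clip(adj, 0.0, 1.0)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    labels: tuple[str, ...] = ()
    adjusted_p: float = float("nan")
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# Dunn's test
# ---------------------------------------------------------------------------

def kruskal_wallis(values, groups) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def dunn_test(values, groups, p_adjust: str = "bh") -> list[TestResult]:
    """All pairwise Dunn z-tests on pooled ranks with tie correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1)))
    (1/n_i + 1/n_j)]`` with tie term ``T = sum(t^3 - t)``; two-sided
    normal p, BH-adjusted by default.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise InputError("values and groups differ in length")
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ParameterError("need >= 2 groups")
    ranks = sps.rankdata(values)
    N = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    if var_base <= 0:
        raise InputError("degenerate data: all pooled values identical")
    mean_rank = {g: float(ranks[groups == g].mean()) for g in names}
    n = {g: int((groups == g).sum()) for g in names}
    results = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        results.append(TestResult(statistic=float(z), p_value=float(min(p, 1.0)),
                                  labels=(str(a), str(b))))
    if p_adjust == "bh":
        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return results


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _pseudo_f(G: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    groups = pd.unique(labels)
    k = len(groups)
    ss_total = float(np.trace(G))
    ss_within = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        # within-group SS from the centered Gram matrix block
        sub = G[np.ix_(idx, idx)]
        ss_within += float(np.trace(sub) - sub.sum() / len(idx))
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> TestResult:
    """One-way PERMANOVA with label-permutation p (add-one rule)."""
    labels = np.asarray([str(g) for g in groups])
    if len(labels) != len(dist):
        raise InputError("group labels do not match distance matrix size")
    names, counts = np.unique(labels, return_counts=True)
    if len(names) < 2:
        raise ParameterError("need >= 2 groups")
    if (counts < 2).any():
        raise ParameterError("every group needs >= 2 samples")
    G = _gower_center(dist.values)
    f_obs = _pseudo_f(G, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm = _pseudo_f(G, rng.permutation(labels))
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return TestResult(statistic=float(f_obs), p_value=float(p),
                      labels=tuple(names), n_permutations=n_permutations)


def permanova_exhaustive(dist: DistanceMatrix, groups) -> TestResult:
    """Exact p over every distinct label assignment (small n only)."""
    labels = np.asarray([str(g) for g in groups])
    n = len(labels)
    if n > 10:
        raise ParameterError("exhaustive enumeration limited to n <= 10")
    G = _gower_center(dist.values)
    f_obs = _pseudo_f(G, labels)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        f = _pseudo_f(G, labels[list(perm)])
        total += 1
        if f >= f_obs - 1e-12:
            hits += 1
    return TestResult(statistic=float(f_obs), p_value=hits / total,
                      n_permutations=total)


def pairwise_permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[TestResult]:
    labels = np.asarray([str(g) for g in groups])
    names = sorted(set(labels))
    rng = np.random.default_rng(seed)
    results = []
    for a, b in itertools.combinations(names, 2):
        mask = (labels == a) | (labels == b)
        if (labels == a).sum() < 2 or (labels == b).sum() < 2:
            logger.warning("pairwise PERMANOVA: group pair (%s, %s) has a "
                           "singleton group; skipped", a, b)
            continue
        ids = [i for i, m in zip(dist.ids, mask) if m]
        sub = dist.submatrix(ids)
        res = permanova(sub, labels[mask],
                        n_permutations=n_permutations,
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
        res.labels = (a, b)
        results.append(res)
    adj = bh_adjust([r.p_value for r in results]) if results else []
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "pearson",
) -> tuple[float, float]:
    """Two-sided Mantel permutation test between two distance matrices."""
    if set(d1.ids) != set(d2.ids):
        raise InputError("distance matrices have different id sets")
    d2 = d2.submatrix(d1.ids)
    n = len(d1)
    if n < 3:
        raise InputError("Mantel test needs >= 3 objects")
    iu = np.triu_indices(n, k=1)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if method == "spearman":
            a, b = sps.rankdata(a), sps.rankdata(b)
        elif method != "pearson":
            raise ParameterError("method must be 'pearson' or 'spearman'")
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    v1 = d1.values[iu]
    r_obs = corr(v1, d2.values[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        v2p = d2.values[np.ix_(perm, perm)][iu]
        if abs(corr(v1, v2p)) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# environmental PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    contributions: pd.DataFrame  # variables x components, percent


def env_pca(env: pd.DataFrame) -> PCAResult:
    """PCA of z-standardized environmental parameters via SVD.

    Zero-variance columns are dropped with a warning. Contribution of a
    variable to a component is its squared loading share in percent.
    """
    if env.shape[0] < 2 or env.shape[1] < 2:
        raise InputError("need >= 2 samples and >= 2 variables")
    X = env.astype(float)
    sd = X.std(ddof=1)
    drop = sd[sd == 0].index.tolist()
    if drop:
        logger.warning("env_pca: dropping zero-variance column(s) %s", drop)
        X = X.drop(columns=drop)
        if X.shape[1] < 2:
            raise InputError("fewer than 2 variables after dropping constants")
    Z = (X - X.mean()) / X.std(ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    n = Z.shape[0]
    eigvals = S ** 2 / (n - 1)
    evr = eigvals / eigvals.sum()
    comps = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=Z.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=Z.columns, columns=comps)
    contrib = 100.0 * loadings ** 2 / (loadings ** 2).sum(axis=0)
    return PCAResult(scores, loadings, evr, contrib)


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------

def vif_values(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors from regressing each column on the rest."""
    Xc = X.astype(float)
    out = {}
    cols = list(Xc.columns)
    mat = Xc.to_numpy()
    for j, col in enumerate(cols):
        if len(cols) == 1:
            out[col] = 1.0
            continue
        y = mat[:, j]
        others = np.delete(mat, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[col] = 1.0
            continue
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(
    predictors: pd.DataFrame, vif_threshold: float = 10.0
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Drop the highest-VIF column until all are below the threshold.

    Ties break by column order (first of the tied columns is dropped).
    Returns the retained frame and a removal log of (column, VIF).
    """
    if predictors.shape[1] < 1:
        raise InputError("need at least one predictor")
    X = predictors.copy()
    removed: list[tuple[str, float]] = []
    while X.shape[1] > 1:
        vifs = vif_values(X)
        worst = float(vifs.max())
        if worst < vif_threshold:
            break
        # first column attaining the max (deterministic tie-break)
        col = next(c for c in X.columns if vifs[c] == worst)
        removed.append((col, worst))
        X = X.drop(columns=[col])
    return X, removed


# ---------------------------------------------------------------------------
# RDA and variation partitioning
# ---------------------------------------------------------------------------

def hellinger(rel_abundance: np.ndarray) -> np.ndarray:
    """Square-root of row-wise relative abundances (samples x features)."""
    rel = np.asarray(rel_abundance, dtype=float)
    row_sums = rel.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row_sums > 0, rel / row_sums, 0.0)
    return np.sqrt(p)


def rda_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Redundancy-analysis R-squared and adjusted R-squared.

    ``Y`` (samples x responses) and ``X`` (samples x predictors) are
    column-centered internally; adjusted uses the predictor column count
    as the degrees-of-freedom cost.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    m = X.shape[1]
    if n <= m + 1:
        raise ParameterError(f"need n > m + 1 (n={n}, m={m})")
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    ss_total = float((Yc ** 2).sum())
    if ss_total == 0:
        raise InputError("response has zero variance")
    r2 = float((fitted ** 2).sum()) / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    return r2, float(adj)


@dataclass
class VarPartResult:
    set_names: list[str]
    union_adjusted_r2: dict[frozenset, float]
    unique_fractions: dict[str, float]
    shared_fractions: dict[frozenset, float]
    residual_fraction: float
    full_model_adjusted_r2: float
    p_values: dict[str, float] = field(default_factory=dict)

    def ranking(self) -> list[str]:
        return sorted(self.unique_fractions,
                      key=lambda k: -self.unique_fractions[k])


def variation_partitioning(
    response: np.ndarray,
    predictor_sets: dict[str, pd.DataFrame],
    n_permutations: int = 999,
    seed: int = 0,
) -> VarPartResult:
    """Partition adjusted R-squared over 2-4 named predictor sets.

    Fits an RDA for every non-empty union of sets; unique and shared
    fractions follow by inclusion-exclusion and may be negative
    (adjusted-R2 artefact, reported as-is). Each set's marginal model is
    tested by response-row permutation.
    """
    names = list(predictor_sets)
    if not 2 <= len(names) <= 4:
        raise ParameterError("predictor_sets must contain 2-4 sets")
    cols_seen: set[str] = set()
    for name, df in predictor_sets.items():
        overlap = cols_seen & set(df.columns)
        if overlap:
            raise ParameterError(f"predictor column(s) in multiple sets: {overlap}")
        cols_seen |= set(df.columns)
    Y = np.asarray(response, dtype=float)

    union_r2: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            X = pd.concat([predictor_sets[c] for c in combo], axis=1)
            _, adj = rda_r2(Y, X.to_numpy())
            union_r2[frozenset(combo)] = adj

    full = union_r2[frozenset(names)]
    exclusive = _moebius_exclusive(names, union_r2)
    unique = {n: exclusive[frozenset([n])] for n in names}
    shared = {S: v for S, v in exclusive.items() if len(S) > 1}

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    for name in names:
        X = predictor_sets[name].to_numpy()
        r2_obs, _ = rda_r2(Y, X)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(Y.shape[0])
            r2_perm, _ = rda_r2(Y[perm], X)
            if r2_perm >= r2_obs - 1e-12:
                hits += 1
        p_values[name] = (1 + hits) / (1 + n_permutations)

    return VarPartResult(
        set_names=names,
        union_adjusted_r2=union_r2,
        unique_fractions=unique,
        shared_fractions=shared,
        residual_fraction=1.0 - full,
        full_model_adjusted_r2=full,
        p_values=p_values,
    )


def _moebius_exclusive(
    names: list[str], union_r2: dict[frozenset, float]
) -> dict[frozenset, float]:
    """Exclusive (Venn-region) fractions from union-model adjusted R2.

    For the region explained by exactly the sets in S and no others:
    ``f(S) = sum_{extra subseteq S} (-1)^(|extra|+1) * R2((all - S) u
    extra)`` with ``R2(empty) = 0`` (Moebius inversion over the union
    lattice; for two sets this reduces to the familiar
    ``unique_A = R2(AB) - R2(B)`` and ``shared = R2(A)+R2(B)-R2(AB)``).
    """
    all_names = frozenset(names)
    r2 = dict(union_r2)
    r2[frozenset()] = 0.0
    out: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            S = frozenset(combo)
            comp = all_names - S
            total = 0.0
            for k in range(len(S) + 1):
                for extra in itertools.combinations(sorted(S), k):
                    total += (-1) ** (k + 1) * r2[comp | frozenset(extra)]
            out[S] = total
    return out
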