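"""Core/variable/individual classification, sequence clustering, sharing.

Membership is evaluated on sponge samples only. "Individual" features
occur in exactly one sponge sample; "core" features occur in strictly
more than ``core_fraction`` of sponge samples (occurrence at exactly the
70% boundary is variable); everything in between is "variable". No
relative-abundance threshold is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from scipy import stats

from spongiome.data import (
    FeatureTable,
    InputError,
    ParameterError,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

MEMBERSHIP_CATEGORIES = ("individual", "variable", "core")


# ---------------------------------------------------------------------------
# membership classification
# ---------------------------------------------------------------------------

def core_boundary(n_samples: int, core_fraction: float) -> int:
    """Smallest occurrence count classified as core (> fraction rule)."""
    if not 0 < core_fraction <= 1:
        raise ParameterError("core_fraction must be in (0, 1]")
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    return int(np.floor(core_fraction * n_samples)) + 1


def classify_membership(
    table: FeatureTable, core_fraction: float = 0.7
) -> pd.DataFrame:
    """Occurrence-based membership of every feature in the given table.

    The table must already be restricted to sponge samples. Returns a
    frame indexed by feature with ``occurrence`` and ``category``;
    all-zero features are excluded.
    """
    n = len(table.sample_ids)
    if n < 1 or len(table.feature_ids) == 0:
        raise InputError("empty table")
    boundary = core_boundary(n, core_fraction)
    occ = (table.counts > 0).sum(axis=1)
    records = []
    for fid, k in zip(table.feature_ids, occ):
        if k == 0:
            continue
        if k == 1:
            cat = "individual"
        elif k >= boundary:
            cat = "core"
        else:
            cat = "variable"
        records.append({"feature_id": fid, "occurrence": int(k), "category": cat})
    return pd.DataFrame.from_records(records).set_index("feature_id")


def membership_across_thresholds(
    table: FeatureTable,
    sequences: dict[str, str] | None,
    thresholds,
    core_fraction: float = 0.7,
) -> pd.DataFrame:
    """Membership at each sequence-clustering threshold.

    At threshold 1.0 units are the ASVs themselves; below, features are
    greedily clustered by global-alignment identity and counts summed
    per cluster before classification.
    """
    frames = []
    for thr in thresholds:
        if thr >= 1.0 or sequences is None:
            unit_table = table
        else:
            mapping = cluster_features(sequences, thr)
            unit_table = collapse_by_cluster(table, mapping)
        mem = classify_membership(unit_table, core_fraction)
        mem = mem.reset_index().rename(columns={"feature_id": "unit"})
        mem.insert(0, "threshold", thr)
        frames.append(mem)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# greedy sequence clustering
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity(a: str, b: str, aligner=None) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def cluster_features(sequences: dict[str, str], threshold: float) -> dict[str, str]:
    """Greedy seed-first clustering at the given identity threshold.

    Sequences are processed by decreasing length then lexicographic id; a
    query joins the first seed with identity >= threshold, else founds a
    new cluster. Returns a feature -> cluster-representative map.
    """
    if not sequences:
        raise InputError("empty sequence set")
    if not 0 < threshold <= 1:
        raise ParameterError("threshold must be in (0, 1]")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    aligner = _make_aligner()
    seeds: list[str] = []
    assignment: dict[str, str] = {}
    for fid in order:
        seq = sequences[fid].upper()
        joined = None
        for seed in seeds:
            seed_seq = sequences[seed].upper()
            if threshold >= 1.0:
                ident = 1.0 if seq == seed_seq else 0.0
            else:
                ident = alignment_identity(seq, seed_seq, aligner)
            if ident >= threshold:
                joined = seed
                break
        if joined is None:
            seeds.append(fid)
            joined = fid
        assignment[fid] = joined
    return assignment


def read_fasta(path) -> dict[str, str]:
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no sequences in FASTA {path}")
    return records


def collapse_by_cluster(table: FeatureTable, mapping: dict[str, str]) -> FeatureTable:
    """Sum feature rows by cluster representative; unmapped rows keep their id."""
    groups: dict[str, list[int]] = {}
    for i, fid in enumerate(table.feature_ids):
        groups.setdefault(mapping.get(fid, fid), []).append(i)
    reps = sorted(groups)
    counts = np.vstack([table.counts[groups[r], :].sum(axis=0) for r in reps])
    return FeatureTable(counts, reps, table.sample_ids)


# ---------------------------------------------------------------------------
# sample-type sharing
# ---------------------------------------------------------------------------

@dataclass
class SharingSummary:
    per_feature_groups: dict[str, frozenset]
    group_feature_sets: dict[str, set]
    fraction_single_group: float
    pairwise_shared_fraction: dict[tuple[str, str], float]
    fraction_all_groups: float


def sample_type_sharing(
    table: FeatureTable, metadata: SampleMetadata, group_column: str = "group"
) -> SharingSummary:
    """Label every feature by the set of sample groups it occurs in.

    ``metadata`` must carry ``group_column`` mapping every sample to
    exactly one group (e.g. HMA / LMA_demo / LMA_glass / seawater /
    sediment). All-zero features are excluded with a warning.
    """
    groups = metadata.column(group_column)
    if groups.isna().any():
        bad = list(metadata.frame.index[groups.isna()])
        raise InputError(f"samples without a group: {bad[:10]}")
    group_names = sorted(set(groups))
    pres = table.presence()
    sample_idx = {s: j for j, s in enumerate(table.sample_ids)}
    group_cols = {
        g: [sample_idx[s] for s in metadata.frame.index[groups == g] if s in sample_idx]
        for g in group_names
    }
    per_feature: dict[str, frozenset] = {}
    group_sets: dict[str, set] = {g: set() for g in group_names}
    n_zero = 0
    for i, fid in enumerate(table.feature_ids):
        present_in = frozenset(
            g for g, cols in group_cols.items() if pres[i, cols].any()
        )
        if not present_in:
            n_zero += 1
            continue
        per_feature[fid] = present_in
        for g in present_in:
            group_sets[g].add(fid)
    if n_zero:
        logger.warning("sample_type_sharing: %d all-zero feature(s) excluded", n_zero)
    total = len(per_feature)
    single = sum(1 for s in per_feature.values() if len(s) == 1)
    in_all = sum(1 for s in per_feature.values() if len(s) == len(group_names))
    pairwise = {}
    for a in range(len(group_names)):
        for b in range(a + 1, len(group_names)):
            ga, gb = group_names[a], group_names[b]
            shared = len(group_sets[ga] & group_sets[gb])
            pairwise[(ga, gb)] = shared / total if total else 0.0
    return SharingSummary(
        per_feature_groups=per_feature,
        group_feature_sets=group_sets,
        fraction_single_group=single / total if total else 0.0,
        pairwise_shared_fraction=pairwise,
        fraction_all_groups=in_all / total if total else 0.0,
    )


# ---------------------------------------------------------------------------
# abundance-occupancy
# ---------------------------------------------------------------------------

def abundance_occupancy(
    table: FeatureTable,
    sample_ids: list[str] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Mean relative abundance vs occupancy with a permutation Spearman test.

    Zeros are included in the mean. Returns ``(frame, rho, p)``; rho/p are
    null for single-sample groups.
    """
    sub = table if sample_ids is None else table.select_samples(sample_ids)
    if len(sub.sample_ids) == 0:
        raise InputError("empty sample group")
    rel = sub.relative_abundance()
    mean_rel = rel.mean(axis=1)
    occupancy = (sub.counts > 0).sum(axis=1)
    frame = pd.DataFrame(
        {"mean_relative_abundance": mean_rel, "occupancy": occupancy},
        index=sub.feature_ids,
    )
    keep = occupancy > 0
    if len(sub.sample_ids) < 2 or keep.sum() < 3:
        return frame, float("nan"), float("nan")
    x, y = mean_rel[keep], occupancy[keep].astype(float)
    rho = _spearman(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r = _spearman(x, rng.permutation(y))
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return frame, float(rho), float(p)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])
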