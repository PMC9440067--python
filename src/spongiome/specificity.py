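"""Host-specific and exclusive ASV detection at every host taxonomic rank.

An ASV is *specific* to a host group at a rank when it is present in at
least one sponge sample of that group, absent from every other group at
the same rank, and absent from all seawater and sediment reference
samples. An *exclusive* ASV is a specific ASV whose within-group
prevalence strictly exceeds the threshold (default 0.9). ASVs occurring
in exactly one sample overall ("individual" fraction) are excluded
before detection by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spongiome.data import (
    FeatureTable,
    InputError,
    ParameterError,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

HOST_RANKS = ("host_species", "host_genus", "host_family",
              "host_order", "host_class")


@dataclass
class RankSpecificity:
    """Specific/exclusive sets for every group at one host rank."""

    rank: str
    specific: dict[str, set[str]]
    exclusive: dict[str, set[str]] = field(default_factory=dict)
    group_sample_count: dict[str, int] = field(default_factory=dict)
    prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    single_sample_groups: list[str] = field(default_factory=list)

    @property
    def groups_with_specific(self) -> int:
        return sum(1 for s in self.specific.values() if s)

    def all_specific(self) -> set[str]:
        out: set[str] = set()
        for s in self.specific.values():
            out |= s
        return out

    def all_exclusive(self) -> set[str]:
        out: set[str] = set()
        for s in self.exclusive.values():
            out |= s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.specific):
            for asv in sorted(self.specific[g]):
                rows.append({
                    "rank": self.rank,
                    "group": g,
                    "asv": asv,
                    "specific": True,
                    "exclusive": asv in self.exclusive.get(g, set()),
                    "prevalence": self.prevalence.get(g, {}).get(asv, np.nan),
                })
        return pd.DataFrame(rows, columns=["rank", "group", "asv", "specific",
                                           "exclusive", "prevalence"])


def _rank_groups(metadata: SampleMetadata, rank: str) -> dict[str, list[str]]:
    if rank not in HOST_RANKS:
        raise ParameterError(f"unknown host rank {rank!r}; valid: {HOST_RANKS}")
    if rank not in metadata.frame.columns:
        raise InputError(f"metadata lacks column {rank!r}")
    sponge = metadata.frame[metadata.frame["sample_type"] == "sponge"]
    groups: dict[str, list[str]] = {}
    for sid, g in sponge[rank].items():
        if pd.isna(g):
            continue
        groups.setdefault(str(g), []).append(str(sid))
    return groups


def host_specific_asvs(
    table: FeatureTable,
    metadata: SampleMetadata,
    rank: str,
    exclude_individual: bool = True,
) -> RankSpecificity:
    """Detect host-specific ASVs for every group at one host rank."""
    groups = _rank_groups(metadata, rank)
    if not groups:
        raise InputError(f"no sponge samples with rank {rank!r}")
    ref_samples = [s for s in metadata.reference_samples()
                   if s in set(table.sample_ids)]
    pres = table.presence()
    sample_idx = {s: j for j, s in enumerate(table.sample_ids)}
    group_cols = {
        g: [sample_idx[s] for s in samples if s in sample_idx]
        for g, samples in groups.items()
    }
    ref_cols = [sample_idx[s] for s in ref_samples]

    # occurrence over ALL samples, for the individual-fraction exclusion
    total_occ = pres.sum(axis=1)
    eligible = np.ones(len(table.feature_ids), dtype=bool)
    if exclude_individual:
        eligible &= total_occ != 1

    in_ref = (
        pres[:, ref_cols].any(axis=1)
        if ref_cols else np.zeros(len(table.feature_ids), dtype=bool)
    )
    group_names = sorted(group_cols)
    occ_by_group = np.column_stack([
        pres[:, group_cols[g]].sum(axis=1) for g in group_names
    ])
    present_by_group = occ_by_group > 0
    n_groups_present = present_by_group.sum(axis=1)

    result = RankSpecificity(rank=rank, specific={}, exclusive={},
                             group_sample_count={}, prevalence={})
    for gi, g in enumerate(group_names):
        n_g = len(group_cols[g])
        result.group_sample_count[g] = n_g
        if n_g == 0:
            logger.warning("group %s at rank %s has 0 samples; skipped", g, rank)
            result.specific[g] = set()
            continue
        if n_g == 1:
            result.single_sample_groups.append(g)
        mask = (
            eligible
            & present_by_group[:, gi]
            & (n_groups_present == 1)
            & ~in_ref
        )
        idx = np.nonzero(mask)[0]
        result.specific[g] = {table.feature_ids[i] for i in idx}
        result.prevalence[g] = {
            table.feature_ids[i]: float(occ_by_group[i, gi]) / n_g for i in idx
        }
    return result


def exclusive_asvs(
    result: RankSpecificity, prevalence_threshold: float = 0.9
) -> RankSpecificity:
    """Mark the specific ASVs whose within-group prevalence is strictly
    above the threshold as exclusive; mutates and returns ``result``."""
    if not 0 < prevalence_threshold <= 1:
        raise ParameterError("prevalence_threshold must be in (0, 1]")
    for g, asvs in result.specific.items():
        prev = result.prevalence.get(g, {})
        result.exclusive[g] = {
            a for a in asvs if prev.get(a, 0.0) > prevalence_threshold
        }
    return result


def specificity_by_rank(
    table: FeatureTable,
    metadata: SampleMetadata,
    ranks=HOST_RANKS,
    prevalence_threshold: float = 0.9,
    exclude_individual: bool = True,
) -> dict[str, RankSpecificity]:
    return {
        rank: exclusive_asvs(
            host_specific_asvs(table, metadata, rank, exclude_individual),
            prevalence_threshold,
        )
        for rank in ranks
    }


def median_specific_fraction(
    result: RankSpecificity, table: FeatureTable, metadata: SampleMetadata
) -> float:
    """Median over groups of (specific ASVs / ASV pool of the group) x 100."""
    groups = _rank_groups(metadata, result.rank)
    pres = table.presence()
    sample_idx = {s: j for j, s in enumerate(table.sample_ids)}
    fractions = []
    for g, samples in groups.items():
        cols = [sample_idx[s] for s in samples if s in sample_idx]
        pool = int(pres[:, cols].any(axis=1).sum())
        if pool == 0:
            continue
        fractions.append(100.0 * len(result.specific.get(g, set())) / pool)
    return float(np.median(fractions)) if fractions else float("nan")


def specific_fraction_by_type(
    species_result: RankSpecificity,
    table: FeatureTable,
    metadata: SampleMetadata,
) -> dict[str, float]:
    """Percent of each sponge type's ASV pool that is species-specific."""
    if species_result.rank != "host_species":
        raise ParameterError("requires the species-rank specificity result")
    frame = metadata.frame
    sponge = frame[frame["sample_type"] == "sponge"]
    pres = table.presence()
    sample_idx = {s: j for j, s in enumerate(table.sample_ids)}
    species_by_type: dict[str, set[str]] = {}
    samples_by_type: dict[str, list[str]] = {}
    for sid, row in sponge.iterrows():
        t = row.get("sponge_type")
        if pd.isna(t):
            continue
        samples_by_type.setdefault(str(t), []).append(str(sid))
        sp = row.get("host_species")
        if not pd.isna(sp):
            species_by_type.setdefault(str(t), set()).add(str(sp))
    out: dict[str, float] = {}
    for t, samples in samples_by_type.items():
        cols = [sample_idx[s] for s in samples if s in sample_idx]
        pool_mask = pres[:, cols].any(axis=1)
        pool = int(pool_mask.sum())
        if pool == 0:
            out[t] = float("nan")
            continue
        specific: set[str] = set()
        for sp in species_by_type.get(t, set()):
            specific |= species_result.specific.get(sp, set())
        pool_ids = {table.feature_ids[i] for i in np.nonzero(pool_mask)[0]}
        out[t] = 100.0 * len(specific & pool_ids) / pool
    return out
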