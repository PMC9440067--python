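"""Bundle I/O and table transforms: TSV read/write, filtering, aggregation.

A "bundle" is the on-disk form of one dataset: feature counts TSV
(``#FeatureID`` leading header, features as rows), sample metadata TSV
(``sample-id`` first column), taxonomy TSV, a rooted newick tree, and —
for synthetic data — an ESRI ASCII bathymetry grid and a ground-truth
JSON file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from spongiome.data import (
    EmptyResultError,
    FeatureTable,
    InputError,
    ParameterError,
    SampleMetadata,
    TaxonomyTable,
    TAXONOMY_RANKS,
    reconcile,
)

logger = logging.getLogger(__name__)

COUNTS_FILE = "counts.tsv"
METADATA_FILE = "metadata.tsv"
TAXONOMY_FILE = "taxonomy.tsv"
TREE_FILE = "tree.nwk"
GROUNDTRUTH_FILE = "ground_truth.json"
BATHYMETRY_FILE = "bathymetry.asc"


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "#FeatureID"
    df.to_csv(path, sep="\t")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            row = df.index[series.isna().argmax()]
            raise InputError(
                f"non-numeric count at feature {row!r}, sample {col!r}"
            )
        neg = series < 0
        if neg.any():
            row = df.index[neg.argmax()]
            raise InputError(
                f"negative count {series[neg].iloc[0]} at feature {row!r}, "
                f"sample {col!r}"
            )
        df[col] = series
    return FeatureTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# metadata / taxonomy
# ---------------------------------------------------------------------------

def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.frame.copy()
    df.index.name = "sample-id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    rows = [
        {"feature_id": fid, "lineage": taxonomy.lineage_string(fid)}
        for fid in taxonomy.lineages
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "feature_id" not in df.columns or "lineage" not in df.columns:
        raise InputError("taxonomy TSV needs 'feature_id' and 'lineage' columns")
    if df["feature_id"].duplicated().any():
        raise InputError("duplicate feature ids in taxonomy")
    return TaxonomyTable.from_lineage_strings(
        dict(zip(df["feature_id"], df["lineage"].fillna("")))
    )


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def validate_tree_covers(tree: TreeNode, table: FeatureTable) -> None:
    leaves = {t.name for t in tree.tips()}
    missing = sorted(set(table.feature_ids) - leaves)
    if missing:
        raise InputError(
            f"{len(missing)} table feature(s) missing from tree leaves: "
            f"{missing[:10]}"
        )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    table: FeatureTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable | None = None
    tree: TreeNode | None = None


def write_bundle(bundle: Bundle, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(bundle.table, outdir / COUNTS_FILE)
    write_metadata(bundle.metadata, outdir / METADATA_FILE)
    if bundle.taxonomy is not None:
        write_taxonomy(bundle.taxonomy, outdir / TAXONOMY_FILE)
    if bundle.tree is not None:
        write_tree(bundle.tree, outdir / TREE_FILE)
    return outdir


def read_bundle(indir: str | Path) -> Bundle:
    indir = Path(indir)
    counts_path = indir / COUNTS_FILE
    meta_path = indir / METADATA_FILE
    for p in (counts_path, meta_path):
        if not p.exists():
            raise InputError(f"bundle file missing: {p}")
    table = read_feature_table(counts_path)
    metadata = read_metadata(meta_path)
    table, metadata = reconcile(table, metadata)
    taxonomy = None
    tax_path = indir / TAXONOMY_FILE
    if tax_path.exists():
        taxonomy = read_taxonomy(tax_path)
    tree = None
    tree_path = indir / TREE_FILE
    if tree_path.exists():
        tree = read_tree(tree_path)
        validate_tree_covers(tree, table)
    return Bundle(table, metadata, taxonomy, tree)


# ---------------------------------------------------------------------------
# filtering / aggregation
# ---------------------------------------------------------------------------

def filter_samples(
    table: FeatureTable, metadata: SampleMetadata, min_reads: int
) -> tuple[FeatureTable, SampleMetadata]:
    """Remove samples whose library size is strictly below ``min_reads``.

    The boundary is kept: a sample with exactly ``min_reads`` reads passes.
    Features left with all-zero rows afterwards are pruned.
    """
    if min_reads < 0:
        raise ParameterError("min_reads must be >= 0")
    sums = table.sample_sums()
    keep = [s for s, n in zip(table.sample_ids, sums) if n >= min_reads]
    if not keep:
        raise EmptyResultError(
            f"all {len(table.sample_ids)} samples below min_reads={min_reads}"
        )
    n_dropped = len(table.sample_ids) - len(keep)
    if n_dropped:
        logger.info("filter_samples: dropped %d sample(s) below %d reads",
                    n_dropped, min_reads)
    filtered = table.select_samples(keep).drop_empty_features()
    return filtered, metadata.select([s for s in keep if s in set(metadata.sample_ids)])


def aggregate_taxa(
    table: FeatureTable, taxonomy: TaxonomyTable, rank: str
) -> FeatureTable:
    """Sum counts per lineage prefix down to ``rank``.

    Features unassigned at ``rank`` pool into an explicit
    ``unclassified@<rank>`` row. Column sums are preserved exactly.
    """
    if rank not in TAXONOMY_RANKS:
        raise ParameterError(f"unknown rank {rank!r}; valid: {TAXONOMY_RANKS}")
    depth = TAXONOMY_RANKS.index(rank) + 1
    groups: dict[str, list[int]] = {}
    unclassified = f"unclassified@{rank}"
    for i, fid in enumerate(table.feature_ids):
        entry = taxonomy.lineages.get(fid)
        name = entry.get(rank) if entry else None
        if name is None:
            key = unclassified
        else:
            prefix = [entry.get(r) or "?" for r in TAXONOMY_RANKS[:depth]]
            key = ";".join(prefix)
        groups.setdefault(key, []).append(i)
    keys = sorted(k for k in groups if k != unclassified)
    if unclassified in groups:
        keys.append(unclassified)
    counts = np.vstack([table.counts[groups[k], :].sum(axis=0) for k in keys])
    return FeatureTable(counts, keys, table.sample_ids)
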