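"""Core data containers: feature table, metadata, taxonomy, distance matrix.

All containers are thin, validated wrappers around numpy/pandas objects.
Feature tables are stored features-as-rows, samples-as-columns, mirroring
common amplicon-export conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOST_RANKS = ("host_species", "host_genus", "host_family", "host_order", "host_class")
SAMPLE_TYPES = ("sponge", "seawater", "sediment")
SPONGE_TYPES = ("HMA", "LMA_demo", "LMA_glass")

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class SpongiomeError(Exception):
    """Base class for all package errors."""


class InputError(SpongiomeError):
    """Malformed or inconsistent input data."""


class ParameterError(SpongiomeError):
    """Invalid analysis parameter."""


class EmptyResultError(SpongiomeError):
    """An operation removed every sample/feature."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise InputError(f"duplicate {what}: {sorted(set(dups))[:5]}")


class FeatureTable:
    """Non-negative integer counts of features (ASVs/OTUs/taxa) per sample.

    Parameters
    ----------
    counts
        ``(n_features, n_samples)`` array of non-negative counts.
    feature_ids, sample_ids
        Unique ordered identifiers for rows and columns.
    """

    def __init__(self, counts, feature_ids, sample_ids):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise InputError("counts must be a 2-D matrix")
        feature_ids = [str(f) for f in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        _check_unique(feature_ids, "feature ids")
        _check_unique(sample_ids, "sample ids")
        if counts.shape != (len(feature_ids), len(sample_ids)):
            raise InputError(
                f"counts shape {counts.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if counts.size and counts.min() < 0:
            i, j = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise InputError(
                f"negative count {counts[i, j]} at feature "
                f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if counts.size and not np.allclose(counts, rounded):
                raise InputError("counts must be integers")
            counts = rounded
        self.counts = counts.astype(np.int64)
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self._feature_index = {f: i for i, f in enumerate(feature_ids)}
        self._sample_index = {s: j for j, s in enumerate(sample_ids)}

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureTable)
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"FeatureTable({self.shape[0]} features x {self.shape[1]} samples)"

    # -- accessors -----------------------------------------------------
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def feature_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self._sample_index[sample_id]]

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized proportions; all-zero columns stay zero."""
        sums = self.sample_sums().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / sums
        rel[:, sums == 0] = 0.0
        return rel

    def presence(self) -> np.ndarray:
        return self.counts > 0

    # -- subsetting ----------------------------------------------------
    def select_samples(self, sample_ids) -> "FeatureTable":
        idx = [self._sample_index[s] for s in sample_ids]
        return FeatureTable(self.counts[:, idx], self.feature_ids, list(sample_ids))

    def select_features(self, feature_ids) -> "FeatureTable":
        idx = [self._feature_index[f] for f in feature_ids]
        return FeatureTable(self.counts[idx, :], list(feature_ids), self.sample_ids)

    def drop_empty_features(self) -> "FeatureTable":
        keep = self.feature_sums() > 0
        return FeatureTable(
            self.counts[keep, :],
            [f for f, k in zip(self.feature_ids, keep) if k],
            self.sample_ids,
        )

    # -- pandas bridge -------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))


@dataclass
class SampleMetadata:
    """Per-sample annotations keyed by ``sample-id``.

    Wraps a DataFrame indexed by sample id. Recognised columns:
    ``sample_type`` (sponge/seawater/sediment), ``sponge_type``
    (HMA/LMA_demo/LMA_glass, NA for references), host rank columns
    (``host_species`` .. ``host_class``), ``location_id``, ``lat``,
    ``lon``, ``depth``, ``temperature``, ``salinity``, plus any number
    of continuous environmental parameters. Unknown columns pass
    through untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise InputError(f"duplicate sample ids in metadata: {dups[:5]}")
        if "sample_type" in self.frame.columns:
            bad = set(self.frame["sample_type"].dropna()) - set(SAMPLE_TYPES)
            if bad:
                raise InputError(f"unknown sample_type values: {sorted(bad)}")
        for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
            if col in self.frame.columns:
                vals = pd.to_numeric(self.frame[col], errors="coerce").dropna()
                if len(vals) and ((vals < lo) | (vals > hi)).any():
                    raise InputError(f"{col} outside [{lo}, {hi}]")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())

    def samples_where(self, column: str, value) -> list[str]:
        if column not in self.frame.columns:
            raise InputError(f"metadata column {column!r} missing")
        mask = self.frame[column] == value
        return [str(s) for s in self.frame.index[mask]]

    def sponge_samples(self) -> list[str]:
        return self.samples_where("sample_type", "sponge")

    def reference_samples(self) -> list[str]:
        mask = self.frame["sample_type"].isin(["seawater", "sediment"])
        return [str(s) for s in self.frame.index[mask]]

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise InputError(f"metadata column {name!r} missing")
        return self.frame[name]


class TaxonomyTable:
    """feature id -> ranked lineage (domain..genus); missing ranks are None."""

    def __init__(self, lineages: dict[str, dict[str, str | None]]):
        self.lineages = {
            str(f): {r: (ranks.get(r) or None) for r in TAXONOMY_RANKS}
            for f, ranks in lineages.items()
        }

    def __len__(self) -> int:
        return len(self.lineages)

    def rank_of(self, feature_id: str, rank: str) -> str | None:
        if rank not in TAXONOMY_RANKS:
            raise ParameterError(
                f"unknown rank {rank!r}; valid ranks: {TAXONOMY_RANKS}"
            )
        entry = self.lineages.get(feature_id)
        return entry[rank] if entry else None

    def lineage_string(self, feature_id: str) -> str:
        entry = self.lineages.get(feature_id, {})
        parts = []
        for prefix, rank in zip("dpcofg", TAXONOMY_RANKS):
            name = entry.get(rank)
            parts.append(f"{prefix}__{name if name else ''}")
        return "; ".join(parts)

    @classmethod
    def from_lineage_strings(cls, mapping: dict[str, str]) -> "TaxonomyTable":
        """Parse semicolon-ranked lineages, tolerating ``d__``-style prefixes."""
        lineages = {}
        for fid, s in mapping.items():
            fields = [p.strip() for p in str(s).split(";")]
            entry: dict[str, str | None] = {}
            for rank, part in zip(TAXONOMY_RANKS, fields):
                if "__" in part:
                    part = part.split("__", 1)[1]
                entry[rank] = part if part else None
            lineages[fid] = entry
        return cls(lineages)


@dataclass
class DistanceMatrix:
    """Symmetric, non-negative, zero-diagonal pairwise distances."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        _check_unique(self.ids, "distance matrix ids")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise InputError("distance matrix shape does not match ids")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-10):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise InputError("distance matrix diagonal is not zero")
        if v[finite].size and v[finite].min() < -1e-10:
            raise InputError("negative distances")
        v[finite & (v < 0)] = 0.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float))


def reconcile(table: FeatureTable, metadata: SampleMetadata):
    """Inner-join table and metadata on sample ids, warning on drops."""
    common = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    dropped_t = sorted(set(table.sample_ids) - set(common))
    dropped_m = sorted(set(metadata.sample_ids) - set(common))
    if dropped_t:
        logger.warning(
            "%d table sample(s) missing from metadata, dropped: %s",
            len(dropped_t), dropped_t[:10],
        )
    if dropped_m:
        logger.warning(
            "%d metadata sample(s) missing from table, dropped: %s",
            len(dropped_m), dropped_m[:10],
        )
    if not common:
        raise EmptyResultError("no samples shared between table and metadata")
    return table.select_samples(common), metadata.select(common)
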