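"""Synthetic dataset generator with full ground-truth labels.

Emulates the structure the downstream analysis assumes: three sponge
types with a balanced host taxonomy, multiple sampling locations with
coordinates and environmental covariates, seawater/sediment reference
samples, planted species-specific and exclusive ASVs, universal core
ASVs, distance-driven compositional turnover, and environmental effects
on designated taxa. Counts are Dirichlet-multinomial draws around a
closed-form expected composition so oracles can evaluate the generative
mean directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from spongiome.config import SimulationConfig
from spongiome.data import (
    FeatureTable,
    InputError,
    ParameterError,
    SampleMetadata,
    TaxonomyTable,
)

import pandas as pd

HOST_RANK_COLUMNS = ("host_species", "host_genus", "host_family",
                     "host_order", "host_class")

# phyla 0..2 are HMA-enriched, 3..5 LMA-enriched, rest neutral
_N_PHYLA = 8
_HMA_PHYLA = (0, 1, 2)
_LMA_PHYLA = (3, 4, 5)

_EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two points in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted labels for every synthetic structure the analysis detects."""

    specific_asv_labels: dict[str, dict[str, list[str]]]
    exclusive_asv_labels: dict[str, dict[str, list[str]]]
    membership_labels: dict[str, str]
    hma_lma_labels: dict[str, str]
    location_coordinates: dict[str, tuple[float, float]]
    planted_decay_rate: float
    core_asvs: list[str] = field(default_factory=list)
    responsive_asvs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = {
            "specific_asv_labels": self.specific_asv_labels,
            "exclusive_asv_labels": self.exclusive_asv_labels,
            "membership_labels": self.membership_labels,
            "hma_lma_labels": self.hma_lma_labels,
            "location_coordinates": {
                k: list(v) for k, v in self.location_coordinates.items()
            },
            "planted_decay_rate": self.planted_decay_rate,
            "core_asvs": self.core_asvs,
            "responsive_asvs": self.responsive_asvs,
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["location_coordinates"] = {
            k: tuple(v) for k, v in d["location_coordinates"].items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# internal layout
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    """Deterministic structural skeleton derived from a SimulationConfig."""

    species: list[str]                      # ordered species ids
    species_type: dict[str, str]
    host_lineage: dict[str, dict[str, str]]
    feature_ids: list[str]
    background_idx: np.ndarray              # indices of background ASVs
    core_idx: np.ndarray
    specific_idx: dict[str, np.ndarray]     # species -> planted ASV indices
    seawater_idx: np.ndarray
    sediment_idx: np.ndarray
    baseline_weights: dict[str, np.ndarray]  # type -> weights over all features
    seawater_weights: np.ndarray
    sediment_weights: np.ndarray
    origin_location: np.ndarray             # per-feature origin location index
    responsive: np.ndarray                  # per-feature env responsiveness
    locations: list[str]
    loc_coords: dict[str, tuple[float, float]]
    loc_dist_km: np.ndarray
    loc_env: np.ndarray                     # locations x n_env
    phylum_of_feature: np.ndarray


_LEAK_FACTOR = {"HMA": 0.02, "LMA_demo": 0.10, "LMA_glass": 0.10}
_N_CORE_ASVS = 8
_SPECIFIC_WEIGHT = 3.0  # relative to a typical baseline ASV weight of 1


def _host_taxonomy(cfg: SimulationConfig) -> tuple[list[str], dict, dict]:
    """Balanced species->genus->family->order->class hierarchy per type."""
    species, species_type, lineage = [], {}, {}
    for t in sorted(cfg.n_species_per_type):
        n = cfg.n_species_per_type[t]
        klass = "Hexactinellida" if t == "LMA_glass" else "Demospongiae"
        for i in range(n):
            sp = f"sp_{t}_{i:02d}"
            g = i // cfg.genus_fanout
            f = g // cfg.family_fanout
            o = f // cfg.order_fanout
            species.append(sp)
            species_type[sp] = t
            lineage[sp] = {
                "host_species": sp,
                "host_genus": f"genus_{t}_{g:02d}",
                "host_family": f"family_{t}_{f:02d}",
                "host_order": f"order_{t}_{o:02d}",
                "host_class": klass,
            }
    return species, species_type, lineage


def _build_layout(cfg: SimulationConfig, rng: np.random.Generator) -> _Layout:
    species, species_type, lineage = _host_taxonomy(cfg)

    n_bg = cfg.n_background_asvs
    n_spec_total = cfg.n_specific_asvs_per_species * len(species)
    n_sw, n_sed = max(10, n_bg // 4), max(6, n_bg // 8)
    ids: list[str] = []
    ids += [f"asv_bg_{i:05d}" for i in range(n_bg)]
    core_local = rng.choice(n_bg, size=min(_N_CORE_ASVS, n_bg), replace=False)
    ids += [f"asv_sp_{i:05d}" for i in range(n_spec_total)]
    ids += [f"asv_sw_{i:05d}" for i in range(n_sw)]
    ids += [f"asv_sed_{i:05d}" for i in range(n_sed)]
    n_feat = len(ids)

    background_idx = np.arange(n_bg)
    specific_start = n_bg
    seawater_idx = np.arange(n_bg + n_spec_total, n_bg + n_spec_total + n_sw)
    sediment_idx = np.arange(n_bg + n_spec_total + n_sw, n_feat)

    specific_idx = {}
    for k, sp in enumerate(species):
        lo = specific_start + k * cfg.n_specific_asvs_per_species
        specific_idx[sp] = np.arange(lo, lo + cfg.n_specific_asvs_per_species)

    # phylum assignment: background ASVs biased so HMA/LMA baselines differ
    phylum_of_feature = rng.integers(0, _N_PHYLA, size=n_feat)

    # per-type baseline over background ASVs; pool size tracks target richness
    baseline_weights = {}
    type_phylum_pref = {
        "HMA": _HMA_PHYLA,
        "LMA_demo": _LMA_PHYLA,
        "LMA_glass": _LMA_PHYLA,
    }
    for t in sorted(cfg.n_species_per_type):
        target = cfg.richness_mean_by_type.get(t, 40.0)
        pool_size = int(min(n_bg, max(2, round(target))))
        pref = type_phylum_pref.get(t, ())
        prob = np.where(np.isin(phylum_of_feature[background_idx], pref), 4.0, 1.0)
        prob = prob / prob.sum()
        pool = rng.choice(n_bg, size=pool_size, replace=False, p=prob)
        w = np.zeros(n_feat)
        w[pool] = rng.lognormal(0.0, 0.8, size=pool_size)
        w[core_local] = np.maximum(w[core_local], 2.0)  # universal core
        baseline_weights[t] = w

    sw = np.zeros(n_feat)
    sw[seawater_idx] = rng.lognormal(0.0, 0.8, size=len(seawater_idx))
    shared = rng.choice(n_bg, size=max(1, n_bg // 10), replace=False)
    sw[shared] = rng.lognormal(0.0, 0.8, size=len(shared))  # sw/sponge overlap
    sed = np.zeros(n_feat)
    sed[sediment_idx] = rng.lognormal(0.0, 0.8, size=len(sediment_idx))

    # locations on a rough great-circle line with jitter
    locations = [f"loc_{i:02d}" for i in range(cfg.n_locations)]
    lats = np.linspace(50.0, 70.0, cfg.n_locations) + rng.normal(0, 0.3, cfg.n_locations)
    lons = np.linspace(-40.0, 0.0, cfg.n_locations) + rng.normal(0, 0.3, cfg.n_locations)
    loc_coords = {L: (float(a), float(o)) for L, a, o in zip(locations, lats, lons)}
    D = np.zeros((cfg.n_locations, cfg.n_locations))
    for i in range(cfg.n_locations):
        for j in range(i + 1, cfg.n_locations):
            D[i, j] = D[j, i] = haversine_km(lats[i], lons[i], lats[j], lons[j])

    origin_location = rng.integers(0, cfg.n_locations, size=n_feat)
    responsive = np.zeros(n_feat)
    resp_pick = rng.choice(n_bg, size=max(1, n_bg // 5), replace=False)
    responsive[resp_pick] = rng.choice([-1.0, 1.0], size=len(resp_pick))

    # location-level environmental covariates (lat-correlated first axis)
    n_env = cfg.n_env_parameters
    loc_env = rng.normal(0.0, 1.0, size=(cfg.n_locations, n_env))
    loc_env[:, 0] = (lats - lats.mean()) / max(lats.std(), 1e-9)

    return _Layout(
        species=species,
        species_type=species_type,
        host_lineage=lineage,
        feature_ids=ids,
        background_idx=background_idx,
        core_idx=core_local,
        specific_idx=specific_idx,
        seawater_idx=seawater_idx,
        sediment_idx=sediment_idx,
        baseline_weights=baseline_weights,
        seawater_weights=sw,
        sediment_weights=sed,
        origin_location=origin_location,
        responsive=responsive,
        locations=locations,
        loc_coords=loc_coords,
        loc_dist_km=D,
        loc_env=loc_env,
        phylum_of_feature=phylum_of_feature,
    )


def _sponge_mean_weights(
    cfg: SimulationConfig, layout: _Layout, sponge_type: str,
    loc_index: int, env_z: np.ndarray,
) -> np.ndarray:
    """Unnormalized expected weights of a sponge sample, specific ASVs aside."""
    w = layout.baseline_weights[sponge_type].copy()
    if cfg.decay_rate > 0:
        d = layout.loc_dist_km[layout.origin_location, loc_index]
        w = w * np.exp(-cfg.decay_rate * d)
    if cfg.env_effect_size != 0:
        w = w * np.exp(cfg.env_effect_size * layout.responsive * env_z[0])
    w = w + _LEAK_FACTOR.get(sponge_type, 0.05) * layout.seawater_weights
    return w


def expected_composition(
    cfg: SimulationConfig, sponge_type: str, species: str | None = None,
) -> dict[str, np.ndarray]:
    """Closed-form expected relative composition per location.

    Evaluates the generative mean for a sponge of ``sponge_type`` (and
    optionally a species, adding its planted ASVs at expected prevalence)
    at every location. Oracles compare this against directly sampled data.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = _build_layout(cfg, rng)
    if species is not None and species not in layout.specific_idx:
        raise ParameterError(f"unknown species {species!r}")
    out = {}
    for li, loc in enumerate(layout.locations):
        env_z = layout.loc_env[li]
        w = _sponge_mean_weights(cfg, layout, sponge_type, li, env_z)
        if species is not None:
            w = w.copy()
            w[layout.specific_idx[species]] = (
                _SPECIFIC_WEIGHT * cfg.exclusive_prevalence
            )
        total = w.sum()
        out[loc] = w / total if total > 0 else w
    return out


def location_distance_km(cfg: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Great-circle distances between the generator's planted locations."""
    rng = np.random.default_rng(cfg.seed)
    layout = _build_layout(cfg, rng)
    return layout.locations, layout.loc_dist_km


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _draw_counts(
    rng: np.random.Generator, weights: np.ndarray, depth: int, dispersion: float,
) -> np.ndarray:
    """One Dirichlet-multinomial draw; huge dispersion degrades to multinomial."""
    support = weights > 0
    p = np.zeros_like(weights)
    base = weights[support] / weights[support].sum()
    if dispersion >= 1e8:
        p[support] = base
    else:
        p[support] = rng.dirichlet(dispersion * base)
    counts = np.zeros(len(weights), dtype=np.int64)
    counts[support] = rng.multinomial(depth, p[support] / p[support].sum())
    return counts


def generate_dataset(cfg: SimulationConfig):
    """Generate a full labelled bundle.

    Returns ``(FeatureTable, SampleMetadata, TaxonomyTable, TreeNode,
    GroundTruth)``. Identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = _build_layout(cfg, rng)
    n_feat = len(layout.feature_ids)
    lo_spp, hi_spp = cfg.sample_count_range()
    mu, sigma = cfg.depth_distribution

    sample_rows: list[dict] = []
    weight_list: list[np.ndarray] = []
    presence_draws: dict[str, list[np.ndarray]] = {sp: [] for sp in layout.species}

    # sponge samples: species spread over locations
    sid = 0
    for sp in layout.species:
        t = layout.species_type[sp]
        n_samp = int(rng.integers(lo_spp, hi_spp + 1)) if hi_spp > lo_spp else lo_spp
        locs = rng.integers(0, cfg.n_locations, size=n_samp)
        for li in locs:
            li = int(li)
            env_z = layout.loc_env[li] + rng.normal(0, 0.2, cfg.n_env_parameters)
            w = _sponge_mean_weights(cfg, layout, t, li, env_z)
            present = rng.random(len(layout.specific_idx[sp])) < cfg.exclusive_prevalence
            w[layout.specific_idx[sp]] = np.where(present, _SPECIFIC_WEIGHT, 0.0)
            presence_draws[sp].append(present)
            weight_list.append(w)
            lat, lon = layout.loc_coords[layout.locations[li]]
            sample_rows.append({
                "sample_id": f"S{sid:04d}",
                "sample_type": "sponge",
                "sponge_type": t,
                **layout.host_lineage[sp],
                "location_id": layout.locations[li],
                "lat": lat, "lon": lon,
                "depth": float(300 + 150 * li + rng.normal(0, 20)),
                "temperature": float(8.0 - 0.4 * li + rng.normal(0, 0.2)),
                "salinity": float(35.0 - 0.05 * li + rng.normal(0, 0.02)),
                **{f"env_{k + 1:02d}": float(v) for k, v in enumerate(env_z)},
            })
            sid += 1

    # reference samples
    for ref_type, wvec in (("seawater", layout.seawater_weights),
                           ("sediment", layout.sediment_weights)):
        for _ in range(cfg.n_reference_samples.get(ref_type, 0)):
            li = int(rng.integers(0, cfg.n_locations))
            env_z = layout.loc_env[li] + rng.normal(0, 0.2, cfg.n_env_parameters)
            weight_list.append(wvec.copy())
            lat, lon = layout.loc_coords[layout.locations[li]]
            sample_rows.append({
                "sample_id": f"S{sid:04d}",
                "sample_type": ref_type,
                "sponge_type": None,
                **{r: None for r in HOST_RANK_COLUMNS},
                "location_id": layout.locations[li],
                "lat": lat, "lon": lon,
                "depth": float(300 + 150 * li + rng.normal(0, 20)),
                "temperature": float(8.0 - 0.4 * li + rng.normal(0, 0.2)),
                "salinity": float(35.0 - 0.05 * li + rng.normal(0, 0.02)),
                **{f"env_{k + 1:02d}": float(v) for k, v in enumerate(env_z)},
            })
            sid += 1

    # library sizes and count draws
    n_samples = len(sample_rows)
    depths = np.maximum(
        np.rint(rng.lognormal(mu, sigma, size=n_samples)).astype(int),
        max(cfg.min_library_size, 1),
    )
    counts = np.zeros((n_feat, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = _draw_counts(rng, weight_list[j], int(depths[j]), cfg.dispersion)

    sample_ids = [r.pop("sample_id") for r in sample_rows]
    table = FeatureTable(counts, layout.feature_ids, sample_ids)
    meta_frame = pd.DataFrame(sample_rows, index=pd.Index(sample_ids, name="sample-id"))
    metadata = SampleMetadata(meta_frame)
    taxonomy = _make_taxonomy(layout, rng)
    tree = generate_tree(layout.feature_ids, seed=int(rng.integers(0, 2**31 - 1)))
    truth = _make_ground_truth(cfg, layout, table, metadata, presence_draws)
    return table, metadata, taxonomy, tree, truth


def _make_taxonomy(layout: _Layout, rng: np.random.Generator) -> TaxonomyTable:
    lineages = {}
    for i, fid in enumerate(layout.feature_ids):
        p = int(layout.phylum_of_feature[i])
        c = i % 3
        lineages[fid] = {
            "domain": "Bacteria",
            "phylum": f"Phylum_{p:02d}",
            "class": f"Class_{p:02d}_{c}",
            "order": f"Order_{p:02d}_{c}",
            "family": None,
            "genus": None,
        }
    return TaxonomyTable(lineages)


def _map_rank_upward(layout: _Layout, rank_col: str,
                     species_sets: dict[str, set[str]]) -> dict[str, list[str]]:
    groups: dict[str, set[str]] = {}
    for sp, asvs in species_sets.items():
        g = layout.host_lineage[sp][rank_col]
        groups.setdefault(g, set()).update(asvs)
    return {g: sorted(v) for g, v in groups.items()}


def _make_ground_truth(
    cfg: SimulationConfig, layout: _Layout, table: FeatureTable,
    metadata: SampleMetadata, presence_draws: dict[str, list[np.ndarray]],
) -> GroundTruth:
    fid = layout.feature_ids
    specific_sets = {
        sp: {fid[i] for i in idx} for sp, idx in layout.specific_idx.items()
    }
    # realized within-species prevalence of each planted ASV
    exclusive_sets: dict[str, set[str]] = {}
    for sp, draws in presence_draws.items():
        if not draws:
            exclusive_sets[sp] = set()
            continue
        mat = np.vstack(draws)  # samples x planted ASVs
        prev = mat.mean(axis=0)
        exclusive_sets[sp] = {
            fid[i] for i, p in zip(layout.specific_idx[sp], prev) if p > 0.9
        }

    specific_labels = {"host_species": {sp: sorted(v) for sp, v in specific_sets.items()}}
    exclusive_labels = {"host_species": {sp: sorted(v) for sp, v in exclusive_sets.items()}}
    for rank in ("host_genus", "host_family", "host_order", "host_class"):
        specific_labels[rank] = _map_rank_upward(layout, rank, specific_sets)
        exclusive_labels[rank] = _map_rank_upward(layout, rank, exclusive_sets)

    # realized membership over sponge samples
    sponge = metadata.sponge_samples()
    sub = table.select_samples(sponge)
    occ = (sub.counts > 0).sum(axis=1)
    n = len(sponge)
    boundary = int(np.floor(cfg_core_fraction() * n)) + 1
    membership = {}
    for i, f in enumerate(fid):
        if occ[i] == 0:
            continue
        if occ[i] == 1:
            membership[f] = "individual"
        elif occ[i] >= boundary:
            membership[f] = "core"
        else:
            membership[f] = "variable"

    return GroundTruth(
        specific_asv_labels=specific_labels,
        exclusive_asv_labels=exclusive_labels,
        membership_labels=membership,
        hma_lma_labels=dict(layout.species_type),
        location_coordinates=dict(layout.loc_coords),
        planted_decay_rate=cfg.decay_rate,
        core_asvs=sorted(fid[i] for i in layout.core_idx),
        responsive_asvs=sorted(
            fid[i] for i in np.nonzero(layout.responsive)[0]
        ),
    )


def cfg_core_fraction() -> float:
    """Reference core prevalence used to record realized membership labels."""
    return 0.7


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def generate_tree(feature_ids: list[str], seed: int) -> TreeNode:
    """Random rooted binary tree by coalescent-style pairwise joins.

    Branch lengths are i.i.d. Exponential(1). Leaves are exactly
    ``feature_ids``.
    """
    ids = list(feature_ids)
    if len(ids) < 2:
        raise InputError("need at least 2 features for a tree")
    if len(set(ids)) != len(ids):
        raise InputError("duplicate feature ids")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in ids:
        leaf = TreeNode(name=name)
        leaf.length = float(rng.exponential(1.0))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# bathymetry
# ---------------------------------------------------------------------------

@dataclass
class BathymetryGrid:
    """Regular lat/lon elevation raster; negative elevation = below sea level."""

    lats: np.ndarray        # cell-center latitudes, one per row
    lons: np.ndarray        # cell-center longitudes, one per column
    elevation: np.ndarray   # rows x cols, metres
    nodata: float = -9999.0

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != (len(self.lats), len(self.lons)):
            raise InputError("elevation shape does not match coordinate vectors")
        for v, name in ((self.lats, "lats"), (self.lons, "lons")):
            d = np.diff(v)
            if len(d) and not (np.all(d > 0) or np.all(d < 0)):
                raise InputError(f"{name} must be monotone")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def navigable_mask(self, depth_threshold_m: float) -> np.ndarray:
        """Cells whose sea floor is at least ``depth_threshold_m`` deep."""
        return self.elevation <= -abs(depth_threshold_m)


def generate_bathymetry(
    extent: tuple[float, float, float, float],
    shape: tuple[int, int],
    features: list[dict] | None = None,
    seed: int = 0,
    base_elevation: float = -4000.0,
    noise_sd: float = 10.0,
) -> BathymetryGrid:
    """Synthetic bathymetry raster with shelf/ridge/basin primitives.

    ``extent`` is (lat_min, lat_max, lon_min, lon_max); ``shape`` is
    (rows, cols). Feature dicts:

    - ``{"kind": "ridge", "axis": "row"|"col", "index": i, "elevation": z,
       "gap": j?}`` — a wall of cells at elevation ``z`` with an optional
      gap left at the given cross index.
    - ``{"kind": "shelf", "side": "north"|"south"|"east"|"west",
       "width": w, "elevation": z}`` — border band raised to ``z``.
    - ``{"kind": "basin", "row": r, "col": c, "radius": k,
       "elevation": z}`` — disc lowered/raised to ``z``.
    """
    lat_min, lat_max, lon_min, lon_max = extent
    rows, cols = shape
    if rows < 2 or cols < 2:
        raise ParameterError("grid must be at least 2x2")
    if lat_min >= lat_max or lon_min >= lon_max:
        raise ParameterError("extent bounds reversed or degenerate")
    rng = np.random.default_rng(seed)
    lats = np.linspace(lat_min, lat_max, rows)
    lons = np.linspace(lon_min, lon_max, cols)
    elev = np.full((rows, cols), float(base_elevation))
    elev += rng.normal(0.0, noise_sd, size=elev.shape)
    for feat in features or []:
        kind = feat.get("kind")
        z = float(feat.get("elevation", -50.0))
        if kind == "ridge":
            axis, idx = feat.get("axis", "row"), int(feat["index"])
            if axis == "row":
                elev[idx, :] = z
                if "gap" in feat and feat["gap"] is not None:
                    elev[idx, int(feat["gap"])] = float(base_elevation)
            else:
                elev[:, idx] = z
                if "gap" in feat and feat["gap"] is not None:
                    elev[int(feat["gap"]), idx] = float(base_elevation)
        elif kind == "shelf":
            w = int(feat.get("width", 1))
            side = feat.get("side", "north")
            if side == "north":
                elev[-w:, :] = z
            elif side == "south":
                elev[:w, :] = z
            elif side == "east":
                elev[:, -w:] = z
            else:
                elev[:, :w] = z
        elif kind == "basin":
            r, c, k = int(feat["row"]), int(feat["col"]), int(feat.get("radius", 1))
            rr, cc = np.ogrid[:rows, :cols]
            disc = (rr - r) ** 2 + (cc - c) ** 2 <= k ** 2
            elev[disc] = z
        else:
            raise ParameterError(f"unknown bathymetry feature kind {kind!r}")
    return BathymetryGrid(lats, lons, elev)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_esri_ascii(grid: BathymetryGrid, path: str | Path) -> None:
    rows, cols = grid.shape
    cell_lat = abs(float(grid.lats[1] - grid.lats[0])) if rows > 1 else 1.0
    cell_lon = abs(float(grid.lons[1] - grid.lons[0])) if cols > 1 else cell_lat
    if abs(cell_lat - cell_lon) > 1e-9:
        raise InputError(
            "ESRI ASCII requires square cells; grid spacing is "
            f"{cell_lat:.6g} deg lat vs {cell_lon:.6g} deg lon"
        )
    lines = [
        f"ncols {cols}",
        f"nrows {rows}",
        f"xllcorner {grid.lons.min() - cell_lat / 2:.8f}",
        f"yllcorner {grid.lats.min() - cell_lat / 2:.8f}",
        f"cellsize {cell_lat:.8f}",
        f"NODATA_value {grid.nodata}",
    ]
    # ESRI rows run north->south
    data = grid.elevation if grid.lats[0] > grid.lats[-1] else grid.elevation[::-1]
    for row in data:
        lines.append(" ".join(f"{v:.3f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_esri_ascii(path: str | Path) -> BathymetryGrid:
    text = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise InputError(f"ESRI ASCII grid missing header field {key!r}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    data = np.loadtxt(text[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (rows, cols):
        raise InputError(
            f"grid body shape {data.shape} does not match header {(rows, cols)}"
        )
    # file rows run north->south; store south->north ascending lats
    lats = header["yllcorner"] + cell / 2 + cell * np.arange(rows)
    lons = header["xllcorner"] + cell / 2 + cell * np.arange(cols)
    return BathymetryGrid(
        lats, lons, data[::-1], nodata=header.get("nodata_value", -9999.0)
    )
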