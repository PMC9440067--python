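"""Adapted rarefaction: microbial richness vs number of host species.

For each step ``n`` in ``1..S`` and each replicate, ``n`` host species
of the sponge type are drawn uniformly without replacement —
independently of earlier steps — all their samples are pooled, and
richness is the number of features with pooled count > 0. The curve's
plateau is the type's microbiome carrying capacity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from spongiome.data import (
    FeatureTable,
    InputError,
    ParameterError,
    SampleMetadata,
)


@dataclass
class RarefactionCurve:
    sponge_type: str
    frame: pd.DataFrame  # columns: n_species, mean_richness, sd, q025, q975
    replicates: int
    richness_per_replicate: np.ndarray  # steps x replicates


def _species_samples(
    metadata: SampleMetadata, sponge_type: str
) -> dict[str, list[str]]:
    frame = metadata.frame
    mask = (frame["sample_type"] == "sponge") & (frame["sponge_type"] == sponge_type)
    if not mask.any():
        raise ParameterError(f"unknown or empty sponge type {sponge_type!r}")
    out: dict[str, list[str]] = {}
    for sid, sp in frame.loc[mask, "host_species"].items():
        if pd.isna(sp):
            continue
        out.setdefault(str(sp), []).append(str(sid))
    if not out:
        raise InputError(f"no species annotations for type {sponge_type!r}")
    return out


def adapted_rarefaction(
    table: FeatureTable,
    metadata: SampleMetadata,
    sponge_type: str,
    replicates: int = 100,
    seed: int = 0,
) -> RarefactionCurve:
    """Richness-vs-host-species curve for one sponge type."""
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    species_samples = _species_samples(metadata, sponge_type)
    species = sorted(species_samples)
    S = len(species)
    rng = np.random.default_rng(seed)
    # pre-pool presence per species
    sample_idx = {s: j for j, s in enumerate(table.sample_ids)}
    pres = table.presence()
    species_presence = np.vstack([
        pres[:, [sample_idx[s] for s in species_samples[sp]
                 if s in sample_idx]].any(axis=1)
        for sp in species
    ])  # species x features
    richness = np.zeros((S, replicates), dtype=np.int64)
    for step, n in enumerate(range(1, S + 1)):
        for r in range(replicates):
            chosen = rng.choice(S, size=n, replace=False)
            richness[step, r] = int(species_presence[chosen, :].any(axis=0).sum())
    frame = pd.DataFrame({
        "n_species": np.arange(1, S + 1),
        "mean_richness": richness.mean(axis=1),
        "sd": richness.std(axis=1, ddof=1) if replicates > 1 else 0.0,
        "q025": np.quantile(richness, 0.025, axis=1),
        "q975": np.quantile(richness, 0.975, axis=1),
    })
    return RarefactionCurve(sponge_type, frame, replicates, richness)


def fit_asymptote(curve: RarefactionCurve) -> tuple[float, float]:
    """Convenience two-parameter saturating fit ``a*n/(b+n)``.

    Extension beyond the core procedure; returns ``(a, b)`` where ``a``
    estimates the carrying-capacity plateau.
    """
    x = curve.frame["n_species"].to_numpy(dtype=float)
    y = curve.frame["mean_richness"].to_numpy(dtype=float)
    if len(x) < 2:
        raise InputError("need >= 2 curve points to fit an asymptote")
    (a, b), _ = curve_fit(
        lambda n, a, b: a * n / (b + n), x, y,
        p0=(float(y.max()), 1.0), maxfev=10000,
    )
    return float(a), float(b)
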