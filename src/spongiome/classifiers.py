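"""HMA/LMA status prediction and T-S water-mass classification.

Status prediction trains a random forest on phylum- plus class-level
relative abundance profiles and aggregates per-sample votes into a
per-species majority label. Water masses are rectangular boxes in
temperature-salinity space; overlaps resolve to the nearest box center
in z-scored T-S units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from spongiome.data import InputError, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# HMA/LMA random forest
# ---------------------------------------------------------------------------

@dataclass
class StatusModel:
    forest: RandomForestClassifier
    feature_names: list[str]
    oob_accuracy: float
    importances: pd.Series


def hma_lma_train(
    profiles: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> StatusModel:
    """Train a seeded random forest on row-normalized taxon profiles.

    ``profiles`` is samples x taxa (phylum + class level relative
    abundances); ``labels`` maps each sample to HMA or LMA.
    """
    y = labels.loc[profiles.index].astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise InputError(f"need both labels present, got only {classes}")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(profiles.to_numpy(dtype=float), y.to_numpy())
    return StatusModel(
        forest=forest,
        feature_names=list(profiles.columns),
        oob_accuracy=float(forest.oob_score_),
        importances=pd.Series(forest.feature_importances_,
                              index=profiles.columns).sort_values(ascending=False),
    )


@dataclass
class StatusPrediction:
    per_sample: pd.Series
    per_species: pd.DataFrame  # label, vote_fraction, n_samples


def _align_features(profiles: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Zero-fill taxa unseen in training; drop extras."""
    out = pd.DataFrame(0.0, index=profiles.index, columns=names)
    common = [c for c in profiles.columns if c in set(names)]
    out[common] = profiles[common].astype(float)
    return out.to_numpy()


def hma_lma_predict(
    model: StatusModel,
    profiles: pd.DataFrame,
    species: pd.Series | None = None,
) -> StatusPrediction:
    """Per-sample labels plus per-species majority with vote fraction.

    Samples with empty (all-zero) profiles and species with tied votes
    are labelled ``ambiguous``.
    """
    X = _align_features(profiles, model.feature_names)
    raw = model.forest.predict(X)
    empty = X.sum(axis=1) == 0
    per_sample = pd.Series(raw, index=profiles.index, dtype=object)
    if empty.any():
        logger.warning("%d empty profile(s) labelled ambiguous", int(empty.sum()))
        per_sample[empty] = "ambiguous"
    if species is None:
        return StatusPrediction(per_sample, pd.DataFrame())
    rows = []
    sp = species.loc[profiles.index]
    for name in sorted(set(sp.dropna().astype(str))):
        votes = per_sample[(sp.astype(str) == name).to_numpy()]
        votes = votes[votes != "ambiguous"]
        if len(votes) == 0:
            rows.append({"species": name, "label": "ambiguous",
                         "vote_fraction": np.nan, "n_samples": 0})
            continue
        counts = votes.value_counts()
        top = counts.iloc[0]
        winners = counts[counts == top].index.tolist()
        if len(winners) > 1:
            rows.append({"species": name, "label": "ambiguous",
                         "vote_fraction": top / len(votes),
                         "n_samples": int(len(votes))})
        else:
            rows.append({"species": name, "label": winners[0],
                         "vote_fraction": top / len(votes),
                         "n_samples": int(len(votes))})
    per_species = pd.DataFrame(rows).set_index("species")
    return StatusPrediction(per_sample, per_species)


def status_summary(per_species: pd.DataFrame) -> dict[str, int]:
    """Species counts per predicted status (LMA pooled over subtypes)."""
    counts: dict[str, int] = {}
    for label in per_species["label"]:
        key = "LMA" if str(label).startswith("LMA") else str(label)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# water-mass boxes
# ---------------------------------------------------------------------------

@dataclass
class WaterMassBoxes:
    boxes: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, b in self.boxes.items():
            for axis in ("T", "S"):
                lo, hi = b[f"{axis}_min"], b[f"{axis}_max"]
                if not lo < hi:
                    raise ParameterError(
                        f"box {name!r}: {axis}_min must be < {axis}_max"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WaterMassBoxes":
        df = pd.read_csv(path, sep="\t")
        required = {"name", "T_min", "T_max", "S_min", "S_max"}
        if not required <= set(df.columns):
            raise InputError(f"boxes TSV needs columns {sorted(required)}")
        if df["name"].duplicated().any():
            raise InputError("duplicate water-mass names")
        return cls({
            str(r["name"]): {k: float(r[k])
                             for k in ("T_min", "T_max", "S_min", "S_max")}
            for _, r in df.iterrows()
        })

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"name": n, **b} for n, b in self.boxes.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def watermass_classify(
    temperature, salinity, boxes: WaterMassBoxes
) -> list[str]:
    """Label each (T, S) pair by its containing box.

    Multiple matches resolve to the nearest box center in z-scored T-S
    units (scales from the box corner spread); no match or NaN input
    gives ``unclassified``.
    """
    if not boxes.boxes:
        raise ParameterError("no water-mass boxes defined")
    T = np.asarray(temperature, dtype=float)
    S = np.asarray(salinity, dtype=float)
    names = list(boxes.boxes)
    corners_T = np.array([[b["T_min"], b["T_max"]] for b in boxes.boxes.values()])
    corners_S = np.array([[b["S_min"], b["S_max"]] for b in boxes.boxes.values()])
    t_scale = max(float(np.std(corners_T)), 1e-9)
    s_scale = max(float(np.std(corners_S)), 1e-9)
    centers = [((b["T_min"] + b["T_max"]) / 2, (b["S_min"] + b["S_max"]) / 2)
               for b in boxes.boxes.values()]
    out = []
    for t, s in zip(np.atleast_1d(T), np.atleast_1d(S)):
        if not (np.isfinite(t) and np.isfinite(s)):
            logger.warning("non-finite T/S pair -> unclassified")
            out.append("unclassified")
            continue
        matches = [
            k for k, b in enumerate(boxes.boxes.values())
            if b["T_min"] <= t <= b["T_max"] and b["S_min"] <= s <= b["S_max"]
        ]
        if not matches:
            out.append("unclassified")
        elif len(matches) == 1:
            out.append(names[matches[0]])
        else:
            dists = [
                ((t - centers[k][0]) / t_scale) ** 2
                + ((s - centers[k][1]) / s_scale) ** 2
                for k in matches
            ]
            out.append(names[matches[int(np.argmin(dists))]])
    return out
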