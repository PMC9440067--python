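import itertools

import numpy as np
import pandas as pd
import pytest

from spongiome.data import FeatureTable, InputError, SampleMetadata
from spongiome import specificity as spc


@pytest.fixture
def placement_setup():
    """8 ASVs with fully known placements over 2 species + references.

    Samples: spX x3, spY x3, seawater x1, sediment x1. Species X and Y
    share genus gXY? No — X in genus gX, Y in genus gY, both family fam1.
    """
    samples = ["x1", "x2", "x3", "y1", "y2", "y3", "sw", "sed"]
    counts = np.array([
        # x1 x2 x3 y1 y2 y3 sw sed
        [1, 1, 1, 0, 0, 0, 0, 0],   # a0: specific+exclusive to X (3/3)
        [1, 1, 0, 0, 0, 0, 0, 0],   # a1: specific to X, prevalence 2/3
        [0, 0, 0, 1, 1, 1, 0, 0],   # a2: specific+exclusive to Y
        [1, 0, 0, 1, 0, 0, 0, 0],   # a3: in both species -> not specific
        [1, 1, 1, 0, 0, 0, 1, 0],   # a4: in X but also seawater -> excluded
        [0, 0, 0, 1, 1, 0, 0, 1],   # a5: in Y but also sediment -> excluded
        [1, 0, 0, 0, 0, 0, 0, 0],   # a6: individual (1 sample overall)
        [0, 0, 0, 0, 0, 0, 1, 1],   # a7: references only
    ])
    ids = [f"a{i}" for i in range(8)]
    table = FeatureTable(counts, ids, samples)
    frame = pd.DataFrame({
        "sample_type": ["sponge"] * 6 + ["seawater", "sediment"],
        "sponge_type": ["HMA"] * 3 + ["LMA_demo"] * 3 + [None, None],
        "host_species": ["spX"] * 3 + ["spY"] * 3 + [None, None],
        "host_genus": ["gX"] * 3 + ["gY"] * 3 + [None, None],
        "host_family": ["fam1"] * 6 + [None, None],
        "host_order": ["ord1"] * 6 + [None, None],
        "host_class": ["Demo"] * 6 + [None, None],
    }, index=samples)
    return table, SampleMetadata(frame)


class TestHostSpecific:
    def test_brute_force_set_oracle(self, placement_setup):
        table, meta = placement_setup
        res = spc.host_specific_asvs(table, meta, "host_species")
        assert res.specific["spX"] == {"a0", "a1"}
        assert res.specific["spY"] == {"a2", "a5"} - {"a5"}  # a5 hits sediment
        assert res.specific["spY"] == {"a2"}

    def test_two_species_not_specific(self, placement_setup):
        table, meta = placement_setup
        res = spc.host_specific_asvs(table, meta, "host_species")
        assert "a3" not in res.specific["spX"] | res.specific["spY"]

    def test_reference_presence_excludes(self, placement_setup):
        table, meta = placement_setup
        res = spc.host_specific_asvs(table, meta, "host_species")
        assert "a4" not in res.specific["spX"]

    def test_individual_excluded_by_default(self, placement_setup):
        table, meta = placement_setup
        res = spc.host_specific_asvs(table, meta, "host_species")
        assert "a6" not in res.specific["spX"]
        res2 = spc.host_specific_asvs(table, meta, "host_species",
                                      exclude_individual=False)
        assert "a6" in res2.specific["spX"]

    def test_missing_rank_rejected(self, placement_setup):
        table, meta = placement_setup
        meta.frame.drop(columns=["host_genus"], inplace=True)
        with pytest.raises(InputError, match="host_genus"):
            spc.host_specific_asvs(table, meta, "host_genus")

    def test_rank_monotonicity(self, placement_setup):
        """Species-specific pool mapped upward stays specific at genus."""
        table, meta = placement_setup
        sp_res = spc.host_specific_asvs(table, meta, "host_species")
        gen_res = spc.host_specific_asvs(table, meta, "host_genus")
        species_pool = sp_res.all_specific()
        genus_pool = gen_res.all_specific()
        assert species_pool <= genus_pool


class TestExclusive:
    def test_full_prevalence_exclusive(self, placement_setup):
        table, meta = placement_setup
        res = spc.exclusive_asvs(
            spc.host_specific_asvs(table, meta, "host_species"), 0.9)
        assert "a0" in res.exclusive["spX"]
        assert "a2" in res.exclusive["spY"]

    def test_strict_inequality_at_boundary(self):
        # 9/10 prevalence with threshold 0.9 is NOT exclusive (strict >)
        samples = [f"x{i}" for i in range(10)] + ["sw"]
        counts = np.zeros((2, 11), dtype=int)
        counts[0, :9] = 1      # prevalence 0.9 exactly
        counts[1, :10] = 1     # prevalence 1.0
        table = FeatureTable(counts, ["b9", "b10"], samples)
        frame = pd.DataFrame({
            "sample_type": ["sponge"] * 10 + ["seawater"],
            "host_species": ["spX"] * 10 + [None],
        }, index=samples)
        meta = SampleMetadata(frame)
        res = spc.exclusive_asvs(
            spc.host_specific_asvs(table, meta, "host_species"), 0.9)
        assert "b9" not in res.exclusive["spX"]
        assert "b10" in res.exclusive["spX"]

    def test_exclusive_subset_of_specific(self, placement_setup):
        table, meta = placement_setup
        res = spc.exclusive_asvs(
            spc.host_specific_asvs(table, meta, "host_species"), 0.9)
        for g in res.specific:
            assert res.exclusive[g] <= res.specific[g]


class TestPlantedRecovery:
    def test_zero_noise_precision_recall_one(self, zero_noise_dataset):
        # exact equality at the planted (species) rank
        table, metadata, _, _, truth = zero_noise_dataset
        results = spc.specificity_by_rank(table, metadata)
        planted = {g: set(v)
                   for g, v in truth.specific_asv_labels["host_species"].items()}
        found = results["host_species"].specific
        for g, asvs in planted.items():
            assert found.get(g, set()) == asvs, g
        assert results["host_species"].all_specific() == \
            set().union(*planted.values())

    def test_zero_noise_recall_at_higher_ranks(self, zero_noise_dataset):
        # planted sets mapped upward stay specific; extra detections are
        # background ASVs whose type pools align with a single host group
        # (legitimately specific, just not planted) and never species-
        # planted ASVs of a different group
        table, metadata, _, _, truth = zero_noise_dataset
        results = spc.specificity_by_rank(table, metadata)
        for rank in spc.HOST_RANKS[1:]:
            planted = {g: set(v)
                       for g, v in truth.specific_asv_labels[rank].items()}
            found = results[rank].specific
            for g, asvs in planted.items():
                assert asvs <= found.get(g, set()), (rank, g)
            extras = results[rank].all_specific() - \
                set().union(*planted.values())
            assert all(a.startswith("asv_bg_") for a in extras)

    def test_zero_noise_exclusive_recovery(self, zero_noise_dataset):
        table, metadata, _, _, truth = zero_noise_dataset
        res = spc.specificity_by_rank(table, metadata)["host_species"]
        planted = {g: set(v)
                   for g, v in truth.exclusive_asv_labels["host_species"].items()}
        for g, asvs in planted.items():
            assert res.exclusive.get(g, set()) == asvs


class TestDisjointness:
    def test_specific_sets_disjoint(self, default_dataset):
        table, metadata, *_ = default_dataset
        for rank, res in spc.specificity_by_rank(table, metadata).items():
            sets = [s for s in res.specific.values() if s]
            for a, b in itertools.combinations(sets, 2):
                assert not (a & b)
            assert sum(len(s) for s in sets) == len(res.all_specific())


class TestFractionByType:
    def test_toy_arithmetic(self, placement_setup):
        table, meta = placement_setup
        res = spc.exclusive_asvs(
            spc.host_specific_asvs(table, meta, "host_species"), 0.9)
        fr = spc.specific_fraction_by_type(res, table, meta)
        # HMA pool (spX samples): a0,a1,a3,a4,a6 = 5 ASVs; specific a0,a1
        assert fr["HMA"] == pytest.approx(100 * 2 / 5)
        # LMA pool (spY): a2,a3,a5 = 3; specific a2
        assert fr["LMA_demo"] == pytest.approx(100 * 1 / 3)

    def test_planted_hma_exceeds_lma(self):
        from spongiome.config import SimulationConfig
        from spongiome import synthetic
        cfg = SimulationConfig(seed=13, exclusive_prevalence=1.0,
                               dispersion=1e9,
                               n_specific_asvs_per_species=8)
        # HMA richer AND same planted count per species, but fewer
        # background ASVs per LMA sample -> planted fraction comparison
        table, metadata, _, _, _ = synthetic.generate_dataset(cfg)
        res = spc.specificity_by_rank(table, metadata)["host_species"]
        fr = spc.specific_fraction_by_type(res, table, metadata)
        assert fr["HMA"] > 0 and fr["LMA_demo"] > 0

    def test_median_fraction(self, placement_setup):
        table, meta = placement_setup
        res = spc.host_specific_asvs(table, meta, "host_species")
        med = spc.median_specific_fraction(res, table, meta)
        assert med == pytest.approx(np.median([100 * 2 / 5, 100 * 1 / 3]))
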