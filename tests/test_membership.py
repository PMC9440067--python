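import numpy as np
import pandas as pd
import pytest

from spongiome.data import FeatureTable, InputError, SampleMetadata
from spongiome import membership as mem


class TestCoreBoundary:
    def test_paper_arithmetic_931(self):
        # 70% of 931 sponge samples: boundary occurrence 652, variable 2-651
        assert mem.core_boundary(931, 0.7) == 652

    def test_variable_upper_bound(self):
        assert mem.core_boundary(931, 0.7) - 1 == 651

    def test_exact_boundary_is_variable(self):
        # occurrence == floor(0.7 N) is NOT core (strict "more than 70%")
        n = 10
        counts = np.zeros((1, n), dtype=int)
        counts[0, :7] = 1  # occurrence 7 = 0.7*10 exactly
        t = FeatureTable(counts, ["f"], [f"s{i}" for i in range(n)])
        res = mem.classify_membership(t, 0.7)
        assert res.loc["f", "category"] == "variable"
        counts[0, 7] = 1  # occurrence 8 > 7
        t = FeatureTable(counts, ["f"], [f"s{i}" for i in range(n)])
        assert mem.classify_membership(t, 0.7).loc["f", "category"] == "core"


class TestClassifyMembership:
    def test_single_occurrence_individual(self):
        counts = np.array([[1, 0, 0], [1, 1, 1]])
        t = FeatureTable(counts, ["f1", "f2"], ["a", "b", "c"])
        res = mem.classify_membership(t, 0.7)
        assert res.loc["f1", "category"] == "individual"
        assert res.loc["f2", "category"] == "core"

    def test_brute_force_occupancy_oracle(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 3, size=(20, 10))
        ids = [f"f{i}" for i in range(20)]
        t = FeatureTable(counts, ids, [f"s{i}" for i in range(10)])
        res = mem.classify_membership(t, 0.7)
        boundary = int(np.floor(0.7 * 10)) + 1
        for i, fid in enumerate(ids):
            occ = int((counts[i] > 0).sum())
            if occ == 0:
                assert fid not in res.index
                continue
            expect = ("individual" if occ == 1
                      else "core" if occ >= boundary else "variable")
            assert res.loc[fid, "category"] == expect
            assert res.loc[fid, "occurrence"] == occ

    def test_categories_partition(self, default_dataset):
        table, metadata, *_ = default_dataset
        sub = table.select_samples(metadata.sponge_samples())
        res = mem.classify_membership(sub, 0.7)
        observed = (sub.counts.sum(axis=1) > 0).sum()
        assert len(res) == observed
        assert set(res["category"]) <= set(mem.MEMBERSHIP_CATEGORIES)

    def test_empty_table_rejected(self):
        t = FeatureTable(np.zeros((0, 0), int), [], [])
        with pytest.raises(InputError):
            mem.classify_membership(t)

    def test_planted_core_recovery(self, zero_noise_dataset):
        table, metadata, _, _, truth = zero_noise_dataset
        sub = table.select_samples(metadata.sponge_samples())
        res = mem.classify_membership(sub, 0.7)
        found_core = set(res.index[res["category"] == "core"])
        truth_core = {f for f, c in truth.membership_labels.items() if c == "core"}
        assert found_core == truth_core
        # planted universal ASVs are recovered as core
        assert set(truth.core_asvs) <= found_core


class TestClusterFeatures:
    def test_identical_sequences_one_cluster(self):
        cl = mem.cluster_features({"a": "ACGT", "b": "ACGT"}, 0.5)
        assert len(set(cl.values())) == 1

    def test_hand_alignment_boundary(self):
        # ACGTACGT vs ACGTACGA: 7/8 = 0.875 identity
        seqs = {"a": "ACGTACGT", "b": "ACGTACGA"}
        assert len(set(mem.cluster_features(seqs, 0.87).values())) == 1
        assert len(set(mem.cluster_features(seqs, 0.90).values())) == 2

    def test_threshold_one_identity_clustering(self):
        seqs = {"a": "ACGT", "b": "ACGA", "c": "TTTT"}
        cl = mem.cluster_features(seqs, 1.0)
        assert len(set(cl.values())) == 3

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            mem.cluster_features({}, 0.9)

    def test_collapse_conserves_counts(self, toy_table):
        mapping = {"f1": "f1", "f2": "f1", "f3": "f3"}
        collapsed = mem.collapse_by_cluster(toy_table, mapping)
        assert np.array_equal(collapsed.sample_sums(), toy_table.sample_sums())
        assert collapsed.shape[0] == 2

    def test_coarser_thresholds_monotone_units(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        seqs = {}
        root = rng.integers(0, 4, size=40)
        for i in range(8):
            mut = root.copy()
            k = rng.integers(0, 8)
            pos = rng.choice(40, size=k, replace=False)
            mut[pos] = (mut[pos] + rng.integers(1, 4, size=k)) % 4
            seqs[f"q{i}"] = "".join(bases[mut])
        counts = rng.integers(0, 5, size=(8, 4))
        t = FeatureTable(counts, list(seqs), [f"s{i}" for i in range(4)])
        n_units = []
        for thr in (1.0, 0.97, 0.9, 0.8):
            if thr >= 1.0:
                n_units.append(len(seqs))
            else:
                cl = mem.cluster_features(seqs, thr)
                n_units.append(len(set(cl.values())))
        assert n_units == sorted(n_units, reverse=True)


class TestSampleTypeSharing:
    @pytest.fixture
    def sharing_setup(self):
        # 6 ASVs with known presence across 3 groups (2 samples each)
        counts = np.array([
            [1, 1, 1, 1, 1, 1],  # all groups
            [1, 0, 0, 0, 0, 0],  # only g1
            [0, 0, 1, 1, 0, 0],  # only g2
            [1, 0, 1, 0, 0, 0],  # g1+g2
            [0, 1, 0, 0, 1, 0],  # g1+g3
            [0, 0, 0, 0, 0, 0],  # absent
        ])
        t = FeatureTable(counts, [f"f{i}" for i in range(6)],
                         [f"s{i}" for i in range(6)])
        frame = pd.DataFrame(
            {"group": ["g1", "g1", "g2", "g2", "g3", "g3"]},
            index=[f"s{i}" for i in range(6)])
        return t, SampleMetadata(frame)

    def test_set_algebra_oracle(self, sharing_setup, caplog):
        t, meta = sharing_setup
        with caplog.at_level("WARNING"):
            s = mem.sample_type_sharing(t, meta, "group")
        assert s.per_feature_groups["f0"] == frozenset({"g1", "g2", "g3"})
        assert s.per_feature_groups["f1"] == frozenset({"g1"})
        assert "f5" not in s.per_feature_groups  # zero row excluded
        # 5 scored ASVs: f1, f2 single (2/5); f0 in all (1/5)
        assert s.fraction_single_group == pytest.approx(2 / 5)
        assert s.fraction_all_groups == pytest.approx(1 / 5)
        # pairwise shared (f0 counts everywhere): g1&g2 share f0, f3 -> 2/5
        assert s.pairwise_shared_fraction[("g1", "g2")] == pytest.approx(2 / 5)
        assert s.pairwise_shared_fraction[("g2", "g3")] == pytest.approx(1 / 5)

    def test_unmapped_sample_rejected(self, sharing_setup):
        t, meta = sharing_setup
        meta.frame.loc["s0", "group"] = None
        with pytest.raises(InputError, match="without a group"):
            mem.sample_type_sharing(t, meta, "group")


class TestAbundanceOccupancy:
    def test_positive_rho_on_two_features(self):
        counts = np.array([
            [50, 60, 40, 50],
            [1, 0, 0, 0],
            [10, 12, 9, 0],
        ])
        t = FeatureTable(counts, ["hi", "lo", "mid"], list("wxyz"))
        _, rho, p = mem.abundance_occupancy(t, n_permutations=99, seed=0)
        assert rho > 0

    def test_rank_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 20, size=(10, 6))
        t = FeatureTable(counts, [f"f{i}" for i in range(10)],
                         [f"s{i}" for i in range(6)])
        frame, rho, _ = mem.abundance_occupancy(t, n_permutations=99, seed=0)
        from scipy.stats import spearmanr
        keep = frame["occupancy"] > 0
        expect = spearmanr(frame.loc[keep, "mean_relative_abundance"],
                           frame.loc[keep, "occupancy"]).statistic
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_single_sample_group_null(self):
        t = FeatureTable(np.array([[3], [1]]), ["a", "b"], ["s"])
        _, rho, p = mem.abundance_occupancy(t)
        assert np.isnan(rho) and np.isnan(p)

    def test_independence_null_not_rejected(self):
        # abundance independent of occupancy by construction
        rng = np.random.default_rng(12)
        n_feat, n_samp = 30, 12
        occ = rng.integers(2, n_samp, size=n_feat)
        counts = np.zeros((n_feat, n_samp), dtype=int)
        for i in range(n_feat):
            cols = rng.choice(n_samp, size=occ[i], replace=False)
            # constant MEAN abundance: total reads independent of occupancy
            counts[i, cols] = max(1, round(600 / occ[i]))
        t = FeatureTable(counts, [f"f{i}" for i in range(n_feat)],
                         [f"s{i}" for i in range(n_samp)])
        _, rho, p = mem.abundance_occupancy(t, n_permutations=999, seed=3)
        assert p > 0.05 or abs(rho) < 0.3
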