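"""MGS profiling, sharing percentages and taxon aggregation."""

import numpy as np
import pandas as pd
import pytest

from mucoseq.mgs import (MGS, MGSSet, SampleMetadata, aggregate_taxa,
                         mgs_richness, profile_mgs, shared_mgs_percentage,
                         subject_sharing_percentage)
from mucoseq.quantify import AbundanceMatrix
from mucoseq.synth import generate_read_counts, generate_world
from mucoseq.workflow import world_pipeline

from conftest import small_config


_TAX = {"Bacteroides": ("Bacteroidetes", "Bacteroidia"),
        "Bifidobacterium": ("Actinobacteria", "Actinobacteria")}


def make_mgs(mgs_id, genes, centroids, genus="Bacteroides"):
    phylum, klass = _TAX[genus]
    return MGS(mgs_id, frozenset(genes), tuple(centroids),
               {"phylum": phylum, "class": klass,
                "genus": genus, "species": f"{genus} sp. {mgs_id}"})


@pytest.fixture
def toy_mgs_set():
    genes_a = [f"a{i}" for i in range(101)]
    genes_b = [f"b{i}" for i in range(101)]
    return MGSSet([
        make_mgs("M1", genes_a, genes_a[:4]),
        make_mgs("M2", genes_b, genes_b[:4], genus="Bifidobacterium"),
    ])


class TestMGSValidation:
    def test_small_cluster_rejected(self):
        with pytest.raises(ValueError, match="100"):
            make_mgs("M", [f"g{i}" for i in range(50)], ["g0"])

    def test_centroids_must_be_members(self):
        with pytest.raises(ValueError, match="centroid"):
            make_mgs("M", [f"g{i}" for i in range(101)], ["other"])

    def test_gene_in_two_mgs_rejected(self):
        genes = [f"g{i}" for i in range(101)]
        genes2 = [f"h{i}" for i in range(100)] + ["g0"]
        with pytest.raises(ValueError, match="multiple"):
            MGSSet([make_mgs("M1", genes, genes[:2]),
                    make_mgs("M2", genes2, genes2[:2])])


class TestProfileMGS:
    def test_constant_centroid_abundance(self, toy_mgs_set):
        df = pd.DataFrame(
            {"s": {g: 3.0 for g in [f"a{i}" for i in range(4)]}}).fillna(0.0)
        m = AbundanceMatrix(df)
        prof = profile_mgs(m, toy_mgs_set)
        assert prof.values.loc["M1", "s"] == pytest.approx(3.0)

    def test_half_zero_half_two_gives_one(self, toy_mgs_set):
        df = pd.DataFrame({"s": {"a0": 2.0, "a1": 2.0, "a2": 0.0, "a3": 0.0}})
        prof = profile_mgs(AbundanceMatrix(df), toy_mgs_set)
        assert prof.values.loc["M1", "s"] == pytest.approx(1.0)

    def test_missing_centroids_count_in_denominator(self, toy_mgs_set):
        df = pd.DataFrame({"s": {"a0": 4.0}})  # a1..a3 absent from matrix
        prof = profile_mgs(AbundanceMatrix(df), toy_mgs_set)
        assert prof.values.loc["M1", "s"] == pytest.approx(1.0)

    def test_matches_brute_force_mean(self, rng, toy_mgs_set):
        genes = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        df = pd.DataFrame(rng.random((8, 3)), index=genes,
                          columns=["s1", "s2", "s3"])
        prof = profile_mgs(AbundanceMatrix(df), toy_mgs_set)
        for m_id, pre in [("M1", "a"), ("M2", "b")]:
            expect = df.loc[[f"{pre}{i}" for i in range(4)]].mean(axis=0)
            np.testing.assert_allclose(prof.values.loc[m_id], expect)

    def test_linearity(self, rng, toy_mgs_set):
        genes = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        x = pd.DataFrame(rng.random((8, 2)), index=genes, columns=["s1", "s2"])
        y = pd.DataFrame(rng.random((8, 2)), index=genes, columns=["s1", "s2"])
        p_sum = profile_mgs(AbundanceMatrix(x + y), toy_mgs_set).values
        p_x = profile_mgs(AbundanceMatrix(x), toy_mgs_set).values
        p_y = profile_mgs(AbundanceMatrix(y), toy_mgs_set).values
        pd.testing.assert_frame_equal(p_sum, p_x + p_y)


def _meta(samples):
    return SampleMetadata(pd.DataFrame(samples).T)


class TestSharing:
    def setup_method(self):
        # 5 MGSs, two location groups with detection sets {1,2,3,4} / {3,4,5}
        df = pd.DataFrame(0.0, index=[f"M{i}" for i in range(1, 6)],
                          columns=["x1", "y1"])
        df.loc[["M1", "M2", "M3", "M4"], "x1"] = 1.0
        df.loc[["M3", "M4", "M5"], "y1"] = 1.0
        self.mat = AbundanceMatrix(df, feature_axis="mgs")
        self.meta = _meta({"x1": {"subject_id": "S1", "location": "TI"},
                           "y1": {"subject_id": "S1", "location": "TC"}})

    def test_hand_enumeration(self):
        assert shared_mgs_percentage(self.mat, self.meta, "TI", "TC",
                                     "jaccard") == pytest.approx(40.0)
        assert shared_mgs_percentage(self.mat, self.meta, "TI", "TC",
                                     "of_a") == pytest.approx(50.0)

    def test_identical_sets_100_disjoint_0(self):
        df = pd.DataFrame({"x1": {"M1": 1.0, "M2": 0.0},
                           "y1": {"M1": 0.0, "M2": 2.0}})
        mat = AbundanceMatrix(df, feature_axis="mgs")
        assert shared_mgs_percentage(mat, self.meta, "TI", "TC",
                                     "jaccard") == 0.0
        assert shared_mgs_percentage(self.mat, self.meta, "TI", "TI",
                                     "jaccard") == 100.0
        assert shared_mgs_percentage(self.mat, self.meta, "TI", "TI",
                                     "of_a") == 100.0

    def test_jaccard_symmetric_and_dominated_by_of_a(self):
        j_ab = shared_mgs_percentage(self.mat, self.meta, "TI", "TC", "jaccard")
        j_ba = shared_mgs_percentage(self.mat, self.meta, "TC", "TI", "jaccard")
        assert j_ab == j_ba
        assert shared_mgs_percentage(self.mat, self.meta, "TI", "TC",
                                     "of_a") >= j_ab


class TestSubjectSharing:
    def test_headline_thirty_percent_fixture(self):
        """10 MGSs across 5 subjects, 3 of them in >= 2 subjects -> 30%."""
        subjects = [f"S{i}" for i in range(1, 6)]
        samples = {f"{s}_TI": {"subject_id": s, "location": "TI"}
                   for s in subjects}
        df = pd.DataFrame(0.0, index=[f"M{i}" for i in range(10)],
                          columns=list(samples))
        for i in range(10):  # each MGS private to one subject...
            df.iloc[i, i % 5] = 1.0
        for i in range(3):   # ...except three, shared with a second subject
            df.iloc[i, (i + 1) % 5] = 1.0
        mat = AbundanceMatrix(df, feature_axis="mgs")
        assert subject_sharing_percentage(mat, _meta(samples),
                                          "biopsy") == pytest.approx(30.0)

    def test_all_shared_and_all_private(self):
        samples = {"S1_TI": {"subject_id": "S1", "location": "TI"},
                   "S2_TI": {"subject_id": "S2", "location": "TI"}}
        all_shared = AbundanceMatrix(
            pd.DataFrame(1.0, index=["M1", "M2"], columns=list(samples)),
            feature_axis="mgs")
        assert subject_sharing_percentage(all_shared, _meta(samples)) == 100.0
        private = AbundanceMatrix(
            pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["M1", "M2"],
                         columns=list(samples)), feature_axis="mgs")
        assert subject_sharing_percentage(private, _meta(samples)) == 0.0


class TestAggregation:
    def test_same_genus_sums(self, toy_mgs_set):
        df = pd.DataFrame({"s": {"M1": 0.2, "M2": 0.3}})
        mat = AbundanceMatrix(df, feature_axis="mgs")
        out = aggregate_taxa(mat, toy_mgs_set, "phylum")
        assert out.values.loc["Bacteroidetes", "s"] == pytest.approx(0.2)
        assert out.values.loc["Actinobacteria", "s"] == pytest.approx(0.3)

    def test_conserves_total_per_sample_at_every_rank(self, world_and_reads, rng):
        _, world, _ = world_and_reads
        df = pd.DataFrame(rng.random((len(world.mgs_set), 3)),
                          index=world.mgs_set.ids, columns=list("abc"))
        mat = AbundanceMatrix(df, feature_axis="mgs")
        for rank in ("phylum", "class", "genus", "species"):
            agg = aggregate_taxa(mat, world.mgs_set, rank)
            np.testing.assert_allclose(agg.values.sum(axis=0),
                                       df.sum(axis=0), atol=1e-9)

    def test_matches_groupby_oracle(self, world_and_reads, rng):
        _, world, _ = world_and_reads
        df = pd.DataFrame(rng.random((len(world.mgs_set), 2)),
                          index=world.mgs_set.ids, columns=["s1", "s2"])
        agg = aggregate_taxa(AbundanceMatrix(df, feature_axis="mgs"),
                             world.mgs_set, "genus")
        tax = world.mgs_set.taxonomy_table()["genus"]
        oracle = df.groupby(tax).sum()
        pd.testing.assert_frame_equal(agg.values.sort_index(),
                                      oracle.sort_index(), check_names=False)

    def test_unknown_rank_rejected(self, toy_mgs_set):
        mat = AbundanceMatrix(pd.DataFrame({"s": {"M1": 1.0, "M2": 1.0}}),
                              feature_axis="mgs")
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxa(mat, toy_mgs_set, "kingdom")


class TestGeneratorRecovery:
    def test_faecal_mgs_richness_exceeds_biopsy(self):
        """Deep faecal sampling vs shallow biopsies: faecal MGS richness must
        come out higher (qualitative depth-asymmetry recovery, 8 seeds)."""
        wins = 0
        for seed in range(8):
            cfg = small_config(seed=seed, n_mgs=12, depth_biopsy=40_000,
                               depth_faeces=60_000, n_subjects=3)
            world = generate_world(cfg)
            reads = generate_read_counts(world, cfg)
            res = world_pipeline(world, reads, seed=seed)
            rich = mgs_richness(res.mgs_profile, 0.0)
            loc = world.metadata.table["location"]
            fe = rich[loc[rich.index] == "FE"].median()
            bi = rich[loc[rich.index] != "FE"].median()
            wins += fe > bi
        assert wins >= 5

    def test_biopsy_mgs_mostly_detected_in_faeces(self, world_and_reads):
        """Nearly every MGS seen in a biopsy should also be seen in faeces
        (at most one exception), since faecal sampling is much deeper."""
        cfg, world, reads = world_and_reads
        res = world_pipeline(world, reads, seed=0)
        loc = world.metadata.table["location"]
        vals = res.mgs_profile.values
        biopsy_det = set(vals.index[(vals.loc[:, (loc != "FE").to_numpy()] > 0).any(axis=1)])
        faecal_det = set(vals.index[(vals.loc[:, (loc == "FE").to_numpy()] > 0).any(axis=1)])
        assert len(biopsy_det - faecal_det) <= 1
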