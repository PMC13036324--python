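"""Generators: determinism, planted truth, and degenerate configurations."""

import numpy as np
import pytest

from sedarch import synthetic_data as sd
from sedarch.exceptions import InvalidConfigError


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"ancient_fraction": 1.5},
        {"ancient_fraction": -0.1},
        {"ncm_m": 0.0},
        {"ncm_m": 1.5},
        {"ncm_N": 10},
        {"n_tips": 0},
        {"ddr_lambda": -1.0},
    ])
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(InvalidConfigError):
            sd.SimulationConfig(seed=0, **kwargs)

    def test_stream_independence(self):
        cfg = sd.SimulationConfig(seed=9)
        a = cfg.rng("tree").random(4)
        b = cfg.rng("ddr").random(4)
        assert not np.allclose(a, b)
        assert np.allclose(a, cfg.rng("tree").random(4))


class TestDeterminism:
    def test_tree_bytes_identical(self):
        trees = []
        for _ in range(2):
            tree, groups, truth = sd.gen_time_tree(sd.SimulationConfig(seed=5))
            trees.append((
                tree.as_string(schema="newick"),
                groups.to_csv(),
                truth["parent_age_ma"],
            ))
        assert trees[0] == trees[1]

    def test_mag_table_identical(self):
        a, _ = sd.gen_mag_table(sd.SimulationConfig(seed=5))
        b, _ = sd.gen_mag_table(sd.SimulationConfig(seed=5))
        assert a.to_csv() == b.to_csv()

    def test_seed_changes_output(self):
        a, _ = sd.gen_mag_table(sd.SimulationConfig(seed=5))
        b, _ = sd.gen_mag_table(sd.SimulationConfig(seed=6))
        assert a.to_csv() != b.to_csv()


class TestTimeTree:
    def test_min_tips_enforced(self):
        with pytest.raises(InvalidConfigError):
            sd.gen_time_tree(sd.SimulationConfig(seed=0, n_tips=2))

    def test_zero_fraction_no_ancient_parents(self):
        cfg = sd.SimulationConfig(seed=1, n_tips=40, ancient_fraction=0.0)
        _, _, truth = sd.gen_time_tree(cfg)
        assert max(truth["parent_age_ma"].values()) <= 541.0
        assert truth["planted_ancient"] == []

    def test_full_fraction_all_ancient(self):
        cfg = sd.SimulationConfig(seed=1, n_tips=40, ancient_fraction=1.0)
        _, _, truth = sd.gen_time_tree(cfg)
        assert min(truth["parent_age_ma"].values()) > 541.0

    def test_branch_lengths_nonnegative_and_binary(self):
        tree, _, _ = sd.gen_time_tree(sd.SimulationConfig(seed=2, n_tips=30))
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0
            if not node.is_leaf():
                assert len(node.child_nodes()) == 2

    def test_every_tip_has_habitat_group(self):
        tree, groups, _ = sd.gen_time_tree(sd.SimulationConfig(seed=3, n_tips=25))
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert set(groups["species_id"]) == labels
        assert set(groups["group"]) <= {"Sediment only", "Water only", "Shared"}


class TestMagTable:
    def test_planted_tier_counts_exact(self):
        mags, truth = sd.gen_mag_table(
            sd.SimulationConfig(seed=4), tier_counts=(10, 50, 40))
        assert truth["tier_counts"] == {"high": 10, "medium": 50, "fail": 40}
        assert len(mags) == 100

    def test_all_perfect_records_are_high(self):
        mags, _ = sd.gen_mag_table(
            sd.SimulationConfig(seed=4, n_mags=10), tier_counts=(10, 0, 0))
        assert (mags["completeness"] > 90).all()
        assert (mags["contamination"] < 5).all()
        assert mags["has_rrna_16s"].all()
        assert (mags["n_trna"] >= 18).all()

    def test_counts_must_sum(self):
        with pytest.raises(InvalidConfigError):
            sd.gen_mag_table(sd.SimulationConfig(seed=0), tier_counts=(1, 1, 1))


class TestDDRCommunity:
    def test_coordinates_valid(self):
        abund, geo, _ = sd.gen_ddr_community(sd.SimulationConfig(seed=6))
        assert geo["latitude"].between(-90, 90).all()
        assert geo["longitude"].between(-180, 180).all()
        assert (abund.to_numpy() >= 0).all()
        assert (abund.sum(axis=1) > 0).all()

    def test_min_samples_enforced(self):
        with pytest.raises(InvalidConfigError):
            sd.gen_ddr_community(sd.SimulationConfig(seed=0, n_samples=3))


class TestNCMData:
    def test_frequencies_in_unit_interval(self):
        table, _ = sd.gen_ncm_data(sd.SimulationConfig(seed=8))
        assert table["frequency"].between(0, 1).all()
        assert table["mean_abundance"].between(0, 1, inclusive="neither").all()

    def test_exact_mode_on_model_curve(self):
        from sedarch.community_ecology import sloan_frequency
        table, truth = sd.gen_ncm_data(sd.SimulationConfig(seed=8), exact=True)
        pred = sloan_frequency(table["mean_abundance"], truth["ncm_N"],
                               truth["ncm_m"], truth["detection_limit"])
        assert np.allclose(table["frequency"], pred)


class TestKOMatrix:
    def test_planted_enriched_ratio_by_construction(self):
        from sedarch import ko_enrichment as ko
        counts, sizes, labels, truth = sd.gen_ko_matrix(
            sd.SimulationConfig(seed=9))
        profiles = ko.normalize_profiles(counts, sizes, labels)
        background = profiles.drop(index=truth["excluded"])
        for ko_id in truth["enriched_kos"]:
            a_f = profiles.loc[truth["focal"], ko_id]
            r, label = ko.enrichment_ratio(a_f, background[ko_id])
            assert label == "enriched"
            # prevalent: present in > 30% of background ecosystems
            assert (background[ko_id] > 0).mean() > 0.30

    def test_singleton_planted(self):
        counts, sizes, labels, truth = sd.gen_ko_matrix(
            sd.SimulationConfig(seed=10))
        per_eco_presence = (
            counts.groupby(labels).sum()[truth["singleton_ko"]] > 0
        )
        assert per_eco_presence.sum() == 1

    def test_too_few_ecosystems_raise(self):
        with pytest.raises(InvalidConfigError):
            sd.gen_ko_matrix(sd.SimulationConfig(seed=0),
                             ecosystems=("only one",))


class TestBGCCatalog:
    def test_contig_lengths_at_least_5kb(self):
        records, _, _ = sd.gen_bgc_catalog(sd.SimulationConfig(seed=12))
        assert (records["contig_length"] >= 5000).all()
        assert (records["length"] >= 5000).all()

    def test_matched_bgcs_have_low_membership(self):
        records, _, truth = sd.gen_bgc_catalog(sd.SimulationConfig(seed=12))
        matched = records[records["bgc_id"].isin(truth["matched_bgcs"])]
        unmatched = records[~records["bgc_id"].isin(truth["matched_bgcs"])]
        assert (matched["membership"] <= 900).all()
        assert (unmatched["membership"].isna()
                | (unmatched["membership"] > 900)).all()

    def test_planted_novel_gcf_count(self):
        cfg = sd.SimulationConfig(seed=13, novel_bgc_fraction=0.5)
        records, _, truth = sd.gen_bgc_catalog(cfg)
        n_gcfs = records["gcf_id"].nunique()
        assert len(truth["novel_gcfs"]) == round(0.5 * n_gcfs)


class TestProbeGenomes:
    def test_shared_windows_present_in_offtargets(self):
        target, refs, truth = sd.gen_probe_genomes(sd.SimulationConfig(seed=14))
        seq = target["contig_1"]
        for start in truth["shared_starts"]:
            sub = seq[start:start + 30]
            rc = sub.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            for genus, contigs in refs.items():
                joined = "".join(contigs.values())
                assert sub in joined or rc in joined

    def test_unique_windows_absent_from_offtargets(self):
        target, refs, truth = sd.gen_probe_genomes(sd.SimulationConfig(seed=14))
        seq = target["contig_1"]
        joined = "".join(c for contigs in refs.values() for c in contigs.values())
        rc_joined = joined.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for wid in truth["unique_window_ids"][:20]:
            start = int(wid.split(":")[1])
            sub = seq[start:start + 30]
            assert sub not in joined and sub not in rc_joined
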