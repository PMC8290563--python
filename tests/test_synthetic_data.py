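"""Planted-structure recovery and determinism of the study generator."""

import dataclasses

import numpy as np
import pytest

from hmlnet.de_screen import filter_differential, read_de_table
from hmlnet.enrichment import enrich
from hmlnet.expression_stats import ddct, pearson
from hmlnet.network import build_network, degree_centrality
from hmlnet.proximity import pair_by_proximity
from hmlnet.synthetic_data import (
    SimulationConfig,
    make_ground_truth,
    simulate_ct_table,
    simulate_de_table,
    simulate_genome,
    simulate_phenotypes,
    simulate_ppi_and_sets,
    write_fixture_dir,
)


class TestConfig:
    def test_separability_invariant_enforced(self):
        with pytest.raises(ValueError, match="separable"):
            SimulationConfig(true_pair_max_gap=60_000, decoy_min_gap=50_000)

    def test_frac_de_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_de=1.5)


class TestGenome:
    def test_planted_pairs_recovered_and_nothing_else(self, small_config):
        mrnas, lncs, truth = simulate_genome(small_config)
        pairs = pair_by_proximity(mrnas, lncs, 50_000)
        assert {(p.mrna_id, p.lncrna_id) for p in pairs} == truth.true_pairs

    def test_no_lncrnas_yields_zero_pairs_downstream(self, small_config):
        config = dataclasses.replace(
            small_config, n_lncrnas=0, n_true_pairs=0, pair_names=()
        )
        mrnas, lncs, _ = simulate_genome(config)
        assert len(mrnas) == config.n_mrnas and len(lncs) == 0

    def test_features_non_overlapping_within_chrom(self, small_config):
        mrnas, lncs, _ = simulate_genome(small_config)
        by_chrom = {}
        for f in list(mrnas) + list(lncs):
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_genome_too_small_errors(self, small_config):
        config = dataclasses.replace(small_config, chrom_length=100_000)
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(config)

    def test_same_seed_byte_identical_files(self, small_config, tmp_path):
        p1, _ = write_fixture_dir(small_config, tmp_path / "a")
        p2, _ = write_fixture_dir(small_config, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_different_seed_differs(self, small_config, tmp_path):
        p1, _ = write_fixture_dir(small_config, tmp_path / "a")
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        p2, _ = write_fixture_dir(other, tmp_path / "b")
        assert p1["gtf"].read_bytes() != p2["gtf"].read_bytes()


class TestDETable:
    def test_planted_count_passes_threshold_exactly(self, small_config):
        truth = make_ground_truth(small_config)
        df = simulate_de_table(small_config, truth)
        kept = df[df["log2fc"].abs() > small_config.logfc_threshold]
        assert (kept["class"] == "mRNA").sum() == small_config.n_de_mrnas
        assert set(kept["feature_id"]) == truth.de_features

    def test_frac_de_zero_gives_empty_filter(self, small_config):
        config = dataclasses.replace(small_config, frac_de=0.0)
        truth = make_ground_truth(config)
        df = simulate_de_table(config, truth)
        assert (df["log2fc"].abs() > config.logfc_threshold).sum() == 0

    def test_planted_down_feature_is_negative(self, small_config):
        truth = make_ground_truth(small_config)
        df = simulate_de_table(small_config, truth).set_index("feature_id")
        assert df.loc["Cpt1b", "log2fc"] < 0
        assert df.loc["Gm44502", "log2fc"] < 0  # its lncRNA co-directional
        assert df.loc["Srebf1", "log2fc"] > 0

    def test_pvalues_rank_consistent_with_magnitude(self, small_config):
        truth = make_ground_truth(small_config)
        df = simulate_de_table(small_config, truth)
        order = df["log2fc"].abs().to_numpy().argsort()
        p_sorted = df["pvalue"].to_numpy()[order]
        assert np.all(np.diff(p_sorted) <= 1e-15)


class TestCTTable:
    def test_rho_one_gives_sample_r_one(self, small_config):
        config = dataclasses.replace(
            small_config,
            planted_rho={k: 1.0 for k in small_config.planted_rho},
        )
        truth = make_ground_truth(config)
        table = simulate_ct_table(config, truth)
        rel = ddct(table)
        sub = rel[rel["group"] == "HF-Sed"].pivot_table(
            index="sample", columns="target", values="delta_ct"
        )
        res = pearson(sub["Srebf1"], sub["Gm38501"])
        assert res.r == pytest.approx(1.0)

    def test_directions_match_preset_in_every_group(self, small_config):
        """Fold changes recover up/reversed/down planting at generous n."""
        sizes = {g: 30 for g in ("Ctrl", "HF-Sed", "HF-Exe", "Diabetic")}
        config = dataclasses.replace(small_config, group_sizes=sizes)
        truth = make_ground_truth(config)
        rel = ddct(simulate_ct_table(config, truth))
        means = rel.pivot_table(index="target", columns="group", values="fold")
        assayed = {
            t: d for t, d in truth.planted_directions.items() if t in means.index
        }
        assert len(assayed) == 3
        for target, direction in assayed.items():
            hf, ctrl, exe = (
                means.loc[target, "HF-Sed"],
                means.loc[target, "Ctrl"],
                means.loc[target, "HF-Exe"],
            )
            if direction == "up":
                assert hf > ctrl > exe * 0.999  # exercise reverses
            else:
                assert hf < ctrl < exe * 1.001

    def test_null_group_means_give_uniform_anova_p(self, small_config):
        from scipy.stats import kstest

        from hmlnet.expression_stats import group_anova

        mult = {g: 0.0 for g in ("Ctrl", "HF-Sed", "HF-Exe", "Diabetic")}
        pvals = []
        for seed in range(120):
            config = dataclasses.replace(
                small_config, seed=seed, group_effect_multipliers=mult
            )
            truth = make_ground_truth(config)
            rel = ddct(simulate_ct_table(config, truth))
            sub = rel[rel["target"] == "Srebf1"]
            groups = {g: s["fold"].tolist() for g, s in sub.groupby("group")}
            pvals.append(group_anova(groups).p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPpiAndSets:
    def test_planted_hub_attains_max_centrality(self, small_config):
        truth = make_ground_truth(small_config)
        simulate_de_table(small_config, truth)  # fills de_features
        edges, sets, _, _ = simulate_ppi_and_sets(small_config, truth)
        mrnas, lncs, _ = simulate_genome(small_config)
        pairs = pair_by_proximity(mrnas, lncs, 50_000)
        graph = build_network(edges, pairs, small_config.ppi_score_threshold)
        centrality = degree_centrality(graph)
        assert max(centrality, key=centrality.get) == truth.hub

    def test_planted_sets_are_the_enriched_ones(self, small_config):
        truth = make_ground_truth(small_config)
        de = simulate_de_table(small_config, truth)
        edges, sets, cats, annot = simulate_ppi_and_sets(small_config, truth)
        mrna_mask = de["class"] == "mRNA"
        universe = set(de.loc[mrna_mask, "feature_id"])
        query = set(
            de.loc[
                mrna_mask & (de["log2fc"].abs() > small_config.logfc_threshold),
                "feature_id",
            ]
        )
        results = enrich(query, sets, universe)
        sig = {r.set_id for r in results if r.p_adjusted < 0.05}
        assert truth.enriched_sets <= sig

    def test_null_odds_give_uniform_enrichment_p(self, small_config):
        pvals = []
        for seed in range(25):
            config = dataclasses.replace(
                small_config, seed=seed, enrichment_odds=1.0
            )
            truth = make_ground_truth(config)
            de = simulate_de_table(config, truth)
            _, sets, _, _ = simulate_ppi_and_sets(config, truth)
            mrna_mask = de["class"] == "mRNA"
            universe = set(de.loc[mrna_mask, "feature_id"])
            query = set(
                de.loc[
                    mrna_mask & (de["log2fc"].abs() > config.logfc_threshold),
                    "feature_id",
                ]
            )
            # background sets only: the funnel sets still seed pair genes
            results = enrich(query, sets, universe)
            pvals += [
                r.pvalue for r in results if r.set_id.startswith("pathway_")
            ]
        # discrete p-values are super-uniform; a one-sided KS guards against
        # anti-conservative behaviour
        from scipy.stats import ks_1samp, uniform

        res = ks_1samp(pvals, uniform.cdf, alternative="greater")
        assert res.pvalue > 0.01

    def test_funnel_counts_planted_exactly(self, small_config):
        truth = make_ground_truth(small_config)
        simulate_de_table(small_config, truth)
        _, sets, cats, annot = simulate_ppi_and_sets(small_config, truth)
        target = next(s for s in sets if s.set_id == "insulin_resistance")
        pair_mrnas = {m for m, _ in truth.true_pairs}
        assert len(target.members & pair_mrnas) == small_config.n_funnel_target
        assert sum(annot.values()) == len(truth.annotated_lncrnas)


class TestPhenotypes:
    def test_groups_and_columns_present(self, small_config):
        df = simulate_phenotypes(small_config)
        assert set(df["group"]) == set(small_config.group_sizes)
        assert {"fasting_glucose", "fasting_insulin", "glucose_120"} <= set(df.columns)

    def test_diseased_groups_have_higher_glucose(self, small_config):
        sizes = {g: 30 for g in ("Ctrl", "HF-Sed", "HF-Exe", "Diabetic")}
        config = dataclasses.replace(small_config, group_sizes=sizes)
        df = simulate_phenotypes(config)
        means = df.groupby("group")["fasting_glucose"].mean()
        assert means["HF-Sed"] > means["Ctrl"]
        assert means["Diabetic"] > means["HF-Sed"]


class TestFixtureFiles:
    def test_ground_truth_ids_exist_in_emitted_files(self, study_fixture):
        _, paths, truth = study_fixture
        de_ids = {r.feature_id for r in read_de_table(paths["de_table"])}
        for m, l in truth.true_pairs:
            assert m in de_ids and l in de_ids
        assert truth.de_features <= de_ids

    def test_ground_truth_round_trips_through_json(self, study_fixture):
        from hmlnet.synthetic_data import GroundTruth

        _, paths, truth = study_fixture
        back = GroundTruth.from_json(paths["ground_truth"])
        assert back.true_pairs == truth.true_pairs
        assert back.expected_shortlist == truth.expected_shortlist
        assert back.planted_rho == truth.planted_rho
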