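"""Generator contracts: mixes, determinism, planted structure, counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from erfkit.profiles import DIAGNOSTIC_COLUMNS, SUBGROUPS
from erfkit.synthetic import (ConfigurationError, GenerationError,
                              TruthConfig, apportion, generate_cds_pairs,
                              generate_counts, generate_gene_models,
                              generate_go_annotations, generate_proteomes,
                              resolved_de_effects)


class TestConfigValidation:
    def test_zero_genes_rejected(self):
        with pytest.raises(ConfigurationError):
            TruthConfig(genes_per_species=0).validate()

    def test_mix_must_sum_to_one(self):
        cfg = TruthConfig(subfamily_mix={"ERF": 0.5, "DREB": 0.2})
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_mix_proportions_in_unit_interval(self):
        cfg = TruthConfig(subfamily_mix={"ERF": 1.2, "DREB": -0.2})
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_unknown_subgroup_rejected(self):
        with pytest.raises(ConfigurationError):
            TruthConfig(subgroup_mix={"Z9": 1.0}).validate()

    def test_negative_ks_target_rejected(self):
        with pytest.raises(ConfigurationError):
            TruthConfig(ks_targets=(-0.1,)).validate()

    def test_fractions_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            TruthConfig(species_specific_fraction=1.5).validate()


@settings(derandomize=True, max_examples=50)
@given(n=st.integers(1, 500),
       weights=st.lists(st.integers(1, 50), min_size=2, max_size=12))
def test_apportion_sums_and_stays_within_one_of_quota(n, weights):
    keys = SUBGROUPS[:len(weights)]
    total = sum(weights)
    mix = {k: w / total for k, w in zip(keys, weights)}
    counts = apportion(n, mix, order=keys)
    assert sum(counts.values()) == n
    for k in keys:
        assert abs(counts[k] - n * mix[k]) < 1.0


class TestProteomes:
    def test_degenerate_mix_all_erf_with_diagnostics(self):
        cfg = TruthConfig(n_species=1, genes_per_species=10,
                          background_genes=0, tandem_arrays=(),
                          subfamily_mix={"ERF": 1.0}, seed=0)
        ds = generate_proteomes(cfg)
        truth = ds.truth.family_genes()
        assert list(truth["subfamily"].unique()) == ["ERF"]
        assert len(truth) == 10
        planted = ds.truth.domains.set_index("gene")
        for gene, row in planted.iterrows():
            domain = ds.sequences["ca"][gene][row["start"] - 1:row["end"]]
            assert domain[13] == "A" and domain[18] == "D"

    def test_rav_proportion_gives_exact_ap2_b3_gene_count(self):
        cfg = TruthConfig(n_species=1, genes_per_species=50,
                          background_genes=0, tandem_arrays=(),
                          subfamily_mix={"RAV": 0.2, "ERF": 0.8}, seed=1)
        ds = generate_proteomes(cfg)
        hits = ds.hits["ca"]
        passing = hits[hits["evalue"].astype(float) <= 1e-5]
        by_gene = passing.groupby("protein")["accession"].agg(set)
        both = [g for g, accs in by_gene.items()
                if {"PF00847", "PF02362"} <= accs]
        assert len(both) == 10

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = TruthConfig(n_species=2, genes_per_species=30,
                          background_genes=10, tandem_arrays=(), seed=3)
        for sub in ("a", "b"):
            generate_proteomes(cfg).write(tmp_path / sub)
        for name in ("ca.proteins.fasta", "ca.domains.tsv",
                     "sl.proteins.fasta", "sl.domains.tsv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_species_specific_fraction_sets_truth_counts(self):
        cfg = TruthConfig(n_species=3, genes_per_species=100,
                          background_genes=0, tandem_arrays=(),
                          two_species_fraction=0.0,
                          species_specific_fraction=0.5, seed=4)
        truth = generate_proteomes(cfg).truth
        for sp in cfg.species_names:
            fam = truth.family_genes(sp)
            assert (fam["ortholog_group"] == "").sum() == 50

    def test_every_emitted_gene_unique_and_consistent(self, small_dataset):
        truth = small_dataset.truth
        truth.check_invariants()
        for sp in truth.config.species_names:
            assert set(truth.genes[truth.genes["species"] == sp]["gene"]) \
                == set(small_dataset.sequences[sp])

    def test_noise_spares_diagnostic_columns(self):
        cfg = TruthConfig(n_species=1, genes_per_species=40,
                          background_genes=0, tandem_arrays=(),
                          subfamily_mix={"ERF": 0.5, "DREB": 0.5},
                          domain_noise=0.05, seed=5)
        ds = generate_proteomes(cfg)
        planted = ds.truth.domains.merge(
            ds.truth.genes[["gene", "subgroup"]], on="gene")
        from erfkit.profiles import SUBGROUP_CONSENSUS
        for _, row in planted.iterrows():
            domain = ds.sequences["ca"][row["gene"]][row["start"] - 1:
                                                     row["end"]]
            consensus = SUBGROUP_CONSENSUS[row["subgroup"]]
            for col in DIAGNOSTIC_COLUMNS:
                assert domain[col - 1] == consensus[col - 1]


class TestGeneModels:
    def test_tandem_array_occupies_consecutive_ranks(self, small_dataset):
        truth = small_dataset.truth
        for array_id in ("ta1", "ta2"):
            members = truth.genes[truth.genes["tandem_array"] == array_id]
            assert len(members["chromosome"].unique()) == 1
            ranks = sorted(members["rank"])
            assert ranks == list(range(ranks[0], ranks[0] + len(ranks)))

    def test_full_collinearity_preserves_group_order_across_species(self):
        cfg = TruthConfig(n_species=3, genes_per_species=40,
                          background_genes=0, tandem_arrays=(),
                          species_specific_fraction=0.0,
                          two_species_fraction=0.0,
                          collinear_block_fraction=1.0, seed=6)
        truth = generate_proteomes(cfg).truth
        orders = {}
        for sp in cfg.species_names:
            fam = truth.family_genes(sp).sort_values(["chromosome", "rank"])
            orders[sp] = list(fam["ortholog_group"])
        assert orders["ca"] == orders["sl"] == orders["st"]

    def test_gene_models_match_truth_coordinates(self, small_dataset):
        cfg = small_dataset.config
        models = generate_gene_models(cfg, small_dataset.truth)
        for sp in cfg.species_names:
            table = models[sp]
            assert (table["start"] <= table["end"]).all()
            assert set(table["gene"]) == set(
                small_dataset.truth.genes[
                    small_dataset.truth.genes["species"] == sp]["gene"])

    def test_oversized_tandem_array_raises(self):
        cfg = TruthConfig(n_species=1, genes_per_species=20,
                          background_genes=0,
                          tandem_arrays=(("chr1", "B2", 15),), seed=0)
        with pytest.raises(ConfigurationError):
            generate_proteomes(cfg)


class TestCdsPairs:
    def test_target_zero_gives_identical_pair(self):
        cfg = TruthConfig(ks_targets=(0.0,), seed=0)
        ps = generate_cds_pairs(cfg, n_codons=60)
        row = ps.pairs.iloc[0]
        assert ps.sequences[row["gene1"]] == ps.sequences[row["gene2"]]

    def test_negative_target_raises(self):
        cfg = TruthConfig(ks_targets=(0.1,), seed=0)
        object.__setattr__(cfg, "ks_targets", (-0.2,))
        with pytest.raises(GenerationError):
            generate_cds_pairs(cfg, n_codons=60)

    def test_pairs_translate_without_stops(self):
        from Bio.Seq import Seq
        cfg = TruthConfig(ks_targets=(0.5, 2.0), seed=1)
        ps = generate_cds_pairs(cfg, n_codons=50, pairs_per_target=3)
        for seq in ps.sequences.values():
            assert "*" not in str(Seq(seq).translate())


class TestCounts:
    def test_planted_log2fc_shifts_condition_means(self):
        cfg = TruthConfig(n_species=1, genes_per_species=10,
                          background_genes=200, tandem_arrays=(),
                          de_effects=[("caAP2_1", "cold", 3.0)], seed=7)
        truth = generate_proteomes(cfg).truth
        cs = generate_counts(cfg, truth)
        cold = cs.design[cs.design["condition"] == "cold"]["sample"]
        ctrl = cs.design[cs.design["condition"] == "control"]["sample"]
        ratio = (cs.counts.loc["caAP2_1", list(cold)].mean()
                 / cs.counts.loc["caAP2_1", list(ctrl)].mean())
        assert 5.0 < ratio < 13.0  # planted 8x within sampling noise

    def test_single_replicate_rejected(self, small_dataset):
        cfg = TruthConfig(replicates=1)
        with pytest.raises(ConfigurationError):
            generate_counts(cfg, small_dataset.truth)

    def test_design_lists_condition_time_replicate(self, small_dataset):
        cfg = small_dataset.config
        cs = generate_counts(cfg, small_dataset.truth)
        assert set(cs.design.columns) == {"sample", "condition", "time",
                                          "replicate"}
        expected = (1 + len(cfg.conditions)) * len(cfg.time_points) \
            * cfg.replicates
        assert len(cs.design) == expected
        assert cs.counts.shape[1] == expected

    def test_auto_effects_shared_across_species_via_groups(self, small_dataset):
        cfg = small_dataset.config
        effects = resolved_de_effects(cfg, small_dataset.truth)
        assert effects, "default conditions should plant some effects"
        subjects = {e[0] for e in effects}
        assert any(s.startswith("og") for s in subjects)


class TestGoAnnotations:
    def test_enriched_term_covers_whole_subgroup(self, small_dataset):
        go = generate_go_annotations(small_dataset.truth)
        fam = small_dataset.truth.family_genes("ca")
        b2 = set(fam[fam["subgroup"] == "B2"]["gene"])
        annotated = set(go[go["go_id"] == "GO:0050794"]["gene"])
        assert annotated == b2

    def test_background_rate_matches_binomial_expectation(self, small_dataset):
        go = generate_go_annotations(small_dataset.truth,
                                     background_rate=0.1,
                                     n_background_terms=1)
        term = [t for t in go["go_id"].unique() if t != "GO:0050794"][0]
        n_genes = (small_dataset.truth.genes["species"] == "ca").sum()
        hits = (go["go_id"] == term).sum()
        sd = np.sqrt(n_genes * 0.1 * 0.9)
        assert abs(hits - 0.1 * n_genes) < 4 * sd

    def test_rerun_same_seed_identical(self, small_dataset):
        a = generate_go_annotations(small_dataset.truth)
        b = generate_go_annotations(small_dataset.truth)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_truth_rejected(self, small_dataset):
        from erfkit.synthetic import ConsistencyError, TruthTable
        empty = TruthTable(genes=small_dataset.truth.genes.iloc[:0],
                           domains=small_dataset.truth.domains.iloc[:0],
                           config=small_dataset.config)
        with pytest.raises(ConsistencyError):
            generate_go_annotations(empty)
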