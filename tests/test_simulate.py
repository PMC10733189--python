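"""Simulator: species trees, gene histories, sequences, genome bundles."""

import itertools
import random

import pytest

from photorep._seq import pairwise_identity, translate
from photorep.screening import count_tm_segments
from photorep.simulate import (
    DEFAULT_MOTIF_SLOTS,
    GenomeBundle,
    InvalidConfigError,
    InvalidTemplateError,
    SimConfig,
    emit_genome_bundle,
    emit_sequences,
    generate_family_template,
    quota_alleles,
    simulate_gene_family,
    simulate_species_tree,
    species_tree_newick,
    spliced_cds,
    simulate_bundle,
)


class TestSpeciesTree:
    def test_two_species_unique_topology(self):
        t = simulate_species_tree(SimConfig(seed=0, n_species=2))
        leaves = sorted(l.taxon.label for l in t.leaf_node_iter())
        assert leaves == ["A", "B"]
        h = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert h["A"] == pytest.approx(h["B"])
        assert h["A"] == pytest.approx(1.0)

    def test_seeded_runs_are_byte_identical(self):
        a = species_tree_newick(simulate_species_tree(SimConfig(seed=1, n_species=8)))
        b = species_tree_newick(simulate_species_tree(SimConfig(seed=1, n_species=8)))
        assert a == b

    def test_ultrametric_with_unique_labels(self):
        t = simulate_species_tree(SimConfig(seed=7, n_species=16))
        labels = [l.taxon.label for l in t.leaf_node_iter()]
        assert len(set(labels)) == 16
        for lf in t.leaf_node_iter():
            depth, nd = 0.0, lf
            while nd.parent_node is not None:
                depth += nd.edge.length
                nd = nd.parent_node
            assert depth == pytest.approx(1.0, abs=1e-9)

    def test_rejects_single_species(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(seed=0, n_species=1)


class TestGeneFamily:
    def test_no_events_gives_congruent_tree(self):
        t = simulate_species_tree(SimConfig(seed=1, n_species=4))
        h = simulate_gene_family(t, 0.0, 0.0, seed=5)
        assert sorted(h.leaf_species.values()) == ["A", "B", "C", "D"]
        assert sum(h.dup_raw.values()) == 0 and sum(h.loss_raw.values()) == 0
        assert all(v == 1 for v in h.copy_number.values())

    @pytest.mark.parametrize("seed", range(8))
    def test_pure_duplication_leaf_count(self, seed):
        # a duplication above k extant species adds k leaves; with no losses
        # the leaf count is the species count plus the weighted event count
        t = simulate_species_tree(SimConfig(seed=1, n_species=4))
        below = {}
        for nd in t.postorder_node_iter():
            below[nd.label] = 1 if nd.is_leaf() else sum(
                below[c.label] for c in nd.child_nodes())
        h = simulate_gene_family(t, 0.5, 0.0, seed=seed)
        expect = 4 + sum(c * below[b] for b, c in h.dup_raw.items())
        assert h.n_leaves == expect
        assert all(v >= 1 for v in h.copy_number.values())

    def test_pure_loss_prunes_species(self):
        t = simulate_species_tree(SimConfig(seed=1, n_species=8))
        h = simulate_gene_family(t, 0.0, 2.0, seed=7)
        assert sum(h.dup_raw.values()) == 0
        assert any(v == 0 for v in h.copy_number.values())
        assert sum(h.loss_raw.values()) >= 1
        # every loss event kills exactly one lineage; survivors + losses
        # account for every lineage the species tree would have produced
        assert sum(h.copy_number.values()) == h.n_leaves

    def test_leaf_names_encode_species(self):
        t = simulate_species_tree(SimConfig(seed=1, n_species=4))
        h = simulate_gene_family(t, 0.4, 0.1, seed=3)
        for name, sp in h.leaf_species.items():
            assert name.split("_g")[0] == sp

    def test_negative_rates_rejected(self):
        t = simulate_species_tree(SimConfig(seed=1, n_species=4))
        with pytest.raises(InvalidConfigError):
            simulate_gene_family(t, -0.1, 0.0, seed=1)

    def test_knockout_species_has_no_copies_and_a_loss(self):
        t = simulate_species_tree(SimConfig(seed=1, n_species=4))
        h = simulate_gene_family(t, 0.0, 0.0, seed=5, knockout_species=("B",))
        assert h.copy_number["B"] == 0
        assert h.loss_raw["B"] == 1


class TestSequences:
    def setup_method(self):
        self.config = SimConfig(seed=1, n_species=4)
        self.tree = simulate_species_tree(self.config)
        self.hist = simulate_gene_family(self.tree, 0.0, 0.0, seed=5)
        from photorep.simulate import _assign_ultrametric_lengths

        _assign_ultrametric_lengths(self.hist.gene_tree, 1.0)
        self.template = generate_family_template(42)

    def test_zero_rate_emits_template_everywhere(self):
        cfg = SimConfig(seed=1, n_species=4, subst_rate=0.0)
        seqs = emit_sequences(self.hist.gene_tree, self.template, cfg, seed=9)
        assert all(s == self.template for s in seqs.values())

    def test_degenerate_allele_distribution(self):
        seqs = emit_sequences(self.hist.gene_tree, self.template, self.config,
                              motif_alleles={"E/DRY": {"DRY": 1.0}}, seed=9)
        assert all(s[133:136] == "DRY" for s in seqs.values())

    def test_within_family_exceeds_between_family_identity(self):
        seqs = emit_sequences(self.hist.gene_tree, self.template, self.config, seed=9)
        within = [pairwise_identity(a, b)
                  for a, b in itertools.combinations(seqs.values(), 2)]
        other = emit_sequences(self.hist.gene_tree, generate_family_template(43),
                               self.config, seed=11)
        between = [pairwise_identity(a, b)
                   for a, b in itertools.product(list(seqs.values())[:3],
                                                 list(other.values())[:3])]
        assert min(within) > max(between)
        assert min(within) >= 0.6  # within-family floor

    def test_templates_keep_anchor_architecture(self):
        for seed in range(40, 46):
            t = generate_family_template(seed)
            assert len(t) == 348
            assert t[295] == "K"
            assert count_tm_segments(t) == 7

    def test_template_without_anchor_lysine_rejected(self):
        bad = self.template[:295] + "R" + self.template[296:]
        with pytest.raises(InvalidTemplateError):
            emit_sequences(self.hist.gene_tree, bad, self.config, seed=1)


class TestQuotaAlleles:
    def test_exact_counts_at_n20(self):
        out = quota_alleles({"DRF": 0.45, "DRY": 0.30, "DRC": 0.25}, 20, seed=3)
        assert len(out) == 20
        assert out.count("DRF") == 9 and out.count("DRY") == 6 and out.count("DRC") == 5

    def test_deterministic(self):
        a = quota_alleles({"A": 0.5, "B": 0.5}, 11, seed=4)
        assert a == quota_alleles({"A": 0.5, "B": 0.5}, 11, seed=4)


class TestGenomeBundle:
    def _bundle(self, **kw) -> tuple:
        cfg = SimConfig(seed=3, n_species=4, **kw)
        return cfg, simulate_bundle(cfg)

    def test_truth_round_trip_both_strands(self):
        _, b = self._bundle()
        strands = set()
        for g in b.genome.truth_for():
            scaf = b.genome.scaffolds[g.species][g.scaffold]
            assert translate(spliced_cds(scaf, g)).rstrip("*") == g.protein
            strands.add(g.strand)
        assert strands == {"+", "-"}  # both orientations exercised

    def test_all_pseudogenes_when_fraction_is_one(self):
        cfg = SimConfig(seed=4, n_species=2, pseudogene_fraction=1.0)
        b = simulate_bundle(cfg)
        k296 = DEFAULT_MOTIF_SLOTS["K296"][0]
        for g in b.genome.genes:
            assert g.status == "pseudogene"
            scaf = b.genome.scaffolds[g.species][g.scaffold]
            prot = translate(spliced_cds(scaf, g))
            disabled = "*" in prot.rstrip("*") or prot[k296 - 1] != "K"
            assert disabled

    def test_fragments_truncated(self):
        cfg = SimConfig(seed=4, n_species=2, fragment_fraction=1.0)
        b = simulate_bundle(cfg)
        for g in b.genome.genes:
            assert g.status == "fragment"
            assert len(g.protein) < 348 * 0.62

    def test_contaminants_on_short_scaffolds(self):
        cfg, b = self._bundle(contaminant_count=2)
        conts = [g for g in b.genome.genes if g.status == "contaminant"]
        assert len(conts) == 2
        for g in conts:
            scaf = b.genome.scaffolds[g.species][g.scaffold]
            assert len(scaf) < cfg.short_scaffold_threshold

    def test_seeded_outputs_byte_identical(self, tmp_path):
        from photorep.simulate import write_bundle

        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(simulate_bundle(SimConfig(seed=6, n_species=3)), d1)
        write_bundle(simulate_bundle(SimConfig(seed=6, n_species=3)), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_copy_numbers_match_gene_tree_leaves(self, small_bundle):
        for fam, h in small_bundle.histories.items():
            assert sum(h.copy_number.values()) == h.n_leaves
            if h.gene_tree is not None:
                assert len(list(h.gene_tree.leaf_node_iter())) == h.n_leaves
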