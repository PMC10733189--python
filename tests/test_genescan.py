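"""Gene prediction: six-frame translation, local hits, chaining, model recovery."""

import itertools
import random

import pytest

from photorep._seq import blosum62, revcomp
from photorep.genescan import (
    GenescanConfig,
    LocalHit,
    chain_hits,
    local_align,
    predict_gene_models,
    six_frame_translate,
)
from photorep.simulate import SimConfig, _place_gene, _random_dna


class TestSixFrame:
    def test_forward_frame_one(self):
        frames = six_frame_translate("s", "ATGGCC")
        fwd0 = next(f for f in frames if f.strand == "+" and f.frame == 0)
        assert fwd0.peptide == "MA"

    def test_ambiguous_codon_translates_to_x(self):
        frames = six_frame_translate("s", "ATGNTT")
        fwd0 = next(f for f in frames if f.strand == "+" and f.frame == 0)
        assert fwd0.peptide == "MX"

    def test_reverse_complement_symmetry(self):
        seq = _random_dna(random.Random(1), 300)
        a = sorted(f.peptide for f in six_frame_translate("s", seq))
        b = sorted(f.peptide for f in six_frame_translate("s", revcomp(seq)))
        assert a == b

    def test_empty_scaffold(self):
        assert six_frame_translate("s", "") == []

    def test_coordinate_map_round_trip(self):
        seq = _random_dna(random.Random(2), 99)
        for f in six_frame_translate("s", seq):
            c0, c1 = f.pep_to_coding(2, 5)
            assert (c1 - c0) == 9
            g0, g1 = f.coding_to_genomic(c0, c1)
            assert 0 <= g0 < g1 <= len(seq)


class TestLocalAlign:
    def test_exact_exon_scores_sum_of_diagonal(self):
        rng = random.Random(3)
        query = "".join(rng.choice("ACDEFGHIKLMNPQRSTWYV") for _ in range(60))
        scaffold = _random_dna(rng, 300) + "".join(
            {"A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
             "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
             "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
             "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC"}[a]
            for a in query) + _random_dna(rng, 300)
        m = blosum62()
        expected = sum(float(m[a, a]) for a in query)
        hits = []
        for f in six_frame_translate("s", scaffold):
            hits += local_align("q", query, f)
        best = max(hits, key=lambda h: h.score)
        assert best.score == pytest.approx(expected)
        assert best.q_span == (0, 60)

    def test_disjoint_alphabets_give_no_hits(self):
        frames = six_frame_translate("s", "GGA" * 200)
        for f in frames:
            assert local_align("q", "W" * 80, f) == []


def _mk_hit(q0, q1, c0, c1, score):
    return LocalHit("q", "s", "+", 0, (q0, q1), (c0, c1), score)


class TestChaining:
    def test_dp_matches_brute_force(self):
        rng = random.Random(11)
        for _ in range(30):
            hits = []
            for _ in range(rng.randint(2, 8)):
                q0 = rng.randrange(0, 300)
                c0 = rng.randrange(0, 5000)
                hits.append(_mk_hit(q0, q0 + rng.randint(10, 80),
                                    c0, c0 + rng.randint(30, 240),
                                    rng.randint(40, 400)))
            chain, score = chain_hits(hits, max_intron=2000, max_query_overlap=0)
            best = 0.0
            for r in range(1, len(hits) + 1):
                for combo in itertools.permutations(hits, r):
                    ok = all(a.q_span[1] <= b.q_span[0] and a.q_span[0] < b.q_span[0]
                             and a.c_span[1] <= b.c_span[0]
                             and b.c_span[0] - a.c_span[1] <= 2000
                             for a, b in zip(combo, combo[1:]))
                    if ok:
                        best = max(best, sum(h.score for h in combo))
            assert score == pytest.approx(best)

    def test_distant_hits_not_chained(self):
        a = _mk_hit(0, 50, 0, 150, 100)
        b = _mk_hit(50, 100, 150 + 30_000, 150 + 30_150, 100)
        chain, score = chain_hits([a, b], max_intron=20_000)
        assert len(chain) == 1


class TestModelRecovery:
    def _single_gene_scaffold(self, seed, strand=None, introns=(2, 2)):
        from photorep.simulate import TruthGene, generate_family_template

        cfg = SimConfig(seed=seed, n_species=2, intron_count_range=introns)
        rng = random.Random(seed)
        protein = generate_family_template(50 + seed)
        while True:
            scaf, tg = _place_gene(protein, rng, cfg, "scafX", "A", "fam", "g1")
            if strand is None or tg.strand == strand:
                return scaf, tg, protein

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_multi_exon_gene_recovered_exactly(self, strand, small_bundle):
        scaf, tg, protein = self._single_gene_scaffold(1, strand=strand)
        panel = {k: v for k, v in small_bundle.panel_records.items()
                 if "outgroup" not in k}
        panel["self"] = protein  # a perfect reference exists in the panel
        models = predict_gene_models({"scafX": scaf}, panel)
        assert len(models) == 1
        m = models[0]
        assert m.protein == protein
        assert m.strand == tg.strand
        assert sorted(tuple(e) for e in m.exons) == sorted(tuple(e) for e in tg.exons)
        assert m.has_start and m.has_stop and m.internal_stops == 0

    def test_homologous_query_recovers_exact_protein(self):
        # an ~90%-identical family member suffices for exact recovery
        from photorep.simulate import _mutate, generate_family_template

        scaf, tg, protein = self._single_gene_scaffold(2)
        query = _mutate(protein, 1.0, 0.1, random.Random(9))
        models = predict_gene_models({"scafX": scaf}, {"ref": query})
        assert len(models) == 1
        assert models[0].protein == protein

    def test_two_loci_far_apart_give_two_models(self):
        scaf1, tg1, p1 = self._single_gene_scaffold(3, strand="+")
        scaf2, tg2, p2 = self._single_gene_scaffold(4, strand="+")
        spacer = _random_dna(random.Random(0), 100_000)
        scaffold = scaf1 + spacer + scaf2
        models = predict_gene_models({"big": scaffold}, {"r1": p1, "r2": p2})
        assert len(models) == 2
        assert {m.protein for m in models} == {p1, p2}

    def test_fragment_flagged_incomplete(self):
        from photorep.simulate import TruthGene

        cfg = SimConfig(seed=5, n_species=2)
        rng = random.Random(5)
        from photorep.simulate import generate_family_template

        protein = generate_family_template(60)
        frag = protein[80:220]  # interior slice: no start, no stop
        scaf, tg = _place_gene(frag, rng, cfg, "s", "A", "fam", "g1",
                               status="fragment")
        # fragments are embedded without ATG/stop context
        models = predict_gene_models({"s": scaf}, {"ref": protein})
        assert models
        m = max(models, key=lambda m: m.score)
        assert not (m.has_start and m.has_stop)

    def test_strand_symmetry(self, small_bundle):
        sp = "A"
        scafs = dict(list(small_bundle.genome.scaffolds[sp].items())[:3])
        panel = small_bundle.panel_records
        fwd = predict_gene_models(scafs, panel)
        rc = predict_gene_models({k: revcomp(v) for k, v in scafs.items()}, panel)
        assert sorted(m.protein for m in fwd) == sorted(m.protein for m in rc)
        rc_by_prot = {m.protein: m for m in rc}
        for m in fwd:
            mm = rc_by_prot[m.protein]
            L = len(scafs[m.scaffold_id])
            mirrored = sorted((L - e, L - s) for s, e in mm.exons)
            assert sorted(tuple(e) for e in m.exons) == [tuple(x) for x in mirrored]

    def test_exons_within_scaffold_and_frame_complete(self, small_bundle):
        sp = "B"
        scafs = small_bundle.genome.scaffolds[sp]
        for m in predict_gene_models(scafs, small_bundle.panel_records):
            L = len(scafs[m.scaffold_id])
            for s, e in m.exons:
                assert 0 <= s < e <= L
            total = sum(e - s for s, e in m.exons)
            assert total % 3 == 0 or not m.has_stop
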