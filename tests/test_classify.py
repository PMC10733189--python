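"""Classification: joint alignment, neighbor joining, placement, contaminants."""

import random

import dendropy
import numpy as np
import pytest

from photorep.classify import (
    DegenerateInputError,
    Placement,
    ReferencePanel,
    assign_clade,
    build_tree,
    classify_queries,
    neighbor_joining,
    reference_guided_align,
)


class TestReferenceGuidedAlign:
    def test_panel_member_aligns_to_its_own_row(self, small_panel):
        rid = sorted(small_panel.records)[0]
        joint, kept = reference_guided_align({"q": small_panel.records[rid]},
                                             small_panel)
        assert joint["q"] == small_panel.master_alignment[rid]

    def test_query_insertion_is_dropped(self, small_panel):
        rid = sorted(small_panel.records)[0]
        seq = small_panel.records[rid]
        with_ins = seq[:100] + "W" * 10 + seq[100:]
        joint, _ = reference_guided_align({"q": with_ins}, small_panel)
        assert len(joint["q"]) == len(small_panel.master_alignment[rid])
        assert joint["q"] == small_panel.master_alignment[rid]

    def test_high_gap_columns_filtered(self):
        panel = ReferencePanel(
            records={"a": "ACDEF", "b": "ACDEF"},
            labels={"a": "x", "b": "x"}, outgroup_ids={"b"},
            master_alignment={"a": "ACDEF", "b": "ACDEF"})
        # seven queries leave column 0 gapped in 7/9 rows (~78% > 60%)
        queries = {f"q{i}": "CDEF" for i in range(7)}
        joint, kept = reference_guided_align(queries, panel)
        assert 0 not in kept
        assert all(c in kept for c in (1, 2, 3, 4))

    def test_invalid_alphabet_rejected(self, small_panel):
        from photorep.classify import InputError

        with pytest.raises(InputError):
            reference_guided_align({"q": "ACD1EF"}, small_panel)


class TestNeighborJoining:
    def test_recovers_additive_tree(self):
        true = dendropy.Tree.get(
            data="((A:1.0,B:2.0):1.0,(C:3.0,D:1.0):2.0,E:4.0);", schema="newick")
        pdm = true.phylogenetic_distance_matrix()
        names = sorted(t.label for t in true.taxon_namespace)
        n = len(names)
        D = np.zeros((n, n))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    D[i, j] = D[j, i] = pdm.distance(
                        true.taxon_namespace.get_taxon(a),
                        true.taxon_namespace.get_taxon(b))
        out = dendropy.Tree.get(data=neighbor_joining(D, names), schema="newick",
                                taxon_namespace=true.taxon_namespace)
        out.encode_bipartitions()
        true.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(true, out) == 0

    def test_matches_scikit_bio_on_random_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        n = 8
        M = rng.random((n, n)) * 2 + 0.5
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        names = [f"L{i}" for i in range(n)]
        tns = dendropy.TaxonNamespace()
        mine = dendropy.Tree.get(data=neighbor_joining(M, names),
                                 schema="newick", taxon_namespace=tns)
        theirs = dendropy.Tree.get(data=str(skbio_nj(DistanceMatrix(M, names))).strip(),
                                   schema="newick", taxon_namespace=tns)
        mine.encode_bipartitions()
        theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(mine, theirs) == 0

    def test_identical_sequences_are_zero_length_sisters(self):
        D = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 0.5], [1, 1, 0.5, 0]], dtype=float)
        nwk = neighbor_joining(D, ["a", "b", "c", "d"])
        assert "(a:0.000000,b:0.000000)" in nwk

    def test_too_few_sequences_rejected(self):
        with pytest.raises(DegenerateInputError):
            neighbor_joining(np.zeros((1, 1)), ["a"])


class TestBuildTree:
    def test_no_bootstrap_is_deterministic(self, small_panel):
        joint, kept = reference_guided_align({}, small_panel)
        t1 = build_tree(joint, kept, small_panel.outgroup_ids, n_bootstrap=0)
        t2 = build_tree(joint, kept, small_panel.outgroup_ids, n_bootstrap=0)
        s1 = t1.tree.as_string(schema="newick", unquoted_underscores=True)
        assert s1 == t2.tree.as_string(schema="newick", unquoted_underscores=True)
        assert all(v is None for v in t1.support.values())

    def test_bootstrap_supports_in_unit_interval(self, small_panel):
        joint, kept = reference_guided_align({}, small_panel)
        st = build_tree(joint, kept, small_panel.outgroup_ids,
                        n_bootstrap=20, seed=1)
        vals = [v for v in st.support.values() if v is not None]
        assert vals and all(0.0 <= v <= 1.0 for v in vals)

    def test_degenerate_input_rejected(self, small_panel):
        with pytest.raises(DegenerateInputError):
            build_tree({"a": "ACDEF", "b": "ACDEF"}, [0, 1, 2],
                       {"a"}, n_bootstrap=0)


class TestAssignClade:
    def test_family_member_assigned_with_support(self, small_bundle, small_panel):
        fam = "retinochrome"
        gid = sorted(small_bundle.proteins[fam])[0]
        queries = {"q1": small_bundle.proteins[fam][gid]}
        placements, _, _ = classify_queries(queries, small_panel,
                                            n_bootstrap=50, seed=4)
        p = placements[0]
        assert p.assigned_label == fam
        assert p.support is not None and p.support >= 0.7
        assert not p.is_contaminant

    def test_balanced_chimera_is_unclassified(self, small_bundle, small_panel):
        # alternate the two parents over exactly the positions where they
        # differ, so the chimera is equidistant from both families by
        # construction and its placement cannot be supported
        t1 = small_bundle.templates["retinochrome"]
        t2 = small_bundle.templates["xenopsin"]
        out, k = [], 0
        for a, b in zip(t1, t2):
            if a == b:
                out.append(a)
            else:
                out.append(a if k % 2 == 0 else b)
                k += 1
        mosaic = "".join(out)
        placements, _, _ = classify_queries({"q": mosaic}, small_panel,
                                            n_bootstrap=50, seed=4)
        assert placements[0].assigned_label == "unclassified"
        assert not placements[0].is_contaminant

    def test_short_scaffold_outgroup_neighbor_is_contaminant(self, small_bundle,
                                                             small_panel):
        cont = small_bundle.templates["contaminant"]
        placements, _, _ = classify_queries(
            {"q": cont}, small_panel, n_bootstrap=50, seed=4,
            short_scaffold_queries={"q"})
        p = placements[0]
        assert p.is_contaminant
        assert p.assigned_label == "unclassified"

    def test_long_scaffold_outgroup_neighbor_stays_unclassified(self, small_bundle,
                                                                small_panel):
        cont = small_bundle.templates["contaminant"]
        placements, _, _ = classify_queries({"q": cont}, small_panel,
                                            n_bootstrap=50, seed=4)
        assert placements[0].assigned_label == "unclassified"
        assert not placements[0].is_contaminant

    def test_missing_query_raises(self, small_panel):
        joint, kept = reference_guided_align({}, small_panel)
        st = build_tree(joint, kept, small_panel.outgroup_ids, n_bootstrap=0)
        with pytest.raises(KeyError):
            assign_clade(st, small_panel, "nope")

    def test_no_query_both_assigned_and_contaminant(self, small_bundle, small_panel):
        queries = {}
        for fam, d in small_bundle.proteins.items():
            for gid, prot in list(sorted(d.items()))[:1]:
                queries[f"{fam}__{gid}"] = prot
        queries["cont"] = small_bundle.templates["contaminant"]
        placements, _, _ = classify_queries(
            queries, small_panel, n_bootstrap=30, seed=2,
            short_scaffold_queries={"cont"})
        for p in placements:
            assert not (p.assigned_label != "unclassified" and p.is_contaminant)


class TestPanelProperties:
    def test_leave_one_out_self_assignment(self, small_bundle):
        # every held-out non-outgroup reference returns to its own clade
        records = dict(small_bundle.panel_records)
        labels = dict(small_bundle.panel_labels)
        outgroups = set(small_bundle.panel_outgroups)
        held = [r for r in sorted(records) if r not in outgroups]
        n_ok = 0
        for rid in held:
            rest = {k: v for k, v in records.items() if k != rid}
            panel = ReferencePanel.from_ungapped(
                rest, {k: labels[k] for k in rest}, outgroups)
            placements, _, _ = classify_queries({rid: records[rid]}, panel,
                                                n_bootstrap=25, seed=7)
            p = placements[0]
            if p.assigned_label == labels[rid] and (p.support or 0) >= 0.7:
                n_ok += 1
        assert n_ok / len(held) >= 0.95

    def test_stability_under_dilution(self, small_bundle, small_panel):
        fam = "neuropsin"
        gid = sorted(small_bundle.proteins[fam])[0]
        queries = {"q1": small_bundle.proteins[fam][gid]}
        before, _, _ = classify_queries(queries, small_panel, n_bootstrap=40, seed=3)
        assert before[0].support >= 0.9
        rng = random.Random(0)
        noise = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(348))
        after, _, _ = classify_queries({**queries, "noise": noise}, small_panel,
                                       n_bootstrap=40, seed=3)
        q_after = next(p for p in after if p.query_id == "q1")
        assert q_after.assigned_label == before[0].assigned_label
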