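"""Species x clade repertoire matrices, loss flags, and pipeline orchestration.

`build_matrix` aggregates placements into a dense copy-number matrix with
explicit zeros; unclassified and contaminant counts live in side columns
and never enter family totals.  `flag_losses` is a pure function of the
matrix (complete opsin loss, CRY-II-only repertoires, total photopigment
loss).  `run_all` chains the whole pipeline -- simulate, curate, scan,
screen, classify, reconcile, motif-profile, report -- deterministically
from one seed, and computes recovery metrics against the simulator truth.
"""

from __future__ import annotations

import hashlib
import json
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

SIDE_COLUMNS = ("unclassified", "contaminant")


class SpeciesError(ValueError):
    pass


def species_of(query_id: str, species_map: dict | None = None) -> str:
    if species_map and query_id in species_map:
        return species_map[query_id]
    if "_g" in query_id:
        return query_id.split("_g")[0]
    raise SpeciesError(f"cannot determine species for {query_id!r}")


def build_matrix(placements, species: list, labels: list,
                 species_map: dict | None = None, metadata: dict | None = None,
                 strict: bool = True) -> pd.DataFrame:
    """Dense species x clade copy-number matrix from placements.

    Assigned non-contaminant placements fill the label columns;
    unclassified and contaminant placements are tallied in side columns.
    Species without placements appear as all-zero rows.  Metadata columns
    (habitat, photic, eye_type) are joined when provided.
    """
    counts: Counter = Counter()
    for p in placements:
        sp = species_of(p.query_id, species_map)
        if sp not in species:
            if strict:
                raise SpeciesError(f"placement species {sp!r} not in species list")
            continue
        if p.is_contaminant:
            counts[(sp, "contaminant")] += 1
        elif p.assigned_label == "unclassified":
            counts[(sp, "unclassified")] += 1
        else:
            counts[(sp, p.assigned_label)] += 1

    cols = list(labels) + list(SIDE_COLUMNS)
    mat = pd.DataFrame(0, index=sorted(species), columns=cols, dtype=int)
    for (sp, lab), c in counts.items():
        if lab not in mat.columns:
            mat[lab] = 0
        mat.loc[sp, lab] = c
    mat["total"] = mat[list(labels)].sum(axis=1)
    if metadata:
        for col in ("habitat", "photic", "eye_type"):
            mat[col] = [metadata.get(sp, {}).get(col, "") for sp in mat.index]
    mat.index.name = "species"
    return mat


def default_loss_rules(opsin_labels, cry_labels=()):
    opsin_labels = list(opsin_labels)
    cry_labels = list(cry_labels)

    def opsinless(row):
        return all(row.get(c, 0) == 0 for c in opsin_labels)

    def cry_ii_only(row):
        others = [c for c in cry_labels if c != "CRY-II"]
        return bool(cry_labels) and row.get("CRY-II", 0) > 0 \
            and all(row.get(c, 0) == 0 for c in others)

    def photopigmentless(row):
        return all(row.get(c, 0) == 0 for c in opsin_labels + cry_labels)

    return {"opsinless": opsinless, "cry_II_only": cry_ii_only,
            "photopigmentless": photopigmentless}


def flag_losses(matrix: pd.DataFrame, rules: dict) -> pd.DataFrame:
    """Evaluate loss predicates per species; pure function of the matrix."""
    rows = []
    for sp, row in matrix.iterrows():
        d = row.to_dict()
        flags = sorted(name for name, rule in rules.items() if rule(d))
        rows.append({"species": sp, "flags": ";".join(flags)})
    return pd.DataFrame(rows, columns=["species", "flags"])


# ---------------------------------------------------------------------------
# orchestrated pipeline


@dataclass
class RunResult:
    bundle: object
    panel: object
    models: list
    screen_reports: list
    placements: list
    tree: object
    matrix: pd.DataFrame
    loss_report: pd.DataFrame
    reconciliations: list
    event_summary: pd.DataFrame
    motif_table: object
    metrics: dict
    manifest: dict = field(default_factory=dict)


def run_all(config, seed: int | None = None, outdir=None,
            n_bootstrap: int = 100) -> RunResult:
    """Simulate a bundle and run the full analysis pipeline on it.

    Deterministic given (config, seed).  Computes recovery metrics against
    the simulator's truth: exact-match gene-model recall/precision,
    classification accuracy at the support threshold, repertoire-matrix
    accuracy, and per-family reconciliation summaries.
    """
    from . import classify as _classify
    from . import genescan as _genescan
    from . import motifs as _motifs
    from . import reconcile as _reconcile
    from . import screening as _screening
    from .simulate import simulate_bundle

    if seed is not None:
        config = _with_seed(config, seed)
    bundle = simulate_bundle(config)
    family_names = sorted(h for h in bundle.histories)

    # --- curate: build panel object, calibrate the domain screen
    panel = _classify.ReferencePanel.from_ungapped(
        bundle.panel_records, bundle.panel_labels, bundle.panel_outgroups)
    rows = [panel.master_alignment[r] for r in sorted(panel.records)]
    profile = _screening.DomainProfile.from_alignment(rows, name="7tm_1 (PF00001.24)")
    floor = _screening.calibrate_domain_threshold(
        profile, n=200, seed=config.seed * 13 + 1, composition="".join(rows))
    threshold = _screening.gathering_threshold(profile, rows, null_floor=floor)
    fam_config = _screening.FamilyConfig(
        family_name="opsin", required_domains=[profile.name],
        domain_score_threshold=threshold)
    profiles = {profile.name: profile}

    # --- scan every genome
    models = []
    scan_cfg = _genescan.GenescanConfig()
    for sp in sorted(bundle.genome.scaffolds):
        models.extend(_genescan.predict_gene_models(
            bundle.genome.scaffolds[sp], bundle.panel_records, scan_cfg))

    # --- screen predicted models; the anchor-site check maps positions
    # through the panel consensus, which carries anchor numbering exactly
    # (per-query alignments to the distant anchor itself can wobble)
    consensus = _classify._consensus(panel.master_alignment)
    reports = _screening.screen_set(models, fam_config, profiles=profiles,
                                    anchor=consensus.replace("-", ""))
    passing = [m for m, r in zip(models, reports) if r.passed]

    # rename passing models to the reserved <species>_g<k> convention
    scaffold_species = bundle.genome.scaffold_species
    scaffold_len = {sid: len(s) for scafs in bundle.genome.scaffolds.values()
                    for sid, s in scafs.items()}
    per_species = Counter()
    queries, query_model, short_queries = {}, {}, set()
    for m in sorted(passing, key=lambda m: (m.scaffold_id, m.span)):
        sp = scaffold_species[m.scaffold_id]
        per_species[sp] += 1
        qid = f"{sp}_g{per_species[sp]}"
        queries[qid] = m.protein
        query_model[qid] = m
        if scaffold_len[m.scaffold_id] < config.short_scaffold_threshold:
            short_queries.add(qid)

    # --- classify
    placements, joint, stree = _classify.classify_queries(
        queries, panel, n_bootstrap=n_bootstrap, seed=config.seed * 17 + 3,
        short_scaffold_queries=short_queries)

    # --- reconcile: prune the placement tree per family
    recs = []
    for fam in family_names:
        members = [p.query_id for p in placements if p.assigned_label == fam]
        if len(members) < 2:
            continue
        sub = _extract_subtree(stree.tree, members)
        if sub is None:
            continue
        rec = _reconcile.lca_reconcile(sub, bundle.species_tree, family=fam)
        recs.append(rec)
    summary = _reconcile.summarize_families(recs)

    # --- motifs: read residues through the joint master alignment columns
    motif_defs = _motifs.default_motifs()
    extractions = {qid: _motifs.extract_motifs_from_row(joint[qid], panel.anchor_map,
                                                        motif_defs)
                   for qid in sorted(queries)}
    clade_of = {p.query_id: p.assigned_label for p in placements}
    motif_table = _motifs.motif_frequency_table(clade_of, extractions)

    # --- repertoire
    species = sorted(l.taxon.label for l in bundle.species_tree.leaf_node_iter())
    matrix = build_matrix(placements, species, family_names,
                          metadata=bundle.metadata)
    rules = default_loss_rules(family_names)
    loss_report = flag_losses(matrix, rules)

    metrics = _recovery_metrics(bundle, models, passing, placements,
                                queries, matrix, family_names)
    manifest = {
        "seed": config.seed,
        "n_species": config.n_species,
        "families": family_names,
        "n_bootstrap": n_bootstrap,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "n_models": len(models), "n_passing": len(passing),
    }
    result = RunResult(bundle, panel, models, reports, placements, stree, matrix,
                       loss_report, recs, summary, motif_table, metrics, manifest)
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _with_seed(config, seed: int):
    from dataclasses import replace

    return replace(config, seed=seed)


def _extract_subtree(tree, leaf_labels):
    """Induced rooted subtree on the given leaves (unifurcations suppressed)."""
    t = tree.extract_tree_with_taxa_labels(labels=set(leaf_labels))
    t.suppress_unifurcations()
    t.is_rooted = True
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    if len(leaves) != len(set(leaf_labels)):
        return None
    return t


def _recovery_metrics(bundle, models, passing, placements, queries,
                      matrix, family_names) -> dict:
    truth_clean = bundle.genome.truth_for(statuses=("clean",))
    truth_prot = Counter((g.species, g.protein) for g in truth_clean)
    truth_family = {}
    for g in truth_clean:
        truth_family[(g.species, g.protein)] = g.family

    contaminant_ids = {p.query_id for p in placements if p.is_contaminant}
    accepted = [(qid, prot) for qid, prot in queries.items()
                if qid not in contaminant_ids]
    pred_prot = Counter((qid.split("_g")[0], prot) for qid, prot in accepted)

    tp = sum(min(c, pred_prot.get(k, 0)) for k, c in truth_prot.items())
    recall = tp / sum(truth_prot.values()) if truth_prot else 1.0
    precision = tp / sum(pred_prot.values()) if pred_prot else 1.0

    label_of = {p.query_id: p for p in placements}
    n_eval = n_correct = 0
    for qid, prot in accepted:
        key = (qid.split("_g")[0], prot)
        fam = truth_family.get(key)
        if fam is None:
            continue
        n_eval += 1
        p = label_of[qid]
        if p.assigned_label == fam and (p.support or 0.0) >= 0.7:
            n_correct += 1
    class_acc = n_correct / n_eval if n_eval else 1.0

    truth_counts = {(sp, fam): 0 for sp in matrix.index for fam in family_names}
    for g in truth_clean:
        truth_counts[(g.species, g.family)] += 1
    cells = len(truth_counts)
    agree = sum(1 for (sp, fam), c in truth_counts.items()
                if matrix.loc[sp, fam] == c)
    matrix_acc = agree / cells if cells else 1.0
    matrix_exact = agree == cells

    return {"gene_model_recall": recall, "gene_model_precision": precision,
            "classification_accuracy": class_acc, "n_classified_eval": n_eval,
            "matrix_accuracy": matrix_acc, "matrix_exact": matrix_exact}


def _write_outputs(result: RunResult, outdir) -> None:
    from . import genescan as _genescan
    from ._seq import write_fasta
    from .simulate import write_bundle

    os.makedirs(outdir, exist_ok=True)
    j = lambda *p: os.path.join(outdir, *p)
    write_bundle(result.bundle, j("simulated"))
    _genescan.models_to_gff3(result.models, j("predicted_models.gff3"))
    write_fasta(j("predicted_proteins.fasta"),
                {m.model_id: m.protein for m in sorted(result.models,
                                                       key=lambda m: m.model_id)})
    pd.DataFrame([r.as_row() for r in result.screen_reports]).to_csv(
        j("screen_report.tsv"), sep="\t", index=False)
    pd.DataFrame([
        {"query_id": p.query_id, "label": p.assigned_label,
         "support": "" if p.support is None else round(p.support, 3),
         "is_contaminant": p.is_contaminant}
        for p in result.placements
    ]).to_csv(j("placements.tsv"), sep="\t", index=False)
    with open(j("classification_tree.nwk"), "w") as fh:
        fh.write(result.tree.tree.as_string(schema="newick", unquoted_underscores=True).strip() + "\n")
    result.matrix.to_csv(j("repertoire_matrix.tsv"), sep="\t")
    result.loss_report.to_csv(j("loss_report.tsv"), sep="\t", index=False)
    result.event_summary.to_csv(j("event_summary.tsv"), sep="\t", index=False)
    from .reconcile import branch_event_map

    branch_event_map(result.reconciliations).to_csv(
        j("branch_events.tsv"), sep="\t", index=False)
    result.motif_table.allele_counts.to_csv(j("motif_alleles.tsv"), sep="\t", index=False)
    result.motif_table.position_abundance.to_csv(
        j("motif_abundance.tsv"), sep="\t", index=False)
    with open(j("run_manifest.json"), "w") as fh:
        json.dump({**result.manifest, "metrics": result.metrics}, fh, indent=2,
                  sort_keys=True)
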