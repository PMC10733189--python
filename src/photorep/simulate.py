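"""Synthetic photopigment genome simulator.

Generates the full study substrate without any download: an ultrametric
species tree, per-family gene histories under duplication-loss regimes
("static" families stay near single copy, "dynamic" families expand
repeatedly), opsin-like protein sequences with seven hydrophobic
transmembrane segments, an anchor-position lysine (the K296 homolog in
bovine-rhodopsin numbering) and configurable motif alleles, and genome
scaffolds carrying multi-exon gene models plus fragment, pseudogene and
short-scaffold contaminant decoys, together with exact truth tables.

The model is a birth-death process inside the species tree: a single gene
copy enters the root, and along every species-tree branch each surviving
copy duplicates at rate lambda_d and is lost at rate lambda_l per unit
branch length.  Sequences evolve by residue substitution along the gene
tree; transmembrane positions substitute within a hydrophobic alphabet so
the 7-TM architecture is conserved, loop positions within a hydrophilic
alphabet, and motif slots plus the anchor lysine are protected.  Motif
alleles are assigned to leaves by seeded largest-remainder quotas so that
realised allele counts match the configured frequencies exactly.
"""

from __future__ import annotations

import math
import random
import zlib
from collections import Counter
from dataclasses import dataclass, field, replace

import dendropy

from ._seq import (
    KD,
    LOOP_ALPHABET,
    TM_ALPHABET,
    TM_KEEPABLE,
    anchor_record,
    back_translate,
    revcomp,
)

# Simulated transmembrane spans in anchor numbering, 1-based inclusive.  The
# layout is synthetic: segments are placed so that K296 and NPxxY fall inside
# TM7, E113 inside TM3 and E/DRY just past TM3 (as in the anchor), while
# every inter-segment loop is >= 20 residues so window-19 hydropathy cleanly
# resolves seven distinct segments.  TM7 is longer (30) and TM3 slightly
# longer (24) to offset their interior hydrophilic anchor sites.
TM_SPANS = ((19, 41), (62, 84), (110, 133), (156, 178), (201, 223), (245, 267), (288, 317))

# Motif slots in anchor numbering; these positions (plus the initiator M) are
# protected from substitution so motif alleles stay exactly where planted.
DEFAULT_MOTIF_SLOTS = {
    "K296": (296,),
    "E/DRY": (134, 135, 136),
    "NPxxY": (302, 303, 304, 305, 306),
    "EC_tripeptide": (280, 281, 282),
    "counterions": (113, 181),
}
PROTECTED_POSITIONS = (1,) + tuple(p for slots in DEFAULT_MOTIF_SLOTS.values() for p in slots)


class InvalidConfigError(ValueError):
    pass


class InvalidTemplateError(ValueError):
    pass


@dataclass
class FamilySpec:
    """One gene family: duplication-loss regime plus motif allele frequencies."""

    name: str
    regime: str = "static"
    dup_rate: float | None = None
    loss_rate: float | None = None
    # motif name -> {allele string: frequency}; omitted motifs keep the template allele
    motif_alleles: dict = field(default_factory=dict)


@dataclass
class SimConfig:
    seed: int = 0
    n_species: int = 16
    species_tree_height: float = 1.0
    dup_rate_static: float = 0.02
    dup_rate_dynamic: float = 0.5
    loss_rate: float = 0.1
    families: list = field(default_factory=list)
    subst_rate: float = 0.1  # substitutions per mutable site per unit branch length
    intron_count_range: tuple = (0, 3)
    intron_length_range: tuple = (90, 300)
    scaffold_margin: int = 800
    fragment_fraction: float = 0.0
    pseudogene_fraction: float = 0.0
    contaminant_count: int = 0
    contaminant_scaffold_length: int = 2000
    short_scaffold_threshold: int = 5000
    knockout_species: list = field(default_factory=list)
    n_refs_per_family: int = 4
    n_outgroup_refs: int = 4
    ref_divergence: float = 0.06

    def __post_init__(self):
        if self.n_species < 2:
            raise InvalidConfigError("n_species must be >= 2")
        for r in (self.dup_rate_static, self.dup_rate_dynamic, self.loss_rate, self.subst_rate):
            if r < 0:
                raise InvalidConfigError("rates must be >= 0")
        for f in (self.fragment_fraction, self.pseudogene_fraction):
            if not 0.0 <= f <= 1.0:
                raise InvalidConfigError("fractions must be in [0, 1]")
        if self.species_tree_height <= 0:
            raise InvalidConfigError("species_tree_height must be > 0")
        self.intron_count_range = tuple(self.intron_count_range)
        self.intron_length_range = tuple(self.intron_length_range)
        self.families = [
            FamilySpec(**f) if isinstance(f, dict) else f for f in self.families
        ]

    def rates_for(self, fam: FamilySpec) -> tuple[float, float]:
        dup = fam.dup_rate
        if dup is None:
            dup = self.dup_rate_dynamic if fam.regime == "dynamic" else self.dup_rate_static
        loss = fam.loss_rate if fam.loss_rate is not None else self.loss_rate
        return dup, loss


def default_families() -> list:
    """The seven-opsin-family fixture: five static, two dynamic families."""
    dry = {"E/DRY": {"DRY": 1.0}}
    return [
        FamilySpec("canonical_r_opsin", "static",
                   motif_alleles={"E/DRY": {"DRF": 0.45, "DRY": 0.30, "DRC": 0.25}}),
        FamilySpec("noncanonical_r_opsin", "static", motif_alleles=dict(dry)),
        FamilySpec("xenopsin", "dynamic", motif_alleles=dict(dry)),
        FamilySpec("peropsin", "static", motif_alleles=dict(dry)),
        FamilySpec("retinochrome", "static", motif_alleles=dict(dry)),
        FamilySpec("neuropsin", "static", motif_alleles=dict(dry)),
        FamilySpec("go_opsin", "dynamic", motif_alleles=dict(dry)),
    ]


def fixture_config(seed: int = 1) -> SimConfig:
    """The packaged end-to-end study fixture.

    Sixteen species, the seven opsin families (retinochrome-like static
    through xenopsin-like dynamic regimes), fragment/pseudogene decoys,
    short-scaffold contaminants, and one species (P) with every family
    deleted, emulating a deep-sea total photopigment loss.
    """
    return SimConfig(seed=seed, n_species=16, families=default_families(),
                     fragment_fraction=0.05, pseudogene_fraction=0.05,
                     contaminant_count=4, knockout_species=["P"])


# ---------------------------------------------------------------------------
# species tree


def species_names(n: int) -> list:
    if n <= 26:
        return [chr(ord("A") + i) for i in range(n)]
    return [f"S{i + 1:03d}" for i in range(n)]


def simulate_species_tree(config: SimConfig) -> dendropy.Tree:
    """Pure-birth (Yule) topology rescaled to a fixed ultrametric height.

    Internal nodes are labeled n1, n2, ... in preorder; these labels key the
    per-branch truth tables and the reconciliation event maps.
    """
    if config.n_species < 2:
        raise InvalidConfigError("n_species must be >= 2")
    rng = random.Random(config.seed * 7919 + 11)
    n = config.n_species
    root = {"split": 0.0, "children": []}
    tips = []
    for _ in range(2):
        child = {"children": [], "parent_split": 0.0}
        root["children"].append(child)
        tips.append(child)
    t = 0.0
    while len(tips) < n:
        t += rng.expovariate(len(tips))
        node = tips.pop(rng.randrange(len(tips)))
        node["split"] = t
        for _ in range(2):
            child = {"children": [], "parent_split": t}
            node["children"].append(child)
            tips.append(child)
    t_final = t + rng.expovariate(len(tips))
    names = species_names(n)
    order = list(range(n))
    rng.shuffle(order)
    for tip, k in zip(tips, order):
        tip["name"] = names[k]
        tip["split"] = t_final
    scale = config.species_tree_height / t_final

    tree = dendropy.Tree()
    tree.is_rooted = True

    def build(node, dnode):
        if node["children"]:
            for ch in node["children"]:
                d = dnode.new_child()
                d.edge.length = (ch["split"] - node["split"]) * scale
                build(ch, d)
        else:
            dnode.taxon = tree.taxon_namespace.new_taxon(label=node["name"])

    tree.seed_node.edge.length = 0.0
    build(root, tree.seed_node)

    counter = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.label = nd.taxon.label
        else:
            counter += 1
            nd.label = f"n{counter}"
    return tree


def species_tree_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True,
                          suppress_internal_node_labels=False).strip()


# ---------------------------------------------------------------------------
# gene family histories

_DUP, _SPEC, _LEAF, _LOST = "dup", "spec", "leaf", "lost"


class _GNode:
    __slots__ = ("kind", "branch", "children", "species", "extant")

    def __init__(self, kind, branch, children=(), species=None):
        self.kind = kind
        self.branch = branch          # label of species node at child end of branch
        self.children = list(children)
        self.species = species        # species leaf label for extant leaves
        self.extant = False


@dataclass
class GeneFamilyHistory:
    """Ground truth for one simulated gene family."""

    family: str
    gene_tree: dendropy.Tree | None   # pruned to survivors; None if extinct
    leaf_species: dict                # gene leaf name -> species name
    copy_number: dict                 # species -> surviving copy count
    dup_raw: Counter = field(default_factory=Counter)       # species branch -> count
    loss_raw: Counter = field(default_factory=Counter)
    dup_observable: Counter = field(default_factory=Counter)
    loss_observable: Counter = field(default_factory=Counter)
    any_dup_subtree_lost: bool = False

    @property
    def n_leaves(self):
        return len(self.leaf_species)


def simulate_gene_family(species_tree: dendropy.Tree, dup_rate: float, loss_rate: float,
                         seed: int, family: str = "fam",
                         knockout_species: tuple = ()) -> GeneFamilyHistory:
    """Birth-death gene evolution inside the species tree, with event truth.

    A single copy enters the species root.  Returns the pruned gene tree
    (leaves named ``<species>_g<k>``), raw per-branch duplication/loss
    counts, and the *observable* counts: a duplication is observable when
    both daughter copies leave extant descendants; each maximal extinct
    subtree hanging off a surviving speciation lineage contributes exactly
    one observable loss (on the species branch it entered), while losses
    below a fully lost duplication copy are invisible to reconciliation.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise InvalidConfigError("rates must be >= 0")
    rng = random.Random(seed)
    knockout = set(knockout_species)

    def evolve_branch(sp_node, t_left):
        total = dup_rate + loss_rate
        if total > 0:
            wait = rng.expovariate(total)
            if wait < t_left:
                if rng.random() < dup_rate / total:
                    left = evolve_branch(sp_node, t_left - wait)
                    right = evolve_branch(sp_node, t_left - wait)
                    return _GNode(_DUP, sp_node.label, [left, right])
                return _GNode(_LOST, sp_node.label)
        return arrive(sp_node)

    def arrive(sp_node):
        if sp_node.is_leaf():
            if sp_node.label in knockout:
                return _GNode(_LOST, sp_node.label)
            return _GNode(_LEAF, sp_node.label, species=sp_node.label)
        children = [evolve_branch(ch, ch.edge.length) for ch in sp_node.child_nodes()]
        return _GNode(_SPEC, sp_node.label, children)

    root = arrive(species_tree.seed_node)

    def mark(n):
        if n.kind == _LEAF:
            n.extant = True
        else:
            for c in n.children:
                mark(c)
            n.extant = any(c.extant for c in n.children)

    mark(root)

    hist = GeneFamilyHistory(family=family, gene_tree=None, leaf_species={}, copy_number={})
    hist.copy_number = {lf.taxon.label: 0 for lf in species_tree.leaf_node_iter()}

    # the visible root: first event node with survivors on more than one
    # child; losses attached above it are stem losses, invisible to a
    # reconciliation that maps the pruned gene-tree root by LCA
    vroot = root
    while vroot.extant:
        live = [c for c in vroot.children if c.extant]
        if len(live) != 1:
            break
        vroot = live[0]

    def walk(n, below_vroot):
        if n is vroot:
            below_vroot = True
        if n.kind == _DUP:
            hist.dup_raw[n.branch] += 1
            if all(c.extant for c in n.children):
                hist.dup_observable[n.branch] += 1
            else:
                hist.any_dup_subtree_lost = True
        elif n.kind == _LOST:
            hist.loss_raw[n.branch] += 1
        for c in n.children:
            if below_vroot and n.kind == _SPEC and n.extant and not c.extant:
                hist.loss_observable[c.branch] += 1
            walk(c, below_vroot)

    walk(root, False)

    counters = Counter()
    leaf_names = {}

    def prune(n):
        """Nested (name, children) spec of the surviving gene tree."""
        if n.kind == _LEAF:
            counters[n.species] += 1
            name = f"{n.species}_g{counters[n.species]}"
            leaf_names[name] = n.species
            return (name, [])
        live = [c for c in n.children if c.extant]
        if len(live) == 1:
            return prune(live[0])
        return (None, [prune(c) for c in live])

    if root.extant:
        spec = prune(root)
        tree = dendropy.Tree()
        tree.is_rooted = True

        def attach(node_spec, dnode):
            name, children = node_spec
            if not children:
                dnode.taxon = tree.taxon_namespace.new_taxon(label=name)
                dnode.label = name
            for ch in children:
                attach(ch, dnode.new_child())

        attach(spec, tree.seed_node)
        if len(leaf_names) >= 1:
            hist.gene_tree = tree
    hist.leaf_species = leaf_names
    for name, sp in leaf_names.items():
        hist.copy_number[sp] += 1
    return hist


def _assign_ultrametric_lengths(tree: dendropy.Tree, height: float) -> None:
    """Branch lengths such that every root-to-leaf path sums to ``height``."""
    depth = {}
    max_below = {}
    for nd in tree.preorder_node_iter():
        depth[nd] = 0 if nd.parent_node is None else depth[nd.parent_node] + 1
    for nd in tree.postorder_node_iter():
        max_below[nd] = depth[nd] if nd.is_leaf() else max(max_below[c] for c in nd.child_nodes())
    h = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd.edge.length = 0.0
            h[nd] = 0.0
        else:
            remaining = max_below[nd] - depth[nd] + 1
            step = (height - h[nd.parent_node]) / remaining
            nd.edge.length = step
            h[nd] = h[nd.parent_node] + step


# ---------------------------------------------------------------------------
# sequences


def generate_family_template(seed: int, p_tm: float = 0.55, p_loop: float = 0.75,
                             base: str | None = None) -> str:
    """Family founder sequence derived from the anchor.

    Loop positions are randomised into a hydrophilic alphabet with
    probability ``p_loop`` and transmembrane positions into a hydrophobic
    alphabet with probability ``p_tm``; motif slots, counterions, the
    initiator methionine and the K296 lysine keep the anchor residues, so
    every template aligns to anchor numbering without indels.
    """
    rng = random.Random(seed)
    if base is None:
        _, base = anchor_record()
    protected = set(PROTECTED_POSITIONS)
    tm_positions = _tm_position_set()
    out = []
    for pos1, aa in enumerate(base, start=1):
        if pos1 in protected:
            out.append(aa)
        elif pos1 in tm_positions:
            # retain the anchor residue only when it is itself strongly
            # hydrophobic; otherwise draw from the TM alphabet
            if rng.random() < p_tm or aa not in TM_KEEPABLE:
                out.append(rng.choice(TM_ALPHABET))
            else:
                out.append(aa)
        else:
            # loops stay strictly hydrophilic so segments never bridge
            if rng.random() < p_loop or KD[aa] > 0:
                out.append(rng.choice(LOOP_ALPHABET))
            else:
                out.append(aa)
    return "".join(out)


def _tm_position_set() -> frozenset:
    return frozenset(p for a, b in TM_SPANS for p in range(a, b + 1))


def _mutate(seq: str, t: float, rate: float, rng: random.Random) -> str:
    """Substitute mutable sites with probability 1-exp(-rate*t), class-preserving."""
    p = 1.0 - math.exp(-rate * t)
    if p <= 0:
        return seq
    protected = set(PROTECTED_POSITIONS)
    tm_positions = _tm_position_set()
    out = list(seq)
    for pos1 in range(1, len(seq) + 1):
        if pos1 in protected or rng.random() >= p:
            continue
        alphabet = TM_ALPHABET if pos1 in tm_positions else LOOP_ALPHABET
        cur = out[pos1 - 1]
        nxt = rng.choice(alphabet)
        while nxt == cur:
            nxt = rng.choice(alphabet)
        out[pos1 - 1] = nxt
    return "".join(out)


def quota_alleles(freqs: dict, n: int, seed: int) -> list:
    """Largest-remainder allele counts, seeded shuffle of the assignment order.

    Guarantees realised counts equal the configured frequencies as exactly
    as integers allow, e.g. {DRF: .45, DRY: .30, DRC: .25} at n=20 gives
    9/6/5 exactly.
    """
    items = sorted(freqs.items())
    quotas = [(name, n * f) for name, f in items]
    counts = {name: int(q) for name, q in quotas}
    short = n - sum(counts.values())
    by_rem = sorted(quotas, key=lambda kv: (-(kv[1] - int(kv[1])), kv[0]))
    for name, _ in by_rem[:short]:
        counts[name] += 1
    out = [name for name, c in sorted(counts.items()) for _ in range(c)]
    random.Random(seed).shuffle(out)
    return out


def emit_sequences(gene_tree: dendropy.Tree | None, template: str, config: SimConfig,
                   motif_alleles: dict | None = None, seed: int = 0,
                   leaf_names: tuple = ()) -> dict:
    """One protein per gene-tree leaf, evolved from the family template.

    Motif slots and the anchor lysine are protected during substitution;
    configured motif alleles are then written into the slots by quota
    assignment over the (sorted) leaves.
    """
    k_slot = DEFAULT_MOTIF_SLOTS["K296"][0]
    if len(template) < k_slot or template[k_slot - 1] != "K":
        raise InvalidTemplateError("template lacks the anchor-position lysine")
    rng = random.Random(seed)
    seqs = {}
    if gene_tree is not None:
        node_seq = {gene_tree.seed_node: template}
        for nd in gene_tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            parent = node_seq[nd.parent_node]
            node_seq[nd] = _mutate(parent, nd.edge.length or 0.0, config.subst_rate, rng)
            if nd.is_leaf():
                seqs[nd.taxon.label] = node_seq[nd]
    else:
        for name in leaf_names:
            seqs[name] = _mutate(template, config.species_tree_height, config.subst_rate, rng)

    if motif_alleles:
        names = sorted(seqs)
        for motif, freqs in sorted(motif_alleles.items()):
            slots = DEFAULT_MOTIF_SLOTS[motif]
            tag = zlib.crc32(motif.encode()) % 100003
            assignment = quota_alleles(freqs, len(names), seed * 31 + tag)
            for leaf, allele in zip(names, assignment):
                if len(allele) != len(slots):
                    raise InvalidConfigError(f"allele {allele} does not fit motif {motif}")
                s = list(seqs[leaf])
                for p, aa in zip(slots, allele):
                    s[p - 1] = aa
                seqs[leaf] = "".join(s)
    return seqs


# ---------------------------------------------------------------------------
# genome bundle


@dataclass
class TruthGene:
    gene_id: str
    species: str
    family: str
    scaffold: str
    strand: str
    exons: list            # 0-based half-open genomic intervals, genomic order
    protein: str           # protein used for embedding (pre-decoy conversion)
    status: str            # clean | fragment | pseudogene | contaminant


@dataclass
class GenomeBundle:
    scaffolds: dict        # species -> {scaffold_id: sequence}
    genes: list            # list[TruthGene]
    scaffold_species: dict  # scaffold_id -> species

    def truth_for(self, species=None, statuses=("clean",)):
        return [g for g in self.genes
                if (species is None or g.species == species)
                and (statuses is None or g.status in statuses)]


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _split_exons(n_codons, n_introns, rng, min_exon=25):
    if n_introns == 0 or n_codons < (n_introns + 1) * min_exon:
        return [n_codons]
    for _ in range(50):
        cuts = sorted(rng.sample(range(min_exon, n_codons - min_exon + 1), n_introns))
        if all(b - a >= min_exon for a, b in zip(cuts, cuts[1:])):
            bounds = [0] + cuts + [n_codons]
            return [b - a for a, b in zip(bounds, bounds[1:])]
    step = n_codons // (n_introns + 1)
    bounds = [i * step for i in range(n_introns + 1)] + [n_codons]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _place_gene(protein, rng, config, scaffold_id, species, family, gene_id,
                status="clean", margin=None, pseudo_mode=None):
    """Build one scaffold hosting one (possibly decoy) gene model."""
    cds = back_translate(protein, stop=True)
    if pseudo_mode == "stop":
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        k = rng.randrange(len(protein) // 4, 3 * len(protein) // 4)
        codons[k] = "TAA"
        cds = "".join(codons)
    elif pseudo_mode == "deK":
        k296 = DEFAULT_MOTIF_SLOTS["K296"][0] - 1
        cds = cds[:k296 * 3] + "CGT" + cds[k296 * 3 + 3:]

    lo, hi = config.intron_count_range
    n_introns = rng.randint(lo, hi)
    exon_codons = _split_exons(len(cds) // 3, n_introns, rng)
    pieces = []
    cursor = 0
    for i, nc in enumerate(exon_codons):
        pieces.append(("exon", cds[cursor * 3:(cursor + nc) * 3]))
        cursor += nc
        if i < len(exon_codons) - 1:
            ilen = rng.randint(*config.intron_length_range)
            pieces.append(("intron", "GT" + _random_dna(rng, ilen - 4) + "AG"))
    gene_seq = "".join(s for _, s in pieces)

    margin = margin if margin is not None else config.scaffold_margin
    left = margin + rng.randrange(200)
    right = margin + rng.randrange(200)
    strand = "+" if rng.random() < 0.5 else "-"
    fwd = _random_dna(rng, left) + gene_seq + _random_dna(rng, right)
    pos = left
    spans = []
    for kind, s in pieces:
        if kind == "exon":
            spans.append((pos, pos + len(s)))
        pos += len(s)
    if strand == "-":
        L = len(fwd)
        scaffold_seq = revcomp(fwd)
        spans = [(L - e, L - s) for s, e in spans][::-1]
    else:
        scaffold_seq = fwd
    return scaffold_seq, TruthGene(gene_id, species, family, scaffold_id, strand,
                                   spans, protein, status)


def emit_genome_bundle(proteins_by_family: dict, config: SimConfig,
                       contaminant_template: str | None = None) -> GenomeBundle:
    """Embed every gene copy in its own scaffold; inject decoys.

    ``proteins_by_family``: family -> {gene leaf name ("<sp>_g<k>") -> protein}.
    A seeded fraction of embedded models is converted to fragments
    (interior truncation: no start/stop and missing the K296 region) or
    pseudogenes (in-frame stop, or anchor lysine replaced); contaminants
    derived from ``contaminant_template`` land on scaffolds shorter than
    ``short_scaffold_threshold``.
    """
    rng = random.Random(config.seed * 104729 + 7)
    scaffolds: dict = {}
    scaffold_species = {}
    genes: list = []

    all_genes = [(fam, gid, prot) for fam, d in sorted(proteins_by_family.items())
                 for gid, prot in sorted(d.items())]
    n = len(all_genes)
    idx = list(range(n))
    rng.shuffle(idx)
    n_frag = int(round(config.fragment_fraction * n))
    n_pseudo = int(round(config.pseudogene_fraction * n))
    frag_ids = set(idx[:n_frag])
    pseudo_ids = set(idx[n_frag:n_frag + n_pseudo])

    counters = Counter()
    for i, (fam, gid, prot) in enumerate(all_genes):
        species = gid.split("_g")[0]
        counters[species] += 1
        scaf_id = f"{species}_scaf{counters[species]}"
        status, pseudo_mode, emit_prot = "clean", None, prot
        if i in frag_ids:
            status = "fragment"
            emit_prot = prot[len(prot) * 22 // 100: len(prot) * 62 // 100]
        elif i in pseudo_ids:
            status = "pseudogene"
            pseudo_mode = "stop" if rng.random() < 0.5 else "deK"
        seq, tg = _place_gene(emit_prot, rng, config, scaf_id, species, fam,
                              f"{fam}.{gid}", status=status, pseudo_mode=pseudo_mode)
        scaffolds.setdefault(species, {})[scaf_id] = seq
        scaffold_species[scaf_id] = species
        genes.append(tg)

    if config.contaminant_count and contaminant_template:
        species_list = sorted({g.species for g in genes}) or ["A"]
        short_cfg = replace(config, intron_count_range=(0, 1),
                            intron_length_range=(60, 120))
        for k in range(config.contaminant_count):
            species = species_list[rng.randrange(len(species_list))]
            counters[species] += 1
            scaf_id = f"{species}_scaf{counters[species]}"
            prot = _mutate(contaminant_template, 0.5, config.subst_rate, rng)
            margin = max(60, (config.contaminant_scaffold_length - len(prot) * 3 - 400) // 2)
            seq, tg = _place_gene(prot, rng, short_cfg, scaf_id, species, "contaminant",
                                  f"{species}_cont{k + 1}", status="contaminant",
                                  margin=margin)
            scaffolds.setdefault(species, {})[scaf_id] = seq
            scaffold_species[scaf_id] = species
            genes.append(tg)

    # one gene-free background scaffold per species (prediction noise substrate)
    for species in sorted(scaffolds):
        counters[species] += 1
        scaf_id = f"{species}_scaf{counters[species]}"
        scaffolds[species][scaf_id] = _random_dna(rng, 3000)
        scaffold_species[scaf_id] = species
    return GenomeBundle(scaffolds, genes, scaffold_species)


def spliced_cds(scaffold_seq: str, gene: TruthGene) -> str:
    """Splice a truth gene's CDS from its scaffold (minus strand aware)."""
    if gene.strand == "+":
        return "".join(scaffold_seq[s:e] for s, e in gene.exons)
    return "".join(revcomp(scaffold_seq[s:e]) for s, e in reversed(gene.exons))


# ---------------------------------------------------------------------------
# full bundle: trees + histories + sequences + genomes + panel + metadata


@dataclass
class SimBundle:
    config: SimConfig
    species_tree: dendropy.Tree
    histories: dict            # family -> GeneFamilyHistory
    proteins: dict             # family -> {gene id -> protein}
    templates: dict            # family -> template (plus "outgroup", "contaminant")
    genome: GenomeBundle
    panel_records: dict        # ref id -> sequence
    panel_labels: dict         # ref id -> clade label
    panel_outgroups: set
    metadata: dict             # species -> {habitat, photic, eye_type}


def simulate_bundle(config: SimConfig) -> SimBundle:
    if not config.families:
        config.families = default_families()
    sp_tree = simulate_species_tree(config)

    templates = {}
    histories = {}
    proteins = {}
    for fi, fam in enumerate(sorted(config.families, key=lambda f: f.name)):
        dup, loss = config.rates_for(fam)
        templates[fam.name] = generate_family_template(config.seed * 131 + fi * 17 + 3)
        hist = simulate_gene_family(sp_tree, dup, loss,
                                    seed=config.seed * 9973 + fi * 389 + 1,
                                    family=fam.name,
                                    knockout_species=tuple(config.knockout_species))
        if hist.gene_tree is not None:
            _assign_ultrametric_lengths(hist.gene_tree, config.species_tree_height)
        histories[fam.name] = hist
        if hist.gene_tree is not None:
            seqs = emit_sequences(hist.gene_tree, templates[fam.name], config,
                                  motif_alleles=fam.motif_alleles,
                                  seed=config.seed * 557 + fi * 41 + 5)
        else:
            seqs = {}
        proteins[fam.name] = seqs

    templates["outgroup"] = generate_family_template(config.seed * 131 + 7717,
                                                     p_tm=0.8, p_loop=0.9)
    # contaminants descend from the outgroup founder but are further diverged
    templates["contaminant"] = _mutate(templates["outgroup"], 1.0, config.subst_rate,
                                       random.Random(config.seed * 131 + 7719))

    genome = emit_genome_bundle(proteins, config, contaminant_template=templates["contaminant"])

    panel_records, panel_labels, panel_outgroups = {}, {}, set()
    rrng = random.Random(config.seed * 263 + 77)
    t_div = (config.ref_divergence / config.subst_rate) if config.subst_rate > 0 else 0.0
    for fam in sorted(templates):
        if fam == "contaminant":
            continue
        n_ref = config.n_outgroup_refs if fam == "outgroup" else config.n_refs_per_family
        for j in range(n_ref):
            rid = f"ref_{fam}_{j + 1}"
            panel_records[rid] = _mutate(templates[fam], t_div, config.subst_rate, rrng)
            panel_labels[rid] = fam
            if fam == "outgroup":
                panel_outgroups.add(rid)

    habitats = ["marine", "marine", "freshwater", "intertidal"]
    eyes = ["camera eye", "pit eye", "eyeless", "compound eye"]
    metadata = {}
    mrng = random.Random(config.seed * 17 + 2)
    for s in sorted(l.taxon.label for l in sp_tree.leaf_node_iter()):
        if s in config.knockout_species:
            metadata[s] = {"habitat": "deep sea", "photic": "aphotic", "eye_type": "eyeless"}
        else:
            metadata[s] = {"habitat": mrng.choice(habitats),
                           "photic": mrng.choice(["photic", "dim"]),
                           "eye_type": mrng.choice(eyes)}
    return SimBundle(config, sp_tree, histories, proteins, templates, genome,
                     panel_records, panel_labels, panel_outgroups, metadata)


# ---------------------------------------------------------------------------
# serialization


def write_gff3(path, genes: list) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = min(s for s, _ in g.exons) + 1
            end = max(e for _, e in g.exons)
            attrs = f"ID={g.gene_id};family={g.family};status={g.status}"
            fh.write(f"{g.scaffold}\tphotorep_sim\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.scaffold}\tphotorep_sim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                         f"Parent={g.gene_id}\n")


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write scaffolds/proteome FASTA, truth GFF3 + event TSV, trees, panel, metadata."""
    import os

    import pandas as pd

    from ._seq import write_fasta

    os.makedirs(outdir, exist_ok=True)
    j = lambda *p: os.path.join(outdir, *p)
    with open(j("species_tree.nwk"), "w") as fh:
        fh.write(species_tree_newick(bundle.species_tree) + "\n")
    os.makedirs(j("genomes"), exist_ok=True)
    for sp, scafs in sorted(bundle.genome.scaffolds.items()):
        write_fasta(j("genomes", f"{sp}.fasta"), dict(sorted(scafs.items())))
    write_gff3(j("truth.gff3"), bundle.genome.genes)
    prots = {gid: seq for fam, d in sorted(bundle.proteins.items())
             for gid, seq in sorted(d.items())}
    write_fasta(j("proteins.fasta"), prots)
    os.makedirs(j("gene_trees"), exist_ok=True)
    for fam, hist in sorted(bundle.histories.items()):
        if hist.gene_tree is not None:
            with open(j("gene_trees", f"{fam}.nwk"), "w") as fh:
                fh.write(hist.gene_tree.as_string(
                    schema="newick", suppress_rooting=True,
                    unquoted_underscores=True).strip() + "\n")
    rows = []
    for fam, hist in sorted(bundle.histories.items()):
        for b in sorted(set(hist.dup_raw) | set(hist.loss_raw)):
            rows.append({"family": fam, "species_branch": b,
                         "D": hist.dup_raw.get(b, 0), "L": hist.loss_raw.get(b, 0)})
    pd.DataFrame(rows, columns=["family", "species_branch", "D", "L"]).to_csv(
        j("truth_events.tsv"), sep="\t", index=False)
    write_fasta(j("panel.fasta"), dict(sorted(bundle.panel_records.items())))
    pd.DataFrame(
        [{"seq_id": r, "superfamily": "opsin", "clade_label": bundle.panel_labels[r],
          "is_outgroup": r in bundle.panel_outgroups}
         for r in sorted(bundle.panel_records)]
    ).to_csv(j("panel_labels.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"species": s, **m} for s, m in sorted(bundle.metadata.items())]
    ).to_csv(j("metadata.tsv"), sep="\t", index=False)
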