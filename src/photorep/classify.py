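"""Placement-based clade classification against a labeled reference panel.

Queries are merged into the panel's fixed master-alignment coordinate
system (query-specific insertions are discarded), high-gap columns are
filtered, a neighbor-joining tree with seeded site-resampling bootstrap is
built from Poisson-corrected mismatch distances and rooted on the
outgroup, and each query is assigned the label of the first labeled clade
encountered walking rootward -- provided the labels are uniform and the
node's bootstrap support clears the threshold.  Queries whose nearest
references are exclusively outgroup sequences and which came from short
scaffolds are flagged as contaminants.

Neighbor joining is implemented on numpy matrices so that bootstrap
replicates on a few hundred leaves stay fast; joins tie-break on the
lexicographically smallest cluster-name pair for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._seq import aligned_blocks, make_global_aligner


class InputError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX*-")


@dataclass
class ReferencePanel:
    """Curated, labeled reference sequences with a fixed master alignment."""

    records: dict                  # seq_id -> unaligned sequence
    labels: dict                   # seq_id -> clade label
    outgroup_ids: set
    master_alignment: dict         # seq_id -> aligned row (one shared length)
    anchor_map: list | None = None  # master column index -> anchor position (1-based) or None

    def __post_init__(self):
        missing = set(self.records) - set(self.labels)
        if missing:
            raise InputError(f"unlabeled panel records: {sorted(missing)[:3]}...")
        if not self.outgroup_ids:
            raise InputError("panel outgroup must be nonempty (needed for rooting)")
        lengths = {len(r) for r in self.master_alignment.values()}
        if len(lengths) > 1:
            raise InputError("master alignment rows differ in length")

    @classmethod
    def from_ungapped(cls, records, labels, outgroup_ids, anchor_positions=None):
        """Panel whose members are already positionally homologous (no indels)."""
        L = len(next(iter(records.values())))
        anchor_map = list(range(1, L + 1)) if anchor_positions is None else anchor_positions
        return cls(records=dict(records), labels=dict(labels),
                   outgroup_ids=set(outgroup_ids),
                   master_alignment=dict(records), anchor_map=anchor_map)


@dataclass
class Placement:
    query_id: str
    assigned_label: str            # clade label or "unclassified"
    support: float | None
    nearest_labeled_ids: list = field(default_factory=list)
    is_contaminant: bool = False


# ---------------------------------------------------------------------------
# reference-guided alignment


def _consensus(master: dict) -> str:
    rows = list(master.values())
    L = len(rows[0])
    cons = []
    for i in range(L):
        col = [r[i] for r in rows if r[i] != "-"]
        cons.append(max(sorted(set(col)), key=col.count) if col else "-")
    return "".join(cons)


def reference_guided_align(queries: dict, panel: ReferencePanel,
                           max_gap_fraction: float = 0.6) -> tuple:
    """Align queries into the master columns; filter high-gap columns.

    Each query is globally aligned (affine gaps, BLOSUM62) to the master
    consensus; master columns are fixed, so query insertions relative to
    the consensus are dropped.  Columns with more than ``max_gap_fraction``
    gaps across the joint alignment are removed for tree building.

    Returns (joint alignment dict, kept column indices).
    """
    cons = _consensus(panel.master_alignment)
    cons_cols = [i for i, a in enumerate(cons) if a != "-"]
    cons_seq = "".join(cons[i] for i in cons_cols)
    aligner = make_global_aligner()
    L = len(cons)

    joint = dict(panel.master_alignment)
    for qid in sorted(queries):
        seq = queries[qid]
        if not seq or any(a not in VALID_AA for a in seq):
            raise InputError(f"query {qid!r} has an invalid alphabet")
        aln = aligner.align(cons_seq, seq)[0]
        tb, qb = aligned_blocks(aln)
        row = ["-"] * L
        for (ts, te), (qs, qe) in zip(tb, qb):
            for i in range(te - ts):
                row[cons_cols[ts + i]] = seq[qs + i]
        joint[qid] = "".join(row)

    rows = list(joint.values())
    n = len(rows)
    kept = [i for i in range(L)
            if sum(1 for r in rows if r[i] == "-") / n <= max_gap_fraction]
    return joint, kept


# ---------------------------------------------------------------------------
# distances and neighbor joining


def _encode(joint: dict, kept_cols: list) -> tuple:
    names = sorted(joint)
    arr = np.full((len(names), len(kept_cols)), 255, dtype=np.uint8)
    for i, nm in enumerate(names):
        row = joint[nm]
        arr[i] = np.frombuffer("".join(row[c] for c in kept_cols).encode(), dtype=np.uint8)
    arr[arr == ord("-")] = 255
    arr[arr == ord("X")] = 255
    return names, arr


def _distance_matrix(arr: np.ndarray, max_dist: float = 5.0) -> np.ndarray:
    n = arr.shape[0]
    D = np.zeros((n, n))
    valid = arr != 255
    for i in range(n):
        both = valid[i] & valid
        diff = (arr[i] != arr) & both
        nv = both.sum(axis=1)
        p = np.where(nv > 0, diff.sum(axis=1) / np.maximum(nv, 1), 1.0)
        with np.errstate(divide="ignore"):
            d = -np.log(np.maximum(1.0 - p, np.exp(-max_dist)))
        D[i] = np.minimum(d, max_dist)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def neighbor_joining(D: np.ndarray, names: list) -> str:
    """NJ tree as a Newick string; deterministic lexicographic tie-breaking."""
    n = len(names)
    if n < 2:
        raise DegenerateInputError("need >= 2 sequences")
    if n == 2:
        d = max(D[0, 1], 0.0) / 2
        return f"({names[0]}:{d:.6f},{names[1]}:{d:.6f});"
    newick = {i: names[i] for i in range(n)}
    canon = {i: names[i] for i in range(n)}
    next_id = n
    mat = D.copy()
    idx = list(range(n))
    while len(idx) > 3:
        m = len(idx)
        sub = mat
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        pick = min(
            (tuple(sorted((canon[idx[a]], canon[idx[b]]))), (a, b))
            for a, b in ties if a < b
        )[1]
        a, b = pick
        ia, ib = idx[a], idx[b]
        dab = sub[a, b]
        va = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        vb = dab - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        new_newick = f"({newick[ia]}:{va:.6f},{newick[ib]}:{vb:.6f})"
        new_canon = min(canon[ia], canon[ib])
        # distances to the new node
        dn = 0.5 * (sub[a] + sub[b] - dab)
        keep = [i for i in range(m) if i not in (a, b)]
        new_mat = np.empty((m - 1, m - 1))
        new_mat[:-1, :-1] = sub[np.ix_(keep, keep)]
        new_mat[-1, :-1] = dn[keep]
        new_mat[:-1, -1] = dn[keep]
        new_mat[-1, -1] = 0.0
        newick[next_id] = new_newick
        canon[next_id] = new_canon
        idx = [idx[i] for i in keep] + [next_id]
        mat = new_mat
        next_id += 1
    # join the last three
    a, b, c = 0, 1, 2
    ia, ib, ic = idx
    da = 0.5 * (mat[a, b] + mat[a, c] - mat[b, c])
    db = 0.5 * (mat[a, b] + mat[b, c] - mat[a, c])
    dc = 0.5 * (mat[a, c] + mat[b, c] - mat[a, b])
    parts = sorted([(canon[ia], f"{newick[ia]}:{max(da,0):.6f}"),
                    (canon[ib], f"{newick[ib]}:{max(db,0):.6f}"),
                    (canon[ic], f"{newick[ic]}:{max(dc,0):.6f}")])
    return "(" + ",".join(p for _, p in parts) + ");"


def _root_on_outgroup(tree: dendropy.Tree, outgroup_ids: set) -> dendropy.Tree:
    present = [t for t in tree.taxon_namespace if t.label in outgroup_ids]
    if not present:
        return tree
    tree.is_rooted = True
    if len(present) == 1:
        node = tree.find_node_with_taxon_label(present[0].label)
    else:
        node = tree.mrca(taxa=present)
    if node is None or node is tree.seed_node:
        node = tree.find_node_with_taxon_label(sorted(t.label for t in present)[0])
    edge = node.edge
    if edge.length is None:
        edge.length = 0.0
    tree.reroot_at_edge(edge, length1=edge.length / 2.0, length2=edge.length / 2.0,
                        update_bipartitions=False)
    tree.suppress_unifurcations()
    return tree


def _clades(tree: dendropy.Tree, all_leaves: frozenset, t0: str) -> dict:
    """Map internal node -> canonical bipartition id (side not containing t0)."""
    out = {}
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        bip = clade if t0 not in clade else all_leaves - clade
        out[nd] = bip
    return out


class _LabelWalker:
    """Rootward label walk over one rooted tree, shared by main/replicates.

    Ascends from a query leaf while the enclosing clade's reference labels
    stay uniform (non-outgroup); returns the last uniform label (None when
    the first labeled ancestor is mixed) and whether the first labeled
    neighborhood was exclusively outgroup.
    """

    def __init__(self, tree: dendropy.Tree, labels: dict, outgroup_ids: set):
        self.parent = {}
        self.leaf_of = {}
        self.node_labels = {}
        self.node_out = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                name = nd.taxon.label
                self.leaf_of[name] = nd
                lab = labels.get(name)
                if lab is not None and name in outgroup_ids:
                    self.node_labels[nd], self.node_out[nd] = frozenset(), 1
                elif lab is not None:
                    self.node_labels[nd], self.node_out[nd] = frozenset([lab]), 0
                else:
                    self.node_labels[nd], self.node_out[nd] = frozenset(), 0
            else:
                labs = frozenset().union(*(self.node_labels[c] for c in nd.child_nodes()))
                self.node_labels[nd] = labs
                self.node_out[nd] = sum(self.node_out[c] for c in nd.child_nodes())
            self.parent[nd] = nd.parent_node

    def walk(self, query_id: str) -> tuple:
        leaf = self.leaf_of.get(query_id)
        if leaf is None:
            return None, False
        node = self.parent[leaf]
        candidate = None
        outgroup_first = False
        first = True
        while node is not None:
            labs = self.node_labels[node]
            n_out = self.node_out[node]
            if labs or n_out:
                if not labs:
                    outgroup_first = first
                    break
                if len(labs) == 1 and (candidate is None or labs == {candidate}):
                    candidate = next(iter(labs))
                    first = False
                else:
                    break
            node = self.parent[node]
        return candidate, outgroup_first


@dataclass
class SupportTree:
    tree: dendropy.Tree
    support: dict                  # dendropy node -> bootstrap proportion or None
    n_bootstrap: int
    nearest_labeled: dict = field(default_factory=dict)  # leaf -> closest ref id
    replicates: list = field(default_factory=list)       # rooted bootstrap trees
    _walkers: dict = field(default_factory=dict, repr=False)

    def walkers(self, labels: dict, outgroup_ids: set) -> tuple:
        key = (id(labels), id(outgroup_ids))
        if key not in self._walkers:
            main = _LabelWalker(self.tree, labels, outgroup_ids)
            reps = [_LabelWalker(t, labels, outgroup_ids) for t in self.replicates]
            self._walkers[key] = (main, reps)
        return self._walkers[key]


def build_tree(joint: dict, kept_cols: list, outgroup_ids: set,
               n_bootstrap: int = 100, seed: int = 0,
               labeled_ids: set | None = None) -> SupportTree:
    """NJ tree from Poisson-corrected distances with site-resampling bootstrap.

    The tree is rooted on the smallest clade containing the outgroup.  With
    ``n_bootstrap=0`` the tree carries no support values and is fully
    deterministic.  ``labeled_ids`` (usually the panel members) enables the
    nearest-labeled-reference lookup used for contaminant detection.
    """
    if len(joint) < 4:
        raise DegenerateInputError("tree building needs >= 4 sequences")
    names, arr = _encode(joint, kept_cols)
    D = _distance_matrix(arr)
    newick = neighbor_joining(D, names)
    labeled_idx = [i for i, nm in enumerate(names) if labeled_ids and nm in labeled_ids]
    nearest = {}
    for i, nm in enumerate(names):
        cands = [j for j in labeled_idx if j != i]
        if cands:
            nearest[nm] = names[min(cands, key=lambda j: (D[i, j], names[j]))]
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    tree = _root_on_outgroup(tree, outgroup_ids)

    support: dict = {nd: None for nd in tree.preorder_internal_node_iter()}
    replicate_trees = []
    if n_bootstrap > 0:
        all_leaves = frozenset(names)
        t0 = min(names)
        target = _clades(tree, all_leaves, t0)
        counts = {bip: 0 for bip in target.values()}
        rng = np.random.default_rng(seed)
        ncol = arr.shape[1]
        for _ in range(n_bootstrap):
            cols = rng.integers(0, ncol, size=ncol)
            Db = _distance_matrix(arr[:, cols])
            nwk = neighbor_joining(Db, names)
            tb = dendropy.Tree.get(data=nwk, schema="newick",
                                   suppress_internal_node_taxa=True,
                                   preserve_underscores=True)
            tb = _root_on_outgroup(tb, outgroup_ids)
            replicate_trees.append(tb)
            seen = set()
            for nd in tb.preorder_internal_node_iter():
                if nd.parent_node is None:
                    continue
                clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                seen.add(clade if t0 not in clade else all_leaves - clade)
            for bip in counts:
                if bip in seen:
                    counts[bip] += 1
        for nd, bip in target.items():
            support[nd] = counts[bip] / n_bootstrap
    return SupportTree(tree=tree, support=support, n_bootstrap=n_bootstrap,
                       nearest_labeled=nearest, replicates=replicate_trees)


# ---------------------------------------------------------------------------
# clade assignment


def assign_clade(stree: SupportTree, panel: ReferencePanel, query_id: str,
                 support_threshold: float = 0.7,
                 from_short_scaffold: bool = False) -> Placement:
    """Place a query by walking rootward through uniformly labeled clades.

    The walk ascends while the enclosing clade's reference labels stay
    uniform (and non-outgroup).  Placement support is the fraction of
    bootstrap replicate trees whose own walk lands on the same label, so a
    query solidly inside a family clade keeps full support even when its
    exact insertion point wobbles, while a between-clade chimera splits
    its replicate walks and stays "unclassified".  A query whose
    neighborhood is exclusively outgroup -- first labeled ancestor
    all-outgroup, or nearest labeled reference an outgroup member when the
    walk ends mixed -- is a contaminant when it came from a short
    scaffold.  With bootstrapping disabled the walk label is assigned
    without a support value.
    """
    if stree.tree.find_node_with_taxon_label(query_id) is None:
        raise KeyError(f"query {query_id!r} not in tree")
    main, reps = stree.walkers(panel.labels, panel.outgroup_ids)
    candidate, outgroup_first = main.walk(query_id)

    if candidate is None:
        nearest = stree.nearest_labeled.get(query_id)
        outgroupish = outgroup_first or (nearest is not None
                                         and nearest in panel.outgroup_ids)
        return Placement(query_id, "unclassified", None,
                         nearest_labeled_ids=[nearest] if nearest else [],
                         is_contaminant=outgroupish and from_short_scaffold)

    if reps:
        agree = sum(1 for w in reps if w.walk(query_id)[0] == candidate)
        support = agree / len(reps)
    else:
        support = None  # deterministic mode: no resampling requested

    refs = sorted(r for r, lab in panel.labels.items()
                  if lab == candidate and r not in panel.outgroup_ids)
    if support is None or support >= support_threshold:
        return Placement(query_id, candidate, support, nearest_labeled_ids=refs)
    return Placement(query_id, "unclassified", None, nearest_labeled_ids=refs)


def classify_queries(queries: dict, panel: ReferencePanel, n_bootstrap: int = 100,
                     seed: int = 0, support_threshold: float = 0.7,
                     short_scaffold_queries: set | None = None) -> tuple:
    """End-to-end classification: align, build tree, place every query.

    Returns (placements list, joint alignment, SupportTree).
    """
    short = short_scaffold_queries or set()
    joint, kept = reference_guided_align(queries, panel)
    stree = build_tree(joint, kept, panel.outgroup_ids,
                       n_bootstrap=n_bootstrap, seed=seed,
                       labeled_ids=set(panel.labels))
    placements = [
        assign_clade(stree, panel, qid, support_threshold=support_threshold,
                     from_short_scaffold=qid in short)
        for qid in sorted(queries)
    ]
    return placements, joint, stree
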