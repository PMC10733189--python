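"""Gene-tree / species-tree reconciliation under duplication-loss parsimony.

Each gene-tree node g is mapped to M(g), the last common ancestor in the
species tree of the species below g.  An internal node is a duplication
when it maps to the same species node as one of its children, otherwise a
speciation.  Losses are counted per gene-tree edge as the number of
species-tree edges skipped between the parent's and the child's mapping
(minus one below a speciation), the standard embedding count; losses on
the root edge are not counted (no stem losses).  This LCA mapping
simultaneously minimises duplications and losses over all valid
embeddings, which the brute-force oracle in this module verifies by
exhaustive enumeration on small trees.

Leaf-to-species mapping follows the reserved ``<species>_g<k>`` delimiter
convention unless an explicit map is given.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import dendropy
import pandas as pd


class MappingError(ValueError):
    pass


class NonBinaryTreeError(ValueError):
    pass


def leaf_species_from_name(leaf: str) -> str:
    if "_g" not in leaf:
        raise MappingError(f"leaf {leaf!r} does not follow the <species>_g<k> convention")
    return leaf.split("_g")[0]


# ---------------------------------------------------------------------------
# species-tree index


class _SpeciesIndex:
    """Parent/depth tables over a rooted binary species tree."""

    def __init__(self, species_tree: dendropy.Tree):
        self.nodes = []
        self.parent = {}
        self.depth = {}
        self.by_leaf = {}
        self.label = {}
        self.children = {}
        for nd in species_tree.preorder_node_iter():
            kids = nd.child_nodes()
            if kids and len(kids) != 2:
                raise NonBinaryTreeError("species tree must be binary")
            self.nodes.append(nd)
            self.children[nd] = kids
            self.parent[nd] = nd.parent_node
            self.depth[nd] = 0 if nd.parent_node is None else self.depth[nd.parent_node] + 1
            label = nd.taxon.label if nd.is_leaf() else nd.label
            self.label[nd] = label
            if nd.is_leaf():
                self.by_leaf[nd.taxon.label] = nd

    def lca(self, a, b):
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a, b = self.parent[a], self.parent[b]
        return a

    def is_ancestor_or_equal(self, a, b) -> bool:
        """a is on the path from root to b (inclusive)."""
        while b is not None and self.depth[b] >= self.depth[a]:
            if b is a:
                return True
            b = self.parent[b]
        return False

    def path_down(self, top, bottom):
        """Nodes from ``top`` (exclusive) down to ``bottom`` (inclusive)."""
        path = []
        nd = bottom
        while nd is not top:
            if nd is None:
                raise MappingError("nodes not on an ancestor path")
            path.append(nd)
            nd = self.parent[nd]
        return list(reversed(path))


# ---------------------------------------------------------------------------
# reconciliation result containers


@dataclass
class Reconciliation:
    family: str
    gene_tree: dendropy.Tree
    leaf_map: dict                      # gene leaf -> species leaf label
    node_events: dict                   # gene node -> "S" | "D"
    edge_losses: dict                   # gene child-node -> int
    branch_dups: Counter = field(default_factory=Counter)    # species branch label -> D
    branch_losses: Counter = field(default_factory=Counter)  # species branch label -> L
    S: int = 0
    L: int = 0
    D: int = 0


@dataclass
class FamilySummary:
    family: str
    S: int
    L: int
    D: int

    @property
    def total_nonloss(self) -> int:
        return self.S + self.D

    @staticmethod
    def _round2(x: float) -> float:
        return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    @property
    def S_frac(self) -> float:
        return self._round2(self.S / self.total_nonloss) if self.total_nonloss else 1.0

    @property
    def D_frac(self) -> float:
        return self._round2(self.D / self.total_nonloss) if self.total_nonloss else 0.0


# ---------------------------------------------------------------------------
# LCA reconciliation


def _check_binary(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_node_iter():
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise NonBinaryTreeError("gene tree must be binary (refusing to resolve)")


def lca_reconcile(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                  leaf_map: dict | None = None, family: str = "fam") -> Reconciliation:
    """Duplication-loss parsimony reconciliation by LCA mapping."""
    idx = _SpeciesIndex(species_tree)
    _check_binary(gene_tree)

    leaves = [lf.taxon.label for lf in gene_tree.leaf_node_iter()]
    if leaf_map is None:
        leaf_map = {l: leaf_species_from_name(l) for l in leaves}
    for l in leaves:
        sp = leaf_map.get(l)
        if sp is None or sp not in idx.by_leaf:
            raise MappingError(f"gene leaf {l!r} maps to unknown species {sp!r}")

    M = {}
    events = {}
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            M[nd] = idx.by_leaf[leaf_map[nd.taxon.label]]
        else:
            c1, c2 = nd.child_nodes()
            M[nd] = idx.lca(M[c1], M[c2])
            events[nd] = "D" if (M[nd] is M[c1] or M[nd] is M[c2]) else "S"

    rec = Reconciliation(family=family, gene_tree=gene_tree, leaf_map=dict(leaf_map),
                         node_events=events, edge_losses={})
    for nd, ev in events.items():
        if ev == "D":
            rec.D += 1
            rec.branch_dups[idx.label[M[nd]]] += 1
        else:
            rec.S += 1
    for nd in gene_tree.preorder_node_iter():
        parent = nd.parent_node
        if parent is None:
            rec.edge_losses[nd] = 0
            continue
        path = idx.path_down(M[parent], M[nd]) if M[parent] is not M[nd] else []
        dist = len(path)
        n_loss = dist if events[parent] == "D" else max(dist - 1, 0)
        rec.edge_losses[nd] = n_loss
        # attribute each loss to the sibling branch skipped at each node
        # passed through strictly between M(parent) and M(nd) (plus, for a
        # duplication, the first step out of M(parent) itself)
        walk = [M[parent]] + path if events[parent] == "D" else path
        for u, v in zip(walk, walk[1:]):
            for child in idx.children[u]:
                if child is not v:
                    rec.branch_losses[idx.label[child]] += 1
        rec.L += n_loss
    return rec


# ---------------------------------------------------------------------------
# rooting


def root_gene_tree(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                   leaf_map: dict | None = None) -> dendropy.Tree:
    """Root an unrooted gene tree at the branch minimising D + L.

    Ties break by fewest duplications, then by the lexicographically
    smallest leaf-set bipartition of the root.
    """
    leaves = [lf.taxon.label for lf in gene_tree.leaf_node_iter()]
    if len(leaves) < 3:
        t = gene_tree.clone(depth=1)
        t.is_rooted = True
        return t
    best = None
    for rooted in _all_rootings(gene_tree):
        rec = lca_reconcile(rooted, species_tree, leaf_map=leaf_map)
        sides = sorted(
            tuple(sorted(lf.taxon.label for lf in ch.leaf_iter()))
            for ch in rooted.seed_node.child_nodes()
        )
        key = (rec.D + rec.L, rec.D, sides)
        if best is None or key < best[0]:
            best = (key, rooted)
    return best[1]


def _all_rootings(tree: dendropy.Tree):
    """Yield one rooted tree per branch of the (un)rooted input."""
    newick = tree.as_string(schema="newick", unquoted_underscores=True).strip()
    base = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    base.is_rooted = False
    base.update_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=True)
    n_edges = sum(1 for e in base.preorder_edge_iter() if e.head_node.parent_node is not None)
    for k in range(n_edges):
        t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        t.is_rooted = False
        t.update_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=True)
        edges = [e for e in t.preorder_edge_iter() if e.head_node.parent_node is not None]
        e = edges[k]
        if e.length is None:
            e.length = 1.0
        t.reroot_at_edge(e, length1=e.length / 2.0, length2=e.length / 2.0)
        t.is_rooted = True
        t.suppress_unifurcations()
        if all(len(nd.child_nodes()) in (0, 2) for nd in t.preorder_node_iter()):
            yield t


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_min_events(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                           leaf_map: dict | None = None) -> tuple:
    """(D, L) minimising D+L over all valid embeddings, by exhaustive enumeration.

    A valid embedding assigns every gene node a species node that is an
    ancestor-or-equal of its children's assignments (leaves are fixed to
    their species).  Intended for small trees only; independent of
    :func:`lca_reconcile`.
    """
    idx = _SpeciesIndex(species_tree)
    _check_binary(gene_tree)
    leaves = [lf.taxon.label for lf in gene_tree.leaf_node_iter()]
    if leaf_map is None:
        leaf_map = {l: leaf_species_from_name(l) for l in leaves}

    nodes = list(gene_tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    assign = {n: idx.by_leaf[leaf_map[n.taxon.label]] for n in nodes if n.is_leaf()}

    best = [None]

    def ancestors_or_self(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = idx.parent[nd]
        return out

    def count(assignment) -> tuple:
        D = L = 0
        for g in internal:
            c1, c2 = g.child_nodes()
            a, a1, a2 = assignment[g], assignment[c1], assignment[c2]
            dup = (a is a1) or (a is a2) or not (
                idx.lca(a1, a2) is a and a1 is not a and a2 is not a
                and _distinct_children(idx, a, a1, a2))
            ev = "D" if dup else "S"
            for ac in (a1, a2):
                d = idx.depth[ac] - idx.depth[a]
                L += d if ev == "D" else max(d - 1, 0)
            D += 1 if ev == "D" else 0
        return D, L

    def rec(i, assignment):
        if i == len(internal):
            D, L = count(assignment)
            if best[0] is None or (D + L, D, L) < best[0]:
                best[0] = (D + L, D, L)
            return
        g = internal[i]
        c1, c2 = g.child_nodes()
        if assignment.get(c1) is None or assignment.get(c2) is None:
            # postorder guarantees children first
            raise RuntimeError("enumeration order broken")
        top = idx.lca(assignment[c1], assignment[c2])
        for cand in ancestors_or_self(top):
            assignment[g] = cand
            rec(i + 1, assignment)
        del assignment[g]

    rec(0, dict(assign))
    _, D, L = best[0]
    return D, L


def enumerate_gene_tree_shapes(labels, max_leaves: int) -> list:
    """All distinct rooted binary leaf-labeled trees (labels may repeat).

    Trees are nested tuples: a leaf is a label string, an internal node a
    pair tuple sorted by canonical form, so each unordered shape appears
    exactly once.  Supports the exhaustive reconciliation oracle check.
    """
    def canon(t):
        return t if isinstance(t, str) else "(" + canon(t[0]) + "," + canon(t[1]) + ")"

    by_size = {1: sorted(labels)}
    for k in range(2, max_leaves + 1):
        seen = {}
        for i in range(1, k // 2 + 1):
            j = k - i
            for a in by_size[i]:
                for b in by_size[j]:
                    if i == j and canon(a) > canon(b):
                        continue
                    t = tuple(sorted((a, b), key=canon))
                    seen[canon(t)] = t
        by_size[k] = [seen[c] for c in sorted(seen)]
    out = []
    for k in range(2, max_leaves + 1):
        out.extend(by_size[k])
    return out


def gene_tree_from_shape(shape) -> dendropy.Tree:
    """Nested-tuple shape -> dendropy tree with ``<species>_g<k>`` leaf names."""
    counters = Counter()
    tree = dendropy.Tree()
    tree.is_rooted = True

    def attach(node, dnode):
        if isinstance(node, str):
            counters[node] += 1
            name = f"{node}_g{counters[node]}"
            dnode.taxon = tree.taxon_namespace.new_taxon(label=name)
        else:
            for ch in node:
                attach(ch, dnode.new_child())

    attach(shape, tree.seed_node)
    return tree


def _distinct_children(idx, a, a1, a2) -> bool:
    """True when a1 and a2 descend through different children of a (speciation)."""
    kids = idx.children[a]
    if not kids:
        return False
    side1 = next((k for k in kids if idx.is_ancestor_or_equal(k, a1)), None)
    side2 = next((k for k in kids if idx.is_ancestor_or_equal(k, a2)), None)
    return side1 is not None and side2 is not None and side1 is not side2


# ---------------------------------------------------------------------------
# summaries


def summarize_families(reconciliations) -> pd.DataFrame:
    """One row per family: S, L, D, total_nonloss (=S+D), S_frac, D_frac.

    Fractions are the proportions of non-loss events, rounded half-up to
    two decimals.
    """
    rows = []
    for rec in reconciliations:
        if isinstance(rec, FamilySummary):
            fs = rec
        else:
            fs = FamilySummary(rec.family, rec.S, rec.L, rec.D)
        rows.append({"family": fs.family, "S": fs.S, "L": fs.L, "D": fs.D,
                     "total_nonloss": fs.total_nonloss,
                     "S_frac": fs.S_frac, "D_frac": fs.D_frac})
    return pd.DataFrame(rows, columns=["family", "S", "L", "D", "total_nonloss",
                                       "S_frac", "D_frac"])


def branch_event_map(reconciliations) -> pd.DataFrame:
    """Per species-branch duplication/loss tallies across families."""
    rows = []
    for rec in reconciliations:
        for b in sorted(set(rec.branch_dups) | set(rec.branch_losses)):
            rows.append({"species_branch": b, "family": rec.family,
                         "n_dup": rec.branch_dups.get(b, 0),
                         "n_loss": rec.branch_losses.get(b, 0)})
    return pd.DataFrame(rows, columns=["species_branch", "family", "n_dup", "n_loss"])
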