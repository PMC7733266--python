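"""Tree I/O, alignment block filtering, distance/NJ building and
gene-tree/species-tree reconciliation.

Trees are ``dendropy.Tree`` objects (rooted).  Reconciliation maps each
gene-tree node to the species-tree LCA of its leaves' species; a node
whose mapping equals a child's mapping is a duplication, and losses are
counted along each gene-tree edge by the standard path-depth rule.  The
result is the minimum duplication-loss reconciliation for the given
rooting; an optional exhaustive root search keeps the
duplication-minimizing rooting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Alignment",
    "ReconciliationResult",
    "NodeEvent",
    "parse_newick",
    "write_newick",
    "read_newick",
    "read_alignment",
    "conserved_block_filter",
    "distance_matrix",
    "nj_tree",
    "midpoint_root",
    "resolve_polytomies",
    "is_binary",
    "lca_reconcile",
    "best_rooting_reconcile",
    "clade_absence_report",
    "assign_ortholog_names",
    "write_reconciliation_report",
]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Internal node labels (e.g. support values) and branch lengths are
    preserved.  Unbalanced parentheses or duplicate leaf labels raise
    ``ValueError``.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ValueError(f"invalid newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf label(s): {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line Newick string."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(node.child_nodes()) in (0, 2) for node in tree.preorder_node_iter()
    )


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve multifurcations left-associatively (in place), with a warning."""
    changed = False
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            changed = True
            left = children[0]
            right = children[1]
            for ch in (left, right):
                node.remove_child(ch)
            merged = dendropy.Node()
            merged.edge.length = 0.0
            merged.add_child(left)
            merged.add_child(right)
            node.insert_child(0, merged)
            children = node.child_nodes()
    if changed:
        warnings.warn("multifurcation(s) resolved left-associatively")
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a tree in place (branch lengths required)."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


# ---------------------------------------------------------------------------
# Alignments and block filtering
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """An aligned set of sequences; gap character ``-``."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != width:
                raise ValueError(f"row {rid!r} has length {len(seq)} != {width}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.rows)


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment (format auto-detected)."""
    from Bio import AlignIO

    path = Path(path)
    if fmt is None:
        first = path.read_text().lstrip().splitlines()[0] if path.read_text().strip() else ""
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return Alignment(rows=[(rec.id, str(rec.seq).upper()) for rec in aln])


def conserved_block_filter(
    aln: Alignment,
    min_ident_fraction: float = 0.5,
    max_gap_fraction: float = 0.2,
    min_block_length: int = 5,
) -> Alignment:
    """Simplified conserved-block column filter.

    A column is kept when its most frequent non-gap residue occurs in at
    least ``min_ident_fraction`` of the rows and its gap fraction is at
    most ``max_gap_fraction``; kept columns are grouped into maximal
    runs and runs shorter than ``min_block_length`` are dropped.  Column
    order is preserved.  This is a deliberately simplified three-
    parameter filter, not a re-creation of any particular trimming tool.
    """
    if not 0 < min_ident_fraction <= 1:
        raise ValueError("min_ident_fraction must be in (0, 1]")
    if not 0 <= max_gap_fraction < 1:
        raise ValueError("max_gap_fraction must be in [0, 1)")
    if min_block_length < 1:
        raise ValueError("min_block_length must be >= 1")
    n_rows = len(aln.rows)
    keep = []
    for j in range(aln.n_columns):
        col = aln.column(j)
        gaps = col.count("-")
        if gaps / n_rows > max_gap_fraction:
            continue
        residues = [c for c in col if c != "-"]
        if not residues:
            continue
        top = max(residues.count(c) for c in set(residues))
        if top / n_rows >= min_ident_fraction:
            keep.append(j)
    # group into runs of consecutive kept columns
    blocks: list[list[int]] = []
    for j in keep:
        if blocks and j == blocks[-1][-1] + 1:
            blocks[-1].append(j)
        else:
            blocks.append([j])
    cols = [j for b in blocks if len(b) >= min_block_length for j in b]
    new_rows = [(rid, "".join(seq[j] for j in cols)) for rid, seq in aln.rows]
    return Alignment(rows=new_rows)


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def distance_matrix(aln: Alignment, model: str = "p") -> tuple[list[str], np.ndarray]:
    """Pairwise p- or Poisson-corrected distances over shared ungapped sites."""
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    ids = aln.ids
    n = len(ids)
    mat = np.zeros((n, n))
    seqs = [seq for _, seq in aln.rows]
    for i in range(n):
        for j in range(i + 1, n):
            shared = mism = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a == "-" or b == "-":
                    continue
                shared += 1
                if a != b:
                    mism += 1
            if shared == 0:
                raise ValueError(
                    f"{ids[i]!r} and {ids[j]!r} share no ungapped sites"
                )
            p = mism / shared
            if model == "poisson":
                if p >= 1:
                    raise ValueError(
                        f"p-distance {p} >= 1 between {ids[i]!r} and {ids[j]!r}: "
                        "poisson correction undefined"
                    )
                d = -np.log(1.0 - p)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return ids, mat


def nj_tree(ids: Sequence[str], dist: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree, midpoint-rooted for downstream reconciliation."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dist = np.asarray(dist, dtype=float)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    if dist.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValueError("distances must be non-negative")
    tnode = nj(DistanceMatrix(dist, list(ids)))
    tree = parse_newick(str(tnode))
    return midpoint_root(tree)


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeEvent:
    """Event call for one internal gene-tree node."""

    gene_leaves: tuple[str, ...]
    event: str  # "duplication" | "speciation"
    species: str  # label of the mapped species-tree node


@dataclass
class ReconciliationResult:
    events: list[NodeEvent]
    total_duplications: int
    total_losses: int
    loss_branches: list[str] = field(default_factory=list)


def _species_node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))


def lca_reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: Mapping[str, str],
) -> ReconciliationResult:
    """LCA gene-tree/species-tree reconciliation with duplication and
    loss calling.

    Both trees must be rooted and binary; every gene leaf label must map
    to a species leaf label via ``leaf_map``.
    """
    for tree, name in ((gene_tree, "gene tree"), (species_tree, "species tree")):
        if not is_binary(tree):
            raise ValueError(f"{name} is not binary; resolve polytomies first")

    # species-tree bookkeeping
    depth: dict[dendropy.Node, int] = {}
    parent: dict[dendropy.Node, dendropy.Node | None] = {}
    species_leaf: dict[str, dendropy.Node] = {}
    for node in species_tree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
        if node.is_leaf():
            species_leaf[node.taxon.label] = node

    def species_lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while depth[a] > depth[b]:
            a = parent[a]
        while depth[b] > depth[a]:
            b = parent[b]
        while a is not b:
            a, b = parent[a], parent[b]
        return a

    # map gene nodes to species nodes (postorder)
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_map:
                raise KeyError(f"gene leaf {label!r} missing from leaf map")
            sp = leaf_map[label]
            if sp not in species_leaf:
                raise KeyError(f"species {sp!r} not a species-tree leaf")
            mapping[node] = species_leaf[sp]
        else:
            left, right = node.child_nodes()
            mapping[node] = species_lca(mapping[left], mapping[right])

    events: list[NodeEvent] = []
    is_dup: dict[dendropy.Node, bool] = {}
    for node in gene_tree.preorder_internal_node_iter():
        dup = any(mapping[ch] is mapping[node] for ch in node.child_nodes())
        is_dup[node] = dup
        events.append(
            NodeEvent(
                gene_leaves=tuple(sorted(l.taxon.label for l in node.leaf_iter())),
                event="duplication" if dup else "speciation",
                species=_species_node_label(mapping[node]),
            )
        )

    # losses per gene-tree edge by the path-depth rule
    total_losses = 0
    loss_branches: list[str] = []
    for node in gene_tree.preorder_node_iter():
        u = node.parent_node
        if u is None:
            continue
        mu, mv = mapping[u], mapping[node]
        d = depth[mv] - depth[mu]
        # species nodes where a sibling lineage was lost: the lineage
        # passes from mu down to mv; a duplication at u also covers mu.
        path: list[dendropy.Node] = []
        cur = mv
        while cur is not mu:
            path.append(cur)
            cur = parent[cur]
        path.append(mu)
        path.reverse()  # mu ... mv
        if is_dup.get(u, False):
            lost_at = path[:-1]  # includes mu
        else:
            lost_at = path[1:-1]  # strictly between
        for k, sp_node in enumerate(lost_at):
            on_path = path[path.index(sp_node) + 1]
            for ch in sp_node.child_nodes():
                if ch is not on_path:
                    loss_branches.append(_species_node_label(ch))
        total_losses += len(lost_at)
        assert len(lost_at) == (d if is_dup.get(u, False) else max(d - 1, 0))

    return ReconciliationResult(
        events=events,
        total_duplications=sum(1 for e in events if e.event == "duplication"),
        total_losses=total_losses,
        loss_branches=sorted(loss_branches),
    )


def best_rooting_reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: Mapping[str, str],
) -> tuple[dendropy.Tree, ReconciliationResult]:
    """Try every rooting of the gene tree; keep the duplication-minimizing
    one (ties broken by loss count, then first encountered)."""
    best: tuple[int, int] | None = None
    best_pair: tuple[dendropy.Tree, ReconciliationResult] | None = None
    base = write_newick(gene_tree)
    n_edges = sum(1 for _ in parse_newick(base).preorder_edge_iter())
    for i in range(n_edges):
        t = parse_newick(base)
        edges = list(t.preorder_edge_iter())
        edge = edges[i]
        if edge.head_node is t.seed_node:
            continue
        try:
            t.reroot_at_edge(edge, update_bipartitions=False)
        except Exception:
            continue
        t.resolve_polytomies()
        if not is_binary(t):
            continue
        try:
            res = lca_reconcile(t, species_tree, leaf_map)
        except ValueError:
            continue
        key = (res.total_duplications, res.total_losses)
        if best is None or key < best:
            best = key
            best_pair = (t, res)
    if best_pair is None:
        raise ValueError("no valid rooting found")
    return best_pair


# ---------------------------------------------------------------------------
# Clade reports and ortholog naming
# ---------------------------------------------------------------------------

def clade_absence_report(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: Mapping[str, str],
    clade_label_sets: Mapping[str, set[str]],
    taxon_groups: Mapping[str, set[str]],
) -> list[tuple[str, list[str]]]:
    """For each named gene clade, list the taxon groups present in the
    species tree but absent from the clade's leaves."""
    species_in_tree = set(leaf_labels(species_tree))
    out: list[tuple[str, list[str]]] = []
    for clade_name, gene_leaves in clade_label_sets.items():
        missing = [g for g in gene_leaves if g not in leaf_map]
        if missing:
            raise KeyError(f"clade {clade_name!r}: unmapped leaves {missing}")
        present_species = {leaf_map[g] for g in gene_leaves}
        absent = [
            grp
            for grp, members in taxon_groups.items()
            if members & species_in_tree and not members & present_species
        ]
        out.append((clade_name, absent))
    return out


def assign_ortholog_names(
    gene_tree: dendropy.Tree,
    reference_labels: Mapping[str, str],
    queries: Sequence[str],
    leaf_map: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Name query leaves after the reference(s) in the smallest clade
    containing the query and at least one reference.

    Multiple reference names in that clade resolve by majority, ties to
    ``"ambiguous"``.  When several same-species queries share a name,
    numeric suffixes are appended in tree order.
    """
    leaves = {leaf.taxon.label: leaf for leaf in gene_tree.leaf_node_iter()}
    missing = [q for q in queries if q not in leaves]
    if missing:
        raise KeyError(f"query leaves not in gene tree: {missing}")
    if not any(r in leaves for r in reference_labels):
        raise ValueError("no reference leaf present in the gene tree")

    names: dict[str, str] = {}
    for q in queries:
        node = leaves[q]
        chosen = "ambiguous"
        while node is not None:
            refs = [
                reference_labels[l.taxon.label]
                for l in node.leaf_iter()
                if l.taxon.label in reference_labels
            ]
            if refs:
                counts: dict[str, int] = {}
                for name in refs:
                    counts[name] = counts.get(name, 0) + 1
                top = max(counts.values())
                winners = sorted(n for n, c in counts.items() if c == top)
                chosen = winners[0] if len(winners) == 1 else "ambiguous"
                break
            node = node.parent_node
        names[q] = chosen

    # numeric suffixes within a species, in tree order
    tree_order = {label: i for i, label in enumerate(leaf_labels(gene_tree))}
    groups: dict[tuple[str, str], list[str]] = {}
    for q in queries:
        if names[q] == "ambiguous":
            continue
        sp = leaf_map.get(q, "") if leaf_map else ""
        groups.setdefault((names[q], sp), []).append(q)
    out = dict(names)
    for (name, _sp), members in groups.items():
        if len(members) > 1:
            members.sort(key=lambda q: tree_order[q])
            for i, q in enumerate(members, start=1):
                out[q] = f"{name}{i}"
    return out


def write_reconciliation_report(
    result: ReconciliationResult, path: str | Path, sep: str = "\t"
) -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["gene_clade", "event", "mapped_species_node"]) + "\n")
        for e in result.events:
            fh.write(sep.join([",".join(e.gene_leaves), e.event, e.species]) + "\n")
        fh.write(f"# total_duplications{sep}{result.total_duplications}\n")
        fh.write(f"# total_losses{sep}{result.total_losses}\n")
        if result.loss_branches:
            fh.write(f"# loss_branches{sep}{';'.join(result.loss_branches)}\n")
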