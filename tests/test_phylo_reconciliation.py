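import itertools

import dendropy
import numpy as np
import pytest

from clcfam.phylo_reconciliation import (
    Alignment,
    assign_ortholog_names,
    clade_absence_report,
    conserved_block_filter,
    distance_matrix,
    is_binary,
    lca_reconcile,
    nj_tree,
    parse_newick,
    read_alignment,
    resolve_polytomies,
    write_newick,
)
from clcfam.synthetic_data import TAXON_GROUPS, default_species_tree

from conftest import random_binary_newick


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _topology_key(tree: dendropy.Tree):
    """Rooted-topology fingerprint: frozenset of leaf-label clades."""
    return frozenset(
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in tree.preorder_node_iter()
    )


class TestNewickIO:
    def test_three_leaf_tree(self):
        t = parse_newick("((A,B),C);")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["A", "B", "C"]
        assert is_binary(t)

    def test_roundtrip_random_trees(self, rng):
        for i in range(50):
            labels = [f"t{j}" for j in range(int(rng.integers(3, 12)))]
            nw = random_binary_newick(rng, labels)
            t1 = parse_newick(nw)
            t2 = parse_newick(write_newick(t1))
            assert _topology_key(t1) == _topology_key(t2)

    def test_branch_lengths_preserved(self):
        t = parse_newick("((A:1.5,B:2.5):0.5,C:3);")
        out = write_newick(t)
        assert "1.5" in out and "2.5" in out

    def test_internal_labels_preserved(self):
        t = parse_newick("((A,B)98,C);")
        assert "98" in write_newick(t)

    def test_unbalanced_parens_error(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B,C);")

    def test_duplicate_leaves_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A,A),C);")

    def test_resolve_polytomies(self):
        t = parse_newick("(A,B,C,D);")
        with pytest.warns(UserWarning):
            resolve_polytomies(t)
        assert is_binary(t)


# ---------------------------------------------------------------------------
# Block filter
# ---------------------------------------------------------------------------

class TestBlockFilter:
    def test_identical_sequences_all_retained(self):
        aln = Alignment(rows=[(f"s{i}", "MKTVLE" * 3) for i in range(5)])
        out = conserved_block_filter(aln, min_block_length=1)
        assert out.n_columns == aln.n_columns

    def test_all_gap_column_removed(self):
        rows = [("a", "MK-TVLEMKT"), ("b", "MK-TVLEMKT"), ("c", "MK-TVLEMKT")]
        out = conserved_block_filter(Alignment(rows=rows), max_gap_fraction=0.5,
                                     min_block_length=1)
        assert all("-" not in seq for _, seq in out.rows)

    def test_short_block_dropped(self):
        # 4 conserved columns then a disruptor; min block 5 drops everything
        rows = [("a", "MKTVW"), ("b", "MKTVC"), ("c", "MKTVD")]
        out = conserved_block_filter(Alignment(rows=rows), min_ident_fraction=1.0,
                                     max_gap_fraction=0.0, min_block_length=5)
        assert out.n_columns == 0

    def test_output_subset_in_order(self, rng):
        alphabet = list("MKTVLE-")
        rows = [
            (f"s{i}", "".join(rng.choice(alphabet, size=60))) for i in range(6)
        ]
        aln = Alignment(rows=rows)
        out = conserved_block_filter(aln, min_ident_fraction=0.4,
                                     max_gap_fraction=0.3, min_block_length=2)
        # every output row must be a subsequence of its input row
        for (rid, s_in), (_, s_out) in zip(aln.rows, out.rows):
            it = iter(s_in)
            assert all(ch in it for ch in s_out)

    def test_empty_alignment_error(self):
        with pytest.raises(ValueError):
            Alignment(rows=[])

    def test_param_validation(self):
        aln = Alignment(rows=[("a", "MK"), ("b", "MK")])
        with pytest.raises(ValueError):
            conserved_block_filter(aln, min_ident_fraction=0.0)
        with pytest.raises(ValueError):
            conserved_block_filter(aln, max_gap_fraction=1.0)


class TestAlignmentIO:
    def test_fasta_roundtrip(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nMK-TV\n>b\nMKCTV\n")
        aln = read_alignment(p)
        assert aln.rows == [("a", "MK-TV"), ("b", "MKCTV")]

    def test_clustal_detected(self, tmp_path):
        p = tmp_path / "aln.aln"
        p.write_text(
            "CLUSTAL W (1.82) multiple sequence alignment\n\n"
            "a    MK-TV\nb    MKCTV\n"
        )
        aln = read_alignment(p)
        assert aln.rows == [("a", "MK-TV"), ("b", "MKCTV")]


# ---------------------------------------------------------------------------
# Distances and NJ
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = Alignment(rows=[("a", "MKTV"), ("b", "MKTV")])
        _, d = distance_matrix(aln)
        assert d[0, 1] == 0.0

    def test_p_distance_count(self):
        aln = Alignment(rows=[("a", "MKTVLEMKTV"), ("b", "MKTVLEMKAA")])
        _, d = distance_matrix(aln)
        assert d[0, 1] == pytest.approx(0.2)

    def test_poisson_correction(self):
        aln = Alignment(rows=[("a", "MKTVLEMKTV"), ("b", "MKTVLEMKAA")])
        _, d = distance_matrix(aln, model="poisson")
        assert d[0, 1] == pytest.approx(-np.log(0.8))  # 0.22314...

    def test_no_shared_sites_error(self):
        aln = Alignment(rows=[("a", "MK--"), ("b", "--TV")])
        with pytest.raises(ValueError, match="share no ungapped"):
            distance_matrix(aln)

    def test_saturated_poisson_error(self):
        aln = Alignment(rows=[("a", "MKTV"), ("b", "ACDE")])
        with pytest.raises(ValueError, match="poisson"):
            distance_matrix(aln, model="poisson")


def _unrooted_rf(nw1: str, nw2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nw1, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=nw2, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    for t in (t1, t2):
        t.is_rooted = False
        t.update_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


def _path_distance_matrix(nw: str, labels: list[str]) -> np.ndarray:
    pdm = parse_newick(nw).phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return d


class TestNJ:
    def test_three_taxa(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        t = nj_tree(["A", "B", "C"], d)
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["A", "B", "C"]

    def test_four_taxon_additive_matrix_recovers_topology(self):
        # hand-built from ((A:1,B:2):1,(C:3,D:4):1): dAB=3, dCD=7, dAC=5, ...
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        t = nj_tree(ids, d)
        assert _unrooted_rf(write_newick(t), "((A:1,B:2):1,(C:3,D:4):1);") == 0

    def test_permutation_invariance(self, rng):
        labels = [f"t{i}" for i in range(6)]
        nw = random_binary_newick(rng, labels)
        d = _path_distance_matrix(nw, labels)
        t_ref = nj_tree(labels, d)
        perm = list(rng.permutation(len(labels)))
        labels_p = [labels[i] for i in perm]
        t_perm = nj_tree(labels_p, d[np.ix_(perm, perm)])
        assert _unrooted_rf(write_newick(t_ref), write_newick(t_perm)) == 0

    def test_additive_matrices_recover_generating_topology(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 11))
            labels = [f"t{i}" for i in range(n)]
            nw = random_binary_newick(rng, labels)
            d = _path_distance_matrix(nw, labels)
            t = nj_tree(labels, d)
            assert _unrooted_rf(write_newick(t), nw) == 0

    def test_too_few_taxa_error(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B"], np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------

def brute_force_min_duplications(gene_tree, species_tree, leaf_map) -> int:
    """Exhaustive minimum duplication count over all valid reconciliation
    maps (independent oracle; gene trees must be tiny)."""
    s_nodes = list(species_tree.preorder_node_iter())
    parent = {n: n.parent_node for n in s_nodes}
    depth = {}
    for n in s_nodes:
        depth[n] = 0 if parent[n] is None else depth[parent[n]] + 1
    leaf_by_label = {l.taxon.label: l for l in species_tree.leaf_node_iter()}

    def lca(a, b):
        while depth[a] > depth[b]:
            a = parent[a]
        while depth[b] > depth[a]:
            b = parent[b]
        while a is not b:
            a, b = parent[a], parent[b]
        return a

    def ancestors_or_self(n):
        out = []
        while n is not None:
            out.append(n)
            n = parent[n]
        return out

    g_internal = [n for n in gene_tree.postorder_node_iter() if not n.is_leaf()]
    fixed = {
        n: leaf_by_label[leaf_map[n.taxon.label]]
        for n in gene_tree.leaf_node_iter()
    }
    best = [float("inf")]

    def assign(i, mapping):
        if i == len(g_internal):
            dups = 0
            for n in g_internal:
                l, r = n.child_nodes()
                ml = mapping.get(l, fixed.get(l))
                mr = mapping.get(r, fixed.get(r))
                mv = mapping[n]
                speciation = (
                    mv is lca(ml, mr) and ml is not mv and mr is not mv
                )
                if not speciation:
                    dups += 1
            best[0] = min(best[0], dups)
            return
        node = g_internal[i]
        l, r = node.child_nodes()
        ml = mapping.get(l, fixed.get(l))
        mr = mapping.get(r, fixed.get(r))
        for cand in ancestors_or_self(lca(ml, mr)):
            mapping[node] = cand
            assign(i + 1, mapping)
        del mapping[node]

    assign(0, {})
    return int(best[0])


class TestLcaReconcile:
    def setup_method(self):
        self.stree_nw = "(A:1,B:1);"

    def test_root_duplication_no_losses(self):
        st = parse_newick(self.stree_nw)
        gt = parse_newick("((a1,b1),(a2,b2));")
        r = lca_reconcile(gt, st, {"a1": "A", "b1": "B", "a2": "A", "b2": "B"})
        assert (r.total_duplications, r.total_losses) == (1, 0)

    def test_duplication_with_one_loss(self):
        st = parse_newick(self.stree_nw)
        gt = parse_newick("(a1,(a2,b2));")
        r = lca_reconcile(gt, st, {"a1": "A", "a2": "A", "b2": "B"})
        assert (r.total_duplications, r.total_losses) == (1, 1)
        assert r.loss_branches == ["B"]

    def test_congruent_trees_no_events(self):
        st = parse_newick("((A,B),C);")
        gt = parse_newick("((a,b),c);")
        r = lca_reconcile(gt, st, {"a": "A", "b": "B", "c": "C"})
        assert (r.total_duplications, r.total_losses) == (0, 0)
        assert all(e.event == "speciation" for e in r.events)

    def test_unmapped_leaf_error(self):
        st = parse_newick(self.stree_nw)
        gt = parse_newick("(a1,b1);")
        with pytest.raises(KeyError):
            lca_reconcile(gt, st, {"a1": "A"})

    def test_non_binary_rejected(self):
        st = parse_newick(self.stree_nw)
        gt = parse_newick("(a1,b1,a2);")
        with pytest.raises(ValueError, match="binary"):
            lca_reconcile(gt, st, {"a1": "A", "b1": "B", "a2": "A"})

    def test_duplications_match_brute_force_on_random_trees(self, rng):
        # 200 seeded random gene trees with <= 6 leaves
        for case in range(200):
            n_species = int(rng.integers(2, 5))
            species = [chr(65 + i) for i in range(n_species)]
            st = parse_newick(random_binary_newick(rng, species, with_lengths=False))
            n_leaves = int(rng.integers(2, 7))
            picks = [str(rng.choice(species)) for _ in range(n_leaves)]
            labels = [f"{sp.lower()}{i}" for i, sp in enumerate(picks)]
            gt = parse_newick(random_binary_newick(rng, labels, with_lengths=False))
            leaf_map = dict(zip(labels, picks))
            r = lca_reconcile(gt, st, leaf_map)
            oracle = brute_force_min_duplications(gt, st, leaf_map)
            assert r.total_duplications == oracle, f"case {case}"


# ---------------------------------------------------------------------------
# Clade reports and naming
# ---------------------------------------------------------------------------

class TestCladeAbsence:
    def test_gymnosperms_reported_absent(self):
        st = default_species_tree()
        gt = parse_newick("((Pgr_g1,Ath_g1),Osa_g1);")
        lm = {"Pgr_g1": "Pgr", "Ath_g1": "Ath", "Osa_g1": "Osa"}
        report = clade_absence_report(
            gt, st, lm, {"cladeX": {"Pgr_g1", "Ath_g1", "Osa_g1"}}, TAXON_GROUPS
        )
        assert report == [("cladeX", ["gymnosperms", "bryophytes"])]

    def test_full_coverage_empty(self):
        st = parse_newick("(A:1,B:1);")
        gt = parse_newick("(a,b);")
        report = clade_absence_report(
            gt, st, {"a": "A", "b": "B"}, {"all": {"a", "b"}},
            {"grp": {"A", "B"}},
        )
        assert report == [("all", [])]

    def test_empty_clade_sets_empty_report(self):
        st = parse_newick("(A:1,B:1);")
        gt = parse_newick("(a,b);")
        assert clade_absence_report(gt, st, {"a": "A", "b": "B"}, {}, TAXON_GROUPS) == []


class TestOrthologNaming:
    def test_sister_to_reference(self):
        gt = parse_newick("((q1,AtC),(AtG,other));")
        names = assign_ortholog_names(gt, {"AtC": "CLC-C", "AtG": "CLC-G"}, ["q1"])
        assert names["q1"] == "CLC-C"

    def test_same_species_duplicates_suffixed_in_tree_order(self):
        gt = parse_newick("(((q2,q1),AtC),out);")
        names = assign_ortholog_names(
            gt,
            {"AtC": "CLC-C", "out": "CLC-Z"},
            ["q1", "q2"],
            leaf_map={"q1": "Pgr", "q2": "Pgr"},
        )
        # q2 precedes q1 in tree order
        assert names == {"q2": "CLC-C1", "q1": "CLC-C2"}

    def test_equal_mix_is_ambiguous(self):
        gt = parse_newick("((AtC,AtG),q1);")
        names = assign_ortholog_names(gt, {"AtC": "CLC-C", "AtG": "CLC-G"}, ["q1"])
        assert names["q1"] == "ambiguous"

    def test_majority_wins(self):
        gt = parse_newick("(((AtC1,AtC2),AtG),q1);")
        names = assign_ortholog_names(
            gt, {"AtC1": "CLC-C", "AtC2": "CLC-C", "AtG": "CLC-G"}, ["q1"]
        )
        assert names["q1"] == "CLC-C"

    def test_no_references_error(self):
        gt = parse_newick("(a,b);")
        with pytest.raises(ValueError):
            assign_ortholog_names(gt, {"zz": "CLC-A"}, ["a"])
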