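import math

import numpy as np
import pytest

from foxsurvey.msa import MultipleAlignment
from foxsurvey.phylo import (
    DistanceMatrix,
    PhyloTree,
    SaturationError,
    bootstrap_support,
    clade_support,
    distances,
    neighbor_joining,
)


def random_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """Random binary tree -> exact leaf path-length matrix + true splits."""
    import itertools

    from skbio import TreeNode

    names = [f"t{i}" for i in range(n_taxa)]
    lineages = [TreeNode(name=x) for x in names]
    for node in lineages:
        node.length = float(rng.uniform(0.1, 1.0))
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b, a = lineages.pop(j), lineages.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.1, 1.0))
        lineages.append(parent)
    root = lineages[0]
    tips = {t.name: t for t in root.tips()}
    d = np.zeros((n_taxa, n_taxa))
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        d[i, j] = d[j, i] = tips[a].distance(tips[b])
    true_splits = PhyloTree(root=root).bipartitions().keys()
    return DistanceMatrix(ids=names, d=d), set(true_splits)


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["MKVL", "MKVL"])
        assert distances(msa).d[0, 1] == 0.0

    def test_p_distance_counts_mismatches_over_gapfree_columns(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAACCCCC"])
        assert distances(msa, model="p").d[0, 1] == 0.5

    def test_poisson_correction_closed_form(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAACCCCC"])
        assert math.isclose(distances(msa, model="poisson").d[0, 1], 0.693147, abs_tol=1e-6)

    def test_pairwise_deletion_ignores_gapped_columns(self):
        msa = MultipleAlignment(ids=["a", "b", "c"], rows=["AC-A", "ACCA", "TCCA"])
        d = distances(msa, model="p")
        assert d.d[0, 1] == 0.0  # gap column skipped for this pair

    def test_saturated_pair_raises_under_poisson(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["AAAA", "CCCC"])
        with pytest.raises(SaturationError):
            distances(msa, model="poisson")

    def test_no_comparable_columns_names_the_pair(self):
        msa = MultipleAlignment(ids=["a", "b", "c"], rows=["AA--", "--CC", "AAAA"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distances(msa, model="p")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_four_taxon_additive_matrix_recovers_tree(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        splits = set(tree.bipartitions().keys())
        assert splits == {frozenset({"C", "D"})}  # the AB|CD split
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internal = [n.length for n in tree.root.non_tips()]
        assert internal == [1.0]

    def test_two_taxa_trivial_tree(self):
        tree = neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 2], [2, 0]], float)))
        assert sorted(tree.leaf_names()) == ["a", "b"]

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            dm, true_splits = random_additive_matrix(int(rng.integers(4, 9)), rng)
            got = set(neighbor_joining(dm).bipartitions().keys())
            assert got == true_splits

    def test_agrees_with_skbio_on_additive_input(self):
        import skbio

        rng = np.random.default_rng(9)
        for _ in range(5):
            dm, true_splits = random_additive_matrix(6, rng)
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.ids))
            sk_splits = set(PhyloTree(root=sk_tree).bipartitions().keys())
            ours = set(neighbor_joining(dm).bipartitions().keys())
            # both implementations must recover the generating topology
            assert ours == true_splits
            assert sk_splits == true_splits

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


def _two_cluster_alignment(n_diagnostic: int = 200):
    """Two clearly separated 4-leaf clusters with diagnostic columns."""
    a_block = "A" * n_diagnostic
    c_block = "C" * n_diagnostic
    rows = []
    ids = []
    rng = np.random.default_rng(1)
    for k in range(4):
        noise = "".join(rng.choice(list("DEFG"), size=10))
        ids.append(f"x{k}")
        rows.append(a_block + noise)
    for k in range(4):
        noise = "".join(rng.choice(list("DEFG"), size=10))
        ids.append(f"y{k}")
        rows.append(c_block + noise)
    return MultipleAlignment(ids=ids, rows=rows)


class TestBootstrap:
    def test_unambiguous_split_supported_at_100(self):
        msa = _two_cluster_alignment()
        tree = bootstrap_support(msa, n_replicates=100, seed=1)
        central = frozenset(f"y{k}" for k in range(4))
        bips = tree.bipartitions()
        assert central in bips
        assert bips[central].support == 100.0

    def test_supports_bounded_and_deterministic(self, small_family):
        from foxsurvey.msa import progressive_align

        domains = [small_family.domain_of(o) for o in sorted(small_family.labels)][:6]
        msa = progressive_align(domains)
        t1 = bootstrap_support(msa, n_replicates=30, seed=7)
        t2 = bootstrap_support(msa, n_replicates=30, seed=7)
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())

    def test_zero_replicates_is_error(self):
        with pytest.raises(ValueError):
            bootstrap_support(_two_cluster_alignment(20), n_replicates=0, seed=0)


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self):
        msa = _two_cluster_alignment(50)
        tree = bootstrap_support(msa, n_replicates=20, seed=3)
        back = PhyloTree.from_newick(tree.to_newick())
        assert set(back.leaf_names()) == set(tree.leaf_names())
        assert set(back.bipartitions().keys()) == set(tree.bipartitions().keys())
        orig = {t.name: t.length for t in tree.root.tips()}
        reread = {t.name: round(t.length, 6) for t in back.root.tips()}
        assert reread == {k: round(v, 6) for k, v in orig.items()}
        sup_orig = {k: n.support for k, n in tree.bipartitions().items()}
        sup_back = {k: getattr(n, "support", None) for k, n in back.bipartitions().items()}
        assert sup_back == sup_orig


class TestCladeSupport:
    @staticmethod
    def _tree(newick: str) -> PhyloTree:
        return PhyloTree.from_newick(newick)

    def test_query_inside_target_pair_groups_with_full_support(self):
        tree = self._tree("((query:1,refJ1:1)100:1,refJ2:1,(refN3:1,refD2:1)90:1);")
        grouped, support = clade_support(
            tree, "query", {"refJ1"}, {"refJ2", "refN3", "refD2"}
        )
        assert grouped
        assert support == 100.0

    def test_query_nested_in_other_subfamily_not_grouped(self):
        tree = self._tree("((query:1,refJ2:1)98:1,refJ1:1,(refN3:1,refD2:1)90:1);")
        grouped, support = clade_support(
            tree, "query", {"refJ1"}, {"refJ2", "refN3", "refD2"}
        )
        assert not grouped
        assert support is None

    def test_weakly_supported_grouping_reported_as_is(self):
        # grouping present but with low bootstrap: reported (True, 49);
        # the classifier downstream will not call this definite
        tree = self._tree("((query:1,refJ1:1)49:1,refJ2:1,(refN3:1,refD2:1)90:1);")
        grouped, support = clade_support(
            tree, "query", {"refJ1"}, {"refJ2", "refN3", "refD2"}
        )
        assert grouped
        assert support == 49.0

    def test_missing_query_is_error(self):
        tree = self._tree("((a:1,b:1):1,c:1,d:1);")
        with pytest.raises(ValueError, match="query"):
            clade_support(tree, "nope", {"a"}, {"c"})
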