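"""Tree I/O, BLADJ calibration, Faith's PD, MPD, and the tip-shuffle NRI,
each checked against an independent brute-force computation."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from gridphylo.gridding import CommunityMatrix
from gridphylo.phylo import (
    bladj_calibrate,
    faith_pd,
    mpd,
    nri,
    parse_newick,
    patristic_matrix,
    write_newick,
)
from gridphylo.simulate import simulate_yule_tree


# ---------------------------------------------------------------------------
# independent oracles

def patristic_oracle(tree, a, b):
    """Path-sum distance via each tip's root path (edge set symmetric difference)."""
    def root_path(label):
        node = next(l for l in tree.leaf_node_iter() if l.taxon.label == label)
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return path

    pa, pb = root_path(a), root_path(b)
    shared = {id(n) for n in pa} & {id(n) for n in pb}
    return sum(
        (n.edge.length or 0.0) for n in pa + pb if id(n) not in shared
    )


def faith_pd_oracle(tree, taxa):
    """Union of root-ward edge sets, truncated at the taxa's MRCA."""
    taxa = list(taxa)
    if len(taxa) < 2:
        return 0.0
    mrca = tree.mrca(taxon_labels=taxa)
    edges = {}
    for label in taxa:
        node = next(l for l in tree.leaf_node_iter() if l.taxon.label == label)
        while node is not mrca:
            edges[id(node)] = node.edge.length or 0.0
            node = node.parent_node
    return sum(edges.values())


def mpd_oracle(tree, taxa):
    taxa = list(taxa)
    ds = [patristic_oracle(tree, a, b) for a, b in itertools.combinations(taxa, 2)]
    return sum(ds) / len(ds)


# ---------------------------------------------------------------------------

class TestNewickIO:
    def test_two_tip_parse(self):
        tree = parse_newick("(A:1,B:1);")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B"]
        assert all(l.edge.length == 1.0 for l in tree.leaf_node_iter())

    def test_hand_patristic_distance(self):
        tree = parse_newick("((A:1,B:1):0.5,C:1.5);")
        labels, d = patristic_matrix(tree)
        assert d[labels.index("A"), labels.index("C")] == pytest.approx(3.0)

    def test_round_trip_preserves_distances(self):
        tree = simulate_yule_tree(100, 1.0, seed=8)
        again = parse_newick(write_newick(tree))
        l1, d1 = patristic_matrix(tree)
        l2, d2 = patristic_matrix(again)
        assert l1 == l2
        assert np.allclose(d1, d2, atol=1e-12)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(A:1,A:1);")

    def test_malformed_newick_raises(self):
        with pytest.raises(Exception):
            parse_newick("((A:1,B:1;")


class TestBladj:
    def test_single_undated_node_is_placed_halfway(self):
        tree = parse_newick("((tip:1)X:1)root;")
        out = bladj_calibrate(tree, {"root": 10.0})
        node = {n.label: n for n in out.preorder_node_iter() if n.label}
        assert node["X"].edge.length == pytest.approx(5.0)  # root(10) -> X(5)
        tip = next(out.leaf_node_iter())
        assert tip.edge.length == pytest.approx(5.0)        # X(5) -> tip(0)

    def test_fully_dated_tree_uses_exact_age_differences(self):
        tree = parse_newick("((A:1,B:1)X:1,C:2)root;")
        out = bladj_calibrate(tree, {"root": 12.0, "X": 4.0})
        lengths = {
            (n.label or n.taxon.label): n.edge.length
            for n in out.preorder_node_iter()
            if n.parent_node is not None
        }
        assert lengths["X"] == pytest.approx(8.0)
        assert lengths["A"] == pytest.approx(4.0)
        assert lengths["C"] == pytest.approx(12.0)

    def test_child_older_than_parent_rejected(self):
        tree = parse_newick("((A:1,B:1)X:1,C:2)root;")
        with pytest.raises(ValueError, match="calibration"):
            bladj_calibrate(tree, {"root": 5.0, "X": 9.0})

    def test_missing_root_age_rejected(self):
        tree = parse_newick("((A:1,B:1)X:1,C:2)root;")
        with pytest.raises(ValueError, match="root"):
            bladj_calibrate(tree, {"X": 3.0})

    def test_random_partial_calibration_matches_chain_walk_oracle(self):
        """Every undated node sits evenly between its nearest dated
        ancestor and nearest dated descendant (ties -> oldest)."""
        rng = np.random.default_rng(17)
        tree = simulate_yule_tree(20, 1.0, seed=17)
        internals = [n for n in tree.preorder_internal_node_iter()]
        for i, node in enumerate(internals):
            node.label = f"n{i}"
        root_age = 50.0
        ages = {"n0": root_age}
        # date a random subset with ages consistent with the topology
        depth = {}
        for node in tree.preorder_node_iter():
            depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1
        for node in internals[1:]:
            if rng.random() < 0.4:
                parent_ages = [root_age]
                ages[node.label] = root_age * 0.95 ** depth[id(node)] * rng.uniform(0.3, 0.9)
        # make the age table topologically consistent by clipping child <= parent
        for node in tree.preorder_node_iter():
            lab = getattr(node, "label", None)
            if lab in ages and node.parent_node is not None:
                anc = node.parent_node
                while anc is not None:
                    if anc.label in ages:
                        ages[lab] = min(ages[lab], ages[anc.label] * 0.99)
                        break
                    anc = anc.parent_node

        out = bladj_calibrate(tree, ages)
        node_age = {}
        for n in out.postorder_node_iter():
            if n.is_leaf():
                node_age[id(n)] = 0.0
            else:
                child = n.child_nodes()[0]
                node_age[id(n)] = node_age[id(child)] + child.edge.length

        # oracle: walk each undated node's chain independently
        for n in out.preorder_node_iter():
            if n.is_leaf() or n.label in ages or n.parent_node is None:
                continue
            up, du = n.parent_node, 1
            while up.label not in ages and up.parent_node is not None:
                up, du = up.parent_node, du + 1
            # ancestor age as calibrated (may itself be interpolated)
            anc_age = node_age[id(n.parent_node)]
            dated = []
            stack = [(c, 1) for c in n.child_nodes()]
            while stack:
                m, d = stack.pop()
                lab = m.taxon.label if m.is_leaf() else m.label
                if m.is_leaf() or lab in ages:
                    dated.append((d, 0.0 if m.is_leaf() else ages[lab]))
                else:
                    stack.extend((c, d + 1) for c in m.child_nodes())
            dmin = min(d for d, _ in dated)
            amax = max(a for d, a in dated if d == dmin)
            expected = anc_age - (anc_age - amax) / (dmin + 1)
            assert node_age[id(n)] == pytest.approx(expected, abs=1e-9)

    def test_all_tips_at_zero_gives_ultrametric_output(self):
        tree = simulate_yule_tree(15, 1.0, seed=5)
        for i, n in enumerate(tree.preorder_internal_node_iter()):
            n.label = f"n{i}"
        out = bladj_calibrate(tree, {"n0": 100.0})
        depths = [t.distance_from_root() for t in out.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9


class TestFaithPD:
    def test_all_tips_equals_total_tree_length(self):
        tree = simulate_yule_tree(25, 1.0, seed=2)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        total = sum(
            (n.edge.length or 0.0) for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        assert faith_pd(tree, tips) == pytest.approx(total, abs=1e-9)

    def test_single_taxon_is_zero(self):
        tree = parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert faith_pd(tree, ["A"]) == 0.0
        assert faith_pd(tree, []) == 0.0

    def test_stem_flag_adds_the_mrca_edge(self):
        tree = parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert faith_pd(tree, ["A", "B"]) == pytest.approx(2.0)
        assert faith_pd(tree, ["A", "B"], include_stem=True) == pytest.approx(2.5)

    def test_unknown_taxon_raises(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            faith_pd(tree, ["Z"])

    def test_random_subsets_match_edge_union_oracle(self):
        rng = np.random.default_rng(9)
        tree = simulate_yule_tree(20, 1.0, seed=9)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        for _ in range(50):
            sub = list(rng.choice(tips, size=5, replace=False))
            assert faith_pd(tree, sub) == pytest.approx(
                faith_pd_oracle(tree, sub), abs=1e-10
            )


class TestMPD:
    def test_two_taxa_is_their_distance(self):
        tree = parse_newick("((A:1,B:1):0.5,C:1.5);")
        labels, d = patristic_matrix(tree)
        assert mpd(d, labels, ["A", "C"]) == pytest.approx(3.0)

    def test_star_tree_unit_branches(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        labels, d = patristic_matrix(tree)
        for k in (2, 3, 5):
            assert mpd(d, labels, labels[:k]) == pytest.approx(2.0)

    def test_fewer_than_two_taxa_signalled(self):
        tree = parse_newick("(A:1,B:1);")
        labels, d = patristic_matrix(tree)
        with pytest.raises(ValueError):
            mpd(d, labels, ["A"])

    def test_random_subsets_match_double_loop(self):
        rng = np.random.default_rng(4)
        tree = simulate_yule_tree(18, 1.0, seed=4)
        labels, d = patristic_matrix(tree)
        for _ in range(50):
            k = int(rng.integers(2, 10))
            sub = list(rng.choice(labels, size=k, replace=False))
            assert mpd(d, labels, sub) == pytest.approx(
                mpd_oracle(tree, sub), abs=1e-10
            )


def _matrix(cells: dict[str, list[str]], species: list[str]) -> CommunityMatrix:
    data = pd.DataFrame(0, index=list(cells), columns=species)
    for c, present in cells.items():
        data.loc[c, present] = 1
    return CommunityMatrix(data)


class TestNRI:
    def test_default_iteration_count_is_999(self):
        import inspect

        assert inspect.signature(nri).parameters["n_iter"].default == 999

    def test_full_pool_community_is_flagged(self, two_clade_tree):
        species = [l.taxon.label for l in two_clade_tree.leaf_node_iter()]
        m = _matrix({"c1": species}, species)
        out = nri(m, two_clade_tree, n_iter=99, seed=0)
        assert np.isnan(out.loc["c1", "nri"])
        assert out.loc["c1", "n_taxa"] == 8

    def test_single_species_cell_is_flagged(self, two_clade_tree):
        species = [l.taxon.label for l in two_clade_tree.leaf_node_iter()]
        m = _matrix({"c1": ["a"], "c2": ["a", "b", "c"]}, species)
        out = nri(m, two_clade_tree, n_iter=99, seed=0)
        assert np.isnan(out.loc["c1", "nri"])
        assert np.isfinite(out.loc["c2", "nri"])

    def test_clade_community_clusters_and_spanning_community_overdisperses(
        self, two_clade_tree
    ):
        species = [l.taxon.label for l in two_clade_tree.leaf_node_iter()]
        m = _matrix({"clade": ["a", "b", "c", "d"], "span": ["a", "c", "e", "g"]}, species)
        out = nri(m, two_clade_tree, n_iter=999, seed=1)
        assert out.loc["clade", "nri"] > 0
        assert out.loc["span", "nri"] < 0

    def test_null_moments_match_exhaustive_permutation_enumeration(self):
        """On a 6-tip tree the sampled null mean/SD of a pair community must
        agree with the exact moments over all label permutations."""
        tree = parse_newick("(((a:1,b:1):1,c:2):3,((d:1,e:1):1,f:2):3);")
        labels, dist = patristic_matrix(tree)
        m = _matrix({"c1": ["a", "b"]}, labels)
        # exhaustive: a pair community under label shuffling is a uniform
        # draw of an unordered pair of distinct tips
        pair_ds = [dist[i, j] for i in range(6) for j in range(i + 1, 6)]
        exact_mean = np.mean(pair_ds)
        exact_sd = np.std(pair_ds, ddof=0)
        out = nri(m, tree, n_iter=2999, seed=3)
        se = exact_sd / np.sqrt(2999)
        assert out.loc["c1", "null_mean"] == pytest.approx(exact_mean, abs=4 * se)
        assert out.loc["c1", "null_sd"] == pytest.approx(exact_sd, rel=0.1)

    def test_missing_species_reported(self, two_clade_tree):
        m = _matrix({"c1": ["zz"]}, ["zz"])
        with pytest.raises(KeyError, match="zz"):
            nri(m, two_clade_tree, n_iter=9, seed=0)

    def test_fixed_seed_reproducible_to_full_precision(self, two_clade_tree):
        species = [l.taxon.label for l in two_clade_tree.leaf_node_iter()]
        m = _matrix({"c1": ["a", "b", "e"], "c2": ["a", "d", "f", "g"]}, species)
        a = nri(m, two_clade_tree, n_iter=199, seed=11)
        b = nri(m, two_clade_tree, n_iter=199, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_sign_convention_positive_means_clustered(self, two_clade_tree):
        """mpd_obs below the null mean (close relatives) must give NRI > 0."""
        species = [l.taxon.label for l in two_clade_tree.leaf_node_iter()]
        m = _matrix({"c1": ["a", "b"]}, species)
        out = nri(m, two_clade_tree, n_iter=499, seed=5)
        assert out.loc["c1", "mpd_obs"] < out.loc["c1", "null_mean"]
        assert out.loc["c1", "nri"] > 0
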