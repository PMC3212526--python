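import itertools

import dendropy
import numpy as np
import pytest

from bhlh_survey.phylo import (
    BootstrapConfig,
    DistanceMatrix,
    PhyloError,
    bootstrap_support,
    edge_bipartitions,
    is_monophyletic,
    max_parsimony,
    ml_surrogate_distances,
    neighbor_joining,
    pairwise_distances,
    pam250_step_matrix,
    read_newick,
    write_newick,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# oracles


def random_additive(n, rng):
    """Pair-distance matrix of a random tree with positive branch lengths."""
    D = np.zeros((n, n))
    active = {i: frozenset([i]) for i in range(n)}
    # grow a tree recording distances explicitly
    dists = {}

    def d(a, b):
        return dists[frozenset((a, b))]

    clusters = [frozenset([i]) for i in range(n)]
    depth = {frozenset([i]): 0.0 for i in range(n)}
    bips = []
    while len(clusters) > 2:
        idx = sorted(rng.choice(len(clusters), 2, replace=False))
        a, b = clusters[idx[0]], clusters[idx[1]]
        la = float(rng.uniform(0.5, 3.0))
        lb = float(rng.uniform(0.5, 3.0))
        for x in a:
            for y in b:
                D[x, y] = D[y, x] = depth_of(a, x, depth, dists) + la \
                    + depth_of(b, y, depth, dists) + lb
        merged = a | b
        dists[merged] = (la, lb, a, b)
        depth[merged] = 0.0
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
        if 2 <= len(merged) <= n - 2:
            bips.append(merged)
    a, b = clusters
    if 2 <= len(a) <= n - 2:
        bips.append(a)
    lab = float(rng.uniform(0.5, 3.0))
    for x in a:
        for y in b:
            D[x, y] = D[y, x] = depth_of(a, x, depth, dists) + lab \
                + depth_of(b, y, depth, dists)
    return D, bips


def depth_of(cluster, leaf, depth, dists):
    """Distance from *leaf* up to the root of *cluster*."""
    if len(cluster) == 1:
        return 0.0
    la, lb, a, b = dists[cluster]
    if leaf in a:
        return la + depth_of(a, leaf, depth, dists)
    return lb + depth_of(b, leaf, depth, dists)


def enumerate_topologies(n):
    """All unrooted binary topologies over taxa 0..n-1 as rooted nested
    tuples with taxon 0 at the top (independent enumerator)."""
    def grow(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            for g in grow(t[0], leaf):
                yield (g, t[1])
            for g in grow(t[1], leaf):
                yield (t[0], g)

    tops = [(0, 1)]
    for leaf in range(2, n):
        tops = [g for t in tops for g in grow(t, leaf)]
    return tops


def fitch_len(topology, cols):
    """Plain set-based Fitch length over columns (independent oracle)."""
    total = 0

    def post(node, col):
        nonlocal total
        if isinstance(node, int):
            return {col[node]}
        l, r = post(node[0], col), post(node[1], col)
        inter = l & r
        if inter:
            return inter
        total += 1
        return l | r

    for col in cols:
        post(topology, col)
    return total


# ---------------------------------------------------------------------------
# distances


def test_distance_identity_zero_and_symmetry(rng):
    seqs = ["".join(np.array(list(AA))[rng.integers(0, 20, 40)])
            for _ in range(6)]
    dm = pairwise_distances([f"t{i}" for i in range(6)], seqs)
    assert np.allclose(np.diag(dm.d), 0.0)
    assert np.allclose(dm.d, dm.d.T)
    assert dm.d[0, 0] == 0.0


def test_distances_match_columnwise_cost_oracle(rng):
    """Distances equal a direct per-column cost summation over non-gap
    column pairs, normalised by compared columns."""
    cost = pam250_step_matrix()
    alpha = "ACDEFGHIKLMNPQRSTVWYX"
    for _ in range(10):
        a = list("".join(np.array(list(AA))[rng.integers(0, 20, 30)]))
        b = list("".join(np.array(list(AA))[rng.integers(0, 20, 30)]))
        for pos in rng.integers(0, 30, 4):
            a[pos] = "-"
        dm = pairwise_distances(["a", "b"], ["".join(a), "".join(b)])
        tot, ncmp = 0.0, 0
        for x, y in zip(a, b):
            if x == "-" or y == "-":
                continue
            tot += cost[alpha.index(x), alpha.index(y)]
            ncmp += 1
        assert dm.d[0, 1] == pytest.approx(tot / ncmp)


def test_all_gap_pair_raises():
    with pytest.raises(PhyloError, match="no"):
        pairwise_distances(["a", "b"], ["A---", "-CC-"])


def test_ml_surrogate_distance_closed_form():
    # 10 of 40 sites differ: d = -(19/20) ln(1 - 20*0.25/19)
    a = "A" * 40
    b = "C" * 10 + "A" * 30
    dm = ml_surrogate_distances(["a", "b"], [a, b])
    p = 0.25
    assert dm.d[0, 1] == pytest.approx(-(19 / 20) * np.log(1 - 20 * p / 19))


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_three_taxa_closed_form():
    D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), D))
    lens = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lens["a"] == pytest.approx(0.5 * (3 + 4 - 5))
    assert lens["b"] == pytest.approx(0.5 * (3 + 5 - 4))
    assert lens["c"] == pytest.approx(0.5 * (4 + 5 - 3))


def test_nj_recovers_random_additive_trees_exactly():
    """On additive matrices NJ returns the generating topology with exact
    branch lengths (checked via path distances), for 100 random trees."""
    rng = np.random.default_rng(7)
    for trial in range(100):
        n = int(rng.integers(4, 11))
        D, bips = random_additive(n, rng)
        labels = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(tuple(labels), D))
        got = {
            frozenset(int(x[1:]) for x in side)
            for side in edge_bipartitions(tree, anchor="t0")
            if 1 < len(side) < n - 1
        }
        expected = {
            b if 0 not in b else frozenset(range(n)) - b for b in bips
        }
        expected = {b for b in expected if 1 < len(b) < n - 1}
        assert got == expected, trial
        pdm = tree.phylogenetic_distance_matrix()
        tn = tree.taxon_namespace
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm.distance(
                    tn.get_taxon(f"t{i}"), tn.get_taxon(f"t{j}")
                ) == pytest.approx(D[i, j], abs=1e-8), trial


def test_nj_agrees_with_scikit_bio_on_additive_matrices():
    """Independent cross-check against scikit-bio's neighbor joining."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(3)
    for _ in range(5):
        n = 7
        D, _ = random_additive(n, rng)
        labels = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(DistanceMatrix(tuple(labels), D))
        theirs = sk_nj(SkDM(D, labels))
        mine_bips = {
            frozenset(s)
            for s in edge_bipartitions(mine, anchor="t0")
            if 1 < len(s) < n - 1
        }
        their_bips = set()
        for node in theirs.non_tips():
            tips = frozenset(t.name for t in node.tips())
            side = tips if "t0" not in tips else (
                frozenset(labels) - tips
            )
            if 1 < len(side) < n - 1:
                their_bips.add(side)
        assert mine_bips == their_bips


def test_nj_four_point_condition_quartet():
    """A matrix satisfying the four-point condition resolves to the quartet
    with the smallest sum, out of the three possibilities."""
    labels = ("a", "b", "c", "d")
    # ab|cd: d(a,b)+d(c,d) < d(a,c)+d(b,d) = d(a,d)+d(b,c)
    D = np.array([
        [0.0, 2.0, 6.0, 6.0],
        [2.0, 0.0, 6.0, 6.0],
        [6.0, 6.0, 0.0, 2.0],
        [6.0, 6.0, 2.0, 0.0],
    ])
    sums = {
        "ab|cd": D[0, 1] + D[2, 3],
        "ac|bd": D[0, 2] + D[1, 3],
        "ad|bc": D[0, 3] + D[1, 2],
    }
    assert min(sums, key=sums.get) == "ab|cd"
    tree = neighbor_joining(DistanceMatrix(labels, D))
    assert frozenset({"c", "d"}) in edge_bipartitions(tree, anchor="a")


def test_nj_requires_three_taxa():
    with pytest.raises(PhyloError):
        neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# maximum parsimony


def test_mp_four_taxa_hand_countable():
    """Sites supporting the a,b | c,d split: minimum length is hand
    countable (3 constant-ish columns of one change plus one homoplasy)."""
    labels = ["a", "b", "c", "d"]
    seqs = ["AAAA", "AAAC", "CCCA", "CCCC"]
    tree, length = max_parsimony(labels, seqs)
    assert length == 5  # 3 columns x 1 step + 1 column x 2 steps
    assert frozenset({"a", "b"}) in edge_bipartitions(tree, anchor="d")


def test_mp_equals_exhaustive_enumeration_six_taxa(rng):
    """Branch-and-bound length equals a brute-force minimum over all 105
    unrooted six-taxon topologies scored by an independent Fitch."""
    for _ in range(5):
        n = 6
        seqs = ["".join(np.array(list("ACDE"))[rng.integers(0, 4, 12)])
                for _ in range(n)]
        labels = [f"t{i}" for i in range(n)]
        _, length = max_parsimony(labels, seqs)
        cols = [tuple(s[c] for s in seqs) for c in range(12)]
        tops = enumerate_topologies(n)
        # 945 rooted topologies = each of the 105 unrooted ones rooted on
        # each of its 9 edges; Fitch length is rooting-invariant
        assert len(tops) == 945
        brute = min(fitch_len(t, cols) for t in tops)
        assert length == brute


def test_mp_duplicate_taxon_adds_no_length(rng):
    seqs = ["".join(np.array(list("ACDE"))[rng.integers(0, 4, 15)])
            for _ in range(5)]
    labels = [f"t{i}" for i in range(5)]
    _, base = max_parsimony(labels, seqs)
    _, dup = max_parsimony(labels + ["t5"], seqs + [seqs[0]])
    assert dup == base


def test_mp_rejects_too_many_taxa():
    with pytest.raises(PhyloError, match="max_taxa"):
        max_parsimony([f"t{i}" for i in range(13)], ["A"] * 13)


# ---------------------------------------------------------------------------
# monophyly


def _random_tree(n, rng):
    labels = [f"t{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree.seed_node = root
    return tree, labels


def test_monophyly_cherry_and_root_clade(rep_set):
    tree = read_newick("((cand,partner),(x,(y,outg)));")
    assert is_monophyletic(tree, ["cand", "partner"], outgroup="outg")
    assert is_monophyletic(tree, ["cand", "partner", "x", "y"],
                           outgroup="outg")
    assert not is_monophyletic(tree, ["cand", "x"], outgroup="outg")


def test_monophyly_agrees_with_clade_enumeration(rng):
    """On random 8-leaf trees the test agrees with brute-force enumeration
    of rooted clades for every subset of size 2-4."""
    for _ in range(20):
        tree, labels = _random_tree(8, rng)
        outg = labels[int(rng.integers(8))]
        # brute-force: reroot mentally by listing, for every edge, the side
        # away from the outgroup
        clades = set()
        all_set = frozenset(labels)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            below = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            clades.add(below if outg not in below else all_set - below)
        others = [l for l in labels if l != outg]
        for size in (2, 3, 4):
            for taxa in itertools.combinations(others, size):
                assert is_monophyletic(tree, taxa, outg) == (
                    frozenset(taxa) in clades
                )


def test_monophyly_requires_outgroup():
    tree = read_newick("((a,b),(c,d));")
    with pytest.raises(PhyloError, match="outgroup"):
        is_monophyletic(tree, ["a", "b"], outgroup="zz")


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_two_clean_clades_full_support():
    """Two clearly separated clades of near-identical sequences put 100 on
    the separating edge."""
    # the two clades differ radically (Ala-rich vs Trp-rich); members of a
    # clade differ by one conservative D->E change
    labels = ["a1", "a2", "b1", "b2", "outg"]
    seqs = [
        "AAAAAAAAAADDDDD",
        "AAAAAAAAAADDDDE",
        "WWWWWWWWWWDDDDD",
        "WWWWWWWWWWDDDDE",
        "HHHHHHHHHHPPPPP",
    ]
    _, support = bootstrap_support(
        labels, seqs, "NJ", BootstrapConfig(200, 5), anchor="outg"
    )
    assert support[frozenset({"a1", "a2"})] == 100.0
    assert support[frozenset({"b1", "b2"})] == 100.0


@pytest.mark.parametrize("builder", ["NJ", "MP", "ML-surrogate"])
def test_bootstrap_deterministic_for_fixed_seed(rng, builder):
    labels = [f"t{i}" for i in range(6)]
    seqs = ["".join(np.array(list(AA))[rng.integers(0, 20, 30)])
            for _ in range(6)]
    _, s1 = bootstrap_support(labels, seqs, builder, BootstrapConfig(60, 42))
    _, s2 = bootstrap_support(labels, seqs, builder, BootstrapConfig(60, 42))
    assert s1 == s2


def test_bootstrap_supports_bounded_and_stable_at_high_replicates(rng):
    """200-replicate supports sit within 5 points of a 10,000-replicate
    reference run on the same data (self-oracle at high replicates)."""
    labels = [f"t{i}" for i in range(5)]
    base = "".join(np.array(list(AA))[rng.integers(0, 20, 40)])

    def mut(s, k, seed):
        r = np.random.default_rng(seed)
        s = list(s)
        for pos in r.choice(len(s), k, replace=False):
            s[pos] = AA[int(r.integers(20))]
        return "".join(s)

    seqs = [base, mut(base, 3, 1), mut(base, 12, 2), mut(base, 14, 3),
            mut(base, 25, 4)]
    _, s_small = bootstrap_support(labels, seqs, "NJ",
                                   BootstrapConfig(200, 11))
    _, s_big = bootstrap_support(labels, seqs, "NJ",
                                 BootstrapConfig(10_000, 12))
    for bip in set(s_small) | set(s_big):
        a = s_small.get(bip, 0.0)
        b = s_big.get(bip, 0.0)
        if min(a, b) > 5:  # compare meaningful splits only
            assert abs(a - b) <= 5.0, bip
        assert 0.0 <= a <= 100.0


def test_newick_round_trip_preserves_topology_lengths_supports():
    labels = ["a", "b", "c", "d", "e"]
    seqs = ["AAAAAAAA", "AAAAAAAC", "CCCCCCCC", "CCCCCCCA", "GGGGGGGG"]
    tree, _ = bootstrap_support(labels, seqs, "NJ", BootstrapConfig(50, 1),
                                anchor="e")
    text = write_newick(tree)
    back = read_newick(text)
    assert write_newick(back) == text
    assert edge_bipartitions(back, anchor="e") == edge_bipartitions(
        tree, anchor="e"
    )
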