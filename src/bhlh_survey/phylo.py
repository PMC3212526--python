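"""Phylogenetic substrate: distances, neighbor joining, bootstrap, parsimony.

Distances between aligned amino-acid motifs are computed with a symmetric
step-matrix cost table derived from the Dayhoff PAM250 log-odds matrix
(``cost(a,b) = (S(a,a)+S(b,b))/2 - S(a,b)``, so identities cost zero),
normalised per compared column.  Trees are neighbor-joining with a
deterministic smallest-index tie-break; statistical support comes from
bootstrap resampling of alignment columns.  Maximum parsimony is an exact
branch-and-bound minimisation of the Fitch length, practical for the small
in-group trees this survey builds (a dozen taxa or fewer).  A third,
likelihood-flavoured route ("ML-surrogate") applies neighbor joining to
maximum-likelihood distances under the 20-state equal-frequency Markov
model, d = -(19/20) ln(1 - 20p/19).

Trees are dendropy objects throughout; Newick round-trips preserve topology,
branch lengths and internal-node support labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
GAP = "-"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cost model


def pam250_step_matrix() -> np.ndarray:
    """Symmetric integer step-matrix over ALPHABET derived from PAM250.

    The historical step matrix used with parsimony/distance software is a
    cost table in which similar residues cost little and dissimilar residues
    cost much; inverting the sign of the log-odds score and shifting so the
    diagonal is zero reproduces that structure:
    ``cost(a, b) = (S(a,a) + S(b,b)) / 2 - S(a,b)``.
    """
    S = substitution_matrices.load("PAM250")
    n = len(ALPHABET)
    C = np.zeros((n, n))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            C[i, j] = (S[a, a] + S[b, b]) / 2.0 - S[a, b]
    return C


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise PhyloError("non-finite distances")
        if not np.allclose(d, d.T):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise PhyloError("distance matrix diagonal not zero")

    def __len__(self) -> int:
        return len(self.labels)


def encode_alignment(seqs: Sequence[str]) -> np.ndarray:
    """Aligned sequences -> int matrix; gaps -> -1, unknown residues -> X."""
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise PhyloError("aligned sequences must have equal length")
    M = np.empty((len(seqs), ncol), dtype=np.int16)
    for i, s in enumerate(seqs):
        M[i] = [
            -1 if c == GAP else _AA_INDEX.get(c.upper(), _AA_INDEX["X"]) for c in s
        ]
    return M


def pairwise_distances(
    labels: Sequence[str],
    seqs: Sequence[str],
    cost: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> DistanceMatrix:
    """Per-column step-matrix cost summed over non-gap column pairs,
    normalised by the number of compared columns."""
    if cost is None:
        cost = pam250_step_matrix()
    M = encode_alignment(seqs)
    n, ncol = M.shape
    w = np.ones(ncol) if weights is None else np.asarray(weights, dtype=float)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (M[i] >= 0) & (M[j] >= 0)
            wt = w[ok]
            denom = wt.sum()
            if denom == 0:
                raise PhyloError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no "
                    "aligned columns"
                )
            D[i, j] = D[j, i] = (cost[M[i][ok], M[j][ok]] * wt).sum() / denom
    return DistanceMatrix(labels=tuple(labels), d=D)


def ml_surrogate_distances(
    labels: Sequence[str],
    seqs: Sequence[str],
    weights: np.ndarray | None = None,
    max_distance: float = 10.0,
) -> DistanceMatrix:
    """Maximum-likelihood distances under the equal-frequency 20-state model."""
    M = encode_alignment(seqs)
    n, ncol = M.shape
    w = np.ones(ncol) if weights is None else np.asarray(weights, dtype=float)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (M[i] >= 0) & (M[j] >= 0)
            wt = w[ok]
            denom = wt.sum()
            if denom == 0:
                raise PhyloError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no "
                    "aligned columns"
                )
            p = (wt * (M[i][ok] != M[j][ok])).sum() / denom
            if p >= 19.0 / 20.0:
                d = max_distance
            else:
                d = -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)
            D[i, j] = D[j, i] = min(d, max_distance)
    return DistanceMatrix(labels=tuple(labels), d=D)


# ---------------------------------------------------------------------------
# neighbor joining


def _nj_core(D0: np.ndarray):
    """Neighbor-joining join schedule.

    Returns ``(joins, final)`` where joins is a list of
    ``(i, j, li, lj, new_index)`` (indices into the growing node list,
    leaves first) and final is ``((a, b, c), (la, lb, lc))`` for the last
    three clusters.  Among equal-Q pairs the smallest index pair in the
    current join order is taken, so the schedule is deterministic.
    """
    n = D0.shape[0]
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = D0
    active = list(range(n))
    joins = []
    nxt = n
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        rest = [a for a in active if a not in (ai, aj)]
        idx = np.array(rest, dtype=int)
        dnew = 0.5 * (D[ai, idx] + D[aj, idx] - dij)
        D[nxt, idx] = dnew
        D[idx, nxt] = dnew
        joins.append((ai, aj, max(0.0, li), max(0.0, lj), nxt))
        active = rest + [nxt]
        nxt += 1
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    lens = (
        max(0.0, 0.5 * (dab + dac - dbc)),
        max(0.0, 0.5 * (dab + dbc - dac)),
        max(0.0, 0.5 * (dac + dbc - dab)),
    )
    return joins, ((a, b, c), lens)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou & Nei neighbor joining; unrooted binary tree.

    Deterministic: among equal-Q candidate pairs the smallest index pair (in
    current join order) is taken.  Branch lengths are clamped at zero.
    """
    n = len(dm)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=taxa.get_taxon(label)) for label in dm.labels
    ]
    joins, ((a, b, c), lens) = _nj_core(dm.d)
    for ai, aj, li, lj, _ in joins:
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        nodes[ai].edge.length = li
        parent.add_child(nodes[aj])
        nodes[aj].edge.length = lj
        nodes.append(parent)
    center = dendropy.Node()
    for node_idx, ln in zip((a, b, c), lens):
        center.add_child(nodes[node_idx])
        nodes[node_idx].edge.length = ln
    tree.seed_node = center
    return tree


def _nj_clade_sets(D0: np.ndarray) -> list[frozenset[int]]:
    """Leaf-index sets below every edge of the NJ tree (fast path used by
    the bootstrap; equivalent to the clades of :func:`neighbor_joining`).

    Runs the join schedule in plain Python, which beats the array version
    for the small in-group matrices the bootstrap feeds it.
    """
    n = D0.shape[0]
    D = [list(map(float, row)) for row in D0]
    active = list(range(n))
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    while len(active) > 3:
        m = len(active)
        r = [sum(D[a][b] for b in active) for a in active]
        best = None
        for i in range(m):
            di = D[active[i]]
            ri = r[i]
            for j in range(i + 1, m):
                q = (m - 2) * di[active[j]] - ri - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = D[ai][aj]
        new = len(sets)
        sets.append(sets[ai] | sets[aj])
        row = [0.0] * (new + 1)
        for a in active:
            if a not in (ai, aj):
                row[a] = 0.5 * (D[ai][a] + D[aj][a] - dij)
        for dr in D:
            dr.append(0.0)
        D.append(row)
        for a in active:
            if a not in (ai, aj):
                D[a][new] = row[a]
        active = [a for a in active if a not in (ai, aj)] + [new]
    return sets


# ---------------------------------------------------------------------------
# tree utilities


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def edge_bipartitions(
    tree: dendropy.Tree, anchor: str | None = None
) -> set[frozenset[str]]:
    """Leaf sets of the side of every internal edge away from *anchor*.

    With ``anchor`` the outgroup label, these are exactly the clades of the
    tree rooted on the outgroup edge.  Trivial splits (single leaf / all but
    anchor) are included; callers filter as needed.
    """
    all_leaves = leaf_labels(tree)
    if anchor is None:
        anchor = min(all_leaves)
    if anchor not in all_leaves:
        raise PhyloError(f"anchor {anchor!r} not among leaves")
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else all_leaves - below
        if side:
            out.add(side)
    return out


def is_monophyletic(
    tree: dendropy.Tree, taxa: Sequence[str], outgroup: str
) -> bool:
    """True iff *taxa* form a clade after rooting on the outgroup edge."""
    leaves = leaf_labels(tree)
    if outgroup not in leaves:
        raise PhyloError(f"outgroup {outgroup!r} missing from tree")
    target = frozenset(taxa)
    if not target <= leaves:
        raise PhyloError("taxa not a subset of tree leaves")
    if outgroup in target:
        raise PhyloError("taxa set may not contain the outgroup")
    if len(target) == 1:
        return True
    return target in edge_bipartitions(tree, anchor=outgroup)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )


# ---------------------------------------------------------------------------
# maximum parsimony (exact branch and bound)


def _pattern_compress(
    seqs: Sequence[str], weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Columns -> unique site patterns of residue bitmasks with weights.

    Gaps and unknown residues become full-ambiguity states (all bits set),
    the standard missing-data treatment for Fitch parsimony.  Returns a
    (n_taxa, n_patterns) uint32 state matrix and the pattern weights.
    """
    ncol = len(seqs[0])
    w = np.ones(ncol) if weights is None else np.asarray(weights, dtype=float)
    full = (1 << 20) - 1
    patterns: dict[tuple[int, ...], float] = {}
    for c in range(ncol):
        if w[c] == 0:
            continue
        col = []
        for s in seqs:
            ch = s[c].upper()
            idx = _AA_INDEX.get(ch)
            if ch == GAP or idx is None or ch == "X":
                col.append(full)
            else:
                col.append(1 << idx)
        key = tuple(col)
        patterns[key] = patterns.get(key, 0.0) + w[c]
    keys = list(patterns)
    P = np.array(keys, dtype=np.uint32).T.copy() if keys else np.zeros(
        (len(seqs), 0), dtype=np.uint32
    )
    return P, np.array([patterns[k] for k in keys], dtype=float)


def _fitch_length(topology, P: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Fitch length of a rooted nested-tuple topology.

    Leaves are taxon indices; internal nodes are 2-tuples.  Vectorised over
    site patterns.  The length of the unrooted tree equals the Fitch length
    of any rooting.
    """
    counts = np.zeros(P.shape[1], dtype=float)

    def post(node) -> np.ndarray:
        if isinstance(node, int):
            return P[node]
        left = post(node[0])
        right = post(node[1])
        inter = left & right
        empty = inter == 0
        counts[empty] += 1.0
        return np.where(empty, left | right, inter)

    post(topology)
    return float(counts @ weights)


def _insertions(topology, leaf: int):
    """All topologies obtained by attaching *leaf* on each edge."""
    yield (topology, leaf)
    if isinstance(topology, tuple):
        a, b = topology
        for sub in _insertions(a, leaf):
            yield (sub, b)
        for sub in _insertions(b, leaf):
            yield (a, sub)


def _canonical(topology):
    """Canonical form (sorted nested tuples) for lexicographic tie-breaks."""
    if isinstance(topology, int):
        return (0, topology)
    a, b = _canonical(topology[0]), _canonical(topology[1])
    return (1,) + tuple(sorted((a, b)))


def max_parsimony(
    labels: Sequence[str],
    seqs: Sequence[str],
    max_taxa: int = 12,
    weights: np.ndarray | None = None,
) -> tuple[dendropy.Tree, float]:
    """Exact minimum-Fitch-length tree via branch and bound.

    Taxa are added in input order; a partial topology is pruned as soon as
    its Fitch length reaches the incumbent, which is valid because adding
    taxa never decreases the parsimony length.  Among minimum-length trees
    the lexicographically smallest canonical topology is returned.
    """
    n = len(labels)
    if n < 3:
        raise PhyloError("parsimony needs at least 3 taxa")
    if n > max_taxa:
        raise PhyloError(
            f"{n} taxa exceeds max_taxa={max_taxa}; use neighbor joining"
        )
    patterns, wts = _pattern_compress(seqs, weights)

    # greedy stepwise addition for the initial bound
    topo = (0, 1)
    for leaf in range(2, n):
        topo = min(
            _insertions(topo, leaf),
            key=lambda t: (_fitch_length(t, patterns, wts), _canonical(t)),
        )
    best_len = _fitch_length(topo, patterns, wts)
    best_topo = topo

    def search(partial, next_leaf: int) -> None:
        nonlocal best_len, best_topo
        plen = _fitch_length(partial, patterns, wts)
        if plen > best_len:
            return
        if next_leaf == n:
            if plen < best_len or (
                plen == best_len and _canonical(partial) < _canonical(best_topo)
            ):
                best_len = plen
                best_topo = partial
            return
        for t in _insertions(partial, next_leaf):
            search(t, next_leaf + 1)

    search((0, 1), 2)
    return _topology_to_tree(best_topo, labels), best_len


def _topology_to_tree(topology, labels: Sequence[str]) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node):
        if isinstance(node, int):
            return dendropy.Node(taxon=taxa.get_taxon(labels[node]))
        nd = dendropy.Node()
        nd.add_child(build(node[0]))
        nd.add_child(build(node[1]))
        return nd

    # root trifurcation like an unrooted tree when possible
    root = dendropy.Node()
    if isinstance(topology, tuple) and isinstance(topology[0], tuple):
        root.add_child(build(topology[0][0]))
        root.add_child(build(topology[0][1]))
        root.add_child(build(topology[1]))
    else:
        root.add_child(build(topology[0]))
        root.add_child(build(topology[1]))
    tree.seed_node = root
    return tree


# ---------------------------------------------------------------------------
# bootstrap

TreeBuilder = Callable[[Sequence[str], Sequence[str], np.ndarray | None],
                       dendropy.Tree]


def nj_builder(labels, seqs, weights=None) -> dendropy.Tree:
    return neighbor_joining(pairwise_distances(labels, seqs, weights=weights))


def ml_surrogate_builder(labels, seqs, weights=None) -> dendropy.Tree:
    return neighbor_joining(ml_surrogate_distances(labels, seqs, weights=weights))


def _combine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    inter = a & b
    return np.where(inter == 0, a | b, inter)


def _best_insertion(topo, leaf: int, P: np.ndarray, w: np.ndarray):
    """Best topology obtained by grafting *leaf* on any edge of *topo*.

    Uses directed Fitch state sets: attaching a leaf with states ``s`` at an
    edge whose combined directed set is ``S`` costs one extra step exactly
    on the patterns where ``s & S == 0``.  One vectorised scoring operation
    per edge instead of a full Fitch recomputation per candidate topology.
    """
    base = _fitch_length(topo, P, w)
    if isinstance(topo, int):
        return (topo, leaf), base + float(w[(P[leaf] & P[topo]) == 0].sum())
    s = P[leaf]
    downs: dict[int, np.ndarray] = {}

    def down(t) -> np.ndarray:
        if isinstance(t, int):
            return P[t]
        key = id(t)
        got = downs.get(key)
        if got is None:
            got = downs[key] = _combine(down(t[0]), down(t[1]))
        return got

    best_extra = float(w[(s & down(topo)) == 0].sum())
    best_path: tuple[int, ...] = ()  # () = root edge

    def visit(t, up: np.ndarray, path: tuple[int, ...]) -> None:
        nonlocal best_extra, best_path
        S = _combine(down(t), up)
        extra = float(w[(s & S) == 0].sum())
        if extra < best_extra:
            best_extra, best_path = extra, path
        if isinstance(t, tuple):
            a, b = t
            visit(a, _combine(up, down(b)), path + (0,))
            visit(b, _combine(up, down(a)), path + (1,))

    a, b = topo
    visit(a, down(b), (0,))
    visit(b, down(a), (1,))

    def rebuild(t, path):
        if not path:
            return (t, leaf)
        a, b = t
        if path[0] == 0:
            return (rebuild(a, path[1:]), b)
        return (a, rebuild(b, path[1:]))

    return rebuild(topo, best_path), base + best_extra


def mp_stepwise_topology(P: np.ndarray, w: np.ndarray, n: int, passes: int = 3):
    """Greedy stepwise addition followed by leaf re-insertion passes.

    The deterministic heuristic parsimony search used inside bootstrap
    loops (full branch and bound per replicate is unnecessary for the
    small, strongly structured in-group alignments this survey builds).
    """
    topo = (0, 1)
    best = _fitch_length(topo, P, w)
    for leaf in range(2, n):
        topo, best = _best_insertion(topo, leaf, P, w)
    for _ in range(passes):  # leaf re-insertion improvement passes
        improved = False
        for leaf in range(n):
            pruned = _remove_leaf(topo, leaf)
            if pruned is None or isinstance(pruned, int):
                continue
            cand, clen = _best_insertion(pruned, leaf, P, w)
            if clen < best:
                topo, best = cand, clen
                improved = True
        if not improved:
            break
    return topo, best


def _remove_leaf(topology, leaf):
    """Topology with *leaf* pruned (its parent collapsed); None if the
    whole subtree was the leaf."""
    if isinstance(topology, int):
        return None if topology == leaf else topology
    a, b = topology
    ra = _remove_leaf(a, leaf)
    rb = _remove_leaf(b, leaf)
    if ra is None:
        return rb
    if rb is None:
        return ra
    return (ra, rb)


def mp_builder(labels, seqs, weights=None) -> dendropy.Tree:
    """Heuristic-search maximum parsimony (stepwise addition plus leaf
    re-insertion); use :func:`max_parsimony` for the exact search."""
    P, w = _pattern_compress(seqs, weights)
    topo, _ = mp_stepwise_topology(P, w, len(labels))
    return _topology_to_tree(topo, labels)


BUILDERS: dict[str, TreeBuilder] = {
    "NJ": nj_builder,
    "MP": mp_builder,
    "ML-surrogate": ml_surrogate_builder,
}


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise PhyloError("replicates must be >= 1")


def bootstrap_support(
    labels: Sequence[str],
    seqs: Sequence[str],
    builder: str | TreeBuilder = "NJ",
    cfg: BootstrapConfig = BootstrapConfig(),
    anchor: str | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Reference tree plus per-bipartition bootstrap percentages (0-100).

    Columns of the alignment are resampled with replacement ``replicates``
    times (reproducibly for a fixed seed); support of a bipartition is the
    percentage of replicate trees containing it.  Supports for the reference
    tree's internal bipartitions are written to internal node labels.
    """
    name = builder if isinstance(builder, str) else None
    if isinstance(builder, str):
        builder = BUILDERS[builder]
    ncol = len(seqs[0])
    ref_tree = builder(labels, seqs, None)
    rng = np.random.default_rng(cfg.seed)
    counts: dict[frozenset[str], int] = {}
    if anchor is None:
        anchor = min(labels)

    all_leaves = frozenset(labels)

    def canon(side_idx: frozenset[int]) -> frozenset[str]:
        side = frozenset(labels[i] for i in side_idx)
        return side if anchor not in side else all_leaves - side

    def tally(bips) -> None:
        for bip in bips:
            counts[bip] = counts.get(bip, 0) + 1

    # replicate column weights, drawn once (reproducible for fixed seed)
    idx = rng.integers(0, ncol, size=(cfg.replicates, ncol))
    W = np.zeros((cfg.replicates, ncol))
    for r in range(cfg.replicates):
        W[r] = np.bincount(idx[r], minlength=ncol)

    if name in ("NJ", "ML-surrogate"):
        # Fast replicate path: the per-column cost tensor is fixed, so all
        # replicate distance matrices come from one matrix product, and the
        # join schedule alone determines the bipartitions.
        M = encode_alignment(seqs)
        n = len(labels)
        valid = (M[:, None, :] >= 0) & (M[None, :, :] >= 0)
        if name == "NJ":
            C = pam250_step_matrix()
            tensor = C[M[:, None, :], M[None, :, :]] * valid
        else:
            tensor = ((M[:, None, :] != M[None, :, :]) & valid).astype(float)
        flat = tensor.reshape(n * n, ncol)
        vflat = valid.reshape(n * n, ncol).astype(float)
        D_all = flat @ W.T
        denom = vflat @ W.T
        bad = denom == 0
        denom[bad] = 1.0
        D_all = D_all / denom
        if name == "ML-surrogate":
            p = np.minimum(D_all, 19.0 / 20.0 - 1e-12)
            D_all = np.minimum(
                -(19.0 / 20.0) * np.log(1.0 - 20.0 * p / 19.0), 10.0
            )
        for r in range(cfg.replicates):
            if bad[:, r].any():
                # a pair shares no sampled columns; use the checked builder
                rep = builder(labels, seqs, W[r])
                tally(edge_bipartitions(rep, anchor=anchor))
                continue
            D = D_all[:, r].reshape(n, n)
            np.fill_diagonal(D, 0.0)
            tally(canon(s) for s in _nj_clade_sets((D + D.T) / 2.0))
    elif name == "MP":
        for r in range(cfg.replicates):
            P, w = _pattern_compress(seqs, W[r])
            topo, _ = mp_stepwise_topology(P, w, len(labels), passes=1)
            sets: list[frozenset[int]] = []

            def collect(t) -> frozenset[int]:
                if isinstance(t, int):
                    s = frozenset([t])
                else:
                    s = collect(t[0]) | collect(t[1])
                sets.append(s)
                return s

            collect(topo)
            tally({canon(s) for s in sets})
    else:
        for r in range(cfg.replicates):
            rep = builder(labels, seqs, W[r])
            tally(edge_bipartitions(rep, anchor=anchor))
    support = {
        bip: 100.0 * c / cfg.replicates for bip, c in counts.items()
    }
    _annotate_support(ref_tree, support, anchor)
    return ref_tree, support


def _annotate_support(tree, support, anchor):
    all_leaves = leaf_labels(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else all_leaves - below
        val = support.get(side)
        if val is not None:
            node.label = f"{val:g}"
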