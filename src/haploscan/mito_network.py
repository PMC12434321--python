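"""Mitochondrial haplotype networks and trees.

Aligned mitogenomes are collapsed into haplotypes (identical sequences after
alignment-wide removal of gap/ambiguity columns, named by frequency), joined
into a median-joining network with epsilon = 0 (minimum-spanning connections
plus cost-reducing quasi-median nodes), and summarized by a neighbor-joining
tree with column-resampling bootstrap.  A carrier test reports whether a
marked subset of individuals (e.g. inversion carriers) is confined to a
connected, exclusive part of the network -- the monophyly proxy used to ask
whether carriers share ancestry more recent than the whole radiation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

__all__ = [
    "HaplotypeSet",
    "collapse_haplotypes",
    "hamming",
    "minimum_spanning_network",
    "mj_network",
    "nj_tree",
    "carrier_clade_test",
]

_UNAMBIG = frozenset("ACGT")


@dataclass
class HaplotypeSet:
    """Distinct haplotypes ranked by frequency (id 1 = most frequent)."""

    sequences: list[str]  # retained-column sequences, index = id - 1
    frequencies: list[int]
    members: list[list[str]]  # individual ids per haplotype
    carrier: list[int] = field(default_factory=list)  # carriers per haplotype
    n_columns_removed: int = 0

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def name(self, i: int) -> str:
        return f"H{i + 1}"


def collapse_haplotypes(records, carrier_flags: dict | None = None) -> HaplotypeSet:
    """Group identical aligned sequences into frequency-ranked haplotypes.

    ``records`` is an iterable of (name, sequence).  Columns containing a
    gap or ambiguity code in any sequence are removed alignment-wide before
    comparison, so distances are plain Hamming counts on the retained
    columns.  Ties in frequency rank by first occurrence.
    """
    names, seqs = zip(*[(n, s.upper()) for n, s in records])
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    arr = np.array([list(s) for s in seqs])
    keep = np.array([set(arr[:, j]) <= _UNAMBIG for j in range(L)])
    arr = arr[:, keep]
    reduced = ["".join(row) for row in arr]
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for name, seq in zip(names, reduced):
        if seq not in groups:
            groups[seq] = []
            order.append(seq)
        groups[seq].append(name)
    ranked = sorted(order, key=lambda s: (-len(groups[s]), order.index(s)))
    carriers = []
    if carrier_flags is not None:
        carriers = [sum(bool(carrier_flags.get(n, False)) for n in groups[s])
                    for s in ranked]
    return HaplotypeSet(
        sequences=ranked,
        frequencies=[len(groups[s]) for s in ranked],
        members=[groups[s] for s in ranked],
        carrier=carriers,
        n_columns_removed=int((~keep).sum()),
    )


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def minimum_spanning_network(seqs: list[str], epsilon: int = 0):
    """Epsilon-relaxed minimum spanning network over sequences.

    Edges are processed in ascending weight classes; an edge joins the
    network if its endpoints are not yet connected by edges of weight
    <= w - 1 - epsilon.  With epsilon = 0 this is the union of all minimum
    spanning trees.  Returns (edge list [(i, j, w)], total cost of one MST).
    """
    n = len(seqs)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = hamming(seqs[i], seqs[j])
    edges = []
    mst_cost = 0
    weights = sorted(set(dist.values()))
    included_below: list[tuple[int, int, int]] = []
    for w in weights:
        # connectivity from edges of weight <= w - 1 - epsilon
        uf = _UnionFind(n)
        for (a, b, wv) in included_below:
            if wv <= w - 1 - epsilon:
                uf.union(a, b)
        # and an MST-progress union-find for the cost bookkeeping
        cls = [(i, j) for (i, j), d in dist.items() if d == w]
        new = [(i, j, w) for i, j in cls if uf.find(i) != uf.find(j)]
        edges.extend(new)
        included_below.extend(new)
        # MST cost: greedily union within this class
        uf2 = _UnionFind(n)
        for (a, b, wv) in edges[: len(edges) - len(new)]:
            uf2.union(a, b)
        for i, j, wv in new:
            if uf2.find(i) != uf2.find(j):
                uf2.union(i, j)
                mst_cost += wv
    return edges, mst_cost


def _quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Column-wise majority consensus; three-state columns branch."""
    options = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append((a, b, c))
    n_branch = int(np.prod([len(o) for o in options]))
    if n_branch > 81:  # degenerate alignment; keep the search bounded
        options = [(o[0],) if len(o) > 1 else o for o in options]
    return ["".join(t) for t in itertools.product(*options)]


def _prune_medians(nodes, n_observed, cost_of):
    """Drop median vectors whose removal does not increase the network cost."""
    cost = cost_of(nodes)
    changed = True
    while changed:
        changed = False
        for idx in range(len(nodes) - 1, n_observed - 1, -1):
            trial = nodes[:idx] + nodes[idx + 1:]
            if cost_of(trial) <= cost:
                nodes = trial
                cost = cost_of(nodes)
                changed = True
                break
    return nodes


def _median_closure(observed, max_extra):
    """Quasi-median closure of the observed set, or None if it exceeds the cap."""
    closure = set(observed)
    grew = True
    while grew:
        grew = False
        for u, v, w in itertools.combinations(sorted(closure), 3):
            for med in _quasi_medians(u, v, w):
                if med not in closure:
                    closure.add(med)
                    grew = True
                    if len(closure) - len(observed) > max_extra:
                        return None
    return sorted(closure - set(observed))


def _exact_median_subset(observed, extras, cost_of):
    """Minimum-spanning-cost subset of candidate medians, by subset search.

    Returns the lowest-cost node set; among ties, the fewest medians, then
    the lexicographically smallest combination (determinism).
    """
    best_cost = cost_of(observed)
    best_combo: tuple = ()
    for r in range(1, len(extras) + 1):
        for combo in itertools.combinations(extras, r):
            c = cost_of(observed + list(combo))
            if c < best_cost:
                best_cost, best_combo = c, combo
    return observed + list(best_combo)


def mj_network(
    hapset: HaplotypeSet | list[str],
    epsilon: int = 0,
    max_iter: int = 50,
    max_exact_medians: int = 14,
) -> nx.Graph:
    """Median-joining haplotype network (epsilon = 0 by default).

    Quasi-median (column-consensus) sequences of haplotype triples are
    candidate unobserved nodes; the network is the epsilon-relaxed minimum
    spanning network over the observed haplotypes plus the median set that
    minimizes the spanning cost.  When the quasi-median closure is small
    (at most ``max_exact_medians`` candidates) the minimizing median subset
    is found exactly by subset search; otherwise a greedy ascent adds the
    single most cost-reducing median per pass (ties: lexicographically
    smallest sequence) to a fixpoint.  Median vectors whose removal leaves
    the cost unchanged are pruned.  Nodes carry ``observed``, ``frequency``
    and ``carrier`` attributes; edge weights are mutational steps.
    """
    if isinstance(hapset, HaplotypeSet):
        observed = list(hapset.sequences)
        freqs = list(hapset.frequencies)
        carriers = list(hapset.carrier) if hapset.carrier else [0] * len(observed)
    else:
        observed = list(hapset)
        freqs = [1] * len(observed)
        carriers = [0] * len(observed)
    if len(observed) < 2:
        raise ValueError("need >= 2 haplotypes")
    # constant columns carry no distance or median information; work on the
    # variant columns and restore full sequences at the end
    L = len(observed[0])
    arr = np.array([list(s) for s in observed])
    variant = np.flatnonzero((arr != arr[0]).any(axis=0))
    template = list(observed[0])
    full_of = {}

    def expand(reduced: str) -> str:
        if reduced not in full_of:
            chars = template.copy()
            for col, ch in zip(variant, reduced):
                chars[col] = ch
            full_of[reduced] = "".join(chars)
        return full_of[reduced]

    observed_full = list(observed)
    observed = ["".join(arr[i, variant]) for i in range(len(observed))]
    for red, full in zip(observed, observed_full):
        full_of[red] = full
    nodes = list(observed)

    def cost_of(node_list):
        _, c = minimum_spanning_network(node_list, epsilon)
        return c

    extras = _median_closure(observed, max_exact_medians)
    if extras is not None:
        nodes = _exact_median_subset(observed, extras, cost_of)
    else:
        cost = cost_of(nodes)
        for _ in range(max_iter):
            edges, _ = minimum_spanning_network(nodes, epsilon)
            adj = {i: set() for i in range(len(nodes))}
            for i, j, _w in edges:
                adj[i].add(j)
                adj[j].add(i)
            candidates = set()
            for i, j, k in itertools.combinations(range(len(nodes)), 3):
                linked = (j in adj[i]) + (k in adj[i]) + (k in adj[j])
                if linked >= 2:
                    for med in _quasi_medians(nodes[i], nodes[j], nodes[k]):
                        if med not in nodes:
                            candidates.add(med)
            best = None
            for med in sorted(candidates):
                c = cost_of(nodes + [med])
                if c < cost and (best is None or c < best[0]):
                    best = (c, med)
            if best is None:
                break
            cost = best[0]
            nodes.append(best[1])
    nodes = _prune_medians(nodes, len(observed), cost_of)
    edges, _ = minimum_spanning_network(nodes, epsilon)
    g = nx.Graph()
    for i, seq in enumerate(nodes):
        obs = i < len(observed)
        g.add_node(
            expand(seq),
            observed=obs,
            name=f"H{i + 1}" if obs else f"median{i - len(observed) + 1}",
            frequency=freqs[i] if obs else 0,
            carrier=carriers[i] if obs else 0,
        )
    for i, j, w in edges:
        g.add_edge(expand(nodes[i]), expand(nodes[j]), weight=w)
    return g


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class NjTree:
    newick: str
    supports: dict[frozenset, float]  # bipartition (non-outgroup side) -> support
    splits: set


def _nj_topology(dist: np.ndarray, names: list[str]):
    """Canonical neighbor joining; returns (adjacency, splits).

    Ties in the Q matrix break toward the lowest (i, j) index pair.  The
    adjacency maps node -> list of (node, branch length); internal nodes are
    negative integers, leaves are their names.
    """
    n = len(names)
    active = list(range(n))
    D = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i < j}

    def d(a, b):
        return D[(a, b) if a < b else (b, a)]

    adj: dict = {i: [] for i in range(n)}
    next_internal = -1
    node_key = {i: i for i in range(n)}
    while len(active) > 2:
        r = len(active)
        R = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = active[ai], active[bi]
                q = (r - 2) * d(a, b) - R[a] - R[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        dij = d(a, b)
        la = dij / 2.0 + (R[a] - R[b]) / (2.0 * (r - 2))
        lb = dij - la
        new = next_internal
        next_internal -= 1
        adj[new] = [(a, la), (b, lb)]
        adj[a].append((new, la))
        adj[b].append((new, lb))
        for c in active:
            if c in (a, b):
                continue
            D[(min(new, c), max(new, c))] = 0.5 * (d(a, c) + d(b, c) - dij)
        active = [c for c in active if c not in (a, b)] + [new]
    if len(active) == 2:
        a, b = active
        w = d(a, b)
        adj[a].append((b, w))
        adj[b].append((a, w))

    # splits: for each edge, the leaf set on the side away from leaf 0
    splits = set()
    leaves = set(range(n))

    def leafset(frm, to, seen):
        out = set()
        stack = [to]
        seen = {frm}
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x in leaves:
                out.add(x)
            for y, _w in adj[x]:
                if y not in seen:
                    stack.append(y)
        return out

    for x in adj:
        for y, _w in adj[x]:
            if x < 0 or y < 0:
                side = leafset(x, y, set())
                if 0 < len(side) < n and 0 not in side:
                    splits.add(frozenset(side))
    return adj, splits


def nj_tree(
    hapset: HaplotypeSet | list[str],
    outgroup: str,
    n_boot: int = 1000,
    seed: int = 0,
    names: list[str] | None = None,
) -> NjTree:
    """Neighbor-joining tree with bootstrap support, rooted on the outgroup.

    Distances are Hamming counts on the retained alignment columns.
    Bootstrap replicates resample columns with replacement; the support of
    an internal bipartition is the fraction of replicates containing it.
    """
    if isinstance(hapset, HaplotypeSet):
        seqs = list(hapset.sequences)
        names = [hapset.name(i) for i in range(len(seqs))]
    else:
        seqs = list(hapset)
        if names is None:
            names = [f"H{i + 1}" for i in range(len(seqs))]
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} not among haplotype names")
    if len(seqs) < 3:
        raise ValueError("need >= 3 haplotypes for a tree")
    arr = np.array([list(s) for s in seqs])
    n, L = arr.shape

    def dist_from(cols):
        sub = arr[:, cols]
        return np.array(
            [[np.sum(sub[i] != sub[j]) for j in range(n)] for i in range(n)],
            dtype=float,
        )

    dist = dist_from(np.arange(L))
    adj, splits = _nj_topology(dist, names)

    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in splits}
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        _, bsplits = _nj_topology(dist_from(cols), names)
        for s in splits:
            if s in bsplits:
                counts[s] += 1
    supports = {s: counts[s] / n_boot for s in splits}

    # root on the outgroup pendant edge
    og = names.index(outgroup)

    def split_for(frm, to):
        leaves = set(range(n))
        out = set()
        stack = [to]
        seen = {frm}
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x in leaves:
                out.add(x)
            for y, _w in adj[x]:
                if y not in seen:
                    stack.append(y)
        if 0 in out:
            out = leaves - out - ({frm} if frm in leaves else set())
        return frozenset(out)

    def newick(node, parent, length):
        children = [(c, w) for c, w in adj[node] if c != parent]
        if not children:  # leaf
            return f"{names[node]}:{length:.6g}"
        inner = ",".join(newick(c, node, w) for c, w in children)
        label = ""
        if parent is not None:
            sp = supports.get(split_for(parent, node))
            if sp is not None:
                label = f"{sp:.3g}"
        return f"({inner}){label}:{length:.6g}"

    (nbr, w0) = adj[og][0]
    sub = newick(nbr, og, w0 / 2.0)
    nwk = f"({names[og]}:{w0 / 2.0:.6g},{sub});"
    named = {frozenset(names[i] for i in s): v for s, v in supports.items()}
    return NjTree(newick=nwk, supports=named, splits=splits)


def carrier_clade_test(network: nx.Graph, hapset: HaplotypeSet) -> dict:
    """Where do marked (carrier) individuals sit in the network?

    Reports the number of haplotypes with >= 1 carrier, how many of those
    are shared with non-carriers, and whether carrier haplotypes form a
    connected subnetwork that excludes non-carrier haplotypes (TRUE only if
    every carrier haplotype is carrier-exclusive and the carrier haplotypes
    are connected through, at most, median vectors).
    """
    if not hapset.carrier or sum(hapset.carrier) == 0:
        return {}
    carrier_haps = [
        i for i in range(hapset.n_haplotypes) if hapset.carrier[i] > 0
    ]
    shared = [
        i for i in carrier_haps if hapset.carrier[i] < hapset.frequencies[i]
    ]
    exclusive = len(shared) == 0
    connected = False
    if exclusive:
        allowed = set()
        seq_of = {i: hapset.sequences[i] for i in carrier_haps}
        for node, data in network.nodes(data=True):
            if not data.get("observed", True):
                allowed.add(node)
        allowed |= set(seq_of.values())
        sub = network.subgraph(allowed)
        targets = set(seq_of.values())
        if targets:
            comp = nx.node_connected_component(sub, next(iter(targets)))
            connected = targets <= comp
    return {
        "n_carrier_haplotypes": len(carrier_haps),
        "n_shared_with_noncarriers": len(shared),
        "connected_exclusive": bool(exclusive and connected),
    }
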