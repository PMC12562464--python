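"""Median-joining networks of STR haplotypes and their parsimony resolution.

The median-joining construction follows the classical heuristic for
intraspecific data: build an epsilon-relaxed minimum-spanning network over
the observed haplotype states, propose "median" states as the per-locus
median of state triplets connected in that network, keep those whose
insertion shortens the minimal spanning length, and iterate to a fixed
point before pruning obsolete inferred nodes.  All tie-breaks are
lexicographic on canonical state labels, so the result is invariant under
permutation of the input samples.

Distances are weighted single-step counts: ``sum_l w_l * |a_l - b_l|`` over
loci typed in both states, with multicopy markers compared by the
minimum-cost assignment of their sorted repeat values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

from .io import Haplotype, HaplotypeSet, LocusPanel

_TOL = 1e-9


@dataclass(frozen=True)
class MJParams:
    """Parameters of the median-joining construction.

    epsilon relaxes the minimum-spanning network: a link enters the network
    if its weighted length is within ``epsilon`` of the smallest length at
    which its endpoints become connected.  ``weight`` multiplies per-locus
    step counts (uniform positive integer by default, or a per-locus map).
    """

    epsilon: float = 0
    weight: object = 10

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    def column_weights(self, panel: LocusPanel) -> np.ndarray:
        if isinstance(self.weight, Mapping):
            w = np.array([float(self.weight.get(loc, 1)) for loc in panel.column_locus])
        else:
            w = np.full(panel.L, float(self.weight))
        if np.any(w <= 0):
            raise ValueError("all weights must be positive")
        return w

    @property
    def max_weight(self) -> float:
        if isinstance(self.weight, Mapping):
            return float(max(self.weight.values()))
        return float(self.weight)


# ---------------------------------------------------------------------------
# state handling

def state_key(vec: Sequence[float]) -> tuple:
    """Canonical hashable label of a state vector (None marks missing)."""
    return tuple(None if np.isnan(v) else int(v) for v in vec)


def _sort_key(key: tuple) -> tuple:
    return tuple(-1 if v is None else v for v in key)


def _key_to_vec(key: tuple) -> np.ndarray:
    return np.array([np.nan if v is None else float(v) for v in key])


def distance_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pairwise weighted step distances, skipping columns missing in either row."""
    diff = np.abs(X[:, None, :] - X[None, :, :])  # NaN where either missing
    return np.nansum(diff * w, axis=2)


def _dist_to(X: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.nansum(np.abs(X - v) * w, axis=1)


def str_distance(a: Haplotype, b: Haplotype, params: MJParams, panel: LocusPanel) -> float:
    """Weighted step distance between two haplotypes.

    Loci missing in either haplotype are skipped; multicopy loci are compared
    by the minimum-cost assignment between the two (sorted) multisets.
    Raises if the haplotypes share no typed locus.
    """
    va, vb = panel.encode(a.repeats), panel.encode(b.repeats)
    shared = ~np.isnan(va) & ~np.isnan(vb)
    if not shared.any():
        raise ValueError(f"no shared typed loci between {a.sample_id} and {b.sample_id}")
    w = params.column_weights(panel)
    return float(np.sum(np.abs(va[shared] - vb[shared]) * w[shared]))


# ---------------------------------------------------------------------------
# spanning structure helpers

def _dense_mst(D: np.ndarray) -> tuple[float, list[tuple[int, int, float]]]:
    """Minimum spanning tree of a dense symmetric distance matrix."""
    mst = _scipy_mst(csr_matrix(np.triu(D, 1))).tocoo()
    edges = [(int(i), int(j), float(w)) for i, j, w in zip(mst.row, mst.col, mst.data)]
    return float(mst.data.sum()), edges


def _minimax_matrix(n: int, mst_edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Max edge weight on the (unique) MST path between every node pair."""
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, w in mst_edges:
        adj[i].append((j, w))
        adj[j].append((i, w))
    mm = np.zeros((n, n))
    for src in range(n):
        stack = [(src, 0.0)]
        seen = np.zeros(n, dtype=bool)
        seen[src] = True
        while stack:
            node, cur = stack.pop()
            for nb, w in adj[node]:
                if not seen[nb]:
                    seen[nb] = True
                    mm[src, nb] = max(cur, w)
                    stack.append((nb, mm[src, nb]))
    return mm


def _msn_edges(D: np.ndarray, epsilon: float) -> list[tuple[int, int]]:
    """Epsilon-relaxed minimum spanning network.

    An edge (i, j) belongs to the network iff D[i, j] is within epsilon of
    the minimax path distance between i and j, i.e. of the largest distance
    at which i and j merge in a Kruskal construction.  With epsilon = 0 this
    is exactly the union of all minimum spanning trees.
    """
    n = D.shape[0]
    _, mst_edges = _dense_mst(D)
    mm = _minimax_matrix(n, mst_edges)
    ii, jj = np.where(np.triu(D <= mm + epsilon + _TOL, 1))
    return list(zip(ii.tolist(), jj.tolist()))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def _augmented_mst(n: int, mst_edges: list[tuple[int, int, float]],
                   dvec: np.ndarray) -> tuple[float, list[tuple[int, int, float]]]:
    """MST of the point set after appending one node (index n).

    Uses the fact that the new MST is contained in the old MST edges plus the
    star of edges from the new node.
    """
    cand = mst_edges + [(k, n, float(dvec[k])) for k in range(n)]
    cand.sort(key=lambda e: e[2])
    uf = _UnionFind(n + 1)
    out, total = [], 0.0
    for i, j, w in cand:
        if uf.union(i, j):
            out.append((i, j, w))
            total += w
            if len(out) == n:
                break
    return total, out


# ---------------------------------------------------------------------------
# the network object

@dataclass
class MJNetwork:
    """A median-joining network over haplotype states.

    Nodes are canonical state tuples.  Node attributes: ``vec`` (float state
    vector), ``observed``, ``multiplicity``, ``populations`` (label -> count),
    ``samples``, ``ancient``.  Edge attributes: ``length`` (weighted),
    ``steps`` (unweighted mutation count) and ``diff`` (per-column steps).
    """

    panel: LocusPanel
    params: MJParams
    graph: nx.Graph

    @property
    def nodes(self) -> list[tuple]:
        return sorted(self.graph.nodes, key=_sort_key)

    @property
    def observed_nodes(self) -> list[tuple]:
        return [k for k in self.nodes if self.graph.nodes[k]["observed"]]

    @property
    def median_nodes(self) -> list[tuple]:
        return [k for k in self.nodes if not self.graph.nodes[k]["observed"]]

    def state(self, key: tuple) -> np.ndarray:
        return self.graph.nodes[key]["vec"]

    def mst_edges(self) -> list[tuple[tuple, tuple, float]]:
        """Canonical minimum spanning tree restricted to network edges."""
        edges = sorted(
            ((d["length"], *sorted((u, v), key=_sort_key))
             for u, v, d in self.graph.edges(data=True)),
            key=lambda e: (e[0], _sort_key(e[1]), _sort_key(e[2])),
        )
        idx = {k: i for i, k in enumerate(self.nodes)}
        uf = _UnionFind(len(idx))
        out = []
        for w, u, v in edges:
            if uf.union(idx[u], idx[v]):
                out.append((u, v, w))
        return out

    @property
    def total_length(self) -> float:
        """Weighted length of a minimal resolution (spanning tree) of the network."""
        return float(sum(w for _, _, w in self.mst_edges()))

    def node_for_state(self, repeats_or_vec) -> Optional[tuple]:
        if isinstance(repeats_or_vec, Mapping):
            key = state_key(self.panel.encode(repeats_or_vec))
        else:
            key = state_key(np.asarray(repeats_or_vec, dtype=float))
        return key if key in self.graph else None

    def to_edge_table(self):
        import pandas as pd
        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append({
                "node1": _label(u), "node2": _label(v),
                "length": d["length"], "steps": d["steps"],
                "diff": ";".join(f"{c}:{s}" for c, s in d["diff"].items()),
            })
        return pd.DataFrame(rows, columns=["node1", "node2", "length", "steps", "diff"])

    def to_node_table(self):
        import pandas as pd
        rows = []
        for k in self.nodes:
            d = self.graph.nodes[k]
            rows.append({
                "node": _label(k),
                "type": "observed" if d["observed"] else "median",
                "multiplicity": d["multiplicity"],
                "populations": ";".join(f"{p}:{c}" for p, c in sorted(d["populations"].items())),
                "samples": ";".join(d["samples"]),
            })
        return pd.DataFrame(rows, columns=["node", "type", "multiplicity", "populations", "samples"])

    def to_dot(self) -> str:
        lines = ["graph mjnetwork {"]
        for k in self.nodes:
            d = self.graph.nodes[k]
            shape = "circle" if d["observed"] else "point"
            lines.append(f'  "{_label(k)}" [shape={shape}, label="{d["multiplicity"]}"];')
        for u, v, d in self.graph.edges(data=True):
            lines.append(f'  "{_label(u)}" -- "{_label(v)}" [label="{d["steps"]}"];')
        lines.append("}")
        return "\n".join(lines)


def _label(key: tuple) -> str:
    return "-".join("?" if v is None else str(v) for v in key)


# ---------------------------------------------------------------------------
# construction

def build_mj_network(hs: HaplotypeSet, params: Optional[MJParams] = None, *,
                     extra_states: Iterable[Sequence[float]] = (),
                     max_median_factor: float = 3.0,
                     max_rounds: int = 200) -> MJNetwork:
    """Build the median-joining network of a haplotype set.

    Identical haplotypes collapse into one observed node carrying a sample
    multiplicity and per-population tally.  ``extra_states`` (e.g. a known
    founder state) are inserted as inferred nodes.  The number of inferred
    medians is capped at ``max_median_factor`` times the number of distinct
    observed states — a numerical bound, reached only on extremely diverse
    inputs.
    """
    params = params or MJParams()
    panel = hs.panel
    w = params.column_weights(panel)

    # collapse to unique observed states, canonically ordered
    groups: dict[tuple, list[Haplotype]] = {}
    for h in hs.haplotypes:
        groups.setdefault(state_key(panel.encode(h.repeats)), []).append(h)
    keys = sorted(groups, key=_sort_key)
    if len(keys) + len(list(extra_states)) < 2:
        raise ValueError("need at least 2 distinct haplotype states")

    vecs = [_key_to_vec(k) for k in keys]
    observed = [True] * len(keys)
    protected = set(keys)  # observed and user-supplied states survive pruning
    for st in extra_states:
        vec = panel.encode(st) if isinstance(st, Mapping) else np.asarray(st, dtype=float)
        key = state_key(vec)
        if key not in groups:
            keys.append(key)
            vecs.append(vec)
            observed.append(False)
            groups[key] = []
        protected.add(key)

    X = np.vstack(vecs)
    key_set = set(keys)
    n_obs = sum(observed)
    budget = max(16, int(max_median_factor * n_obs))

    D = distance_matrix(X, w)
    mst_len, mst_edges = _dense_mst(D)

    for _ in range(max_rounds):
        msn = _msn_edges(D, params.epsilon)
        adj: dict[int, list[int]] = {}
        for i, j in msn:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)

        # candidate medians from triplets connected in the MSN
        cands: dict[tuple, tuple[float, np.ndarray]] = {}
        for v, nbs in adj.items():
            if len(nbs) < 2:
                continue
            for ai in range(len(nbs)):
                for bi in range(ai + 1, len(nbs)):
                    tri = X[[nbs[ai], v, nbs[bi]]]
                    med = np.where(np.isnan(tri).any(axis=0), np.nan,
                                   np.median(tri, axis=0))
                    if np.all(np.isnan(med)):
                        continue
                    key = state_key(med)
                    if key in key_set:
                        continue
                    cost = float(_dist_to(tri, med, w).sum())
                    if key not in cands or cost < cands[key][0]:
                        cands[key] = (cost, med)

        added = 0
        n_inferred = len(keys) - n_obs
        for key in sorted(cands, key=lambda k: (cands[k][0], _sort_key(k))):
            if n_inferred + added >= budget:
                break
            _, med = cands[key]
            dvec = _dist_to(X, med, w)
            new_len, new_edges = _augmented_mst(X.shape[0], mst_edges, dvec)
            if new_len < mst_len - _TOL:  # insertion shortens the network
                X = np.vstack([X, med])
                D = np.pad(D, ((0, 1), (0, 1)))
                D[-1, :-1] = D[:-1, -1] = dvec
                keys.append(key)
                key_set.add(key)
                observed.append(False)
                groups[key] = []
                mst_len, mst_edges = new_len, new_edges
                added += 1
        if added == 0:
            break

    # prune obsolete inferred nodes until fixpoint
    while True:
        msn = _msn_edges(D, params.epsilon)
        deg: dict[int, list[int]] = {i: [] for i in range(X.shape[0])}
        for i, j in msn:
            deg[i].append(j)
            deg[j].append(i)
        drop = set()
        for i in range(X.shape[0]):
            if observed[i] or keys[i] in protected:
                continue
            nbs = deg[i]
            if len(nbs) <= 1:
                drop.add(i)
            elif len(nbs) == 2:
                u, v = nbs
                # a pass-through median is obsolete if the direct link is as short
                if D[u, v] <= D[u, i] + D[i, v] + _TOL:
                    drop.add(i)
        if not drop:
            break
        keep = [i for i in range(X.shape[0]) if i not in drop]
        X = X[keep]
        D = D[np.ix_(keep, keep)]
        keys = [keys[i] for i in keep]
        observed = [observed[i] for i in keep]

    # assemble the graph from the final relaxed spanning network
    g = nx.Graph()
    for i, key in enumerate(keys):
        haps = groups.get(key, [])
        pops: dict[str, int] = {}
        for h in haps:
            pops[h.population] = pops.get(h.population, 0) + 1
        g.add_node(key, vec=X[i], observed=observed[i], multiplicity=len(haps),
                   populations=pops, samples=sorted(h.sample_id for h in haps),
                   ancient=any(h.ancient for h in haps))
    for i, j in _msn_edges(D, params.epsilon):
        diff = X[i] - X[j]
        steps = {panel.columns[c]: int(abs(diff[c]))
                 for c in range(panel.L)
                 if not np.isnan(diff[c]) and abs(diff[c]) > 0}
        g.add_edge(keys[i], keys[j], length=float(D[i, j]),
                   steps=int(sum(steps.values())), diff=steps)
    return MJNetwork(panel=panel, params=params, graph=g)


# ---------------------------------------------------------------------------
# parsimony resolution

@dataclass
class ParsimonyTree:
    """A rooted minimal-length resolution of a median-joining network.

    ``tree`` spans every node of the network (hence every observed state);
    reticulations are resolved by a deterministic minimum spanning tree with
    lexicographic tie-breaking, which attains the minimum total length over
    all spanning-tree resolutions.  Edge attribute ``mutations`` counts
    unweighted repeat steps.
    """

    tree: nx.Graph
    root: tuple
    parent: dict[tuple, Optional[tuple]] = field(repr=False)

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.tree.edges(data=True)))

    @property
    def total_mutations(self) -> int:
        return int(sum(d["mutations"] for _, _, d in self.tree.edges(data=True)))

    def path_mutations(self, node: tuple) -> int:
        """Mutation count on the path from the root to ``node``."""
        total, cur = 0, node
        while self.parent[cur] is not None:
            total += self.tree.edges[cur, self.parent[cur]]["mutations"]
            cur = self.parent[cur]
        return total

    def tips_below(self) -> dict[tuple, int]:
        """For each node: total sample multiplicity in its subtree (inclusive)."""
        order = list(nx.bfs_tree(self.tree, self.root))
        counts = {k: int(self.tree.nodes[k].get("multiplicity", 0)) for k in order}
        for node in reversed(order):
            p = self.parent[node]
            if p is not None:
                counts[p] += counts[node]
        return counts


def extract_parsimony_tree(net: MJNetwork, root: tuple) -> ParsimonyTree:
    """Resolve a network into a minimum-total-length rooted spanning tree.

    Ties between equal-length resolutions are broken lexicographically on
    canonical node labels, so the result is reproducible and independent of
    sample input order.
    """
    if root not in net.graph:
        raise ValueError("root is not a node of the network")
    if not nx.is_connected(net.graph):
        raise ValueError("network is disconnected")
    tree = nx.Graph()
    for k, d in net.graph.nodes(data=True):
        tree.add_node(k, **d)
    for u, v, w in net.mst_edges():
        d = net.graph.edges[u, v]
        tree.add_edge(u, v, length=w, mutations=d["steps"], diff=d["diff"])
    parent: dict[tuple, Optional[tuple]] = {root: None}
    for u, v in nx.bfs_edges(tree, root, sort_neighbors=lambda ks: sorted(ks, key=_sort_key)):
        parent[v] = u
    return ParsimonyTree(tree=tree, root=root, parent=parent)


# ---------------------------------------------------------------------------
# founder inference

def tree_centroid(tree: ParsimonyTree) -> tuple:
    """The tree's balance point: the node minimizing the largest sample
    multiplicity left in any component after its removal (Jordan centroid,
    lexicographic tie-break).  Used to root subtree-based cluster
    delimitation, where a balanced root keeps distinct radiations in
    distinct root-adjacent subtrees."""
    below = tree.tips_below()
    total = below[tree.root]
    children: dict[tuple, list[tuple]] = {}
    for node, par in tree.parent.items():
        if par is not None:
            children.setdefault(par, []).append(node)
    best, best_score = None, None
    for node in sorted(tree.tree.nodes, key=_sort_key):
        comps = [below[c] for c in children.get(node, [])]
        if tree.parent[node] is not None:
            comps.append(total - below[node])
        score = max(comps) if comps else 0
        if best_score is None or score < best_score:
            best, best_score = node, score
    return best


def infer_founder(net: MJNetwork, cluster_nodes: Optional[Iterable[tuple]] = None,
                  anchors: Optional[Iterable[tuple]] = None) -> tuple:
    """Infer the founder node of a cluster.

    Returns the network node minimizing the multiplicity-weighted sum of
    weighted step distances to the observed cluster members.  If ancient
    ``anchors`` are given and one attains within a single mutation step of
    the minimum, the anchor is preferred (ancient states are direct evidence
    of the ancestral haplotype).  Ties break lexicographically.
    """
    members = list(cluster_nodes) if cluster_nodes is not None else net.observed_nodes
    members = [k for k in members if net.graph.nodes[k]["multiplicity"] > 0]
    if not members:
        raise ValueError("empty cluster")
    w = net.params.column_weights(net.panel)
    M = np.vstack([net.state(k) for k in members])
    mult = np.array([net.graph.nodes[k]["multiplicity"] for k in members], dtype=float)

    candidates = net.nodes
    scores = {k: float((_dist_to(M, net.state(k), w) * mult).sum()) for k in candidates}
    best = min(candidates, key=lambda k: (scores[k], _sort_key(k)))
    if anchors:
        anchors = [a for a in anchors if a in scores]
        if anchors:
            abest = min(anchors, key=lambda k: (scores[k], _sort_key(k)))
            if scores[abest] <= scores[best] + net.params.max_weight + _TOL:
                return abest
    return best
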