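"""Haplotype collapsing and weighted median-joining network construction.

The median-joining (MJ) algorithm of Bandelt, Forster & Röhl builds a
phylogenetic network from haplotype state vectors: it starts from the
minimum spanning network (all minimum-spanning-tree edges, tolerance
``epsilon``) and repeatedly augments the node set with median vectors —
column-wise majority consensus of triplets of linked nodes — that reduce
the connection cost, pruning synthetic nodes that end up with fewer than
three links.  Median vectors represent unsampled or ancestral haplotypes.

Distances are weighted Hamming distances with per-position integer weights
(positions weighted inversely to their mutation frequency downweight
hotspots); missing states (N) contribute zero.  Multistate indel characters
(states {absent, A, C, G, T}) are handled like any other column, which is
what lets a whitelisted insertion column carry two independent insertion
events with different bases.

Feasible links are computed with the bottleneck (minimax-path)
characterisation: a pair (u, v) is linked iff d(u, v) ≤ b(u, v) + ε where
b(u, v) is the smallest possible maximum edge length over paths from u to v
in the complete distance graph.  For ε = 0 this is exactly the minimum
spanning network, and raising ε only ever adds links.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .errors import InputError
from .refcoords import HaplotypeAlignment, RefInterval, RefPosition, extract_region

MISSING = "N"


@dataclass
class HaplotypeCluster:
    """Labels identical over the analyzed variable columns, collapsed to one
    network node ("revised haplotype")."""

    cluster_id: str
    members: list[str]
    state_vector: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError("cluster with no members")

    @property
    def size(self) -> int:
        return len(self.members)


def variable_columns(aln: HaplotypeAlignment) -> list[int]:
    """Indices of columns with at least two distinct non-N states."""
    out = []
    for i in range(aln.ncols):
        states = {s for s in aln.column(i) if s != MISSING}
        if len(states) >= 2:
            out.append(i)
    return out


def _compatible(pattern: tuple[str, ...], vec: tuple[str, ...]) -> bool:
    return all(a == b or a == MISSING or b == MISSING for a, b in zip(pattern, vec))


def _merge(pattern: tuple[str, ...], vec: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(b if a == MISSING else a for a, b in zip(pattern, vec))


def collapse_haplotypes(
    aln: HaplotypeAlignment,
    region: Optional[RefInterval] = None,
    missing: str = "permissive",
) -> tuple[list[HaplotypeCluster], list[RefPosition]]:
    """Collapse labels identical over the region's variable columns.

    Returns the clusters and the RefPositions of the variable columns.  In
    ``"permissive"`` mode an N matches any base, so partially sequenced
    haplotypes merge into the first compatible cluster (in input order) and
    residual Ns in a cluster's vector are filled with the column-wise
    majority state over all sequences; ``"strict"`` requires exact identity.
    """
    if not aln.labels:
        raise InputError("empty alignment")
    if region is not None:
        aln = extract_region(aln, region)
    var_idx = variable_columns(aln)
    positions = [aln.colmap[i] for i in var_idx]
    vectors = {
        lab: tuple(aln.rows[r][i] for i in var_idx)
        for r, lab in enumerate(aln.labels)
    }

    clusters: list[HaplotypeCluster] = []
    for lab in aln.labels:
        vec = vectors[lab]
        placed = False
        for cl in clusters:
            if missing == "permissive":
                if _compatible(cl.state_vector, vec):
                    cl.members.append(lab)
                    cl.state_vector = _merge(cl.state_vector, vec)
                    placed = True
                    break
            elif cl.state_vector == vec:
                cl.members.append(lab)
                placed = True
                break
        if not placed:
            clusters.append(HaplotypeCluster(lab, [lab], vec))

    # fill any residual missing states with the column majority
    fill = []
    for i in var_idx:
        counts = Counter(s for s in aln.column(i) if s != MISSING)
        fill.append(counts.most_common(1)[0][0])
    for cl in clusters:
        cl.state_vector = tuple(
            f if s == MISSING else s for s, f in zip(cl.state_vector, fill)
        )
    return clusters, positions


def weighted_distance(
    a: Sequence[str], b: Sequence[str], w: Sequence[int]
) -> int:
    """Weighted Hamming distance; missing states contribute 0."""
    if not (len(a) == len(b) == len(w)):
        raise InputError("state vectors / weights length mismatch")
    return sum(
        wi for ai, bi, wi in zip(a, b, w)
        if ai != bi and ai != MISSING and bi != MISSING
    )


@dataclass
class HaplotypeNetwork:
    """A median-joining network: observed clusters plus median vectors.

    Backed by a networkx graph whose nodes carry ``vector`` (state tuple),
    ``is_median`` and ``members`` attributes, and whose edges carry
    ``labels`` (the RefPositions at which the endpoint vectors differ) and
    ``length`` (the weighted distance).
    """

    graph: nx.Graph
    positions: list[RefPosition]
    weights: list[int]
    epsilon: int = 0

    def node_vector(self, node: str) -> tuple[str, ...]:
        return self.graph.nodes[node]["vector"]

    def is_median(self, node: str) -> bool:
        return bool(self.graph.nodes[node]["is_median"])

    @property
    def median_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.is_median(n)]

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if not self.is_median(n)]

    def edge_labels(self, u: str, v: str) -> tuple[RefPosition, ...]:
        return self.graph.edges[u, v]["labels"]

    def spanning_length(self, exact_limit: int = 14) -> int:
        """Tree length of the network: the minimal total weighted length of
        a tree connecting every observed node, using any subset of the
        network's median vectors as optional branching points.

        The network typically carries several equally parsimonious
        alternative medians, and a tree is only charged for the medians it
        actually routes through; connections are scored by the weighted
        vector distance.  Exact (enumeration over median subsets) up to
        ``exact_limit`` medians; beyond that a deterministic hill-climbing
        heuristic adds medians one at a time while they shorten the tree.
        """
        obs = sorted(self.observed_nodes)
        vecs = [self.node_vector(n) for n in obs] + [
            self.node_vector(n) for n in sorted(self.median_nodes)
        ]
        return _tree_length(vecs, len(obs), self.weights, exact_limit)

    def total_edge_length(self) -> int:
        return int(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def to_node_table(self):
        import pandas as pd

        rows = [
            {
                "id": n,
                "members": ",".join(d.get("members", ()) or ()),
                "is_median": int(d["is_median"]),
                "size": len(d.get("members", ()) or ()),
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["id", "members", "is_median", "size"])

    def to_edge_table(self):
        import pandas as pd

        rows = [
            {
                "node1": u,
                "node2": v,
                "labels": ",".join(str(p) for p in d["labels"]),
                "weighted_length": d["length"],
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["node1", "node2", "labels", "weighted_length"]
        )

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(
                n,
                vector="".join(d["vector"]),
                is_median=int(d["is_median"]),
                members=",".join(d.get("members", ()) or ()),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(
                u, v,
                labels=",".join(str(p) for p in d["labels"]),
                length=int(d["length"]),
            )
        nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# median-joining internals

def _tree_length(
    vectors: list[tuple[str, ...]],
    n_obs: int,
    weights: Sequence[int],
    exact_limit: int = 14,
) -> int:
    """Minimal MST length over the observed vectors (the first ``n_obs``)
    plus any subset of the remaining (median) vectors, under weighted
    vector distance.  Exact by subset enumeration up to ``exact_limit``
    medians, deterministic hill-climbing beyond."""
    from scipy.sparse.csgraph import minimum_spanning_tree as _mst

    if n_obs <= 1:
        return 0
    n = len(vectors)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = weighted_distance(vectors[i], vectors[j], weights)

    def mst_total(idx: list[int]) -> int:
        return int(round(_mst(D[np.ix_(idx, idx)]).sum()))

    obs_idx = list(range(n_obs))
    med_idx = list(range(n_obs, n))
    if len(med_idx) <= exact_limit:
        return min(
            mst_total(obs_idx + list(extra))
            for r in range(len(med_idx) + 1)
            for extra in itertools.combinations(med_idx, r)
        )
    chosen: list[int] = []
    best = mst_total(obs_idx)
    while True:
        gains = [
            (mst_total(obs_idx + chosen + [m]), m)
            for m in med_idx
            if m not in chosen
        ]
        if not gains:
            break
        tot, m = min(gains)
        if tot >= best:
            break
        best = tot
        chosen.append(m)
    return best


def _distance_matrix(vectors: list[tuple[str, ...]], w: Sequence[int]) -> np.ndarray:
    n = len(vectors)
    D = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = weighted_distance(vectors[i], vectors[j], w)
    return D


def _bottleneck_matrix(D: np.ndarray) -> np.ndarray:
    """Minimax path distances over the complete graph (Floyd–Warshall on the
    (min, max) semiring)."""
    B = D.astype(np.int64).copy()
    n = len(B)
    for k in range(n):
        np.minimum(B, np.maximum.outer(B[:, k], B[k, :]), out=B)
    return B


def _feasible_links(D: np.ndarray, epsilon: int) -> np.ndarray:
    B = _bottleneck_matrix(D)
    feas = D <= B + epsilon
    np.fill_diagonal(feas, False)
    return feas


def _quasi_medians(
    u: tuple[str, ...], v: tuple[str, ...], w: tuple[str, ...],
    max_variants: int = 4096,
) -> list[tuple[str, ...]]:
    """Column-wise majority consensus of a triplet; columns where all three
    states differ branch into all three choices (quasi-medians)."""
    options: list[tuple[str, ...]] = []
    n_variants = 1
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append((a, b, c))
            n_variants *= 3
            if n_variants > max_variants:
                raise InputError("too many quasi-median variants in one triplet")
    return [tuple(m) for m in itertools.product(*options)]


def build_mj_network(
    clusters: Sequence[HaplotypeCluster],
    weights: Sequence[int],
    epsilon: int = 0,
    positions: Optional[Sequence[RefPosition]] = None,
    max_rounds: int = 100,
    steiner_completion: Optional[bool] = None,
) -> HaplotypeNetwork:
    """Median-joining network over haplotype clusters.

    ``weights`` gives one integer weight per variable column (at least one
    must be positive); ``positions`` names the columns for edge labels
    (defaults to 1..n).  Deterministic: observed nodes are processed in
    cluster-id order and candidate medians in (cost, vector) order.

    The classic greedy iteration (only medians of minimal connection cost
    per round) can, at ε = 0, occasionally strand a cost-reducing median
    behind links that earlier medians made infeasible.  A completion sweep
    therefore re-proposes quasi-medians of every linked pair with every
    third node and accepts any that strictly shorten the minimal connection
    length, repeating until a true fixed point.  The sweep is exponential in
    the median count, so by default (``steiner_completion=None``) it runs
    only for networks of at most 12 observed haplotypes; pass True/False to
    force either behavior.
    """
    if len(clusters) < 2:
        raise InputError("need at least 2 clusters to build a network")
    ncol = len(clusters[0].state_vector)
    weights = list(weights)
    if len(weights) != ncol:
        raise InputError("one weight per variable column required")
    if ncol and not any(w > 0 for w in weights):
        raise InputError("at least one positive weight required")
    if positions is None:
        positions = [RefPosition(i + 1) for i in range(ncol)]
    positions = list(positions)

    observed = sorted(clusters, key=lambda c: c.cluster_id)
    vectors: list[tuple[str, ...]] = [c.state_vector for c in observed]
    ids: list[str] = [c.cluster_id for c in observed]
    n_obs = len(observed)
    obs_ids = set(ids)
    median_counter = 0
    median_ids: set[str] = set()
    seen_vectors = set(vectors)

    def prune_obsolete() -> None:
        """Iteratively drop synthetic nodes with fewer than 3 feasible
        links that do not shorten the network (a degree ≤ 2 median can
        still be a Steiner branching point of the minimal tree, in which
        case it stays)."""
        nonlocal vectors, ids
        while len(vectors) > 2:
            D = _distance_matrix(vectors, weights)
            feas = _feasible_links(D, epsilon)
            deg = feas.sum(axis=1)
            removable = [
                i for i in range(len(vectors)) if i >= n_obs and deg[i] <= 2
            ]
            if not removable:
                return
            current = _tree_length(vectors, n_obs, weights)
            # lowest degree first, vector as deterministic tie-break
            for drop in sorted(removable, key=lambda i: (deg[i], vectors[i])):
                without = vectors[:drop] + vectors[drop + 1:]
                if _tree_length(without, n_obs, weights) <= current:
                    del vectors[drop], ids[drop]
                    break
            else:
                return

    for _ in range(max_rounds):
        prune_obsolete()
        D = _distance_matrix(vectors, weights)
        feas = _feasible_links(D, epsilon)
        n = len(vectors)
        candidates: dict[tuple[str, ...], int] = {}
        for i, j, k in itertools.combinations(range(n), 3):
            linked = int(feas[i, j]) + int(feas[i, k]) + int(feas[j, k])
            if linked < 2:
                continue
            for m in _quasi_medians(vectors[i], vectors[j], vectors[k]):
                if m in seen_vectors:
                    continue
                cost = (
                    weighted_distance(vectors[i], m, weights)
                    + weighted_distance(vectors[j], m, weights)
                    + weighted_distance(vectors[k], m, weights)
                )
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = sorted(
            (m for m, c in candidates.items() if c <= lam + epsilon),
            key=lambda m: (candidates[m], m),
        )
        for m in new:
            median_counter += 1
            mid = f"MV{median_counter}"
            while mid in obs_ids:
                mid += "_"
            vectors.append(m)
            ids.append(mid)
            median_ids.add(mid)
            seen_vectors.add(m)

    prune_obsolete()

    members = {c.cluster_id: tuple(c.members) for c in observed}

    def make_network(vecs: list[tuple[str, ...]], nids: list[str],
                     med_ids: set[str]) -> HaplotypeNetwork:
        D = _distance_matrix(vecs, weights)
        feas = _feasible_links(D, epsilon)
        g = nx.Graph()
        for nid, vec in zip(nids, vecs):
            g.add_node(
                nid,
                vector=vec,
                is_median=nid in med_ids,
                members=members.get(nid, ()),
            )
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                if feas[i, j]:
                    labels = tuple(
                        p
                        for p, a, b in zip(positions, vecs[i], vecs[j])
                        if a != b and a != MISSING and b != MISSING
                    )
                    g.add_edge(nids[i], nids[j], labels=labels,
                               length=int(D[i, j]))
        return HaplotypeNetwork(
            graph=g, positions=positions, weights=weights, epsilon=epsilon
        )

    if steiner_completion is None:
        steiner_completion = n_obs <= 12
    if steiner_completion:
        for _ in range(max_rounds):
            best_len = _tree_length(vectors, n_obs, weights)
            n = len(vectors)
            candidates: set[tuple[str, ...]] = set()
            for i, j, k in itertools.combinations(range(n), 3):
                candidates.update(
                    _quasi_medians(vectors[i], vectors[j], vectors[k])
                )
            candidates -= set(vectors)
            best = None
            for m in sorted(candidates):
                tlen = _tree_length(vectors + [m], n_obs, weights)
                if tlen < best_len and (best is None or (tlen, m) < best):
                    best = (tlen, m)
            if best is None:
                break
            median_counter += 1
            mid = f"MV{median_counter}"
            while mid in obs_ids:
                mid += "_"
            vectors.append(best[1])
            ids.append(mid)
            median_ids.add(mid)
            seen_vectors.add(best[1])
            prune_obsolete()

    return make_network(vectors, ids, median_ids)
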