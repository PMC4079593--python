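"""Network annotation: mutation frequencies, hotspots, inverse-frequency
weights, haplogroup-diagnostic motifs and placement reports.

A position's *frequency* is the number of network branches (edges, including
those incident to median vectors) whose label set contains it.  Positions
recurring on several independent branches are homoplasic "hotspots" and are
weak phylogenetic markers; positions mutating exactly once are strong
candidates for a haplogroup-diagnostic motif.  The motif of a haplogroup is
read off the stem: the labels on the minimal edge cut separating the
haplogroup's nodes from the rest of the network, restricted to frequency-1
positions.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError, TopologyError
from .mjnet import HaplotypeNetwork
from .refcoords import RefPosition


@dataclass
class FrequencyTable:
    """Per-position edge-occurrence counts over a network."""

    counts: dict[RefPosition, int]

    def __getitem__(self, pos: RefPosition) -> int:
        return self.counts[pos]

    def get(self, pos: RefPosition, default: int = 0) -> int:
        return self.counts.get(pos, default)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def hotspots(self) -> list[RefPosition]:
        """All positions attaining the maximum frequency (ties reported)."""
        if not self.counts:
            return []
        top = max(self.counts.values())
        return sorted(p for p, c in self.counts.items() if c == top)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"position": str(p), "frequency": c}
            for p, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["position", "frequency"])


@dataclass
class MotifReport:
    """Diagnostic-motif candidates for one haplogroup.

    ``stem_positions`` lists every position on the stem cut with its
    network-wide frequency; ``motif`` is the frequency-1 subset;
    ``ancestor_candidate`` is the external node adjacent to the cut that is
    closest to the haplogroup.
    """

    haplogroup: str
    stem_positions: list[tuple[RefPosition, int]]
    motif: list[RefPosition] = field(init=False)
    ancestor_candidate: Optional[str] = None

    def __post_init__(self) -> None:
        self.motif = sorted(p for p, f in self.stem_positions if f == 1)

    def to_dict(self) -> dict:
        return {
            "haplogroup": self.haplogroup,
            "stem_positions": [
                {"position": str(p), "frequency": f}
                for p, f in self.stem_positions
            ],
            "motif": [str(p) for p in self.motif],
            "ancestor_candidate": self.ancestor_candidate,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def mutation_frequencies(net: HaplotypeNetwork) -> FrequencyTable:
    """Count, per reference position, the edges whose label set contains it
    (branches incident to median vectors included)."""
    counts: Counter = Counter()
    for _, _, d in net.graph.edges(data=True):
        counts.update(d["labels"])
    return FrequencyTable(dict(counts))


def inverse_frequency_weights(
    ft: FrequencyTable,
    scale: int = 10,
    positions: Optional[Iterable[RefPosition]] = None,
) -> dict[RefPosition, int]:
    """Integer position weights inversely proportional to mutation
    frequency: w = clamp(round(scale / f), 1, 99).  Positions absent from
    the table (no observed mutation) get the full ``scale`` weight."""
    if scale <= 0:
        raise InputError(f"weight scale must be positive, got {scale}")
    out: dict[RefPosition, int] = {}
    for pos, f in ft.counts.items():
        out[pos] = int(min(99, max(1, round(scale / f))))
    for pos in positions or ():
        out.setdefault(pos, int(min(99, max(1, scale))))
    return out


def infer_motif(
    net: HaplotypeNetwork,
    ft: FrequencyTable,
    haplogroup_nodes: Iterable[str],
    haplogroup: str = "",
) -> MotifReport:
    """Diagnostic motif of a haplogroup from its stem cut.

    The stem cut is the set of edges with exactly one endpoint in the
    haplogroup node set.  Both the haplogroup-induced subnetwork and its
    complement must be connected — a reticulate haplogroup whose node set
    cannot be separated by a single stem is refused rather than guessed at.
    """
    nodes = set(haplogroup_nodes)
    g = net.graph
    unknown = nodes - set(g.nodes)
    if unknown:
        raise InputError(f"unknown nodes: {sorted(unknown)}")
    other_obs = {n for n in net.observed_nodes if n not in nodes}
    if not nodes or not other_obs:
        raise TopologyError("haplogroup node set must be a proper subset")
    # median vectors are unsampled intermediates: the minimum cut assigns
    # each to whichever side needs it, with observed nodes as terminals
    flow = nx.Graph()
    flow.add_nodes_from(g.nodes)
    for u, v in g.edges:
        flow.add_edge(u, v, capacity=1)
    big = g.number_of_edges() + 1
    for n in sorted(nodes):
        flow.add_edge("__src__", n, capacity=big)
    for n in sorted(other_obs):
        flow.add_edge(n, "__snk__", capacity=big)
    _, (reach, nonreach) = nx.minimum_cut(flow, "__src__", "__snk__")
    side = (reach - {"__src__"}) & set(g.nodes)
    rest = set(g.nodes) - side
    if not nx.is_connected(g.subgraph(side)):
        raise TopologyError(
            f"haplogroup {haplogroup or nodes} does not induce a connected "
            "subnetwork; motif undefined"
        )
    if not nx.is_connected(g.subgraph(rest)):
        raise TopologyError(
            f"complement of haplogroup {haplogroup or nodes} is disconnected; "
            "motif undefined"
        )
    cut = [
        (u, v, d)
        for u, v, d in g.edges(data=True)
        if (u in side) != (v in side)
    ]
    nodes = side
    stem: dict[RefPosition, int] = {}
    for _, _, d in cut:
        for p in d["labels"]:
            stem[p] = ft.get(p, 1)
    # ancestor candidate: external cut endpoint nearest to the haplogroup
    best, best_len = None, None
    for u, v, d in cut:
        ext = v if u in nodes else u
        if best_len is None or (d["length"], ext) < (best_len, best):
            best, best_len = ext, d["length"]
    return MotifReport(
        haplogroup=haplogroup,
        stem_positions=sorted(stem.items()),
        ancestor_candidate=best,
    )


def cluster_distance_report(
    net: HaplotypeNetwork, a: str, b: str
) -> dict:
    """Shortest weighted path between two nodes with per-branch labels.

    Returns the path, its total weighted length, the total number of
    position labels along it, and each branch's label set — the evidence
    behind placement statements such as "25 differences".
    """
    g = net.graph
    for n in (a, b):
        if n not in g:
            raise InputError(f"unknown node {n!r}")
    path = nx.shortest_path(g, a, b, weight="length")
    branches = []
    total_labels = 0
    total_length = 0
    for u, v in zip(path, path[1:]):
        d = g.edges[u, v]
        branches.append(
            {
                "from": u,
                "to": v,
                "labels": [str(p) for p in d["labels"]],
                "weighted_length": int(d["length"]),
            }
        )
        total_labels += len(d["labels"])
        total_length += int(d["length"])
    return {
        "from": a,
        "to": b,
        "path": path,
        "total_weighted_length": total_length,
        "total_label_count": total_labels,
        "branches": branches,
    }
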