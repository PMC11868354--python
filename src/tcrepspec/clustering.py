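"""Hamming-distance-1 CDR3 similarity graphs and cluster motif summaries.

Two CDR3 amino-acid sequences are joined by an edge when they have equal
length and differ at exactly one position. A cluster is a connected component
with at least two members (singletons are never reported). Components are
found by single-linkage at distance 1, which matches the operational cluster
definition "each sequence differs in only one amino acid from at least one
other sequence in the cluster".

The graph is built in O(n * L) expected time by bucketing sequences on
(length, position, sequence-with-that-position-deleted): two unique
equal-length sequences share a bucket iff they differ exactly at the deleted
position.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .resources import AMINO_ACIDS


@dataclass
class ClusterGraph:
    """Hamming-1 similarity graph plus its size->=2 connected components.

    ``clusters`` maps a reproducible cluster id (the lexicographically
    smallest member sequence) to the sorted member list.
    """

    graph: nx.Graph
    clusters: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_clustered(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    @property
    def fraction_clustered(self) -> float:
        return self.n_clustered / self.n_nodes if self.n_nodes else 0.0

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges()}


def hamming1_graph(
    sequences: Iterable[str],
    metadata: Optional[Mapping[str, dict]] = None,
) -> ClusterGraph:
    """Build the Hamming-1 graph over unique CDR3 sequences.

    ``metadata`` optionally attaches per-sequence node attributes (e.g.
    ``donor_ids``, ``group`` sets) used by :func:`cluster_summary`.
    """
    seqs = sorted(set(sequences))
    g = nx.Graph()
    g.add_nodes_from(seqs)
    buckets: dict[tuple[int, int, str], list[str]] = defaultdict(list)
    for s in seqs:
        L = len(s)
        for i in range(L):
            buckets[(L, i, s[:i] + s[i + 1 :])].append(s)
    for members in buckets.values():
        if len(members) > 1:
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    g.add_edge(a, b)
    if metadata:
        for s in seqs:
            g.nodes[s].update(metadata.get(s, {}))
    clusters = {}
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            members = sorted(comp)
            clusters[members[0]] = members
    return ClusterGraph(graph=g, clusters=clusters)


def cluster_summary(cg: ClusterGraph, group_labels: Sequence[str] = ()) -> pd.DataFrame:
    """One row per cluster: size, length, donor and group composition.

    Expects node metadata ``donor_ids`` (set of donor identifiers) and/or
    ``groups`` (set of group labels); absent metadata yields zero counts.
    Per-group member counts appear as ``n_<group>`` columns for the labels in
    ``group_labels`` (a member counts toward every group it occurs in).
    """
    rows = []
    for cid in sorted(cg.clusters):
        members = cg.clusters[cid]
        donors: set = set()
        groups: set = set()
        group_counts = {f"n_{lbl}": 0 for lbl in group_labels}
        for m in members:
            attrs = cg.graph.nodes[m]
            donors |= set(attrs.get("donor_ids", ()))
            member_groups = set(attrs.get("groups", ()))
            groups |= member_groups
            for lbl in member_groups & set(group_labels):
                group_counts[f"n_{lbl}"] += 1
        rows.append(
            {
                "cluster_id": cid,
                "size": len(members),
                "length": len(cid),
                "n_donors": len(donors),
                "n_groups": len(groups),
                **group_counts,
            }
        )
    cols = ["cluster_id", "size", "length", "n_donors", "n_groups"] + [
        f"n_{lbl}" for lbl in group_labels
    ]
    return pd.DataFrame(rows, columns=cols)


def cluster_pfm(cluster: Sequence[str]) -> pd.DataFrame:
    """Position-frequency matrix of an equal-length sequence cluster.

    Returns an L x 20 DataFrame (rows = positions 1..L, columns = amino
    acids, each row summing to 1), the orientation sequence-logo tools
    consume directly.
    """
    members = list(cluster)
    if not members:
        raise ValueError("empty cluster")
    L = len(members[0])
    if any(len(s) != L for s in members):
        raise ValueError("cluster members must have equal length")
    counts = pd.DataFrame(
        0.0, index=pd.RangeIndex(1, L + 1, name="position"), columns=list(AMINO_ACIDS)
    )
    for s in members:
        for pos, aa in enumerate(s, start=1):
            counts.at[pos, aa] += 1.0
    return counts / len(members)


def write_graph(cg: ClusterGraph, edges_path, membership_path) -> None:
    """Export the edge list (TSV) and cluster membership (CSV)."""
    pd.DataFrame(sorted(tuple(sorted(e)) for e in cg.graph.edges()),
                 columns=["seq_a", "seq_b"]).to_csv(edges_path, sep="\t", index=False)
    rows = [
        (cid, m) for cid in sorted(cg.clusters) for m in cg.clusters[cid]
    ]
    pd.DataFrame(rows, columns=["cluster_id", "cdr3_aa"]).to_csv(
        membership_path, index=False
    )


def spring_layout_table(cg: ClusterGraph, seed: int = 0) -> pd.DataFrame:
    """2-D spring-layout coordinates for clustered nodes (plotting data)."""
    sub = cg.graph.subgraph([m for ms in cg.clusters.values() for m in ms])
    pos = nx.spring_layout(sub, seed=seed)
    return pd.DataFrame(
        [(s, xy[0], xy[1]) for s, xy in sorted(pos.items())],
        columns=["cdr3_aa", "x", "y"],
    )
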