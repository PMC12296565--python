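"""Median-Joining haplotype networks.

Starting from the distinct haplotypes of a group, the algorithm

1. computes pairwise Hamming distances over the comparison mask,
2. builds the epsilon-relaxed minimum-spanning network (union of all
   minimum spanning trees, plus links within epsilon of feasibility),
3. proposes, for connected triplets, the per-site majority median
   ("median vector"); a median is adopted when it reduces the total network
   length (minimum spanning length over the node set),
4. iterates to a fixed point, and
5. prunes median vectors whose removal leaves the total length unchanged.

Sites are handled natively over the nucleotide alphabet; a triplet with
three distinct states at any site proposes no median (the majority is
undefined there). Character weights are uniform. Iteration order is
deterministic (lexicographic by node name / sequence) so repeated runs give
identical networks.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeTable


@dataclasses.dataclass(frozen=True)
class NetNode:
    name: str
    sequence: str
    observed: bool
    count: int


@dataclasses.dataclass(frozen=True)
class HaplotypeNetwork:
    """Nodes (observed haplotypes + median vectors) and weighted edges."""

    nodes: tuple[NetNode, ...]
    edges: tuple[tuple[str, str, int], ...]  # (nameA, nameB, hamming weight)
    epsilon: int

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.name, sequence=node.sequence, observed=node.observed, count=node.count)
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def total_length(self) -> int:
        """Minimum spanning length over the network's nodes."""
        g = self.graph()
        return int(sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)))

    def path_weight(self, a: str, b: str) -> int:
        """Total weight of the lightest path between two named nodes."""
        return int(nx.shortest_path_length(self.graph(), a, b, weight="weight"))


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def _mst_length(seqs: list[np.ndarray]) -> int:
    """Minimum spanning length of the complete Hamming graph (Prim)."""
    m = len(seqs)
    if m < 2:
        return 0
    mat = np.zeros((m, m), dtype=np.int64)
    for i, j in itertools.combinations(range(m), 2):
        mat[i, j] = mat[j, i] = _hamming(seqs[i], seqs[j])
    in_tree = np.zeros(m, dtype=bool)
    best = np.full(m, np.iinfo(np.int64).max)
    in_tree[0] = True
    best = mat[0].copy()
    best[0] = np.iinfo(np.int64).max
    total = 0
    for _ in range(m - 1):
        nxt = int(np.argmin(np.where(in_tree, np.iinfo(np.int64).max, best)))
        total += int(best[nxt])
        in_tree[nxt] = True
        best = np.minimum(best, mat[nxt])
        best[in_tree] = np.iinfo(np.int64).max
    return total


def _minimax(mst: nx.Graph, u: str, v: str) -> int:
    """Largest edge weight on the (unique) MST path between u and v."""
    path = nx.shortest_path(mst, u, v)
    return max(mst[a][b]["weight"] for a, b in zip(path, path[1:]))


def _msn_edges(names: list[str], arrs: dict[str, np.ndarray], epsilon: int) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum-spanning-network edges.

    An edge (u, v) is feasible iff its weight is within epsilon of the
    minimax distance between u and v (the threshold at which they become
    connected); epsilon = 0 yields the union of all MSTs.
    """
    g = nx.Graph()
    g.add_nodes_from(names)
    for u, v in itertools.combinations(sorted(names), 2):
        g.add_edge(u, v, weight=_hamming(arrs[u], arrs[v]))
    mst = nx.minimum_spanning_tree(g)
    edges = []
    for u, v in itertools.combinations(sorted(names), 2):
        w = g[u][v]["weight"]
        if w <= _minimax(mst, u, v) + epsilon:
            edges.append((u, v, int(w)))
    return edges


def _triple_median(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray | None:
    """Per-site majority of three sequences; None when any site is a
    three-way tie (majority undefined)."""
    med = a.copy()
    take_b = (b == c) & (a != b)
    med[take_b] = b[take_b]
    undecided = (a != b) & (b != c) & (a != c)
    if undecided.any():
        return None
    return med


def mj_network(table: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """Median-Joining network of a haplotype table.

    A single haplotype yields the trivial one-node network. Heterogeneous
    sequence lengths are an error.
    """
    names = [h.name for h in table.haplotypes]
    seqs = {h.name: h.sequence for h in table.haplotypes}
    counts = {h.name: h.count for h in table.haplotypes}
    return network_from_sequences(names, seqs, counts, epsilon=epsilon)


def network_from_sequences(
    names: list[str],
    seqs: dict[str, str],
    counts: dict[str, int] | None = None,
    epsilon: int = 0,
) -> HaplotypeNetwork:
    """Median-Joining network from named equal-length sequences."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    lengths = {len(seqs[n]) for n in names}
    if len(lengths) > 1:
        raise ValueError("haplotype sequences have heterogeneous lengths")
    counts = counts or {n: 1 for n in names}
    if len(names) == 1:
        node = NetNode(names[0], seqs[names[0]], True, counts[names[0]])
        return HaplotypeNetwork(nodes=(node,), edges=(), epsilon=epsilon)

    arrs: dict[str, np.ndarray] = {
        n: np.frombuffer(seqs[n].encode("ascii"), dtype=np.uint8).copy() for n in names
    }
    observed = set(names)
    median_counter = 0

    def current_length() -> int:
        return _mst_length([arrs[n] for n in sorted(arrs)])

    # --- median insertion to fixed point -------------------------------
    while True:
        base = current_length()
        existing = {arrs[n].tobytes() for n in arrs}
        edges = _msn_edges(sorted(arrs), arrs, epsilon)
        adj: dict[str, set[str]] = {n: set() for n in arrs}
        for u, v, _ in edges:
            adj[u].add(v)
            adj[v].add(u)
        candidates: dict[bytes, np.ndarray] = {}
        for u, v, w in itertools.combinations(sorted(arrs), 3):
            # connected triplet: at least two of its three links are in the
            # current network
            links = (v in adj[u]) + (w in adj[u]) + (w in adj[v])
            if links < 2:
                continue
            med = _triple_median(arrs[u], arrs[v], arrs[w])
            if med is None:
                continue
            key = med.tobytes()
            if key not in existing:
                candidates[key] = med
        best_gain = 0
        best_key: bytes | None = None
        for key in sorted(candidates):
            trial = _mst_length([arrs[n] for n in sorted(arrs)] + [candidates[key]])
            gain = base - trial
            if gain > best_gain:
                best_gain, best_key = gain, key
        if best_key is None:
            break
        median_counter += 1
        arrs[f"mv{median_counter}"] = candidates[best_key]

    # --- prune obsolete median vectors ---------------------------------
    changed = True
    while changed:
        changed = False
        base = current_length()
        for name in sorted(n for n in arrs if n not in observed):
            rest = [arrs[n] for n in sorted(arrs) if n != name]
            if _mst_length(rest) <= base:
                del arrs[name]
                base = current_length()
                changed = True

    final_names = sorted(arrs, key=lambda n: (n not in observed, n))
    edges = _msn_edges(list(arrs), arrs, epsilon)
    nodes = tuple(
        NetNode(
            name=n,
            sequence=arrs[n].tobytes().decode("ascii"),
            observed=n in observed,
            count=counts.get(n, 0) if n in observed else 0,
        )
        for n in final_names
    )
    return HaplotypeNetwork(nodes=nodes, edges=tuple(sorted(edges)), epsilon=epsilon)


def export_network(net: HaplotypeNetwork, path: str | Path, format: str = "tsv") -> Path:
    """Export a network as edge-list TSV, GraphML, or dot-like text.

    The TSV export writes a companion ``<path>.nodes.tsv`` carrying the
    observed flag, count and sequence so re-import is lossless.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("nodeA\tnodeB\tweight\n")
            for a, b, w in net.edges:
                fh.write(f"{a}\t{b}\t{w}\n")
        with open(path.with_suffix(path.suffix + ".nodes.tsv"), "w") as fh:
            fh.write("name\tobserved\tcount\tsequence\n")
            for node in net.nodes:
                fh.write(f"{node.name}\t{int(node.observed)}\t{node.count}\t{node.sequence}\n")
        return path
    if format == "graphml":
        nx.write_graphml(net.graph(), str(path))
        return path
    if format == "dot":
        lines = ["graph haplotypes {"]
        for node in net.nodes:
            shape = "circle" if node.observed else "point"
            lines.append(f'  "{node.name}" [shape={shape}, count={node.count}];')
        for a, b, w in net.edges:
            lines.append(f'  "{a}" -- "{b}" [label={w}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unknown format {format!r}")


def import_edge_list(path: str | Path) -> HaplotypeNetwork:
    """Re-import a network written by :func:`export_network` (tsv format)."""
    path = Path(path)
    edges = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            edges.append((a, b, int(w)))
    nodes = []
    with open(path.with_suffix(path.suffix + ".nodes.tsv")) as fh:
        next(fh)
        for line in fh:
            name, obs, count, seq = line.rstrip("\n").split("\t")
            nodes.append(NetNode(name, seq, bool(int(obs)), int(count)))
    return HaplotypeNetwork(nodes=tuple(nodes), edges=tuple(sorted(edges)), epsilon=0)
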