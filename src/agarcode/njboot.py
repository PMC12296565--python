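"""Neighbor-Joining trees, column-resampling bootstrap, species monophyly.

The tree builder is the classical Saitou-Nei agglomeration: repeatedly join
the pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with branch lengths from the standard split formula. Ties in the Q matrix
are broken on the lowest (row, column) index pair so trees are reproducible.
Negative branch-length estimates are clamped to zero for display/output;
the raw estimate is retained on the node.

Bootstrap support is obtained by resampling alignment columns with
replacement, rebuilding the NJ tree per replicate, and mapping bipartition
frequencies (percent) onto the point-estimate tree.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from pathlib import Path

import numpy as np

from .alignio import LabeledAlignment
from .distances import DistanceMatrix, distance_matrix, encode, _k2p_from_counts

logger = logging.getLogger(__name__)


class _Node:
    """Tree node; ``length`` is the (clamped) edge length to the parent."""

    __slots__ = ("name", "children", "length", "raw_length", "support")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[_Node] = []
        self.length: float | None = None
        self.raw_length: float | None = None
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["_Node"]:
        if self.is_leaf:
            return [self]
        out: list[_Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclasses.dataclass
class PhyloTree:
    """Unrooted NJ tree, stored rooted at the final trifurcation."""

    root: _Node
    leaf_ids: tuple[str, ...]

    def bipartitions(self) -> dict[frozenset, _Node]:
        """Non-trivial bipartitions, canonicalized to the side not holding
        the first leaf id, mapped to the internal node that induces them."""
        ref = self.leaf_ids[0]
        full = frozenset(self.leaf_ids)
        out: dict[frozenset, _Node] = {}

        def walk(node: _Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(self.leaf_ids) - 1:
                side = full - below if ref in below else below
                out[side] = node
            return below

        walk(self.root)
        return out

    def leaf_path_length(self, a: str, b: str) -> float:
        """Sum of raw branch lengths on the path between two leaves."""
        paths: dict[str, list[_Node]] = {}

        def walk(node: _Node, trail: list["_Node"]) -> None:
            trail = trail + [node]
            if node.is_leaf:
                paths[node.name] = trail
            for c in node.children:
                walk(c, trail)

        walk(self.root, [])
        pa, pb = paths[a], paths[b]
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        return sum(n.raw_length for n in pa[k:]) + sum(n.raw_length for n in pb[k:])

    def newick(self, digits: int = 6) -> str:
        def fmt(node: _Node) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.support is None else f"{int(round(node.support))}"
                body = f"({inner}){label}"
            if node.length is None:
                return body
            return f"{body}:{node.length:.{digits}f}"

        return fmt(self.root) + ";"


def _impute_undefined(d: np.ndarray, quiet: bool = False) -> tuple[np.ndarray, int]:
    """Replace NaN cells with the max defined off-diagonal distance."""
    d = d.copy()
    mask = np.isnan(d)
    n_undef = int(mask.sum() // 2)
    if n_undef:
        defined = d[~mask & ~np.eye(len(d), dtype=bool)]
        fill = float(defined.max()) if defined.size else 1.0
        d[mask] = fill
        (logger.debug if quiet else logger.warning)(
            "imputed %d undefined distance cells with %.6f", n_undef, fill
        )
    return d, n_undef


def _nj_from_matrix(d: np.ndarray, ids: tuple[str, ...], quiet: bool = False) -> PhyloTree:
    n = len(ids)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances; impute undefined cells first")
    nodes = [_Node(rid) for rid in ids]
    d = d.astype(float).copy()
    active = list(range(n))
    n_clamped = 0

    def set_len(node: _Node, raw: float) -> None:
        nonlocal n_clamped
        node.raw_length = float(raw)
        node.length = max(0.0, float(raw))
        if raw < 0:
            n_clamped += 1

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) tie rule: argmin on the flattened array scans
        # row-major, so the first minimum is the lexicographically lowest.
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = _Node()
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        set_len(ni, li)
        set_len(nj_, lj)
        parent.children = [ni, nj_]
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_local, g in enumerate(active):
            d[-1, g] = d[g, -1] = new_row[k_local]
        d[-1, -1] = 0.0
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = _Node()
    for g, raw in ((a, (dab + dac - dbc) / 2), (b, (dab + dbc - dac) / 2), (c, (dac + dbc - dab) / 2)):
        set_len(nodes[g], raw)
        root.children.append(nodes[g])
    if n_clamped:
        (logger.debug if quiet else logger.warning)(
            "clamped %d negative branch length estimate(s) to 0", n_clamped
        )
    return PhyloTree(root=root, leaf_ids=ids)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-Joining tree from a K2P distance matrix.

    Undefined cells are imputed with the maximum defined distance (count
    logged) so saturation flags never abort tree building.
    """
    d, _ = _impute_undefined(dm.d)
    return _nj_from_matrix(d, dm.ids)


def _replicate_matrix(codes: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """K2P matrix for a column-resampled alignment (NaN for undefined)."""
    sub = codes[:, cols]
    n = len(sub)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = sub[i], sub[j]
        valid = (a < 4) & (b < 4)
        diff = valid & (a != b)
        ts = int((diff & ((a & 1) == (b & 1))).sum())
        tv = int(diff.sum()) - ts
        _, _, dist, _ = _k2p_from_counts(ts, tv, int(valid.sum()))
        d[i, j] = d[j, i] = np.nan if dist is None else dist
    return d


def bootstrap_support(aln: LabeledAlignment, B: int = 1000, seed: int = 0) -> PhyloTree:
    """NJ tree with bootstrap support from B column resamples.

    Support on each internal node is the percentage of replicates whose NJ
    tree contains the same bipartition. Reproducible for a fixed seed.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if aln.length < 2:
        raise ValueError("alignment too short to resample")
    dm = distance_matrix(aln)
    tree = nj_tree(dm)
    point_bips = tree.bipartitions()
    counts = {bip: 0 for bip in point_bips}
    codes = np.stack([encode(s) for s in aln.seqs])
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, aln.length, aln.length)
        d, _ = _impute_undefined(_replicate_matrix(codes, cols), quiet=True)
        rep = _nj_from_matrix(d, aln.ids, quiet=True)
        rep_bips = rep.bipartitions()
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for bip, node in point_bips.items():
        node.support = 100.0 * counts[bip] / B
    return tree


def species_monophyly(tree: PhyloTree, species: dict[str, str | None]) -> dict[str, dict]:
    """Per-species monophyly on an unrooted tree.

    A species is monophyletic iff some bipartition separates exactly its
    members (singletons trivially so). ``support`` is the bootstrap percent
    of that bipartition when available.
    """
    bips = tree.bipartitions()
    ref = tree.leaf_ids[0]
    full = frozenset(tree.leaf_ids)
    out: dict[str, dict] = {}
    labels = {sp for sp in species.values() if sp is not None}
    for sp in sorted(labels):
        members = frozenset(rid for rid in tree.leaf_ids if species.get(rid) == sp)
        if len(members) == 1 or len(members) == len(tree.leaf_ids):
            out[sp] = {"monophyletic": True, "support": None, "n": len(members)}
            continue
        side = full - members if ref in members else members
        node = bips.get(side)
        out[sp] = {
            "monophyletic": node is not None,
            "support": None if node is None else node.support,
            "n": len(members),
        }
    return out


def write_newick(tree: PhyloTree, path: str | Path) -> Path:
    """Write Newick with branch lengths and integer supports as labels."""
    path = Path(path)
    path.write_text(tree.newick() + "\n")
    return path
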