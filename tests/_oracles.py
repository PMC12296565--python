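"""Independent oracles used by tests and the acceptance script.

These deliberately avoid the package's own code paths: the site recount is
a per-column pure-Python loop, the Steiner length is an exact
Dreyfus-Wagner dynamic program on the binary hypercube, and the additive
trees are generated directly with networkx.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def recount_pair(seqA: str, seqB: str) -> tuple[int, int, int]:
    """Brute-force per-site classification: (transitions, transversions,
    comparable sites)."""
    ts = tv = n = 0
    for a, b in zip(seqA, seqB):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    return ts, tv, n


def k2p_closed_form(ts: int, tv: int, n: int) -> float | None:
    if n == 0:
        return None
    P, Q = ts / n, tv / n
    a, b = 1 - 2 * P - Q, 1 - 2 * Q
    if a <= 0 or b <= 0:
        return None
    return -0.5 * math.log(a * math.sqrt(b))


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree with positive branch lengths.

    Returns (distance matrix over leaves 'L0'..'L{n-1}', set of non-trivial
    bipartitions canonicalized to the side not containing 'L0').
    """
    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n_leaves)]
    g.add_edge(leaves[0], "I0", weight=float(rng.uniform(0.1, 1.0)))
    g.add_edge(leaves[1], "I0", weight=float(rng.uniform(0.1, 1.0)))
    g.add_edge(leaves[2], "I0", weight=float(rng.uniform(0.1, 1.0)))
    n_internal = 1
    for leaf in leaves[3:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"I{n_internal}"
        n_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.1, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    dm = np.array([[dist[a][b] for b in leaves] for a in leaves])
    bips = set()
    full = frozenset(leaves)
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u) if x in full)
        if 1 < len(side) < n_leaves - 1:
            bips.add(side if "L0" not in side else full - side)
    return dm, leaves, bips


def random_genealogy_haplotypes(
    rng: np.random.Generator,
    n_haps: int,
    n_sites: int,
    max_subs_per_branch: int = 3,
    sample_fraction: float = 0.7,
) -> list[int]:
    """Bit-coded binary haplotypes generated along a random genealogy.

    Each new haplotype derives from a random existing one by 1..max
    substitutions; a fraction of nodes is then left unsampled (ancestral
    types missing from the data), which is what forces median vectors."""
    nodes = [0]
    while len(nodes) < n_haps + 2:
        parent = nodes[rng.integers(0, len(nodes))]
        child = parent
        for _ in range(int(rng.integers(1, max_subs_per_branch + 1))):
            child ^= 1 << int(rng.integers(0, n_sites))
        if child not in nodes:
            nodes.append(child)
    return sorted({n for n in nodes if rng.random() < sample_fraction})


def bits_to_seq(bits: int, n_sites: int) -> str:
    return "".join("G" if (bits >> k) & 1 else "A" for k in range(n_sites))


def steiner_length_binary(terminals: list[int], n_sites: int) -> int:
    """Exact Steiner minimal tree length in the {0,1}^n_sites Hamming
    hypercube (Dreyfus-Wagner, vectorized over the 2^n_sites nodes)."""
    V = 1 << n_sites
    nodes = np.arange(V)
    pop = np.zeros(V, dtype=np.int64)
    for b in range(n_sites):
        pop += (nodes >> b) & 1
    t = len(terminals)
    full = (1 << t) - 1
    INF = np.int64(1 << 40)
    dp: dict[int, np.ndarray] = {}
    for i, term in enumerate(terminals):
        dp[1 << i] = pop[nodes ^ term]

    def closure(best: np.ndarray) -> np.ndarray:
        # min-plus closure with Hamming distance = repeated unit-neighbor
        # relaxation on the hypercube
        best = best.copy()
        for _ in range(V.bit_length() + n_sites):
            changed = False
            for b in range(n_sites):
                cand = best[nodes ^ (1 << b)] + 1
                better = cand < best
                if better.any():
                    best[better] = cand[better]
                    changed = True
            if not changed:
                break
        return best

    for size in range(2, t + 1):
        for subset in itertools.combinations(range(t), size):
            S = sum(1 << i for i in subset)
            best = np.full(V, INF)
            sub = (S - 1) & S
            while sub:
                comp = S & ~sub
                if comp and sub <= comp:
                    best = np.minimum(best, dp[sub] + dp[comp])
                sub = (sub - 1) & S
            dp[S] = closure(best)
    return int(dp[full].min())
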