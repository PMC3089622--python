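"""Independent brute-force oracles used to cross-check the metric engine.

Everything here works directly on a dendropy tree via explicit path
enumeration, deliberately sharing no code with the package's vectorised
implementations.
"""

from __future__ import annotations

import numpy as np


def random_newick(rng: np.random.Generator, n_tips: int) -> str:
    """A random binary tree with uniform-random branch lengths in (0.05, 2)."""
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [f"{lab}:{rng.uniform(0.05, 2.0):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.uniform(0.05, 2.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    # strip the root edge length
    body = nodes[0].rsplit(":", 1)[0]
    return body + ";"


def _path_edges_to_root(dtree, label):
    """Edges (as node ids with lengths) on the path from a tip to the root."""
    node = next(
        leaf for leaf in dtree.leaf_node_iter() if leaf.taxon.label == label
    )
    edges = []
    while node.parent_node is not None:
        edges.append((id(node), node.edge.length))
        node = node.parent_node
    return edges


def patristic_bruteforce(dtree, a: str, b: str) -> float:
    """Symmetric-difference of the two root paths."""
    ea = dict(_path_edges_to_root(dtree, a))
    eb = dict(_path_edges_to_root(dtree, b))
    sym = set(ea) ^ set(eb)
    total = {**ea, **eb}
    return sum(total[e] for e in sym)


def pd_bruteforce(dtree, community) -> float:
    """Union of tip-to-root path edges, minus the MRCA-to-root path."""
    community = sorted(set(community))
    union: dict[int, float] = {}
    per_tip = []
    for sp in community:
        edges = dict(_path_edges_to_root(dtree, sp))
        per_tip.append(set(edges))
        union.update(edges)
    shared = set.intersection(*per_tip) if per_tip else set()
    return sum(l for e, l in union.items() if e not in shared)


def mnnd_bruteforce(dtree, community) -> float:
    community = sorted(set(community))
    total = 0.0
    for a in community:
        total += min(patristic_bruteforce(dtree, a, b) for b in community if b != a)
    return total / len(community)


def mpd_bruteforce(dtree, community) -> float:
    community = sorted(set(community))
    dists = [
        patristic_bruteforce(dtree, a, b)
        for i, a in enumerate(community)
        for b in community[i + 1 :]
    ]
    return sum(dists) / len(dists)


def cross_mnnd_bruteforce(dtree, focal, reference) -> float:
    focal, reference = sorted(set(focal)), sorted(set(reference))
    total = 0.0
    for f in focal:
        total += min(patristic_bruteforce(dtree, f, r) for r in reference)
    return total / len(focal)
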