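"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from methylatlas import repertoire as rp

INF = float("inf")


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted topology over A..H, polytomies allowed (join 2-4)."""
    nodes = [chr(ord("A") + i) for i in range(n_leaves)]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(4, len(nodes)) + 1))
        idx = rng.choice(len(nodes), size=k, replace=False)
        group = [nodes[i] for i in idx]
        rest = [nodes[i] for i in range(len(nodes)) if i not in set(idx.tolist())]
        nodes = rest + ["(" + ",".join(group) + ")"]
    return nodes[0] + ";"


def tree_as_dict(tree: rp.SpeciesTree):
    """Plain children-dict view of a dendropy tree (oracle-side structure)."""
    ids = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is not None and node.taxon.label:
            ids[id(node)] = node.taxon.label
        elif node.label:
            ids[id(node)] = node.label
        else:
            ids[id(node)] = f"node{i}"
    children = {}
    for node in tree.preorder_node_iter():
        children[ids[id(node)]] = [ids[id(c)] for c in node.child_nodes()]
    root = ids[id(tree.seed_node)]
    return children, root


def oracle_min_losses(children: dict, root: str, leaf_state: dict) -> int | None:
    """Exhaustive single-gain minimisation, independent of the MRCA algorithm.

    Enumerates every candidate gain node; for each, a Sankoff-style DP over
    its subtree finds the minimal number of present->absent edges matching
    the leaf pattern (absence is absorbing). Returns the minimum over gain
    placements, or None when no leaf possesses the family.
    """
    if not any(leaf_state.values()):
        return None

    leaves_under: dict[str, set] = {}

    def collect(v: str) -> set:
        if not children[v]:
            leaves_under[v] = {v}
        else:
            leaves_under[v] = set().union(*(collect(c) for c in children[v]))
        return leaves_under[v]

    collect(root)
    possessors = {l for l, b in leaf_state.items() if b}

    def cost(v: str, present: bool) -> float:
        if not children[v]:
            return 0.0 if present == leaf_state[v] else INF
        if not present:
            return 0.0 if not (leaves_under[v] & possessors) else INF
        return sum(min(cost(c, True), 1.0 + cost(c, False)) for c in children[v])

    best = INF
    for g in children:
        if possessors <= leaves_under[g]:
            best = min(best, cost(g, True))
    assert best < INF
    return int(best)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def calibrated_transcriptome():
    """5,000 transcripts at target o/e 0.55 (shared across tests)."""
    from methylatlas import synthdata as sd

    return sd.simulate_transcriptome(
        n=5000, length_range=(500, 3000), gc=0.4, target_oe=0.55, seed=101
    )
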