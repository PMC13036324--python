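"""Shared fixtures: configs, small trees, and an independent RED oracle."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from sedarch.synthetic_data import SimulationConfig


@pytest.fixture
def config() -> SimulationConfig:
    return SimulationConfig(seed=11)


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths (not
    ultrametric) built by repeated joining — used to exercise RED."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    namespace = dendropy.TaxonNamespace(taxa)
    nodes = []
    for label in taxa:
        node = dendropy.Node()
        node.taxon = namespace.get_taxon(label)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        left.edge.length = float(rng.exponential(1.0)) + 1e-3
        right.edge.length = float(rng.exponential(1.0)) + 1e-3
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = nodes[0]
    return tree


def red_oracle(tree: dendropy.Tree) -> dict:
    """Brute-force RED: recursive, recomputing each node's mean distance to
    descendant leaves by explicit path enumeration (independent of the
    implementation's single-pass bookkeeping)."""

    def leaf_distances(node) -> list[float]:
        if node.is_leaf():
            return [0.0]
        out = []
        for child in node.child_nodes():
            e = child.edge.length or 0.0
            out.extend(e + d for d in leaf_distances(child))
        return out

    values = {tree.seed_node: 0.0}

    def walk(node):
        for child in node.child_nodes():
            if child.is_leaf():
                values[child] = 1.0
            else:
                d = child.edge.length or 0.0
                u = d + float(np.mean(leaf_distances(child)))
                p = values[node]
                values[child] = p + (d / u) * (1.0 - p)
            walk(child)

    walk(tree.seed_node)
    return values
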