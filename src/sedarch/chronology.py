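"""Divergence-time classification on time-calibrated trees.

Given a rooted ultrametric tree with branch lengths in Ma (million years ago)
this module derives node ages, maps each tip to the age of its most recent
split ("latest divergence"), and classifies tips as possible ancient species
(PAS, latest divergence strictly older than the eon boundary, 541 Ma by
default — the Cryptozoic/Phanerozoic boundary) or extant. It also computes
group-wise contingency summaries, proportion-over-time curves, relative
evolutionary distance (RED, the GTDB root-to-leaf interpolation), and the
stratified 200-genome subsampler used to keep molecular dating tractable on
large catalogs.

Trees are :class:`dendropy.Tree` objects; tips are addressed by taxon label.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .exceptions import MissingDataError, UltrametricityError

EON_BOUNDARY_MA = 541.0  # Cryptozoic / Phanerozoic
HABITAT_GROUPS = ("Sediment only", "Water only", "Shared")


def _edge_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def node_ages(tree: dendropy.Tree, rel_tol: float = 1e-6) -> dict:
    """Age of every node in Ma (leaves at 0), keyed by ``dendropy.Node``.

    Ages are tree height minus root-to-node path length. The tree must be
    ultrametric: any leaf whose depth deviates from the height by more than
    ``rel_tol`` (relative to the height) makes the tree rejected, and the
    error lists the offending leaves.
    """
    root = tree.seed_node
    depth: dict = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depth[node] = depth[node.parent_node] + _edge_length(node)
    leaves = list(tree.leaf_node_iter())
    if not leaves:
        raise ValueError("tree has no leaves")
    height = max(depth[leaf] for leaf in leaves)
    tol = rel_tol * max(height, 1.0)
    offenders = [
        (leaf.taxon.label if leaf.taxon else "<unlabelled>")
        for leaf in leaves
        if abs(depth[leaf] - height) > tol
    ]
    if offenders:
        raise UltrametricityError(
            f"tree is not ultrametric within relative tolerance {rel_tol}; "
            f"offending leaves: {offenders[:10]}"
            + ("…" if len(offenders) > 10 else ""),
            offenders=offenders,
        )
    return {node: max(height - dist, 0.0) for node, dist in depth.items()}


def latest_divergence(tree: dendropy.Tree) -> dict[str, float]:
    """Per-tip age (Ma) of the immediate parent node — the most recent split
    that involves the tip's lineage."""
    ages = node_ages(tree)
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        parent = leaf.parent_node
        out[leaf.taxon.label] = ages[parent if parent is not None else leaf]
    return out


def classify_pas(
    latest_ages: Mapping[str, float], boundary_ma: float = EON_BOUNDARY_MA
) -> dict[str, str]:
    """PAS/extant call per species: PAS iff latest divergence > boundary
    (strictly; an age exactly at the boundary is extant, "prior to" read
    strictly)."""
    if boundary_ma <= 0:
        raise ValueError("eon boundary must be positive")
    return {
        sp: ("PAS" if age > boundary_ma else "extant")
        for sp, age in latest_ages.items()
    }


def pas_group_summary(
    classification: Mapping[str, str],
    habitat_groups: Mapping[str, str],
    groups: Sequence[str] = HABITAT_GROUPS,
) -> dict:
    """Eon × habitat-group contingency counts with percentages (1 dp).

    ``classification`` maps species → {"PAS", "extant"}; ``habitat_groups``
    maps species → habitat group. Percentages are within each eon (rows sum
    to 100); empty eons give zero rows without division errors.
    """
    missing = [sp for sp in classification if sp not in habitat_groups]
    if missing:
        raise MissingDataError(
            f"species without habitat group: {missing[:10]}"
            + ("…" if len(missing) > 10 else "")
        )
    counts = pd.DataFrame(0, index=["PAS", "extant"], columns=list(groups))
    for sp, cls in classification.items():
        grp = habitat_groups[sp]
        if grp not in counts.columns:
            counts[grp] = 0
        counts.loc[cls, grp] += 1
    totals = counts.sum(axis=1)
    pct = counts.div(totals.replace(0, np.nan), axis=0).mul(100).round(1).fillna(0.0)
    return {
        "counts": counts,
        "percentages": pct,
        "totals": totals.to_dict(),
    }


def proportion_curves(
    latest_ages: Mapping[str, float],
    habitat_groups: Mapping[str, str],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Per-group fraction of species with latest divergence ≥ t over a grid.

    ``grid`` must be strictly decreasing toward 0 (ages in Ma). Curves are
    nondecreasing as t decreases and reach 1 at t = 0 for every nonempty
    group; an empty group yields a flat zero curve with a warning.
    """
    grid = list(grid)
    if any(b >= a for a, b in zip(grid, grid[1:])) or (grid and grid[-1] < 0):
        raise ValueError("grid must be strictly decreasing and nonnegative")
    by_group: dict[str, list[float]] = {}
    for sp, age in latest_ages.items():
        by_group.setdefault(habitat_groups[sp], []).append(age)
    out = {}
    for grp in sorted(by_group) if by_group else []:
        ages = np.asarray(by_group[grp])
        if len(ages) == 0:
            warnings.warn(f"group {grp!r} is empty; flat zero curve", stacklevel=2)
            out[grp] = np.zeros(len(grid))
        else:
            out[grp] = np.array([(ages >= t).mean() for t in grid])
    return pd.DataFrame(out, index=pd.Index(grid, name="age_ma"))


# ---------------------------------------------------------------------------
# relative evolutionary distance
# ---------------------------------------------------------------------------

def red(tree: dendropy.Tree) -> dict:
    """Relative evolutionary distance per node (GTDB interpolation).

    RED(root) = 0 and leaves are assigned 1. For an internal node n with
    parent p, branch length d and u = d + mean distance from n to its
    descendant leaves:  RED(n) = RED(p) + (d/u)·(1 − RED(p)).

    Works on any rooted tree with branch lengths (time or substitution
    units). A zero-length root-to-leaf path makes the interpolation
    undefined and raises.
    """
    # mean distance from each node to its descendant leaves, by postorder
    mean_to_leaves: dict = {}
    n_leaves: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mean_to_leaves[node] = 0.0
            n_leaves[node] = 1
        else:
            total, count = 0.0, 0
            for child in node.child_nodes():
                total += (mean_to_leaves[child] + _edge_length(child)) * n_leaves[child]
                count += n_leaves[child]
            mean_to_leaves[node] = total / count
            n_leaves[node] = count

    root = tree.seed_node
    out: dict = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.is_leaf():
            out[node] = 1.0
            continue
        d = _edge_length(node)
        u = d + mean_to_leaves[node]
        if u == 0:
            raise ValueError(
                "zero-length root-to-leaf path; RED undefined at an internal node"
            )
        parent_red = out[node.parent_node]
        out[node] = parent_red + (d / u) * (1.0 - parent_red)
    return out


def red_table(tree: dendropy.Tree) -> pd.DataFrame:
    """RED values as a tidy table (leaf rows carry their taxon label)."""
    values = red(tree)
    rows = []
    for i, node in enumerate(tree.preorder_node_iter()):
        rows.append({
            "node_id": i,
            "label": node.taxon.label if node.taxon else (node.label or ""),
            "is_leaf": node.is_leaf(),
            "red": values[node],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified subsampling
# ---------------------------------------------------------------------------

def largest_remainder_allocation(sizes: Mapping[str, int], n_target: int) -> dict[str, int]:
    """Apportion ``n_target`` draws across strata proportionally to size,
    rounding by the largest-remainder method (deterministic tie-break by
    descending stratum size then name). Allocations never exceed stratum
    sizes; any overflow is redistributed to strata with spare capacity."""
    total = sum(sizes.values())
    if n_target > total:
        raise ValueError(f"n_target={n_target} exceeds table size {total}")
    quotas = {s: n_target * n / total for s, n in sizes.items()}
    alloc = {s: int(np.floor(q)) for s, q in quotas.items()}
    remainder = n_target - sum(alloc.values())
    order = sorted(
        sizes,
        key=lambda s: (-(quotas[s] - alloc[s]), -sizes[s], s),
    )
    for s in order:
        if remainder == 0:
            break
        if alloc[s] < sizes[s]:
            alloc[s] += 1
            remainder -= 1
    # cap at stratum size and redistribute (can only trigger with tiny strata)
    spare = 0
    for s in alloc:
        if alloc[s] > sizes[s]:
            spare += alloc[s] - sizes[s]
            alloc[s] = sizes[s]
    for s in sorted(sizes, key=lambda s: (-(sizes[s] - alloc[s]), s)):
        while spare > 0 and alloc[s] < sizes[s]:
            alloc[s] += 1
            spare -= 1
    return alloc


def stratified_subsample(
    mags: pd.DataFrame,
    n_target: int = 200,
    min_phylum: int = 30,
    reps: int = 15,
    seed: int = 0,
    phylum_col: str = "phylum",
    id_col: str = "mag_id",
    merged_label: str = "merged",
) -> list[list[str]]:
    """Repeated stratified draws of ``n_target`` MAGs by phylum.

    Phyla with fewer than ``min_phylum`` members are merged into a single
    stratum before allocation. Each of the ``reps`` replicates draws without
    replacement, with per-stratum counts from largest-remainder proportional
    allocation; replicates are independent under one seeded generator.
    """
    if len(mags) < n_target:
        raise ValueError(f"table has {len(mags)} rows; need ≥ {n_target}")
    phyla = mags[phylum_col].astype(str)
    counts = phyla.value_counts()
    small = set(counts[counts < min_phylum].index)
    strata = phyla.where(~phyla.isin(small), merged_label)
    sizes = strata.value_counts().to_dict()
    alloc = largest_remainder_allocation(sizes, n_target)
    rng = np.random.default_rng(seed)
    members = {s: mags.loc[strata == s, id_col].to_numpy() for s in sizes}
    draws = []
    for _ in range(reps):
        picked: list[str] = []
        for s in sorted(sizes):
            take = alloc[s]
            if take:
                picked.extend(rng.choice(members[s], size=take, replace=False))
        draws.append(sorted(picked))
    return draws
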