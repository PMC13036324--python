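"""Biosynthetic gene cluster (BGC) catalog accounting and novelty calls.

Consumes upstream cluster assignments (GCF = gene cluster family at 0.3
distance, GCC = gene cluster clan at 0.7 distance) and reference-database
membership values, and provides:

* dereplication — the longest BGC per (GCF, species) pair;
* abundance aggregation — a BGC's per-sample abundance is the median of its
  biosynthetic genes; GCF/GCC abundances sum their representative BGCs;
* novelty — a BGC is *matched* iff its best reference membership value is
  ≤ 900, novel otherwise; a GCF (GCC) is novel iff strictly less than 20 %
  (40 %) of its member BGCs are matched;
* per-category counts over the eight product classes;
* Ward clustering of samples on Bray–Curtis distances of GCC abundances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .catalog_stats import percent
from .exceptions import MissingDataError

BGC_CATEGORIES = (
    "PKSI", "PKSother", "NRPS", "RiPPs",
    "Saccharides", "Terpene", "PKS-NRP_Hybrids", "Others",
)
MEMBERSHIP_CUTOFF = 900.0
GCF_NOVEL_FRACTION = 0.20
GCC_NOVEL_FRACTION = 0.40


def dereplicate_bgcs(records: pd.DataFrame) -> pd.DataFrame:
    """Keep the longest BGC per (gcf_id, species_id) pair.

    ``records`` columns: ``bgc_id, species_id, gcf_id, length`` (extra columns
    pass through). Ties on length break to the lexicographically smallest
    ``bgc_id`` so dereplication is deterministic.
    """
    for col in ("bgc_id", "species_id", "gcf_id", "length"):
        if col not in records.columns:
            raise MissingDataError(f"BGC table lacks column {col!r}")
    if records["gcf_id"].isna().any():
        bad = records.loc[records["gcf_id"].isna(), "bgc_id"].tolist()
        raise MissingDataError(f"BGCs without GCF assignment: {bad[:10]}")
    ordered = records.sort_values(
        ["gcf_id", "species_id", "length", "bgc_id"],
        ascending=[True, True, False, True],
    )
    return ordered.drop_duplicates(["gcf_id", "species_id"], keep="first").reset_index(drop=True)


def bgc_abundance(gene_abundances: pd.DataFrame) -> pd.Series:
    """Per-sample BGC abundance: the median over its biosynthetic genes.

    ``gene_abundances`` is genes × samples for one BGC; an even gene count
    takes the mean of the two middle values (numpy median convention).
    """
    if len(gene_abundances) == 0:
        raise ValueError("BGC has no biosynthetic genes")
    return gene_abundances.median(axis=0)


def gcf_gcc_abundance(
    bgc_abundances: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """Sum representative-BGC abundance profiles within each GCF or GCC.

    ``bgc_abundances`` is representative BGCs × samples; ``assignment`` maps
    bgc_id → group id (gcf_id or gcc_id).
    """
    groups = assignment.reindex(bgc_abundances.index)
    if groups.isna().any():
        bad = bgc_abundances.index[groups.isna()].tolist()
        raise MissingDataError(f"BGCs without group assignment: {bad[:10]}")
    return bgc_abundances.groupby(groups).sum()


def classify_bgc_novel(membership: float | None, cutoff: float = MEMBERSHIP_CUTOFF) -> bool:
    """True iff the BGC is novel: no reference hit, or best membership value
    above the cutoff (membership ≤ 900 counts as matched)."""
    if membership is None or (isinstance(membership, float) and np.isnan(membership)):
        return True
    if membership < 0:
        raise ValueError(f"negative membership value: {membership}")
    return membership > cutoff


def classify_group_novel(member_novel_flags, level: str) -> tuple[bool, float]:
    """Group-level novelty from member-BGC novelty flags.

    Returns ``(novel, mapped_fraction)`` where mapped_fraction is the share
    of member BGCs that matched a reference. A GCF is novel iff that share
    is strictly below 0.20; a GCC iff strictly below 0.40.
    """
    flags = np.asarray(list(member_novel_flags), dtype=bool)
    if len(flags) == 0:
        raise ValueError("empty group")
    thresholds = {"GCF": GCF_NOVEL_FRACTION, "GCC": GCC_NOVEL_FRACTION}
    if level not in thresholds:
        raise ValueError(f"level must be GCF or GCC, got {level!r}")
    mapped_fraction = float((~flags).mean())
    return mapped_fraction < thresholds[level], mapped_fraction


def group_novelty_table(
    bgc_flags: pd.Series, assignment: pd.Series, level: str
) -> pd.DataFrame:
    """Apply :func:`classify_group_novel` per group.

    ``bgc_flags`` maps bgc_id → novel flag; ``assignment`` maps bgc_id →
    group id. The output also carries the secondary "novel-member fraction
    < threshold" statistic (the inverted reading) for cross-checking.
    """
    df = pd.DataFrame({"novel": bgc_flags, "group": assignment.reindex(bgc_flags.index)})
    if df["group"].isna().any():
        raise MissingDataError("BGC flags without group assignment")
    rows = []
    threshold = {"GCF": GCF_NOVEL_FRACTION, "GCC": GCC_NOVEL_FRACTION}[level]
    for gid, sub in df.groupby("group"):
        novel, mapped_frac = classify_group_novel(sub["novel"], level)
        rows.append({
            "group_id": gid,
            "level": level,
            "n_bgcs": len(sub),
            "mapped_fraction": mapped_frac,
            "novel": novel,
            "novel_member_fraction": float(sub["novel"].mean()),
            "novel_inverted_reading": float(sub["novel"].mean()) < threshold,
        })
    return pd.DataFrame(rows).set_index("group_id")


def category_summary(categories: pd.Series) -> pd.DataFrame:
    """Counts and percentages (2 dp) of BGCs per product category."""
    cats = categories.astype(str)
    unknown = set(cats) - set(BGC_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown BGC categories: {sorted(unknown)}")
    if len(cats) == 0:
        warnings.warn("empty BGC table; empty category summary", stacklevel=2)
        return pd.DataFrame(columns=["count", "pct"])
    counts = cats.value_counts().reindex(BGC_CATEGORIES, fill_value=0)
    out = pd.DataFrame({"count": counts})
    out["pct"] = [percent(c, len(cats)) for c in counts]
    return out


def ward_cluster_samples(
    gcc_abundance: pd.DataFrame, k: int = 3
) -> tuple[pd.Series, np.ndarray]:
    """Ward clustering of samples on Bray–Curtis distances of GCC profiles.

    ``gcc_abundance`` is samples × GCCs. The Lance–Williams Ward recurrence
    is applied to the Bray–Curtis dissimilarities directly (the matrix is not
    Euclidean-embedded first). Returns per-sample integer labels (1…k) and
    the scipy linkage matrix.
    """
    n = len(gcc_abundance)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    if k < 1:
        raise ValueError("k must be ≥ 1")
    condensed = pdist(gcc_abundance.to_numpy(float), metric="braycurtis")
    linkage = hierarchy.linkage(condensed, method="ward")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=gcc_abundance.index, name="cluster"), linkage


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialize a scipy linkage dendrogram as a Newick string."""
    tree = hierarchy.to_tree(linkage)
    labels = list(labels)

    def walk(node, parent_height: float) -> str:
        branch = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{branch:.6g}"
        inner = ",".join(
            walk(child, node.dist) for child in (node.get_left(), node.get_right())
        )
        return f"({inner}):{branch:.6g}"

    return walk(tree, tree.dist) + ";"


def cluster_composition(labels: pd.Series, sample_groups: pd.Series) -> pd.DataFrame:
    """Cluster × ecosystem contingency table for interpreting sample clusters."""
    return pd.crosstab(labels, sample_groups.reindex(labels.index))
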