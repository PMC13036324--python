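"""MAG catalog accounting: quality scores, MIMAG tiers, novelty and exclusivity.

This module implements the bookkeeping layer of a sediment MAG catalog:

* a linear quality score, ``completeness − 5 × contamination``;
* MIMAG tier assignment (high / medium / fail) from completeness,
  contamination, rRNA presence and tRNA counts;
* the eukaryotic-contig flag based on 1-kb sub-contig best hits;
* species novelty against reference catalogs from ANI/AF match tables
  (a species is *known* in a catalog iff some reference genome reaches
  ANI ≥ 0.95 with aligned fraction ≥ 0.30, the genome-species boundary);
* region / ecosystem / site exclusivity summaries;
* gene-catalog rarefaction with a 5 % sampling step.

Tables are plain :class:`pandas.DataFrame` objects; required column names are
documented per function.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingDataError

REGIONS = ("Tibet", "Qilian")
ECOSYSTEMS = ("River", "Saline Lake", "Wetland", "Freshwater Lake")
REFERENCE_CATALOGS = ("GTDB", "GEM", "SMAG", "TPMC-A")

#: MAG metadata columns consumed by the tiering and exclusivity stages.
MAG_COLUMNS = (
    "mag_id", "species_id", "region", "ecosystem", "site_id",
    "completeness", "contamination", "n_trna",
    "has_rrna_5s", "has_rrna_16s", "has_rrna_23s",
)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits``, the convention used for
    every percentage printed in catalog reports (e.g. 86.215 → 86.22)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """``100 × numerator / denominator`` rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def quality_score(completeness, contamination):
    """Genome quality score: ``completeness − 5 × contamination``.

    Both arguments are on the percent scale; the score may be negative.
    Accepts scalars or array-likes (vectorized). Missing values raise
    :class:`MissingDataError` rather than propagating NaN into reports.
    """
    c = np.asarray(completeness, dtype=float)
    k = np.asarray(contamination, dtype=float)
    if np.any(np.isnan(c)) or np.any(np.isnan(k)):
        raise MissingDataError("completeness/contamination missing (NaN) in quality_score")
    score = c - 5.0 * k
    return float(score) if score.ndim == 0 else score


def mimag_tier(
    completeness: float,
    contamination: float,
    has_rrna_5s: bool,
    has_rrna_16s: bool,
    has_rrna_23s: bool,
    n_trna: int,
) -> str:
    """Assign the MIMAG tier of a single genome.

    high   : completeness > 90 and contamination < 5 and all of the 5S/16S/23S
             rRNA genes present and ≥ 18 tRNAs;
    medium : completeness ≥ 50 and contamination < 10 (and not high);
    fail   : everything else.
    """
    if (
        completeness > 90.0
        and contamination < 5.0
        and has_rrna_5s and has_rrna_16s and has_rrna_23s
        and n_trna >= 18
    ):
        return "high"
    if completeness >= 50.0 and contamination < 10.0:
        return "medium"
    return "fail"


def mimag_tier_table(mags: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`mimag_tier` over a MAG metadata table.

    Requires columns ``completeness, contamination, has_rrna_5s, has_rrna_16s,
    has_rrna_23s, n_trna``; returns a Series of tiers indexed like ``mags``.
    """
    needed = ["completeness", "contamination", "has_rrna_5s", "has_rrna_16s",
              "has_rrna_23s", "n_trna"]
    missing = [c for c in needed if c not in mags.columns]
    if missing:
        raise MissingDataError(f"MAG table lacks columns: {missing}")
    high = (
        (mags["completeness"] > 90.0)
        & (mags["contamination"] < 5.0)
        & mags["has_rrna_5s"].astype(bool)
        & mags["has_rrna_16s"].astype(bool)
        & mags["has_rrna_23s"].astype(bool)
        & (mags["n_trna"] >= 18)
    )
    medium = (mags["completeness"] >= 50.0) & (mags["contamination"] < 10.0)
    tier = pd.Series("fail", index=mags.index, name="tier")
    tier[medium] = "medium"
    tier[high] = "high"
    return tier


def window_count(length: int, window: int = 1000, step: int = 500) -> int:
    """Number of fixed-size sub-contig windows on a contig of ``length`` bp.

    Windows are 0-based half-open at starts 0, step, 2·step, …; a trailing
    partial window is discarded: ``max(0, floor((L − window)/step) + 1)``.
    """
    if length < window:
        return 0
    return (length - window) // step + 1


def flag_eukaryotic(window_labels: Sequence[str], threshold: float = 0.60) -> bool:
    """Flag a contig as eukaryotic from per-window best-hit domain labels.

    ``window_labels`` holds one label per 1-kb sub-contig window, each one of
    ``{"eukaryote", "prokaryote", "virus", "none"}``. The contig is flagged
    iff the fraction of windows whose best hit is eukaryotic is ≥ ``threshold``
    (inclusive at exactly 60 %). Zero windows → not flagged, with a warning.
    """
    labels = list(window_labels)
    if not labels:
        warnings.warn("contig has no windows; not flagged", stacklevel=2)
        return False
    frac = sum(1 for lab in labels if lab == "eukaryote") / len(labels)
    return frac >= threshold


def classify_novel(
    species_ids: Iterable[str],
    matches: pd.DataFrame,
    catalogs: Sequence[str] = REFERENCE_CATALOGS,
    ani_min: float = 0.95,
    af_min: float = 0.30,
) -> pd.DataFrame:
    """Per-catalog novelty flags for each species.

    ``matches`` columns: ``species_id, catalog, ani, af`` — the best hit of a
    species against one reference catalog (ANI and AF as fractions in [0, 1]);
    species with no row for a catalog have no match there.

    A species is *known* in a catalog iff it has a match with
    ANI ≥ ``ani_min`` and AF ≥ ``af_min``; otherwise novel. The column
    ``unique`` marks species novel against every catalog. A second column
    ``novel_literal_<cat>`` records the literal conjunction "ANI < 0.95 and
    AF < 0.30" for comparison (it differs whenever exactly one threshold is
    met).
    """
    bad = set(matches["catalog"]) - set(catalogs)
    if bad:
        raise MissingDataError(f"unknown reference catalogs in match table: {sorted(bad)}")
    ids = list(species_ids)
    out = pd.DataFrame(index=pd.Index(ids, name="species_id"))
    for cat in catalogs:
        sub = matches[matches["catalog"] == cat]
        known = sub[(sub["ani"] >= ani_min) & (sub["af"] >= af_min)]["species_id"]
        out[f"novel_{cat}"] = ~out.index.isin(set(known))
        lit_known = sub[(sub["ani"] >= ani_min) | (sub["af"] >= af_min)]["species_id"]
        out[f"novel_literal_{cat}"] = ~out.index.isin(set(lit_known))
    out["unique"] = out[[f"novel_{c}" for c in catalogs]].all(axis=1)
    return out


def exclusivity_summary(mags: pd.DataFrame) -> dict:
    """Region / ecosystem / site exclusivity of genome-resolved species.

    ``mags`` is a per-MAG table with columns ``species_id, region, ecosystem,
    site_id``. A species is X-exclusive iff the set of X labels over its
    member MAGs has size 1. Percentages (2 dp, half-up) are reported against
    the total species count, and separately for non-singleton species
    (≥ 2 member MAGs) against the non-singleton count.
    """
    if len(mags) == 0:
        raise MissingDataError("empty MAG table")
    grouped = mags.groupby("species_id")
    n_members = grouped.size()
    label_counts = grouped.agg(
        n_regions=("region", "nunique"),
        n_ecosystems=("ecosystem", "nunique"),
        n_sites=("site_id", "nunique"),
    )
    total = len(label_counts)
    nonsingleton = label_counts[n_members >= 2]

    def _block(df: pd.DataFrame, denom: int) -> dict:
        block = {}
        for axis, col in (("region", "n_regions"),
                          ("ecosystem", "n_ecosystems"),
                          ("site", "n_sites")):
            n_excl = int((df[col] == 1).sum())
            block[f"{axis}_exclusive_n"] = n_excl
            block[f"{axis}_exclusive_pct"] = percent(n_excl, denom) if denom else 0.0
        return block

    summary = {"n_species": total, **_block(label_counts, total)}
    summary["n_nonsingleton"] = len(nonsingleton)
    summary["nonsingleton"] = _block(nonsingleton, len(nonsingleton))
    return summary


def rarefaction_curve(
    gene_clusters: Mapping[str, str] | pd.Series,
    step: float = 0.05,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-catalog rarefaction: mean distinct clusters vs sampled fraction.

    ``gene_clusters`` maps gene id → cluster id. For each fraction
    f ∈ {step, 2·step, …, 1.0}, ``⌊f·G⌋`` genes are drawn without replacement
    and the distinct clusters counted, averaged over ``reps`` independent
    draws. Each draw is one permutation whose prefixes give all fractions at
    once, so curves are nondecreasing in f by construction.
    """
    if isinstance(gene_clusters, pd.Series):
        clusters = gene_clusters.to_numpy()
    else:
        clusters = np.asarray(list(gene_clusters.values()))
    n_genes = len(clusters)
    if n_genes == 0:
        raise MissingDataError("empty gene→cluster map")
    codes, _ = pd.factorize(clusters)
    fractions = np.round(np.arange(step, 1.0 + step / 2, step), 10)
    sizes = np.floor(fractions * n_genes).astype(int)
    rng = np.random.default_rng(seed)
    counts = np.zeros((reps, len(fractions)))
    for r in range(reps):
        perm = codes[rng.permutation(n_genes)]
        first_seen = np.zeros(n_genes, dtype=bool)
        _, first_idx = np.unique(perm, return_index=True)
        first_seen[first_idx] = True
        cum_distinct = np.cumsum(first_seen)
        counts[r] = [cum_distinct[s - 1] if s > 0 else 0 for s in sizes]
    return pd.DataFrame({
        "fraction": fractions,
        "n_genes": sizes,
        "mean_clusters": counts.mean(axis=0),
    })


def removal_bookkeeping(initial: int, removed: int) -> dict:
    """Contig-removal report: count and percentage (2 dp) of removed contigs."""
    if removed > initial:
        raise ValueError(f"removed ({removed}) exceeds initial ({initial})")
    if initial <= 0:
        raise ValueError("initial contig count must be positive")
    return {
        "initial": int(initial),
        "removed": int(removed),
        "removed_pct": percent(removed, initial),
    }
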