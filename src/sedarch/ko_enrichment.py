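"""Differential KEGG-orthology (KO) analysis across sedimentary ecosystems.

The statistic works on a MAG × KO count matrix, per-MAG genome sizes (Mb),
and a MAG → ecosystem labelling:

1. *normalize*: each MAG's KO counts are divided by its genome size (copies
   per Mb), then averaged over the MAGs of each ecosystem, giving one per-Mb
   profile per ecosystem;
2. *prevalence*: a KO is prevalent iff it is present (abundance > 0) in
   strictly more than 30 % of the non-focal ecosystems;
3. *ratio*: with A_f the focal ecosystem's abundance and S_o the sum over
   the other ecosystems, r = (A_f − S_o) / (A_f + S_o) ∈ [−1, 1]; a KO is
   *enriched* iff r > 0.9 and *reduced* iff r < −0.9 (both strict);
4. *singleton/conserved*: a KO present in exactly one ecosystem is a
   singleton, in two or more it is conserved.

The pooled-sum ratio is the default; a per-ecosystem variant (enriched only
if the ratio against every other ecosystem exceeds the cutoff) is available
via ``per_ecosystem=True``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingDataError

RATIO_CUTOFF = 0.9
PREVALENCE_THRESHOLD = 0.30

#: The study's two focal habitat classes; when both are present in the
#: labelling they are jointly excluded from the prevalence/ratio background.
DEFAULT_FOCAL_CLASSES = (
    "Qilian Saline Lake sediment",
    "Tibet Freshwater Lake sediment",
)


def normalize_profiles(
    counts: pd.DataFrame, sizes_mb: pd.Series, ecosystems: pd.Series
) -> pd.DataFrame:
    """Ecosystem × KO per-Mb abundance profiles.

    ``counts`` is MAG × KO (nonnegative); ``sizes_mb`` maps mag_id → genome
    size in Mb; ``ecosystems`` maps mag_id → ecosystem label. For ecosystem e
    and KO k:  A(e, k) = mean over MAGs m ∈ e of count(m, k) / size(m).
    """
    missing = [m for m in counts.index if m not in sizes_mb.index]
    if missing:
        raise MissingDataError(f"MAGs without genome size: {missing[:10]}")
    missing = [m for m in counts.index if m not in ecosystems.index]
    if missing:
        raise MissingDataError(f"MAGs without ecosystem label: {missing[:10]}")
    sizes = sizes_mb.reindex(counts.index).astype(float)
    if (sizes <= 0).any():
        raise ValueError("genome sizes must be positive (Mb)")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative KO counts")
    per_mb = counts.div(sizes, axis=0)
    return per_mb.groupby(ecosystems.reindex(counts.index)).mean()


def prevalence_filter(
    profiles: pd.DataFrame,
    excluded: Sequence[str],
    threshold: float = PREVALENCE_THRESHOLD,
) -> pd.Index:
    """KOs present in strictly more than ``threshold`` of the non-excluded
    ecosystems. Presence means per-Mb abundance > 0 exactly (no pseudocount).
    """
    background = profiles.drop(index=[e for e in excluded if e in profiles.index])
    if len(background) < 2:
        raise ValueError("need at least two non-focal ecosystems")
    presence_frac = (background > 0).mean(axis=0)
    return profiles.columns[presence_frac > threshold]


def enrichment_ratio(a_focal: float, others) -> tuple[float, str]:
    """Pooled enrichment ratio and label for one KO.

    r = (A_f − S_o)/(A_f + S_o) with S_o the sum over the other ecosystems;
    enriched iff r > 0.9, reduced iff r < −0.9 (strict); ``nan`` and label
    ``"undefined"`` when A_f + S_o = 0.
    """
    s_other = float(np.sum(others))
    if a_focal < 0 or s_other < 0:
        raise ValueError("abundances must be nonnegative")
    denom = a_focal + s_other
    if denom == 0:
        return float("nan"), "undefined"
    r = (a_focal - s_other) / denom
    if r > RATIO_CUTOFF:
        label = "enriched"
    elif r < -RATIO_CUTOFF:
        label = "reduced"
    else:
        label = "neither"
    return float(r), label


def singleton_conserved(profiles: pd.DataFrame) -> pd.Series:
    """Per-KO label: "singleton" (present in exactly one ecosystem) or
    "conserved" (present in ≥ 2); KOs absent everywhere are dropped."""
    n_present = (profiles > 0).sum(axis=0)
    labels = pd.Series(
        np.where(n_present == 1, "singleton", "conserved"),
        index=profiles.columns,
        name="ko_class",
    )
    return labels[n_present > 0]


def differential_report(
    counts: pd.DataFrame,
    sizes_mb: pd.Series,
    ecosystems: pd.Series,
    focal: str,
    excluded: Sequence[str] | None = None,
    ratio_cutoff: float = RATIO_CUTOFF,
    prevalence_threshold: float = PREVALENCE_THRESHOLD,
    per_ecosystem: bool = False,
) -> pd.DataFrame:
    """Full differential-KO pipeline for one focal ecosystem.

    ``excluded`` lists the ecosystems left out of the background (prevalence
    denominator and ratio sum); it defaults to the study's two focal habitat
    classes when both occur in the labels, else to the focal class alone. The
    focal class is always excluded from its own background. KOs with an
    all-zero focal + background signal are skipped with a warning. Rows are
    ordered by |r| descending, then KO id.
    """
    profiles = normalize_profiles(counts, sizes_mb, ecosystems)
    if focal not in profiles.index:
        raise MissingDataError(f"focal ecosystem {focal!r} absent from labels")
    if excluded is None:
        if all(e in profiles.index for e in DEFAULT_FOCAL_CLASSES):
            excluded = list(DEFAULT_FOCAL_CLASSES)
        else:
            excluded = [focal]
    excluded = sorted(set(excluded) | {focal})
    prevalent = prevalence_filter(profiles, excluded, prevalence_threshold)
    background = profiles.drop(index=[e for e in excluded if e in profiles.index])

    rows, skipped = [], []
    for ko in prevalent:
        a_f = float(profiles.loc[focal, ko])
        others = background[ko].to_numpy(float)
        r, label = enrichment_ratio(a_f, others)
        if label == "undefined":
            skipped.append(ko)
            continue
        if per_ecosystem:
            per_eco = [
                enrichment_ratio(a_f, [v])[0] if (a_f + v) > 0 else np.nan
                for v in others
            ]
            if all(v > ratio_cutoff for v in per_eco):
                label = "enriched"
            elif all(v < -ratio_cutoff for v in per_eco):
                label = "reduced"
            else:
                label = "neither"
        rows.append({"ko_id": ko, "ratio": r, "label": label, "abundance_focal": a_f,
                     "abundance_others_sum": float(others.sum())})
    if skipped:
        warnings.warn(
            f"{len(skipped)} KOs undefined (zero everywhere in scope); skipped",
            stacklevel=2,
        )
    report = pd.DataFrame(rows, columns=["ko_id", "ratio", "label",
                                         "abundance_focal", "abundance_others_sum"])
    if len(report):
        report = report.reindex(
            report.assign(absr=report["ratio"].abs())
            .sort_values(["absr", "ko_id"], ascending=[False, True])
            .index
        ).reset_index(drop=True)
    return report


def enriched_set(report: pd.DataFrame) -> set[str]:
    """KO ids labelled enriched in a differential report."""
    return set(report.loc[report["label"] == "enriched", "ko_id"])
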