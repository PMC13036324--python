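"""Oligonucleotide probe candidate generation and specificity screening.

Target contigs are segmented into 30-bp windows at 15-bp steps; candidate
windows are screened against off-target references and removed whenever an
off-target hit simultaneously satisfies E-value < 20, query coverage ≥ 60 %
and identity ≥ 90 % (the conjunctive reading — each criterion alone is far
too permissive to be disqualifying on its own). Hits to the candidate's own
genome or genus are ignored. A built-in naive both-strand ungapped search
stands in for an external aligner at desk scale, and a final selector picks
up to 10 probes at distinct, non-overlapping loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

WINDOW = 30
STEP = 15
EVALUE_MAX = 20.0
COVERAGE_MIN = 60.0
IDENTITY_MIN = 90.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class WindowCandidate:
    """A 30-mer window at a 0-based half-open locus on a source contig."""

    contig_id: str
    start: int
    sequence: str

    @property
    def candidate_id(self) -> str:
        return f"{self.contig_id}:{self.start}"

    def overlaps(self, other: "WindowCandidate") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.start + len(other.sequence)
            and other.start < self.start + len(self.sequence)
        )


@dataclass(frozen=True)
class HitRecord:
    """One alignment of a candidate against a reference sequence."""

    candidate_id: str
    target_id: str
    taxon: str
    evalue: float
    coverage: float   # percent of the query aligned
    identity: float   # percent identity over the aligned region
    strand: str = "+"

    def disqualifies(
        self,
        evalue_max: float = EVALUE_MAX,
        coverage_min: float = COVERAGE_MIN,
        identity_min: float = IDENTITY_MIN,
    ) -> bool:
        """True iff the hit meets all three nonspecificity criteria."""
        return (
            self.evalue < evalue_max
            and self.coverage >= coverage_min
            and self.identity >= identity_min
        )


@dataclass
class ProbeSet:
    probes: list[WindowCandidate]
    requested: int
    shortfall: int = 0
    notes: str = ""


def sliding_windows(
    contigs: Mapping[str, str], window: int = WINDOW, step: int = STEP
) -> tuple[list[WindowCandidate], int]:
    """All fixed-length windows over a set of contigs.

    A contig of length L ≥ window yields ⌊(L − window)/step⌋ + 1 windows at
    starts 0, step, 2·step, …. Windows containing N are dropped and counted
    in the second return value. Empty input raises.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    candidates: list[WindowCandidate] = []
    n_dropped = 0
    for contig_id, seq in contigs.items():
        seq = seq.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"contig {contig_id!r} has non-ACGTN characters")
        for start in range(0, len(seq) - window + 1, step):
            sub = seq[start:start + window]
            if "N" in sub:
                n_dropped += 1
                continue
            candidates.append(WindowCandidate(contig_id, start, sub))
    return candidates, n_dropped


def dedupe_by_sequence(candidates: Iterable[WindowCandidate]) -> list[WindowCandidate]:
    """Drop candidates whose sequence was already seen (first locus wins),
    so identical windows share one fate in the filters."""
    seen: set[str] = set()
    out = []
    for cand in candidates:
        if cand.sequence not in seen:
            seen.add(cand.sequence)
            out.append(cand)
    return out


def naive_match_oracle(
    candidate: WindowCandidate,
    targets: Mapping[str, tuple[str, str]],
    max_mismatches: int = 3,
) -> list[HitRecord]:
    """Exhaustive ungapped search of a candidate against reference sequences.

    ``targets`` maps target_id → (taxon label, sequence). Both strands are
    scanned for windows within ``max_mismatches`` substitutions. Every hit
    has coverage 100 %; identity = 100·(w − mm)/w; the E-value is 0 for an
    exact match and the mismatch count itself otherwise — a documented
    monotone surrogate (more mismatches ⇒ larger E), always below the
    screening cutoff so the coverage/identity criteria decide.
    """
    if max_mismatches > 10:
        raise ValueError("max_mismatches capped at 10")
    w = len(candidate.sequence)
    query = np.frombuffer(candidate.sequence.encode(), dtype=np.uint8)
    hits: list[HitRecord] = []
    for target_id, (taxon, seq) in targets.items():
        seq = seq.upper()
        if len(seq) < w:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, q in (("+", query),
                          ("-", np.frombuffer(revcomp(candidate.sequence).encode(),
                                              dtype=np.uint8))):
            windows = np.lib.stride_tricks.sliding_window_view(arr, w)
            mismatches = (windows != q).sum(axis=1)
            # one record per (target, strand, mismatch level) — positions are
            # irrelevant to the screening decision
            for mm in np.unique(mismatches[mismatches <= max_mismatches]):
                hits.append(HitRecord(
                    candidate_id=candidate.candidate_id,
                    target_id=target_id,
                    taxon=taxon,
                    evalue=float(mm),
                    coverage=100.0,
                    identity=100.0 * (w - int(mm)) / w,
                    strand=strand,
                ))
    return hits


def specificity_filter(
    candidates: Sequence[WindowCandidate],
    hits: Iterable[HitRecord],
    self_taxa: Iterable[str] = (),
    evalue_max: float = EVALUE_MAX,
    coverage_min: float = COVERAGE_MIN,
    identity_min: float = IDENTITY_MIN,
) -> list[WindowCandidate]:
    """Remove candidates with at least one disqualifying off-target hit.

    A hit disqualifies iff it satisfies *all* of: E < ``evalue_max``,
    coverage ≥ ``coverage_min``, identity ≥ ``identity_min``. Hits whose
    taxon is in ``self_taxa`` (the candidate's own genome/genus) are
    ignored. Hits naming unknown candidates raise.
    """
    known = {c.candidate_id for c in candidates}
    self_taxa = set(self_taxa)
    removed: set[str] = set()
    for hit in hits:
        if hit.candidate_id not in known:
            raise KeyError(f"hit references unknown candidate {hit.candidate_id!r}")
        if hit.taxon in self_taxa:
            continue
        if hit.disqualifies(evalue_max, coverage_min, identity_min):
            removed.add(hit.candidate_id)
    return [c for c in candidates if c.candidate_id not in removed]


def cross_set_uniqueness(
    candidates: Sequence[WindowCandidate],
    references: Mapping[str, Mapping[str, str]],
    self_genus: str,
    max_mismatches: int = 3,
) -> list[WindowCandidate]:
    """Retain only candidates without qualifying matches in other genera.

    ``references`` maps genus label → {sequence_id: sequence}. The naive
    oracle searches each other-genus reference; a candidate is removed iff a
    hit passes the standard specificity criteria. Unlabelled (empty) genus
    keys raise.
    """
    flat: dict[str, tuple[str, str]] = {}
    for genus, seqs in references.items():
        if not genus:
            raise ValueError("reference set with empty genus label")
        if genus == self_genus:
            continue
        for seq_id, seq in seqs.items():
            flat[f"{genus}/{seq_id}"] = (genus, seq)
    retained = []
    for cand in candidates:
        hits = naive_match_oracle(cand, flat, max_mismatches=max_mismatches)
        if not any(h.disqualifies() for h in hits):
            retained.append(cand)
    return retained


def select_probe_set(
    retained: Sequence[WindowCandidate],
    k: int = 10,
    near_miss_counts: Mapping[str, int] | None = None,
) -> ProbeSet:
    """Choose up to ``k`` probes at distinct, non-overlapping loci.

    Candidates are ranked by fewest near-miss hits (off-target hits that
    failed the disqualification criteria; 0 when unknown) and then by
    coordinate; overlapping windows never co-occur in the set. A shortfall
    below ``k`` is reported as a warning on the result, not an error.
    """
    counts = near_miss_counts or {}
    ranked = sorted(
        retained,
        key=lambda c: (counts.get(c.candidate_id, 0), c.contig_id, c.start),
    )
    chosen: list[WindowCandidate] = []
    for cand in ranked:
        if len(chosen) >= k:
            break
        if any(cand.overlaps(c) for c in chosen):
            continue
        chosen.append(cand)
    shortfall = max(0, k - len(chosen))
    notes = ""
    if shortfall:
        notes = f"only {len(chosen)} probes available (requested {k})"
        warnings.warn(notes, stacklevel=2)
    return ProbeSet(probes=chosen, requested=k, shortfall=shortfall, notes=notes)


def design_probes(
    target_contigs: Mapping[str, str],
    references: Mapping[str, Mapping[str, str]],
    self_genus: str,
    k: int = 10,
    max_mismatches: int = 3,
) -> ProbeSet:
    """End-to-end probe design with the built-in oracle.

    Windows the target, dedupes identical sequences, screens against every
    other-genus reference set, and selects up to ``k`` non-overlapping
    probes.
    """
    candidates, _ = sliding_windows(target_contigs)
    candidates = dedupe_by_sequence(candidates)
    retained = cross_set_uniqueness(
        candidates, references, self_genus, max_mismatches=max_mismatches
    )
    near_miss: dict[str, int] = {}
    flat = {
        f"{genus}/{sid}": (genus, seq)
        for genus, seqs in references.items()
        if genus != self_genus
        for sid, seq in seqs.items()
    }
    for cand in retained:
        hits = naive_match_oracle(cand, flat, max_mismatches=max_mismatches)
        near_miss[cand.candidate_id] = sum(1 for h in hits if not h.disqualifies())
    return select_probe_set(retained, k=k, near_miss_counts=near_miss)
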