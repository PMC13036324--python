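# Methods

This note describes the statistical procedures sedarch implements, the
synthetic data they are validated against, and the numerical and design
choices made where more than one reading was defensible.

## Catalog accounting

**Quality score.** `score = completeness − 5 × contamination`, both on the
percent scale; the score is linear and may be negative. The catalog-level
report counts genomes above 50.

**MIMAG tiers.** High quality requires completeness > 90 %, contamination
< 5 %, all of the 5S/16S/23S rRNA genes and ≥ 18 tRNAs; medium requires
completeness ≥ 50 % and contamination < 10 %; everything else fails. The
numeric clauses of "high" imply "medium", so the three tiers partition any
record set.

**Eukaryotic-contig flag.** Contigs are cut into 1-kb windows at 0.5-kb
steps (0-based half-open starts 0, 500, 1000, …; a trailing partial window
is discarded, giving `max(0, ⌊(L − 1000)/500⌋ + 1)` windows). A contig is
flagged when the fraction of windows whose best hit is eukaryotic is
**≥ 0.60** — the inclusive reading of "60 % of the sub-contigs"; whether
exactly 60 % should flag is genuinely ambiguous, and the threshold is an
argument.

**Species novelty.** A species is *known* in a reference catalog iff some
reference genome reaches ANI ≥ 0.95 **and** aligned fraction ≥ 0.30 — the
logical complement of the dereplication rule that defines the species
boundary. The literal conjunction "ANI < 0.95 and AF < 0.30" (which differs
whenever exactly one threshold is met) is computed alongside as
`novel_literal_*` columns so both counts are reportable. "Unique" means
novel against every catalog.

**Exclusivity.** A species is region-/ecosystem-/site-exclusive iff the
label set over its member MAGs has size 1. Percentages are reported twice:
against all species, and against non-singletons (≥ 2 member MAGs), each
rounded half-up to 2 dp. Raw floats are retained internally; rounding is a
presentation step only.

**Rarefaction.** For fractions f = 0.05 … 1.00 in 5 % steps, ⌊f·G⌋ genes
are drawn without replacement and distinct clusters counted, averaged over
10 replicate draws. Each replicate is one permutation whose prefixes give
every fraction, so the curve is nondecreasing by construction and the
f = 1 point equals the total cluster count exactly.

## Community ecology

**Diversity.** Shannon H in nats over normalized positive entries;
Bray–Curtis dissimilarity `Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)`; similarity is
1 − dissimilarity throughout.

**PCoA.** Classical scaling (through scikit-bio) on the double-centered
squared-dissimilarity matrix. Bray–Curtis matrices are generally
non-Euclidean, so negative eigenvalues are expected; they are reported but
their axes are never returned as coordinates, and requesting more axes than
there are positive eigenvalues truncates with a warning.

**Distance–decay (DDR).** Geographic distances are great-circle
(haversine, R = 6371 km); vertical distance is |Δ elevation|. The default
fit regresses ln(similarity) on **ln(distance)** — the standard power-law
form of distance–decay — with a linear-distance option
(`log_distance=False`) whose slope is −λ when similarity ∝ exp(−λ·d).
Pairs at zero distance or zero similarity have no defined log and are
excluded and counted; fewer than 3 usable pairs is an error. Per-region
fitting is left to the caller (pass the subset), since pooling across
regions mixes decay regimes.

**Sloan neutral community model.** Occurrence frequency is modeled as
`f(p) = 1 − BetaCDF(d; N·m·p, N·m·(1−p))` with community size N, migration
rate m ∈ (0, 1], and detection limit d on relative abundance. d defaults
to the minimum observed mean relative abundance (the common convention in
Sloan-model implementations) and can be set explicitly — e.g. to 1/N when
the sampling depth is known. m is fitted by bounded scalar least squares
(tolerance 1e-10); R² = 1 − SSE/SST is unbounded below, so strongly
non-neutral communities yield negative values — a meaningful regime, not
an error. Non-convergence is reported on the result object with the
optimizer message rather than raised.

**Group tests.** Kruskal–Wallis across groups and all pairwise two-sided
Mann–Whitney tests with Benjamini–Hochberg adjustment; significance at
adjusted p < 0.05. Scipy's automatic method selection uses the exact
Mann–Whitney distribution for small tie-free samples and the tie-corrected
normal approximation otherwise.

## Chronology

**Node ages.** Leaf ages are 0; an internal node's age is the tree height
minus its root distance. The tree must be ultrametric within a relative
tolerance of 1e-6 of its height; violations raise an error listing the
offending leaves rather than silently averaging.

**Latest divergence and PAS.** Each tip's "latest divergence" is the age
of its immediate parent node — the most recent split involving that
lineage. A species is a *possible ancient species* (PAS) iff that age is
**strictly greater** than the eon boundary; ties go to extant ("prior to
541 Ma" read strictly). The boundary defaults to 541 Ma
(Cryptozoic/Phanerozoic); 600 Ma — the variant drawn in some figure
conventions — is exposed as an option.

**Proportion curves.** Per habitat group, the fraction of species with
latest divergence ≥ t over a strictly decreasing age grid; every nonempty
group reaches 1 at t = 0; empty groups give a flat zero curve with a
warning.

**Relative evolutionary distance (RED).** The GTDB interpolation:
RED(root) = 0, leaves = 1, and for node n with parent p, branch d and
u = d + mean distance from n to its descendant leaves,
`RED(n) = RED(p) + (d/u)·(1 − RED(p))`. Computed in one postorder pass
(per-node mean leaf distance) plus one preorder pass; a brute-force
path-enumeration recursion serves as the independent test oracle. RED is
computed on whichever tree is supplied — time-calibrated by default, a
substitution-length tree if the caller prefers, since rank comparisons are
meaningful on either.

**Stratified subsampling.** Phyla below 30 members are merged into one
stratum; 200 genomes are allocated across strata by largest-remainder
proportional rounding (deterministic tie-break by remainder, then stratum
size, then name) and drawn without replacement, 15 independent replicates
under one seeded generator. The allocation deviates from exact
proportionality by less than one genome per stratum. A verbal description
of per-phylum normal approximations in the source protocol is not
implementable as an algorithm; proportional allocation is the package's
choice and is stated here as such.

## BGC novelty

Dereplication keeps the longest BGC per (GCF, species) pair, ties broken
to the lexicographically smallest id. A BGC's per-sample abundance is the
median over its biosynthetic genes (even counts: mean of the two middle
values); GCF/GCC profiles sum their representative BGCs. A BGC is matched
iff its best reference membership value is ≤ 900 (smaller is better; no
hit means novel). A GCF is novel iff strictly less than 20 % of its member
BGCs matched, a GCC iff strictly less than 40 % — the reading consistent
with "novel if less than 20 %/40 % … were mapped"; the inverted statistic
("fraction of novel members < threshold") is emitted alongside for
cross-checking since the two phrasings circulate. Ward clustering of
samples applies the Lance–Williams recurrence directly to the Bray–Curtis
dissimilarity matrix (the common practice for "Ward on Bray–Curtis",
rather than embedding into Euclidean space first), cut to k = 3 clusters;
the dendrogram serializes to Newick.

## KO enrichment

Counts are normalized per Mb of genome and averaged over the MAGs of each
ecosystem: `A(e, k) = mean over m∈e of count(m,k)/size(m)`. A KO is
*prevalent* iff present (abundance > 0, no pseudocount) in strictly more
than 30 % of the background ecosystems — the 14 classes left after
excluding the two focal habitat classes (Qilian Saline Lake sediment and
Tibet Freshwater Lake sediment, each analyzed as focal in its own run).
For prevalent KOs, `r = (A_f − S_o)/(A_f + S_o)` with S_o the **sum** over
background ecosystems ("divided by the summary" supports the pooled-sum
reading); enriched iff r > 0.9, reduced iff r < −0.9, both strict, so
r = 0.9 exactly is neither. A per-ecosystem variant (enriched only when
the ratio against every single background ecosystem clears the cutoff) is
available as an option. r is antisymmetric under swapping the focal and
pooled roles and invariant to rescaling all counts. KOs present in exactly
one ecosystem are singletons; in ≥ 2, conserved; absent KOs are dropped.

## Probe design

Target contigs are segmented into 30-bp windows at 15-bp steps; windows
containing N are dropped and counted; identical sequences are deduplicated
before filtering so they share one fate. A candidate is removed iff some
off-target hit satisfies **all** of E < 20, coverage ≥ 60 %, identity
≥ 90 % — the conjunctive reading; any single criterion alone (E < 20
especially) would disqualify essentially everything. The permissive
E-cutoff is an exposed flag. Hits to the candidate's own genome or genus
are ignored. The built-in search oracle scans both strands for ungapped
matches within a mismatch budget; identity is 100·(30 − mm)/30, coverage
100 %, and the E-value surrogate is the mismatch count itself (0 for exact
matches) — monotone in match quality and documented as such. The final
selection ranks retained candidates by fewest near-miss hits then by
coordinate and takes up to 10 probes at non-overlapping loci, warning on
shortfall. Probes are reported as full 30-mers; trimming to 20–30 nt
(thermodynamics, secondary structure) is out of scope.

## Synthetic data: what is planted, and what it does not emulate

All generators draw from named streams of one seed
(`SimulationConfig.rng("tree")`, …), so a config reproduces every artifact
byte-for-byte while artifacts stay mutually independent. Each generator
returns a ground-truth sidecar consumed only by tests.

* **Time tree** — an ultrametric tree built directly from the planted
  classification: "recent" tips coalesce at ages drawn in (5, 498) Ma,
  each "ancient" tip attaches to the spine at an age in (600, 3200) Ma.
  Every ancient tip's parent is its attachment node, so the planted PAS
  count is exact (a birth–death draw rescaled afterwards cannot guarantee
  this when cherries share parent nodes — the reason for the direct
  construction). Habitat groups skew ancient tips toward Sediment only
  (0.8/0.15/0.05) and spread recent tips (0.5/0.4/0.1), mirroring a
  sediment-archive pattern. Not emulated: realistic diversification
  dynamics, rate variation, calibration uncertainty.
* **MAG table** — tier counts are planted exactly by drawing each record
  inside its tier's defining region (e.g. medium completeness ≤ 90 so it
  can never satisfy the high clause). Default mix ≈ 6 % high / 90 %
  medium / 4 % fail, the tier mix of a refined sediment catalog. Field
  correlations (completeness vs genome size, ecosystem effects) are not
  emulated.
* **DDR community** — species occupy contiguous ranges on a 1,500-km
  transect (starts uniform, lengths exponential with mean 1/λ), so
  persistence over distance d is exp(−λd) by memorylessness and expected
  Bray–Curtis similarity inherits that decay up to a constant. The
  regional pool is 2,000 species (catalog-scale richness; a few hundred
  per sample) so far-transect pairs still share enough species that
  log-similarity noise stays small against the signal — with a pool of a
  few hundred, the planted λ is not identifiable at useful tolerance.
  λ = 0 plants unbounded ranges (flat similarity). Abundance noise is
  multiplicative lognormal (σ = 0.25). Not emulated: environmental
  selection, 2-D geography, regional structure.
* **NCM data** — per-species local abundances drawn from the model's own
  beta distribution at planted (N = 1000, m = 0.1), detection at
  d = 1/N, frequencies over 50 samples; `exact=True` returns the
  noise-free curve. Recovery of m to ±0.03 therefore validates the
  fitting machinery, not the model's adequacy for real communities.
* **KO matrix** — 16 ecosystems × 8 MAGs. Planted enriched KOs carry
  60–120 copies per focal MAG and exactly one copy in 6 background
  ecosystems (prevalent at 6/14 ≈ 43 %, yet the pooled ratio stays far
  above 0.9); background KOs are Poisson(20) in ≥ 60 % of ecosystems,
  keeping their ratios well inside (−0.9, 0.9); one KO is planted as a
  singleton. Background KOs absent from the focal class legitimately come
  out "reduced" (r = −1).
* **BGC catalog** — per-GCF mapped counts are planted on the correct side
  of the 20 % rule (novel GCFs: < 0.2 by integer construction; others:
  ≥ 0.45, so a catalog with fraction 0 also yields no novel GCC under the
  40 % rule). Matched members draw membership in (0, 900]; unmatched are
  half missing, half above 900.
* **Probe genomes** — a random 6-kb target (uniform ACGT, so 30-mers are
  unique against random off-targets with probability astronomically close
  to 1 even at a 3-mismatch radius) plus off-target genera into which
  selected non-overlapping windows are copied verbatim, forward or
  reverse-complement. Not emulated: repeats, conserved genes,
  compositional bias — the reason real screening needs nt/GTDB-scale
  references.

## Problem sizes

The default validation runs use 200-tip trees, 50 samples × 2,000 species
for DDR, 500 species for NCM, 128 MAGs × ~120 KOs, 300 BGCs, 6-kb probe
targets, and 1,000 (tests) / 250 (acceptance script) random 50-leaf trees
for the RED oracle sweep — sizes at which every planted parameter is
recoverable at its stated tolerance and the whole suite completes in well
under a minute of CPU.

## Known limitations

* The ratio statistics of the worked examples are exact integer/decimal
  arithmetic; the recovery metrics are stochastic and their tolerances
  (±0.03 on m, 25 % on λ, ±0.05 on the ancient fraction) were chosen from
  the generators' noise models, not from asymptotic theory.
* Ward on Bray–Curtis is a heuristic (the recurrence assumes squared
  Euclidean distances); it is used because it matches field practice, and
  the dendrogram should be read accordingly.
* The per-ecosystem enrichment variant and the literal-conjunction novelty
  counts exist to quantify how much the ambiguous phrasings matter; the
  defaults are the readings argued for above.
* `group_stats` treats observations as exchangeable within groups; no
  spatial or phylogenetic autocorrelation correction is applied.
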