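"""Seeded synthetic-data generators with planted, recoverable structure.

Every pipeline stage consumes a standard input format (Newick trees, TSV
tables, FASTA genomes); the generators here emit all of them with known
ground truth so each stage can be tested for parameter recovery without any
external download. One integer seed governs everything: each artifact draws
from its own named generator stream (``SimulationConfig.rng("tree")`` etc.),
so artifacts are independent yet jointly reproducible — the same config
always produces byte-identical outputs.

Each generator returns its data objects plus a ``truth`` dict (the planted
labels and parameters). The truth sidecars exist for tests and acceptance
checks only; no pipeline stage reads them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .community_ecology import sloan_frequency
from .exceptions import InvalidConfigError

#: 16 sedimentary habitat classes for the KO enrichment stage; the first two
#: are the focal classes excluded from the differential background.
KO_ECOSYSTEMS = (
    "Qilian Saline Lake sediment", "Tibet Freshwater Lake sediment",
    "Marine sediment", "Hydrothermal sediment", "Cold seep sediment",
    "Saline Lake sediment", "Marine water", "Hot spring sediment",
    "Estuary sediment", "Lake sediment", "Permafrost", "Soil",
    "Wetland sediment", "River sediment", "Mangrove sediment", "Glacier",
)

_BGC_CATEGORY_WEIGHTS = {
    # roughly the product-class mix of a large sediment BGC catalog
    "Terpene": 0.28, "RiPPs": 0.23, "NRPS": 0.14, "Others": 0.12,
    "PKSother": 0.08, "PKSI": 0.06, "Saccharides": 0.05, "PKS-NRP_Hybrids": 0.04,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults that define it.

    seed drives every stream; n_* are sizes; the planted parameters are the
    quantities downstream stages must recover (ancient tip fraction, DDR
    decay rate per km, neutral-model migration rate and community size, the
    enriched KO ids, the novel-GCF fraction).
    """

    seed: int = 0
    n_tips: int = 200
    n_samples: int = 50
    n_species: int = 500
    n_mags: int = 100
    n_kos: int = 120
    ancient_fraction: float = 0.4
    ddr_lambda: float = 0.002          # per km
    ncm_m: float = 0.1
    ncm_N: int = 1000
    enriched_ko_ids: tuple[str, ...] = ("K00978", "K01709")
    novel_bgc_fraction: float = 0.5
    eon_boundary_ma: float = 541.0

    def __post_init__(self):
        for name in ("n_tips", "n_samples", "n_species", "n_mags", "n_kos"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        for name in ("ancient_fraction", "novel_bgc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.ddr_lambda < 0:
            raise InvalidConfigError("ddr_lambda must be nonnegative")
        if not 0.0 < self.ncm_m <= 1.0:
            raise InvalidConfigError("ncm_m must be in (0, 1]")
        if self.ncm_N < 100:
            raise InvalidConfigError("ncm_N must be ≥ 100")

    def rng(self, stream: str) -> np.random.Generator:
        """A named, reproducible generator stream derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(zlib.crc32(stream.encode()),))
        )


# ---------------------------------------------------------------------------
# time-calibrated tree
# ---------------------------------------------------------------------------

def gen_time_tree(config: SimulationConfig):
    """A rooted ultrametric tree (branch lengths in Ma) with a planted
    fraction of tips whose parent node is older than the eon boundary.

    Construction: "recent" tips coalesce at node ages drawn below the
    boundary; each "ancient" tip then attaches to the spine at an age drawn
    above it, oldest last. Every ancient tip's parent is its attachment
    node, so the planted ancient count is met exactly (off by at most one
    only in the corner case of a single recent tip, which must pair with an
    ancient one).

    Returns ``(tree, groups, truth)``: a dendropy Tree, a habitat-group
    DataFrame (species_id, group), and the truth sidecar with per-tip parent
    ages and planted classes.
    """
    n = config.n_tips
    if n < 3:
        raise InvalidConfigError("n_tips must be ≥ 3")
    rng = config.rng("tree")
    boundary = config.eon_boundary_ma
    n_anc = int(round(config.ancient_fraction * n))
    n_rec = n - n_anc

    taxa = [f"sp{i:05d}" for i in range(n)]
    namespace = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=namespace)

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = namespace.get_taxon(label)
        node.age_ma = 0.0
        return node

    anc_labels = list(rng.choice(taxa, size=n_anc, replace=False))
    rec_labels = [t for t in taxa if t not in set(anc_labels)]

    subtree = None
    subtree_age = 0.0
    if n_rec >= 2:
        # random coalescence of recent tips at ordered ages below the boundary
        ages = np.sort(rng.uniform(5.0, boundary * 0.92, size=n_rec - 1))
        active = [leaf(lab) for lab in rec_labels]
        for age in ages:
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
            right = active.pop(j)
            left = active.pop(i)
            parent = dendropy.Node()
            parent.age_ma = float(age)
            parent.add_child(left)
            parent.add_child(right)
            active.append(parent)
        subtree = active[0]
        subtree_age = float(ages[-1])
    elif n_rec == 1:
        subtree = leaf(rec_labels[0])

    if n_anc:
        ancient_nodes = [leaf(lab) for lab in anc_labels]
        n_joins = n_anc if subtree is not None else n_anc - 1
        attach_ages = np.sort(rng.uniform(boundary * 1.11, 3200.0, size=n_joins))
        remaining = ancient_nodes
        if subtree is None:
            # pure-ancient tree: base cherry of the first two ancient tips
            cherry = dendropy.Node()
            cherry.age_ma = float(attach_ages[0])
            cherry.add_child(ancient_nodes[0])
            cherry.add_child(ancient_nodes[1])
            subtree = cherry
            remaining = ancient_nodes[2:]
            attach_ages = attach_ages[1:]
        for node, age in zip(remaining, attach_ages):
            parent = dendropy.Node()
            parent.age_ma = float(age)
            parent.add_child(subtree)
            parent.add_child(node)
            subtree = parent
        subtree_age = subtree.age_ma

    tree.seed_node = subtree
    # branch lengths from node ages
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        node.edge.length = None if parent is None else parent.age_ma - node.age_ma

    # habitat groups: ancient tips skew sediment-only, mirroring the study's
    # sediment-archive pattern; recent tips are more evenly spread
    grp_rng = config.rng("tree-groups")
    groups = {}
    for lab in taxa:
        if lab in set(anc_labels):
            groups[lab] = grp_rng.choice(
                ["Sediment only", "Water only", "Shared"], p=[0.8, 0.15, 0.05])
        else:
            groups[lab] = grp_rng.choice(
                ["Sediment only", "Water only", "Shared"], p=[0.5, 0.4, 0.1])
    group_df = pd.DataFrame(
        {"species_id": taxa, "group": [groups[t] for t in taxa]}
    )

    parent_age = {
        lf.taxon.label: float(lf.parent_node.age_ma)
        for lf in tree.leaf_node_iter()
    }
    truth = {
        "planted_ancient": sorted(
            lab for lab, age in parent_age.items() if age > boundary
        ),
        "requested_ancient_fraction": config.ancient_fraction,
        "realized_ancient_fraction": sum(
            1 for a in parent_age.values() if a > boundary
        ) / n,
        "parent_age_ma": parent_age,
        "eon_boundary_ma": boundary,
        "groups": groups,
    }
    return tree, group_df, truth


# ---------------------------------------------------------------------------
# MAG metadata table
# ---------------------------------------------------------------------------

def gen_mag_table(
    config: SimulationConfig,
    tier_counts: tuple[int, int, int] | None = None,
):
    """MAG metadata with exactly planted MIMAG tier counts.

    ``tier_counts`` = (high, medium, fail); by default ≈ 6 % high and 4 %
    fail (the refined-catalog mix of a deeply sequenced sediment survey),
    the rest medium. Completeness/contamination/rRNA/tRNA fields are drawn
    inside each tier's defining region so the tiering stage recovers the
    planted counts exactly.

    Returns ``(mags, truth)``.
    """
    n = config.n_mags
    if tier_counts is None:
        n_high = max(1, round(0.06 * n)) if n >= 5 else 0
        n_fail = max(1, round(0.04 * n)) if n >= 5 else 0
        tier_counts = (n_high, n - n_high - n_fail, n_fail)
    n_high, n_medium, n_fail = tier_counts
    if min(tier_counts) < 0:
        raise InvalidConfigError("tier counts must be nonnegative")
    if n_high + n_medium + n_fail != n:
        raise InvalidConfigError(
            f"tier counts {tier_counts} do not sum to n_mags={n}"
        )
    rng = config.rng("mags")
    tiers = ["high"] * n_high + ["medium"] * n_medium + ["fail"] * n_fail
    rng.shuffle(tiers)

    rows = []
    ecosystems = ("River", "Saline Lake", "Wetland", "Freshwater Lake")
    for i, tier in enumerate(tiers):
        if tier == "high":
            comp = rng.uniform(90.5, 99.5)
            cont = rng.uniform(0.0, 4.9)
            rrna = (True, True, True)
            trna = int(rng.integers(18, 46))
        elif tier == "medium":
            comp = rng.uniform(50.0, 90.0)  # ≤ 90 ⇒ never high
            cont = rng.uniform(0.0, 9.9)
            rrna = tuple(rng.random(3) < 0.5)
            trna = int(rng.integers(0, 46))
        else:
            if rng.random() < 0.6:
                comp = rng.uniform(15.0, 49.9)
                cont = rng.uniform(0.0, 9.9)
            else:
                comp = rng.uniform(50.0, 95.0)
                cont = rng.uniform(10.1, 25.0)
            rrna = tuple(rng.random(3) < 0.3)
            trna = int(rng.integers(0, 46))
        region = "Tibet" if rng.random() < 175 / 248 else "Qilian"
        eco = str(rng.choice(ecosystems))
        rows.append({
            "mag_id": f"mag{i:05d}",
            "species_id": f"sp{int(rng.integers(0, max(2, n // 2))):05d}",
            "sample_id": f"S{int(rng.integers(0, 60)):03d}",
            "region": region,
            "ecosystem": eco,
            "site_id": f"{region[:2]}-{eco.replace(' ', '')[:4]}-{int(rng.integers(1, 6))}",
            "completeness": round(float(comp), 2),
            "contamination": round(float(cont), 2),
            "strain_heterogeneity": round(float(rng.uniform(0, 30)), 2),
            "n_trna": trna,
            "has_rrna_5s": bool(rrna[0]),
            "has_rrna_16s": bool(rrna[1]),
            "has_rrna_23s": bool(rrna[2]),
            "genome_size": int(np.clip(rng.normal(2.7e6, 0.8e6), 5e5, 8e6)),
            "gc": round(float(rng.uniform(0.35, 0.70)), 4),
        })
    mags = pd.DataFrame(rows)
    truth = {
        "tier_counts": {"high": n_high, "medium": n_medium, "fail": n_fail},
        "planted_tiers": dict(zip(mags["mag_id"], tiers)),
    }
    return mags, truth


# ---------------------------------------------------------------------------
# distance–decay community
# ---------------------------------------------------------------------------

def gen_ddr_community(config: SimulationConfig, n_species_pool: int = 2000):
    """Samples along a transect whose community similarity decays as
    exp(−λ·d) in geographic distance.

    Species occupy contiguous ranges on the transect: range starts are
    uniform, range lengths exponential with mean 1/λ, so the probability
    that a species present at one point persists to a point d km away is
    exp(−λ·d) (memorylessness), which transfers to the expected Bray–Curtis
    similarity up to a constant factor. λ = 0 means unbounded ranges —
    similarity flat in distance. Abundances get multiplicative lognormal
    noise (σ = 0.25).

    ``n_species_pool`` is the regional richness (catalog scale, thousands);
    each sample then holds a few hundred species, keeping the shared-species
    count at the far end of the transect large enough that log-similarity
    noise stays small against the decay signal.

    Returns ``(abundance, geo, truth)``: samples × species abundances,
    sample coordinates (latitude, longitude, elevation_m), and the truth
    sidecar (planted λ, transect positions).
    """
    if config.n_samples < 4:
        raise InvalidConfigError("n_samples must be ≥ 4 for a DDR community")
    if config.ddr_lambda < 0:
        raise InvalidConfigError("ddr_lambda must be nonnegative")
    rng = config.rng("ddr")
    lam = config.ddr_lambda
    n_samp, n_sp = config.n_samples, n_species_pool
    transect_km = 1500.0
    positions = np.sort(rng.uniform(0.0, transect_km, size=n_samp))

    # species ranges on the transect
    if lam > 0:
        lengths = rng.exponential(1.0 / lam, size=n_sp)
        starts = rng.uniform(-3.0 / lam, transect_km, size=n_sp)
        ends = starts + lengths
    else:
        starts = np.full(n_sp, -1.0)
        ends = np.full(n_sp, np.inf)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_sp)

    abundance = np.zeros((n_samp, n_sp))
    for i, x in enumerate(positions):
        present = (starts <= x) & (x <= ends)
        noise = rng.lognormal(0.0, 0.25, size=int(present.sum()))
        abundance[i, present] = base[present] * noise
    # guarantee no empty sample (possible at sparse coverage)
    for i in range(n_samp):
        if abundance[i].sum() == 0:
            j = int(rng.integers(0, n_sp))
            abundance[i, j] = base[j]

    sample_ids = [f"S{i:03d}" for i in range(n_samp)]
    species_ids = [f"sp{i:05d}" for i in range(n_sp)]
    lat0 = 29.0
    geo = pd.DataFrame({
        "latitude": lat0 + positions / 111.195,  # transect along a meridian
        "longitude": np.full(n_samp, 88.0),
        "elevation_m": rng.uniform(3000.0, 5200.0, size=n_samp),
    }, index=pd.Index(sample_ids, name="sample_id"))
    abund = pd.DataFrame(abundance, index=sample_ids, columns=species_ids)
    truth = {
        "ddr_lambda": lam,
        "transect_km": transect_km,
        "positions_km": positions.tolist(),
        "noise_model": "multiplicative lognormal, sigma=0.25",
    }
    return abund, geo, truth


# ---------------------------------------------------------------------------
# neutral community model data
# ---------------------------------------------------------------------------

def gen_ncm_data(config: SimulationConfig, exact: bool = False):
    """Per-species occurrence frequency and mean abundance under Sloan's
    neutral model at the planted (N, m).

    Species mean relative abundances p are a normalized lognormal rank
    curve. With ``exact=True`` frequencies are the model curve itself (no
    sampling noise); otherwise each of ``n_samples`` samples draws a local
    relative abundance from Beta(N·m·p, N·m·(1−p)) and the species counts
    as detected when it exceeds the detection limit d = 1/N.

    Returns ``(table, truth)`` where table has columns
    ``species_id, mean_abundance, frequency``.
    """
    if config.n_species < 50:
        raise InvalidConfigError("n_species must be ≥ 50 for NCM data")
    rng = config.rng("ncm")
    N, m = float(config.ncm_N), float(config.ncm_m)
    d = 1.0 / N
    p = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_species)
    p = p / p.sum()
    p = np.clip(p, 1e-7, 1 - 1e-7)

    if exact:
        freq = sloan_frequency(p, N, m, d)
        mean_abund = p
    else:
        a = N * m * p
        b = N * m * (1.0 - p)
        draws = rng.beta(a[None, :], b[None, :],
                         size=(config.n_samples, config.n_species))
        freq = (draws > d).mean(axis=0)
        mean_abund = draws.mean(axis=0)
        mean_abund = np.clip(mean_abund, 1e-9, 1 - 1e-9)
    table = pd.DataFrame({
        "species_id": [f"sp{i:05d}" for i in range(config.n_species)],
        "mean_abundance": mean_abund,
        "frequency": freq,
    })
    truth = {"ncm_m": m, "ncm_N": N, "detection_limit": d, "exact": exact,
             "true_p": p.tolist()}
    return table, truth


# ---------------------------------------------------------------------------
# KO matrix
# ---------------------------------------------------------------------------

def gen_ko_matrix(
    config: SimulationConfig,
    ecosystems: tuple[str, ...] = KO_ECOSYSTEMS,
    mags_per_ecosystem: int = 8,
):
    """MAG × KO counts with a planted enriched set in the first (focal)
    ecosystem, a planted singleton KO, and a broadly conserved background.

    The planted enriched KOs carry high copy counts in every focal MAG and
    exactly one copy in a MAG of 6 of the background ecosystems — enough to
    be prevalent (6/14 > 30 %) yet so scarce that the pooled enrichment
    ratio exceeds 0.9 by construction. Background KOs are Poisson(20) in a
    random ≥ 60 % subset of ecosystems, keeping every background ratio far
    inside (−0.9, 0.9).

    Returns ``(counts, sizes_mb, labels, truth)``.
    """
    if len(ecosystems) < 2:
        raise InvalidConfigError("need at least 2 ecosystems")
    rng = config.rng("ko")
    focal = ecosystems[0]
    excluded = list(ecosystems[:2]) if len(ecosystems) > 2 else [focal]
    background_ecos = [e for e in ecosystems if e not in excluded]

    mag_ids, labels = [], {}
    for eco in ecosystems:
        for j in range(mags_per_ecosystem):
            mid = f"mag_{ecosystems.index(eco):02d}_{j:02d}"
            mag_ids.append(mid)
            labels[mid] = eco
    sizes = pd.Series(rng.uniform(2.0, 6.0, size=len(mag_ids)), index=mag_ids,
                      name="size_mb")
    labels = pd.Series(labels, name="ecosystem")

    enriched = list(config.enriched_ko_ids)
    n_background = max(config.n_kos - len(enriched) - 1, 1)
    background_kos = [f"K{90000 + i:05d}" for i in range(n_background)]
    singleton_ko = "K99999"
    kos = enriched + background_kos + [singleton_ko]

    counts = pd.DataFrame(0, index=mag_ids, columns=kos, dtype=int)
    by_eco = {eco: [m for m in mag_ids if labels[m] == eco] for eco in ecosystems}

    for ko in background_kos:
        n_present = rng.integers(int(0.6 * len(ecosystems)), len(ecosystems) + 1)
        chosen = rng.choice(len(ecosystems), size=int(n_present), replace=False)
        for ei in chosen:
            for m in by_eco[ecosystems[ei]]:
                counts.loc[m, ko] = rng.poisson(20)

    for ko in enriched:
        for m in by_eco[focal]:
            counts.loc[m, ko] = int(rng.integers(60, 120))
        carriers = rng.choice(len(background_ecos), size=6, replace=False)
        for ei in carriers:
            eco_mags = by_eco[background_ecos[ei]]
            counts.loc[eco_mags[int(rng.integers(0, len(eco_mags)))], ko] = 1

    # singleton: present in exactly one (non-focal) ecosystem
    single_eco = background_ecos[int(rng.integers(0, len(background_ecos)))]
    for m in by_eco[single_eco]:
        counts.loc[m, singleton_ko] = rng.poisson(10) + 1

    truth = {
        "focal": focal,
        "excluded": excluded,
        "enriched_kos": sorted(enriched),
        "singleton_ko": singleton_ko,
        "singleton_ecosystem": single_eco,
    }
    return counts, sizes, labels, truth


# ---------------------------------------------------------------------------
# BGC catalog
# ---------------------------------------------------------------------------

def gen_bgc_catalog(
    config: SimulationConfig,
    n_bgcs: int = 300,
    n_samples: int = 10,
):
    """BGC records with GCF/GCC assignments, reference membership values and
    a planted fraction of novel GCFs.

    ``novel_bgc_fraction`` is the fraction of GCFs planted novel: their
    member BGCs get mapped counts strictly below the 20 % rule; non-novel
    GCFs get ≥ 45 % mapped members, so with fraction 0 no GCC can fall
    below the 40 % rule either. Matched BGCs draw membership values in
    (0, 900]; unmatched members either carry no hit or a value above 900.

    Returns ``(records, gene_abundances, truth)``.
    """
    rng = config.rng("bgc")
    n_gcfs = max(2, n_bgcs // 3)
    n_gccs = max(1, n_gcfs // 6)
    gcf_ids = [f"GCF{i:04d}" for i in range(n_gcfs)]
    gcf_to_gcc = {g: f"GCC{int(rng.integers(0, n_gccs)):03d}" for g in gcf_ids}

    n_novel_gcfs = int(round(config.novel_bgc_fraction * n_gcfs))
    novel_gcfs = set(rng.choice(gcf_ids, size=n_novel_gcfs, replace=False))

    # distribute BGCs over GCFs (≥1 each)
    assignment = list(gcf_ids) + list(rng.choice(gcf_ids, size=n_bgcs - n_gcfs))
    rng.shuffle(assignment)
    cats = list(_BGC_CATEGORY_WEIGHTS)
    cat_p = np.array(list(_BGC_CATEGORY_WEIGHTS.values()))
    cat_p = cat_p / cat_p.sum()

    rows = []
    for i, gcf in enumerate(assignment):
        length = int(rng.integers(5_000, 120_000))
        rows.append({
            "bgc_id": f"BGC{i:05d}",
            "mag_id": f"mag{int(rng.integers(0, config.n_mags)):05d}",
            "species_id": f"sp{int(rng.integers(0, max(2, n_bgcs // 4))):05d}",
            "gcf_id": gcf,
            "gcc_id": gcf_to_gcc[gcf],
            "category": str(rng.choice(cats, p=cat_p)),
            "length": length,
            "contig_length": int(length + rng.integers(0, 50_000)),
        })
    records = pd.DataFrame(rows)

    # plant per-GCF mapped counts
    membership = pd.Series(np.nan, index=records["bgc_id"], name="membership")
    matched_flags = {}
    for gcf, sub in records.groupby("gcf_id"):
        size = len(sub)
        if gcf in novel_gcfs:
            hi = int(np.ceil(0.2 * size)) - 1  # mapped/size < 0.2 guaranteed
            n_mapped = int(rng.integers(0, hi + 1)) if hi >= 0 else 0
        else:
            lo = int(np.ceil(0.45 * size))
            n_mapped = int(rng.integers(lo, size + 1))
        mapped_ids = rng.choice(sub["bgc_id"], size=n_mapped, replace=False)
        for bid in sub["bgc_id"]:
            if bid in set(mapped_ids):
                membership[bid] = float(rng.uniform(1.0, 900.0))
                matched_flags[bid] = True
            else:
                # half missing, half above-cutoff hits
                membership[bid] = float(rng.uniform(901.0, 2500.0)) \
                    if rng.random() < 0.5 else np.nan
                matched_flags[bid] = False
    records["membership"] = membership.to_numpy()

    # biosynthetic-gene abundances: 3–9 genes per BGC × n_samples
    gene_rows = []
    sample_cols = [f"S{i:03d}" for i in range(n_samples)]
    for bid in records["bgc_id"]:
        n_genes = int(rng.integers(3, 10))
        for g in range(n_genes):
            vals = rng.lognormal(1.0, 0.8, size=n_samples)
            gene_rows.append({"bgc_id": bid, "gene_id": f"{bid}_g{g}",
                              **dict(zip(sample_cols, vals))})
    gene_abundances = pd.DataFrame(gene_rows)

    gcc_mapped = {}
    for gcc, sub in records.groupby("gcc_id"):
        flags = [matched_flags[b] for b in sub["bgc_id"]]
        gcc_mapped[gcc] = float(np.mean(flags))
    truth = {
        "novel_gcfs": sorted(novel_gcfs),
        "novel_gcf_fraction": config.novel_bgc_fraction,
        "matched_bgcs": sorted(b for b, f in matched_flags.items() if f),
        "gcc_mapped_fraction": gcc_mapped,
        "novel_gccs": sorted(g for g, f in gcc_mapped.items() if f < 0.4),
    }
    return records, gene_abundances, truth


# ---------------------------------------------------------------------------
# probe genomes
# ---------------------------------------------------------------------------

def gen_probe_genomes(
    config: SimulationConfig,
    target_length: int = 6_000,
    n_offtargets: int = 3,
    offtarget_length: int = 8_000,
    n_shared: int = 5,
):
    """A target genome plus off-target genomes with planted shared 30-mers.

    The target is a uniform random sequence (so its 30-mers are unique
    against random off-targets with overwhelming probability); ``n_shared``
    non-overlapping candidate windows are copied verbatim into the
    off-target genomes and must be removed by the specificity screen, while
    all remaining windows are planted unique and must survive.

    Returns ``(target, references, truth)`` where ``target`` maps contig →
    sequence, ``references`` maps genus → {sequence_id: sequence}.
    """
    rng = config.rng("probes")
    alphabet = np.array(list("ACGT"))

    def random_seq(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length))

    target_seq = random_seq(target_length)
    target = {"contig_1": target_seq}

    window_starts = list(range(0, target_length - 30 + 1, 15))
    # non-overlapping shared windows: even step positions spaced ≥ 2 steps
    candidates = window_starts[::2]
    shared_starts = sorted(
        rng.choice(candidates, size=n_shared, replace=False).tolist()
    )
    shared_seqs = [target_seq[s:s + 30] for s in shared_starts]

    references: dict[str, dict[str, str]] = {}
    for g in range(n_offtargets):
        genus = f"OffGenus{g + 1}"
        seq = list(random_seq(offtarget_length))
        # each off-target carries every shared window (forward or reverse)
        for si, sub in enumerate(shared_seqs):
            pos = 100 + si * (offtarget_length - 200) // max(1, len(shared_seqs))
            insert = sub if rng.random() < 0.5 else _revcomp(sub)
            seq[pos:pos + 30] = list(insert)
        references[genus] = {f"{genus}_contig": "".join(seq)}

    truth = {
        "shared_starts": shared_starts,
        "shared_window_ids": [f"contig_1:{s}" for s in shared_starts],
        "unique_window_ids": [
            f"contig_1:{s}" for s in window_starts if s not in set(shared_starts)
        ],
        "target_genus": "Asgard-Qilian-1",
    }
    return target, references, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
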