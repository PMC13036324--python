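"""Diversity, ordination, distance–decay, and neutral community model fitting.

The ecology stages consume a samples × taxa abundance matrix (TPM-like,
nonnegative) and per-sample coordinates, and provide:

* Shannon diversity (natural log) and Bray–Curtis dissimilarity;
* principal coordinate analysis (classical scaling, via scikit-bio);
* great-circle distances between samples (haversine, R = 6371 km);
* the distance–decay relationship (DDR): a least-squares fit of
  log community similarity against geographic (or vertical) distance;
* Sloan's neutral community model (NCM): occurrence frequency of a taxon as
  a function of its mean relative abundance,
  ``f(p) = 1 − BetaCDF(d; N·m·p, N·m·(1−p))``, fitted for the migration
  rate m by nonlinear least squares;
* nonparametric group comparisons (Kruskal–Wallis, two-sided Mann–Whitney)
  with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# diversity metrics
# ---------------------------------------------------------------------------

def shannon(abundances) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ (nats) after normalization.

    Zero entries are ignored; an all-zero vector raises.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundances")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) ∈ [0, 1]."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative abundances")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between the rows (samples)."""
    d = squareform(pdist(abundance.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame        # samples × retained axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    negative_eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dissimilarity: pd.DataFrame | np.ndarray, k: int = 2) -> PCoAResult:
    """Classical scaling (PCoA) of a symmetric, zero-diagonal dissimilarity.

    Axes are ordered by descending eigenvalue; axes with negative eigenvalues
    (possible for non-Euclidean dissimilarities such as Bray–Curtis) are
    reported but never returned as coordinates. If fewer than ``k`` positive
    eigenvalues exist the result is truncated with a warning.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        ids = [str(i) for i in dissimilarity.index]
        mat = dissimilarity.to_numpy(dtype=float)
    else:
        mat = np.asarray(dissimilarity, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    try:
        dm = DistanceMatrix(mat, ids=ids)  # validates symmetry + hollowness
    except Exception as exc:
        raise ValueError(f"invalid dissimilarity matrix: {exc}") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = int((eig > 1e-12).sum())
    if pos < k:
        warnings.warn(
            f"only {pos} positive eigenvalues; truncating from k={k}", stacklevel=2
        )
    keep = min(k, pos)
    coords = res.samples.iloc[:, :keep]
    coords.index = ids
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eig,
        negative_eigenvalues=eig[eig < 0],
        proportion_explained=res.proportion_explained.to_numpy(),
    )


# ---------------------------------------------------------------------------
# geography and distance–decay
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6,371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def pairwise_geo_km(geo: pd.DataFrame) -> pd.DataFrame:
    """Pairwise haversine distances from a table with lat/lon columns.

    ``geo`` is indexed by sample id with columns ``latitude, longitude``.
    """
    ids = geo.index
    n = len(ids)
    out = np.zeros((n, n))
    lat = geo["latitude"].to_numpy(float)
    lon = geo["longitude"].to_numpy(float)
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(lat[i], lon[i], lat[j], lon[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass
class DDRFit:
    """A distance–decay fit of ln(similarity) against distance.

    ``slope`` is per log-km when ``log_distance`` (power-law form) and per km
    otherwise (exponential form, slope ≈ −λ).
    """

    slope: float
    intercept: float
    correlation: float
    p_value: float
    n_pairs: int
    n_excluded: int
    kind: str = "geographic"
    log_distance: bool = True


def ddr_fit(
    similarities,
    distances,
    kind: str = "geographic",
    log_distance: bool = True,
) -> DDRFit:
    """Least-squares distance–decay fit.

    Regresses ln(similarity) on ln(distance) (default, the power-law form) or
    on raw distance (``log_distance=False``, the exponential form whose slope
    recovers −λ when similarity ∝ exp(−λ·d)). Pairs with zero distance or
    nonpositive similarity are excluded and counted; < 3 usable pairs raise.
    """
    s = np.asarray(similarities, dtype=float)
    d = np.asarray(distances, dtype=float)
    if s.shape != d.shape:
        raise ValueError("similarity/distance arrays differ in length")
    usable = (d > 0) & (s > 0)
    n_excluded = int((~usable).sum())
    s, d = s[usable], d[usable]
    if len(s) < 3:
        raise ValueError(f"only {len(s)} usable pairs (need ≥ 3)")
    x = np.log(d) if log_distance else d
    res = stats.linregress(x, np.log(s))
    return DDRFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        p_value=float(res.pvalue),
        n_pairs=int(len(s)),
        n_excluded=n_excluded,
        kind=kind,
        log_distance=log_distance,
    )


def vertical_distances(elevations_m: pd.Series, pairs: pd.DataFrame) -> np.ndarray:
    """|Δ elevation| in metres for each (sample_a, sample_b) row of ``pairs``."""
    e = elevations_m
    return np.abs(
        e.loc[pairs["sample_a"]].to_numpy(float)
        - e.loc[pairs["sample_b"]].to_numpy(float)
    )


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NCMModel:
    """Fitted Sloan neutral community model.

    N is the community size, m the migration rate (fitted, ∈ (0, 1]), d the
    detection limit on relative abundance. R² = 1 − SSE/SST may be negative
    when communities deviate from neutrality worse than a flat predictor.
    """

    N: float
    m: float
    d: float
    r2: float
    converged: bool
    message: str = ""
    n_species: int = 0
    predicted: np.ndarray | None = field(default=None, repr=False)


def sloan_frequency(p, N: float, m: float, d: float) -> np.ndarray:
    """Predicted occurrence frequency 1 − BetaCDF(d; N·m·p, N·m·(1−p))."""
    p = np.asarray(p, dtype=float)
    return 1.0 - stats.beta.cdf(d, N * m * p, N * m * (1.0 - p))


def ncm_fit(mean_abundance, frequency, N: float, d: float | None = None) -> NCMModel:
    """Fit Sloan's neutral model for the migration rate m.

    ``mean_abundance`` (pᵢ ∈ (0,1)) and ``frequency`` (fᵢ ∈ [0,1]) are
    per-taxon; ``N`` is the community size. The detection limit ``d``
    defaults to the minimum observed mean relative abundance. m is found by
    bounded 1-D nonlinear least squares on the model curve; non-convergence
    is reported on the result rather than raised.
    """
    p = np.asarray(mean_abundance, dtype=float)
    f = np.asarray(frequency, dtype=float)
    if p.shape != f.shape:
        raise ValueError("abundance/frequency arrays differ in length")
    if len(p) < 10:
        raise ValueError("need ≥ 10 taxa for an NCM fit")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("mean relative abundances must lie in (0, 1)")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if d is None:
        d = float(p.min())

    def sse(m: float) -> float:
        resid = f - sloan_frequency(p, N, m, d)
        return float(resid @ resid)

    res = optimize.minimize_scalar(sse, bounds=(1e-9, 1.0), method="bounded",
                                   options={"xatol": 1e-10})
    m_hat = float(res.x)
    pred = sloan_frequency(p, N, m_hat, d)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - sse(m_hat) / sst if sst > 0 else float("nan")
    return NCMModel(
        N=float(N), m=m_hat, d=d, r2=float(r2),
        converged=bool(res.success),
        message=str(getattr(res, "message", "")),
        n_species=int(len(p)),
        predicted=pred,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment of a vector of p-values."""
    return false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


@dataclass
class GroupStats:
    kruskal_statistic: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adj, significant


def group_stats(groups: dict, alpha: float = 0.05) -> GroupStats:
    """Kruskal–Wallis across ≥ 2 groups plus all pairwise two-sided
    Mann–Whitney tests, BH-adjusted; significance at adjusted p < ``alpha``.

    ``groups`` maps group label → 1-D array of observations. Small samples
    without ties use the exact Mann–Whitney distribution (scipy's automatic
    method selection); ties fall back to the tie-corrected normal
    approximation.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(np.asarray(vals)) < 1:
            raise ValueError(f"group {name!r} is empty")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    kw = stats.kruskal(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mw = stats.mannwhitneyu(arrays[i], arrays[j],
                                    alternative="two-sided", method="auto")
            rows.append((names[i], names[j], float(mw.statistic), float(mw.pvalue)))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    pw["p_adj"] = bh_adjust(pw["p_raw"].to_numpy()) if len(pw) else []
    pw["significant"] = pw["p_adj"] < alpha
    return GroupStats(
        kruskal_statistic=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        pairwise=pw,
    )
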