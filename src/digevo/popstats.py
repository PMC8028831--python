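"""Population-level analysis.

Fitness distributions are summarized by a Gaussian kernel density estimate
(Silverman bandwidth); local maxima of the density are fitness peaks, and the
genotypes lying within two bandwidths of a peak are its representatives.
Unimodality is tested with Hartigan's dip statistic (implemented here as a
convex/concave band fit to the empirical CDF, with a seeded uniform-null
bootstrap p-value).  Population heterogeneity is measured two ways, both in
nats: genotypic heterogeneity is the sum over the 120 genomic sites of the
per-site Shannon entropy of instruction frequencies, and phenotypic
heterogeneity is the Shannon entropy of the distribution over the 512
possible task-performance profiles.  Populations are called
signaling-positive when their median marginal utility of messaging exceeds
the midpoint between the zero-centered and positive-shifted peaks of the
pooled utility distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .instructions import GENOME_LEN, N_CODES

__all__ = [
    "PeakSet",
    "HeterogeneityResult",
    "SignalingLabel",
    "fitness_kde",
    "dip_statistic",
    "dip_unimodality",
    "genotypic_heterogeneity",
    "phenotypic_heterogeneity",
    "population_heterogeneity",
    "classify_signaling",
    "incidence_table",
    "N_PHENOTYPE_CLASSES",
]

N_PHENOTYPE_CLASSES = 512  # 2**9 task presence/absence combinations


# ---------------------------------------------------------------------------
# kernel density peaks

@dataclass
class PeakSet:
    bandwidth: float
    peaks: list[float]  # ascending fitness values at density maxima
    grid: np.ndarray
    density: np.ndarray
    samples: list[np.ndarray] = field(default_factory=list)  # indices per peak

    def window(self, peak_index: int) -> tuple[float, float]:
        p = self.peaks[peak_index]
        return (p - 2.0 * self.bandwidth, p + 2.0 * self.bandwidth)


def fitness_kde(values, grid_points: int = 512) -> PeakSet:
    """Gaussian KDE with Silverman's bandwidth; strict local maxima on a
    512-point grid spanning the data range ±3 bandwidths are the peaks.

    Per-peak samples are the indices of the input values lying within two
    bandwidths of the peak location.  Degenerate all-equal input collapses
    to a single peak at that value with a floor bandwidth.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values for a density estimate")
    if np.ptp(x) == 0.0:
        bw = max(abs(x[0]), 1.0) * 1e-9
        peaks = [float(x[0])]
        grid = np.array([x[0]])
        dens = np.array([1.0])
        ps = PeakSet(bw, peaks, grid, dens)
        ps.samples = [np.arange(x.size)]
        return ps
    kde = gaussian_kde(x, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    peak_vals = [float(grid[i + 1]) for i in np.flatnonzero(interior)]
    ps = PeakSet(bw, sorted(peak_vals), grid, dens)
    for p in ps.peaks:
        ps.samples.append(np.flatnonzero(np.abs(x - p) <= 2.0 * bw))
    return ps


# ---------------------------------------------------------------------------
# Hartigan's dip

def _prefix_convex_eps(x: np.ndarray) -> np.ndarray:
    """For each prefix [0..k] of distinct sorted x, the minimal ε for which a
    convex function fits the ECDF band.  Uses the exact identity: the best
    sup-norm convex fit to midpoints c_i = (i + 1/2)/n errs by half the
    largest gap between c and its greatest convex minorant.
    """
    n = x.size
    c = (np.arange(n) + 0.5) / n
    eps = np.empty(n)
    hull: list[int] = []  # indices of hull vertices
    seg_max: list[float] = []  # cumulative max gap up to each hull vertex
    for k in range(n):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            # pop j if it lies above the chord i->k (non-convex turn)
            if (c[j] - c[i]) * (x[k] - x[i]) >= (c[k] - c[i]) * (x[j] - x[i]):
                hull.pop()
                seg_max.pop()
            else:
                break
        prev_max = seg_max[-1] if seg_max else 0.0
        if hull:
            i = hull[-1]
            if k > i + 1:
                t = (x[i + 1 : k] - x[i]) / (x[k] - x[i])
                line = c[i] + t * (c[k] - c[i])
                gap = float(np.max(c[i + 1 : k] - line))
                prev_max = max(prev_max, gap)
        hull.append(k)
        seg_max.append(prev_max)
        eps[k] = 0.5 / n + 0.5 * max(prev_max, 0.0)
    return eps


def dip_statistic(values) -> float:
    """Hartigan's dip: the smallest sup-norm distance between the empirical
    CDF and the class of unimodal distribution functions.

    Computed by splitting at every candidate mode and fitting the convex
    (left) and concave (right) parts of a unimodal CDF inside the ECDF band;
    ties are collapsed into interval constraints first.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0 if n < 2 else 0.25  # all-equal: point mass vs. band edges
    ux, counts = np.unique(x, return_counts=True)
    if ux.size == n:
        eps_l = _prefix_convex_eps(x)
        eps_r = _prefix_convex_eps((-x)[::-1])[::-1]
        return float(np.min(np.maximum(eps_l, eps_r)))
    # ties: per-point boxes [hi_cum/n - eps, lo_cum/n + eps]; bisect on eps
    cum = np.cumsum(counts)
    upper_f = (cum - counts) / n  # F just below each unique point
    lower_f = cum / n  # F at each unique point
    lo_e, hi_e = 0.0, 0.5
    for _ in range(40):
        mid = 0.5 * (lo_e + hi_e)
        if _band_feasible(ux, lower_f - mid, upper_f + mid):
            hi_e = mid
        else:
            lo_e = mid
    return float(hi_e)


def _band_feasible(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> bool:
    """Is there a convex-then-concave function through the boxes [lo, hi]?"""
    if np.any(lo > hi):
        return False
    left_ok = _prefix_fit(x, lo, hi)
    # concave fit on a suffix == convex fit on the reversed, negated axis
    right_ok = _prefix_fit((-x)[::-1], -hi[::-1], -lo[::-1])[::-1]
    return bool(np.any(left_ok & right_ok))


def _prefix_fit(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """prefix_ok[k]: a convex function can pass through boxes 0..k.

    Feasible iff the greatest convex minorant of the upper bounds stays at
    or above the lower bounds; prefix feasibility is monotone, so one
    incremental hull scan suffices.
    """
    m = x.size
    ok = np.zeros(m, dtype=bool)
    hull: list[int] = []
    feasible = True
    for k in range(m):
        if feasible:
            while len(hull) >= 2:
                i, j = hull[-2], hull[-1]
                if (hi[j] - hi[i]) * (x[k] - x[i]) >= (hi[k] - hi[i]) * (x[j] - x[i]):
                    hull.pop()
                else:
                    break
            if hull:
                i = hull[-1]
                if k > i + 1:
                    t = (x[i + 1 : k] - x[i]) / (x[k] - x[i])
                    line = hi[i] + t * (hi[k] - hi[i])
                    if np.any(line < lo[i + 1 : k] - 1e-12):
                        feasible = False
            if feasible and hi[k] < lo[k]:
                feasible = False
            hull.append(k)
        ok[k] = feasible
    return ok


def dip_unimodality(values, n_boot: int = 200, seed: int = 0):
    """Dip statistic plus a bootstrap p-value under a uniform null.

    The alternative hypothesis is multimodality: small p-values reject
    unimodality.  The null distribution is the dip of uniform samples of the
    same size, drawn from a seeded generator.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 4:
        raise ValueError("dip test needs at least 4 observations")
    d = dip_statistic(x)
    rng = np.random.default_rng(seed)
    boots = np.array([dip_statistic(rng.random(x.size)) for _ in range(n_boot)])
    p = (1 + np.sum(boots >= d)) / (n_boot + 1)
    return d, float(p)


# ---------------------------------------------------------------------------
# heterogeneity entropies

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def genotypic_heterogeneity(genomes) -> float:
    """Σ_i s_i over the 120 sites, s_i the Shannon entropy (nats) of
    instruction frequencies at site i; 0·ln0 = 0."""
    mat = _genome_matrix(genomes)
    total = 0.0
    for site in range(GENOME_LEN):
        counts = np.bincount(mat[:, site], minlength=N_CODES)
        total += _entropy(counts.astype(float))
    return total


def _genome_matrix(genomes) -> np.ndarray:
    from .genetics import parse

    rows = []
    for g in genomes:
        rows.append(parse(g) if isinstance(g, str) else list(g))
    if not rows:
        raise ValueError("need at least one genome")
    return np.asarray(rows, dtype=np.int64)


def phenotypic_heterogeneity(class_ids) -> float:
    """Shannon entropy (nats) of the phenotype-class distribution.

    ``class_ids`` are integers in [0, 512): the 9-bit task presence
    profiles.  0 for a monoclonal phenotype; ln 512 at the uniform maximum.
    """
    ids = np.asarray(list(class_ids), dtype=np.int64)
    if ids.size == 0:
        raise ValueError("need at least one phenotype")
    if np.any((ids < 0) | (ids >= N_PHENOTYPE_CLASSES)):
        raise ValueError("phenotype class ids must be in [0, 512)")
    return _entropy(np.bincount(ids, minlength=N_PHENOTYPE_CLASSES).astype(float))


@dataclass(frozen=True)
class HeterogeneityResult:
    genotypic_entropy: float  # nats, in [0, 120 ln 32]
    phenotypic_entropy: float  # nats, in [0, ln 512]
    fitness_sd: float


def population_heterogeneity(genomes, phenotype_ids, fitnesses) -> HeterogeneityResult:
    f = np.asarray(list(fitnesses), dtype=float)
    return HeterogeneityResult(
        genotypic_entropy=genotypic_heterogeneity(genomes),
        phenotypic_entropy=phenotypic_heterogeneity(phenotype_ids),
        fitness_sd=float(f.std(ddof=0)) if f.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# signaling classification

@dataclass(frozen=True)
class SignalingLabel:
    threshold: float
    median_utility: float
    positive: bool
    fallback_used: bool = False


def signaling_threshold(pooled_utilities, fallback: float = 0.05):
    """Midpoint between the zero-centered and the positive-shifted peaks of
    the pooled marginal-utility distribution.

    Falls back to a fixed threshold when the pooled density has fewer than
    two peaks.  Returns (threshold, fallback_used).
    """
    pooled = np.asarray(list(pooled_utilities), dtype=float)
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size >= 2 and np.ptp(pooled) > 0:
        ps = fitness_kde(pooled)
        if len(ps.peaks) >= 2:
            zero_peak = min(ps.peaks, key=abs)
            pos_peaks = [p for p in ps.peaks if p > zero_peak]
            if pos_peaks:
                return 0.5 * (zero_peak + max(pos_peaks)), False
    return fallback, True


def classify_signaling(population_utilities, fallback: float = 0.05) -> list[SignalingLabel]:
    """Label each population from its genotypes' messaging utilities.

    ``population_utilities``: one array of marginal utilities per
    population.  Utilities are pooled across populations to locate the two
    pooled peaks; each population is signaling-positive when its median
    utility exceeds the midpoint threshold.  Invariant to population order.
    """
    pops = [np.asarray(list(u), dtype=float) for u in population_utilities]
    if len(pops) < 2:
        raise ValueError("need at least two populations to pool a threshold")
    pooled = np.concatenate(pops) if pops else np.array([])
    threshold, fallback_used = signaling_threshold(pooled, fallback)
    labels = []
    for u in pops:
        med = float(np.nanmedian(u)) if u.size else float("nan")
        labels.append(
            SignalingLabel(
                threshold=float(threshold),
                median_utility=med,
                positive=bool(med > threshold),
                fallback_used=fallback_used,
            )
        )
    return labels


def incidence_table(runs):
    """Signaling incidence per (world size, resource level) condition cell.

    ``runs``: iterable of dicts with keys ``size``, ``rstar``, ``extinct``
    (bool) and ``positive`` (bool, ignored for extinct runs).  Returns a
    DataFrame with counts of signaling-positive, completed and extinct runs;
    extinct runs are excluded from the denominator and reported separately.
    """
    import pandas as pd

    df = pd.DataFrame(list(runs))
    df["extinct"] = df["extinct"].astype(bool)
    df["positive"] = df["positive"].astype(bool)
    rows = []
    for (size, rstar), group in df.groupby(["size", "rstar"]):
        extinct = int(group["extinct"].sum())
        done = group[~group["extinct"]]
        rows.append(
            {
                "size": size,
                "rstar": rstar,
                "n_runs": len(group),
                "n_completed": len(done),
                "n_extinct": extinct,
                "n_signaling": int(done["positive"].sum()),
            }
        )
    return pd.DataFrame(rows).sort_values(["size", "rstar"]).reset_index(drop=True)
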