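"""Cluster-based permutation test on time-scale coherence maps.

Group differences are tested pixelwise with an independent-samples t-test;
supra-threshold pixels (cluster-forming threshold p < 0.05, one-tailed) are
grouped by 4-connectivity in the (period, time) plane and scored by cluster
mass (sum of t).  Family-wise inference compares each observed cluster mass
against the permutation distribution of the maximum cluster mass under
random relabelings of subjects (group sizes preserved), with the
(1 + k) / (1 + N) p-value estimator.  No Monte-Carlo surrogate signals are
involved anywhere: the null is built from the observed maps themselves.

Cone-of-influence pixels are included in the test; a per-cluster report of
the fraction of pixels inside the COI is attached for interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .wtc import CoherenceMap

logger = logging.getLogger(__name__)

#: 4-connectivity: clusters grow along time or scale, not diagonally.
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class ClusterError(ValueError):
    pass


@dataclass
class Cluster:
    pixels: np.ndarray          # boolean mask on the map grid
    mass: float                 # sum of t over the cluster
    sign: int                   # +1: group A > B, -1: B > A
    p_perm: float | None = None
    coi_fraction: float | None = None


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    df: int
    z_map: np.ndarray
    clusters: list[Cluster]
    null_distribution: np.ndarray
    significant_mask: np.ndarray
    n_permutations: int
    seed: int
    alpha: float
    alpha_cluster: float
    tail: str
    periods_min: np.ndarray | None = None
    time_h: np.ndarray | None = None

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_perm is not None
                and c.p_perm < self.alpha]


@dataclass
class BandResult:
    """Period extent of the dominant significant cluster (and the union)."""

    found: bool
    min_period_min: float | None = None
    max_period_min: float | None = None
    min_freq_mhz: float | None = None
    max_freq_mhz: float | None = None
    union_min_period_min: float | None = None
    union_max_period_min: float | None = None


def _stack(maps: list[CoherenceMap]) -> np.ndarray:
    arrs = [np.asarray(m.r2, dtype=float) for m in maps]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ClusterError("maps are not on a common grid; regrid first")
    return np.stack(arrs)


def pixelwise_tmap(maps_a: list[CoherenceMap], maps_b: list[CoherenceMap],
                   min_coverage: int = 2):
    """Two-sample pooled-variance t per pixel; returns (t_map, df, valid mask).

    NaN pixels (periods a subject's rate cannot resolve) are dropped per
    pixel; a pixel enters the map only when at least ``min_coverage``
    subjects per group cover it.  df is reported for the fully covered case
    (nA + nB - 2).
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ClusterError("need at least 2 subjects per group")
    A, B = _stack(maps_a), _stack(maps_b)
    t, valid = _tmap_from_stacks(A, B, min_coverage)
    df = len(maps_a) + len(maps_b) - 2
    return t, df, valid


def _tmap_from_stacks(A: np.ndarray, B: np.ndarray, min_coverage: int = 2):
    nA = np.sum(~np.isnan(A), axis=0)
    nB = np.sum(~np.isnan(B), axis=0)
    valid = (nA >= min_coverage) & (nB >= min_coverage)
    with np.errstate(invalid="ignore", divide="ignore"):
        mA = np.nanmean(A, axis=0)
        mB = np.nanmean(B, axis=0)
        vA = np.nanvar(A, axis=0, ddof=1)
        vB = np.nanvar(B, axis=0, ddof=1)
        sp2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
        se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
        t = (mA - mB) / se
    zero_var = valid & (sp2 <= 0)
    if zero_var.any():
        logger.warning("zero pooled variance at %d pixels; t set to 0",
                       int(zero_var.sum()))
    t[zero_var] = 0.0
    t[~valid] = np.nan
    return t, valid


def form_clusters(t_map: np.ndarray, df: int, alpha_cluster: float = 0.05,
                  tail: str = "a>b") -> list[Cluster]:
    """Group supra-threshold pixels into 4-connected clusters.

    The cluster-forming threshold is the one-tailed p < ``alpha_cluster``
    quantile of t with ``df`` degrees of freedom.  ``tail`` is "a>b", "b>a"
    or "two" (both signs, each thresholded one-tailed at alpha_cluster).
    """
    thr = stats.t.ppf(1.0 - alpha_cluster, df)
    finite = np.isfinite(t_map)
    clusters: list[Cluster] = []
    signs = {"a>b": (1,), "b>a": (-1,), "two": (1, -1)}.get(tail)
    if signs is None:
        raise ClusterError(f"unknown tail {tail!r}")
    for sign in signs:
        supra = finite & (sign * t_map > thr)
        labels, n = ndimage.label(supra, structure=FOUR_CONN)
        for k in range(1, n + 1):
            mask = labels == k
            clusters.append(Cluster(pixels=mask,
                                    mass=float(t_map[mask].sum()),
                                    sign=sign))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_mass(t_map: np.ndarray, df: int, alpha_cluster: float, tail: str) -> float:
    cl = form_clusters(t_map, df, alpha_cluster, tail)
    return max((abs(c.mass) for c in cl), default=0.0)


def permutation_null(all_maps: np.ndarray, labels: np.ndarray, n_perm: int = 1000,
                     alpha_cluster: float = 0.05, tail: str = "a>b",
                     seed: int = 0, min_coverage: int = 2) -> np.ndarray:
    """Max-cluster-mass null over random group relabelings.

    ``all_maps`` is the (n_subjects, n_periods, n_times) stack; ``labels`` a
    boolean array, True = group A.  Group sizes are preserved in every
    permutation.  Deterministic under a fixed seed.
    """
    labels = np.asarray(labels, dtype=bool)
    if all_maps.shape[0] != len(labels):
        raise ClusterError("labels do not match map stack")
    nA = int(labels.sum())
    if nA < 2 or len(labels) - nA < 2:
        raise ClusterError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    df = len(labels) - 2
    null = np.empty(n_perm)
    idx = np.arange(len(labels))
    for p in range(n_perm):
        perm = rng.permutation(idx)
        la = np.zeros(len(labels), dtype=bool)
        la[perm[:nA]] = True
        t, _ = _tmap_from_stacks(all_maps[la], all_maps[~la], min_coverage)
        null[p] = _max_mass(t, df, alpha_cluster, tail)
    return null


def cluster_inference(clusters: list[Cluster], null: np.ndarray,
                      alpha: float = 0.05) -> tuple[list[Cluster], np.ndarray]:
    """Permutation p per cluster: p = (1 + #{null >= mass}) / (1 + N)."""
    if len(null) == 0:
        raise ClusterError("empty permutation null")
    N = len(null)
    for c in clusters:
        k = int(np.sum(null >= abs(c.mass)))
        c.p_perm = (1.0 + k) / (1.0 + N)
    if clusters:
        shape = clusters[0].pixels.shape
        sig = np.zeros(shape, dtype=bool)
        for c in clusters:
            if c.p_perm < alpha:
                sig |= c.pixels
    else:
        sig = np.zeros((0, 0), dtype=bool)
    return clusters, sig


def z_transform(t_map: np.ndarray, df: int) -> np.ndarray:
    """Probit transform of the t CDF, for display (a z-statistic map)."""
    cdf = stats.t.cdf(t_map, df)
    eps = np.finfo(float).tiny
    return stats.norm.ppf(np.clip(cdf, eps, 1.0 - eps))


def cluster_test(maps_a: list[CoherenceMap], maps_b: list[CoherenceMap],
                 n_perm: int = 1000, alpha: float = 0.05,
                 alpha_cluster: float = 0.05, tail: str = "a>b",
                 seed: int = 0) -> ClusterTestResult:
    """Full cluster-based permutation comparison of two groups of maps."""
    t_map, df, valid = pixelwise_tmap(maps_a, maps_b)
    clusters = form_clusters(t_map, df, alpha_cluster, tail)
    stack = np.concatenate([_stack(maps_a), _stack(maps_b)])
    labels = np.array([True] * len(maps_a) + [False] * len(maps_b))
    null = permutation_null(stack, labels, n_perm, alpha_cluster, tail, seed)
    clusters, sig = cluster_inference(clusters, null, alpha)
    if sig.size == 0:
        sig = np.zeros_like(t_map, dtype=bool)
    ref = maps_a[0]
    # COI-overlap report: fraction of each cluster's pixels inside the COI
    coi_invalid = ref.periods_min[:, None] > ref.coi_min[None, :]
    for c in clusters:
        npix = int(c.pixels.sum())
        c.coi_fraction = float((c.pixels & coi_invalid).sum() / npix) if npix else 0.0
    return ClusterTestResult(
        t_map=t_map, df=df, z_map=z_transform(t_map, df), clusters=clusters,
        null_distribution=null, significant_mask=sig, n_permutations=n_perm,
        seed=seed, alpha=alpha, alpha_cluster=alpha_cluster, tail=tail,
        periods_min=ref.periods_min, time_h=ref.time_h)


def extract_band(result: ClusterTestResult,
                 periods_min: np.ndarray | None = None) -> BandResult:
    """Period range of the largest significant cluster (by |mass|).

    Also reports the union envelope over all significant clusters.  Returns
    ``found=False`` (not an exception) when nothing is significant.
    """
    periods = result.periods_min if periods_min is None else np.asarray(periods_min)
    sig = result.significant_clusters
    if not sig:
        return BandResult(found=False)
    top = max(sig, key=lambda c: abs(c.mass))
    rows = np.nonzero(top.pixels.any(axis=1))[0]
    lo, hi = float(periods[rows.min()]), float(periods[rows.max()])
    union_rows = np.nonzero(result.significant_mask.any(axis=1))[0]
    ulo, uhi = float(periods[union_rows.min()]), float(periods[union_rows.max()])
    return BandResult(
        found=True, min_period_min=lo, max_period_min=hi,
        min_freq_mhz=round(1000.0 / (hi * 60.0), 2),
        max_freq_mhz=round(1000.0 / (lo * 60.0), 2),
        union_min_period_min=ulo, union_max_period_min=uhi)
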