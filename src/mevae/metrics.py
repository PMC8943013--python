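"""Embedding-quality and radial-profile metrics.

Covers population separability (k-means cluster purity, normalized mutual
information, ANOVA + Tukey), nuisance leakage (max Spearman correlation
between latent columns and a nuisance series), and the radius-indexed
intensity metrics computed on circle-registered cells (radial slope and
inner/middle/outer compartment means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .exceptions import InvalidInputError
from .models import EmbeddingMatrix  # re-exported container

__all__ = [
    "EmbeddingMatrix",
    "RadialProfile",
    "cluster_purity",
    "normalized_mutual_information",
    "max_nuisance_correlation",
    "radial_slope",
    "compartment_means",
    "separability",
    "kmeans_embed",
]


def kmeans_embed(embedding: EmbeddingMatrix | np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means (k-means++ init, 10 restarts, best inertia kept)."""
    values = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    if k > values.shape[0]:
        raise InvalidInputError("k exceeds number of cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(values)


def cluster_purity(labels, assignments, k: int | None = None):
    """Per-cluster purity = fraction of the modal ground-truth population.

    Returns (mean, sd, per_cluster dict); mean and sd are unweighted over
    clusters (population sd).  Empty clusters are excluded with a warning.
    """
    labels = np.asarray(labels)
    assignments = np.asarray(assignments)
    if labels.shape != assignments.shape:
        raise InvalidInputError("labels and assignments length mismatch")
    cluster_ids = np.arange(k) if k is not None else np.unique(assignments)
    per_cluster = {}
    for c in cluster_ids:
        members = labels[assignments == c]
        if members.size == 0:
            warnings.warn(f"cluster {c} is empty; excluded from purity mean", RuntimeWarning)
            continue
        _, counts = np.unique(members, return_counts=True)
        per_cluster[int(c)] = counts.max() / members.size
    vals = np.array(list(per_cluster.values()))
    return float(vals.mean()), float(vals.std()), per_cluster


def normalized_mutual_information(labels, assignments) -> float:
    """NMI = I(L;C) / sqrt(H(L) H(C)) with natural-log entropies.

    Returns 0 (with a warning) when either partition is single-class.
    """
    labels = np.asarray(labels)
    assignments = np.asarray(assignments)
    if labels.shape != assignments.shape:
        raise InvalidInputError("labels and assignments length mismatch")
    n = labels.size
    _, li = np.unique(labels, return_inverse=True)
    _, ci = np.unique(assignments, return_inverse=True)
    contingency = np.zeros((li.max() + 1, ci.max() + 1))
    np.add.at(contingency, (li, ci), 1.0)
    pl = contingency.sum(1) / n
    pc = contingency.sum(0) / n
    h_l = -np.sum(pl * np.log(pl, where=pl > 0, out=np.zeros_like(pl)))
    h_c = -np.sum(pc * np.log(pc, where=pc > 0, out=np.zeros_like(pc)))
    if h_l <= 0 or h_c <= 0:
        warnings.warn("single-class partition; NMI defined as 0", RuntimeWarning)
        return 0.0
    pij = contingency / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pij > 0, pij / np.outer(pl, pc), 1.0)
        mi = np.sum(np.where(pij > 0, pij * np.log(ratio), 0.0))
    return float(mi / np.sqrt(h_l * h_c))


def _spearman_vs_series(values: np.ndarray, series: np.ndarray) -> np.ndarray:
    """|Spearman rho| of each column against a series; constant columns -> 0."""
    n, d = values.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    rs = stats.rankdata(series)
    rs = (rs - rs.mean()) / max(rs.std(), 1e-12)
    out = np.zeros(d)
    for j in range(d):
        col = ranks[:, j]
        sd = col.std()
        if sd < 1e-12:
            continue
        out[j] = abs(np.mean((col - col.mean()) / sd * rs))
    return out


def max_nuisance_correlation(
    embedding: EmbeddingMatrix | np.ndarray,
    nuisance_values: np.ndarray,
    circular: bool = False,
) -> float:
    """Max over latent columns of |Spearman| with a nuisance series.

    Circular quantities (angles in degrees) are correlated through their sin
    and cos components, max over both, since rank correlation with a raw
    angle is discontinuous at the wrap-around.
    """
    values = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    nuisance = np.asarray(nuisance_values, float)
    if values.shape[0] < 3:
        raise InvalidInputError("need at least 3 cells")
    if values.shape[0] != nuisance.size:
        raise InvalidInputError("nuisance series does not align with cells")
    if circular:
        rad = np.deg2rad(nuisance)
        series = [np.sin(rad), np.cos(rad)]
    else:
        series = [nuisance]
    return float(max(_spearman_vs_series(values, s).max() for s in series))


@dataclass
class RadialProfile:
    """Per-ring mean intensities of a circularized cell and their OLS fit.

    The slope is the metric; the intercept is computed and stored but not
    used downstream.
    """

    radii: np.ndarray
    means: np.ndarray
    slope: float
    intercept: float


def radial_slope(circular_image: np.ndarray, radius: int) -> RadialProfile:
    """OLS slope of ring-mean intensity vs. ring index on a circularized cell.

    Ring r holds the pixels with floor(distance to center) == r; empty rings
    are interpolated from neighbors with a warning.
    """
    img = circular_image[..., 0] if circular_image.ndim == 3 else circular_image
    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dist = np.hypot(rows - cy, cols - cx)
    ring = np.floor(dist).astype(int)
    disc = dist <= radius  # rings partition the disc; outside pixels excluded
    means = np.full(radius + 1, np.nan)
    for r in range(radius + 1):
        sel = (ring == r) & disc
        if sel.any():
            means[r] = img[sel].mean()
    if np.isnan(means).any():
        warnings.warn("empty radial ring; interpolating from neighbors", RuntimeWarning)
        idx = np.arange(radius + 1)
        good = ~np.isnan(means)
        means = np.interp(idx, idx[good], means[good])
    radii = np.arange(radius + 1)
    fit = stats.linregress(radii, means)
    return RadialProfile(radii=radii, means=means, slope=float(fit.slope), intercept=float(fit.intercept))


def compartment_means(circular_image: np.ndarray, radius: int):
    """Area-weighted mean intensities of the inner/middle/outer thirds of a
    circularized cell plus the whole-cell mean.  Compartment boundaries sit
    at radius/3 and 2*radius/3."""
    img = circular_image[..., 0] if circular_image.ndim == 3 else circular_image
    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dist = np.hypot(rows - cy, cols - cx)
    disc = dist <= radius
    inner = disc & (dist < radius / 3.0)
    middle = disc & (dist >= radius / 3.0) & (dist < 2.0 * radius / 3.0)
    outer = disc & (dist >= 2.0 * radius / 3.0)
    def _mean(sel):
        return float(img[sel].mean()) if sel.any() else 0.0
    return _mean(inner), _mean(middle), _mean(outer), _mean(disc)


@dataclass
class SeparabilityResult:
    f_statistic: float
    anova_p: float
    mean_tukey_p: float
    mean_effect_size: float
    pairwise: list[dict]


def separability(features: np.ndarray, labels) -> SeparabilityResult:
    """One-way ANOVA F/p plus pairwise Tukey HSD p-values and standardized
    mean differences (pooled sd), averaged over group pairs."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    groups = [features[labels == g] for g in np.unique(labels)]
    names = list(np.unique(labels))
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 observations each")
    if all(g.std() < 1e-15 for g in groups):
        raise InvalidInputError("zero within-group variance everywhere; F undefined")
    f_stat, p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(features, labels)
    tukey_p = np.asarray(tk.pvalues, float)
    pairwise = []
    for (i, j), pval in zip(combinations(range(len(groups)), 2), tukey_p):
        a, b = groups[i], groups[j]
        pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2))
        effect = abs(a.mean() - b.mean()) / max(pooled, 1e-15)
        pairwise.append({"groups": (str(names[i]), str(names[j])), "tukey_p": float(pval), "effect_size": float(effect)})
    return SeparabilityResult(
        f_statistic=float(f_stat),
        anova_p=float(p),
        mean_tukey_p=float(np.mean([d["tukey_p"] for d in pairwise])),
        mean_effect_size=float(np.mean([d["effect_size"] for d in pairwise])),
        pairwise=pairwise,
    )
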