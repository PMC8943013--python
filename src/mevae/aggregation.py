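"""Feature aggregation, explanatory-feature scoring, and cross-modality
correlation.

Latent dimensions are hierarchically clustered (on their standardized
per-cell profiles) into a small number of aggregated features; cells get a
score per aggregate (mean of the member features).  Aggregated features per
condition can then be correlated against pathway activity scores computed
from a protein-abundance table with signed, weighted pathway memberships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .exceptions import InvalidInputError
from .models import EmbeddingMatrix


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Column-wise zero mean, unit (population) sd; constant columns -> 0."""
    X = np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples to standardize")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd < 1e-12
    if const.any():
        warnings.warn("constant column(s) standardized to zeros", RuntimeWarning)
    out = np.where(const[None, :], 0.0, (X - mu[None, :]) / np.where(const, 1.0, sd)[None, :])
    return out


def feature_self_correlation(embedding: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Spearman correlation matrix between latent features (dims x dims)."""
    X = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    if X.shape[0] < 3:
        raise InvalidInputError("need at least 3 cells")
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    sd = ranks.std(axis=0)
    const = sd < 1e-12
    centered = (ranks - ranks.mean(axis=0)) / np.where(const, 1.0, sd)
    corr = centered.T @ centered / X.shape[0]
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


@dataclass
class AggregatedFeatures:
    """Latent-dim -> cluster assignment plus per-cell aggregated scores."""

    assignments: np.ndarray  # cluster id (0-based) per latent dim
    scores: np.ndarray  # cells x clusters; mean of member standardized features
    linkage_matrix: np.ndarray
    n_clusters: int


def aggregate_features(embedding: EmbeddingMatrix | np.ndarray, n_clusters: int,
                       method: str = "average") -> AggregatedFeatures:
    """Hierarchically cluster latent dimensions (Euclidean distance on the
    standardized features, average linkage by default) and average members."""
    X = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    d = X.shape[1]
    if n_clusters > d:
        raise InvalidInputError("n_clusters exceeds number of latent dims")
    Z = standardize(X)
    link = linkage(Z.T, method=method, metric="euclidean")
    labels = fcluster(link, t=n_clusters, criterion="maxclust") - 1
    scores = np.stack([Z[:, labels == c].mean(axis=1) for c in range(labels.max() + 1)], axis=1)
    return AggregatedFeatures(assignments=labels, scores=scores, linkage_matrix=link, n_clusters=int(labels.max() + 1))


def feature_score(embedding: EmbeddingMatrix | np.ndarray, cluster_labels) -> np.ndarray:
    """Explanatory-feature score per latent dimension.

    score = Var_all - (sum over cell clusters of Var_within) / n_clusters,
    with population variances.  High scores mark features whose variance is
    between clusters rather than within them; used to rank and select the
    top-k explanatory features.
    """
    X = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    labels = np.asarray(cluster_labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        return np.zeros(X.shape[1])
    var_all = X.var(axis=0)
    within = np.zeros_like(var_all)
    for c in clusters:
        members = X[labels == c]
        if members.shape[0] == 1:
            warnings.warn("cluster of size 1; its variance taken as 0", RuntimeWarning)
            continue
        within += members.var(axis=0)
    return var_all - within / clusters.size


def representative_cells(embedding: EmbeddingMatrix, aggregated: AggregatedFeatures,
                         cluster_id: int, k: int) -> list[str]:
    """Top-k cell ids by the cluster's aggregated score, descending;
    deterministic tie-break by lexicographic cell id."""
    if cluster_id < 0 or cluster_id >= aggregated.scores.shape[1]:
        raise InvalidInputError(f"cluster {cluster_id} does not exist")
    scores = aggregated.scores[:, cluster_id]
    ids = np.asarray(embedding.cell_ids)
    if k > ids.size:
        warnings.warn("k exceeds number of cells; returning all", RuntimeWarning)
        k = ids.size
    order = np.lexsort((ids, -scores))
    return [str(i) for i in ids[order[:k]]]


@dataclass(frozen=True)
class PathwayDefinition:
    """Signed, weighted pathway membership: (protein, sign in {+1,-1}, weight)."""

    name: str
    members: list

    def __post_init__(self):
        if not self.members:
            raise InvalidInputError(f"pathway {self.name!r} has no members")


def pathway_scores(protein_table: pd.DataFrame, definitions: list[PathwayDefinition]) -> pd.DataFrame:
    """Pathway activity per condition from a conditions x proteins table.

    Relative protein level = (x - column median) / column sd; the pathway
    score sums sign * weight * relative level over members (positive
    regulators add, negative regulators subtract).  Zero-sd proteins
    contribute 0 with a warning; a missing protein is an error naming it.
    """
    med = protein_table.median(axis=0)
    sd = protein_table.std(axis=0, ddof=0)
    out = {}
    for pw in definitions:
        total = np.zeros(len(protein_table.index))
        for member in pw.members:
            protein, sign, weight = (member + (1.0,))[:3] if len(member) == 2 else member
            if protein not in protein_table.columns:
                raise InvalidInputError(f"protein {protein!r} (pathway {pw.name!r}) missing from table")
            if sd[protein] < 1e-15:
                warnings.warn(f"protein {protein!r} has zero sd; contributes 0", RuntimeWarning)
                continue
            rel = (protein_table[protein].to_numpy() - med[protein]) / sd[protein]
            total = total + sign * weight * rel
        out[pw.name] = total
    return pd.DataFrame(out, index=protein_table.index)


def condition_mean_scores(aggregated: AggregatedFeatures, labels, feature_names=None) -> pd.DataFrame:
    """Cell-to-condition reduction: mean aggregated score per condition."""
    labels = np.asarray(labels)
    conds = list(np.unique(labels))
    rows = [aggregated.scores[labels == c].mean(axis=0) for c in conds]
    names = feature_names or [f"agg_{i}" for i in range(aggregated.scores.shape[1])]
    return pd.DataFrame(rows, index=conds, columns=names)


def cross_modal_correlation(agg_scores: pd.DataFrame, pathway_table: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between per-condition aggregated features and
    pathway activity scores (features x pathways).

    With few conditions (n <= 6) the result is flagged descriptive via
    ``result.attrs['descriptive_only']`` — too small for significance.
    """
    if list(agg_scores.index) != list(pathway_table.index):
        raise InvalidInputError("condition sets/order differ between modalities")
    feats = agg_scores.columns
    paths = pathway_table.columns
    mat = np.zeros((len(feats), len(paths)))
    for i, f in enumerate(feats):
        for j, p in enumerate(paths):
            rho = stats.spearmanr(agg_scores[f], pathway_table[p]).statistic
            mat[i, j] = 0.0 if np.isnan(rho) else rho
    out = pd.DataFrame(mat, index=feats, columns=paths)
    out.attrs["descriptive_only"] = bool(len(agg_scores.index) <= 6)
    return out
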