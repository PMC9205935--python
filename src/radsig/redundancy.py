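"""Redundancy reduction: Spearman clustering + mutual-information representatives.

Stable features are clustered hierarchically with average linkage on the
distance ``1 - |rho|`` (Spearman); the tree is cut so that features with
|rho| >= 0.8 share a cluster. Within each cluster the feature with the
highest mutual information with the endpoint (equal-frequency 4-bin
discretisation of the feature; the event indicator for survival
endpoints) represents the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .outcomes import OutcomeData

logger = logging.getLogger(__name__)


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho with mid-rank ties; constant columns dropped."""
    if len(table) < 3:
        raise ValueError("Spearman matrix needs at least 3 subjects")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        logger.warning("excluding %d constant columns from clustering",
                       len(constant))
        table = table.drop(columns=constant)
    ranks = np.apply_along_axis(rankdata, 0, table.to_numpy())
    corr = np.atleast_2d(np.corrcoef(ranks, rowvar=False))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=table.columns, columns=table.columns)


@dataclass
class ClusterAssignment:
    clusters: dict[str, int]                 # feature -> cluster id
    representatives: dict[int, str] = field(default_factory=dict)
    linkage: np.ndarray | None = None

    def members(self, cid: int) -> list[str]:
        return [f for f, c in self.clusters.items() if c == cid]

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))


def cluster_features(corr: pd.DataFrame, threshold: float = 0.8
                     ) -> ClusterAssignment:
    """Average-linkage agglomeration on 1 - |rho|, cut at 1 - threshold."""
    names = list(corr.columns)
    if len(names) == 1:
        return ClusterAssignment({names[0]: 1})
    dist = 1.0 - np.abs(corr.to_numpy())
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=1.0 - threshold, criterion="distance")
    return ClusterAssignment(dict(zip(names, (int(l) for l in labels))),
                             linkage=link)


def mutual_information(values: np.ndarray, outcomes: OutcomeData,
                       endpoint_kind: str, n_feature_bins: int = 4) -> float:
    """MI (nats) between a discretised feature and the endpoint.

    The feature is split at equal-frequency quantiles into
    ``n_feature_bins`` bins; the endpoint is the binary label, or the
    event indicator for survival data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("mutual information needs at least 10 subjects")
    if endpoint_kind == "survival" or (outcomes.labels is None):
        y = outcomes.events
    else:
        y = outcomes.labels
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        logger.warning("single-class endpoint: MI set to 0")
        return 0.0
    return _mi_binned(x, y, n_feature_bins)


def _mi_binned(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    xb = np.searchsorted(edges, x, side="right")
    joint = pd.crosstab(xb, y).to_numpy().astype(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def mi_scores(table: pd.DataFrame, outcomes: OutcomeData, endpoint_kind: str,
              n_feature_bins: int = 4) -> pd.Series:
    return pd.Series(
        {c: mutual_information(table[c].to_numpy(), outcomes, endpoint_kind,
                               n_feature_bins)
         for c in table.columns}, name="mi")


def select_representatives(assignment: ClusterAssignment, scores: pd.Series,
                           table: pd.DataFrame) -> pd.DataFrame:
    """Reduced table: per cluster the max-MI feature (lexicographic ties)."""
    reps: dict[int, str] = {}
    for cid in sorted(set(assignment.clusters.values())):
        members = sorted(assignment.members(cid))
        best = max(members, key=lambda f: (scores[f], ))
        tied = [m for m in members if scores[m] == scores[best]]
        if len(tied) > 1:
            best = sorted(tied)[0]
            logger.info("MI tie in cluster %d broken lexicographically: %s",
                        cid, best)
        reps[cid] = best
    assignment.representatives = reps
    kept = sorted(reps.values(), key=list(table.columns).index)
    return table[kept]


def reduce_redundancy(table: pd.DataFrame, outcomes: OutcomeData,
                      endpoint_kind: str, threshold: float = 0.8
                      ) -> tuple[pd.DataFrame, ClusterAssignment, pd.Series]:
    """Full stage: correlation, clustering, representative selection."""
    corr = spearman_matrix(table)
    assignment = cluster_features(corr, threshold)
    scores = mi_scores(table[list(corr.columns)], outcomes, endpoint_kind)
    reduced = select_representatives(assignment, scores, table[list(corr.columns)])
    return reduced, assignment, scores
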