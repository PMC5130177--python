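"""Response-profile clustering and AMPK-dependence classification.

Significant features are standardized per feature (z-score across samples of
the variance-stabilized matrix), hierarchically clustered (complete linkage,
Euclidean distance by default) and the tree is cut into K groups.  Each
cluster's mean condition profile (mu_NT, mu_MET, mu_METCC) is then assigned
one of four response categories using the reversion ratio

    rho = (mu_MET - mu_METCC) / (mu_MET - mu_NT)

A treated-vs-untreated shift of at least ``delta`` standardized units sets
the direction (up/down); the response is AMPK-dependent when the inhibitor
reverts at least ``rho_threshold`` of the shift, AMPK-independent otherwise.
rho is invariant to shifting all three means by a constant and to scaling
them by a positive factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator

from .simulate import CONDITIONS, SampleDesign

RESPONSE_LABELS = (
    "MET_UP_AMPK_DEP",
    "MET_UP_AMPK_INDEP",
    "MET_DOWN_AMPK_DEP",
    "MET_DOWN_AMPK_INDEP",
    "AMBIGUOUS",
)


@dataclass
class ResponseProfiles:
    """Standardized per-feature profiles plus condition means on that scale."""

    z: pd.DataFrame                 # features x samples, mean 0 / sd 1 rows
    condition_means: pd.DataFrame   # features x (mu_NT, mu_MET, mu_METCC)
    zero_variance: pd.Index         # flagged, excluded from clustering


@dataclass
class ClusterModel:
    n_clusters: int
    linkage_method: str
    metric: str
    assignments: pd.Series            # feature_id -> cluster in 1..K
    cluster_mean_profiles: pd.DataFrame  # cluster -> (mu_NT, mu_MET, mu_METCC)


def standardize_profiles(
    matrix: pd.DataFrame,
    design: SampleDesign,
    features: pd.Index | list,
    ddof: int = 1,
) -> ResponseProfiles:
    """Z-score each selected feature across samples; average per condition.

    Zero-variance features are flagged and their rows set to all zeros.
    """
    features = pd.Index(features)
    if len(features) == 0:
        raise ValueError("significant feature set is empty")
    missing = features.difference(matrix.index)
    if len(missing):
        raise ValueError(f"features absent from matrix: {list(missing)[:5]}")
    sub = matrix.loc[features]
    arr = sub.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat] = 0.0
    z_df = pd.DataFrame(z, index=features, columns=sub.columns)

    cond = design.table.reindex(sub.columns)["condition"]
    means = {
        f"mu_{c}": z_df.loc[:, (cond == c).to_numpy()].mean(axis=1) for c in CONDITIONS
    }
    cond_means = pd.DataFrame(means)
    return ResponseProfiles(
        z=z_df, condition_means=cond_means, zero_variance=features[flat]
    )


def cluster_profiles(
    profiles: ResponseProfiles,
    n_clusters: int,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClusterModel:
    """Agglomerative clustering of standardized profiles, tree cut at K."""
    usable = profiles.z.index.difference(profiles.zero_variance)
    z = profiles.z.loc[usable]
    if n_clusters < 1 or n_clusters > len(z):
        raise ValueError(f"n_clusters={n_clusters} outside [1, {len(z)}]")
    if len(z) == n_clusters:
        labels = np.arange(1, len(z) + 1)
    else:
        tree = linkage(z.to_numpy(), method=method, metric=metric)
        labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    assignments = pd.Series(labels, index=z.index, name="cluster")
    means = profiles.condition_means.loc[usable].groupby(assignments).mean()
    return ClusterModel(
        n_clusters=n_clusters,
        linkage_method=method,
        metric=metric,
        assignments=assignments,
        cluster_mean_profiles=means,
    )


def classify_ampk_dependence(
    mu_nt: float,
    mu_met: float,
    mu_metcc: float,
    delta: float = 0.5,
    rho_threshold: float = 0.5,
) -> str:
    """Four-way response label from a (mu_NT, mu_MET, mu_METCC) profile.

    AMBIGUOUS when the treated-vs-untreated shift is below ``delta``.
    """
    vals = np.array([mu_nt, mu_met, mu_metcc], dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("profile means must be finite")
    if delta <= 0 or not (0 < rho_threshold < 1):
        raise ValueError("require delta > 0 and rho_threshold in (0, 1)")
    shift = mu_met - mu_nt
    if abs(shift) < delta:
        return "AMBIGUOUS"
    rho = (mu_met - mu_metcc) / shift
    direction = "UP" if shift > 0 else "DOWN"
    dependence = "DEP" if rho >= rho_threshold else "INDEP"
    return f"MET_{direction}_AMPK_{dependence}"


def classify_clusters(
    model: ClusterModel, delta: float = 0.5, rho_threshold: float = 0.5
) -> tuple[pd.Series, pd.Series]:
    """Label each cluster, and each feature via its cluster."""
    cluster_labels = pd.Series(
        {
            k: classify_ampk_dependence(
                row["mu_NT"], row["mu_MET"], row["mu_METCC"],
                delta=delta, rho_threshold=rho_threshold,
            )
            for k, row in model.cluster_mean_profiles.iterrows()
        },
        name="response_label",
    )
    feature_labels = model.assignments.map(cluster_labels)
    feature_labels.name = "response_label"
    return cluster_labels, feature_labels


class ResponseClusterer(BaseEstimator):
    """Standardize, cluster and classify significant response profiles.

    Parameters mirror the documented defaults: 10 clusters for gene profiles
    (4 is the peak-profile convention), complete linkage on Euclidean
    distance, delta = 0.5 standardized units and a 0.5 reversion-ratio
    threshold.  ``fit(X, design)`` expects the variance-stabilized matrix
    restricted (via ``features``) to the significant set.
    """

    def __init__(
        self,
        n_clusters: int = 10,
        linkage_method: str = "complete",
        metric: str = "euclidean",
        delta: float = 0.5,
        rho_threshold: float = 0.5,
    ):
        self.n_clusters = n_clusters
        self.linkage_method = linkage_method
        self.metric = metric
        self.delta = delta
        self.rho_threshold = rho_threshold

    def fit(self, X: pd.DataFrame, design: SampleDesign, features=None):
        if features is None:
            features = X.index
        self.profiles_ = standardize_profiles(X, design, features)
        self.model_ = cluster_profiles(
            self.profiles_, self.n_clusters,
            method=self.linkage_method, metric=self.metric,
        )
        self.cluster_labels_, self.feature_labels_ = classify_clusters(
            self.model_, delta=self.delta, rho_threshold=self.rho_threshold
        )
        self.labels_ = self.model_.assignments
        return self

    def summary(self) -> pd.DataFrame:
        """Cluster size, mean profile and response label, one row per cluster."""
        out = self.model_.cluster_mean_profiles.copy()
        out.insert(0, "size", self.model_.assignments.value_counts().sort_index())
        out["response_label"] = self.cluster_labels_
        out.index.name = "cluster"
        return out
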