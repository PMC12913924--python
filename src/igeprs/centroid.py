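"""Nearest-centroid assignment of new asthma cases to established clusters.

Centroids are per-cluster means in the standardized four-feature space
(IgE PRS z, log IgE, onset age, pFEV1); the standardization parameters are
carried over from the clustering build so new cases are scaled exactly as
the training cases were. Every complete case receives a label (no distance
threshold); ties go to the lowest cluster index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import TwoStepClusterResults


@dataclass
class CentroidModel:
    feature_names: list
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    centroids: pd.DataFrame  # index: cluster 1..k, standardized space

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_names": list(self.feature_names),
                    "standardize_mean": np.asarray(self.standardize_mean).tolist(),
                    "standardize_sd": np.asarray(self.standardize_sd).tolist(),
                    "clusters": self.centroids.index.tolist(),
                    "centroids": self.centroids.to_numpy().tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CentroidModel":
        with open(path) as fh:
            d = json.load(fh)
        cent = pd.DataFrame(d["centroids"], index=d["clusters"], columns=d["feature_names"])
        cent.index.name = "cluster"
        return cls(
            feature_names=d["feature_names"],
            standardize_mean=np.asarray(d["standardize_mean"]),
            standardize_sd=np.asarray(d["standardize_sd"]),
            centroids=cent,
        )


def fit_centroids(features: pd.DataFrame, labels,
                  standardize_mean=None, standardize_sd=None) -> CentroidModel:
    """Per-cluster means of standardized features.

    When standardization parameters are not supplied they are computed from
    ``features`` (complete cases); supply the clustering build's parameters
    to keep the spaces identical.
    """
    df = features.dropna()
    if isinstance(labels, pd.Series) and not labels.index.equals(df.index):
        lab = np.asarray(labels.loc[df.index])
    else:
        lab = np.asarray(labels)
    if len(lab) != len(df):
        raise ValueError("labels length does not match complete-case rows")
    X = df.to_numpy(dtype=float)
    mu = np.asarray(standardize_mean) if standardize_mean is not None else X.mean(axis=0)
    sd = np.asarray(standardize_sd) if standardize_sd is not None else X.std(axis=0, ddof=1)
    Xs = (X - mu) / sd
    clusters = np.unique(lab)
    rows = []
    for c in clusters:
        mask = lab == c
        if not mask.any():
            raise ValueError(f"cluster {c} is empty")
        rows.append(Xs[mask].mean(axis=0))
    cent = pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"), columns=df.columns)
    return CentroidModel(
        feature_names=list(df.columns), standardize_mean=mu, standardize_sd=sd, centroids=cent
    )


def from_clustering(features: pd.DataFrame, results: TwoStepClusterResults) -> CentroidModel:
    """Centroid model reusing the clustering build's standardization."""
    return fit_centroids(
        features.loc[results.labels.index],
        results.labels,
        standardize_mean=results.standardize_mean,
        standardize_sd=results.standardize_sd,
    )


def assign_nearest(model: CentroidModel, features: pd.DataFrame) -> pd.DataFrame:
    """Assign each complete case to the Euclidean-nearest centroid.

    Returns a DataFrame with the assigned cluster (NaN for rows with missing
    features, reported unassigned) and the distance to every centroid.
    """
    if model.centroids.empty:
        raise ValueError("centroid model has no clusters")
    feats = features[model.feature_names]
    X = feats.to_numpy(dtype=float)
    Xs = (X - model.standardize_mean) / model.standardize_sd
    C = model.centroids.to_numpy()
    d = np.sqrt(((Xs[:, None, :] - C[None, :, :]) ** 2).sum(axis=-1))
    complete = ~np.isnan(Xs).any(axis=1)
    # ties -> lowest cluster index (argmin takes the first minimum)
    idx = np.argmin(d, axis=1)
    clusters = np.asarray(model.centroids.index)
    out = pd.DataFrame(index=feats.index)
    out["cluster"] = np.where(complete, clusters[idx], np.nan)
    for ci, c in enumerate(clusters):
        out[f"dist_{c}"] = d[:, ci]
    return out
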