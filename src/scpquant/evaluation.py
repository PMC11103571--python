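"""Cluster-separation diagnostics: PCA embedding and grouping accuracy."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from scpquant.matrix import QuantMatrix


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame          # samples x components
    explained_variance_ratio: np.ndarray
    labels: pd.Series | None = None


def pca_embed(
    matrix_complete: QuantMatrix,
    n_components: int = 2,
    labels: pd.Series | None = None,
    scale_features: bool = False,
) -> EmbeddingResult:
    """PCA of samples (observations) x proteins (features), center-only by default."""
    if matrix_complete.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = matrix_complete.data.to_numpy().T  # samples x proteins
    if np.isnan(X).any():
        raise ValueError("pca_embed requires a complete matrix")
    if scale_features:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_components = min(n_components, matrix_complete.n_samples - 1, matrix_complete.n_proteins)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    coord_df = pd.DataFrame(
        coords,
        index=matrix_complete.samples,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    if labels is None and matrix_complete.sample_meta is not None:
        labels = matrix_complete.sample_meta["cell_type"]
    if labels is not None:
        labels = labels.reindex(coord_df.index)
    return EmbeddingResult(coord_df, pca.explained_variance_ratio_, labels)


def cluster_accuracy(
    embedding: EmbeddingResult,
    true_labels: pd.Series | None = None,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> float:
    """k-means grouping accuracy against true labels, maximized over label matchings.

    Always at least the majority-class fraction: the best matching can map
    every cluster to the majority label.
    """
    if true_labels is None:
        true_labels = embedding.labels
    if true_labels is None:
        raise ValueError("true labels are required")
    true_labels = true_labels.reindex(embedding.coordinates.index)
    n = len(embedding.coordinates)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k == 1:
        counts = true_labels.value_counts()
        return float(counts.iloc[0] / n)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    pred = km.fit_predict(embedding.coordinates.to_numpy())
    classes = sorted(set(true_labels))
    best = 0.0
    # max over assignments of clusters to classes (clusters may share a class)
    for assign in product(classes, repeat=k):
        acc = float(np.mean([assign[pred[i]] == true_labels.iloc[i] for i in range(n)]))
        if acc > best:
            best = acc
    return best
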