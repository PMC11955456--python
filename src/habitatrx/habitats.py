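"""Habitat clustering: K-means on standardised voxel features, K by CH.

Voxel feature vectors pooled over the *training* lesions are standardised
and clustered with K-means; the number of clusters is chosen by maximising
the Calinski-Harabasz (CH) index over a candidate range.  The fitted model
is then applied to every lesion (training and held-out alike), so habitat
identities are consistent across the cohort.  Cluster indices are relabelled
by ascending centroid raw-ADC, making habitat 1 the lowest-ADC (highest
cellularity proxy) subregion for every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .voxelfeat import VoxelFeatureMatrix


@dataclass
class Standardizer:
    """Per-column mean/sd with zero-variance columns pinned to 0."""

    mean: np.ndarray
    sd: np.ndarray
    constant_columns: np.ndarray  # boolean flags

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        sd = np.where(self.constant_columns, 1.0, self.sd)
        out = (matrix - self.mean) / sd
        out[:, self.constant_columns] = 0.0
        return out

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        sd = np.where(self.constant_columns, 1.0, self.sd)
        return matrix * sd + self.mean


def standardize(matrix: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Column-wise z-scoring; constant columns become 0 and are flagged."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[0] < 2:
        raise ValueError("standardisation needs at least 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    constant = sd < 1e-12
    params = Standardizer(mean=mean, sd=sd, constant_columns=constant)
    return params.transform(matrix), params


def kmeans_fit(
    matrix: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd K-means with k-means++ restarts; returns (labels, centroids, inertia)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if k < 2:
        raise ValueError("k must be >= 2")
    if matrix.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {matrix.shape[0]}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=300,
        tol=1e-6, random_state=seed,
    ).fit(matrix)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def calinski_harabasz(matrix: np.ndarray, labels: np.ndarray) -> float:
    """CH index: [B/(K-1)] / [W/(N-K)] with B, W the between/within dispersions.

    Returns +inf when every cluster is internally constant (W = 0).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = matrix.shape[0], len(uniq)
    if not (2 <= k <= n - 1):
        raise ValueError(f"need 2 <= K <= N-1, got K={k}, N={n}")
    centre = matrix.mean(axis=0)
    between = 0.0
    within = 0.0
    for u in uniq:
        grp = matrix[labels == u]
        c = grp.mean(axis=0)
        between += len(grp) * float(np.sum((c - centre) ** 2))
        within += float(np.sum((grp - c) ** 2))
    if within <= 0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


@dataclass
class HabitatModel:
    """Fitted habitat clustering: scaler, centroids, chosen K and CH curve."""

    standardizer: Standardizer
    centroids: np.ndarray  # (K, n_features) in standardised space
    k: int
    ch_curve: dict[int, float]
    seed: int
    feature_names: list[str] = field(default_factory=list)
    # permutation mapping raw cluster index -> habitat label 1..K (asc. ADC)
    relabel: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def select_k(
    matrix: np.ndarray,
    k_range: range | tuple[int, int] = (2, 9),
    seed: int = 0,
    n_init: int = 10,
    subsample_cap: int = 100_000,
    feature_names: list[str] | None = None,
) -> HabitatModel:
    """Standardise pooled training voxels, scan K and keep the CH argmax.

    ``matrix`` must pool training-set lesions only (fitting on held-out
    voxels would leak).  A seeded uniform subsample caps the clustering
    problem size; ties in CH go to the smaller K.
    """
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    if len(k_range) == 0:
        raise ValueError("empty candidate K range")
    matrix = np.asarray(matrix, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if matrix.shape[0] > subsample_cap:
        idx = rng.choice(matrix.shape[0], subsample_cap, replace=False)
        matrix = matrix[idx]
    std_matrix, params = standardize(matrix)

    curve: dict[int, float] = {}
    best = None
    for k in k_range:
        if std_matrix.shape[0] <= k:
            break
        labels, centroids, _ = kmeans_fit(std_matrix, k, seed=seed, n_init=n_init)
        ch = calinski_harabasz(std_matrix, labels)
        curve[k] = ch
        if best is None or ch > curve[best]:  # strict: ties keep smaller K
            best = k
    if best is None:
        raise ValueError("no candidate K could be evaluated")
    _, centroids, _ = kmeans_fit(std_matrix, best, seed=seed, n_init=n_init)
    model = HabitatModel(
        standardizer=params, centroids=centroids, k=best, ch_curve=curve,
        seed=seed, feature_names=list(feature_names or []),
    )
    model.relabel = _adc_relabel(model)
    return model


def fit_habitat_model(
    features: VoxelFeatureMatrix,
    k_range: tuple[int, int] = (2, 9),
    seed: int = 0,
    n_init: int = 10,
    subsample_cap: int = 100_000,
) -> HabitatModel:
    """Convenience wrapper: select_k on a pooled voxel feature matrix."""
    return select_k(
        features.matrix, k_range, seed=seed, n_init=n_init,
        subsample_cap=subsample_cap, feature_names=features.names,
    )


def _adc_relabel(model: HabitatModel) -> np.ndarray:
    """Permutation sending raw cluster indices to labels 1..K by ascending ADC.

    The raw-ADC coordinate is recovered by inverse-standardising the
    centroids; without feature names the last column is assumed to be the
    raw ADC intensity (the fixed voxel-feature order).
    """
    raw = model.standardizer.inverse_transform(model.centroids)
    if model.feature_names and "adc_intensity" in model.feature_names:
        col = model.feature_names.index("adc_intensity")
    else:
        col = raw.shape[1] - 1
    order = np.argsort(raw[:, col], kind="stable")
    relabel = np.empty(model.k, dtype=int)
    relabel[order] = np.arange(1, model.k + 1)
    return relabel


@dataclass
class HabitatMap:
    """Integer habitat label volume (0 = background) plus proportions."""

    labels: np.ndarray
    proportions: np.ndarray  # length K, sums to 1
    patient_id: str


def assign_habitats(features: VoxelFeatureMatrix, model: HabitatModel,
                    volume_shape: tuple[int, int, int]) -> HabitatMap:
    """Assign each lesion voxel to its nearest centroid, ADC-ordered labels."""
    if model.feature_names and features.names != model.feature_names:
        raise ValueError("feature name schema differs from the fitted model")
    z = model.standardizer.transform(features.matrix)
    d2 = ((z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    raw = np.argmin(d2, axis=1)
    labels_flat = model.relabel[raw]
    vol = np.zeros(volume_shape, dtype=np.int16)
    vol[features.coords[:, 0], features.coords[:, 1], features.coords[:, 2]] = labels_flat
    props = np.array([(labels_flat == h).mean() for h in range(1, model.k + 1)])
    return HabitatMap(labels=vol, proportions=props,
                      patient_id=str(features.patient_ids[0]))
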