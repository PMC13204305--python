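"""Patch featurization and morphological clustering.

Patches (z-scored RGB tensors) are mapped to fixed-length feature vectors
by a pluggable extractor, reduced to 32 dimensions by PCA, and grouped by
K-means. The number of clusters is screened over a range with inertia and
silhouette diagnostics; the downstream default fixes k = 6. Cluster labels
are mapped back onto the slide grid for inspection and composition
summaries.

The default extractor is deterministic and CPU-only: per-channel 16-bin
histograms, 4-orientation gradient energy, and per-channel intensity and
local-variance statistics (64 dims). A CNN embedding (e.g. ResNet-50
average-pool, 2048 dims) can be registered under the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score


def _default_features(patch: np.ndarray) -> np.ndarray:
    """64-dim handcrafted descriptor of a z-scored RGB patch."""
    feats = []
    for c in range(3):
        hist, _ = np.histogram(patch[:, :, c], bins=16, range=(-4.0, 4.0))
        feats.append(hist / patch[:, :, c].size)
    gray = patch.mean(axis=2)
    feats.append(
        np.array(
            [
                np.abs(np.diff(gray, axis=1)).mean(),
                np.abs(np.diff(gray, axis=0)).mean(),
                np.abs(gray[1:, 1:] - gray[:-1, :-1]).mean(),
                np.abs(gray[1:, :-1] - gray[:-1, 1:]).mean(),
            ]
        )
    )
    stats = []
    for c in range(3):
        ch = patch[:, :, c]
        local_var = uniform_filter(ch**2, size=3) - uniform_filter(ch, size=3) ** 2
        stats.extend([ch.mean(), ch.std(), local_var.mean(), local_var.std()])
    feats.append(np.array(stats))
    return np.concatenate(feats)


EXTRACTORS = {"default": (_default_features, 64)}


def register_extractor(name: str, fn, dim: int):
    """Register a patch -> vector feature backend (e.g. a CNN embedding)."""
    EXTRACTORS[name] = (fn, dim)


def extract_features(patches, extractor: str = "default") -> np.ndarray:
    """Featurize z-scored patches with the named backend. Deterministic."""
    if extractor not in EXTRACTORS:
        raise ValueError(
            f"unknown extractor {extractor!r}; available: {sorted(EXTRACTORS)}"
        )
    fn, dim = EXTRACTORS[extractor]
    out = np.stack([fn(np.asarray(p, float)) for p in patches])
    if out.shape[1] != dim:
        raise RuntimeError("extractor produced unexpected dimensionality")
    return out


def reduce_pca(features: np.ndarray, n_components: int = 32,
               seed: int | None = None):
    """Project features onto the top principal components.

    Returns ``(reduced matrix, fitted PCA)``; the PCA object supports
    out-of-sample projection of held-out patches.
    """
    n, d = features.shape
    if d < n_components:
        raise ValueError(f"feature dim {d} < n_components {n_components}")
    if n <= n_components:
        raise ValueError("need more patches than components")
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    reduced = pca.fit_transform(features)
    return reduced, pca


def select_k(
    reduced: np.ndarray,
    k_range=range(3, 11),
    seed: int | None = None,
    n_init: int = 10,
    silhouette_cap: int = 5000,
):
    """Screen cluster counts by inertia (elbow) and silhouette.

    Returns ``(k_best = argmax silhouette, diagnostics table)``. Weak
    structure (max silhouette < 0.3) triggers a warning. Silhouette is
    computed on a seeded subsample of at most ``silhouette_cap`` patches.
    """
    ks = list(k_range)
    n = reduced.shape[0]
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError("k_range outside [2, n_patches - 1]")
    rng = np.random.default_rng(seed)
    idx = (
        rng.choice(n, silhouette_cap, replace=False)
        if n > silhouette_cap
        else np.arange(n)
    )
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(reduced)
        sil = silhouette_score(reduced[idx], labels[idx])
        rows.append((k, km.inertia_, sil))
    table = pd.DataFrame(rows, columns=["k", "inertia", "silhouette"])
    k_best = int(table.loc[table["silhouette"].idxmax(), "k"])
    if table["silhouette"].max() < 0.3:
        warnings.warn("weak cluster structure: max silhouette < 0.3")
    return k_best, table


@dataclass
class ClusterModel:
    """Fitted K-means over PCA-reduced patch features."""

    kmeans: KMeans
    k: int
    assignments: np.ndarray
    inertia: float
    source_slides: tuple = ()  # provenance: slides used to fit centroids

    @property
    def centroids(self) -> np.ndarray:
        return self.kmeans.cluster_centers_

    def assign(self, reduced: np.ndarray) -> np.ndarray:
        return self.kmeans.predict(reduced)


def cluster_patches(
    reduced: np.ndarray,
    k: int = 6,
    seed: int | None = None,
    n_init: int = 10,
    source_slides: tuple = (),
) -> ClusterModel:
    """K-means (k-means++ init, n_init restarts, best inertia kept)."""
    if np.unique(reduced, axis=0).shape[0] < k:
        raise ValueError("fewer distinct patches than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(reduced)
    return ClusterModel(
        kmeans=km,
        k=k,
        assignments=labels,
        inertia=float(km.inertia_),
        source_slides=tuple(source_slides),
    )


def map_clusters_to_slide(
    manifest: pd.DataFrame, assignments, patch_size: int = 256
):
    """Map patch cluster ids back onto per-slide grids.

    ``manifest`` has columns (slide, x, y) aligned row-by-row with
    ``assignments``. Returns ``(grids dict slide -> 2D array with -1 for
    background, composition DataFrame slide x cluster summing to 1)``.
    """
    assignments = np.asarray(assignments)
    if len(manifest) != len(assignments):
        raise ValueError("manifest and assignments are misaligned")
    manifest = manifest.reset_index(drop=True)
    grids = {}
    comps = {}
    k = int(assignments.max()) + 1 if len(assignments) else 0
    for slide, sub in manifest.groupby("slide", sort=True):
        a = assignments[sub.index.to_numpy()]
        rows = sub["y"].to_numpy() // patch_size
        cols = sub["x"].to_numpy() // patch_size
        grid = np.full((rows.max() + 1, cols.max() + 1), -1, dtype=int)
        grid[rows, cols] = a
        grids[slide] = grid
        comps[slide] = np.bincount(a, minlength=k) / len(a)
    comp = pd.DataFrame.from_dict(comps, orient="index")
    comp.columns = [f"cluster_{c}" for c in comp.columns]
    comp.index.name = "slide"
    return grids, comp
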