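"""View construction: KNN affinity graphs and graph low-pass filtering.

The three heterogeneous inputs become the model's views here: expression is
smoothed with a self-loop renormalized graph filter, while spatial
coordinates and morphology features each yield a binary symmetric KNN
affinity graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .exceptions import ContractError, InputError, ParameterError

__all__ = [
    "AffinityGraph",
    "FilteredExpression",
    "knn_indices",
    "build_knn_affinity",
    "laplacian_filter",
    "propagation_operator",
    "FallbackExtractor",
    "extract_morphology",
]

_CHUNK = 1024  # row block size for pairwise-distance computation


@dataclass
class AffinityGraph:
    """Sparse binary symmetric KNN adjacency for one view."""

    adjacency: sp.csr_matrix
    k: int
    metric: str
    view: str

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class FilteredExpression:
    """Graph-filtered expression matrix plus filter provenance."""

    values: np.ndarray
    filter_order: int
    graph_view: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def knn_indices(
    features: np.ndarray, k: int, metric: str = "euclidean"
) -> np.ndarray:
    """Indices of the k nearest neighbours per row, self excluded.

    Distance ties are broken by lower row index (stable sort), so output is
    deterministic even with duplicated points.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not np.all(np.isfinite(X)):
        raise InputError("features contain non-finite values")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k >= n:
        raise ParameterError(f"k={k} must be < number of points ({n})")
    if metric not in ("euclidean", "cosine"):
        raise ParameterError(f"unsupported metric {metric!r}")
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        d = cdist(X[start:stop], X, metric=metric)
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(d, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def build_knn_affinity(
    features: np.ndarray, k: int, metric: str = "euclidean", view: str = "spatial"
) -> AffinityGraph:
    """Binary symmetric KNN graph, symmetrized by union.

    An edge (i, j) is present if i selects j among its k nearest neighbours
    or vice versa; the diagonal is zero.
    """
    nbrs = knn_indices(features, k, metric=metric)
    n = nbrs.shape[0]
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    directed = sp.csr_matrix(
        (np.ones(n * k), (rows, cols)), shape=(n, n)
    )
    sym = directed.maximum(directed.T)
    sym.data[:] = 1.0
    sym.setdiag(0)
    sym.eliminate_zeros()
    return AffinityGraph(adjacency=sym.tocsr(), k=k, metric=metric, view=view)


def propagation_operator(graph: AffinityGraph) -> sp.csr_matrix:
    """Self-loop renormalized propagation H = D̃^{-1/2} (A + I) D̃^{-1/2}."""
    A = graph.adjacency
    data = A.data
    if data.size and not np.all((data == 0) | (data == 1)):
        raise InputError("adjacency must be binary")
    n = A.shape[0]
    A_loop = (A + sp.identity(n, format="csr")).tocsr()
    deg = np.asarray(A_loop.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(inv_sqrt)
    return (D @ A_loop @ D).tocsr()


def laplacian_filter(
    Y: np.ndarray, graph: AffinityGraph, t: int = 2
) -> FilteredExpression:
    """Apply the low-pass filter H^t to a spots x features matrix.

    ``H`` is the self-loop renormalized propagation operator of the graph
    (equivalently ``I`` minus a normalized Laplacian); ``t = 0`` is the
    identity.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if t < 0:
        raise ParameterError(f"filter order t must be >= 0, got {t}")
    if graph.adjacency.shape[0] != Y.shape[0]:
        raise ContractError(
            f"graph has {graph.adjacency.shape[0]} spots, matrix has {Y.shape[0]} rows"
        )
    H = propagation_operator(graph)
    out = Y.copy()
    for _ in range(t):
        out = H @ out
    return FilteredExpression(values=out, filter_order=t, graph_view=graph.view)


# ---------------------------------------------------------------------------
# Morphology feature extraction
# ---------------------------------------------------------------------------

class FallbackExtractor:
    """Deterministic patch featurizer: seeded random projection.

    Patches are intensity-normalized (scaled to [0, 1] for integer images,
    mean-centred) and flattened, then projected through a fixed-seed
    Gaussian matrix.  Stands in for pretrained CNN backbones so no weights
    are ever downloaded; any callable mapping a (batch, p, p, c) patch stack
    to a (batch, d) feature stack can replace it.
    """

    def __init__(self, dim: int = 128, seed: int = 0):
        self.dim = int(dim)
        self.seed = int(seed)
        self._projection: np.ndarray | None = None

    def _get_projection(self, flat_size: int) -> np.ndarray:
        if self._projection is None or self._projection.shape[0] != flat_size:
            rng = np.random.default_rng(self.seed)
            self._projection = rng.standard_normal((flat_size, self.dim)) / np.sqrt(
                flat_size
            )
        return self._projection

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        flat = patches.reshape(patches.shape[0], -1).astype(float)
        if np.issubdtype(patches.dtype, np.integer):
            flat = flat / 255.0
        flat = flat - flat.mean(axis=1, keepdims=True)
        W = self._get_projection(flat.shape[1])
        return flat @ W


def extract_morphology(
    image: np.ndarray,
    coords: np.ndarray,
    patch_px: int = 64,
    extractor: Callable[[np.ndarray], np.ndarray] | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Crop a square patch around each spot and featurize it.

    ``coords`` are (x, y) in full-resolution units and are multiplied by
    ``scale`` to land on the raster; edge patches are zero-padded.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    if patch_px % 2 != 0 or patch_px <= 0:
        raise ParameterError(f"patch_px must be a positive even number, got {patch_px}")
    coords = np.asarray(coords, dtype=float) * scale
    h, w = image.shape[:2]
    cols = np.rint(coords[:, 0]).astype(int)
    rows = np.rint(coords[:, 1]).astype(int)
    if (cols < 0).any() or (cols >= w).any() or (rows < 0).any() or (rows >= h).any():
        raise InputError("scaled coordinates fall outside the image")
    if extractor is None:
        extractor = FallbackExtractor()
    half = patch_px // 2
    patches = np.zeros((len(coords), patch_px, patch_px, image.shape[2]),
                       dtype=image.dtype)
    for i, (r, c) in enumerate(zip(rows, cols)):
        r0, r1 = r - half, r + half
        c0, c1 = c - half, c + half
        sr0, sr1 = max(r0, 0), min(r1, h)
        sc0, sc1 = max(c0, 0), min(c1, w)
        patches[i, sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = image[
            sr0:sr1, sc0:sc1
        ]
    chunks = []
    width = None
    for start in range(0, len(coords), 256):
        batch = patches[start : start + 256]
        feats = np.asarray(extractor(batch), dtype=float)
        if feats.ndim != 2 or feats.shape[0] != batch.shape[0]:
            raise ContractError(
                f"extractor returned shape {feats.shape} for {batch.shape[0]} patches"
            )
        if width is None:
            width = feats.shape[1]
        elif feats.shape[1] != width:
            raise ContractError(
                f"extractor output dimension changed from {width} to {feats.shape[1]}"
            )
        chunks.append(feats)
    return np.vstack(chunks)
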