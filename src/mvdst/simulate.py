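"""Synthetic multiview SRT generator with retained ground truth.

A shared clustered latent structure drives both the transcript and the
morphology view: per-cluster latent centroids are drawn from a unit
Gaussian, per-spot latents add within-cluster jitter, and each view is the
latent matrix times an independent random loading.  Spots are laid out on a
jittered grid partitioned into compact rectangular patches so clusters are
spatially contiguous.  Perturbations (additive Gaussian noise on expression,
independent entry dropout, fixed-level morphology noise) and cluster
merging are applied on top, with the clean matrices and labels kept for
MSE/ARI benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError
from .io_preprocess import SRTDataset

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_multiview",
    "add_noise",
    "add_dropout",
    "merge_clusters",
]

_WITHIN_STD = 0.3   # within-cluster latent jitter
_JITTER = 0.3       # coordinate jitter (grid units)


@dataclass
class SimulationConfig:
    n_spots: int = 900
    n_genes: int = 500
    d_morph: int = 128
    n_clusters: int = 15
    latent_dim: int = 10
    noise_var: float = 0.0
    morph_noise_var: float = 0.1
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_spots:
            raise ParameterError("n_clusters cannot exceed n_spots")
        if self.noise_var < 0 or self.morph_noise_var < 0:
            raise ParameterError("noise variances must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must lie in [0, 1)")


@dataclass
class SimulationTruth:
    """Clean matrices, labels, and the generative pieces needed to re-derive them."""

    clean_expression: np.ndarray
    clean_morphology: np.ndarray
    labels: np.ndarray
    config: SimulationConfig
    centroids: np.ndarray
    loadings_expression: np.ndarray
    loadings_morphology: np.ndarray
    within_offsets: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _grid_coords(n: int) -> np.ndarray:
    """n points on a square-ish integer grid, row-major."""
    n_cols = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    return np.column_stack([idx % n_cols, idx // n_cols]).astype(float)


def _partition_grid(coords: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Assign grid points to clusters as compact contiguous patches.

    Recursive bisection: split the cluster-size list into two halves of
    roughly equal total, cut the point set along its wider axis at the exact
    matching count, recurse.  Exactly ``sizes[c]`` points get label c.
    """
    labels = np.empty(len(coords), dtype=int)

    def recurse(point_idx: np.ndarray, cluster_ids: np.ndarray) -> None:
        if len(cluster_ids) == 1:
            labels[point_idx] = cluster_ids[0]
            return
        totals = sizes[cluster_ids]
        cum = np.cumsum(totals)
        split = int(np.searchsorted(cum, cum[-1] / 2.0)) + 1
        split = min(split, len(cluster_ids) - 1)
        n_left = int(cum[split - 1])
        pts = coords[point_idx]
        axis = int(np.ptp(pts[:, 0]) < np.ptp(pts[:, 1]))
        order = np.argsort(pts[:, axis], kind="stable")
        recurse(point_idx[order[:n_left]], cluster_ids[:split])
        recurse(point_idx[order[n_left:]], cluster_ids[split:])

    recurse(np.arange(len(coords)), np.arange(len(sizes)))
    return labels


def add_noise(clean: np.ndarray, variance: float, seed: int) -> np.ndarray:
    """Add elementwise Gaussian noise with the given variance."""
    if variance < 0:
        raise ParameterError(f"variance must be >= 0, got {variance}")
    clean = np.asarray(clean, dtype=float)
    if variance == 0:
        return clean.copy()
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, np.sqrt(variance), size=clean.shape)


def add_dropout(mat: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Zero each entry independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ParameterError(f"dropout rate must lie in [0, 1), got {rate}")
    mat = np.asarray(mat, dtype=float)
    if rate == 0:
        return mat.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(mat.shape) >= rate
    return mat * keep


def simulate_multiview(
    config: SimulationConfig | None = None,
) -> tuple[SRTDataset, SimulationTruth]:
    """Generate one multiview dataset plus its ground truth.

    Cluster sizes are balanced to within one spot; the observed expression
    is clean + Gaussian(0, noise_var) followed by dropout, and observed
    morphology is clean + Gaussian(0, morph_noise_var).  Fully deterministic
    given ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_spots, config.n_clusters

    centroids = rng.standard_normal((k, config.latent_dim))
    # balanced sizes (within +/-1), laid out as compact grid patches
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    grid = _grid_coords(n)
    labels = _partition_grid(grid, sizes)
    within = _WITHIN_STD * rng.standard_normal((n, config.latent_dim))
    latents = centroids[labels] + within

    W_e = rng.standard_normal((config.latent_dim, config.n_genes)) / np.sqrt(
        config.latent_dim
    )
    W_m = rng.standard_normal((config.latent_dim, config.d_morph)) / np.sqrt(
        config.latent_dim
    )
    clean_expr = latents @ W_e
    clean_morph = latents @ W_m
    coords = grid + rng.uniform(-_JITTER, _JITTER, size=grid.shape)

    noise_seed, dropout_seed, morph_seed = rng.integers(0, 2**31 - 1, size=3)
    observed = add_noise(clean_expr, config.noise_var, int(noise_seed))
    observed = add_dropout(observed, config.dropout_rate, int(dropout_seed))
    observed_morph = add_noise(clean_morph, config.morph_noise_var, int(morph_seed))

    ds = SRTDataset(
        expression=observed,
        coords=coords,
        spot_ids=[f"spot_{i:05d}" for i in range(n)],
        gene_ids=[f"gene_{j:05d}" for j in range(config.n_genes)],
        morphology=observed_morph,
        truth_labels=labels,
        normalized=True,  # simulated values are final expression-scale
    )
    truth = SimulationTruth(
        clean_expression=clean_expr,
        clean_morphology=clean_morph,
        labels=labels,
        config=config,
        centroids=centroids,
        loadings_expression=W_e,
        loadings_morphology=W_m,
        within_offsets=within,
    )
    return ds, truth


def merge_clusters(
    truth: SimulationTruth, target_k: int, seed: int = 0
) -> SimulationTruth:
    """Randomly merge clusters down to ``target_k`` and regenerate clean data.

    Current cluster ids are randomly partitioned into ``target_k`` non-empty
    groups; each group shares the mean of its member centroids, and the
    clean matrices are recomputed from the merged latents (within-cluster
    offsets are preserved).
    """
    current = np.unique(truth.labels)
    k_now = len(current)
    if not 1 <= target_k <= k_now:
        raise ParameterError(
            f"target_k={target_k} must lie in [1, {k_now}]"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(k_now)
    # split the shuffled ids into target_k contiguous non-empty chunks
    group_sizes = np.full(target_k, k_now // target_k)
    group_sizes[: k_now % target_k] += 1
    mapping = np.empty(k_now, dtype=int)
    start = 0
    new_centroids = np.empty((target_k, truth.centroids.shape[1]))
    for g, size in enumerate(group_sizes):
        members = perm[start : start + size]
        mapping[members] = g
        new_centroids[g] = truth.centroids[current[members]].mean(axis=0)
        start += size

    old_index = {c: i for i, c in enumerate(current)}
    new_labels = np.array([mapping[old_index[c]] for c in truth.labels])
    latents = new_centroids[new_labels] + truth.within_offsets
    return replace(
        truth,
        clean_expression=latents @ truth.loadings_expression,
        clean_morphology=latents @ truth.loadings_morphology,
        labels=new_labels,
        centroids=new_centroids,
    )
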