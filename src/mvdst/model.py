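"""Dual-encoder denoising autoencoder with affinity-consistency training.

Two MLP encoders map the filtered expression matrix to latent features; the
second branch receives Gaussian perturbation as stochastic augmentation.
The fused latent matrix is decoded back to expression space, and training
minimizes a squared-Frobenius reconstruction term plus squared-Frobenius
penalties aligning the latent transcription affinity with the spatial and
morphology KNN graphs.  Optimization is full-batch Adam, implemented in
NumPy with hand-derived gradients so runs are exactly reproducible from the
seed and analytic gradients can be verified against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .exceptions import ContractError, ParameterError, StateError
from .multiview import AffinityGraph, FilteredExpression

__all__ = [
    "ModelConfig",
    "LatentFeatures",
    "TranscriptionAffinity",
    "TrainedModel",
    "encode",
    "reconstruction_loss",
    "transcription_affinity",
    "consistency_loss",
    "consistency_loss_grad",
    "train",
    "denoise",
]

_BLOCK = 2048  # row block for affinity terms; keeps memory O(block * n)


@dataclass
class ModelConfig:
    """Hyperparameters for one training run."""

    latent_dim: int = 64
    hidden_dims: tuple[int, ...] = (256,)
    alpha: float = 1.0
    beta: float = 1.0
    sigma_std: float = 1.0
    lr: float = 1e-3
    epochs: int = 500
    seed: int = 0
    filter_order: int = 2
    k_spatial: int = 6
    k_morph: int = 10

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be >= 0")
        if self.sigma_std < 0:
            raise ParameterError("sigma_std must be >= 0")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.lr <= 0:
            raise ParameterError("lr must be positive")


@dataclass
class LatentFeatures:
    """Per-branch and fused latent matrices; Z == (Z1 + Z2) / 2."""

    Z1: np.ndarray
    Z2: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        if self.Z1.shape != self.Z2.shape or self.Z.shape != self.Z1.shape:
            raise ContractError("Z1, Z2, Z must share a shape")
        if not (np.all(np.isfinite(self.Z1)) and np.all(np.isfinite(self.Z2))):
            raise ContractError("latent features contain non-finite values")


@dataclass
class TranscriptionAffinity:
    """Spot-by-spot similarity of the two latent branches."""

    A: np.ndarray


# ---------------------------------------------------------------------------
# Minimal MLP with explicit backprop
# ---------------------------------------------------------------------------

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(x))


class _MLP:
    """Fully connected net: ELU between layers, linear output."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 dtype=np.float64):
        self.dims = list(dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(
                (rng.standard_normal((fan_in, fan_out)) * scale).astype(dtype)
            )
            self.biases.append(np.zeros(fan_out, dtype=dtype))
        self._cache: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        h = X
        cached = []
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            pre = h @ W + b
            if cache:
                cached.append((h, pre))
            h = pre if i == last else _elu(pre)
        if cache:
            self._cache = cached
        return h

    def backward(self, d_out: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Gradients for the last cached forward pass.

        Returns (d_input, grads) with grads ordered like :attr:`params`.
        """
        if self._cache is None:
            raise StateError("backward called before a cached forward pass")
        dW_list = [None] * len(self.weights)
        db_list = [None] * len(self.biases)
        d = d_out
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            h_in, pre = self._cache[i]
            if i != last:
                d = d * _elu_grad(pre)
            dW_list[i] = h_in.T @ d
            db_list[i] = d.sum(axis=0)
            d = d @ self.weights[i].T
        return d, dW_list + db_list


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


@dataclass
class TrainedModel:
    """Encoder/decoder parameters plus the training trace."""

    encoder1: _MLP
    encoder2: _MLP
    decoder: _MLP
    config: ModelConfig
    loss_history: dict[str, np.ndarray] = field(default_factory=dict)
    trained: bool = False

    @property
    def input_dim(self) -> int:
        return self.encoder1.dims[0]

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for name, net in (("enc1", self.encoder1), ("enc2", self.encoder2),
                          ("dec", self.decoder)):
            for i, (W, b) in enumerate(zip(net.weights, net.biases)):
                arrays[f"{name}_W{i}"] = W
                arrays[f"{name}_b{i}"] = b
        for key, vals in self.loss_history.items():
            arrays[f"loss_{key}"] = np.asarray(vals)
        cfg = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.array(cfg), __trained__=np.array(self.trained),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        cfg_dict = json.loads(str(data["__config__"]))
        cfg_dict["hidden_dims"] = tuple(cfg_dict["hidden_dims"])
        config = ModelConfig(**cfg_dict)
        nets = {}
        for name in ("enc1", "enc2", "dec"):
            weights, biases, i = [], [], 0
            while f"{name}_W{i}" in data:
                weights.append(data[f"{name}_W{i}"])
                biases.append(data[f"{name}_b{i}"])
                i += 1
            dims = [weights[0].shape[0]] + [W.shape[1] for W in weights]
            net = _MLP(dims, np.random.default_rng(0), dtype=weights[0].dtype)
            net.weights, net.biases = weights, biases
            nets[name] = net
        history = {
            key[len("loss_"):]: data[key]
            for key in data.files if key.startswith("loss_")
        }
        return cls(encoder1=nets["enc1"], encoder2=nets["enc2"],
                   decoder=nets["dec"], config=config, loss_history=history,
                   trained=bool(data["__trained__"]))


def _build_model(n_features: int, config: ModelConfig,
                 rng: np.random.Generator, dtype=np.float32) -> TrainedModel:
    enc_dims = [n_features, *config.hidden_dims, config.latent_dim]
    dec_dims = enc_dims[::-1]
    return TrainedModel(
        encoder1=_MLP(enc_dims, rng, dtype=dtype),
        encoder2=_MLP(enc_dims, rng, dtype=dtype),
        decoder=_MLP(dec_dims, rng, dtype=dtype),
        config=config,
    )


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _values(X) -> np.ndarray:
    if isinstance(X, FilteredExpression):
        return X.values
    return np.asarray(X)


def reconstruction_loss(X, X_hat) -> float:
    """Squared Frobenius norm of the reconstruction residual."""
    Xv, Hv = _values(X), _values(X_hat)
    if Xv.shape != Hv.shape:
        raise ContractError(f"shape mismatch {Xv.shape} vs {Hv.shape}")
    diff = Xv - Hv
    return float(np.sum(diff * diff))


def _normalize_rows(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Z, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return Z / safe[:, None], norms


def transcription_affinity(latent: LatentFeatures) -> TranscriptionAffinity:
    """A = Ẑ1 Ẑ2ᵀ with row-L2-normalized branches (zero rows stay zero)."""
    U, _ = _normalize_rows(latent.Z1)
    V, _ = _normalize_rows(latent.Z2)
    return TranscriptionAffinity(A=U @ V.T)


def _dense_adjacency(graph) -> np.ndarray:
    if graph is None:
        return None
    if isinstance(graph, AffinityGraph):
        return np.asarray(graph.adjacency.todense(), dtype=float)
    if sp.issparse(graph):
        return np.asarray(graph.todense(), dtype=float)
    return np.asarray(graph, dtype=float)


def consistency_loss(
    A: TranscriptionAffinity | np.ndarray,
    As: AffinityGraph | np.ndarray,
    Am: AffinityGraph | np.ndarray | None,
    alpha: float,
    beta: float,
) -> float:
    """alpha * ||A - A_spatial||^2 + beta * ||A - A_morph||^2.

    With ``beta == 0`` the morphology term is omitted entirely, so the value
    never depends on ``Am`` in that case.
    """
    Av = A.A if isinstance(A, TranscriptionAffinity) else np.asarray(A, dtype=float)
    As_d = _dense_adjacency(As)
    if Av.shape != As_d.shape:
        raise ContractError(f"shape mismatch {Av.shape} vs {As_d.shape}")
    total = alpha * float(np.sum((Av - As_d) ** 2))
    if beta != 0:
        if Am is None:
            raise ParameterError("beta > 0 requires a morphology graph")
        Am_d = _dense_adjacency(Am)
        total += beta * float(np.sum((Av - Am_d) ** 2))
    return total


def _consistency_components_grad(
    Z1: np.ndarray,
    Z2: np.ndarray,
    As,
    Am,
    alpha: float,
    beta: float,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(spatial term, morphology term, dZ1, dZ2) of the consistency loss.

    Computed in row blocks so the full n x n affinity is never materialized
    for large n; the value is identical to :func:`consistency_loss` applied
    to :func:`transcription_affinity`.
    """
    if Z1.shape != Z2.shape:
        raise ContractError("Z1 and Z2 must share a shape")
    if beta != 0 and Am is None:
        raise ParameterError("beta > 0 requires a morphology graph")
    U, n1 = _normalize_rows(Z1)
    V, n2 = _normalize_rows(Z2)
    As_sp = As.adjacency if isinstance(As, AffinityGraph) else sp.csr_matrix(As)
    Am_sp = None
    if beta != 0:
        Am_sp = Am.adjacency if isinstance(Am, AffinityGraph) else sp.csr_matrix(Am)
    n = U.shape[0]
    loss_s = 0.0
    loss_m = 0.0
    dU = np.empty_like(U)
    dV = np.zeros_like(V)
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        A_blk = U[start:stop] @ V.T
        Rs = A_blk - np.asarray(As_sp[start:stop].todense())
        loss_s += alpha * float(np.sum(Rs * Rs))
        G = (2.0 * alpha) * Rs
        if Am_sp is not None:
            Rm = A_blk - np.asarray(Am_sp[start:stop].todense())
            loss_m += beta * float(np.sum(Rm * Rm))
            G += (2.0 * beta) * Rm
        dU[start:stop] = G @ V
        dV += G.T @ U[start:stop]

    def _unnormalize(dN: np.ndarray, N: np.ndarray, norms: np.ndarray) -> np.ndarray:
        # d/dz of z/||z||: (dN - (dN . n̂) n̂) / ||z||; zero rows get zero grad.
        proj = np.sum(dN * N, axis=1, keepdims=True)
        out = (dN - proj * N) / np.where(norms > 0, norms, 1.0)[:, None]
        out[norms == 0] = 0.0
        return out

    return loss_s, loss_m, _unnormalize(dU, U, n1), _unnormalize(dV, V, n2)


def consistency_loss_grad(
    Z1: np.ndarray,
    Z2: np.ndarray,
    As: AffinityGraph | np.ndarray | sp.spmatrix,
    Am: AffinityGraph | np.ndarray | sp.spmatrix | None,
    alpha: float,
    beta: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Consistency loss value and analytic gradients w.r.t. Z1 and Z2."""
    loss_s, loss_m, dZ1, dZ2 = _consistency_components_grad(
        Z1, Z2, As, Am, alpha, beta
    )
    return loss_s + loss_m, dZ1, dZ2


# ---------------------------------------------------------------------------
# Encoding / training / denoising
# ---------------------------------------------------------------------------

def encode(
    X,
    model: TrainedModel,
    perturb: bool = False,
    seed: int = 0,
) -> LatentFeatures:
    """Run both encoder branches; optionally perturb the second branch."""
    Xv = _values(X)
    if Xv.shape[1] != model.input_dim:
        raise ContractError(
            f"input width {Xv.shape[1]} does not match encoder width "
            f"{model.input_dim}"
        )
    Xv = Xv.astype(model.encoder1.weights[0].dtype, copy=False)
    Z1 = model.encoder1.forward(Xv)
    Z2 = model.encoder2.forward(Xv)
    if perturb and model.config.sigma_std > 0:
        rng = np.random.default_rng(seed)
        Z2 = Z2 + model.config.sigma_std * rng.standard_normal(Z2.shape).astype(
            Z2.dtype
        )
    return LatentFeatures(Z1=Z1, Z2=Z2, Z=0.5 * (Z1 + Z2))


def train(
    X,
    As: AffinityGraph,
    Am: AffinityGraph | None,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Full-batch Adam on reconstruction + affinity-consistency objective.

    The run is fully deterministic given ``config.seed``.  When ``Am`` is
    None the morphology weight is forced to 0, which is bit-identical to
    passing ``Am`` with ``beta = 0``.
    """
    config = config or ModelConfig()
    Xv = _values(X).astype(np.float32)
    n, n_features = Xv.shape
    if As.adjacency.shape[0] != n:
        raise ContractError("spatial graph size does not match X")
    beta = config.beta
    if Am is None:
        beta = 0.0
    elif Am.adjacency.shape[0] != n:
        raise ContractError("morphology graph size does not match X")

    rng = np.random.default_rng(config.seed)
    model = _build_model(n_features, config, rng, dtype=np.float32)
    params = model.encoder1.params + model.encoder2.params + model.decoder.params
    opt = _Adam(params, lr=config.lr)
    history = {k: np.empty(config.epochs) for k in
               ("total", "reconstruction", "spatial", "morphology")}

    n1_enc = len(model.encoder1.params)
    n2_enc = len(model.encoder2.params)

    for epoch in range(config.epochs):
        Z1 = model.encoder1.forward(Xv, cache=True)
        Z2_raw = model.encoder2.forward(Xv, cache=True)
        if config.sigma_std > 0:
            eps = config.sigma_std * rng.standard_normal(
                Z2_raw.shape
            ).astype(np.float32)
            Z2 = Z2_raw + eps
        else:
            Z2 = Z2_raw
        Z = 0.5 * (Z1 + Z2)
        X_hat = model.decoder.forward(Z, cache=True)

        diff = X_hat - Xv
        loss_rec = float(np.sum(diff * diff))
        d_Xhat = 2.0 * diff
        dZ, dec_grads = model.decoder.backward(d_Xhat)

        if config.alpha != 0 or beta != 0:
            loss_sp, loss_mo, dZ1_c, dZ2_c = _consistency_components_grad(
                Z1, Z2, As, Am if beta != 0 else None, config.alpha, beta
            )
        else:
            dZ1_c, dZ2_c = 0.0, 0.0
            loss_sp = loss_mo = 0.0
        loss_cons = loss_sp + loss_mo

        dZ1 = 0.5 * dZ + dZ1_c
        dZ2 = 0.5 * dZ + dZ2_c
        _, enc1_grads = model.encoder1.backward(dZ1.astype(np.float32))
        _, enc2_grads = model.encoder2.backward(dZ2.astype(np.float32))

        total = loss_rec + loss_cons
        for key, val in (("total", total), ("reconstruction", loss_rec),
                         ("spatial", loss_sp), ("morphology", loss_mo)):
            if not np.isfinite(val):
                raise StateError(
                    f"non-finite {key} loss ({val}) at epoch {epoch}"
                )
            history[key][epoch] = val

        grads = enc1_grads + enc2_grads + dec_grads
        assert len(grads) == n1_enc + n2_enc + len(model.decoder.params)
        opt.step([g.astype(np.float32, copy=False) for g in grads])

    model.loss_history = history
    model.trained = True
    return model


def denoise(model: TrainedModel, X) -> np.ndarray:
    """Reconstruct expression from a perturbation-free encode pass."""
    if not model.trained:
        raise StateError("model has not been trained")
    latent = encode(X, model, perturb=False)
    return model.decoder.forward(latent.Z)
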