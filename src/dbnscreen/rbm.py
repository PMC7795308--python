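"""Bernoulli restricted Boltzmann machine with contrastive-divergence learning.

An RBM is an energy-based model over binary visible units ``v`` (length V)
and binary hidden units ``h`` (length H) with energy

    E(v, h) = -a.v - b.h - v^T W h

and joint distribution p(v, h) proportional to exp(-E).  With no intra-layer
connections the conditionals factorize into independent logistic units:

    p(h_j = 1 | v) = sigma(b_j + sum_i v_i w_ij)
    p(v_i = 1 | h) = sigma(a_i + sum_j h_j w_ij)

Learning follows the contrastive-divergence (CD-k) approximation to the
log-likelihood gradient: the positive phase uses the data-clamped statistics
``<v h>_data`` (hidden units taken at their conditional probabilities), the
negative phase estimates ``<v h>_model`` from a k-step alternating Gibbs
chain started at each data vector.  Binary states are sampled along the
chain; the final step uses probabilities, the standard variance-reduction
choice.

:func:`exact_moments` computes the model expectations by enumerating all
``2^(V+H)`` joint states and serves as the ground-truth oracle for small
models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy.special import expit as sigmoid

__all__ = [
    "RBMParameters",
    "TrainConfig",
    "sigmoid",
    "hidden_conditional",
    "visible_conditional",
    "gibbs_chain",
    "cd_update",
    "exact_moments",
    "init_parameters",
    "train_rbm",
    "reconstruction_error",
]


@dataclass
class RBMParameters:
    """Weights ``W`` (V x H), visible biases ``a`` (V), hidden biases ``b`` (H)."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be a 2-D matrix")
        if self.W.shape != (self.a.size, self.b.size):
            raise ValueError(
                f"inconsistent dimensions: W{self.W.shape}, "
                f"a({self.a.size}), b({self.b.size})"
            )
        if not (np.isfinite(self.W).all() and np.isfinite(self.a).all()
                and np.isfinite(self.b).all()):
            raise ValueError("parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.a.size

    @property
    def n_hidden(self) -> int:
        return self.b.size

    def copy(self) -> "RBMParameters":
        return RBMParameters(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass
class TrainConfig:
    """Hyperparameters for CD training.

    Defaults follow the full-scale reweighting protocol: learning rate 0.05,
    70 epochs, batch size 128, 50 Gibbs steps.  Desk-scale runs override
    them.  ``convergence_tolerance`` is the error-change threshold used by
    the iterative feature-learning loop.
    """

    learning_rate: float = 0.05
    epochs: int = 70
    batch_size: int = 128
    gibbs_steps: int = 50
    seed: int = 0
    convergence_tolerance: float = 1e-3
    weight_init: str = "uniform"   # "uniform" in [0,1) or "gaussian" (0.01 sd)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size < 1 or self.gibbs_steps < 1:
            raise ValueError("batch_size and gibbs_steps must be >= 1")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")
        if self.weight_init not in ("uniform", "gaussian"):
            raise ValueError("weight_init must be 'uniform' or 'gaussian'")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


def hidden_conditional(v: np.ndarray, params: RBMParameters) -> np.ndarray:
    """``p(h_j = 1 | v)`` for one visible vector or a batch (rows)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError(
            f"visible vector length {v.shape[-1]} != V={params.n_visible}"
        )
    return sigmoid(params.b + v @ params.W)


def visible_conditional(h: np.ndarray, params: RBMParameters) -> np.ndarray:
    """``p(v_i = 1 | h)`` for one hidden vector or a batch (rows)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(
            f"hidden vector length {h.shape[-1]} != H={params.n_hidden}"
        )
    return sigmoid(params.a + h @ params.W.T)


def gibbs_chain(
    v0: np.ndarray,
    params: RBMParameters,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run k rounds of alternating block Gibbs updates starting from ``v0``.

    Each round samples all hidden units in parallel from ``p(h|v)`` and then
    all visible units in parallel from ``p(v|h)``.  Works on a single vector
    or a batch of row vectors.

    Returns
    -------
    (v_k, h_k, p_v, p_h):
        Final binary samples and the mean-field probabilities from which
        they were drawn.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.atleast_2d(np.asarray(v0, dtype=float))
    single = np.asarray(v0).ndim == 1
    p_h = p_v = None
    for _ in range(k):
        p_h = hidden_conditional(v, params)
        h = (rng.random(p_h.shape) < p_h).astype(float)
        p_v = visible_conditional(h, params)
        v = (rng.random(p_v.shape) < p_v).astype(float)
    if single:
        return v[0], h[0], p_v[0], p_h[0]
    return v, h, p_v, p_h


def cd_update(
    batch: np.ndarray,
    params: RBMParameters,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> RBMParameters:
    """One CD-k parameter update from a batch of binary visible vectors.

    Positive-phase hidden statistics use conditional probabilities; the
    negative phase runs a k-step Gibbs chain from each data vector, sampling
    binary states along the chain and using probabilities at the final step.
    Updates are averaged over the batch and scaled by the learning rate.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    if batch.shape[1] != params.n_visible:
        raise ValueError("batch width does not match V")
    n = batch.shape[0]
    eps = cfg.learning_rate
    k = cfg.gibbs_steps

    ph_data = hidden_conditional(batch, params)
    # negative phase: chain state after k rounds, probabilities at the end
    v = batch
    for step in range(k):
        p_h = hidden_conditional(v, params)
        h = (rng.random(p_h.shape) < p_h).astype(float)
        p_v = visible_conditional(h, params)
        if step < k - 1:
            v = (rng.random(p_v.shape) < p_v).astype(float)
        else:
            v_model = p_v
    ph_model = hidden_conditional(v_model, params)

    dW = (batch.T @ ph_data - v_model.T @ ph_model) / n
    da = (batch - v_model).mean(axis=0)
    db = (ph_data - ph_model).mean(axis=0)
    return RBMParameters(
        params.W + eps * dW, params.a + eps * da, params.b + eps * db
    )


def _all_states(n: int) -> np.ndarray:
    return np.array(list(product((0.0, 1.0), repeat=n)), dtype=float)


def exact_moments(
    params: RBMParameters,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Model expectations ``(<v_i h_j>, <v_i>, <h_j>)`` by full enumeration.

    Enumerates all ``2^(V+H)`` joint states of the Boltzmann distribution;
    restricted to small models (V + H <= 20).
    """
    V, H = params.n_visible, params.n_hidden
    if V + H > 20:
        raise ValueError(f"model too large to enumerate: V+H={V + H} > 20")
    vs = _all_states(V)          # (2^V, V)
    hs = _all_states(H)          # (2^H, H)
    # log unnormalized p for every joint state
    logw = (vs @ params.a)[:, None] + (hs @ params.b)[None, :] \
        + vs @ params.W @ hs.T
    logw -= logw.max()
    w = np.exp(logw)
    z = w.sum()
    p = w / z
    vh = vs.T @ p @ hs           # (V, H)
    pv = p.sum(axis=1) @ vs      # (V,)
    ph = p.sum(axis=0) @ hs      # (H,)
    return vh, pv, ph


def init_parameters(
    n_visible: int, n_hidden: int, cfg: TrainConfig,
    rng: np.random.Generator,
) -> RBMParameters:
    """Random weight initialization; biases start at zero.

    ``uniform`` draws weights on [0, 1); ``gaussian`` draws from
    N(0, 0.01^2), a common alternative when the uniform start converges
    slowly.
    """
    if cfg.weight_init == "uniform":
        W = rng.random((n_visible, n_hidden))
    else:
        W = rng.normal(scale=0.01, size=(n_visible, n_hidden))
    return RBMParameters(W, np.zeros(n_visible), np.zeros(n_hidden))


def reconstruction_error(data: np.ndarray, params: RBMParameters) -> float:
    """Mean per-row L2 error of the one-pass mean-field reconstruction."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    p_h = hidden_conditional(data, params)
    p_v = visible_conditional(p_h, params)
    return float(np.linalg.norm(data - p_v, axis=1).mean())


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
    params: RBMParameters | None = None,
) -> tuple[RBMParameters, list[float]]:
    """Train an RBM with minibatch CD-k.

    One seeded shuffle per epoch, contiguous batches of ``cfg.batch_size``.
    Returns the parameters and the per-epoch mean reconstruction error log.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 0:
        raise ValueError("empty training data")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_parameters(data.shape[1], n_hidden, cfg, rng)
    log: list[float] = []
    n = data.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            batch = data[order[lo:lo + cfg.batch_size]]
            params = cd_update(batch, params, cfg, rng)
        log.append(reconstruction_error(data, params))
    return params, log
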