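"""Deep belief network: greedy pretraining, autoencoder fine-tuning,
reconstruction errors and iterative removal of outlier features.

A DBN here is a stack of Bernoulli RBMs trained greedily: each RBM learns on
the mean-field hidden activations of the one below.  The stack is then
unrolled into an encoder-decoder (decoder initialized with the transposed
weights and visible biases) and fine-tuned by backpropagation on the
unsupervised squared reconstruction error — no labels are involved at any
point.

Reconstruction is a deterministic mean-field pass: encode to the deepest
layer with each RBM's hidden conditional, decode back with the (possibly
fine-tuned) decoder.  The per-entry error matrix ``E = |X - Y|``, the
per-molecule error ``e_i = ||row_i(E)||`` and per-feature column means of
``E`` drive feature selection: features that reconstruct poorly ("outliers")
carry little learnable structure and are removed by an iterative
train/reconstruct/remove loop that stops when the mean per-molecule error
settles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fingerprint_io import FingerprintMatrix
from .rbm import (
    RBMParameters,
    TrainConfig,
    hidden_conditional,
    sigmoid,
    train_rbm,
)

__all__ = [
    "DBNModel",
    "ReconstructionResult",
    "pretrain",
    "fine_tune",
    "reconstruct",
    "iterative_feature_learning",
]


def _as_array(data) -> np.ndarray:
    if isinstance(data, FingerprintMatrix):
        return data.values
    return np.atleast_2d(np.asarray(data, dtype=float))


@dataclass
class DBNModel:
    """A stack of RBMs plus the (optional) fine-tuned decoder.

    ``layers[l].W`` maps layer l activations to layer l+1; ``decoder`` holds
    one ``(W, c)`` pair per layer with ``W`` of shape (H_l, V_l), applied in
    reverse layer order when decoding.  Before fine-tuning the decoder is
    exactly the tied transpose of the encoder.
    """

    layers: list[RBMParameters]
    layer_sizes: list[int]
    decoder: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    fine_tuned: bool = False
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a DBN needs at least one RBM layer")
        sizes = [self.layers[0].n_visible] + [l.n_hidden for l in self.layers]
        if list(self.layer_sizes) != sizes:
            raise ValueError(
                f"layer_sizes {self.layer_sizes} inconsistent with RBM shapes {sizes}"
            )
        if not self.decoder:
            self.decoder = [(l.W.T.copy(), l.a.copy()) for l in self.layers]

    @property
    def n_input(self) -> int:
        return self.layer_sizes[0]

    def encode(self, X: np.ndarray) -> list[np.ndarray]:
        """Mean-field activations per layer, input first (len = depth + 1)."""
        acts = [np.atleast_2d(np.asarray(X, dtype=float))]
        for layer in self.layers:
            acts.append(hidden_conditional(acts[-1], layer))
        return acts

    def decode(self, Z: np.ndarray) -> list[np.ndarray]:
        """Mean-field decoding from the deepest code back to the input layer."""
        acts = [np.atleast_2d(np.asarray(Z, dtype=float))]
        for W, c in reversed(self.decoder):
            acts.append(sigmoid(acts[-1] @ W + c))
        return acts


def pretrain(
    data,
    layer_sizes: list[int],
    cfg: TrainConfig,
) -> DBNModel:
    """Greedy layer-wise RBM pretraining.

    ``layer_sizes`` lists the input width first, then each hidden width
    (at least one hidden layer).  Each RBM trains on the mean-field hidden
    activations of the previous one.  Deterministic under ``cfg.seed``.
    """
    X = _as_array(data)
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    layer_sizes = [int(s) for s in layer_sizes]
    if len(layer_sizes) < 2:
        raise ValueError("at least one RBM (two layer sizes) is required")
    if layer_sizes[0] != X.shape[1]:
        raise ValueError(
            f"layer_sizes[0]={layer_sizes[0]} does not match data width {X.shape[1]}"
        )
    rng = np.random.default_rng(cfg.seed)
    layers: list[RBMParameters] = []
    log: list[float] = []
    acts = X
    for n_hidden in layer_sizes[1:]:
        params, errs = train_rbm(acts, n_hidden, cfg, rng=rng)
        layers.append(params)
        log.extend(errs)
        acts = hidden_conditional(acts, params)
    return DBNModel(layers=layers, layer_sizes=layer_sizes, training_log=log)


def _autoencoder_forward(model: DBNModel, X: np.ndarray) -> list[np.ndarray]:
    """All activations through encoder then decoder (input included)."""
    acts = model.encode(X)
    for W, c in reversed(model.decoder):
        acts.append(sigmoid(acts[-1] @ W + c))
    return acts


def reconstruction_loss(model: DBNModel, X: np.ndarray) -> float:
    """Mean over molecules of the squared reconstruction error."""
    X = _as_array(X)
    Y = _autoencoder_forward(model, X)[-1]
    return float(((X - Y) ** 2).sum() / X.shape[0])


def _loss_and_gradients(model: DBNModel, X: np.ndarray):
    """Backpropagate the mean squared reconstruction error.

    Returns (loss, encoder grads [(dW, db)], decoder grads [(dW, dc)])
    with lists in layer order matching ``model.layers`` / ``model.decoder``.
    """
    n = X.shape[0]
    depth = len(model.layers)
    acts = _autoencoder_forward(model, X)
    Y = acts[-1]
    loss = float(((X - Y) ** 2).sum() / n)

    # weights in application order: encoder layers then reversed decoder
    path = [(l.W, "enc", i) for i, l in enumerate(model.layers)]
    path += [(model.decoder[l][0], "dec", l) for l in reversed(range(depth))]

    g_enc = [None] * depth
    g_dec = [None] * depth
    delta = 2.0 * (Y - X) / n * Y * (1.0 - Y)   # dL/d(pre-activation)
    for step in reversed(range(len(path))):
        W, kind, idx = path[step]
        inp = acts[step]
        dW = inp.T @ delta
        dbias = delta.sum(axis=0)
        if kind == "enc":
            g_enc[idx] = (dW, dbias)
        else:
            g_dec[idx] = (dW, dbias)
        if step > 0:
            back = delta @ W.T
            delta = back * inp * (1.0 - inp)
    return loss, g_enc, g_dec


def fine_tune(model: DBNModel, data, cfg: TrainConfig) -> DBNModel:
    """Backpropagation fine-tuning of the unrolled autoencoder.

    Minimizes the squared reconstruction error by minibatch gradient
    descent for ``cfg.epochs`` epochs (one seeded shuffle per epoch).
    Weights are untied from the start of fine-tuning: encoder and decoder
    receive independent updates.  Returns the same model object, updated in
    place, with ``fine_tuned`` set.
    """
    X = _as_array(data)
    if X.shape[1] != model.n_input:
        raise ValueError("data width does not match model input size")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    eps = cfg.learning_rate
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            batch = X[order[lo:lo + cfg.batch_size]]
            _, g_enc, g_dec = _loss_and_gradients(model, batch)
            for layer, (dW, db) in zip(model.layers, g_enc):
                layer.W -= eps * dW
                layer.b -= eps * db
            model.decoder = [
                (W - eps * dW, c - eps * dc)
                for (W, c), (dW, dc) in zip(model.decoder, g_dec)
            ]
        model.training_log.append(
            float(np.linalg.norm(X - _autoencoder_forward(model, X)[-1],
                                 axis=1).mean())
        )
    model.fine_tuned = True
    return model


@dataclass
class ReconstructionResult:
    """Reconstruction ``Y``, per-entry errors ``E`` and per-molecule ``e_i``."""

    Y: np.ndarray
    E: np.ndarray
    per_molecule_error: np.ndarray

    @property
    def per_feature_error(self) -> np.ndarray:
        """Column means of E — the per-feature outlier score."""
        return self.E.mean(axis=0)


def reconstruct(model: DBNModel, data, *, norm: str = "l2"
                ) -> ReconstructionResult:
    """Deterministic mean-field reconstruction of ``data``.

    Encodes to the deepest layer and decodes back; no sampling is involved,
    so the result is a pure function of the model.  ``E = |X - Y|``
    entrywise; ``e_i`` is the L2 norm of row i of E (L1 with
    ``norm="l1"``).
    """
    X = _as_array(data)
    if X.shape[1] != model.n_input:
        raise ValueError("data width does not match model input size")
    Y = _autoencoder_forward(model, X)[-1]
    E = np.abs(X - Y)
    if norm == "l2":
        e = np.linalg.norm(E, axis=1)
    elif norm == "l1":
        e = E.sum(axis=1)
    else:
        raise ValueError("norm must be 'l1' or 'l2'")
    return ReconstructionResult(Y=Y, E=E, per_molecule_error=e)


def iterative_feature_learning(
    data,
    layer_sizes: list[int],
    cfg: TrainConfig,
    outlier_fraction: float,
    *,
    max_rounds: int = 10,
    fine_tune_cfg: TrainConfig | None = None,
) -> tuple[DBNModel, ReconstructionResult, list[int]]:
    """Train / reconstruct / drop-worst-features loop.

    Each round re-initializes and trains a DBN (pretrain + fine-tune) on the
    surviving columns with a seed derived from ``cfg.seed`` and the round
    number, reconstructs, and removes the ``ceil(outlier_fraction * M_cur)``
    features with the largest mean column error.  The loop stops when the
    change in mean per-molecule error between successive rounds falls to
    ``cfg.convergence_tolerance`` or below, after ``max_rounds``, or
    immediately after one round when ``outlier_fraction`` is zero.

    Removed feature indices are reported in the coordinates of the original
    matrix, in removal order.
    """
    if not (0.0 <= outlier_fraction < 0.5):
        raise ValueError("outlier_fraction must be in [0, 0.5)")
    X = _as_array(data)
    ft_cfg = fine_tune_cfg or cfg
    current = np.arange(X.shape[1])
    removed: list[int] = []
    prev_err = math.inf   # so only an infinite tolerance stops round 1
    model = None
    result = None
    for rnd in range(max_rounds):
        seed = int(np.random.SeedSequence([cfg.seed, rnd]).generate_state(1)[0]
                   % (2**31))
        sizes = [len(current)] + list(layer_sizes[1:])
        round_cfg = cfg.with_(seed=seed)
        model = pretrain(X[:, current], sizes, round_cfg)
        model = fine_tune(model, X[:, current], ft_cfg.with_(seed=seed))
        result = reconstruct(model, X[:, current])
        err = float(result.per_molecule_error.mean())
        converged = abs(err - prev_err) <= cfg.convergence_tolerance
        prev_err = err
        if converged or outlier_fraction == 0.0 or rnd == max_rounds - 1:
            # never remove after the final reconstruction: the returned
            # result must describe exactly the surviving columns
            break
        n_remove = math.ceil(outlier_fraction * len(current))
        if n_remove >= len(current):
            raise ValueError("removal would eliminate all features")
        order = np.argsort(-result.per_feature_error, kind="stable")
        worst_local = order[:n_remove]
        removed.extend(int(current[j]) for j in sorted(worst_local))
        current = np.delete(current, worst_local)
    return model, result, removed
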