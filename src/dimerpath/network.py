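"""Committor model: self-normalizing feed-forward network with residual tail.

The model maps a descriptor vector x to a scalar logit q(x); the committor is
pB(x) = logistic(q(x)).  The architecture is a pyramidal stack of 5
self-normalizing (SELU) layers whose widths taper geometrically from the
input width (77 for the two-helix descriptors) down to 11, followed by 3
residual blocks of 4 SELU layers at width 11 and a linear head.  The head is
zero-initialized so an untrained model predicts pB = 0.5 everywhere.

Training minimizes the negative log-likelihood of two-way-shooting outcomes,

    L = - sum_i [ nA_i * log(1 - p(x_i)) + nB_i * log p(x_i) ],

the standard binomial likelihood for shooting results, optimized with Adam.
The learning rate is modulated on the fly by the prediction/generation
mismatch: lr = base_lr * min(1, (1 - nTPgen/nTPpred)^2) counted over a
trailing window of MC steps, so training stalls once the model's expected TP
count matches the realized one.

The network, backpropagation and Adam are implemented directly in numpy; the
model is small enough (width <= 77) that this is both fast and dependency-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CommittorNet", "TrainingSchedule", "shooting_loss", "shooting_loss_grad",
           "effective_lr", "train", "maybe_train", "DescriptorMismatchError"]

_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805


class DescriptorMismatchError(RuntimeError):
    """Checkpoint descriptor ordering does not match the current ordering."""


def _selu(z):
    return _SELU_LAMBDA * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))


def _selu_grad(z):
    return _SELU_LAMBDA * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))


def _sigmoid(q):
    out = np.empty_like(q, dtype=float)
    pos = q >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-q[pos]))
    e = np.exp(q[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class CommittorNet:
    """Numpy feed-forward committor model.

    Parameters
    ----------
    input_dim : width of the descriptor vector (77 for two-helix systems,
        2 for the toy landscape).
    bottleneck : width of the residual tail (11).
    n_pyramid : number of units-per-layer values in the tapering stack (5,
        counting the input layer), i.e. ``n_pyramid - 1`` weight layers.
    n_blocks, block_layers : residual tail shape (3 blocks of 4 layers).
    descriptor_hash : optional hash of the descriptor ordering the model was
        built for; checked when loading checkpoints.
    """

    def __init__(self, input_dim: int = 77, bottleneck: int = 11,
                 n_pyramid: int = 5, n_blocks: int = 3, block_layers: int = 4,
                 seed: int = 0, descriptor_hash: str | None = None):
        self.input_dim = int(input_dim)
        self.bottleneck = int(bottleneck)
        self.n_pyramid = int(n_pyramid)
        self.n_blocks = int(n_blocks)
        self.block_layers = int(block_layers)
        self.descriptor_hash = descriptor_hash
        # geometric taper from input width to the bottleneck
        self.widths = np.rint(np.geomspace(self.input_dim, self.bottleneck,
                                           self.n_pyramid)).astype(int)
        rng = np.random.default_rng(seed)
        self.params: list[tuple[np.ndarray, np.ndarray]] = []
        for w_in, w_out in zip(self.widths[:-1], self.widths[1:]):
            self.params.append(self._init_layer(rng, w_in, w_out))
        for _ in range(self.n_blocks * self.block_layers):
            self.params.append(self._init_layer(rng, self.bottleneck, self.bottleneck))
        # zero-initialized head: untrained model predicts pB = 0.5
        self.params.append((np.zeros((1, self.bottleneck)), np.zeros(1)))
        self._adam_m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.params]
        self._adam_v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.params]
        self._adam_t = 0

    @staticmethod
    def _init_layer(rng, w_in, w_out):
        # variance-preserving (LeCun normal) initialization for SELU layers
        W = rng.normal(0.0, 1.0 / np.sqrt(w_in), size=(w_out, w_in))
        return W, np.zeros(w_out)

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------

    def _forward(self, X, want_cache=False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected input width {self.input_dim}, got {X.shape[1]}")
        cache = {"inputs": [], "preacts": [], "block_in": []}
        h = X
        k = 0
        for _ in range(len(self.widths) - 1):
            W, b = self.params[k]
            z = h @ W.T + b
            if want_cache:
                cache["inputs"].append(h)
                cache["preacts"].append(z)
            h = _selu(z)
            k += 1
        for _ in range(self.n_blocks):
            block_input = h
            if want_cache:
                cache["block_in"].append(block_input)
            for _ in range(self.block_layers):
                W, b = self.params[k]
                z = h @ W.T + b
                if want_cache:
                    cache["inputs"].append(h)
                    cache["preacts"].append(z)
                h = _selu(z)
                k += 1
            h = h + block_input            # identity skip connection
        W, b = self.params[k]
        q = (h @ W.T + b)[:, 0]
        if want_cache:
            cache["head_in"] = h
        return (q, cache) if want_cache else q

    def predict_logit(self, X) -> np.ndarray:
        """Model logit q(x); deterministic given the weights."""
        return self._forward(X)

    def predict(self, X) -> np.ndarray:
        """Committor estimate pB(x) = logistic(q(x)), in (0, 1)."""
        return _sigmoid(self.predict_logit(X))

    def gradients(self, X, dq) -> list[tuple[np.ndarray, np.ndarray]]:
        """Parameter gradients of sum(dq * q(x)) -- i.e. backprop of dL/dq."""
        q, cache = self._forward(X, want_cache=True)
        del q
        dq = np.asarray(dq, dtype=float).reshape(-1, 1)
        grads = [None] * len(self.params)
        # head
        k = len(self.params) - 1
        W, b = self.params[k]
        grads[k] = (dq.T @ cache["head_in"], dq.sum(axis=0))
        dh = dq @ W
        # residual blocks, in reverse
        li = len(cache["preacts"])  # index into per-layer caches
        for blk in reversed(range(self.n_blocks)):
            d_skip = dh.copy()
            for _ in reversed(range(self.block_layers)):
                li -= 1
                k -= 1
                W, b = self.params[k]
                dz = dh * _selu_grad(cache["preacts"][li])
                grads[k] = (dz.T @ cache["inputs"][li], dz.sum(axis=0))
                dh = dz @ W
            dh = dh + d_skip
        # pyramid, in reverse
        for _ in reversed(range(len(self.widths) - 1)):
            li -= 1
            k -= 1
            W, b = self.params[k]
            dz = dh * _selu_grad(cache["preacts"][li])
            grads[k] = (dz.T @ cache["inputs"][li], dz.sum(axis=0))
            dh = dz @ W
        return grads

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, (gW, gb) in enumerate(grads):
            W, b = self.params[k]
            mW, mb = self._adam_m[k]
            vW, vb = self._adam_v[k]
            mW = beta1 * mW + (1 - beta1) * gW
            mb = beta1 * mb + (1 - beta1) * gb
            vW = beta2 * vW + (1 - beta2) * gW ** 2
            vb = beta2 * vb + (1 - beta2) * gb ** 2
            self._adam_m[k] = (mW, mb)
            self._adam_v[k] = (vW, vb)
            mW_hat = mW / (1 - beta1 ** t)
            mb_hat = mb / (1 - beta1 ** t)
            vW_hat = vW / (1 - beta2 ** t)
            vb_hat = vb / (1 - beta2 ** t)
            self.params[k] = (W - lr * mW_hat / (np.sqrt(vW_hat) + eps),
                              b - lr * mb_hat / (np.sqrt(vb_hat) + eps))

    def preactivation_stds(self, X) -> np.ndarray:
        """Per-layer standard deviations of the pre-activations (diagnostics)."""
        _, cache = self._forward(X, want_cache=True)
        return np.array([z.std() for z in cache["preacts"]])

    # ------------------------------------------------------------------
    # checkpointing
    # ------------------------------------------------------------------

    def save(self, path):
        """Write a single-file checkpoint (weights + architecture + hash)."""
        arrays = {}
        for i, (W, b) in enumerate(self.params):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path,
                 input_dim=self.input_dim, bottleneck=self.bottleneck,
                 n_pyramid=self.n_pyramid, n_blocks=self.n_blocks,
                 block_layers=self.block_layers,
                 descriptor_hash=self.descriptor_hash or "",
                 n_params=len(self.params), **arrays)

    @classmethod
    def load(cls, path, expected_hash: str | None = None) -> "CommittorNet":
        with np.load(path, allow_pickle=False) as z:
            stored = str(z["descriptor_hash"])
            if expected_hash is not None and stored and stored != expected_hash:
                raise DescriptorMismatchError(
                    "checkpoint was trained with a different descriptor ordering")
            model = cls(input_dim=int(z["input_dim"]), bottleneck=int(z["bottleneck"]),
                        n_pyramid=int(z["n_pyramid"]), n_blocks=int(z["n_blocks"]),
                        block_layers=int(z["block_layers"]),
                        descriptor_hash=stored or None)
            model.params = [(z[f"W{i}"].copy(), z[f"b{i}"].copy())
                            for i in range(int(z["n_params"]))]
        model._adam_m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.params]
        model._adam_v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.params]
        model._adam_t = 0
        return model

    def copy(self) -> "CommittorNet":
        clone = CommittorNet(self.input_dim, self.bottleneck, self.n_pyramid,
                             self.n_blocks, self.block_layers,
                             descriptor_hash=self.descriptor_hash)
        clone.params = [(W.copy(), b.copy()) for W, b in self.params]
        return clone


# ---------------------------------------------------------------------------
# loss and training schedule
# ---------------------------------------------------------------------------

def _clean_counts(X, n_a, n_b):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    keep = (n_a + n_b) > 0
    if not keep.all():
        warnings.warn(f"excluding {np.count_nonzero(~keep)} results with no "
                      "resolved trial outcomes")
    return X[keep], n_a[keep], n_b[keep]


def shooting_loss(model: CommittorNet, X, n_a, n_b) -> float:
    """Binomial negative log-likelihood of shooting outcomes.

    Each shooting point contributes -[nA log(1-p) + nB log p]; results with
    nA = nB = 0 (both trials unresolved) are excluded with a warning.
    """
    X, n_a, n_b = _clean_counts(X, n_a, n_b)
    q = model.predict_logit(X)
    # -log p = softplus(-q), -log(1-p) = softplus(q)
    return float(np.sum(n_a * np.logaddexp(0.0, q) + n_b * np.logaddexp(0.0, -q)))


def shooting_loss_grad(q, n_a, n_b):
    """dL/dq for the binomial shooting loss."""
    p = _sigmoid(np.asarray(q, dtype=float))
    return n_a * p - n_b * (1.0 - p)


def train(model: CommittorNet, X, n_a, n_b, lr: float = 1e-3, epochs: int = 5,
          batch_size: int = 128, seed: int = 0) -> list[float]:
    """Run ``epochs`` of minibatch Adam on shooting outcomes; returns the
    per-epoch training loss (evaluated after each epoch)."""
    X, n_a, n_b = _clean_counts(X, n_a, n_b)
    if len(X) == 0:
        raise ValueError("no usable shooting results")
    rng = np.random.default_rng(seed)
    history = []
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            q = model.predict_logit(X[idx])
            dq = shooting_loss_grad(q, n_a[idx], n_b[idx])
            grads = model.gradients(X[idx], dq)
            model.adam_step(grads, lr)
        history.append(shooting_loss(model, X, n_a, n_b))
    return history


@dataclass
class TrainingSchedule:
    """On-the-fly training schedule.

    Training runs after every ``train_every``-th MC step for ``epochs``
    epochs at lr = base_lr * alpha_eff, where alpha_eff =
    min(1, (1 - nTPgen/nTPpred)^2) over the trailing ``window`` MC steps;
    the event is skipped when lr drops below ``lr_floor``.
    """

    base_lr: float = 1e-3
    window: int = 100
    train_every: int = 10
    epochs: int = 5
    lr_floor: float = 1e-5
    batch_size: int = 128


def effective_lr(n_gen: float, n_pred: float, base_lr: float = 1e-3) -> float:
    """lr = base_lr * min(1, (1 - n_gen/n_pred)^2); base_lr on a cold start."""
    if n_pred < 0 or n_gen < 0:
        raise ValueError("counts must be non-negative")
    if n_pred == 0:
        warnings.warn("no predicted TPs in window (cold start); using base lr")
        return base_lr
    alpha = min(1.0, (1.0 - n_gen / n_pred) ** 2)
    return base_lr * alpha


def maybe_train(schedule: TrainingSchedule, mc_step_index: int,
                model: CommittorNet, X, n_a, n_b,
                n_gen_window: float, n_pred_window: float,
                seed: int = 0) -> bool:
    """Apply one scheduled training event if due; returns True if trained."""
    if mc_step_index % schedule.train_every != 0 or mc_step_index == 0:
        return False
    lr = effective_lr(n_gen_window, n_pred_window, schedule.base_lr)
    if lr < schedule.lr_floor:
        return False
    train(model, X, n_a, n_b, lr=lr, epochs=schedule.epochs,
          batch_size=schedule.batch_size, seed=seed)
    return True
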