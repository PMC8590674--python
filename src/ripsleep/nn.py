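"""Compact NumPy implementation of the dense + GRU sequence classifier.

The network maps a 25-step window of per-epoch feature vectors to a
3-class posterior for the window's target epoch:

    input (25 x F)
      -> 3 dense layers of 70 ReLU units, applied per time step
      -> GRU with 50 units run over the 25 steps
      -> dense classification layer (3 units) on the final GRU state
      -> softmax

Dropout (default 0.22, inverted scaling) is applied after each dense layer
and on the GRU output during training only.  Training uses Adam on a
class-weighted categorical cross-entropy; gradients are computed by
hand-written backpropagation-through-time and are verified against finite
differences in the test suite.

The GRU follows the standard gating equations with sigmoid update/reset
gates; the candidate activation is ReLU by default (matching the rest of
the network's hidden activations) with a ``tanh`` switch::

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
    c_t = act(W_c x_t + U_c (r_t * h_{t-1}) + b_c)
    h_t = (1 - z_t) * h_{t-1} + z_t * c_t
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["GRUNet", "AdamOptimizer", "softmax", "glorot_uniform"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(
    rng: np.random.Generator, fan_in: int, fan_out: int, dtype
) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class GRUNet:
    """The dense-stack + GRU + softmax network with manual backprop.

    Parameters
    ----------
    n_features : int
        Input feature dimension F.
    dense_layers, dense_width, gru_units, n_classes : int
        Architecture sizes (defaults 3, 70, 50, 3).
    dropout : float
        Dropout probability in [0, 1), active during training only.
    gru_activation : {"relu", "tanh"}
        Candidate-state activation.
    seed : int
        Weight-initialization seed; identical seeds give identical weights.
    dtype : numpy dtype
        float32 (default, fast) or float64 (used by gradient checks).
    """

    def __init__(
        self,
        n_features: int,
        dense_layers: int = 3,
        dense_width: int = 70,
        gru_units: int = 50,
        n_classes: int = 3,
        dropout: float = 0.22,
        gru_activation: str = "relu",
        seed: int = 0,
        dtype=np.float32,
    ):
        if n_features <= 0:
            raise ValueError("n_features must be positive")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if gru_activation not in ("relu", "tanh"):
            raise ValueError("gru_activation must be 'relu' or 'tanh'")
        self.n_features = n_features
        self.dense_layers = dense_layers
        self.dense_width = dense_width
        self.gru_units = gru_units
        self.n_classes = n_classes
        self.dropout = dropout
        self.gru_activation = gru_activation
        self.dtype = np.dtype(dtype)
        self.params = self._init_params(np.random.default_rng(seed))

    # ----- parameters ---------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d, g, c = self.dense_width, self.gru_units, self.n_classes
        p: dict[str, np.ndarray] = {}
        fan_in = self.n_features
        for i in range(self.dense_layers):
            p[f"W{i}"] = glorot_uniform(rng, fan_in, d, self.dtype)
            p[f"b{i}"] = np.zeros(d, dtype=self.dtype)
            fan_in = d
        for gate in ("z", "r", "c"):
            p[f"Wg_{gate}"] = glorot_uniform(rng, d, g, self.dtype)
            p[f"Ug_{gate}"] = glorot_uniform(rng, g, g, self.dtype)
            p[f"bg_{gate}"] = np.zeros(g, dtype=self.dtype)
        p["Wo"] = glorot_uniform(rng, g, c, self.dtype)
        p["bo"] = np.zeros(c, dtype=self.dtype)
        return p

    def parameter_counts(self) -> dict[str, int]:
        """Per-block trainable parameter counts (dense stack / GRU / head)."""
        dense = sum(
            self.params[f"W{i}"].size + self.params[f"b{i}"].size
            for i in range(self.dense_layers)
        )
        gru = sum(
            self.params[f"{m}_{gate}"].size
            for gate in ("z", "r", "c")
            for m in ("Wg", "Ug", "bg")
        )
        head = self.params["Wo"].size + self.params["bo"].size
        return {"dense_stack": dense, "gru": gru, "classifier_head": head,
                "total": dense + gru + head}

    # ----- forward ------------------------------------------------------

    def _act(self) -> tuple[Callable, Callable]:
        if self.gru_activation == "relu":
            return (lambda x: np.maximum(x, 0.0),
                    lambda pre: (pre > 0).astype(self.dtype))
        return (np.tanh, lambda pre: 1.0 - np.tanh(pre) ** 2)

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run the network on a batch of windows.

        Parameters
        ----------
        X : (B, T, F) array
        train : bool
            Enables dropout (requires ``rng``).
        Returns ``(probs, cache)`` where probs is (B, n_classes).
        """
        X = np.ascontiguousarray(X, dtype=self.dtype)
        B, T, F = X.shape
        if F != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {F}")
        p = self.params
        keep = 1.0 - self.dropout
        use_drop = train and self.dropout > 0.0
        if use_drop and rng is None:
            raise ValueError("training forward pass needs an rng for dropout")
        act, _ = self._act()

        cache: dict = {"X": X, "masks": [], "dense": []}
        h_flat = X.reshape(B * T, F)
        for i in range(self.dense_layers):
            pre = h_flat @ p[f"W{i}"] + p[f"b{i}"]
            a = np.maximum(pre, 0.0)
            if use_drop:
                mask = (rng.random(a.shape) < keep).astype(self.dtype) / keep
                a = a * mask
            else:
                mask = None
            cache["dense"].append((h_flat, pre))
            cache["masks"].append(mask)
            h_flat = a
        A = h_flat.reshape(B, T, self.dense_width)
        cache["A"] = A

        # precompute input projections for all gates over all steps
        Xz = (h_flat @ p["Wg_z"] + p["bg_z"]).reshape(B, T, self.gru_units)
        Xr = (h_flat @ p["Wg_r"] + p["bg_r"]).reshape(B, T, self.gru_units)
        Xc = (h_flat @ p["Wg_c"] + p["bg_c"]).reshape(B, T, self.gru_units)

        h = np.zeros((B, self.gru_units), dtype=self.dtype)
        steps = []
        for t in range(T):
            z = _sigmoid(Xz[:, t] + h @ p["Ug_z"])
            r = _sigmoid(Xr[:, t] + h @ p["Ug_r"])
            rh = r * h
            c_pre = Xc[:, t] + rh @ p["Ug_c"]
            c = act(c_pre)
            h_new = (1.0 - z) * h + z * c
            steps.append((h, z, r, rh, c_pre, c))
            h = h_new
        cache["steps"] = steps

        if use_drop:
            hmask = (rng.random(h.shape) < keep).astype(self.dtype) / keep
            h = h * hmask
        else:
            hmask = None
        cache["hmask"] = hmask
        cache["h_final"] = h

        logits = h @ p["Wo"] + p["bo"]
        probs = softmax(logits)
        cache["probs"] = probs
        return probs, cache

    # ----- loss and backward -------------------------------------------

    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        class_weights: np.ndarray,
        rng: np.random.Generator | None = None,
        train: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Class-weighted categorical cross-entropy and its gradients.

        loss = mean_i  w[y_i] * (-log p_i[y_i])
        """
        probs, cache = self.forward(X, train=train, rng=rng)
        B, T, _ = cache["X"].shape
        y = np.asarray(y, dtype=np.int64)
        w = np.asarray(class_weights, dtype=self.dtype)[y]  # (B,)
        eps = np.finfo(self.dtype).tiny
        loss = float(np.mean(w * -np.log(probs[np.arange(B), y] + eps)))

        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (w / B)[:, None]

        h = cache["h_final"]
        grads["Wo"] = h.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T
        if cache["hmask"] is not None:
            dh = dh * cache["hmask"]

        _, act_grad = self._act()
        G = self.gru_units
        dXz = np.zeros((B, T, G), dtype=self.dtype)
        dXr = np.zeros((B, T, G), dtype=self.dtype)
        dXc = np.zeros((B, T, G), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, z, r, rh, c_pre, c = cache["steps"][t]
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1.0 - z)

            dc_pre = dc * act_grad(c_pre)
            dXc[:, t] = dc_pre
            grads["Ug_c"] += rh.T @ dc_pre
            drh = dc_pre @ p["Ug_c"].T
            dr = drh * h_prev
            dh_prev += drh * r

            dz_pre = dz * z * (1.0 - z)
            dXz[:, t] = dz_pre
            grads["Ug_z"] += h_prev.T @ dz_pre
            dh_prev += dz_pre @ p["Ug_z"].T

            dr_pre = dr * r * (1.0 - r)
            dXr[:, t] = dr_pre
            grads["Ug_r"] += h_prev.T @ dr_pre
            dh_prev += dr_pre @ p["Ug_r"].T

            dh = dh_prev

        A_flat = cache["A"].reshape(B * T, self.dense_width)
        dXz_f = dXz.reshape(B * T, G)
        dXr_f = dXr.reshape(B * T, G)
        dXc_f = dXc.reshape(B * T, G)
        grads["Wg_z"] = A_flat.T @ dXz_f
        grads["Wg_r"] = A_flat.T @ dXr_f
        grads["Wg_c"] = A_flat.T @ dXc_f
        grads["bg_z"] = dXz_f.sum(axis=0)
        grads["bg_r"] = dXr_f.sum(axis=0)
        grads["bg_c"] = dXc_f.sum(axis=0)
        da = (dXz_f @ p["Wg_z"].T + dXr_f @ p["Wg_r"].T
              + dXc_f @ p["Wg_c"].T)

        for i in range(self.dense_layers - 1, -1, -1):
            inp, pre = cache["dense"][i]
            mask = cache["masks"][i]
            if mask is not None:
                da = da * mask
            dpre = da * (pre > 0)
            grads[f"W{i}"] = inp.T @ dpre
            grads[f"b{i}"] = dpre.sum(axis=0)
            da = dpre @ p[f"W{i}"].T

        return loss, grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior class probabilities for a batch of windows (no dropout)."""
        probs, _ = self.forward(X, train=False)
        return probs

    # ----- (de)serialization -------------------------------------------

    def get_state(self) -> dict:
        return {
            "n_features": self.n_features,
            "dense_layers": self.dense_layers,
            "dense_width": self.dense_width,
            "gru_units": self.gru_units,
            "n_classes": self.n_classes,
            "dropout": self.dropout,
            "gru_activation": self.gru_activation,
            "dtype": self.dtype.str,
            "params": {k: v.copy() for k, v in self.params.items()},
        }

    @classmethod
    def from_state(cls, state: dict) -> "GRUNet":
        net = cls(
            n_features=state["n_features"],
            dense_layers=state["dense_layers"],
            dense_width=state["dense_width"],
            gru_units=state["gru_units"],
            n_classes=state["n_classes"],
            dropout=state["dropout"],
            gru_activation=state["gru_activation"],
            dtype=np.dtype(state["dtype"]),
        )
        net.params = {k: np.asarray(v) for k, v in state["params"].items()}
        return net


class AdamOptimizer:
    """Adam with bias correction and optional global-norm gradient clipping.

    beta1/beta2/eps use the customary defaults (0.9, 0.999, 1e-8); they are
    recorded in the training log.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )
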