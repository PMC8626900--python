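"""Minimal CPU sequence-to-sequence LSTM with exact backpropagation.

A stack of LSTM layers (tanh cell activation, sigmoid gates), each
returning its full hidden sequence, followed by a time-distributed dense
softmax head that emits one class distribution per timestep. Sized for
tiny wearable-scale models (a 2-layer, 16-unit network has ~4.3k
parameters), where plain numpy is fast enough and keeps training
bit-reproducible on a given platform.

The forward recurrence is strictly causal: the hidden state at timestep t
depends only on inputs up to t, so prefix predictions equal the prefix of
full-sequence predictions — the property a real-time cueing system needs.

Gradients are computed by full backpropagation through time; the input
projections and weight-gradient contractions are vectorized over time so
the per-timestep Python loop touches only the recurrent coupling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMNetwork", "AdamState", "softmax", "cross_entropy"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # exp(-x) overflows to inf for very negative x and the quotient
    # correctly saturates at 0, so the warning is suppressed
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stable."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood over timesteps."""
    p = probs[np.arange(len(targets)), targets]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


class LSTMNetwork:
    """Stacked LSTM + per-timestep dense softmax head.

    Parameters per LSTM layer: ``Wx (D, 4H)``, ``Wh (H, 4H)``, ``b (4H,)``
    with gate order (input, forget, output, cell); head: ``W (H, C)``,
    ``b (C,)``. Weights start uniform in +-1/sqrt(H); the forget-gate bias
    starts at +1 so early training does not flush the cell state.
    """

    def __init__(
        self,
        n_layers: int,
        units: int,
        n_features: int = 16,
        n_classes: int = 2,
        seed: int = 0,
    ) -> None:
        self.n_layers = n_layers
        self.units = units
        self.n_features = n_features
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(units)
        self.layers: list[dict[str, np.ndarray]] = []
        d = n_features
        for _ in range(n_layers):
            b = np.zeros(4 * units)
            b[units : 2 * units] = 1.0
            self.layers.append(
                {
                    "Wx": rng.uniform(-k, k, size=(d, 4 * units)),
                    "Wh": rng.uniform(-k, k, size=(units, 4 * units)),
                    "b": b,
                }
            )
            d = units
        self.head = {
            "W": rng.uniform(-k, k, size=(units, n_classes)),
            "b": np.zeros(n_classes),
        }

    # -- bookkeeping --------------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer["Wx"], layer["Wh"], layer["b"]])
        out.extend([self.head["W"], self.head["b"]])
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward ------------------------------------------------------------

    def forward(
        self, X: np.ndarray, return_cache: bool = False
    ):
        """Run the full sequence; returns (T, n_classes) probabilities."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected input of shape (T, {self.n_features}), got {X.shape}"
            )
        T = X.shape[0]
        H = self.units
        caches = []
        inp = X
        for layer in self.layers:
            Xp = inp @ layer["Wx"] + layer["b"]  # (T, 4H), vectorized
            Wh = layer["Wh"]
            I = np.empty((T, H))
            F = np.empty((T, H))
            G = np.empty((T, H))
            O = np.empty((T, H))
            C = np.empty((T, H))
            TC = np.empty((T, H))
            Hs = np.empty((T, H))
            h = np.zeros(H)
            c = np.zeros(H)
            for t in range(T):
                z = Xp[t] + h @ Wh
                sg = _sigmoid(z[: 3 * H])
                i, f, o = sg[:H], sg[H : 2 * H], sg[2 * H : 3 * H]
                g = np.tanh(z[3 * H :])
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                I[t], F[t], G[t], O[t], C[t], TC[t], Hs[t] = i, f, g, o, c, tc, h
            caches.append({"X": inp, "I": I, "F": F, "G": G, "O": O, "C": C,
                           "TC": TC, "H": Hs})
            inp = Hs
        logits = inp @ self.head["W"] + self.head["b"]
        probs = softmax(logits)
        if return_cache:
            return probs, caches
        return probs

    # -- backward -----------------------------------------------------------

    def backward(
        self, probs: np.ndarray, caches: list[dict], targets: np.ndarray
    ) -> list[np.ndarray]:
        """Gradients of mean cross-entropy, ordered like :meth:`parameters`."""
        T = len(targets)
        H = self.units
        dlogits = probs.copy()
        dlogits[np.arange(T), targets] -= 1.0
        dlogits /= T
        top = caches[-1]["H"]
        dW_head = top.T @ dlogits
        db_head = dlogits.sum(axis=0)
        dH_out = dlogits @ self.head["W"].T  # (T, H)

        grads_layers: list[list[np.ndarray]] = []
        for li in range(self.n_layers - 1, -1, -1):
            cache = caches[li]
            I, F, G, O = cache["I"], cache["F"], cache["G"], cache["O"]
            C, TC, Hs, X = cache["C"], cache["TC"], cache["H"], cache["X"]
            Wh = self.layers[li]["Wh"]
            dZ = np.empty((T, 4 * H))
            dh_next = np.zeros(H)
            dc_next = np.zeros(H)
            for t in range(T - 1, -1, -1):
                dh = dH_out[t] + dh_next
                dc = dc_next + dh * O[t] * (1.0 - TC[t] ** 2)
                c_prev = C[t - 1] if t > 0 else np.zeros(H)
                di = dc * G[t]
                df = dc * c_prev
                dg = dc * I[t]
                do = dh * TC[t]
                dZ[t, :H] = di * I[t] * (1.0 - I[t])
                dZ[t, H : 2 * H] = df * F[t] * (1.0 - F[t])
                dZ[t, 2 * H : 3 * H] = do * O[t] * (1.0 - O[t])
                dZ[t, 3 * H :] = dg * (1.0 - G[t] ** 2)
                dh_next = dZ[t] @ Wh.T
                dc_next = dc * F[t]
            H_prev = np.vstack([np.zeros((1, H)), Hs[:-1]])
            dWx = X.T @ dZ
            dWh = H_prev.T @ dZ
            db = dZ.sum(axis=0)
            grads_layers.append([dWx, dWh, db])
            dH_out = dZ @ self.layers[li]["Wx"].T  # gradient wrt layer input

        grads: list[np.ndarray] = []
        for g3 in reversed(grads_layers):
            grads.extend(g3)
        grads.extend([dW_head, db_head])
        return grads

    # -- serialization ------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for li, layer in enumerate(self.layers):
            for name, arr in layer.items():
                state[f"layer{li}_{name}"] = arr
        state["head_W"] = self.head["W"]
        state["head_b"] = self.head["b"]
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer:
                layer[name] = np.asarray(state[f"layer{li}_{name}"], dtype=np.float64)
        self.head["W"] = np.asarray(state["head_W"], dtype=np.float64)
        self.head["b"] = np.asarray(state["head_b"], dtype=np.float64)


class AdamState:
    """Adam optimizer state for a fixed parameter list."""

    def __init__(
        self,
        params: list[np.ndarray],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(
        self, params: list[np.ndarray], grads: list[np.ndarray], lr: float
    ) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
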