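"""Sequence tagger: a stacked LSTM with peepholes and coupled gates.

Tags every token of a sentence as drug (1) or non-drug (0) from the
200-length per-token inputs of the sequence representation (word vector
concatenated with the distance block).  The recurrent cell is the
peephole variant with *coupled* input/forget gates (f = 1 - i):

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + p_i * c_{t-1} + b_i)
    g_t = tanh   (W_g x_t + U_g h_{t-1}               + b_g)
    c_t = (1 - i_t) * c_{t-1} + i_t * g_t
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + p_o * c_t   + b_o)
    h_t = o_t * tanh(c_t)

Two such layers are stacked; a single sigmoid output unit reads the top
hidden state per timestep.  The loss is per-token sum-of-squares on the
sigmoid output.  Training is per-sequence gradient descent with momentum,
backpropagating each timestep's error at most ``bptt_truncate`` steps back
(the "time frame" of the training setup).  Everything is seeded and
single-threaded, so fits are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .represent import SequenceSample


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class _Layer:
    """Parameter bundle for one recurrent layer."""

    KEYS = ("Wi", "Ui", "pi", "bi", "Wg", "Ug", "bg", "Wo", "Uo", "po", "bo")

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        r = np.sqrt(6.0 / (n_in + n_hidden))
        rr = np.sqrt(6.0 / (2 * n_hidden))
        self.Wi = rng.uniform(-r, r, (n_in, n_hidden))
        self.Ui = rng.uniform(-rr, rr, (n_hidden, n_hidden))
        self.pi = np.zeros(n_hidden)
        self.bi = np.zeros(n_hidden)
        self.Wg = rng.uniform(-r, r, (n_in, n_hidden))
        self.Ug = rng.uniform(-rr, rr, (n_hidden, n_hidden))
        self.bg = np.zeros(n_hidden)
        self.Wo = rng.uniform(-r, r, (n_in, n_hidden))
        self.Uo = rng.uniform(-rr, rr, (n_hidden, n_hidden))
        self.po = np.zeros(n_hidden)
        self.bo = np.zeros(n_hidden)


class LSTMTagger(BaseEstimator):
    """Binary per-token sequence tagger.

    Parameters (defaults are the experiment settings: 2 stacked layers,
    learning rate 0.001, momentum 0.9, 30 epochs, truncation window 2):

    hidden_units : units per recurrent layer (the smallest working network
        in the original experiments used 2)
    bptt_truncate : how many timesteps each output error flows back
    threshold : probability cutoff for the binary prediction

    Fitted attributes: ``layers_``, ``w_out_``, ``b_out_``,
    ``loss_curve_`` (mean per-token loss per epoch, length = epochs).
    """

    def __init__(
        self,
        hidden_units: int = 2,
        n_layers: int = 2,
        learning_rate: float = 0.001,
        momentum: float = 0.9,
        epochs: int = 30,
        bptt_truncate: int = 2,
        threshold: float = 0.5,
        shuffle: bool = True,
        seed: int = 0,
    ):
        self.hidden_units = hidden_units
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.bptt_truncate = bptt_truncate
        self.threshold = threshold
        self.shuffle = shuffle
        self.seed = seed

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, list[dict]]:
        """Run the stack over one (T, n_in) sequence; cache per-layer states."""
        T = x.shape[0]
        H = self.hidden_units
        caches = []
        inp = x
        for layer in self.layers_:
            i_s = np.zeros((T, H))
            g_s = np.zeros((T, H))
            o_s = np.zeros((T, H))
            c_s = np.zeros((T, H))
            h_s = np.zeros((T, H))
            h_prev = np.zeros(H)
            c_prev = np.zeros(H)
            for t in range(T):
                xt = inp[t]
                i = _sigmoid(xt @ layer.Wi + h_prev @ layer.Ui + layer.pi * c_prev + layer.bi)
                g = np.tanh(xt @ layer.Wg + h_prev @ layer.Ug + layer.bg)
                c = (1.0 - i) * c_prev + i * g
                o = _sigmoid(xt @ layer.Wo + h_prev @ layer.Uo + layer.po * c + layer.bo)
                h = o * np.tanh(c)
                i_s[t], g_s[t], o_s[t], c_s[t], h_s[t] = i, g, o, c, h
                h_prev, c_prev = h, c
            caches.append({"x": inp, "i": i_s, "g": g_s, "o": o_s, "c": c_s, "h": h_s})
            inp = h_s
        probs = _sigmoid(inp @ self.w_out_ + self.b_out_)
        return probs, caches

    # -- backward ----------------------------------------------------------

    def _backward(
        self, probs: np.ndarray, y: np.ndarray, caches: list[dict]
    ) -> tuple[list[dict], np.ndarray, float, float]:
        """Truncated-BPTT gradients for one sequence (mean over tokens).

        Every output timestep t0 backpropagates its error at most
        ``bptt_truncate`` steps; the loop over origins is vectorized, so
        each back-step processes all origins at once via arrays shifted by
        the step count.  The output-layer error signal is the logistic
        shortcut ``p - y`` (the squared-error-through-sigmoid factor
        ``p(1-p)`` vanishes exactly where a confidently wrong output needs
        the largest correction, which freezes training on imbalanced
        tags); the monitored loss stays the mean squared error.
        """
        T = len(y)
        H = self.hidden_units
        top_h = caches[-1]["h"]
        e = probs - y
        dz_out = e / T
        gw_out = top_h.T @ dz_out
        gb_out = float(dz_out.sum())

        grads = [
            {k: np.zeros_like(getattr(layer, k)) for k in _Layer.KEYS}
            for layer in self.layers_
        ]

        def shift(A: np.ndarray, b: int) -> np.ndarray:
            """S[t0] = A[t0 - b] (zero-padded): cached value at back-step b."""
            if b == 0:
                return A
            S = np.zeros_like(A)
            S[b:] = A[:-b]
            return S

        nl = len(self.layers_)
        # per-layer gradient carried across back-steps, indexed by origin t0
        DH = [np.zeros((T, H)) for _ in range(nl)]
        DC = [np.zeros((T, H)) for _ in range(nl)]
        DH[-1] = np.outer(dz_out, self.w_out_)
        for back in range(self.bptt_truncate):
            valid = np.zeros((T, 1))
            valid[back:] = 1.0  # origins with t0 - back >= 0
            DX = None
            for li in range(nl - 1, -1, -1):
                layer = self.layers_[li]
                cache = caches[li]
                dh = DH[li] if DX is None else DH[li] + DX
                dh = dh * valid
                dc_in = DC[li] * valid
                i = shift(cache["i"], back)
                g = shift(cache["g"], back)
                o = shift(cache["o"], back)
                c = shift(cache["c"], back)
                x_t = shift(cache["x"], back)
                h_prev = shift(cache["h"], back + 1)
                c_prev = shift(cache["c"], back + 1)
                tc = np.tanh(c)

                do = dh * tc
                dzo = do * o * (1.0 - o)
                dc = dh * o * (1.0 - tc**2) + dc_in + dzo * layer.po
                dg = dc * i
                dzg = dg * (1.0 - g**2)
                di = dc * (g - c_prev)
                dzi = di * i * (1.0 - i)

                gr = grads[li]
                gr["Wi"] += x_t.T @ dzi
                gr["Ui"] += h_prev.T @ dzi
                gr["pi"] += (c_prev * dzi).sum(axis=0)
                gr["bi"] += dzi.sum(axis=0)
                gr["Wg"] += x_t.T @ dzg
                gr["Ug"] += h_prev.T @ dzg
                gr["bg"] += dzg.sum(axis=0)
                gr["Wo"] += x_t.T @ dzo
                gr["Uo"] += h_prev.T @ dzo
                gr["po"] += (c * dzo).sum(axis=0)
                gr["bo"] += dzo.sum(axis=0)

                DC[li] = dc * (1.0 - i) + dzi * layer.pi
                DH[li] = dzi @ layer.Ui.T + dzg @ layer.Ug.T + dzo @ layer.Uo.T
                DX = (
                    dzi @ layer.Wi.T + dzg @ layer.Wg.T + dzo @ layer.Wo.T
                    if li > 0
                    else None
                )
        loss = 0.5 * float((e**2).mean())
        return grads, np.asarray(gw_out), gb_out, loss

    # -- sklearn-ish API ---------------------------------------------------

    def fit(self, samples: list[SequenceSample]) -> "LSTMTagger":
        if not samples:
            raise ValueError("no training sequences")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        n_in = samples[0].x.shape[1]
        for s in samples:
            if s.x.shape[1] != n_in:
                raise ValueError("inconsistent input widths")
            if s.x.shape[0] != len(s.y):
                raise ValueError("labels do not align with inputs")
        rng = np.random.default_rng(self.seed)
        H = self.hidden_units
        self.n_features_in_ = n_in
        self.layers_ = [
            _Layer(n_in if li == 0 else H, H, rng) for li in range(self.n_layers)
        ]
        self.w_out_ = rng.uniform(-np.sqrt(6.0 / (H + 1)), np.sqrt(6.0 / (H + 1)), H)
        self.b_out_ = 0.0

        vel = [
            {k: np.zeros_like(getattr(layer, k)) for k in _Layer.KEYS}
            for layer in self.layers_
        ]
        vel_w_out = np.zeros(H)
        vel_b_out = 0.0

        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(len(samples)) if self.shuffle else np.arange(len(samples))
            losses = []
            for si in order:
                s = samples[si]
                probs, caches = self._forward(s.x)
                grads, gw_out, gb_out, loss = self._backward(
                    probs, s.y.astype(float), caches
                )
                losses.append(loss)
                for li, layer in enumerate(self.layers_):
                    for k in _Layer.KEYS:
                        vel[li][k] = (
                            self.momentum * vel[li][k]
                            - self.learning_rate * grads[li][k]
                        )
                        setattr(layer, k, getattr(layer, k) + vel[li][k])
                vel_w_out = self.momentum * vel_w_out - self.learning_rate * gw_out
                vel_b_out = self.momentum * vel_b_out - self.learning_rate * gb_out
                self.w_out_ = self.w_out_ + vel_w_out
                self.b_out_ = self.b_out_ + vel_b_out
            self.loss_curve_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, sample: SequenceSample) -> np.ndarray:
        """Per-token drug probability, strictly inside (0, 1)."""
        check_is_fitted(self, "layers_")
        if sample.x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected width {self.n_features_in_}, got {sample.x.shape[1]}"
            )
        probs, _ = self._forward(sample.x)
        return probs

    def predict(self, sample: SequenceSample, threshold: float | None = None) -> np.ndarray:
        th = self.threshold if threshold is None else threshold
        return (self.predict_proba(sample) >= th).astype(np.int64)
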