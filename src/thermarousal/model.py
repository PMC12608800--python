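"""Bidirectional LSTM sequence classifier over 30-frame feature windows.

Every labelled frame whose trailing one-second window (lookback 30) is
fully valid becomes a training sample: a ``lookback × 11`` feature window
whose target is the label of its last frame (0 = arousal, 1 =
non-arousal).  The classifier is a single bidirectional LSTM layer — 100
units per direction, final forward and backward hidden states concatenated
into a 200-d vector — feeding one sigmoid output unit, trained with
binary cross-entropy and Adam (step size 0.001, batch 1024, 100 epochs).

The network is implemented directly on numpy (vectorised forward pass and
backpropagation through time, float32), seeded end to end so a fixed seed
reproduces every downstream number.  Features are z-scored per column
with statistics from the training fold before entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .io_streams import LabelTrack


@dataclass(frozen=True)
class ModelConfig:
    """Training hyperparameters (defaults: the study configuration)."""

    lookback: int = 30
    hidden_units: int = 100
    batch_size: int = 1024
    epochs: int = 100
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lookback < 1 or self.hidden_units < 1:
            raise ValueError("lookback and hidden_units must be >= 1")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class WindowedDataset:
    """Sliding windows of valid frames with the last frame's label."""

    windows: np.ndarray          # (n, lookback, n_features)
    targets: np.ndarray          # (n,) in {0, 1}
    groups: np.ndarray           # (n,) participant id per window
    frame_index: np.ndarray      # (n,) index of each window's last frame

    def __post_init__(self) -> None:
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n, lookback, features)")
        if not np.isin(self.targets, (0, 1)).all():
            raise ValueError("targets must be binary")


@dataclass
class PredictionTrack:
    """Per-frame model output: probability of class 1 (non-arousal), the
    thresholded raw label and the majority-corrected label.  Probabilities
    are NaN and labels −1 exactly where no full valid window exists."""

    prob: np.ndarray
    raw_label: np.ndarray
    corrected_label: np.ndarray

    def __post_init__(self) -> None:
        defined = np.isfinite(self.prob)
        if defined.any():
            p = self.prob[defined]
            if p.min() < 0 or p.max() > 1:
                raise ValueError("probabilities must lie in [0, 1]")


def make_windows(features: FeatureMatrix, labels: LabelTrack,
                 cfg: ModelConfig | None = None,
                 participant_id: str = "") -> WindowedDataset:
    """Build stride-1 trailing windows over jointly valid, labelled frames.

    Frame ``f`` yields a window when frames ``[f-lookback+1, f]`` are all
    valid and ``labels[f] != -1``; the target is ``labels[f]``.
    """
    cfg = cfg or ModelConfig()
    if features.n_frames != labels.n_frames:
        raise ValueError("features and labels must share n_frames")
    ends = _window_ends(features.valid, cfg.lookback)
    ends = ends[labels.labels[ends] != -1]
    if ends.size == 0:
        raise ValueError("no frame has a fully valid labelled window")
    windows = _gather_windows(features.values, ends, cfg.lookback)
    return WindowedDataset(
        windows=windows,
        targets=labels.labels[ends].astype(np.int8),
        groups=np.full(ends.size, participant_id, dtype=object),
        frame_index=ends,
    )


def _window_ends(valid: np.ndarray, lookback: int) -> np.ndarray:
    """Indices f such that frames [f-lookback+1, f] are all valid."""
    v = np.asarray(valid, dtype=float)
    run = np.convolve(v, np.ones(lookback), mode="full")[:v.size]
    return np.flatnonzero(run >= lookback)


def _gather_windows(values: np.ndarray, ends: np.ndarray,
                    lookback: int) -> np.ndarray:
    offs = np.arange(-lookback + 1, 1)
    return values[ends[:, None] + offs[None, :]].astype(np.float32)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTMDirection:
    """One direction of the recurrent layer: parameters and BPTT."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        h = hidden
        lim_x = np.sqrt(6.0 / (n_in + 4 * h))
        lim_h = np.sqrt(6.0 / (h + 4 * h))
        self.wx = rng.uniform(-lim_x, lim_x, (n_in, 4 * h)).astype(np.float32)
        self.wh = rng.uniform(-lim_h, lim_h, (h, 4 * h)).astype(np.float32)
        self.b = np.zeros(4 * h, dtype=np.float32)
        self.b[h:2 * h] = 1.0  # forget-gate bias
        self.hidden = h

    def params(self) -> list[np.ndarray]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray, want_cache: bool):
        """x: (B, T, D) already in this direction's time order.
        Returns final hidden state (B, H) and the BPTT cache."""
        bsz, tlen, _ = x.shape
        h = self.hidden
        hs = np.zeros((tlen + 1, bsz, h), dtype=np.float32)
        cs = np.zeros((tlen + 1, bsz, h), dtype=np.float32)
        gates = np.empty((tlen, bsz, 4 * h), dtype=np.float32) \
            if want_cache else None
        ht = hs[0]
        ct = cs[0]
        for t in range(tlen):
            z = x[:, t, :] @ self.wx + ht @ self.wh + self.b
            zi = _sigmoid(z[:, :h])
            zf = _sigmoid(z[:, h:2 * h])
            zg = np.tanh(z[:, 2 * h:3 * h])
            zo = _sigmoid(z[:, 3 * h:])
            ct = zf * ct + zi * zg
            ht = zo * np.tanh(ct)
            hs[t + 1] = ht
            cs[t + 1] = ct
            if want_cache:
                gates[t, :, :h] = zi
                gates[t, :, h:2 * h] = zf
                gates[t, :, 2 * h:3 * h] = zg
                gates[t, :, 3 * h:] = zo
        cache = (x, hs, cs, gates) if want_cache else None
        return ht, cache

    def backward(self, dh_final: np.ndarray, cache):
        """Gradient of the loss w.r.t. parameters given d(final hidden)."""
        x, hs, cs, gates = cache
        bsz, tlen, _ = x.shape
        h = self.hidden
        dwx = np.zeros_like(self.wx)
        dwh = np.zeros_like(self.wh)
        db = np.zeros_like(self.b)
        dh = dh_final.astype(np.float32)
        dc = np.zeros_like(dh)
        for t in range(tlen - 1, -1, -1):
            zi = gates[t, :, :h]
            zf = gates[t, :, h:2 * h]
            zg = gates[t, :, 2 * h:3 * h]
            zo = gates[t, :, 3 * h:]
            tc = np.tanh(cs[t + 1])
            dzo = dh * tc * zo * (1.0 - zo)
            dc = dc + dh * zo * (1.0 - tc * tc)
            dzi = dc * zg * zi * (1.0 - zi)
            dzf = dc * cs[t] * zf * (1.0 - zf)
            dzg = dc * zi * (1.0 - zg * zg)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            dwx += x[:, t, :].T @ dz
            dwh += hs[t].T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.wh.T
            dc = dc * zf
        return [dwx, dwh, db]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) \
            / (1.0 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class BLSTMClassifier:
    """Trained bidirectional LSTM with its feature scaler and config."""

    def __init__(self, cfg: ModelConfig, n_features: int,
                 columns: tuple[str, ...]):
        self.cfg = cfg
        self.n_features = n_features
        self.columns = tuple(columns)
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_units
        self.fwd = _LSTMDirection(n_features, h, rng)
        self.bwd = _LSTMDirection(n_features, h, rng)
        lim = np.sqrt(6.0 / (2 * h + 1))
        self.w_out = rng.uniform(-lim, lim, (2 * h, 1)).astype(np.float32)
        self.b_out = np.zeros(1, dtype=np.float32)
        self.mu = np.zeros(n_features)
        self.sigma = np.ones(n_features)
        self.history: list[float] = []

    # -- scaling ----------------------------------------------------------
    def _fit_scaler(self, windows: np.ndarray) -> None:
        flat = windows.reshape(-1, windows.shape[-1]).astype(np.float64)
        self.mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        self.sigma = np.where(sd > 0, sd, 1.0)

    def _scale(self, windows: np.ndarray) -> np.ndarray:
        z = (windows.astype(np.float64) - self.mu) / self.sigma
        return z.astype(np.float32)

    # -- forward ----------------------------------------------------------
    def _forward(self, xb: np.ndarray, want_cache: bool):
        hf, cache_f = self.fwd.forward(xb, want_cache)
        hb, cache_b = self.bwd.forward(xb[:, ::-1, :], want_cache)
        hcat = np.concatenate([hf, hb], axis=1)
        logits = hcat @ self.w_out + self.b_out
        return logits[:, 0], hcat, cache_f, cache_b

    def predict_proba(self, windows: np.ndarray,
                      scaled: bool = False) -> np.ndarray:
        """Probability of class 1 (non-arousal) for each window."""
        x = windows if scaled else self._scale(windows)
        out = np.empty(x.shape[0], dtype=np.float64)
        bs = self.cfg.batch_size
        for s in range(0, x.shape[0], bs):
            logits, _, _, _ = self._forward(x[s:s + bs], want_cache=False)
            out[s:s + bs] = _sigmoid(logits.astype(np.float64))
        return out

    # -- training ---------------------------------------------------------
    def fit(self, data: WindowedDataset) -> "BLSTMClassifier":
        cfg = self.cfg
        classes = np.unique(data.targets)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        self._fit_scaler(data.windows)
        x = self._scale(data.windows)
        y = data.targets.astype(np.float32)
        rng = np.random.default_rng(cfg.seed + 1)
        params = (self.fwd.params() + self.bwd.params()
                  + [self.w_out, self.b_out])
        opt = _Adam(params, cfg.learning_rate)
        n = x.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits, hcat, cf, cb = self._forward(xb, want_cache=True)
                p = _sigmoid(logits)
                eps = 1e-7
                pc = np.clip(p, eps, 1.0 - eps)
                loss = -np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))
                epoch_loss += loss * len(idx)
                dlogit = ((p - yb) / len(idx)).astype(np.float32)
                dw_out = hcat.T @ dlogit[:, None]
                db_out = np.array([dlogit.sum()], dtype=np.float32)
                dhcat = dlogit[:, None] @ self.w_out.T
                h = cfg.hidden_units
                g_f = self.fwd.backward(dhcat[:, :h], cf)
                g_b = self.bwd.backward(dhcat[:, h:], cb)
                opt.step(g_f + g_b + [dw_out, db_out])
            self.history.append(epoch_loss / n)
        if not np.isfinite(self.history[-1]):
            raise RuntimeError("training diverged: non-finite loss")
        return self


def train(data: WindowedDataset,
          cfg: ModelConfig | None = None,
          columns: tuple[str, ...] = ()) -> BLSTMClassifier:
    """Train the bidirectional LSTM on a windowed dataset.

    Deterministic given ``cfg.seed``: parameter initialisation and the
    per-epoch shuffle both derive from it.
    """
    cfg = cfg or ModelConfig()
    model = BLSTMClassifier(cfg, data.windows.shape[-1], columns)
    return model.fit(data)


def predict(model: BLSTMClassifier, features: FeatureMatrix,
            cfg: ModelConfig | None = None) -> PredictionTrack:
    """Per-frame arousal probability track for one participant.

    Probability is defined exactly for frames with a full valid trailing
    window; elsewhere it is NaN and the labels are −1.  Raw and corrected
    labels are left at −1 here — thresholding and correction live in the
    decision stage.
    """
    cfg = cfg or model.cfg
    if features.values.shape[1] != model.n_features or (
            model.columns and tuple(features.columns) != model.columns):
        raise ValueError("feature schema does not match the trained model")
    ends = _window_ends(features.valid, cfg.lookback)
    if ends.size == 0:
        raise ValueError("no frame has a fully valid window")
    windows = _gather_windows(features.values, ends, cfg.lookback)
    probs = model.predict_proba(windows)
    n = features.n_frames
    prob = np.full(n, np.nan)
    prob[ends] = probs
    labels = np.full(n, -1, dtype=int)
    return PredictionTrack(prob=prob, raw_label=labels.copy(),
                           corrected_label=labels.copy())
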