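"""Recurrent-network Pmus estimator trained on simulator output.

A deliberately small sequence-to-sequence Elman network (single recurrent
layer, tanh units, linear readout) maps per-timestep (Paw, flow, volume) to
Pmus. It demonstrates learning the effort waveform from airway signals alone
— the concept behind embedded ventilator estimators — at desk scale: a few
minutes of CPU training on a few dozen synthetic records. The transparent
model-based inversion in :mod:`pvsim.estimator` remains the primary method;
this estimator is optional and the rest of the package does not depend on it.

Training is deterministic given the seed. The train/eval split is enforced at
scenario level (records of one scenario never appear on both sides). Weights
and normalization constants are saved as an ``.npz`` plus a JSON sidecar with
the split manifest and hyperparameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .waveform import BreathSignals

__all__ = [
    "RecurrentEstimator",
    "build_training_records",
    "train_recurrent_estimator",
    "evaluate_recurrent",
]


@dataclass
class RecurrentEstimator:
    """Trained Elman-network Pmus estimator (weights + normalization)."""

    Wx: np.ndarray  # (3, hidden)
    Wh: np.ndarray  # (hidden, hidden)
    b: np.ndarray  # (hidden,)
    wo: np.ndarray  # (hidden,)
    bo: float
    x_mean: np.ndarray  # (3,)
    x_std: np.ndarray  # (3,)
    seed: int
    train_scenario_ids: tuple[int, ...] = ()
    eval_scenario_ids: tuple[int, ...] = ()
    hyperparams: dict = field(default_factory=dict)

    @property
    def hidden(self) -> int:
        return self.Wx.shape[1]

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        """Run the network over a (n, 3) feature sequence -> (n,) Pmus."""
        Xn = (X - self.x_mean) / self.x_std
        h = np.zeros(self.hidden)
        out = np.empty(X.shape[0])
        for t in range(X.shape[0]):
            h = np.tanh(Xn[t] @ self.Wx + h @ self.Wh + self.b)
            out[t] = h @ self.wo + self.bo
        return np.maximum(out, 0.0)  # muscle pressure is displayed nonnegative

    def predict(self, signals: BreathSignals) -> np.ndarray:
        X = np.column_stack([signals.paw, signals.flow, signals.volume])
        return self.predict_features(X)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            Wx=self.Wx, Wh=self.Wh, b=self.b, wo=self.wo, bo=np.array([self.bo]),
            x_mean=self.x_mean, x_std=self.x_std,
        )
        sidecar = {
            "seed": self.seed,
            "train_scenario_ids": list(self.train_scenario_ids),
            "eval_scenario_ids": list(self.eval_scenario_ids),
            "hyperparams": self.hyperparams,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RecurrentEstimator":
        path = Path(path)
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        dat = np.load(npz_path)
        side = json.loads(Path(str(npz_path) + ".json").read_text())
        return cls(
            Wx=dat["Wx"], Wh=dat["Wh"], b=dat["b"], wo=dat["wo"], bo=float(dat["bo"][0]),
            x_mean=dat["x_mean"], x_std=dat["x_std"],
            seed=int(side["seed"]),
            train_scenario_ids=tuple(side["train_scenario_ids"]),
            eval_scenario_ids=tuple(side["eval_scenario_ids"]),
            hyperparams=side["hyperparams"],
        )


def build_training_records(
    scenario_ids: Sequence[int],
    seed: int = 0,
    noise_sd: float = 0.05,
    battery=None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Render battery scenarios to (features, target) training pairs.

    A little measurement noise on the rendered channels acts as augmentation;
    the target stays the noiseless gold Pmus.
    """
    from .battery import build_default_battery, render_scenario

    if battery is None:
        battery = build_default_battery()
    by_id = {s.scenario_id: s for s in battery}
    records = []
    for sid in scenario_ids:
        r = render_scenario(by_id[sid], seed=seed, noise_sd=noise_sd)
        X = np.column_stack([r.signals.paw, r.signals.flow, r.signals.volume])
        records.append((X, r.signals.pmus_true.copy()))
    return records


def train_recurrent_estimator(
    train_records: Sequence[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
    hidden: int = 32,
    epochs: int = 60,
    chunk_len: int = 300,
    batch_size: int = 32,
    lr: float = 0.01,
    train_scenario_ids: Sequence[int] = (),
    eval_scenario_ids: Sequence[int] = (),
) -> RecurrentEstimator:
    """Train the Elman network with Adam on truncated-BPTT chunks.

    ``train_scenario_ids`` / ``eval_scenario_ids`` document the split in the
    artifact; overlapping splits are rejected (leakage across 30-s records of
    one scenario).
    """
    overlap = set(train_scenario_ids) & set(eval_scenario_ids)
    if overlap:
        raise ValueError(f"train/eval scenario overlap: {sorted(overlap)}")
    rng = np.random.default_rng(seed)

    X_all = np.concatenate([r[0] for r in train_records], axis=0)
    x_mean = X_all.mean(axis=0)
    x_std = X_all.std(axis=0)
    x_std[x_std < 1e-9] = 1.0

    # slice each record into fixed-length chunks (state reset per chunk)
    chunks_X, chunks_y = [], []
    for X, y in train_records:
        Xn = (X - x_mean) / x_std
        for a in range(0, X.shape[0] - chunk_len + 1, chunk_len):
            chunks_X.append(Xn[a : a + chunk_len])
            chunks_y.append(y[a : a + chunk_len])
    CX = np.stack(chunks_X)  # (n_chunks, T, 3)
    CY = np.stack(chunks_y)  # (n_chunks, T)
    n_chunks = CX.shape[0]

    def init(shape, scale):
        return rng.normal(0.0, scale, shape)

    Wx = init((3, hidden), 0.3)
    Wh = init((hidden, hidden), 1.0 / np.sqrt(hidden) * 0.5)
    b = np.zeros(hidden)
    wo = init((hidden,), 0.3)
    bo = 0.0

    params = [Wx, Wh, b, wo]
    m_adam = [np.zeros_like(p) for p in params] + [0.0]
    v_adam = [np.zeros_like(p) for p in params] + [0.0]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    for epoch in range(epochs):
        order = rng.permutation(n_chunks)
        for start in range(0, n_chunks, batch_size):
            idx = order[start : start + batch_size]
            Xb = CX[idx]  # (B, T, 3)
            Yb = CY[idx]  # (B, T)
            B, T, _ = Xb.shape

            # forward
            H = np.empty((T, B, hidden))
            h = np.zeros((B, hidden))
            for t in range(T):
                h = np.tanh(Xb[:, t] @ Wx + h @ Wh + b)
                H[t] = h
            pred = H @ wo + bo  # (T, B)
            err = pred - Yb.T  # (T, B)

            # backward (BPTT)
            gWx = np.zeros_like(Wx)
            gWh = np.zeros_like(Wh)
            gb = np.zeros_like(b)
            gwo = (H * err[:, :, None]).sum(axis=(0, 1)) * (2.0 / err.size)
            gbo = float(err.sum()) * (2.0 / err.size)
            dh_next = np.zeros((B, hidden))
            scale = 2.0 / err.size
            for t in range(T - 1, -1, -1):
                dh = err[t][:, None] * wo[None, :] * scale + dh_next
                dpre = dh * (1.0 - H[t] ** 2)
                gWx += Xb[:, t].T @ dpre
                hprev = H[t - 1] if t > 0 else np.zeros((B, hidden))
                gWh += hprev.T @ dpre
                gb += dpre.sum(axis=0)
                dh_next = dpre @ Wh.T

            grads = [gWx, gWh, gb, gwo, gbo]
            # global-norm gradient clipping for recurrent stability
            gnorm = np.sqrt(sum(float(np.sum(np.square(g))) for g in grads))
            if gnorm > 5.0:
                grads = [g * (5.0 / gnorm) for g in grads]

            step += 1
            all_params = params + [bo]
            new_params = []
            for i, (p, g) in enumerate(zip(all_params, grads)):
                m_adam[i] = beta1 * m_adam[i] + (1 - beta1) * g
                v_adam[i] = beta2 * v_adam[i] + (1 - beta2) * np.square(g)
                mhat = m_adam[i] / (1 - beta1**step)
                vhat = v_adam[i] / (1 - beta2**step)
                new_params.append(p - lr * mhat / (np.sqrt(vhat) + eps))
            Wx, Wh, b, wo = new_params[:4]
            bo = float(new_params[4])
            params = [Wx, Wh, b, wo]

    return RecurrentEstimator(
        Wx=Wx, Wh=Wh, b=b, wo=wo, bo=bo,
        x_mean=x_mean, x_std=x_std, seed=seed,
        train_scenario_ids=tuple(train_scenario_ids),
        eval_scenario_ids=tuple(eval_scenario_ids),
        hyperparams=dict(
            hidden=hidden, epochs=epochs, chunk_len=chunk_len,
            batch_size=batch_size, lr=lr,
        ),
    )


def evaluate_recurrent(
    est: RecurrentEstimator, records: Sequence[tuple[np.ndarray, np.ndarray]]
) -> dict:
    """Pooled rms error (cmH2O) and mean absolute estimate of the network on
    (features, gold) records."""
    ses, abss, n = 0.0, 0.0, 0
    for X, y in records:
        pred = est.predict_features(X)
        ses += float(np.sum((pred - y) ** 2))
        abss += float(np.sum(np.abs(pred)))
        n += y.size
    return {"rms_error_cmh2o": float(np.sqrt(ses / n)), "mean_abs_estimate_cmh2o": abss / n}
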