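"""Bidirectional LSTM sequence classifier with class-modeling training sets.

The classifier reads a T x 4 feature sequence (instantaneous frequency,
spectral entropy, fuzzy recurrence image entropy, fuzzy recurrence entropy)
forward and backward through two LSTM layers, concatenates the two final
hidden states, and maps them through a dense layer and softmax to class
probabilities. Training minimizes cross-entropy with Adam (initial learning
rate 0.01), an L2 penalty on the weight matrices, and global-norm gradient
clipping at 1 — the configuration is deliberately the plain recurrent-network
recipe, with sigmoid gate activations and last-time-step readout.

Class modeling builds the training set for a designated target class: all of
that class's training samples, plus — for every other class — a single donor
sample replicated to match the target-class count. The network thus learns
one class against repeated copies of single counter-examples, which also
balances unbalanced data by construction.

Everything is implemented in NumPy; training is deterministic given the
seed (parameter init and epoch shuffling are the only random elements).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

N_CHANNELS = 4
CHANNEL_NAMES = ("if_hz", "se", "frie", "fre")

CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Feature sequences and standardization
# ---------------------------------------------------------------------------

@dataclass
class FeatureSequence:
    """T x 4 feature matrix, channel order (IF, SE, FRIE, FRE)."""

    data: np.ndarray
    label: object = None
    source_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[1] != N_CHANNELS:
            raise ValueError(f"expected a T x {N_CHANNELS} matrix, got shape {d.shape}")
        if d.shape[0] < 1:
            raise ValueError("sequence must have at least one time step")
        if not np.all(np.isfinite(d)):
            raise ValueError("sequence contains non-finite values")
        self.data = d

    def __len__(self) -> int:
        return self.data.shape[0]


def assemble_features(tfseq, tsseq, label=None, source_id: str = "") -> FeatureSequence:
    """Stack TF (IF, SE) and TS (FRIE, FRE) sequences into a T x 4 matrix."""
    t_tf = len(tfseq)
    t_ts = len(tsseq)
    if t_tf != t_ts:
        raise ValueError(
            f"TF sequence length {t_tf} does not match TS sequence length {t_ts}"
        )
    data = np.column_stack([tfseq.if_hz, tfseq.se, tsseq.frie, tsseq.fre])
    return FeatureSequence(data=data, label=label, source_id=source_id)


@dataclass
class Standardizer:
    """Per-channel (mean, sd) learned on training data; sd floored at 1e-8."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, seq: FeatureSequence) -> np.ndarray:
        return (seq.data - self.mean) / self.sd


def fit_standardizer(train: list[FeatureSequence]) -> Standardizer:
    """Pool all time steps of all training sequences, per channel."""
    if not train:
        raise ValueError("cannot fit a standardizer on an empty training set")
    pooled = np.concatenate([s.data for s in train], axis=0)
    mean = pooled.mean(axis=0)
    sd = np.maximum(pooled.std(axis=0), 1e-8)
    return Standardizer(mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# Class modeling
# ---------------------------------------------------------------------------

def build_class_modeling_set(
    train: list[FeatureSequence],
    target_class,
    donor_index: int | None = None,
    replication_count: int | None = None,
    seed: int = 0,
) -> list[FeatureSequence]:
    """Target-class samples plus replicated single donors from other classes.

    For every class other than ``target_class``, one donor sample is chosen
    from the training split (by ``donor_index``, or the first sample under a
    seeded shuffle when None) and replicated ``replication_count`` times
    (defaulting to the target-class sample count), so the set is balanced.
    """
    by_class: dict[object, list[FeatureSequence]] = {}
    for s in train:
        by_class.setdefault(s.label, []).append(s)
    if target_class not in by_class:
        raise ValueError(f"target class {target_class!r} absent from training set")
    if len(by_class) < 2:
        raise ValueError("class modeling needs at least one other class")
    target_samples = by_class[target_class]
    n_rep = len(target_samples) if replication_count is None else int(replication_count)
    if n_rep < 1:
        raise ValueError("replication_count must be >= 1")

    rng = np.random.default_rng(seed)
    out = list(target_samples)
    for label in sorted(by_class, key=repr):
        if label == target_class:
            continue
        pool = by_class[label]
        if donor_index is None:
            idx = int(rng.permutation(len(pool))[0])
        else:
            idx = donor_index % len(pool)
        donor = pool[idx]
        out.extend(
            FeatureSequence(
                data=donor.data.copy(),
                label=donor.label,
                source_id=f"{donor.source_id}#copy{k}",
            )
            for k in range(n_rep)
        )
    return out


# ---------------------------------------------------------------------------
# Training configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Bi-LSTM training options.

    ``max_epochs`` defaults to 80, the two-class setting; use 180 for the
    8-class problem. ``batch_size`` is capped at the training-set size so
    small experiments still form full batches. ``early_stop_loss`` (optional)
    halts training once the epoch-mean loss falls below it.
    """

    hidden_size: int = 100
    max_epochs: int = 80
    batch_size: int = 150
    learning_rate: float = 0.01
    grad_clip_norm: float = 1.0
    l2_factor: float = 1e-4
    seed: int = 0
    early_stop_loss: float | None = None

    def __post_init__(self) -> None:
        if (
            self.hidden_size < 1
            or self.max_epochs < 1
            or self.batch_size < 1
            or self.learning_rate <= 0
            or self.grad_clip_norm <= 0
            or self.l2_factor < 0
        ):
            raise ValueError("invalid training configuration")


EPOCHS_TWO_CLASS = 80
EPOCHS_EIGHT_CLASS = 180


def default_epochs(n_classes: int) -> int:
    """80 epochs for two-class problems, 180 for eight-class."""
    return EPOCHS_EIGHT_CLASS if n_classes >= 8 else EPOCHS_TWO_CLASS


# ---------------------------------------------------------------------------
# Bi-LSTM internals
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _init_params(rng: np.random.Generator, d_in: int, hidden: int, n_classes: int) -> dict:
    params = {}
    for direction in ("f", "b"):
        params[f"Wx_{direction}"] = _glorot(rng, (d_in, 4 * hidden))
        params[f"Wh_{direction}"] = _glorot(rng, (hidden, 4 * hidden))
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
        params[f"b_{direction}"] = bias
    params["Wo"] = _glorot(rng, (2 * hidden, n_classes))
    params["bo"] = np.zeros(n_classes)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_forward(x: np.ndarray, Wx, Wh, b, hidden: int):
    """Run an LSTM over x (B x T x D); returns final h and the BPTT cache."""
    B, T, _ = x.shape
    h = np.zeros((B, hidden))
    c = np.zeros((B, hidden))
    cache = []
    H = hidden
    for t in range(T):
        z = x[:, t, :] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((x[:, t, :], h, c, i, f, g, o, tc))
        h, c = h_new, c_new
    return h, cache


def _lstm_backward(dh_last, cache, Wx, Wh, hidden: int):
    """BPTT for a last-step-readout LSTM; returns input grads and param grads."""
    H = hidden
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    dx_steps = []
    for x_t, h_prev, c_prev, i, f, g, o, tc in reversed(cache):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx_steps.append(dz @ Wx.T)
        dh = dz @ Wh.T
    dx = np.stack(dx_steps[::-1], axis=1)
    return dx, dWx, dWh, db


def _forward_batch(params: dict, x: np.ndarray, hidden: int):
    """Bidirectional forward pass; returns logits and caches."""
    h_f, cache_f = _lstm_forward(x, params["Wx_f"], params["Wh_f"], params["b_f"], hidden)
    x_rev = x[:, ::-1, :]
    h_b, cache_b = _lstm_forward(x_rev, params["Wx_b"], params["Wh_b"], params["b_b"], hidden)
    h_cat = np.concatenate([h_f, h_b], axis=1)
    logits = h_cat @ params["Wo"] + params["bo"]
    return logits, (cache_f, cache_b, h_cat)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grads(params: dict, x: np.ndarray, y: np.ndarray, hidden: int):
    """Mean cross-entropy over the batch plus gradients for every parameter."""
    B = x.shape[0]
    logits, (cache_f, cache_b, h_cat) = _forward_batch(params, x, hidden)
    probs = _softmax(logits)
    loss = float(-np.log(np.maximum(probs[np.arange(B), y], 1e-300)).mean())
    acc = float((logits.argmax(axis=1) == y).mean())

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {
        "Wo": h_cat.T @ dlogits,
        "bo": dlogits.sum(axis=0),
    }
    dh_cat = dlogits @ params["Wo"].T
    dh_f = dh_cat[:, :hidden]
    dh_b = dh_cat[:, hidden:]
    _, dWx_f, dWh_f, db_f = _lstm_backward(dh_f, cache_f, params["Wx_f"], params["Wh_f"], hidden)
    _, dWx_b, dWh_b, db_b = _lstm_backward(dh_b, cache_b, params["Wx_b"], params["Wh_b"], hidden)
    grads.update(
        Wx_f=dWx_f, Wh_f=dWh_f, b_f=db_f, Wx_b=dWx_b, Wh_b=dWh_b, b_b=db_b
    )
    return loss, acc, grads


_WEIGHT_KEYS = ("Wx_f", "Wh_f", "Wx_b", "Wh_b", "Wo")


def _clip_global_norm(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale


# ---------------------------------------------------------------------------
# Trained model
# ---------------------------------------------------------------------------

@dataclass
class BiLSTMClassifier:
    """Trained bidirectional LSTM with its standardizer and class labels."""

    params: dict
    classes: list
    standardizer: Standardizer
    config: TrainingConfig
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def _prep(self, seq: FeatureSequence) -> np.ndarray:
        if seq.data.shape[1] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels")
        return self.standardizer.transform(seq)

    def predict_proba(self, seqs: list[FeatureSequence]) -> np.ndarray:
        """Softmax class scores, one row per sequence (rows sum to 1)."""
        out = np.empty((len(seqs), self.n_classes))
        groups: dict[int, list[int]] = {}
        for idx, s in enumerate(seqs):
            groups.setdefault(len(s), []).append(idx)
        for length, idxs in groups.items():
            x = np.stack([self._prep(seqs[i]) for i in idxs])
            logits, _ = _forward_batch(self.params, x, self.config.hidden_size)
            out[idxs] = _softmax(logits)
        return out

    def predict(self, seqs: list[FeatureSequence]) -> list:
        """Argmax class per sequence; ties break to the lowest class index."""
        probs = self.predict_proba(seqs)
        return [self.classes[k] for k in probs.argmax(axis=1)]

    def predict_one(self, seq: FeatureSequence):
        """(class id, per-class score vector) for a single sequence."""
        probs = self.predict_proba([seq])[0]
        return self.classes[int(probs.argmax())], probs

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file .npz checkpoint: parameters plus JSON metadata."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "classes": self.classes,
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "hidden_size",
                    "max_epochs",
                    "batch_size",
                    "learning_rate",
                    "grad_clip_norm",
                    "l2_factor",
                    "seed",
                    "early_stop_loss",
                )
            },
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            std_mean=self.standardizer.mean,
            std_sd=self.standardizer.sd,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "BiLSTMClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            params = {
                k: data[k]
                for k in data.files
                if k not in ("meta", "std_mean", "std_sd")
            }
            std = Standardizer(mean=data["std_mean"], sd=data["std_sd"])
        return cls(
            params=params,
            classes=meta["classes"],
            standardizer=std,
            config=TrainingConfig(**meta["config"]),
        )


def _adam_update(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for k, g in grads.items():
        m, v = state[k]
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[k] = (m, v)
        m_hat = m / (1 - beta1**t)
        v_hat = v / (1 - beta2**t)
        params[k] = params[k] - lr * m_hat / (np.sqrt(v_hat) + eps)


def train(
    train_set: list[FeatureSequence],
    cfg: TrainingConfig | None = None,
    standardizer: Standardizer | None = None,
) -> BiLSTMClassifier:
    """Train the bi-LSTM on labeled feature sequences.

    The standardizer, if not supplied, is fitted on ``train_set`` itself;
    when cross-validating, fit it on the training split and pass it in. The
    history records per-iteration (minibatch) loss and accuracy.
    """
    if cfg is None:
        cfg = TrainingConfig()
    classes = sorted({s.label for s in train_set}, key=repr)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    class_index = {c: k for k, c in enumerate(classes)}
    if standardizer is None:
        standardizer = fit_standardizer(train_set)

    xs = [standardizer.transform(s) for s in train_set]
    ys = np.array([class_index[s.label] for s in train_set])
    n = len(xs)
    batch_size = min(cfg.batch_size, n)

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(rng, N_CHANNELS, cfg.hidden_size, len(classes))
    adam_state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
    history = {"loss": [], "accuracy": []}

    step = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            # Group by length so each forward pass is a dense batch; with the
            # fixed pipeline all sequences share T and there is one group.
            groups: dict[int, list[int]] = {}
            for i in idx:
                groups.setdefault(xs[i].shape[0], []).append(i)
            loss_sum = 0.0
            acc_sum = 0.0
            grads_sum: dict | None = None
            for g_idx in groups.values():
                x = np.stack([xs[i] for i in g_idx])
                y = ys[g_idx]
                loss, acc, grads = _loss_and_grads(params, x, y, cfg.hidden_size)
                frac = len(g_idx) / len(idx)
                loss_sum += loss * frac
                acc_sum += acc * frac
                if grads_sum is None:
                    grads_sum = {k: v * frac for k, v in grads.items()}
                else:
                    for k in grads_sum:
                        grads_sum[k] += grads[k] * frac
            assert grads_sum is not None
            for k in _WEIGHT_KEYS:  # L2 on weight matrices, not biases
                grads_sum[k] = grads_sum[k] + cfg.l2_factor * params[k]
            _clip_global_norm(grads_sum, cfg.grad_clip_norm)
            step += 1
            _adam_update(params, grads_sum, adam_state, cfg.learning_rate, step)
            history["loss"].append(loss_sum)
            history["accuracy"].append(acc_sum)
            epoch_losses.append(loss_sum)
        if cfg.early_stop_loss is not None and np.mean(epoch_losses) < cfg.early_stop_loss:
            break

    return BiLSTMClassifier(
        params=params,
        classes=classes,
        standardizer=standardizer,
        config=cfg,
        history=history,
    )


def train_one_vs_rest(
    train_set: list[FeatureSequence],
    cfg: TrainingConfig | None = None,
    standardizer: Standardizer | None = None,
    class_modeling: bool = True,
    seed: int = 0,
) -> "OneVsRestEnsemble":
    """One bi-LSTM per class, each trained on that class's class-modeling set."""
    if cfg is None:
        cfg = TrainingConfig()
    classes = sorted({s.label for s in train_set}, key=repr)
    if standardizer is None:
        standardizer = fit_standardizer(train_set)
    models = {}
    for k, target in enumerate(classes):
        subset = (
            build_class_modeling_set(train_set, target, seed=seed + k)
            if class_modeling
            else train_set
        )
        models[target] = train(subset, replace(cfg, seed=cfg.seed + k), standardizer)
    return OneVsRestEnsemble(models=models, classes=classes)


@dataclass
class OneVsRestEnsemble:
    """Per-class models; prediction is the argmax of target-class scores."""

    models: dict
    classes: list

    def predict(self, seqs: list[FeatureSequence]) -> list:
        scores = np.empty((len(seqs), len(self.classes)))
        for k, target in enumerate(self.classes):
            model = self.models[target]
            j = model.classes.index(target)
            scores[:, k] = model.predict_proba(seqs)[:, j]
        return [self.classes[k] for k in scores.argmax(axis=1)]
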