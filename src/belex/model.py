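"""Attention-based bidirectional LSTM classifier for relation extraction (RE)
and entity function detection (FD).

The same architecture serves both tasks; they differ only in the input form
and label set.  Each token is embedded as the concatenation of a trainable
word vector with one (FD) or two (RE) trainable position vectors encoding the
clipped signed distance to the marked entity placeholder(s).  A forward and a
backward LSTM run over the sequence and their hidden states are combined by
element-wise sum.  An attention layer scores each combined state

    eps_i = w_a . tanh(h_i),    alpha = softmax(eps),    r = sum_i alpha_i h_i,

the sentence vector is squashed, h* = tanh(r), and a softmax output layer
produces class probabilities p(y|s) = softmax(W h* + b).

Training minimizes the mean negative log-likelihood of the gold labels plus
an L2 penalty lambda * ||theta||^2 over all parameters, with Adam.  Both the
forward pass and backpropagation are implemented directly in NumPy; padded
positions are masked out of the recurrences and the attention softmax so
padding can never receive weight.  Everything is deterministic given the
seed.

Function-detection predictions additionally pass through
:func:`threshold_filter`: a predicted function whose top-class probability
falls below a threshold tau is relabeled ``none``, trading recall for
precision before statements are merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ModelConfig",
    "SequenceEncoding",
    "AttBiLSTM",
    "relative_distance",
    "position_index",
    "threshold_filter",
]

PAD, UNK = "<pad>", "<unk>"


@dataclass
class ModelConfig:
    """Hyperparameters shared by the RE and FD models.

    Defaults follow the reference setting (word dim 200, position dim 64,
    600 LSTM units, Adam at 1e-3 with L2 coefficient 1e-4); the reduced
    configurations used in tests shrink the dimensions, not the architecture.
    """

    word_dim: int = 200
    position_dim: int = 64
    lstm_units: int = 600
    learning_rate: float = 0.001
    l2_lambda: float = 0.0001
    max_position: int = 50
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    num_positions: int = 2
    label_set: tuple[str, ...] = ("none", "increases", "decreases")

    def __post_init__(self):
        self.label_set = tuple(self.label_set)
        for name in ("word_dim", "position_dim", "lstm_units", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.num_positions not in (1, 2):
            raise ValueError("num_positions must be 1 (FD) or 2 (RE)")
        if not self.label_set or self.label_set[0] != "none":
            raise ValueError("label_set must contain 'none' at index 0")


@dataclass
class SequenceEncoding:
    """Forward-pass artifacts for one instance."""

    hidden: np.ndarray  # (T, H) combined BiLSTM states
    attention: np.ndarray  # (T,) weights, sum to 1
    sentence: np.ndarray  # (H,) r = sum_i alpha_i h_i
    probabilities: np.ndarray  # (C,) p(y|s)


def relative_distance(word_index: int, entity_index: int, max_position: int = 50) -> int:
    """Signed relative token distance, clipped to [-max_position, max_position]."""
    d = word_index - entity_index
    return max(-max_position, min(max_position, d))


def position_index(word_index: int, entity_index: int, max_position: int = 50) -> int:
    """Non-negative embedding index for the clipped signed distance."""
    return relative_distance(word_index, entity_index, max_position) + max_position


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(x, axis=-1):
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def _entity_indices(instance, num_positions: int) -> tuple[int, ...]:
    if num_positions == 2:
        return (instance.e1_index, instance.e2_index)
    return (instance.entity_index,)


class AttBiLSTM:
    """The att-BiLSTM classifier with its vocabulary and trained parameters.

    ``fit`` builds the vocabulary from the training instances, initializes
    parameters from the config seed, and runs mini-batch Adam on the
    regularized negative log-likelihood.  ``predict`` writes the argmax label
    and the full class-probability vector onto each instance.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.vocab: dict[str, int] = {}
        self.params: dict[str, np.ndarray] = {}
        self.loss_log: list[float] = []

    # -- vocabulary ---------------------------------------------------------

    def _build_vocab(self, instances) -> None:
        vocab = {PAD: 0, UNK: 1}
        for inst in instances:
            for tok in inst.tokens:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
        self.vocab = vocab

    def _token_ids(self, tokens) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(t, unk) for t in tokens], dtype=np.int64)

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        V, dw, dp, H = len(self.vocab), cfg.word_dim, cfg.position_dim, cfg.lstm_units
        D = dw + cfg.num_positions * dp
        P = 2 * cfg.max_position + 1
        C = len(cfg.label_set)

        def uniform(shape, scale):
            return rng.uniform(-scale, scale, size=shape)

        params = {
            "Ew": uniform((V, dw), 0.1),
            "w_a": uniform((H,), np.sqrt(1.0 / H)),
            "Ws": uniform((H, C), np.sqrt(6.0 / (H + C))),
            "bs": np.zeros(C),
        }
        for k in range(cfg.num_positions):
            params[f"Ep{k}"] = uniform((P, dp), 0.1)
        for d in ("f", "b"):
            params[f"Wx_{d}"] = uniform((D, 4 * H), np.sqrt(6.0 / (D + H)))
            params[f"Wh_{d}"] = uniform((H, 4 * H), np.sqrt(6.0 / (2 * H)))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            params[f"b_{d}"] = bias
        self.params = params

    # -- batching -----------------------------------------------------------

    def _make_batch(self, instances):
        cfg = self.config
        B = len(instances)
        T = max(len(inst.tokens) for inst in instances)
        token_ids = np.zeros((B, T), dtype=np.int64)
        pos_ids = np.zeros((cfg.num_positions, B, T), dtype=np.int64)
        mask = np.zeros((B, T))
        for b, inst in enumerate(instances):
            n = len(inst.tokens)
            token_ids[b, :n] = self._token_ids(inst.tokens)
            mask[b, :n] = 1.0
            for k, e_idx in enumerate(_entity_indices(inst, cfg.num_positions)):
                for i in range(n):
                    pos_ids[k, b, i] = position_index(i, e_idx, cfg.max_position)
        return token_ids, pos_ids, mask

    # -- forward ------------------------------------------------------------

    def _forward(self, token_ids, pos_ids, mask):
        """Batched forward pass; returns probabilities and a cache for BPTT."""
        cfg, params = self.config, self.params
        B, T = token_ids.shape
        H = cfg.lstm_units
        x = np.concatenate(
            [params["Ew"][token_ids]]
            + [params[f"Ep{k}"][pos_ids[k]] for k in range(cfg.num_positions)],
            axis=-1,
        )
        x = x * mask[..., None]

        def run_lstm(direction):
            order = range(T) if direction == "f" else range(T - 1, -1, -1)
            Wx, Wh, bias = params[f"Wx_{direction}"], params[f"Wh_{direction}"], params[f"b_{direction}"]
            h_prev = np.zeros((B, H))
            c_prev = np.zeros((B, H))
            hs = np.zeros((B, T, H))
            steps = {}
            for t in order:
                m = mask[:, t : t + 1]
                a = x[:, t] @ Wx + h_prev @ Wh + bias
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H : 2 * H])
                g = np.tanh(a[:, 2 * H : 3 * H])
                o = _sigmoid(a[:, 3 * H :])
                c = (i * g + f * c_prev) * m
                tc = np.tanh(c)
                h = o * tc * m
                steps[t] = (i, f, g, o, c_prev, tc, h_prev, m)
                hs[:, t] = h
                h_prev, c_prev = h, c
            return hs, steps, list(order)

        hf, steps_f, order_f = run_lstm("f")
        hb, steps_b, order_b = run_lstm("b")
        h = (hf + hb) * mask[..., None]
        u = np.tanh(h)
        eps = u @ params["w_a"]
        eps = np.where(mask > 0, eps, -np.inf)
        alpha = _softmax(eps, axis=1)
        r = np.einsum("bt,bth->bh", alpha, h)
        hstar = np.tanh(r)
        logits = hstar @ params["Ws"] + params["bs"]
        probs = _softmax(logits, axis=1)
        cache = dict(
            x=x, mask=mask, token_ids=token_ids, pos_ids=pos_ids,
            steps_f=steps_f, steps_b=steps_b, order_f=order_f, order_b=order_b,
            h=h, u=u, alpha=alpha, hstar=hstar, probs=probs,
        )
        return probs, cache

    # -- backward -----------------------------------------------------------

    def _backward(self, cache, labels):
        """Gradients of the mean NLL w.r.t. every parameter (no L2 term)."""
        cfg, params = self.config, self.params
        mask, x = cache["mask"], cache["x"]
        B, T = mask.shape
        H = cfg.lstm_units
        dw = cfg.word_dim
        grads = {k: np.zeros_like(v) for k, v in params.items()}

        dlogits = cache["probs"].copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads["Ws"] = cache["hstar"].T @ dlogits
        grads["bs"] = dlogits.sum(axis=0)
        dhstar = dlogits @ params["Ws"].T
        dr = dhstar * (1.0 - cache["hstar"] ** 2)

        h, u, alpha = cache["h"], cache["u"], cache["alpha"]
        dalpha = np.einsum("bh,bth->bt", dr, h)
        dh = alpha[..., None] * dr[:, None, :]
        deps = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        grads["w_a"] = np.einsum("bt,bth->h", deps, u)
        du = deps[..., None] * params["w_a"][None, None, :]
        dh = dh + du * (1.0 - u**2)
        dh = dh * mask[..., None]

        dx = np.zeros_like(x)

        def back_lstm(direction, steps, order):
            Wx, Wh = params[f"Wx_{direction}"], params[f"Wh_{direction}"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros_like(params[f"b_{direction}"])
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in reversed(order):
                i, f, g, o, c_prev, tc, h_prev, m = steps[t]
                dh_total = dh[:, t] + dh_next
                dh_inner = dh_total * m
                do = dh_inner * tc
                dc = dh_inner * o * (1.0 - tc**2) + dc_next
                dc_inner = dc * m
                di = dc_inner * g
                dg = dc_inner * i
                df = dc_inner * c_prev
                dc_next = dc_inner * f
                da = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g**2),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                dWx += x[:, t].T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                dx[:, t] += da @ Wx.T
                dh_next = da @ Wh.T
            grads[f"Wx_{direction}"] = dWx
            grads[f"Wh_{direction}"] = dWh
            grads[f"b_{direction}"] = db

        back_lstm("f", cache["steps_f"], cache["order_f"])
        back_lstm("b", cache["steps_b"], cache["order_b"])

        dx = dx * mask[..., None]
        np.add.at(grads["Ew"], cache["token_ids"], dx[..., :dw])
        for k in range(cfg.num_positions):
            sl = slice(dw + k * cfg.position_dim, dw + (k + 1) * cfg.position_dim)
            np.add.at(grads[f"Ep{k}"], cache["pos_ids"][k], dx[..., sl])
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, instances) -> "AttBiLSTM":
        cfg = self.config
        instances = list(instances)
        if not instances:
            raise ValueError("no training instances")
        label_index = {lab: i for i, lab in enumerate(cfg.label_set)}
        for inst in instances:
            if self._instance_label(inst) not in label_index:
                raise ValueError(
                    f"label {self._instance_label(inst)!r} not in label_set {cfg.label_set}"
                )
        seen = {self._instance_label(inst) for inst in instances}
        if len(seen) < 2:
            raise ValueError("training data must contain at least 2 distinct labels")

        rng = np.random.default_rng(cfg.seed)
        self._build_vocab(instances)
        self._init_params(rng)
        labels_all = np.array(
            [label_index[self._instance_label(inst)] for inst in instances], dtype=np.int64
        )
        # bucket by length for stable padding cost; order fixed before shuffling
        order0 = sorted(range(len(instances)), key=lambda k: len(instances[k].tokens))

        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
        step = 0
        self.loss_log = []
        for _epoch in range(cfg.epochs):
            perm = rng.permutation(len(order0))
            idx = [order0[p] for p in perm]
            epoch_nll = 0.0
            for b0 in range(0, len(idx), cfg.batch_size):
                batch_idx = idx[b0 : b0 + cfg.batch_size]
                batch = [instances[k] for k in batch_idx]
                labels = labels_all[batch_idx]
                token_ids, pos_ids, mask = self._make_batch(batch)
                probs, cache = self._forward(token_ids, pos_ids, mask)
                nll = -np.log(probs[np.arange(len(batch)), labels] + 1e-12)
                epoch_nll += nll.sum()
                grads = self._backward(cache, labels)
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for k, p in self.params.items():
                    g = grads[k] + 2.0 * cfg.l2_lambda * p
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                    p -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps_adam)
            l2 = cfg.l2_lambda * sum(float((p**2).sum()) for p in self.params.values())
            self.loss_log.append(epoch_nll / len(idx) + l2)
        return self

    @staticmethod
    def _instance_label(inst) -> str:
        return getattr(inst, "train_label", None) or inst.label

    # -- prediction ---------------------------------------------------------

    def predict(self, instances) -> list:
        """Argmax label + full probability vector stored on each instance."""
        if not self.params:
            raise ValueError("model is not trained")
        cfg = self.config
        instances = list(instances)
        if not instances:
            return instances
        order = sorted(range(len(instances)), key=lambda k: len(instances[k].tokens))
        for b0 in range(0, len(order), cfg.batch_size):
            batch_idx = order[b0 : b0 + cfg.batch_size]
            batch = [instances[k] for k in batch_idx]
            probs, _ = self._forward(*self._make_batch(batch))
            for inst, p in zip(batch, probs):
                inst.probabilities = {lab: float(v) for lab, v in zip(cfg.label_set, p)}
                inst.label = cfg.label_set[int(np.argmax(p))]
        return instances

    def encode(self, tokens, entity_indices) -> SequenceEncoding:
        """Run the encoder on one unbatched instance and expose internals."""
        if not tokens:
            raise ValueError("empty token sequence")
        if len(entity_indices) != self.config.num_positions:
            raise ValueError("entity index count must match config.num_positions")

        class _Stub:
            pass

        stub = _Stub()
        stub.tokens = list(tokens)
        if self.config.num_positions == 2:
            stub.e1_index, stub.e2_index = entity_indices
        else:
            (stub.entity_index,) = entity_indices
        probs, cache = self._forward(*self._make_batch([stub]))
        return SequenceEncoding(
            hidden=cache["h"][0],
            attention=cache["alpha"][0],
            sentence=np.einsum("t,th->h", cache["alpha"][0], cache["h"][0]),
            probabilities=probs[0],
        )

    # -- persistence --------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": self.FORMAT_VERSION,
            "config": asdict(self.config),
            "vocab": self.vocab,
            "loss_log": self.loss_log,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "AttBiLSTM":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != cls.FORMAT_VERSION:
                raise ValueError("unsupported checkpoint format version")
            cfg_dict = meta["config"]
            cfg_dict["label_set"] = tuple(cfg_dict["label_set"])
            model = cls(ModelConfig(**cfg_dict))
            model.vocab = meta["vocab"]
            model.loss_log = meta["loss_log"]
            model.params = {k: data[k] for k in data.files if k != "__meta__"}
        return model


def threshold_filter(fd_predictions, tau: float):
    """Relabel unreliable function predictions as ``none``.

    A prediction whose top-class probability is strictly below ``tau`` is
    relabeled negative; ties at exactly ``tau`` are kept.  ``tau=0`` leaves
    predictions unchanged (naive merging); ``tau=1`` drops every function
    whose confidence is below certainty (relations-only merging).  Applied
    only to function detection.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    for inst in fd_predictions:
        if not inst.probabilities:
            raise ValueError("predictions must carry probabilities")
        if inst.label != "none" and max(inst.probabilities.values()) < tau:
            inst.label = "none"
    return fd_predictions
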