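"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's batched/vectorized code paths: the
encoder oracle is a straight-line, one-sequence transcription of the model
equations, and the scorer oracle enumerates every injective unit assignment.
"""

from itertools import permutations

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def encode_reference(params, config, token_ids, pos_ids):
    """Unbatched forward pass: embeddings, two LSTM recurrences combined by
    element-wise sum, attention weights, sentence vector and class
    probabilities.  Returns (h list, alpha, r, probabilities)."""
    n = len(token_ids)
    H = config.lstm_units
    x = []
    for t in range(n):
        parts = [params["Ew"][token_ids[t]]]
        for k in range(config.num_positions):
            parts.append(params[f"Ep{k}"][pos_ids[k][t]])
        x.append(np.concatenate(parts))

    def lstm(order, d):
        Wx, Wh, b = params[f"Wx_{d}"], params[f"Wh_{d}"], params[f"b_{d}"]
        h = np.zeros(H)
        c = np.zeros(H)
        out = [None] * n
        for t in order:
            a = x[t] @ Wx + h @ Wh + b
            i = sigmoid(a[:H])
            f = sigmoid(a[H : 2 * H])
            g = np.tanh(a[2 * H : 3 * H])
            o = sigmoid(a[3 * H :])
            c = i * g + f * c
            h = o * np.tanh(c)
            out[t] = h
        return out

    h_fwd = lstm(range(n), "f")
    h_bwd = lstm(range(n - 1, -1, -1), "b")
    h = [h_fwd[t] + h_bwd[t] for t in range(n)]
    eps = np.array([float(params["w_a"] @ np.tanh(h[t])) for t in range(n)])
    e = np.exp(eps - eps.max())
    alpha = e / e.sum()
    r = sum(alpha[t] * h[t] for t in range(n))
    hstar = np.tanh(r)
    logits = hstar @ params["Ws"] + params["bs"]
    z = np.exp(logits - logits.max())
    return h, alpha, r, z / z.sum()


# ---------------------------------------------------------------------------
# scorer oracle


def oracle_units(statements, level):
    """Unit extraction restated from the level definitions."""
    units = []
    for s in statements:
        subj, obj = s.subject, s.object
        terms = [subj, obj]
        if level == "T":
            units.extend(t.ns_id for t in terms)
        elif level in ("Fun", "FS"):
            units.extend((t.function_label, t.ns_id) for t in terms if t.function_label != "none")
        elif level in ("Rel", "RS"):
            units.append((subj.ns_id, s.relation, obj.ns_id))
        elif level == "Stat":
            units.append(
                (subj.function_label, subj.ns_id, s.relation, obj.function_label, obj.ns_id)
            )
    return units


def oracle_predicate(level, pred, gold):
    if level == "FS":
        return pred[1] == gold[1]
    if level == "RS":
        return sum(p == g for p, g in zip(pred, gold)) >= 2
    return pred == gold


def brute_force_matches(pred_units, gold_units, level):
    """Maximum one-to-one matching by exhaustive assignment enumeration."""
    if not pred_units or not gold_units:
        return 0
    small, large, flipped = (
        (pred_units, gold_units, False)
        if len(pred_units) <= len(gold_units)
        else (gold_units, pred_units, True)
    )
    best = 0
    for perm in permutations(range(len(large)), len(small)):
        count = 0
        for i, j in enumerate(perm):
            a, b = small[i], large[j]
            pred, gold = (b, a) if flipped else (a, b)
            if oracle_predicate(level, pred, gold):
                count += 1
        best = max(best, count)
    return best
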