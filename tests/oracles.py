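"""Independent brute-force oracles for the multi-label metrics.

These deliberately use pure-Python loops and set arithmetic so they share
no code path with the vectorized implementations they check.
"""

from __future__ import annotations


def _row_sets(row_true, row_pred):
    true_set = {j for j, v in enumerate(row_true) if v == 1}
    pred_set = {j for j, v in enumerate(row_pred) if v == 1}
    return true_set, pred_set


def oracle_hamming(y_true, y_pred) -> float:
    n = len(y_true)
    L = len(y_true[0])
    wrong = 0
    for i in range(n):
        for j in range(L):
            if y_true[i][j] != y_pred[i][j]:
                wrong += 1
    return wrong / (n * L)


def oracle_jaccard(y_true, y_pred) -> float:
    total = 0.0
    for rt, rp in zip(y_true, y_pred):
        t, p = _row_sets(rt, rp)
        union = t | p
        total += 1.0 if not union else len(t & p) / len(union)
    return total / len(y_true)


def oracle_label_macro(y_true, y_pred) -> float:
    n = len(y_true)
    L = len(y_true[0])
    acc = 0.0
    for j in range(L):
        correct = sum(1 for i in range(n) if y_true[i][j] == y_pred[i][j])
        acc += correct / n
    return acc / L


def oracle_alpha(y_true, y_pred, alpha=1.0, beta=1.0, gamma=1.0) -> float:
    total = 0.0
    for rt, rp in zip(y_true, y_pred):
        t, p = _row_sets(rt, rp)
        union = t | p
        if not union:
            total += 1.0
            continue
        fn = len(t - p)
        fp = len(p - t)
        base = 1.0 - (beta * fn + gamma * fp) / len(union)
        total += max(base, 0.0) ** alpha
    return total / len(y_true)
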