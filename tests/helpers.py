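"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the edit distance is the
textbook recursion, the GIP kernel is evaluated entrywise with explicit
loops, and the concordance AUC is a pair-counting statistic.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def recursive_levenshtein(s: str, t: str) -> int:
    """Exhaustive recursive edit distance (memoised on suffix indices)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(s):
            return len(t) - j
        if j == len(t):
            return len(s) - i
        cost = 0 if s[i] == t[j] else 1
        return min(
            rec(i + 1, j) + 1,        # delete s[i]
            rec(i, j + 1) + 1,        # insert t[j]
            rec(i + 1, j + 1) + cost, # substitute / match
        )

    return rec(0, 0)


def brute_force_gip(adjacency: np.ndarray) -> np.ndarray:
    """Entrywise Gaussian interaction-profile kernel with explicit loops."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        total += sum(a[i, k] ** 2 for k in range(n))
    gamma = n / total
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            sq = sum((a[i, k] - a[j, k]) ** 2 for k in range(n))
            out[i, j] = np.exp(-gamma * sq)
    return out


def concordance_auc(scores, labels) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg) with ties as 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def formula_confusion(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Direct evaluation of the five confusion-matrix formulas, 0 when undefined."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * sen / (prec + sen) if prec + sen else 0.0
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return {"accuracy": acc, "precision": prec, "sensitivity": sen, "f1": f1, "mcc": mcc}
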