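"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive quantities with naive loops or closed forms,
sharing no code with the implementation they check.
"""

import math

import numpy as np


def naive_cooccurrence_counts(sentences, rows, columns, half_window):
    """Triple-loop recount of windowed within-sentence co-occurrences,
    including bigram-row targets."""
    ridx = {t: i for i, t in enumerate(rows)}
    cidx = {t: i for i, t in enumerate(columns)}
    mat = np.zeros((len(rows), len(columns)), dtype=np.int64)
    h = half_window
    for sent in sentences:
        n = len(sent)
        for i in range(n):
            if sent[i] in ridx:
                for j in range(n):
                    if j != i and abs(j - i) <= h and sent[j] in cidx:
                        mat[ridx[sent[i]], cidx[sent[j]]] += 1
        for i in range(n - 1):
            pair = (sent[i], sent[i + 1])
            if pair in ridx:
                for j in range(n):
                    if (i - h <= j < i or i + 1 < j <= i + 1 + h) and sent[j] in cidx:
                        mat[ridx[pair], cidx[sent[j]]] += 1
    return mat


def naive_ppmi(counts):
    """Per-cell evaluation of max(0, log(p(a,b) / (p(a) p(b))))."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    out = np.zeros_like(counts)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j] == 0:
                continue
            pab = counts[i, j] / total
            pa = counts[i].sum() / total
            pb = counts[:, j].sum() / total
            out[i, j] = max(0.0, math.log(pab / (pa * pb)))
    return out


def naive_cosine(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def naive_top_k(space_vectors, row_targets, v, k):
    """Exhaustive-sort nearest neighbours over single-lemma rows."""
    sims = []
    for i, t in enumerate(row_targets):
        if isinstance(t, tuple):
            continue
        u = space_vectors[i]
        nu = np.linalg.norm(u)
        s = 0.0 if nu == 0 else float(np.dot(u, v) / (nu * np.linalg.norm(v)))
        sims.append((t, s, i))
    sims.sort(key=lambda x: (-x[1], x[2]))
    return [(t, s) for t, s, _ in sims[:k]]
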