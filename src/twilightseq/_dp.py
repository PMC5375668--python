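"""Numba dynamic-programming kernels for pair and triplet global alignment.

Scoring rules (linear per-column gap cost, end gaps penalized):

* pair column with two residues: matrix entry; column with one gap: -g.
* triplet column with three residues: sum of the three pairwise entries;
  one gap: entry of the two residues minus g; two gaps: -2g.

Score-only kernels keep a rolling plane/row; full-table kernels retain the
whole DP table for traceback.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pair_score(a: np.ndarray, b: np.ndarray, S: np.ndarray, g: int) -> int:
    """Optimal global pair alignment score, score only (rolling row)."""
    L1, L2 = a.shape[0], b.shape[0]
    prev = np.empty(L2 + 1, np.int64)
    cur = np.empty(L2 + 1, np.int64)
    for j in range(L2 + 1):
        prev[j] = -g * j
    for i in range(1, L1 + 1):
        cur[0] = -g * i
        ai = a[i - 1]
        for j in range(1, L2 + 1):
            m = prev[j - 1] + S[ai, b[j - 1]]
            v = prev[j] - g
            if v > m:
                m = v
            v = cur[j - 1] - g
            if v > m:
                m = v
            cur[j] = m
        prev, cur = cur, prev
    return prev[L2]


@njit(cache=True)
def pair_table(a: np.ndarray, b: np.ndarray, S: np.ndarray, g: int) -> np.ndarray:
    """Full pair DP table H[i, j] for traceback."""
    L1, L2 = a.shape[0], b.shape[0]
    H = np.empty((L1 + 1, L2 + 1), np.int64)
    for j in range(L2 + 1):
        H[0, j] = -g * j
    for i in range(1, L1 + 1):
        H[i, 0] = -g * i
        ai = a[i - 1]
        for j in range(1, L2 + 1):
            m = H[i - 1, j - 1] + S[ai, b[j - 1]]
            v = H[i - 1, j] - g
            if v > m:
                m = v
            v = H[i, j - 1] - g
            if v > m:
                m = v
            H[i, j] = m
    return H


@njit(cache=True)
def triplet_score(a: np.ndarray, b: np.ndarray, c: np.ndarray, S: np.ndarray, g: int) -> int:
    """Optimal global triplet alignment score, score only (rolling plane)."""
    L1, L2, L3 = a.shape[0], b.shape[0], c.shape[0]
    g2 = 2 * g
    prev = np.empty((L2 + 1, L3 + 1), np.int64)
    cur = np.empty((L2 + 1, L3 + 1), np.int64)
    # i = 0 plane: s1 exhausted; columns pair b/c residues (one gap) or
    # advance a single sequence (two gaps).
    prev[0, 0] = 0
    for k in range(1, L3 + 1):
        prev[0, k] = prev[0, k - 1] - g2
    for j in range(1, L2 + 1):
        prev[j, 0] = prev[j - 1, 0] - g2
        bj = b[j - 1]
        for k in range(1, L3 + 1):
            m = prev[j - 1, k - 1] + S[bj, c[k - 1]] - g
            v = prev[j - 1, k] - g2
            if v > m:
                m = v
            v = prev[j, k - 1] - g2
            if v > m:
                m = v
            prev[j, k] = m
    for i in range(1, L1 + 1):
        ai = a[i - 1]
        cur[0, 0] = prev[0, 0] - g2
        for k in range(1, L3 + 1):
            m = prev[0, k - 1] + S[ai, c[k - 1]] - g
            v = prev[0, k] - g2
            if v > m:
                m = v
            v = cur[0, k - 1] - g2
            if v > m:
                m = v
            cur[0, k] = m
        for j in range(1, L2 + 1):
            bj = b[j - 1]
            Sab = S[ai, bj]
            m = prev[j - 1, 0] + Sab - g
            v = prev[j, 0] - g2
            if v > m:
                m = v
            v = cur[j - 1, 0] - g2
            if v > m:
                m = v
            cur[j, 0] = m
            for k in range(1, L3 + 1):
                ck = c[k - 1]
                Sac = S[ai, ck]
                Sbc = S[bj, ck]
                m = prev[j - 1, k - 1] + Sab + Sac + Sbc
                v = prev[j - 1, k] + Sab - g
                if v > m:
                    m = v
                v = prev[j, k - 1] + Sac - g
                if v > m:
                    m = v
                v = cur[j - 1, k - 1] + Sbc - g
                if v > m:
                    m = v
                v = prev[j, k] - g2
                if v > m:
                    m = v
                v = cur[j - 1, k] - g2
                if v > m:
                    m = v
                v = cur[j, k - 1] - g2
                if v > m:
                    m = v
                cur[j, k] = m
        prev, cur = cur, prev
    return prev[L2, L3]


@njit(cache=True)
def triplet_table(a: np.ndarray, b: np.ndarray, c: np.ndarray, S: np.ndarray, g: int) -> np.ndarray:
    """Full triplet DP cube E[i, j, k] for traceback."""
    L1, L2, L3 = a.shape[0], b.shape[0], c.shape[0]
    g2 = 2 * g
    NEG = np.int64(-(10 ** 15))
    E = np.empty((L1 + 1, L2 + 1, L3 + 1), np.int64)
    for i in range(L1 + 1):
        for j in range(L2 + 1):
            for k in range(L3 + 1):
                if i == 0 and j == 0 and k == 0:
                    E[0, 0, 0] = 0
                    continue
                m = NEG
                if i > 0 and j > 0 and k > 0:
                    v = E[i - 1, j - 1, k - 1] + S[a[i - 1], b[j - 1]] + S[a[i - 1], c[k - 1]] + S[b[j - 1], c[k - 1]]
                    if v > m:
                        m = v
                if i > 0 and j > 0:
                    v = E[i - 1, j - 1, k] + S[a[i - 1], b[j - 1]] - g
                    if v > m:
                        m = v
                if i > 0 and k > 0:
                    v = E[i - 1, j, k - 1] + S[a[i - 1], c[k - 1]] - g
                    if v > m:
                        m = v
                if j > 0 and k > 0:
                    v = E[i, j - 1, k - 1] + S[b[j - 1], c[k - 1]] - g
                    if v > m:
                        m = v
                if i > 0:
                    v = E[i - 1, j, k] - g2
                    if v > m:
                        m = v
                if j > 0:
                    v = E[i, j - 1, k] - g2
                    if v > m:
                        m = v
                if k > 0:
                    v = E[i, j, k - 1] - g2
                    if v > m:
                        m = v
                E[i, j, k] = m
    return E
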