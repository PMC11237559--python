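"""Affine-gap dynamic-programming kernels for profile-to-sequence alignment.

The alignment is global across the profile columns (every column is either
matched or deleted) but sequence residues before the first and after the
last matched column are free: the profile models a domain, and a
multi-domain protein — a SoxYZ fusion, say — must not be penalized for the
residues flanking the matched domain.  Internal insertions are penalized.

Scores are in bits (log2 odds).  Gap convention: a maximal gap run of
length k costs ``open + (k-1)*extend``; switching directly between a
deletion run and an insertion run re-opens the gap.

The kernels are numba-jitted: `search_proteome` scores thousands of
proteins per cohort and a pure-Python DP would dominate the runtime.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

#: canonical amino-acid order used for emission matrices
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as int64 indices into :data:`ALPHABET`.

    Residues outside the 20-letter alphabet map to index 20 (scored 0
    against every profile column).
    """
    return np.array([AA_INDEX.get(c, 20) for c in seq], dtype=np.int64)


def pad_emissions(em: np.ndarray) -> np.ndarray:
    """Append a zero column for the unknown-residue index."""
    m = em.shape[0]
    out = np.zeros((m, 21), dtype=np.float64)
    out[:, :20] = em
    return out


@njit(cache=True)
def _fill(em, seq, gap_open, gap_ext):  # pragma: no cover - exercised via wrappers
    m = em.shape[0]
    L = seq.shape[0]
    M = np.full((L + 1, m + 1), NEG)
    D = np.full((L + 1, m + 1), NEG)  # column consumed, gap in sequence
    I = np.full((L + 1, m + 1), NEG)  # residue consumed, insertion vs profile
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        D[0, j] = -gap_open if j == 1 else D[0, j - 1] - gap_ext
    for i in range(1, L + 1):
        I[i, 0] = 0.0  # leading flanking residues are free
    for i in range(1, L + 1):
        si = seq[i - 1]
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
            M[i, j] = best + em[j - 1, si]

            d = M[i, j - 1] - gap_open
            t = D[i, j - 1] - gap_ext
            if t > d:
                d = t
            t = I[i, j - 1] - gap_open
            if t > d:
                d = t
            D[i, j] = d

            ins = M[i - 1, j] - gap_open
            t = I[i - 1, j] - gap_ext
            if t > ins:
                ins = t
            t = D[i - 1, j] - gap_open
            if t > ins:
                ins = t
            I[i, j] = ins
    return M, D, I


@njit(cache=True)
def global_score(em, seq, gap_open, gap_ext):  # pragma: no cover
    """Best score over all end rows: trailing flanking residues are free."""
    M, D, I = _fill(em, seq, gap_open, gap_ext)
    L = seq.shape[0]
    m = em.shape[0]
    s = NEG
    for i in range(L + 1):
        if M[i, m] > s:
            s = M[i, m]
        if D[i, m] > s:
            s = D[i, m]
    return s


@njit(cache=True)
def batch_global_scores(em, concat, offsets, gap_open, gap_ext):  # pragma: no cover
    """Score many sequences (concatenated, with offsets) against one profile."""
    n = offsets.shape[0] - 1
    out = np.empty(n)
    for k in range(n):
        out[k] = global_score(em, concat[offsets[k]:offsets[k + 1]], gap_open, gap_ext)
    return out


_EPS = 1e-9


def global_align(em: np.ndarray, seq_idx: np.ndarray, gap_open: float,
                 gap_ext: float) -> tuple[float, np.ndarray]:
    """Optimal global profile alignment with traceback.

    Returns ``(score, trace)`` where ``trace[j]`` is the 0-based residue
    index aligned to profile column ``j``, or ``-1`` where the column is
    deleted.  Insertions relative to the profile are not represented.
    """
    M, D, I = _fill(em, seq_idx, gap_open, gap_ext)
    L = len(seq_idx)
    m = em.shape[0]
    trace = np.full(m, -1, dtype=np.int64)
    # best end row (trailing residues free); prefer M over D on exact ties
    score = NEG
    state = 0
    end_i = 0
    for row in range(L + 1):
        if M[row, m] > score + _EPS:
            score, state, end_i = M[row, m], 0, row
        if D[row, m] > score + _EPS:
            score, state, end_i = D[row, m], 1, row
    i, j = end_i, m
    while i > 0 or j > 0:
        if j == 0:  # leading flanking residues are free
            i = 0
            break
        if state == 0:  # M: residue i-1 on column j-1
            trace[j - 1] = i - 1
            e = em[j - 1, seq_idx[i - 1]]
            vals = (M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            codes = (0, 1, 2)
            target = M[i, j] - e
            i, j = i - 1, j - 1
        elif state == 1:  # D: column j-1 deleted
            vals = (M[i, j - 1] - gap_open, D[i, j - 1] - gap_ext,
                    I[i, j - 1] - gap_open)
            codes = (0, 1, 2)
            target = D[i, j]
            j = j - 1
        else:  # I: residue i-1 inserted
            vals = (M[i - 1, j] - gap_open, I[i - 1, j] - gap_ext,
                    D[i - 1, j] - gap_open)
            codes = (0, 2, 1)
            target = I[i, j]
            i = i - 1
        if (i == 0 and j == 0) or j == 0:
            break  # leading residues (if any) are free
        if i == 0:
            state = 1
        else:
            nxt = None
            for c, v in zip(codes, vals):
                if abs(v - target) <= _EPS:
                    nxt = c
                    break
            if nxt is None:  # numerical safety: take the max predecessor
                nxt = codes[int(np.argmax(np.array(vals)))]
            state = nxt
    return float(score), trace
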