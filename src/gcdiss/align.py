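"""Affine-gap pairwise alignment kernels (desk-scale, numba-jitted).

Scoring is fixed and documented: match +1, mismatch -1, gap open -2
(first gapped column), gap extension -1 (each further column). Global
alignment is end-to-end Needleman-Wunsch/Gotoh; local alignment is
Smith-Waterman with the same scores. Traceback tie-break is
deterministic: diagonal over vertical over horizontal, so identical
inputs always give identical alignments.

These kernels target 16S genes, 1-kb genome fragments and toy proteomes —
thousands of bases, not megabases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0  # score of the first column of a gap
GAP_EXTEND = -1.0  # score of each subsequent column

_NEG = -1e30

# traceback codes: state M/Ix/Iy x predecessor state
_DIAG, _UP, _LEFT = 1, 2, 3


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment with its score and identity bookkeeping.

    ``identity_pct`` uses the full alignment length (gap columns included)
    as denominator, the "global identity" convention of usearch-style
    tools. For local alignments the spans give the 0-based half-open
    aligned region on each input sequence.
    """

    score: float
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int
    a_span: tuple[int, int]
    b_span: tuple[int, int]

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


@njit(cache=True)
def _gotoh_global(a, b):  # pragma: no cover - exercised via wrapper
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (vertical, consumes a)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (horizontal, consumes b)
    tb_m = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_x = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_y = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        tb_x[i, 0] = _UP
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
        tb_y[0, j] = _LEFT
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            # M: diagonal step from the best of the three states
            best, code = M[i - 1, j - 1], 1
            if X[i - 1, j - 1] > best:
                best, code = X[i - 1, j - 1], 2
            if Y[i - 1, j - 1] > best:
                best, code = Y[i - 1, j - 1], 3
            M[i, j] = best + s
            tb_m[i, j] = code
            # X: vertical gap (a consumed, b gapped)
            open_x = M[i - 1, j] + GAP_OPEN
            ext_x = X[i - 1, j] + GAP_EXTEND
            if open_x >= ext_x:
                X[i, j] = open_x
                tb_x[i, j] = 1
            else:
                X[i, j] = ext_x
                tb_x[i, j] = 2
            # Y: horizontal gap
            open_y = M[i, j - 1] + GAP_OPEN
            ext_y = Y[i, j - 1] + GAP_EXTEND
            if open_y >= ext_y:
                Y[i, j] = open_y
                tb_y[i, j] = 1
            else:
                Y[i, j] = ext_y
                tb_y[i, j] = 3
    return M, X, Y, tb_m, tb_x, tb_y


@njit(cache=True)
def _sw_local(a, b):  # pragma: no cover - exercised via wrapper
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    tb_m = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_x = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_y = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best_score = 0.0
    best_i, best_j = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            best, code = M[i - 1, j - 1], 1
            if X[i - 1, j - 1] > best:
                best, code = X[i - 1, j - 1], 2
            if Y[i - 1, j - 1] > best:
                best, code = Y[i - 1, j - 1], 3
            v = best + s
            if v <= 0.0:
                M[i, j] = 0.0
                tb_m[i, j] = 0  # local start
            else:
                M[i, j] = v
                tb_m[i, j] = code
            open_x = M[i - 1, j] + GAP_OPEN
            ext_x = X[i - 1, j] + GAP_EXTEND
            if open_x >= ext_x:
                X[i, j] = open_x
                tb_x[i, j] = 1
            else:
                X[i, j] = ext_x
                tb_x[i, j] = 2
            open_y = M[i, j - 1] + GAP_OPEN
            ext_y = Y[i, j - 1] + GAP_EXTEND
            if open_y >= ext_y:
                Y[i, j] = open_y
                tb_y[i, j] = 1
            else:
                Y[i, j] = ext_y
                tb_y[i, j] = 3
            if M[i, j] > best_score:
                best_score = M[i, j]
                best_i, best_j = i, j
    return M, X, Y, tb_m, tb_x, tb_y, best_score, best_i, best_j


@njit(cache=True, fastmath=True)
def _sw_score_end(a, b):  # pragma: no cover - exercised via wrapper
    """Score-only Smith-Waterman: best score and its first-found end cell.

    Rolling one-row state (M, X, Y per column); used to restrict the
    traceback DP to a subject window around the optimum.
    """
    n, m = len(a), len(b)
    m_prev = np.zeros(m + 1)
    x_prev = np.full(m + 1, _NEG)
    y_prev = np.full(m + 1, _NEG)
    m_cur = np.zeros(m + 1)
    x_cur = np.full(m + 1, _NEG)
    y_cur = np.full(m + 1, _NEG)
    best = 0.0
    best_i, best_j = 0, 0
    for i in range(1, n + 1):
        m_cur[0] = 0.0
        x_cur[0] = _NEG
        y_cur[0] = _NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            diag = m_prev[j - 1]
            if x_prev[j - 1] > diag:
                diag = x_prev[j - 1]
            if y_prev[j - 1] > diag:
                diag = y_prev[j - 1]
            mm = diag + s
            m_cur[j] = mm if mm > 0.0 else 0.0
            ox = m_prev[j] + GAP_OPEN
            ex = x_prev[j] + GAP_EXTEND
            x_cur[j] = ox if ox >= ex else ex
            oy = m_cur[j - 1] + GAP_OPEN
            ey = y_cur[j - 1] + GAP_EXTEND
            y_cur[j] = oy if oy >= ey else ey
            if m_cur[j] > best:
                best = m_cur[j]
                best_i, best_j = i, j
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev
    return best, best_i, best_j


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _traceback(a, b, tb_m, tb_x, tb_y, i, j, state, local):
    """Walk traceback matrices from (i, j); returns aligned strings + spans."""
    out_a: list[str] = []
    out_b: list[str] = []
    end_i, end_j = i, j
    while i > 0 or j > 0:
        if state == 0:  # M state
            code = tb_m[i, j]
            if local and code == 0:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = {1: 0, 2: 1, 3: 2}[code]
        elif state == 1:  # X: gap in b
            code = tb_x[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            state = 0 if code == 1 else 1
        else:  # Y: gap in a
            code = tb_y[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            state = 0 if code == 1 else 2
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return aligned_a, aligned_b, matches, (i, end_i), (j, end_j)


def global_align(a: str, b: str) -> Alignment:
    """Optimal end-to-end alignment of two non-empty sequences."""
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    ea, eb = _encode(a), _encode(b)
    M, X, Y, tb_m, tb_x, tb_y = _gotoh_global(ea, eb)
    n, m = len(a), len(b)
    scores = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(scores))
    aligned_a, aligned_b, matches, a_span, b_span = _traceback(
        a, b, tb_m, tb_x, tb_y, n, m, state, local=False
    )
    return Alignment(
        score=float(scores[state]),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        matches=matches,
        columns=len(aligned_a),
        a_span=a_span,
        b_span=b_span,
    )


def local_align(a: str, b: str) -> Alignment | None:
    """Best local alignment, or None when no positive-scoring pair exists.

    Two passes: a rolling score-only scan over the full subject locates
    the optimum's end cell, then the traceback DP runs on a subject
    window guaranteed to contain the whole alignment (an alignment with
    positive score spans fewer than ``2*len(a)`` subject columns, since
    every gap column must be paid for by a match).
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    ea, eb = _encode(a), _encode(b)
    best, bi, bj = _sw_score_end(ea, eb)
    if best <= 0.0:
        return None
    start = max(0, int(bj) - (2 * len(a) + 8))
    window = b[start : int(bj)]
    M, X, Y, tb_m, tb_x, tb_y, best_w, wi, wj = _sw_local(ea, _encode(window))
    if best_w < best:  # defensive: window missed the optimum, rescan fully
        start = 0
        window = b
        M, X, Y, tb_m, tb_x, tb_y, best_w, wi, wj = _sw_local(ea, eb)
    aligned_a, aligned_b, matches, a_span, b_span = _traceback(
        a, window, tb_m, tb_x, tb_y, int(wi), int(wj), 0, local=True
    )
    return Alignment(
        score=float(best_w),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        matches=matches,
        columns=len(aligned_a),
        a_span=a_span,
        b_span=(b_span[0] + start, b_span[1] + start),
    )
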