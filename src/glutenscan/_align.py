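"""Optimal pairwise alignment with affine gaps (Gotoh algorithm).

Local (Smith-Waterman) and global (Needleman-Wunsch) modes over integer
substitution scores; a gap of length k scores ``gap_open + (k-1) *
gap_extend`` (defaults -10 / -1, BLOSUM62).

Percent identity can differ between co-optimal alignments, so the
traceback is canonical: the end point is the highest-scoring cell with
the smallest query index, then subject index; at every step a
substitution is preferred over a gap in the query, which is preferred
over a gap in the subject; closing a gap is preferred over extending
it.  Identity is matches / alignment columns (gap columns included).

All scores are exact int64 arithmetic; the forward recursions are
JIT-compiled with numba when available.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

NEG = -(2**30)


# ---------------------------------------------------------------- scoring

@lru_cache(maxsize=None)
def blosum62() -> tuple[str, np.ndarray]:
    """(alphabet, int64 matrix) for BLOSUM62."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    arr = np.array(m, dtype=np.int64)
    return alphabet, arr


def encode(seq: str, alphabet: str) -> np.ndarray:
    idx = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        pos = alphabet.find(ch)
        if pos < 0:
            raise ValueError(f"residue {ch!r} not in substitution-matrix alphabet")
        idx[i] = pos
    return idx


# ------------------------------------------------------------- forward DP

def _forward_local_py(a, b, sub, open_, ext):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + open_
            e2 = E[i, j - 1] + ext
            E[i, j] = e if e >= e2 else e2
            f = H[i - 1, j] + open_
            f2 = F[i - 1, j] + ext
            F[i, j] = f if f >= f2 else f2
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if h < 0:
                h = 0
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    return H, E, F


def _forward_global_py(a, b, sub, open_, ext):
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = open_ + (j - 1) * ext
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = open_ + (i - 1) * ext
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + open_
            e2 = E[i, j - 1] + ext
            E[i, j] = e if e >= e2 else e2
            f = H[i - 1, j] + open_
            f2 = F[i - 1, j] + ext
            F[i, j] = f if f >= f2 else f2
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    return H, E, F


try:  # pragma: no cover - exercised wherever numba is present
    from numba import njit

    _forward_local = njit(cache=False)(_forward_local_py)
    _forward_global = njit(cache=False)(_forward_global_py)
except Exception:  # pragma: no cover
    _forward_local = _forward_local_py
    _forward_global = _forward_global_py


# -------------------------------------------------------------- traceback

@dataclass(frozen=True)
class AlignmentResult:
    """Score and canonical-alignment statistics for one pair."""

    score: int
    matches: int
    columns: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    @property
    def aligned_length(self) -> int:
        return self.columns


def _traceback(a, b, sub, open_, H, E, F, i, j, stop_at_zero: bool):
    matches = 0
    columns = 0
    a_end, b_end = i, j
    state = "H"
    while True:
        if state == "H":
            if stop_at_zero and H[i, j] == 0:
                break
            if not stop_at_zero and i == 0 and j == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "E":  # gap in a, consumes b[j-1]
            columns += 1
            if E[i, j] == H[i, j - 1] + open_:
                state = "H"
            j -= 1
        else:  # state == "F": gap in b, consumes a[i-1]
            columns += 1
            if F[i, j] == H[i - 1, j] + open_:
                state = "H"
            i -= 1
    return matches, columns, i, a_end, j, b_end


def align(
    a: str,
    b: str,
    mode: str = "local",
    gap_open: int = -10,
    gap_extend: int = -1,
    matrix: tuple[str, np.ndarray] | None = None,
) -> AlignmentResult:
    """Optimal pairwise alignment of ``a`` against ``b``.

    Local mode returns the empty alignment (score 0, identity 0) when no
    positive-scoring alignment exists.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if mode not in {"local", "global"}:
        raise ValueError(f"unknown alignment mode {mode!r}")
    alphabet, sub = matrix if matrix is not None else blosum62()
    ai = encode(a, alphabet)
    bi = encode(b, alphabet)
    if mode == "local":
        H, E, F = _forward_local(ai, bi, sub, gap_open, gap_extend)
        # canonical end point: best score, then smallest i, then smallest j
        flat = int(np.argmax(H))
        best = int(H.flat[flat])
        if best <= 0:
            return AlignmentResult(0, 0, 0, 0, 0, 0, 0)
        i, j = divmod(flat, H.shape[1])
        matches, columns, a_start, a_end, b_start, b_end = _traceback(
            ai, bi, sub, gap_open, H, E, F, i, j, stop_at_zero=True
        )
        return AlignmentResult(best, matches, columns, a_start, a_end, b_start, b_end)
    H, E, F = _forward_global(ai, bi, sub, gap_open, gap_extend)
    n, m = len(ai), len(bi)
    matches, columns, a_start, a_end, b_start, b_end = _traceback(
        ai, bi, sub, gap_open, H, E, F, n, m, stop_at_zero=False
    )
    return AlignmentResult(int(H[n, m]), matches, columns, 0, n, 0, m)
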