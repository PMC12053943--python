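"""Shared fixtures and independent oracles.

The oracles here deliberately do not share code with the package: the
digestion oracle enumerates substrings and re-applies the cleavage rule
position by position; the alignment oracle is a list-of-lists Gotoh DP
with the same canonical tie-break definition but none of the package's
machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM = substitution_matrices.load("BLOSUM62")
_NEG = -(10**9)


# ------------------------------------------------------- digestion oracle

def brute_force_digest(sequence: str, max_missed: int = 2, min_len: int = 1) -> dict[str, int]:
    """Enumerate all substrings; keep those whose boundaries are cleavage
    sites (or sequence ends) and whose interiors contain at most
    ``max_missed`` sites.  The rule is re-applied at every position:
    cleave after Y/F/W/L unless the next residue is P."""
    n = len(sequence)
    is_site = [
        sequence[i] in "YFWL" and i + 1 < n and sequence[i + 1] != "P"
        for i in range(n)
    ]
    out: dict[str, int] = {}
    for i in range(n):
        if not (i == 0 or is_site[i - 1]):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or is_site[j - 1]):
                continue
            internal = sum(1 for k in range(i, j - 1) if is_site[k])
            if internal > max_missed:
                continue
            pep = sequence[i:j]
            if len(pep) < min_len:
                continue
            if pep not in out or internal < out[pep]:
                out[pep] = internal
    return out


# ------------------------------------------------------- alignment oracle

def oracle_align_local(a: str, b: str, open_: int = -10, ext: int = -1):
    """Canonical Smith-Waterman-Gotoh: (score, matches, columns)."""

    def s(x: str, y: str) -> int:
        return int(_BLOSUM[x, y])

    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            H[i][j] = max(0, H[i - 1][j - 1] + s(a[i - 1], b[j - 1]), E[i][j], F[i][j])
    best = bi = bj = 0
    for i in range(n + 1):
        for j in range(m + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0, 0, 0
    i, j, state = bi, bj, "H"
    matches = cols = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + s(a[i - 1], b[j - 1]):
                cols += 1
                matches += a[i - 1] == b[j - 1]
                i -= 1
                j -= 1
            elif j > 0 and H[i][j] == E[i][j]:
                state = "E"
            elif i > 0 and H[i][j] == F[i][j]:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i][j] == H[i][j - 1] + open_:
                state = "H"
            j -= 1
        else:
            cols += 1
            if F[i][j] == H[i - 1][j] + open_:
                state = "H"
            i -= 1
    return best, matches, cols


def oracle_align_global(a: str, b: str, open_: int = -10, ext: int = -1):
    """Canonical Needleman-Wunsch-Gotoh: (score, matches, columns)."""

    def s(x: str, y: str) -> int:
        return int(_BLOSUM[x, y])

    n, m = len(a), len(b)
    H = [[_NEG] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0
    for j in range(1, m + 1):
        E[0][j] = open_ + (j - 1) * ext
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = open_ + (i - 1) * ext
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            H[i][j] = max(H[i - 1][j - 1] + s(a[i - 1], b[j - 1]), E[i][j], F[i][j])
    i, j, state = n, m, "H"
    matches = cols = 0
    while True:
        if state == "H":
            if i == 0 and j == 0:
                break
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + s(a[i - 1], b[j - 1]):
                cols += 1
                matches += a[i - 1] == b[j - 1]
                i -= 1
                j -= 1
            elif j > 0 and H[i][j] == E[i][j]:
                state = "E"
            elif i > 0 and H[i][j] == F[i][j]:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i][j] == H[i][j - 1] + open_:
                state = "H"
            j -= 1
        else:
            cols += 1
            if F[i][j] == H[i - 1][j] + open_:
                state = "H"
            i -= 1
    return H[n][m], matches, cols


# -------------------------------------------------------------- fixtures

def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def make_design(samples=("w",), n_bio: int = 3, n_tech: int = 3):
    from glutenscan.curation import ReplicateDesign

    rows = [
        {"sample_id": s, "bio_rep": b, "tech_rep": t, "run_id": f"{s}_b{b}_t{t}"}
        for s in samples
        for b in range(1, n_bio + 1)
        for t in range(1, n_tech + 1)
    ]
    return ReplicateDesign(pd.DataFrame(rows))


def make_obs(rows):
    """rows: (run_id, peptide, score, raw_abundance[, modifications])"""
    recs = []
    for row in rows:
        run, pep, score, raw = row[:4]
        mods = row[4] if len(row) > 4 else ""
        recs.append(
            {
                "run_id": run,
                "peptide": pep,
                "modifications": mods,
                "score": float(score),
                "raw_abundance": float(raw),
            }
        )
    return pd.DataFrame(recs, columns=["run_id", "peptide", "modifications", "score", "raw_abundance"])


@pytest.fixture
def design_3x3():
    return make_design()


@pytest.fixture
def curation_fixture():
    """Hand-built 3 bio x 3 tech sample with peptides planned to pass or
    fail each curation rule.

    PASSALL  : 2/3 tech reps in every bio rep, score 10   -> retained
    BOUND5   : score exactly 5, 3 tech reps of bio 1 only -> retained
    LOWSCORE : score 4 everywhere                         -> removed (score)
    ONETECH  : single tech rep of bio 1, absent elsewhere -> removed (replicate)
    MIXEDREP : 2 tech reps in bio 1 but 1 in bio 2        -> removed (replicate, strict rule)
    BOTHBAD  : score 4 and a single tech rep              -> removed (score;replicate)
    """
    rows = []
    for b in (1, 2, 3):
        for t in (1, 2):
            rows.append((f"w_b{b}_t{t}", "PASSALL", 10, 100.0))
    for t in (1, 2, 3):
        rows.append((f"w_b1_t{t}", "BOUND5", 5, 50.0))
    for b in (1, 2, 3):
        for t in (1, 2):
            rows.append((f"w_b{b}_t{t}", "LOWSCORE", 4, 10.0))
    rows.append(("w_b1_t1", "ONETECH", 9, 30.0))
    rows.append(("w_b1_t1", "MIXEDREP", 9, 20.0))
    rows.append(("w_b1_t2", "MIXEDREP", 9, 20.0))
    rows.append(("w_b2_t1", "MIXEDREP", 9, 20.0))
    rows.append(("w_b3_t3", "BOTHBAD", 4, 5.0))
    return make_obs(rows), make_design()
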