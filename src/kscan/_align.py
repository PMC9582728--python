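"""Affine-gap Smith-Waterman engine.

A Gotoh-style local aligner over BLOSUM-family matrices, JIT-compiled
with numba.  A gap of length k costs ``open + k * extend`` (the opening
charge is applied on the first gap residue, the BLAST convention for
"11/1" gap costs).  Translated stop codons ('*') carry a prohibitive
substitution score so no local alignment can cross a stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: Residue ordering used for integer encoding; matches the Biopython
#: BLOSUM62 alphabet.
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: Score forbidding a column; large enough that no optimal local
#: alignment ever includes it, small enough not to overflow int32 sums.
FORBIDDEN = -(10**6)


@lru_cache(maxsize=None)
def score_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Integer substitution matrix over :data:`ALPHABET`.

    Unknown residues are scored as 'X'; '*' is unalignable.
    """
    mat = substitution_matrices.load(name)
    n = len(ALPHABET)
    out = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(mat[a, b])
    stop = _INDEX["*"]
    out[stop, :] = FORBIDDEN
    out[:, stop] = FORBIDDEN
    return out


def encode(seq: str) -> np.ndarray:
    """Encode an amino acid string as indices into :data:`ALPHABET`.

    Characters outside the alphabet map to 'X'.
    """
    x = _INDEX["X"]
    return np.fromiter(
        (_INDEX.get(c, x) for c in seq.upper()), dtype=np.int8, count=len(seq)
    )


@njit(cache=True)
def _sw_fill(q, d, sub, gap_open, gap_extend):  # pragma: no cover - jit
    n = q.shape[0]
    m = d.shape[0]
    neg = np.int32(-(10**8))
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), neg, dtype=np.int32)
    F = np.full((n + 1, m + 1), neg, dtype=np.int32)
    # traceback pointers: pH 0 stop, 1 diag, 2 from E, 3 from F
    #                     pE/pF 0 opened from H, 1 extended
    pH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    go = np.int32(gap_open + gap_extend)
    ge = np.int32(gap_extend)
    stop = np.int8(23)  # index of '*': neither substitutions nor gaps may consume it
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            if d[j - 1] == stop:
                E[i, j] = neg
                pE[i, j] = 0
            else:
                e_open = H[i, j - 1] - go
                e_ext = E[i, j - 1] - ge
                if e_open >= e_ext:
                    E[i, j] = e_open
                    pE[i, j] = 0
                else:
                    E[i, j] = e_ext
                    pE[i, j] = 1
            if qi == stop:
                F[i, j] = neg
                pF[i, j] = 0
            else:
                f_open = H[i - 1, j] - go
                f_ext = F[i - 1, j] - ge
                if f_open >= f_ext:
                    F[i, j] = f_open
                    pF[i, j] = 0
                else:
                    F[i, j] = f_ext
                    pF[i, j] = 1
            diag = H[i - 1, j - 1] + sub[qi, d[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            H[i, j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, pH, pE, pF


@njit(cache=True)
def _sw_traceback(bi, bj, pH, pE, pF):  # pragma: no cover - jit
    # walk back from the best cell; -1 marks a gap on that side
    cap = bi + bj
    qa = np.empty(cap, dtype=np.int32)
    da = np.empty(cap, dtype=np.int32)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0 and j > 0:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                qa[k] = i - 1
                da[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            qa[k] = -1
            da[k] = j - 1
            k += 1
            if pE[i, j] == 0:
                state = 0
            j -= 1
        else:
            qa[k] = i - 1
            da[k] = -1
            k += 1
            if pF[i, j] == 0:
                state = 0
            i -= 1
    return qa[:k][::-1].copy(), da[:k][::-1].copy()


@njit(cache=True)
def _sw_score_only(q, d, sub, gap_open, gap_extend):  # pragma: no cover - jit
    n = q.shape[0]
    m = d.shape[0]
    neg = np.int32(-(10**8))
    go = np.int32(gap_open + gap_extend)
    ge = np.int32(gap_extend)
    stop = np.int8(23)
    Hprev = np.zeros(m + 1, dtype=np.int32)
    Hcur = np.zeros(m + 1, dtype=np.int32)
    Fcol = np.full(m + 1, neg, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        qi = q[i - 1]
        e = neg
        Hcur[0] = 0
        for j in range(1, m + 1):
            if d[j - 1] == stop:
                e = neg
            else:
                e_open = Hcur[j - 1] - go
                e_ext = e - ge
                e = e_open if e_open >= e_ext else e_ext
            if qi == stop:
                f = neg
            else:
                f_open = Hprev[j] - go
                f_ext = Fcol[j] - ge
                f = f_open if f_open >= f_ext else f_ext
            Fcol[j] = f
            h = Hprev[j - 1] + sub[qi, d[j - 1]]
            if h < 0:
                h = 0
            if e > h:
                h = e
            if f > h:
                h = f
            Hcur[j] = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
    return best


@dataclass(frozen=True)
class LocalAlignment:
    """Result of an affine-gap local alignment.

    Coordinates are 1-based inclusive on the input sequences; an empty
    alignment (score 0) has zero-length spans.
    """

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_query: str
    aligned_target: str
    identities: int
    length: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.length if self.length else 0.0


def smith_waterman(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two peptide strings.

    Returns the single best-scoring local alignment (ties broken toward
    the smallest end coordinates, then diagonal moves).  Stops ('*')
    never align, so alignments cannot span a translated stop codon.
    """
    if not query or not target:
        raise ValueError("smith_waterman requires non-empty sequences")
    sub = score_matrix(matrix)
    q = encode(query)
    d = encode(target)
    score, bi, bj, pH, pE, pF = _sw_fill(q, d, sub, gap_open, gap_extend)
    if score <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "", 0, 0)
    qa, da = _sw_traceback(bi, bj, pH, pE, pF)
    aq = "".join(query[i] if i >= 0 else "-" for i in qa)
    at = "".join(target[j] if j >= 0 else "-" for j in da)
    ident = sum(1 for a, b in zip(aq, at) if a == b and a != "-")
    qpos = qa[qa >= 0]
    dpos = da[da >= 0]
    return LocalAlignment(
        score=int(score),
        query_start=int(qpos.min()) + 1,
        query_end=int(qpos.max()) + 1,
        target_start=int(dpos.min()) + 1,
        target_end=int(dpos.max()) + 1,
        aligned_query=aq,
        aligned_target=at,
        identities=ident,
        length=len(aq),
    )


def sw_score(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Score-only Smith-Waterman (linear memory, no traceback)."""
    if not query or not target:
        raise ValueError("sw_score requires non-empty sequences")
    sub = score_matrix(matrix)
    return int(_sw_score_only(encode(query), encode(target), sub, gap_open, gap_extend))
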