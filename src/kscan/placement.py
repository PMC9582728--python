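"""Phylogenetic placement of trimmed query domains.

Trimmed domains are merged into the fixed, prealigned reference
alignment by profile alignment (reference columns are never reordered;
query-only insertions add all-gap columns), and an approximate
neighbor-joining tree over Kimura-corrected protein distances provides
a visual check that each query falls within its assigned class clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from ._align import ALPHABET, _INDEX, encode, score_matrix
from .errors import DataError
from .search import SearchParams


@dataclass
class MergedAlignment:
    """Reference rows plus aligned query rows, all of equal length."""

    reference_rows: dict[str, str]
    query_rows: dict[str, str]
    n_columns: int

    @property
    def rows(self) -> dict[str, str]:
        return {**self.reference_rows, **self.query_rows}


def _profile_scores(ref_rows: Sequence[str], matrix: str) -> np.ndarray:
    """Per-column position-specific scores.

    Entry ``[a, c]`` is the mean substitution score of residue ``a``
    against the non-gap residues in reference column ``c``.
    """
    sub = score_matrix(matrix).astype(np.float64)
    n_cols = len(ref_rows[0])
    counts = np.zeros((len(ALPHABET), n_cols))
    for row in ref_rows:
        for c, ch in enumerate(row):
            if ch != "-":
                counts[_INDEX.get(ch, _INDEX["X"]), c] += 1
    occupancy = counts.sum(axis=0)
    occupancy[occupancy == 0] = 1.0
    return (sub @ counts) / occupancy


def _align_query_to_profile(
    query: str, profile: np.ndarray, gap_open: int, gap_extend: int
) -> tuple[list[str], dict[int, str]]:
    """Global affine alignment of a query to the reference profile.

    Returns the per-column query characters ('-' for deletions) and a
    map of insertion position -> inserted residues (insertions after
    reference column p; p = 0 means before the first column).
    """
    q = encode(query)
    n, m = len(q), profile.shape[1]
    go, ge = gap_open + gap_extend, gap_extend
    neg = -1e18
    H = np.full((n + 1, m + 1), neg)
    E = np.full((n + 1, m + 1), neg)  # gap in query (deletion, consume column)
    F = np.full((n + 1, m + 1), neg)  # gap in profile (insertion, consume residue)
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = max(H[0, j - 1] - go, E[0, j - 1] - ge)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = max(H[i - 1, 0] - go, F[i - 1, 0] - ge)
        H[i, 0] = F[i, 0]
        for j in range(1, m + 1):
            e_open, e_ext = H[i, j - 1] - go, E[i, j - 1] - ge
            E[i, j] = max(e_open, e_ext)
            ptr[i, j, 1] = 0 if e_open >= e_ext else 1
            f_open, f_ext = H[i - 1, j] - go, F[i - 1, j] - ge
            F[i, j] = max(f_open, f_ext)
            ptr[i, j, 2] = 0 if f_open >= f_ext else 1
            diag = H[i - 1, j - 1] + profile[q[i - 1], j - 1]
            best, p = diag, 0
            if E[i, j] > best:
                best, p = E[i, j], 1
            if F[i, j] > best:
                best, p = F[i, j], 2
            H[i, j] = best
            ptr[i, j, 0] = p
    # traceback
    per_column = ["-"] * m
    insertions: dict[int, str] = {}
    i, j, state = n, m, 0
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
            continue
        if j == 0:
            insertions[0] = query[i - 1] + insertions.get(0, "")
            i -= 1
            continue
        if state == 0:
            p = ptr[i, j, 0]
            if p == 0:
                per_column[j - 1] = query[i - 1]
                i -= 1
                j -= 1
            else:
                state = int(p)
        elif state == 1:
            if ptr[i, j, 1] == 0:
                state = 0
            j -= 1
        else:
            insertions[j] = query[i - 1] + insertions.get(j, "")
            if ptr[i, j, 2] == 0:
                state = 0
            i -= 1
    return per_column, insertions


def align_to_reference(
    trimmed_domains: Mapping[str, str],
    reference_alignment: Mapping[str, str],
    params: SearchParams = SearchParams(),
) -> MergedAlignment:
    """Merge trimmed query domains into the fixed reference alignment.

    Each query is aligned against the column-wise profile of the
    reference alignment; reference columns keep their order and
    query-only insertions introduce new all-gap columns in every other
    row.  With no queries the reference alignment is returned unchanged.
    """
    ref_ids = list(reference_alignment)
    if not ref_ids:
        raise DataError("reference alignment is empty")
    ref_rows = [reference_alignment[r] for r in ref_ids]
    n_cols = len(ref_rows[0])
    if any(len(r) != n_cols for r in ref_rows):
        raise DataError("reference alignment rows differ in length")
    if not trimmed_domains:
        return MergedAlignment(dict(reference_alignment), {}, n_cols)
    profile = _profile_scores(ref_rows, params.matrix)
    aligned_queries: dict[str, tuple[list[str], dict[int, str]]] = {}
    for qid, seq in trimmed_domains.items():
        if not seq:
            raise DataError(f"trimmed domain {qid!r} is empty")
        aligned_queries[qid] = _align_query_to_profile(
            seq, profile, params.gap_open, params.gap_extend
        )
    # width of the insertion block after each reference column (queries
    # do not share insertion columns)
    order = list(aligned_queries)
    widths = [0] * (n_cols + 1)
    offsets: dict[str, list[int]] = {}
    for qid in order:
        _, ins = aligned_queries[qid]
        offsets[qid] = [widths[p] for p in range(n_cols + 1)]
        for p, residues in ins.items():
            widths[p] += len(residues)

    def build_row(per_column: Sequence[str], ins: dict[int, str], off: list[int]) -> str:
        parts = []
        for p in range(n_cols + 1):
            block = ["-"] * widths[p]
            if p in ins:
                block[off[p] : off[p] + len(ins[p])] = list(ins[p])
            parts.append("".join(block))
            if p < n_cols:
                parts.append(per_column[p])
        return "".join(parts)

    gap_off = [0] * (n_cols + 1)
    new_ref = {
        rid: build_row(list(row), {}, gap_off)
        for rid, row in reference_alignment.items()
    }
    new_q = {
        qid: build_row(*aligned_queries[qid], offsets[qid]) for qid in order
    }
    total_cols = n_cols + sum(widths)
    return MergedAlignment(new_ref, new_q, total_cols)


def kimura_distance(row_a: str, row_b: str, max_distance: float = 10.0) -> float:
    """Kimura-corrected protein distance with pairwise gap deletion.

    d = -ln(1 - p - p^2/5) over columns where neither row has a gap;
    distances undefined by the correction (p too large) are capped at
    ``max_distance``.
    """
    same = diff = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        if a == b:
            same += 1
        else:
            diff += 1
    total = same + diff
    if total == 0:
        return max_distance
    p = diff / total
    arg = 1.0 - p - p * p / 5.0
    if arg <= 0:
        return max_distance
    return min(-math.log(arg), max_distance)


def build_tree(
    alignment: MergedAlignment | Mapping[str, str],
    method: str = "nj",
    max_distance: float = 10.0,
) -> str:
    """Neighbor-joining tree over the merged alignment, as newick.

    Negative branch lengths from NJ are clamped to zero.  Requires at
    least three rows.
    """
    rows = alignment.rows if isinstance(alignment, MergedAlignment) else dict(alignment)
    if len(rows) < 3:
        raise DataError("tree building requires at least 3 sequences")
    if method != "nj":
        raise DataError(f"unknown tree method {method!r}")
    ids = list(rows)
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kimura_distance(rows[ids[i]], rows[ids[j]], max_distance)
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids), neg_as_zero=True)
    return str(tree).strip()
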