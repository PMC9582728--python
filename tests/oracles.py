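"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive re-derivations (state-explicit dynamic
programming, pair counting) kept free of any code from the package's
own alignment or ROC paths.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    if a == "*" or b == "*":
        return float("-inf")
    return float(_B62[a, b])


def brute_force_local_score(
    query: str, target: str, gap_open: int = 11, gap_extend: int = 1
) -> int:
    """Optimal affine-gap local alignment score by explicit 3-state DP.

    States: M (last column is a substitution), X (gap in target,
    consuming query), Y (gap in query, consuming target).  A gap of
    length k costs open + k * extend.
    """
    n, m = len(query), len(target)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum62(query[i - 1], target[j - 1])
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = prev + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open - gap_extend,
            )
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return int(best)


def pair_count_auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: (concordant pairs + half ties) / all pairs."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def exhaustive_best_cutoff(pos_evalues, neg_evalues):
    """Enumerate all candidate E-value cutoffs; return the smallest one
    keeping every finite positive, with its sensitivity/specificity."""
    finite_pos = [e for e in pos_evalues if e != float("inf")]
    candidates = sorted(set(finite_pos) | {e for e in neg_evalues if e != float("inf")})
    best = None
    for c in candidates:
        sens = sum(1 for e in pos_evalues if e <= c) / len(pos_evalues)
        spec = sum(1 for e in neg_evalues if not e <= c) / len(neg_evalues)
        if sens >= len(finite_pos) / len(pos_evalues):
            if best is None or c < best[0]:
                best = (c, sens, spec)
    return best
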