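"""Statistical calibration of detection thresholds.

Implements the validation framework used to set the pipeline defaults:
leave-one-out cross-validation (each labeled control is scored by the
E-value of its best non-self database match), ROC curves and AUC over
those scores, selection of the most restrictive E-value cutoff that
retains 100% sensitivity, and sliding-window fragmentation of positive
controls to measure how detection and classification accuracy degrade
with query length.

Scores are handled as -log10(E-value) so that "more restrictive"
means "larger"; controls with no database match score 0 (the no-hit
sentinel) and can never be detected at any cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import PipelineParams
from .errors import DataError
from .refdb import ReferenceDB
from .search import Hit, QueryRecord, SearchParams, search_all

NO_HIT = float("inf")  # sentinel E-value; -log10 score of 0 is applied below


@dataclass
class ControlSet:
    """Labeled positive and negative control proteins.

    ``positives`` maps id -> (sequence, true class label); ``negatives``
    maps id -> sequence.  Ids must not collide.
    """

    positives: dict[str, tuple[str, str]]
    negatives: dict[str, str]

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise DataError(f"controls appear in both sets: {sorted(overlap)}")


def score_from_evalue(evalue: float) -> float:
    """-log10 E-value with the no-hit sentinel mapped to 0."""
    if math.isinf(evalue):
        return 0.0
    return max(-math.log10(evalue), 0.0)


def loocv_scores(
    controls: Mapping[str, str],
    db: ReferenceDB,
    params: SearchParams = SearchParams(),
    exclude_ids: Mapping[str, set[str]] | None = None,
) -> dict[str, float]:
    """Best non-self E-value for each control sequence.

    A database match is "self" if it shares the control's id or its
    exact sequence; ``exclude_ids`` can add per-control exclusions
    (e.g. the parent of a window fragment).  Controls with no remaining
    match get the no-hit sentinel (``inf``).
    """
    if not db.domains:
        raise DataError("loocv_scores requires a non-empty database")
    out: dict[str, float] = {}
    for cid, seq in controls.items():
        extra = exclude_ids.get(cid, set()) if exclude_ids else set()
        best = NO_HIT
        hits = search_all([QueryRecord(cid, seq, "protein")], db, params)
        for h in hits:
            dom = db.get(h.db_id)
            if dom.id == cid or dom.id in extra or dom.sequence == seq:
                continue
            best = min(best, h.evalue)
        out[cid] = best
    return out


def best_nonself_hit(
    cid: str,
    seq: str,
    db: ReferenceDB,
    params: SearchParams,
    exclude: set[str] = frozenset(),
) -> Hit | None:
    """Lowest-E-value hit whose match is neither ``cid`` nor excluded."""
    hits = search_all([QueryRecord(cid, seq, "protein")], db, params)
    for h in hits:  # already sorted by evalue
        dom = db.get(h.db_id)
        if dom.id == cid or dom.id in exclude or dom.sequence == seq:
            continue
        return h
    return None


@dataclass
class RocResult:
    """ROC sweep over LOOCV scores plus the selected operating point."""

    pos_scores: list[float]
    neg_scores: list[float]
    points: list[tuple[float, float]]  # (FPR, TPR) along the sweep
    auc: float
    chosen_cutoff_evalue: float = float("nan")
    chosen_cutoff_power10: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")


def roc_auc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> RocResult:
    """ROC curve and trapezoid AUC from positive/negative score sets.

    Thresholds sweep the union of observed scores (predict positive iff
    score >= threshold).  The trapezoid AUC equals the Mann-Whitney
    pair-counting statistic (concordant pairs + half ties).
    """
    if not pos_scores or not neg_scores:
        raise DataError("roc_auc requires non-empty positive and negative sets")
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return RocResult(list(map(float, pos)), list(map(float, neg)), points, auc)


def select_cutoff(
    pos_evalues: Sequence[float], neg_evalues: Sequence[float]
) -> RocResult:
    """Most restrictive E-value cutoff detecting 100% of true positives.

    The cutoff is the maximum finite positive E-value (accept iff
    evalue <= cutoff).  Sensitivity is 1.0 by construction unless some
    positives have no database match at all, in which case the maximum
    attainable sensitivity is reported.  Also reports the nearest
    power-of-ten cutoff that still excludes no positive.
    """
    pos_scores = [score_from_evalue(e) for e in pos_evalues]
    neg_scores = [score_from_evalue(e) for e in neg_evalues]
    result = roc_auc(pos_scores, neg_scores)
    finite = [e for e in pos_evalues if not math.isinf(e)]
    if not finite:
        raise DataError("no positive control has a finite score")
    cutoff = max(finite)
    result.chosen_cutoff_evalue = cutoff
    result.chosen_cutoff_power10 = 10.0 ** math.ceil(math.log10(cutoff))
    result.sensitivity = len(finite) / len(pos_evalues)
    result.specificity = sum(
        1 for e in neg_evalues if math.isinf(e) or e > cutoff
    ) / len(neg_evalues)
    return result


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window fragmentation parameters.

    Overlapping subsequences of each listed size are taken with starts
    offset by ``step``; with ``anchor_final`` a terminal window ending
    exactly at the sequence end is appended when the regular stride
    does not already reach it, so every residue is covered.
    """

    sizes: tuple[int, ...] = (30, 50, 100, 200)
    step: int = 10
    anchor_final: bool = True

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes) or self.step < 1:
            raise ValueError("window sizes and step must be >= 1")


def sliding_windows(
    sequence: str, size: int, step: int = 10, anchor_final: bool = True
) -> list[tuple[int, int, str]]:
    """Overlapping subsequences with 1-based parent coordinates.

    Starts are 1, 1+step, 1+2*step, ... while the window fits; if
    ``anchor_final`` and the last emitted window does not end at the
    sequence end, the terminal window ``[L-size+1, L]`` is appended.
    Returns nothing when ``size`` exceeds the sequence length.
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    length = len(sequence)
    if size > length:
        return []
    out = []
    start = 1
    while start + size - 1 <= length:
        out.append((start, start + size - 1, sequence[start - 1 : start + size - 1]))
        start += step
    if anchor_final and out[-1][1] != length:
        out.append((length - size + 1, length, sequence[length - size :]))
    return out


@dataclass
class LengthAccuracy:
    """Detection and classification rates per window size."""

    per_size: dict[int, dict[str, float]] = field(default_factory=dict)


def length_accuracy(
    positives: Mapping[str, tuple[str, str]],
    db: ReferenceDB,
    windows: WindowSpec = WindowSpec(),
    pipeline: PipelineParams = PipelineParams(),
    search_params: SearchParams = SearchParams(),
    enforce_min_length: bool = False,
) -> LengthAccuracy:
    """Length-robustness benchmark over fragmented positive controls.

    Each positive control (id -> (sequence, true class)) is subdivided
    into sliding windows of each size; each window is searched against
    the database excluding its parent and any identical sequence.  A
    window is detected when its best non-self match passes the E-value
    cutoff (the rule under which the default thresholds were
    calibrated); with ``enforce_min_length`` the match must additionally
    span at least min(size, configured minimum) alignment columns,
    which penalizes local end-trimming on exact-size windows.  A
    detected window is correctly classified when the match's class
    equals the parent's class.
    """
    result = LengthAccuracy()
    for size in windows.sizes:
        n_windows = 0
        n_detected = 0
        n_correct = 0
        min_len = min(size, pipeline.min_alignment_length) if enforce_min_length else 1
        for pid, (seq, true_class) in positives.items():
            for start, end, fragment in sliding_windows(
                seq, size, windows.step, windows.anchor_final
            ):
                n_windows += 1
                hit = best_nonself_hit(
                    f"{pid}:{start}-{end}", fragment, db, search_params,
                    exclude={pid},
                )
                if (
                    hit is None
                    or hit.evalue > pipeline.evalue_cutoff
                    or hit.alignment_length < min_len
                ):
                    continue
                n_detected += 1
                if db.get(hit.db_id).class_label == true_class:
                    n_correct += 1
        result.per_size[size] = {
            "n_windows": n_windows,
            "detection_rate": n_detected / n_windows if n_windows else 0.0,
            "classification_accuracy": (
                n_correct / n_detected if n_detected else 0.0
            ),
        }
    return result
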