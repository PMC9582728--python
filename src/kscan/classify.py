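"""Turn hit tables into accepted, trimmed, classified domain calls.

Classification is nearest-reference: an accepted domain inherits the
class and subclass labels of its single best surviving database match.
Hits are filtered by E-value and minimum alignment length, then
resolved greedily so that no two accepted calls on one query overlap by
more than a configurable fraction; multiple non-overlapping domains per
query are allowed, since a single gene or cluster can carry several
domain types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import DataError
from .refdb import ReferenceDB, Taxonomy
from .search import FrameTranslation, Hit


@dataclass(frozen=True)
class PipelineParams:
    """Detection thresholds.

    Defaults (E-value 1e-8, 200 aa minimum alignment) are the
    statistically calibrated full-length settings; 50 aa is the
    recommended minimum alignment length for amplicon fragments.
    """

    evalue_cutoff: float = 1e-8
    min_alignment_length: int = 200
    overlap_fraction: float = 0.5
    domain_kind: str = "KS"

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.min_alignment_length < 1:
            raise ValueError("min_alignment_length must be >= 1")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")


@dataclass
class DomainCall:
    """An accepted, trimmed, classified domain region on a query."""

    query_id: str
    frame: int
    query_start: int
    query_end: int
    query_nt_start: int | None
    query_nt_end: int | None
    strand: str | None
    best_match_id: str
    class_label: str
    subclass_label: str | None
    evalue: float
    percent_identity: float
    alignment_length: int
    trimmed_sequence: str = ""


def _span(hit: Hit) -> tuple[int, int]:
    if hit.query_nt_start is not None:
        return hit.query_nt_start, hit.query_nt_end
    return hit.query_start, hit.query_end


def _overlap_fraction(a: Hit, b: Hit) -> float:
    """Overlap as a fraction of the shorter span.

    Computed on forward-strand nucleotide coordinates when available
    (so overlapping hits in different frames compete), else on peptide
    coordinates.
    """
    a0, a1 = _span(a)
    b0, b1 = _span(b)
    inter = min(a1, b1) - max(a0, b0) + 1
    if inter <= 0:
        return 0.0
    shorter = min(a1 - a0 + 1, b1 - b0 + 1)
    return inter / shorter


def assign_domains(
    hits: Sequence[Hit],
    db: ReferenceDB,
    params: PipelineParams = PipelineParams(),
    peptides: Mapping[tuple[str, int], str] | None = None,
) -> list[DomainCall]:
    """Filter, greedily resolve, and classify hits into domain calls.

    Surviving hits are grouped by query; the best hit (lowest E-value,
    ties broken by higher bit score then lexicographic database id) is
    accepted and all remaining hits overlapping it by more than
    ``overlap_fraction`` of the shorter span are suppressed, repeating
    until no hits remain.  ``peptides`` maps ``(query_id, frame)`` to
    the frame translation (or protein sequence, frame 0) and is used to
    attach the trimmed domain sequence.
    """
    surviving = [
        h
        for h in hits
        if h.evalue <= params.evalue_cutoff
        and h.alignment_length >= params.min_alignment_length
    ]
    by_query: dict[str, list[Hit]] = {}
    for h in surviving:
        by_query.setdefault(h.query_id, []).append(h)
    calls: list[DomainCall] = []
    for qid in sorted(by_query):
        pool = sorted(
            by_query[qid], key=lambda h: (h.evalue, -h.bit_score, h.db_id)
        )
        while pool:
            best = pool.pop(0)
            pool = [
                h
                for h in pool
                if _overlap_fraction(best, h) <= params.overlap_fraction
            ]
            dom = db.get(best.db_id)
            call = DomainCall(
                query_id=best.query_id,
                frame=best.frame,
                query_start=best.query_start,
                query_end=best.query_end,
                query_nt_start=best.query_nt_start,
                query_nt_end=best.query_nt_end,
                strand=best.strand,
                best_match_id=best.db_id,
                class_label=dom.class_label,
                subclass_label=dom.subclass_label,
                evalue=best.evalue,
                percent_identity=best.percent_identity,
                alignment_length=best.alignment_length,
            )
            if peptides is not None:
                key = (best.query_id, best.frame)
                if key in peptides:
                    call.trimmed_sequence = trim_domain(peptides[key], best)
            calls.append(call)
    calls.sort(key=lambda c: (c.query_id, c.query_nt_start or c.query_start))
    return calls


def trim_domain(peptide: str | FrameTranslation, hit: Hit) -> str:
    """The query peptide spanned by a hit (1-based inclusive, ungapped)."""
    seq = peptide.peptide if isinstance(peptide, FrameTranslation) else peptide
    if not (1 <= hit.query_start <= hit.query_end <= len(seq)):
        raise DataError(
            f"hit span {hit.query_start}..{hit.query_end} outside translation "
            f"of {hit.query_id!r}"
        )
    return seq[hit.query_start - 1 : hit.query_end]


@dataclass
class ClassificationSummary:
    """Hierarchical domain counts (type -> class -> subclass)."""

    total: int
    per_class: dict[str, int]
    per_subclass: dict[str, dict[str, int]]
    per_query: dict[str, list[DomainCall]] = field(default_factory=dict)

    def as_records(self) -> list[dict]:
        rows = []
        for cls, n in sorted(self.per_class.items()):
            rows.append({"class": cls, "subclass": "", "count": n})
            for sub, m in sorted(self.per_subclass.get(cls, {}).items()):
                rows.append({"class": cls, "subclass": sub, "count": m})
        return rows


def summarize(
    calls: Sequence[DomainCall], taxonomy: Taxonomy | None = None
) -> ClassificationSummary:
    """Aggregate domain calls into a classification summary.

    Subclass ``None`` is reported in an explicit "unclassified" bucket;
    class counts sum to the total.
    """
    per_class: dict[str, int] = {}
    per_subclass: dict[str, dict[str, int]] = {}
    per_query: dict[str, list[DomainCall]] = {}
    for call in calls:
        per_class[call.class_label] = per_class.get(call.class_label, 0) + 1
        sub = call.subclass_label or "unclassified"
        bucket = per_subclass.setdefault(call.class_label, {})
        bucket[sub] = bucket.get(sub, 0) + 1
        per_query.setdefault(call.query_id, []).append(call)
    return ClassificationSummary(
        total=len(calls),
        per_class=per_class,
        per_subclass=per_subclass,
        per_query=per_query,
    )
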