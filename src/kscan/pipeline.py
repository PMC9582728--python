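"""End-to-end composition: search -> domain calls -> summary."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classify import (
    ClassificationSummary,
    DomainCall,
    PipelineParams,
    assign_domains,
    summarize,
)
from .refdb import ReferenceDB
from .search import Hit, QueryRecord, SearchParams, search_all, six_frame_translate


@dataclass
class PipelineResult:
    hits: list[Hit]
    calls: list[DomainCall]
    summary: ClassificationSummary


def run_pipeline(
    queries: Sequence[QueryRecord],
    db: ReferenceDB,
    search_params: SearchParams = SearchParams(),
    pipeline_params: PipelineParams = PipelineParams(),
    engine: str = "builtin",
) -> PipelineResult:
    """Detect and classify domains in a batch of queries.

    The reference database is restricted to the requested domain kind
    (KS or C); nucleotide queries are translated, searched in all six
    frames, and calls carry trimmed peptide sequences.
    """
    kind_db = db.subset(pipeline_params.domain_kind)
    hits = search_all(queries, kind_db, search_params, engine)
    peptides: dict[tuple[str, int], str] = {}
    for query in queries:
        if query.alphabet == "nucleotide":
            for trans in six_frame_translate(query):
                peptides[(query.id, trans.frame)] = trans.peptide
        else:
            peptides[(query.id, 0)] = query.sequence
    calls = assign_domains(hits, kind_db, pipeline_params, peptides)
    return PipelineResult(hits, calls, summarize(calls, db.taxonomy))
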