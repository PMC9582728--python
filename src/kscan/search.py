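"""Six-frame translation and similarity search against the reference DB.

Nucleotide queries are translated in all six reading frames; each
stop-free peptide segment is aligned locally against every reference
domain with the built-in Smith-Waterman engine, and alignment scores
are converted to bit scores and E-values with standard gapped BLOSUM62
Karlin-Altschul statistics.  An adapter accepts any external engine that
emits the standard 12-column tabular hit format.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ._align import smith_waterman, sw_score
from .errors import DataError, EngineError
from .refdb import ReferenceDB
from .seqio import write_fasta

logger = logging.getLogger(__name__)

NT_CHARS = set("ACGTUN")
IUPAC_NT = set("ACGTUNRYSWKMBDHV")

#: Minimum stop-free peptide segment length worth aligning.
MIN_SEGMENT = 8


def detect_alphabet(sequence: str) -> str:
    """Classify a sequence as ``"nucleotide"`` or ``"protein"``.

    A sequence is nucleotide iff at least 90% of its characters are in
    {A, C, G, T, U, N} (case-insensitive).
    """
    if not sequence:
        raise DataError("cannot detect alphabet of an empty sequence")
    upper = sequence.upper()
    frac = sum(1 for c in upper if c in NT_CHARS) / len(upper)
    return "nucleotide" if frac >= 0.9 else "protein"


@dataclass
class QueryRecord:
    id: str
    sequence: str
    alphabet: str = ""  # auto-detected when empty

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"query {self.id!r} is empty")
        self.sequence = self.sequence.upper()
        if not self.alphabet:
            self.alphabet = detect_alphabet(self.sequence)


@dataclass(frozen=True)
class FrameTranslation:
    """One reading-frame translation with exact coordinate back-mapping."""

    query_id: str
    frame: int  # +1..+3, -1..-3
    peptide: str
    nt_length: int

    def nt_span(self, pep_start: int, pep_end: int) -> tuple[int, int, str]:
        """Forward-strand 1-based nucleotide span of a peptide interval.

        Returns ``(start, end, strand)`` with start < end regardless of
        strand.
        """
        if not (1 <= pep_start <= pep_end <= len(self.peptide)):
            raise DataError(
                f"peptide span {pep_start}..{pep_end} outside frame translation"
            )
        k = abs(self.frame)
        if self.frame > 0:
            start = k + 3 * (pep_start - 1)
            end = k + 3 * pep_end - 1
        else:
            # peptide position i of frame -k covers forward-strand
            # nucleotides [L-k-3i+2, L-k-3i+4]
            start = self.nt_length - k - 3 * pep_end + 2
            end = self.nt_length - k - 3 * pep_start + 4
        return start, end, "+" if self.frame > 0 else "-"


def _clean_nt(sequence: str) -> str:
    out = []
    for c in sequence.upper():
        if c == "U":
            out.append("T")
        elif c in IUPAC_NT:
            out.append(c)
        else:
            out.append("N")
    return "".join(out)


def six_frame_translate(query: QueryRecord) -> list[FrameTranslation]:
    """Translate a nucleotide query in all six reading frames.

    Uses the standard genetic code; stop codons are emitted as '*',
    ambiguous codons as 'X'; trailing 1-2 nucleotides of each frame are
    ignored.  Frames -1..-3 are the +1..+3 frames of the reverse
    complement, with coordinates reported on the forward strand.
    """
    if query.alphabet != "nucleotide":
        raise DataError(f"query {query.id!r} is not nucleotide")
    seq = _clean_nt(query.sequence)
    length = len(seq)
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    out = []
    for k in (1, 2, 3):
        for strand, s in ((1, fwd), (-1, rev)):
            sub = s[k - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            peptide = str(sub.translate(table=1)) if len(sub) else ""
            out.append(
                FrameTranslation(query.id, strand * k, peptide, length)
            )
    order = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}
    return sorted(out, key=lambda f: order[f.frame])


@dataclass(frozen=True)
class SearchParams:
    """Scoring and statistics parameters for the built-in engine.

    Defaults are the standard gapped BLOSUM62 statistics (gap costs
    11/1, Karlin-Altschul lambda = 0.267, K = 0.041).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_gapped: float = 0.267
    k_gapped: float = 0.041
    max_evalue_report: float = 10.0
    max_builtin_db_size: int = 50_000

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend) <= 0:
            raise ValueError("gap costs must be positive")
        if min(self.lambda_gapped, self.k_gapped) <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass
class Hit:
    """One local alignment between a query (frame) and a database domain."""

    query_id: str
    frame: int  # 0 for protein queries
    db_id: str
    raw_score: int
    bit_score: float
    evalue: float
    percent_identity: float
    alignment_length: int
    query_start: int  # 1-based peptide coords on the frame translation
    query_end: int
    db_start: int
    db_end: int
    query_nt_start: int | None = None
    query_nt_end: int | None = None
    strand: str | None = None


def evalue_from_score(
    raw_score: int,
    query_len: int,
    total_db_len: int,
    params: SearchParams = SearchParams(),
) -> tuple[float, float]:
    """Karlin-Altschul bit score and E-value for a raw alignment score.

    bit = (lambda * S - ln K) / ln 2;  E = m * n * 2**(-bit), with the
    effective search space taken as query length x total database
    residue length (no edge-effect correction).
    """
    if query_len <= 0 or total_db_len <= 0:
        raise ValueError("lengths must be positive")
    bit = (params.lambda_gapped * raw_score - math.log(params.k_gapped)) / math.log(2)
    evalue = query_len * total_db_len * 2.0 ** (-bit)
    return bit, evalue


def _segments(peptide: str) -> Iterable[tuple[int, str]]:
    """Stop-free segments of a peptide as ``(0-based offset, segment)``."""
    start = 0
    for i, c in enumerate(peptide + "*"):
        if c == "*":
            if i - start >= MIN_SEGMENT:
                yield start, peptide[start:i]
            start = i + 1


def _search_peptide(
    query_id: str,
    frame: int,
    peptide: str,
    db: ReferenceDB,
    params: SearchParams,
    translation: FrameTranslation | None,
) -> list[Hit]:
    hits: list[Hit] = []
    m = len(peptide)
    n_total = db.total_residues
    for offset, segment in _segments(peptide):
        for dom in db.domains:
            score = sw_score(
                segment, dom.sequence, params.matrix, params.gap_open, params.gap_extend
            )
            if score <= 0:
                continue
            _, evalue = evalue_from_score(score, m, n_total, params)
            if evalue > params.max_evalue_report:
                continue
            aln = smith_waterman(
                segment, dom.sequence, params.matrix, params.gap_open, params.gap_extend
            )
            bit, evalue = evalue_from_score(aln.score, m, n_total, params)
            qs = offset + aln.query_start
            qe = offset + aln.query_end
            hit = Hit(
                query_id=query_id,
                frame=frame,
                db_id=dom.id,
                raw_score=aln.score,
                bit_score=bit,
                evalue=evalue,
                percent_identity=aln.percent_identity,
                alignment_length=aln.length,
                query_start=qs,
                query_end=qe,
                db_start=aln.target_start,
                db_end=aln.target_end,
            )
            if translation is not None:
                nt_start, nt_end, strand = translation.nt_span(qs, qe)
                hit.query_nt_start = nt_start
                hit.query_nt_end = nt_end
                hit.strand = strand
            hits.append(hit)
    return hits


def search_all(
    queries: Sequence[QueryRecord],
    db: ReferenceDB,
    params: SearchParams = SearchParams(),
    engine: str = "builtin",
) -> list[Hit]:
    """Search queries against the reference database.

    Nucleotide queries are six-frame translated first; hits carry the
    frame and back-mapped forward-strand nucleotide coordinates.  The
    hit schema is identical for the built-in engine and external
    adapters.
    """
    if engine == "builtin":
        if len(db) > params.max_builtin_db_size:
            raise EngineError(
                f"builtin engine refuses databases over "
                f"{params.max_builtin_db_size} sequences; use an external "
                f"search adapter (e.g. BlastpAdapter) for large databases"
            )
        hits: list[Hit] = []
        for query in queries:
            if query.alphabet == "nucleotide":
                for trans in six_frame_translate(query):
                    if trans.peptide:
                        hits.extend(
                            _search_peptide(
                                query.id, trans.frame, trans.peptide, db, params, trans
                            )
                        )
            else:
                hits.extend(
                    _search_peptide(query.id, 0, query.sequence, db, params, None)
                )
        hits.sort(key=lambda h: (h.query_id, h.evalue, -h.bit_score, h.db_id))
        return hits
    if isinstance(engine, ExternalSearchAdapter) or engine == "blastp":
        adapter = engine if isinstance(engine, ExternalSearchAdapter) else BlastpAdapter()
        return adapter.search(queries, db, params)
    raise EngineError(f"unknown search engine {engine!r}")


class ExternalSearchAdapter:
    """Adapter for engines that emit BLAST 12-column tabular output.

    Subclasses implement :meth:`run`, writing hits for protein query
    sequences; frame handling and nucleotide coordinate back-mapping are
    recomputed here from our own translations so that output schema and
    coordinates are engine-independent.
    """

    def run(self, query_fasta: Path, db_fasta: Path, params: SearchParams) -> str:
        raise NotImplementedError

    def search(
        self,
        queries: Sequence[QueryRecord],
        db: ReferenceDB,
        params: SearchParams = SearchParams(),
    ) -> list[Hit]:
        # expand nucleotide queries into per-frame peptide pseudo-queries
        peptides: list[tuple[str, int, str, FrameTranslation | None]] = []
        for query in queries:
            if query.alphabet == "nucleotide":
                for trans in six_frame_translate(query):
                    if trans.peptide.strip("*"):
                        peptides.append(
                            (f"{query.id}__frame{trans.frame:+d}", trans.frame,
                             trans.peptide, trans)
                        )
            else:
                peptides.append((query.id, 0, query.sequence, None))
        with tempfile.TemporaryDirectory() as tmp:
            qpath = Path(tmp) / "query.faa"
            dpath = Path(tmp) / "db.faa"
            # '*' is not accepted by every engine; X never aligns well and
            # preserves coordinates
            write_fasta(
                ((pid, pep.replace("*", "X")) for pid, _, pep, _ in peptides), qpath
            )
            write_fasta(((d.id, d.sequence) for d in db.domains), dpath)
            table = self.run(qpath, dpath, params)
        by_pid = {pid: (frame, trans) for pid, frame, _, trans in peptides}
        hits = []
        for line in table.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            pid, sid = f[0], f[1]
            frame, trans = by_pid[pid]
            qs, qe = int(f[6]), int(f[7])
            hit = Hit(
                query_id=pid.split("__frame")[0],
                frame=frame,
                db_id=sid,
                raw_score=0,  # engines report bit scores, not raw scores
                bit_score=float(f[11]),
                evalue=float(f[10]),
                percent_identity=float(f[2]),
                alignment_length=int(f[3]),
                query_start=qs,
                query_end=qe,
                db_start=int(f[8]),
                db_end=int(f[9]),
            )
            if hit.evalue > params.max_evalue_report:
                continue
            if trans is not None:
                nt_start, nt_end, strand = trans.nt_span(qs, qe)
                hit.query_nt_start = nt_start
                hit.query_nt_end = nt_end
                hit.strand = strand
            hits.append(hit)
        hits.sort(key=lambda h: (h.query_id, h.evalue, -h.bit_score, h.db_id))
        return hits


class BlastpAdapter(ExternalSearchAdapter):
    """Run NCBI blastp as the search engine."""

    def __init__(self, executable: str = "blastp"):
        self.executable = executable

    def run(self, query_fasta: Path, db_fasta: Path, params: SearchParams) -> str:
        if shutil.which(self.executable) is None:
            raise EngineError(f"{self.executable} not found on PATH")
        cmd = [
            self.executable,
            "-query", str(query_fasta),
            "-subject", str(db_fasta),
            "-outfmt", "6",
            "-evalue", str(params.max_evalue_report),
            "-matrix", params.matrix,
            "-gapopen", str(params.gap_open),
            "-gapextend", str(params.gap_extend),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise EngineError(
                f"{self.executable} failed ({proc.returncode}): {proc.stderr.strip()}"
            )
        return proc.stdout


def hits_to_table(hits: Sequence[Hit]):
    """Hits as a pandas DataFrame in extended BLAST tabular layout."""
    import pandas as pd

    cols = [
        "query_id", "db_id", "percent_identity", "alignment_length",
        "query_start", "query_end", "db_start", "db_end", "evalue",
        "bit_score", "raw_score", "frame", "query_nt_start", "query_nt_end",
        "strand",
    ]
    return pd.DataFrame(
        [{c: getattr(h, c) for c in cols} for h in hits], columns=cols
    )
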