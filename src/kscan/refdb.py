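"""Class-labeled reference domain database.

The reference database holds curated ketosynthase (KS) and condensation
(C) domain sequences, each tagged with the biosynthetic gene cluster
(BGC) it comes from, its position within that BGC, and its class and
subclass in the phylogeny-derived taxonomy.  FASTA headers follow the
pipe-delimited match-ID schema ``bgc|domain_number|class|subclass`` so
that search hits are self-describing; the remaining metadata (domain
kind, taxon group, source accession, product) lives in a sidecar TSV.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import Align

from .errors import ValidationError
from .seqio import read_fasta, write_fasta

logger = logging.getLogger(__name__)

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = AA20 | {"X"}
TAXON_GROUPS = ("bacteria", "fungi", "other_eukaryote", "unknown")

METADATA_COLUMNS = [
    "id",
    "bgc_name",
    "domain_number",
    "class",
    "subclass",
    "domain_kind",
    "taxon_group",
    "source_accession",
    "product_name",
]


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


class Taxonomy:
    """Hierarchy of domain classification labels.

    Levels are type -> class -> subclass, rooted per domain kind (KS or
    C).  A query domain is assigned a class label and optionally a
    subclass label that must be a child of that class.
    """

    def __init__(self, tree: dict):
        self._tree = tree
        self._class_parent: dict[tuple[str, str], str] = {}
        self._subclasses: dict[tuple[str, str], list[str]] = {}
        for kind, types in tree.items():
            seen: set[str] = set()
            for type_name, classes in (types or {}).items():
                for cls, subs in (classes or {}).items():
                    if cls in seen:
                        raise ValidationError(f"duplicate class label {cls!r}")
                    seen.add(cls)
                    self._class_parent[(kind, cls)] = type_name
                    subs = list(subs or [])
                    if len(set(subs)) != len(subs):
                        raise ValidationError(f"duplicate subclass under {cls!r}")
                    self._subclasses[(kind, cls)] = subs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Taxonomy":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Taxonomy":
        """The shipped KS/C classification scheme."""
        ref = importlib.resources.files("kscan.data") / "ks_taxonomy.yaml"
        return cls(yaml.safe_load(ref.read_text()))

    def kinds(self) -> list[str]:
        return list(self._tree)

    def classes(self, kind: str) -> list[str]:
        return [c for (k, c) in self._class_parent if k == kind]

    def type_of(self, kind: str, cls: str) -> str:
        return self._class_parent[(kind, cls)]

    def subclasses(self, kind: str, cls: str) -> list[str]:
        return list(self._subclasses.get((kind, cls), []))

    def has_class(self, kind: str, cls: str) -> bool:
        return (kind, cls) in self._class_parent

    def is_child(self, kind: str, cls: str, subclass: str) -> bool:
        return subclass in self._subclasses.get((kind, cls), [])

    def n_assignments(self, kind: str) -> int:
        """Number of class + subclass labels a query can receive."""
        classes = self.classes(kind)
        return len(classes) + sum(len(self.subclasses(kind, c)) for c in classes)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class ReferenceDomain:
    """One labeled domain sequence in the reference database."""

    id: str
    bgc_name: str
    domain_number: int
    class_label: str
    subclass_label: str | None
    domain_kind: str
    sequence: str
    taxon_group: str = "unknown"
    source_accession: str = ""
    product_name: str = ""

    def validate(self, taxonomy: Taxonomy) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_AA
        if bad:
            raise ValidationError(
                f"{self.id}: non-amino-acid characters {sorted(bad)!r}"
            )
        if self.domain_number < 1:
            raise ValidationError(f"{self.id}: domain_number must be >= 1")
        if self.domain_kind not in taxonomy.kinds():
            raise ValidationError(f"{self.id}: unknown domain kind {self.domain_kind!r}")
        if not taxonomy.has_class(self.domain_kind, self.class_label):
            raise ValidationError(
                f"{self.id}: class {self.class_label!r} not in taxonomy"
            )
        if self.subclass_label is not None and not taxonomy.is_child(
            self.domain_kind, self.class_label, self.subclass_label
        ):
            raise ValidationError(
                f"{self.id}: subclass {self.subclass_label!r} is not a child of "
                f"class {self.class_label!r}"
            )


@dataclass
class ReferenceDB:
    """Validated collection of reference domains plus their taxonomy."""

    domains: list[ReferenceDomain]
    taxonomy: Taxonomy
    aligned_reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.domains]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate reference ids: {dupes}")
        for d in self.domains:
            d.validate(self.taxonomy)
        by_id = {d.id: d for d in self.domains}
        for rid, row in self.aligned_reference.items():
            if rid not in by_id:
                raise ValidationError(f"aligned row {rid!r} not in database")
            if row.replace("-", "") != by_id[rid].sequence:
                raise ValidationError(
                    f"aligned row {rid!r} does not ungap to its sequence"
                )

    def __len__(self) -> int:
        return len(self.domains)

    def get(self, domain_id: str) -> ReferenceDomain:
        return next(d for d in self.domains if d.id == domain_id)

    def subset(self, domain_kind: str) -> "ReferenceDB":
        doms = [d for d in self.domains if d.domain_kind == domain_kind]
        aligned = {d.id: self.aligned_reference[d.id] for d in doms
                   if d.id in self.aligned_reference}
        return ReferenceDB(doms, self.taxonomy, aligned)

    @property
    def total_residues(self) -> int:
        return sum(len(d.sequence) for d in self.domains)


# ---------------------------------------------------------------------------
# load / write
# ---------------------------------------------------------------------------


def parse_match_id(header: str) -> tuple[str, int, str, str | None]:
    """Split a ``bgc|domainN|class|subclass`` match ID into its fields."""
    parts = header.split("|")
    if len(parts) != 4:
        raise ValidationError(
            f"header {header!r} does not follow bgc|domainN|class|subclass"
        )
    bgc, num, cls, sub = parts
    try:
        number = int(num)
    except ValueError as exc:
        raise ValidationError(f"header {header!r}: domain number {num!r}") from exc
    subclass = None if sub in ("none", "", "NA") else sub
    return bgc, number, cls, subclass


def load_reference(
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    aligned_fasta_path: str | Path | None = None,
) -> ReferenceDB:
    """Load and validate a reference database from its on-disk form.

    FASTA records are joined to metadata rows by id.  A metadata row
    with no corresponding sequence is skipped with a warning; a FASTA
    record with no metadata row falls back to header-derived fields.
    Duplicate ids and labels absent from the taxonomy are hard errors.
    """
    taxonomy = (
        Taxonomy.from_yaml(taxonomy_path) if taxonomy_path else Taxonomy.default()
    )
    records = read_fasta(fasta_path)
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        table = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        missing = set(METADATA_COLUMNS) - set(table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        meta = {row["id"]: dict(row) for _, row in table.iterrows()}
    seq_ids = {rid for rid, _ in records}
    for mid in meta:
        if mid not in seq_ids:
            logger.warning("metadata row %r has no sequence; skipped", mid)
    domains = []
    for rid, seq in records:
        bgc, number, cls, subclass = parse_match_id(rid)
        row = meta.get(rid)
        if row is None:
            if metadata_path is not None:
                logger.warning("no metadata row for %r; using header fields", rid)
            row = {}
        domains.append(
            ReferenceDomain(
                id=rid,
                bgc_name=row.get("bgc_name") or bgc,
                domain_number=int(row.get("domain_number") or number),
                class_label=row.get("class") or cls,
                subclass_label=(row.get("subclass") or None) if row else subclass,
                domain_kind=row.get("domain_kind") or "KS",
                sequence=seq,
                taxon_group=row.get("taxon_group") or "unknown",
                source_accession=row.get("source_accession", ""),
                product_name=row.get("product_name", ""),
            )
        )
    aligned = {}
    if aligned_fasta_path is not None:
        aligned = dict(read_fasta(aligned_fasta_path))
    return ReferenceDB(domains, taxonomy, aligned)


def write_reference(
    db: ReferenceDB,
    fasta_path: str | Path,
    metadata_path: str | Path,
    aligned_fasta_path: str | Path | None = None,
) -> None:
    """Write a database back to FASTA + metadata TSV (round-trippable)."""
    write_fasta(((d.id, d.sequence) for d in db.domains), fasta_path)
    rows = [
        {
            "id": d.id,
            "bgc_name": d.bgc_name,
            "domain_number": d.domain_number,
            "class": d.class_label,
            "subclass": d.subclass_label or "",
            "domain_kind": d.domain_kind,
            "taxon_group": d.taxon_group,
            "source_accession": d.source_accession,
            "product_name": d.product_name,
        }
        for d in db.domains
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False
    )
    if aligned_fasta_path is not None and db.aligned_reference:
        write_fasta(db.aligned_reference.items(), aligned_fasta_path)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def db_stats(db: ReferenceDB) -> dict:
    """Composition summary: counts, fractions, and length statistics."""
    if not db.domains:
        raise ValidationError("db_stats requires a non-empty database")
    n = len(db.domains)
    lengths = [len(d.sequence) for d in db.domains]
    mean = sum(lengths) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / n) if n > 1 else 0.0

    def _counts(keys: Iterable[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for k in keys:
            out[k] = out.get(k, 0) + 1
        return out

    class_counts = _counts(d.class_label for d in db.domains)
    subclass_counts = _counts(
        f"{d.class_label}/{d.subclass_label}"
        for d in db.domains
        if d.subclass_label is not None
    )
    kind_counts = _counts(d.domain_kind for d in db.domains)
    taxon_counts = _counts(d.taxon_group for d in db.domains)
    return {
        "n_domains": n,
        "mean_length": mean,
        "sd_length": sd,
        "per_kind": kind_counts,
        "per_class": class_counts,
        "per_subclass": subclass_counts,
        "per_taxon_group": taxon_counts,
        "taxon_fractions": {k: v / n for k, v in taxon_counts.items()},
    }


# ---------------------------------------------------------------------------
# identity clustering (control-set construction)
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    """A greedy identity cluster with its founding representative."""

    representative_id: str
    member_ids: list[str]
    threshold: float


def _aligner(gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "global"
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    # free end gaps: identity should not be eroded by length differences
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def pairwise_identity(
    a: str, b: str, denominator: str = "shorter"
) -> float:
    """Fraction of identical aligned residues between two peptides.

    Alignment is semiglobal (free end gaps) under BLOSUM62 with 11/1
    affine gap costs.  ``denominator`` is ``"shorter"`` (CD-HIT-style:
    identities / length of the shorter sequence) or ``"alignment"``
    (identities / aligned columns).
    """
    if not a or not b:
        raise ValidationError("pairwise_identity requires non-empty sequences")
    aln = _aligner().align(a, b)[0]
    identities = aln.counts().identities
    if denominator == "shorter":
        return identities / min(len(a), len(b))
    if denominator == "alignment":
        return identities / aln.length
    raise ValueError(f"unknown identity denominator {denominator!r}")


def cluster_by_identity(
    sequences: Sequence[tuple[str, str]],
    threshold: float = 0.5,
    identity_denominator: str = "shorter",
) -> list[Cluster]:
    """Greedy longest-first identity clustering.

    Sequences are visited by length descending (ties by id); each joins
    the first existing cluster whose representative it matches at
    identity >= threshold, else founds a new cluster.  This mirrors the
    greedy incremental strategy of CD-HIT-style clustering tools used to
    build nonredundant control sets.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(sequences, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[Cluster] = []
    reps: list[tuple[str, str]] = []
    for rid, seq in ordered:
        placed = False
        for cluster, (_, rep_seq) in zip(clusters, reps):
            if pairwise_identity(seq, rep_seq, identity_denominator) >= threshold:
                cluster.member_ids.append(rid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rid, [rid], threshold))
            reps.append((rid, seq))
    return clusters


def export_representatives(
    clusters: Sequence[Cluster], db: ReferenceDB
) -> list[tuple[str, str]]:
    """One ``(id, sequence)`` record per cluster representative."""
    return [(c.representative_id, db.get(c.representative_id).sequence) for c in clusters]
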