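"""Synthetic reference databases, control sets, and query data.

The generator emulates the class structure the classifier assumes: each
class descends from a random ancestor peptide, members diverge from it
by BLOSUM-biased point substitutions at a rate set by the within-class
identity target, and class ancestors are mutually diverged to the
between-class target.  Queries are built from those domains: genome-like
nucleotide sequences with reverse-translated domains embedded on random
strands, amplicon-like subfragments, and decoys (residue-shuffled
domains and unrelated random peptides).  Every output is reproducible
bit-for-bit under a fixed seed and accompanied by a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._align import score_matrix
from .errors import DataError
from .refdb import ReferenceDB, ReferenceDomain, Taxonomy
from .search import QueryRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Standard-code codons per amino acid (uniform synonymous choice).
CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and separation of the synthetic reference database.

    Defaults (5 classes x 8 members x ~400 aa, 0.8 within-class and 0.3
    between-class identity) keep full end-to-end runs fast while giving
    class separations comfortably inside the regime where best-hit
    classification is expected to work.
    """

    n_classes: int = 5
    n_subclasses_per_class: int = 2
    members_per_class: int = 8
    seq_length_mean: int = 400
    seq_length_sd: int = 25
    within_class_identity: float = 0.8
    between_class_identity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.between_class_identity < self.within_class_identity < 1):
            raise DataError(
                "identity targets must satisfy 0 < between < within < 1"
            )


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _substitution_bias() -> dict[str, tuple[list[str], np.ndarray]]:
    """BLOSUM62-biased replacement distributions, one per residue."""
    sub = score_matrix("BLOSUM62")
    from ._align import ALPHABET

    out = {}
    for a in AA20:
        i = ALPHABET.index(a)
        choices, weights = [], []
        for b in AA20:
            if b == a:
                continue
            j = ALPHABET.index(b)
            choices.append(b)
            weights.append(np.exp(sub[i, j] / 2.0))
        w = np.asarray(weights)
        out[a] = (choices, w / w.sum())
    return out


def _mutate(
    seq: str, rate: float, rng: np.random.Generator, bias: dict
) -> str:
    """Substitute exactly round(rate * L) positions (never to the same residue)."""
    length = len(seq)
    n_mut = int(round(rate * length))
    positions = rng.choice(length, size=n_mut, replace=False)
    chars = list(seq)
    for p in positions:
        choices, weights = bias[chars[p]]
        chars[p] = rng.choice(choices, p=weights)
    return "".join(chars)


def _pairwise_rate(target: float) -> float:
    """Per-sequence mutation rate giving pairwise identity ~ target.

    Two sequences independently mutated from a common ancestor at rate
    r agree at a position with probability (1-r)^2 + r^2 * c where c is
    the chance two biased substitutions coincide (~1/12 for the
    BLOSUM-biased kernel); solved numerically so that the *pairwise*
    identity between generated sequences, not their identity to the
    unobserved ancestor, matches the target.
    """
    c = 1.0 / 12.0
    lo, hi = 0.0, 1.0
    for _ in range(60):
        r = (lo + hi) / 2
        ident = (1 - r) ** 2 + r * r * c
        if ident > target:
            lo = r
        else:
            hi = r
    return (lo + hi) / 2


def make_reference(spec: FixtureSpec = FixtureSpec()) -> tuple[ReferenceDB, pd.DataFrame]:
    """Generate a labeled synthetic reference database plus truth table.

    Returns the database (with an ancestor-anchored, gap-free aligned
    reference) and a truth DataFrame (id, class, subclass, length).
    """
    rng = np.random.default_rng(spec.seed)
    taxonomy = Taxonomy.default()
    classes = taxonomy.classes("KS")[: spec.n_classes]
    if len(classes) < spec.n_classes:
        raise DataError("fixture spec requests more classes than the taxonomy has")
    bias = _substitution_bias()
    rate_between = _pairwise_rate(spec.between_class_identity)
    rate_within = _pairwise_rate(spec.within_class_identity)
    domains: list[ReferenceDomain] = []
    aligned: dict[str, str] = {}
    truth_rows = []
    base_len = int(
        np.clip(rng.normal(spec.seq_length_mean, spec.seq_length_sd), 50, None)
    )
    base = _random_peptide(rng, base_len)
    taxa = ("bacteria", "fungi", "other_eukaryote", "unknown")
    for ci, cls in enumerate(classes):
        ancestor = _mutate(base, rate_between, rng, bias)
        subs = taxonomy.subclasses("KS", cls)[: spec.n_subclasses_per_class]
        bgc = f"synbgc{chr(ord('a') + ci)}"
        for mi in range(spec.members_per_class):
            seq = _mutate(ancestor, rate_within, rng, bias)
            subclass = subs[mi % len(subs)] if subs else None
            sub_str = subclass if subclass else "none"
            rid = f"{bgc}|{mi + 1}|{cls}|{sub_str}"
            domains.append(
                ReferenceDomain(
                    id=rid,
                    bgc_name=bgc,
                    domain_number=mi + 1,
                    class_label=cls,
                    subclass_label=subclass,
                    domain_kind="KS",
                    sequence=seq,
                    taxon_group=taxa[mi % len(taxa)],
                    source_accession=f"SYN{ci:02d}{mi:02d}",
                    product_name=f"synthetic product {ci}.{mi}",
                )
            )
            aligned[rid] = seq  # equal lengths: gap-free alignment
            truth_rows.append(
                {"id": rid, "class": cls, "subclass": sub_str, "length": len(seq)}
            )
    db = ReferenceDB(domains, taxonomy, aligned)
    return db, pd.DataFrame(truth_rows)


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Nucleotide encoding with uniform synonymous codon choice."""
    return "".join(rng.choice(CODONS[c]) for c in peptide)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class QueryBundle:
    """Generated queries plus the truth table describing them."""

    queries: list[QueryRecord]
    truth: pd.DataFrame


def make_queries(
    db: ReferenceDB,
    kinds: Sequence[str] = ("genome", "amplicon", "decoy_shuffled", "decoy_random"),
    seed: int = 0,
    domains_per_genome: int = 3,
    n_genomes: int = 2,
    intergenic_length: int = 600,
    amplicon_length_nt: int = 602,
    n_amplicons: int = 6,
    n_decoys: int = 8,
) -> QueryBundle:
    """Generate query data with a ground-truth table.

    genome: random intergenic nucleotide with reverse-translated domain
    instances embedded on random strands at recorded coordinates.
    amplicon: subfragments of domain nucleotide (default 602 bp,
    mimicking longer PCR amplicons).  decoy_shuffled: residue-shuffled
    domains; decoy_random: unrelated random peptides.  Truth rows
    record each embedded domain's source id, class, strand, and 1-based
    forward-strand coordinates (NA for decoys).
    """
    rng = np.random.default_rng(seed)
    queries: list[QueryRecord] = []
    rows = []
    doms = db.domains
    if "genome" in kinds:
        for g in range(n_genomes):
            chosen = rng.choice(len(doms), size=domains_per_genome, replace=False)
            parts = []
            pos = 0
            gid = f"syngenome{g + 1}"
            for idx in chosen:
                dom = doms[int(idx)]
                spacer = _random_nt(rng, intergenic_length)
                insert = reverse_translate(dom.sequence, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                embedded = insert if strand == "+" else _revcomp(insert)
                parts.extend([spacer, embedded])
                start = pos + len(spacer) + 1
                end = start + len(embedded) - 1
                pos = end
                rows.append(
                    {
                        "query_id": gid,
                        "kind": "genome",
                        "source_id": dom.id,
                        "class": dom.class_label,
                        "strand": strand,
                        "nt_start": start,
                        "nt_end": end,
                    }
                )
            parts.append(_random_nt(rng, intergenic_length))
            queries.append(QueryRecord(gid, "".join(parts), "nucleotide"))
    if "amplicon" in kinds:
        for a in range(n_amplicons):
            dom = doms[int(rng.integers(len(doms)))]
            nt = reverse_translate(dom.sequence, rng)
            if len(nt) <= amplicon_length_nt:
                frag, start = nt, 1
            else:
                start = int(rng.integers(0, len(nt) - amplicon_length_nt)) + 1
                frag = nt[start - 1 : start - 1 + amplicon_length_nt]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = _revcomp(frag)
            qid = f"synamplicon{a + 1}"
            queries.append(QueryRecord(qid, frag, "nucleotide"))
            rows.append(
                {
                    "query_id": qid,
                    "kind": "amplicon",
                    "source_id": dom.id,
                    "class": dom.class_label,
                    "strand": strand,
                    "nt_start": 1,
                    "nt_end": len(frag),
                }
            )
    if "decoy_shuffled" in kinds:
        for i in range(n_decoys):
            dom = doms[int(rng.integers(len(doms)))]
            chars = list(dom.sequence)
            rng.shuffle(chars)
            qid = f"syndecoyshuf{i + 1}"
            queries.append(QueryRecord(qid, "".join(chars), "protein"))
            rows.append(
                {
                    "query_id": qid, "kind": "decoy_shuffled", "source_id": dom.id,
                    "class": "", "strand": "", "nt_start": -1, "nt_end": -1,
                }
            )
    if "decoy_random" in kinds:
        for i in range(n_decoys):
            qid = f"syndecoyrand{i + 1}"
            queries.append(
                QueryRecord(qid, _random_peptide(rng, 400), "protein")
            )
            rows.append(
                {
                    "query_id": qid, "kind": "decoy_random", "source_id": "",
                    "class": "", "strand": "", "nt_start": -1, "nt_end": -1,
                }
            )
    return QueryBundle(queries, pd.DataFrame(rows))


def make_controls(
    db: ReferenceDB, seed: int = 0, n_negatives: int = 20
) -> tuple[dict[str, tuple[str, str]], dict[str, str]]:
    """Labeled control sets for calibration from a fixture database.

    Positives are the database members themselves (scored with
    self-exclusion, as in leave-one-out cross-validation); negatives
    are unrelated random peptides plus residue-shuffled domains, i.e.
    sequences with database-like composition but no homology.
    """
    rng = np.random.default_rng(seed)
    positives = {
        d.id: (d.sequence, d.class_label) for d in db.domains
    }
    negatives: dict[str, str] = {}
    for i in range(n_negatives // 2):
        negatives[f"negrand{i + 1}"] = _random_peptide(
            rng, len(db.domains[i % len(db.domains)].sequence)
        )
    for i in range(n_negatives - n_negatives // 2):
        dom = db.domains[int(rng.integers(len(db.domains)))]
        chars = list(dom.sequence)
        rng.shuffle(chars)
        negatives[f"negshuf{i + 1}"] = "".join(chars)
    return positives, negatives
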