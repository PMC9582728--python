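# Methods

## Problem and model

`kscan` treats domain annotation as *nearest-reference classification
under a similarity-search score*. A query region is called a KS (or C)
domain when its best local alignment to a curated, class-labeled
reference database passes an E-value cutoff and a minimum alignment
length; the call inherits the class/subclass labels of that single best
match. The class taxonomy itself is derived from KS phylogenies offline
and shipped as data (`src/kscan/data/ks_taxonomy.yaml`); at run time the
phylogeny is advisory only — the placement module lets users confirm
that a query falls inside its assigned class clade, but never overrides
the best-hit assignment. This separation keeps the runtime decision
simple, fast, and exactly reproducible.

The KS scheme carries 41 class/subclass assignments (11 classes + 30
subclasses). The class inventory (modular/iterative/*trans*-AT *cis*-AT
type I, type I FAS, type II aromatic with nine functionally defined
subclasses, polyene, aryl polyene, noniterative, β-branching, type II
FAS, type II unclassified) is fixed by the underlying phylogenetic
analyses; where members of a class fall outside its functionally defined
subclasses we carry explicit `*_unclassified` subclass buckets (modular
*cis*-AT, *trans*-AT, type II aromatic) so that every sequence has a
well-defined assignment. C domains are detectable as a second reference
set but carry no subclass scheme.

## Search engine and statistics

The builtin engine is an exact affine-gap Smith–Waterman (Gotoh) DP,
JIT-compiled with numba, over BLOSUM62 with gap costs 11/1 (a gap of
length k costs 11 + k). Nucleotide queries are six-frame translated with
the standard code; stops are kept as `*` and are unalignable — neither a
substitution column nor a gap may consume one — so each stop-free
segment behaves like an implicit ORF without explicit ORF calling.
Reverse-frame coordinates are reported on the forward strand with a
strand flag; the peptide↔nucleotide mapping is exact and tested by
re-translation.

Raw scores convert to bit scores and E-values with fixed gapped
Karlin–Altschul constants (λ = 0.267, K = 0.041) and effective search
space = query length × total database residues, with no edge-effect
correction. These are the standard published constants for gapped
BLOSUM62 11/1 scoring, not values fitted by this package. Absolute
E-values therefore differ somewhat from NCBI BLAST or DIAMOND, which
apply composition-based statistics and length corrections; **calibrated
cutoffs are engine-specific** and the calibrate command records the
engine in its reports. The builtin engine is exact but quadratic, so it
refuses databases above a configurable size (default 50 000 sequences)
and points users at the external adapter, which accepts any engine
emitting 12-column BLAST tabular output (a `blastp` adapter is
included); frames and nucleotide coordinates are always recomputed from
our own translations so the hit schema is engine-independent.

## Domain calling

Hits below the E-value cutoff and minimum alignment length are grouped
per query and resolved greedily: accept the best surviving hit (lowest
E-value, ties to higher bit score, then lexicographic match ID), then
suppress hits overlapping it by more than half the shorter span —
computed on forward-strand nucleotide coordinates when available so that
hits in different frames compete for the same locus. The greedy rule and
the 0.5 overlap threshold are this package's choices, made for
determinism; multiple non-overlapping calls per query are allowed
because a single gene or cluster can contain several domains.
`alignment_length` counts alignment columns including gaps, matching the
tabular-format "length" field that minimum-length thresholds are
conventionally applied to. Defaults are an E-value of 1e-8 and 200 aa
minimum alignment length; 50 aa is the recommended minimum for amplicon
fragments, which are shorter than a full domain by construction.

## Placement

Trimmed domains are merged into the fixed reference alignment by profile
alignment: each query is globally aligned (affine 11/1) against
per-column position-specific scores equal to the mean BLOSUM62 score of
the query residue against the column's non-gap residues. Reference
columns are never reordered; query-only insertions introduce new all-gap
columns, and each query's insertion columns are private (not shared
between queries) — the simplest policy that preserves the reference
coordinate system and guarantees each row ungaps to its input. The
builtin tree is neighbor joining over Kimura-corrected protein distances
d = −ln(1 − p − p²/5) with pairwise gap deletion, distances capped at 10
when the correction is undefined, and negative NJ branch lengths clamped
to zero. NJ (via scikit-bio) is deliberate: it is self-contained and
adequate for the question "does the query fall among its class's
references"; users wanting publication trees should export the merged
alignment to an external ML builder.

## Calibration

Controls are scored by leave-one-out cross-validation: the E-value of
the best database match that is neither the control's own ID nor an
identical sequence. Scores are −log10 E so "more restrictive" means
larger; controls with no match score 0 (the no-hit sentinel) and are
undetectable at any cutoff. ROC curves sweep the union of observed
scores; AUC is the trapezoid rule and is verified against Mann–Whitney
pair counting. The selected cutoff is the largest finite positive
E-value (guaranteeing 100% sensitivity when every positive has a match);
both the attained value and the nearest power-of-ten not excluding any
positive are reported, since operating cutoffs are conventionally quoted
as round powers of ten.

The sliding-window benchmark fragments positive controls into windows of
30/50/100/200 aa at a 10 aa step, with an anchored terminal window so
every residue is covered (window count = ⌊(L−w)/step⌋ + 1, +1 when the
last regular window misses the end). Detection uses the E-value cutoff
alone, the rule under which the operating defaults were established; an
`enforce_min_length` option additionally requires min(window size,
configured minimum) alignment columns, but is off by default because
local alignment trims mismatched window ends, which silently converts a
length floor equal to the window size into a requirement that terminal
residues match — penalizing exactly-sized windows in a way that has
nothing to do with detectability.

## Synthetic data

The generator emulates the one structural assumption the classifier
makes: classes are clusters in sequence space. Each class descends from
an ancestor peptide; members are derived by BLOSUM62-biased point
substitutions with the per-sequence rate solved numerically so that the
realized *pairwise* identity between members matches the within-class
target (default 0.8); class ancestors are likewise diverged from a
common base to the between-class target (default 0.3, measured between
ancestors — member-to-member cross-class identity is slightly lower).
All members of a class share their ancestor's length, so the emitted
reference alignment is gap-free and ancestor-anchored. Defaults (5
classes × 8 members × ~400 ± 25 aa) keep end-to-end runs around a minute
on one CPU while placing within/between separations comfortably in the
regime where best-hit classification should work.

Queries: genome-like records embed reverse-translated domains (uniform
synonymous codons — codon bias is irrelevant to protein-level search) on
random strands between random intergenic stretches; amplicon-like
records are 602 bp subfragments of domain nucleotide, mimicking long PCR
amplicons; decoys are residue-shuffled domains (same composition, no
homology) and unrelated uniform-random peptides. Truth tables record
every embedded domain's source, class, strand, and coordinates, and are
verified re-extractable.

What passing on fixtures does **not** show: real KS databases have
unbalanced class sizes, length variation, indels, shared conserved
motifs across classes and with non-KS condensing enzymes, and
non-uniform composition. Fixture separations are cleaner than reality,
so fixture accuracies (typically 100%) are upper bounds; the calibrated
cutoff on a densely sampled fixture is far stricter than an operating
cutoff calibrated on nonredundant controls against a sparse real
database. The published operating point (1e-8 / 200 aa) is carried as
the package default rather than re-derived from fixtures.

## Numerical choices and degenerate inputs

- Alignment ties break toward the smallest end coordinates and diagonal
  moves; score-0 alignments are empty.
- Alphabet detection: nucleotide iff ≥ 90% of characters in
  {A,C,G,T,U,N}; unknown characters translate as X, which BLOSUM62
  scores near zero.
- Clustering is greedy longest-first (ties by ID), identity =
  identities / shorter-sequence length by default (CD-HIT convention;
  the denominator is configurable), alignment semiglobal so length
  differences are not penalized as gaps.
- Empty query files are a success (exit 0) with empty outputs; empty
  databases, duplicate IDs, and labels absent from the taxonomy are
  validation errors (exit 2).
- Problem sizes in the test suite and acceptance script (40-sequence
  databases, ~1000-pair oracle checks, 5 window-benchmark parents) were
  chosen to exercise every code path at a scale a laptop handles in a
  couple of minutes.

## Known limitations

- No heuristic seeding: the builtin engine is exact DP and does not
  scale to large reference databases; that is what the external adapter
  is for.
- Nearest-reference classification cannot flag queries that fall between
  classes; the placement tree is the intended diagnostic.
- Intron-containing eukaryotic genomic DNA is not spliced; use predicted
  proteins or transcripts.
- The C-domain reference set is supported for detection only; no
  C subclass taxonomy is shipped.
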