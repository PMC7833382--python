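"""Sequence kernels shared by every pipeline stage.

Local alignment with Karlin-Altschul E-values, open-reading-frame search,
GC content and greedy identity clustering.  Alignment itself is delegated to
:class:`Bio.Align.PairwiseAligner` (Smith-Waterman with affine gaps, C
implementation); this module owns the scoring schemes, the significance
model and the clustering logic built on top of it.

Conventions
-----------
* All sequence intervals are 1-based and inclusive.
* A gap of length ``L`` costs ``gap_open + L * gap_extend`` (BLAST style).
* Alignment identity is ``matches / aligned columns`` for a single
  alignment and ``matches / len(shorter sequence)`` for clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

NUCLEOTIDES = set("ACGT")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY*X")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class AlignmentScoringScheme:
    """Scoring parameters plus the Karlin-Altschul constants they imply.

    The nucleotide defaults (+2/-3, gap 5/2, lambda=0.625, K=0.41) are the
    standard published constants for that scheme; the protein scheme uses
    BLOSUM62 with its canonical gapped constants.
    """

    mode: str  # "nucleotide" | "protein"
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lambda_: float = 0.625
    k: float = 0.41
    matrix_name: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    @property
    def alphabet(self) -> set[str]:
        return NUCLEOTIDES if self.mode == "nucleotide" else AMINO_ACIDS

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.mode == "nucleotide":
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        else:
            aligner.substitution_matrix = substitution_matrices.load(
                self.matrix_name or "BLOSUM62"
            )
        # Biopython charges open_gap_score for the first gapped position and
        # extend_gap_score thereafter; shift so a length-L gap costs
        # gap_open + L * gap_extend.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


_ALIGNER_CACHE: dict = {}


def _aligner_for(scheme: "AlignmentScoringScheme") -> Align.PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(scheme)
    if aligner is None:
        aligner = _ALIGNER_CACHE[scheme] = scheme.make_aligner()
    return aligner


#: Stand-in for megablast-like nucleotide search.
NUCLEOTIDE_SCHEME = AlignmentScoringScheme(mode="nucleotide")

#: BLOSUM62 with the canonical gapped-BLAST constants (gap 11+k*1 analogue;
#: we keep the module-wide 5/2 affine convention and the published
#: lambda=0.267, K=0.041 significance constants).
PROTEIN_SCHEME = AlignmentScoringScheme(
    mode="protein",
    gap_open=11,
    gap_extend=1,
    lambda_=0.267,
    k=0.041,
    matrix_name="BLOSUM62",
)


@dataclass
class LocalAlignment:
    """A maximal-scoring local alignment of query against one subject."""

    score: float
    bit_score: float
    evalue: float
    identity: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    subject_id: str | None = None
    n_columns: int = 0
    n_matches: int = 0

    @property
    def aligned_length(self) -> int:
        return self.n_columns


@dataclass(frozen=True)
class Orf:
    """A complete open reading frame (ATG..stop, stop codon included)."""

    frame: int  # +1,+2,+3,-1,-2,-3
    start: int  # 1-based inclusive on the forward strand
    end: int
    length: int
    coverage: float
    complete: bool = True

    @property
    def aa_length(self) -> int:
        return self.length // 3 - 1  # minus the stop codon


def _validate_alphabet(seq: str, alphabet: set[str], label: str) -> None:
    for ch in seq:
        if ch not in alphabet:
            raise ValueError(f"invalid symbol {ch!r} in {label} sequence")


def evalue_from_score(
    score: float, m: int, n: int, scheme: AlignmentScoringScheme
) -> float:
    """Karlin-Altschul expected number of chance alignments >= score.

    E = K * m * n * exp(-lambda * S) for query length m searched against a
    database of n letters.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    return scheme.k * m * n * math.exp(-scheme.lambda_ * score)


def bit_score_from_score(score: float, scheme: AlignmentScoringScheme) -> float:
    return (scheme.lambda_ * score - math.log(scheme.k)) / math.log(2)


def smith_waterman(
    query: str,
    subject: str,
    scheme: AlignmentScoringScheme = NUCLEOTIDE_SCHEME,
    subject_id: str | None = None,
    database_length: int | None = None,
    max_tie_alignments: int = 50,
) -> LocalAlignment:
    """Best local alignment of ``query`` against ``subject``.

    ``database_length`` (defaults to ``len(subject)``) is the n used in the
    E-value so callers searching many subjects can apply the whole-database
    convention.  Among co-optimal alignments the one with the smallest
    subject start, then smallest query start, is reported (scanned over the
    aligner's first ``max_tie_alignments`` enumerated optima).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    _validate_alphabet(query, scheme.alphabet, "query")
    _validate_alphabet(subject, scheme.alphabet, "subject")

    alignments = _aligner_for(scheme).align(query, subject)
    best = None
    best_key = None
    for i, aln in enumerate(alignments):
        if i >= max_tie_alignments:
            break
        q_blocks, s_blocks = aln.aligned
        key = (int(s_blocks[0][0]), int(q_blocks[0][0]))
        if best_key is None or key < best_key:
            best, best_key = aln, key
    assert best is not None

    q_blocks, s_blocks = best.aligned
    n_matches = 0
    n_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        n_cols += qe - qs
        n_matches += sum(
            1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b
        )
    # gap columns count toward aligned columns
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    s_span = int(s_blocks[-1][1] - s_blocks[0][0])
    n_cols_total = n_cols + (q_span - n_cols) + (s_span - n_cols)

    score = float(best.score)
    n_db = database_length if database_length is not None else len(subject)
    return LocalAlignment(
        score=score,
        bit_score=bit_score_from_score(score, scheme),
        evalue=evalue_from_score(score, len(query), n_db, scheme),
        identity=n_matches / n_cols_total if n_cols_total else 0.0,
        query_start=int(q_blocks[0][0]) + 1,
        query_end=int(q_blocks[-1][1]),
        subject_start=int(s_blocks[0][0]) + 1,
        subject_end=int(s_blocks[-1][1]),
        subject_id=subject_id,
        n_columns=n_cols_total,
        n_matches=n_matches,
    )


def sw_score(
    query: str, subject: str, scheme: AlignmentScoringScheme = NUCLEOTIDE_SCHEME
) -> float:
    """Score-only local alignment (cheaper than a full traceback)."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    return float(_aligner_for(scheme).score(query, subject))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide ORF, dropping the trailing stop symbol."""
    aa = str(Seq(seq).translate())
    return aa[:-1] if aa.endswith("*") else aa


def find_orfs(
    contig: str, min_len_nt: int = 150, search_strands: str = "sense"
) -> list[Orf]:
    """All complete ORFs (ATG...stop, no internal stop) of length >= min.

    Lengths include the stop codon.  Results are sorted by length
    descending, ties broken by the 5'-most start.  ``search_strands`` is
    ``"sense"`` (stranded library default) or ``"both"``.
    """
    if min_len_nt < 3 or min_len_nt % 3:
        raise ValueError("min_len_nt must be >= 3 and divisible by 3")
    if search_strands not in ("sense", "both"):
        raise ValueError("search_strands must be 'sense' or 'both'")

    n = len(contig)
    orfs: list[Orf] = []

    def scan(seq: str, strand: int) -> None:
        for off in range(3):
            start = None  # codon index of current ATG
            i = off
            while i + 3 <= len(seq):
                codon = seq[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in STOP_CODONS:
                    length = i + 3 - start
                    if length >= min_len_nt:
                        if strand > 0:
                            s, e = start + 1, i + 3
                            frame = off + 1
                        else:
                            # coordinates on the forward strand
                            s, e = n - (i + 3) + 1, n - start
                            frame = -(off + 1)
                        orfs.append(
                            Orf(
                                frame=frame,
                                start=s,
                                end=e,
                                length=length,
                                coverage=length / n,
                            )
                        )
                    start = None
                i += 3

    scan(contig, +1)
    if search_strands == "both":
        scan(reverse_complement(contig), -1)

    orfs.sort(key=lambda o: (-o.length, o.start))
    return orfs


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length; accepts DNA or RNA alphabets."""
    if not sequence:
        raise ValueError("empty sequence")
    gc = sum(1 for b in sequence if b in "GCgc")
    return gc / len(sequence)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_kmer_fraction(
    a: str,
    b: str,
    k: int = 8,
    a_kmers: set[str] | None = None,
    b_kmers: set[str] | None = None,
) -> float:
    """Fraction of the shorter sequence's k-mers found in the longer one.

    Pre-computed k-mer sets may be passed to amortize repeated screens of
    the same sequences.
    """
    ka = _kmer_set(a, k) if a_kmers is None else a_kmers
    kb = _kmer_set(b, k) if b_kmers is None else b_kmers
    if len(a) > len(b):
        ka, kb = kb, ka
    if not ka:
        return 0.0
    return len(ka & kb) / len(ka)


def greedy_cluster(
    contigs: Sequence[tuple[str, str]],
    identity_threshold: float = 0.9,
    prefilter_k: int = 8,
    prefilter_min_shared: float = 0.2,
) -> tuple[list[str], dict[str, str]]:
    """CD-HIT-style greedy clustering of (id, sequence) records.

    Contigs are visited longest first; a contig joins the first existing
    representative whose local-alignment identity (matches / length of the
    shorter sequence) reaches the threshold, otherwise it founds a new
    cluster.  A shared 8-mer prefilter skips representative comparisons that
    cannot plausibly reach the threshold.

    Returns (representative ids in order, contig_id -> representative_id).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")

    order = sorted(contigs, key=lambda c: (-len(c[1]), c[0]))
    reps: list[tuple[str, str, set[str]]] = []
    membership: dict[str, str] = {}
    for cid, seq in order:
        kmers = _kmer_set(seq, prefilter_k) if prefilter_k else set()
        assigned = None
        for rid, rseq, rkmers in reps:
            if (
                prefilter_k
                and shared_kmer_fraction(
                    seq, rseq, prefilter_k, a_kmers=kmers, b_kmers=rkmers
                )
                < prefilter_min_shared
            ):
                continue
            aln = smith_waterman(seq, rseq)
            if aln.n_matches / min(len(seq), len(rseq)) >= identity_threshold:
                assigned = rid
                break
        if assigned is None:
            reps.append((cid, seq, kmers))
            assigned = cid
        membership[cid] = assigned
    return [rid for rid, _, _ in reps], membership
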