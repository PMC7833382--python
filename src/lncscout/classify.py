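"""Decision tree over non-coding candidates.

Order of evidence mirrors the discovery workflow: (1) too-short contigs
are discarded; (2) a significant ncRNA family hit labels the contig a
known ncRNA; (3) a significant nucleotide hit against the annotated mRNA
reference either makes it an autonomous 3'UTR (if >= 90% of the aligned
subject columns fall inside the 3'UTR and a protein-coding partner of the
same mRNA exists) or discards it; (4) what remains is a novel lncRNA
unless its coding score betrays residual coding potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import CodingVerdict
from .families import FamilyModel, count_null_exceedances, encode, pwm_scan_scores
from .seqcore import (
    NUCLEOTIDE_SCHEME,
    LocalAlignment,
    reverse_complement,
    smith_waterman,
    sw_score,
)
from .synthetic import Contig, ReferenceBundle

EVALUE_CUT = 1e-3
UTR_FRACTION_CUT = 0.9
CDS_FRACTION_CUT = 0.1
MIN_LEN = 200

# terminal classes
PCT = "PCT"
KNOWN_NC = "KNOWN_NC"
UTR3 = "UTR3"
NOVEL_LNC = "NOVEL_LNC"
DISCARDED = "DISCARDED"


@dataclass
class FamilyHit:
    family_id: str
    score: float
    pvalue: float
    strand: str  # "+" | "-"
    position: int  # 1-based window start on the given strand


@dataclass
class UtrMapping:
    contig_id: str
    mrna_id: str
    subject_start: int
    subject_end: int
    f_utr3: float
    f_cds: float
    evalue: float

    @property
    def is_utr3(self) -> bool:
        return self.f_utr3 >= UTR_FRACTION_CUT

    @property
    def overlaps_cds(self) -> bool:
        return self.f_cds > CDS_FRACTION_CUT


@dataclass
class UtrPctPair:
    utr_contig: str
    pct_contig: str
    mrna_id: str


@dataclass
class ClassifiedTranscript:
    contig_id: str
    final_class: str
    reason: str
    evidence: object | None = None


def family_scan(
    contig: str,
    models: list[FamilyModel],
    n_shuffles: int = 1000,
    p_cut: float = 0.001,
    seed: int = 0,
    batch: int = 100,
) -> FamilyHit | None:
    """Best significant family-model hit over both strands, or None.

    Significance is the empirical p of the observed best score against the
    best scores of mononucleotide-shuffled copies of the contig (max over
    models and strands, so the null accounts for the same search space);
    the minimum attainable p is 1/(n_shuffles+1).  Shuffles are consumed in
    batches with an early exit once significance is out of reach.
    """
    if not models:
        raise ValueError("no family models supplied")
    fwd = encode(contig)
    rev = encode(reverse_complement(contig))
    usable = [m for m in models if m.length <= len(contig)]
    if not usable:
        return None

    best: FamilyHit | None = None
    for model in usable:
        for strand, codes in (("+", fwd), ("-", rev)):
            scores = pwm_scan_scores(model.pwm, codes)
            i = int(np.argmax(scores))
            if best is None or scores[i] > best.score:
                best = FamilyHit(
                    family_id=model.family_id,
                    score=float(scores[i]),
                    pvalue=1.0,
                    strand=strand,
                    position=i + 1,
                )
    assert best is not None

    if any(m.score_threshold is not None for m in usable):
        thr = next(
            m.score_threshold for m in usable if m.family_id == best.family_id
        )
        if thr is not None:
            return best if best.score >= thr else None

    rng = np.random.default_rng(seed)
    max_exceed = int(np.floor(p_cut * (n_shuffles + 1))) - 1  # tolerated count
    exceed = 0
    done = 0
    while done < n_shuffles:
        b = min(batch, n_shuffles - done)
        shuffled = np.stack([rng.permutation(fwd) for _ in range(b)])
        exceed += count_null_exceedances(usable, shuffled, best.score)
        done += b
        if exceed > max_exceed:
            best.pvalue = (exceed + 1) / (done + 1)
            return None
    best.pvalue = (exceed + 1) / (n_shuffles + 1)
    return best if best.pvalue <= p_cut else None


def map_to_mrna(
    contig_id: str,
    seq: str,
    bundle: ReferenceBundle,
    e_cut: float = EVALUE_CUT,
    prefilter_k: int = 11,
    mrna_kmers: dict[str, set[str]] | None = None,
) -> UtrMapping | None:
    """Best nucleotide hit against the annotated mRNA reference, or None.

    The E-value uses the whole-database length convention.  Ties on
    E-value break toward the longer alignment, then the lexicographically
    smaller mRNA id.  Overlap fractions are computed over aligned subject
    columns against the mRNA's CDS and 3'UTR intervals.
    """
    db_len = sum(len(s) for _, s in bundle.mrnas)
    query_kmers = (
        {seq[i : i + prefilter_k] for i in range(len(seq) - prefilter_k + 1)}
        if prefilter_k
        else None
    )
    # score-only pass over candidate subjects, full traceback only for the
    # top scorers (E-value is monotone in score, so this loses nothing)
    scores: list[tuple[float, str, str]] = []
    for mid, mseq in sorted(bundle.mrnas):
        if prefilter_k:
            mk = mrna_kmers.get(mid) if mrna_kmers else None
            if mk is not None:
                if not (query_kmers & mk):
                    continue
            elif not _shares_kmer(seq, mseq, prefilter_k):
                continue
        scores.append((sw_score(seq, mseq, NUCLEOTIDE_SCHEME), mid, mseq))
    if not scores:
        return None
    top = max(s for s, _, _ in scores)
    best: tuple[int, str, LocalAlignment] | None = None
    for s, mid, mseq in scores:
        if s < top:
            continue
        aln = smith_waterman(
            seq, mseq, NUCLEOTIDE_SCHEME, subject_id=mid, database_length=db_len
        )
        key = (-aln.aligned_length, mid)
        if best is None or key < (-best[0], best[1]):
            best = (aln.aligned_length, mid, aln)
    assert best is not None
    _, mid, aln = best
    if aln.evalue > e_cut:
        return None
    cds_start, cds_end, length = bundle.mrna_annotation(mid)
    lo, hi = aln.subject_start, aln.subject_end
    span = hi - lo + 1
    cds_overlap = max(0, min(hi, cds_end) - max(lo, cds_start) + 1)
    utr3_overlap = max(0, min(hi, length) - max(lo, cds_end + 1) + 1)
    return UtrMapping(
        contig_id=contig_id,
        mrna_id=mid,
        subject_start=lo,
        subject_end=hi,
        f_utr3=utr3_overlap / span,
        f_cds=cds_overlap / span,
        evalue=aln.evalue,
    )


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) > len(b):
        a, b = b, a
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def pct_mrna_assignments(
    verdicts: list[CodingVerdict], bundle: ReferenceBundle
) -> dict[str, tuple[str, float]]:
    """Map PCT contigs to their source mRNA via the best protein hit."""
    out: dict[str, tuple[str, float]] = {}
    for v in verdicts:
        if v.label == PCT and v.best_hit is not None and v.best_hit.subject_id:
            mid = bundle.protein_to_mrna.get(v.best_hit.subject_id)
            if mid is not None:
                out[v.contig_id] = (mid, v.best_hit.evalue)
    return out


def pair_utr_with_pct(
    utr_mappings: list[UtrMapping],
    pct_assignments: dict[str, tuple[str, float]],
) -> tuple[list[UtrPctPair], list[str]]:
    """Pair 3'UTR-mapped contigs with the coding contig of the same mRNA.

    When several PCT contigs claim one mRNA the one with the best protein
    E-value wins (ties break on contig id); several 3'UTR fragments may
    share one PCT partner.  Returns (pairs, unpaired utr contig ids).
    """
    best_pct: dict[str, tuple[float, str]] = {}
    for cid, (mid, ev) in pct_assignments.items():
        key = (ev, cid)
        if mid not in best_pct or key < best_pct[mid]:
            best_pct[mid] = key
    pairs: list[UtrPctPair] = []
    unpaired: list[str] = []
    for m in utr_mappings:
        if not m.is_utr3:
            continue
        if m.mrna_id in best_pct:
            pairs.append(
                UtrPctPair(
                    utr_contig=m.contig_id,
                    pct_contig=best_pct[m.mrna_id][1],
                    mrna_id=m.mrna_id,
                )
            )
        else:
            unpaired.append(m.contig_id)
    return pairs, unpaired


def classify_transcripts(
    candidates: list[Contig],
    verdicts: list[CodingVerdict],
    bundle: ReferenceBundle,
    min_len: int = MIN_LEN,
    e_cut: float = EVALUE_CUT,
    n_shuffles: int = 1000,
    p_cut: float = 0.001,
    seed: int = 0,
) -> tuple[list[ClassifiedTranscript], list[UtrPctPair]]:
    """Classify non-coding candidates into the three non-overlapping groups.

    ``candidates`` are contigs judged NCT_CANDIDATE; ``verdicts`` must
    cover all contigs (including the PCT ones, which supply the pairing
    partners).  Input order does not affect the result.
    """
    verdict_by_id = {v.contig_id: v for v in verdicts}
    results: dict[str, ClassifiedTranscript] = {}
    rng = np.random.default_rng(seed)

    # step 1: length floor
    survivors: list[Contig] = []
    for c in sorted(candidates, key=lambda c: c.contig_id):
        if c.length < min_len:
            results[c.contig_id] = ClassifiedTranscript(
                c.contig_id, DISCARDED, "short"
            )
        else:
            survivors.append(c)

    # step 2: known ncRNA families
    remaining: list[Contig] = []
    for c in survivors:
        hit = family_scan(
            c.seq,
            bundle.families,
            n_shuffles=n_shuffles,
            p_cut=p_cut,
            seed=int(rng.integers(2**31)),
        ) if bundle.families else None
        if hit is not None:
            results[c.contig_id] = ClassifiedTranscript(
                c.contig_id, KNOWN_NC, "family_hit", hit
            )
        else:
            remaining.append(c)

    # step 3: mRNA mapping and 3'UTR pairing
    mrna_kmers = {
        mid: {mseq[i : i + 11] for i in range(len(mseq) - 11 + 1)}
        for mid, mseq in bundle.mrnas
    }
    mappings: list[UtrMapping] = []
    mapped_ids: set[str] = set()
    for c in remaining:
        m = map_to_mrna(c.contig_id, c.seq, bundle, e_cut=e_cut, mrna_kmers=mrna_kmers)
        if m is not None:
            mappings.append(m)
            mapped_ids.add(c.contig_id)
    pct_assign = pct_mrna_assignments(verdicts, bundle)
    pairs, unpaired = pair_utr_with_pct(mappings, pct_assign)
    paired_utr = {p.utr_contig for p in pairs}
    for m in mappings:
        cid = m.contig_id
        if cid in paired_utr:
            results[cid] = ClassifiedTranscript(cid, UTR3, "utr3_paired", m)
        elif m.is_utr3:
            results[cid] = ClassifiedTranscript(cid, DISCARDED, "no_partner", m)
        elif m.overlaps_cds:
            results[cid] = ClassifiedTranscript(cid, DISCARDED, "cds_overlap", m)
        else:
            results[cid] = ClassifiedTranscript(cid, DISCARDED, "mrna_ambiguous", m)

    # step 4: novel lncRNA unless coding potential leaks through
    for c in remaining:
        if c.contig_id in mapped_ids:
            continue
        v = verdict_by_id.get(c.contig_id)
        score = v.coding_score if v is not None else 0.0
        if score <= 0:
            results[c.contig_id] = ClassifiedTranscript(
                c.contig_id, NOVEL_LNC, "no_homology_noncoding"
            )
        else:
            results[c.contig_id] = ClassifiedTranscript(
                c.contig_id, DISCARDED, "coding_leak"
            )

    ordered = [results[c.contig_id] for c in candidates]
    return ordered, pairs
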