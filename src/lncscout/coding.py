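"""Coding-potential assessment: protein/domain homology plus a trained score.

A contig is judged protein-coding if its translated ORF has a reference
protein (or domain) hit at E <= 1e-3, or if a three-feature logistic
coding score is positive.  The score's features are the log10 length of the
best ORF, the ORF's coverage of the contig, and the mean in-frame hexamer
log-odds (coding vs non-coding hexamer usage) -- the classic feature set of
coding-potential classifiers, here trained on sequences supplied by the
caller (typically reference CDSs against their mononucleotide-shuffled
copies, which preserve composition while destroying codon structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .families import encode
from .seqcore import (
    PROTEIN_SCHEME,
    LocalAlignment,
    find_orfs,
    shared_kmer_fraction,
    smith_waterman,
    translate,
)

MIN_ORF_NT = 150
EVALUE_CUT = 1e-3
WEIGHT_CAP = 50.0

AA_INDEX = {a: i for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY")}


@dataclass
class HexamerTable:
    """log2(f_coding(h) / f_noncoding(h)) for all 4096 hexamers."""

    log_odds: np.ndarray  # shape (4096,)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.shape != (4096,):
            raise ValueError("hexamer table must have 4096 entries")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("hexamer log-odds must be finite")

    def score(self, seq: str, step: int = 1) -> float:
        """Mean log-odds of hexamers taken every ``step`` bases."""
        if len(seq) < 6:
            return 0.0
        codes = encode(seq).astype(np.int32)
        idx = (
            codes[:-5] * 1024
            + codes[1:-4] * 256
            + codes[2:-3] * 64
            + codes[3:-2] * 16
            + codes[4:-1] * 4
            + codes[5:]
        )
        idx = idx[::step]
        return float(self.log_odds[idx].mean())


@dataclass
class CodingModel:
    hexamers: HexamerTable
    weights: np.ndarray  # intercept + 3 feature weights
    min_orf_nt: int = MIN_ORF_NT

    def features(self, seq: str) -> np.ndarray:
        """(log10 best ORF length, ORF coverage, hexamer log-odds)."""
        orfs = find_orfs(seq, self.min_orf_nt, "sense")
        if orfs:
            orf = orfs[0]
            hex_score = self.hexamers.score(
                seq[orf.start - 1 : orf.end - 3], step=3
            )
            return np.array(
                [np.log10(orf.length), orf.coverage, hex_score]
            )
        return np.array([0.0, 0.0, self.hexamers.score(seq, step=1)])

    def score(self, seq: str) -> float:
        f = self.features(seq)
        return float(self.weights[0] + self.weights[1:] @ f)


@dataclass
class CodingVerdict:
    contig_id: str
    label: str  # "PCT" | "NCT_CANDIDATE"
    best_hit: LocalAlignment | None
    best_domain: tuple[str, float, float] | None  # (profile_id, score, p)
    coding_score: float
    features: np.ndarray

    @property
    def is_coding(self) -> bool:
        return self.label == "PCT"


def _hexamer_counts(seqs: list[str], step: int) -> np.ndarray:
    counts = np.ones(4096)  # pseudocount 1
    for seq in seqs:
        if len(seq) < 6:
            continue
        codes = encode(seq).astype(np.int32)
        idx = (
            codes[:-5] * 1024
            + codes[1:-4] * 256
            + codes[2:-3] * 64
            + codes[3:-2] * 16
            + codes[4:-1] * 4
            + codes[5:]
        )[::step]
        counts += np.bincount(idx, minlength=4096)
    return counts


def _fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    cap: float = WEIGHT_CAP,
) -> np.ndarray:
    """Maximum-likelihood logistic fit by iterative reweighting.

    A small ridge keeps the Newton steps finite on perfectly separable
    training sets; if the converged weights exceed the cap the whole
    vector is rescaled (the score-0 decision boundary is scale-invariant,
    so the decision rule is unchanged).
    """
    Xd = np.column_stack([np.ones(len(X)), X])
    ridge = 1e-4 * np.eye(Xd.shape[1])
    w = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = np.clip(Xd @ w, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / W
        WX = Xd * W[:, None]
        try:
            new = np.linalg.solve(Xd.T @ WX + ridge, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - w)) < tol:
            w = new
            break
        w = new
    peak = np.max(np.abs(w))
    if peak > cap:
        w = w * (cap / peak)
    return w


def train_coding_model(
    coding_seqs: list[str],
    noncoding_seqs: list[str],
    min_orf_nt: int = MIN_ORF_NT,
) -> CodingModel:
    """Hexamer table plus logistic weights from labelled training sequences.

    Coding sequences are read as in-frame ORFs (hexamers every 3 bases);
    non-coding sequences contribute hexamers in all frames.  The decision
    threshold is score 0.
    """
    if len(coding_seqs) < 50 or len(noncoding_seqs) < 50:
        raise ValueError("need >= 50 training sequences per class")
    cod = _hexamer_counts(coding_seqs, step=3)
    non = _hexamer_counts(noncoding_seqs, step=1)
    table = HexamerTable(np.log2((cod / cod.sum()) / (non / non.sum())))

    probe = CodingModel(hexamers=table, weights=np.zeros(4), min_orf_nt=min_orf_nt)
    X = np.array(
        [probe.features(s) for s in coding_seqs]
        + [probe.features(s) for s in noncoding_seqs]
    )
    y = np.array([1.0] * len(coding_seqs) + [0.0] * len(noncoding_seqs))
    weights = _fit_logistic(X, y)
    return CodingModel(hexamers=table, weights=weights, min_orf_nt=min_orf_nt)


def build_ref_kmers(
    protein_refs: list[tuple[str, str]], k: int = 4
) -> dict[str, set[str]]:
    """Pre-computed k-mer sets of reference proteins for the homology screen."""
    return {
        pid: {p[i : i + k] for i in range(len(p) - k + 1)}
        for pid, p in protein_refs
    }


def shuffled_copies(
    seq: str, n: int, rng: np.random.Generator
) -> list[str]:
    """Mononucleotide-shuffled copies (composition-preserving permutations)."""
    chars = np.array(list(seq))
    return ["".join(chars[rng.permutation(len(chars))]) for _ in range(n)]


@dataclass
class DomainProfile:
    """Protein PWM (L x 20 log-odds) standing in for an HMM domain model."""

    profile_id: str
    pwm: np.ndarray

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 20:
            raise ValueError("protein PWM must have shape (L, 20)")

    def best_score(self, protein: str) -> float:
        codes = np.array([AA_INDEX.get(a, -1) for a in protein])
        L, W = len(codes), self.pwm.shape[0]
        if L < W:
            return -np.inf
        best = -np.inf
        valid = codes >= 0
        safe = np.where(valid, codes, 0)
        for i in range(L - W + 1):
            window = safe[i : i + W]
            s = float(self.pwm[np.arange(W), window][valid[i : i + W]].sum())
            best = max(best, s)
        return best


def scan_domains(
    protein: str,
    profiles: list[DomainProfile],
    n_shuffles: int = 1000,
    p_cut: float = 0.001,
    seed: int = 0,
) -> tuple[str, float, float] | None:
    """Best significant domain hit by uniform-residue-shuffle null, or None."""
    if not profiles or not protein:
        return None
    rng = np.random.default_rng(seed)
    best_id, best_score = None, -np.inf
    for prof in profiles:
        s = prof.best_score(protein)
        if s > best_score:
            best_id, best_score = prof.profile_id, s
    if not np.isfinite(best_score):
        return None
    chars = np.array(list(protein))
    exceed = 0
    for _ in range(n_shuffles):
        shuf = "".join(chars[rng.permutation(len(chars))])
        null = max(p.best_score(shuf) for p in profiles)
        if null >= best_score:
            exceed += 1
            if (exceed + 1) / (n_shuffles + 1) > p_cut:
                return None  # early exit: cannot reach significance
    p = (exceed + 1) / (n_shuffles + 1)
    return (best_id, best_score, p) if p <= p_cut else None


def assess_coding(
    contig_id: str,
    seq: str,
    protein_refs: list[tuple[str, str]],
    model: CodingModel,
    domain_profiles: list[DomainProfile] | None = None,
    evalue_cut: float = EVALUE_CUT,
    n_shuffles: int = 1000,
    seed: int = 0,
    prefilter_k: int = 4,
    prefilter_min_shared: float = 0.05,
    ref_kmers: dict[str, set[str]] | None = None,
) -> CodingVerdict:
    """Classify one contig as PCT or NCT_CANDIDATE.

    The best ORF (>= model.min_orf_nt, sense strand) is translated and
    aligned against every reference protein (whole-database E-value
    convention); a shared 4-mer prefilter skips proteins that cannot hit.
    Domain profiles are scanned only when protein homology has not already
    settled the verdict.  Contigs with no qualifying ORF are scored from
    whole-sequence hexamers with coverage 0.
    """
    features = model.features(seq)
    coding_score = float(model.weights[0] + model.weights[1:] @ features)

    best_hit: LocalAlignment | None = None
    best_domain = None
    orfs = find_orfs(seq, model.min_orf_nt, "sense")
    if orfs and protein_refs:
        orf = orfs[0]
        protein = translate(seq[orf.start - 1 : orf.end])
        db_len = sum(len(p) for _, p in protein_refs)
        query_kmers = {
            protein[i : i + prefilter_k]
            for i in range(len(protein) - prefilter_k + 1)
        }
        for pid, pseq in protein_refs:
            if prefilter_k:
                shared = shared_kmer_fraction(
                    protein,
                    pseq,
                    prefilter_k,
                    a_kmers=query_kmers,
                    b_kmers=ref_kmers.get(pid) if ref_kmers else None,
                )
                if shared < prefilter_min_shared:
                    continue
            aln = smith_waterman(
                protein,
                pseq,
                PROTEIN_SCHEME,
                subject_id=pid,
                database_length=db_len,
            )
            if best_hit is None or aln.evalue < best_hit.evalue:
                best_hit = aln
        if best_hit is not None and best_hit.evalue > evalue_cut:
            best_hit = None
    if orfs and domain_profiles and best_hit is None:
        orf = orfs[0]
        protein = translate(seq[orf.start - 1 : orf.end])
        best_domain = scan_domains(
            protein, domain_profiles, n_shuffles=n_shuffles, seed=seed
        )

    label = (
        "PCT"
        if best_hit is not None or best_domain is not None or coding_score > 0
        else "NCT_CANDIDATE"
    )
    return CodingVerdict(
        contig_id=contig_id,
        label=label,
        best_hit=best_hit,
        best_domain=best_domain,
        coding_score=coding_score,
        features=features,
    )
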