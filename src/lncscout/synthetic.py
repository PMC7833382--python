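"""Ground-truth synthetic transcriptomes and count matrices.

The generator emulates a toxin-versus-vehicle liver RNA-seq study on a
non-model fish: assembled contigs fall into four ground-truth classes --
protein-coding transcripts (PCT), known ncRNA family members (KNOWN_NC),
autonomous 3'UTR fragments paired with a coding fragment of the same parent
mRNA (UTR3), and novel lncRNAs (NOVEL_LNC).  Classes differ in GC content
(lower in lncRNAs), length (shorter in lncRNAs) and ORF content, and
per-contig negative-binomial counts carry per-day condition effects,
including co-regulated and oppositely regulated 3'UTR/PCT pairs.

Defaults encode the emulated study design: two arms (PBS vehicle vs MC-LR
toxin) at days 1, 6 and 9 with six biological replicates each; class GC
targets 0.460 (PCT) vs 0.393 (lncRNA); day-1 pair effects dominated by
co-upregulation with opposing pairs rare, days 6/9 balanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .families import BASES, FamilyModel
from .seqcore import STOP_CODONS, find_orfs, gc_fraction, translate

PCT = "PCT"
KNOWN_NC = "KNOWN_NC"
UTR3 = "UTR3"
NOVEL_LNC = "NOVEL_LNC"
CLASSES = (PCT, KNOWN_NC, UTR3, NOVEL_LNC)

CONTROL = "PBS"
TREATED = "MCLR"

DAYS = (1, 6, 9)

QUADRANTS = ("both_up", "both_down", "utr_up_pct_down", "utr_down_pct_up")


@dataclass
class Contig:
    contig_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class TruthRecord:
    contig_id: str
    true_class: str
    parent_mrna_id: str | None = None
    log2fc: dict[int, float] = field(default_factory=dict)  # day -> lfc
    quadrant: dict[int, str | None] = field(default_factory=dict)
    base_mean: float = 0.0
    duplicate_of: str | None = None


@dataclass
class ParentMrna:
    """Full-length mRNA substrate a 3'UTR/PCT contig pair is cut from."""

    mrna_id: str
    seq: str
    cds_start: int  # 1-based inclusive; CDS begins ATG, ends a stop codon
    cds_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise ValueError("CDS must lie within the mRNA")
        cds = self.seq[self.cds_start - 1 : self.cds_end]
        if len(cds) % 3:
            raise ValueError("CDS length must be divisible by 3")
        if not cds.startswith("ATG") or cds[-3:] not in STOP_CODONS:
            raise ValueError("CDS must begin ATG and end with a stop codon")

    @property
    def utr3_interval(self) -> tuple[int, int]:
        return (self.cds_end + 1, len(self.seq))

    @property
    def cds_seq(self) -> str:
        return self.seq[self.cds_start - 1 : self.cds_end]


@dataclass
class EffectConfig:
    """Per-class, per-day differential-expression assignments.

    Non-pair classes: a contig is affected with probability ``de_fraction``;
    an affected contig draws a sign, a |log2FC| from ``lfc_range`` and a day
    pattern (day-1-only, days 6+9, or all days) so that days 6 and 9 behave
    more like each other than like day 1.  Pairs: per day the pair is DE
    with probability ``pair_de_fraction`` and draws its quadrant from
    ``quadrant_props`` (both up, both down, UTR up / PCT down, UTR down /
    PCT up); defaults follow the emulated study (day 1 dominated by
    co-upregulated pairs, days 6 and 9 balanced with more opposing pairs).
    """

    de_fraction: float = 0.35
    lfc_range: tuple[float, float] = (2.5, 5.0)
    day_patterns: tuple[tuple[int, ...], ...] = ((1,), (6, 9), (1, 6, 9))
    day_pattern_probs: tuple[float, ...] = (0.3, 0.4, 0.3)
    pair_de_fraction: float = 0.6
    pair_lfc_range: tuple[float, float] = (3.0, 5.0)
    quadrant_props: Mapping[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            1: (0.82, 0.11, 0.04, 0.03),
            6: (0.40, 0.41, 0.10, 0.09),
            9: (0.42, 0.42, 0.08, 0.08),
        }
    )

    def __post_init__(self) -> None:
        for day, props in self.quadrant_props.items():
            if len(props) != 4 or any(p < 0 for p in props):
                raise ValueError("quadrant proportions must be 4 non-negatives")
            if sum(props) > 1 + 1e-9:
                raise ValueError("quadrant proportions must sum to <= 1")


@dataclass
class GeneratorConfig:
    n_pct: int = 200
    n_known_nc: int = 50
    n_utr_pairs: int = 100
    n_novel_lnc: int = 150
    # log-normal (mean of log, sd of log) of contig length in nt
    pct_length_dist: tuple[float, float] = (math.log(900.0), 0.35)
    lnc_length_dist: tuple[float, float] = (math.log(450.0), 0.45)
    pct_gc_target: float = 0.460
    lnc_gc_target: float = 0.393
    utr_gc_target: float = 0.430
    min_len: int = 200
    max_len: int = 3000
    nb_dispersion: float = 0.1  # alpha in var = mu + alpha mu^2
    base_mean_dist: tuple[float, float] = (math.log(100.0), 1.0)
    design: tuple[tuple[str, int, int], ...] = tuple(
        (cond, day, 6) for day in DAYS for cond in (CONTROL, TREATED)
    )
    effects: EffectConfig = field(default_factory=EffectConfig)
    redundancy_rate: float = 0.0
    redundancy_identity: float = 0.95
    n_families: int = 5
    pct_orf_min: int = 300  # complete-ORF floor planted in PCT contigs
    lnc_orf_max: int = 150  # complete-ORF ceiling scrubbed from lncRNAs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pct", "n_known_nc", "n_utr_pairs", "n_novel_lnc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for gc in (self.pct_gc_target, self.lnc_gc_target, self.utr_gc_target):
            if not 0 < gc < 1:
                raise ValueError("GC targets must be in (0, 1)")
        if any(reps < 2 for _, _, reps in self.design):
            raise ValueError("each design cell needs >= 2 replicates")
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        if math.exp(self.lnc_length_dist[0] + 3 * self.lnc_length_dist[1]) < self.min_len:
            raise ValueError("lncRNA length distribution lies below min_len")

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted({day for _, day, _ in self.design}))

    def design_frame(self) -> pd.DataFrame:
        rows = []
        for cond, day, reps in self.design:
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_d{day}_r{r}",
                        "condition": cond,
                        "day": day,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ReferenceBundle:
    """Everything downstream homology/annotation stages search against."""

    proteins: list[tuple[str, str]]
    mrnas: list[tuple[str, str]]
    annotations: pd.DataFrame  # mrna_id, cds_start, cds_end, length
    protein_to_mrna: dict[str, str]
    families: list[FamilyModel]
    term_map: pd.DataFrame  # mrna_id, term

    def mrna_annotation(self, mrna_id: str) -> tuple[int, int, int]:
        row = self.annotations.set_index("mrna_id").loc[mrna_id]
        return int(row["cds_start"]), int(row["cds_end"]), int(row["length"])


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """In-frame stop-free codons with approximately the target GC."""
    out = []
    while len(out) < n_codons:
        codon = _random_seq(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _scrub_orfs(rng: np.random.Generator, seq: str, max_orf: int) -> str:
    """Destroy complete sense-strand ORFs >= max_orf by planting stops."""
    seq = list(seq)
    for _ in range(200):
        orfs = [o for o in find_orfs("".join(seq), max_orf, "sense") if o.frame > 0]
        if not orfs:
            break
        orf = orfs[0]
        # overwrite a mid-ORF codon with TAA (1-based coords -> 0-based)
        codon_slots = (orf.length // 3) - 2
        pick = int(rng.integers(1, max(2, codon_slots)))
        pos = orf.start - 1 + 3 * pick
        seq[pos : pos + 3] = "TAA"
    return "".join(seq)


def _draw_length(
    rng: np.random.Generator, dist: tuple[float, float], lo: int, hi: int
) -> int:
    for _ in range(1000):
        L = int(round(rng.lognormal(dist[0], dist[1])))
        if lo <= L <= hi:
            return L
    raise ValueError(
        f"length distribution {dist} cannot produce values in [{lo}, {hi}]"
    )


def _make_pct_contig(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[str, int, int]:
    """A contig carrying one complete ORF; returns (seq, orf_start, orf_end)."""
    L = _draw_length(
        rng, cfg.pct_length_dist, max(cfg.min_len, cfg.pct_orf_min + 60), cfg.max_len
    )
    orf_nt = max(cfg.pct_orf_min, 3 * int(0.6 * L / 3))
    orf_nt = min(orf_nt, 3 * ((L - 40) // 3))
    n_codons = orf_nt // 3 - 2  # minus start and stop
    rest = L - orf_nt
    utr5 = int(rng.integers(10, max(11, rest - 10 + 1)))
    utr3 = rest - utr5
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    cds = "ATG" + _random_codons(rng, n_codons, cfg.pct_gc_target) + stop
    seq = (
        _scrub_orfs(rng, _random_seq(rng, utr5, cfg.utr_gc_target), cfg.lnc_orf_max)
        + cds
        + _scrub_orfs(rng, _random_seq(rng, utr3, cfg.utr_gc_target), cfg.lnc_orf_max)
    )
    return seq, utr5 + 1, utr5 + orf_nt


def _make_family_models(rng: np.random.Generator, cfg: GeneratorConfig) -> list[FamilyModel]:
    models = []
    for i in range(cfg.n_families):
        L = int(rng.integers(60, 121))
        consensus = rng.integers(0, 4, size=L)
        p = np.full((L, 4), 0.05)
        p[np.arange(L), consensus] = 0.85
        pwm = np.log2(p / 0.25)
        models.append(FamilyModel(family_id=f"FAM{i:03d}", pwm=pwm))
    return models


def _emit_family_member(
    rng: np.random.Generator, model: FamilyModel, cfg: GeneratorConfig, length: int
) -> str:
    p = 0.25 * 2.0**model.pwm
    p /= p.sum(axis=1, keepdims=True)
    core = "".join(
        BASES[rng.choice(4, p=p[i])] for i in range(model.length)
    )
    flank = max(0, length - len(core))
    left = int(rng.integers(0, flank + 1))
    seq = (
        _random_seq(rng, left, cfg.lnc_gc_target)
        + core
        + _random_seq(rng, flank - left, cfg.lnc_gc_target)
    )
    return _scrub_orfs(rng, seq, cfg.lnc_orf_max)


def _make_parent_mrna(
    rng: np.random.Generator, cfg: GeneratorConfig, mrna_id: str
) -> ParentMrna:
    utr5 = int(rng.integers(30, 91))
    n_codons = int(rng.integers(100, 301))
    utr3 = int(rng.integers(max(250, cfg.min_len + 50), 651))
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    cds = "ATG" + _random_codons(rng, n_codons - 2, cfg.pct_gc_target) + stop
    seq = (
        _scrub_orfs(rng, _random_seq(rng, utr5, cfg.utr_gc_target), cfg.lnc_orf_max)
        + cds
        + _scrub_orfs(rng, _random_seq(rng, utr3, cfg.utr_gc_target), cfg.lnc_orf_max)
    )
    return ParentMrna(
        mrna_id=mrna_id, seq=seq, cds_start=utr5 + 1, cds_end=utr5 + len(cds)
    )


def _make_novel_lnc(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    L = _draw_length(rng, cfg.lnc_length_dist, cfg.min_len, cfg.max_len)
    gc = float(np.clip(rng.normal(cfg.lnc_gc_target, 0.02), 0.2, 0.8))
    return _scrub_orfs(rng, _random_seq(rng, L, gc), cfg.lnc_orf_max)


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------


def _assign_single_effect(
    rng: np.random.Generator, eff: EffectConfig, days: Sequence[int]
) -> dict[int, float]:
    lfc = {d: 0.0 for d in days}
    if rng.random() >= eff.de_fraction:
        return lfc
    sign = 1.0 if rng.random() < 0.5 else -1.0
    mag = rng.uniform(*eff.lfc_range)
    pattern = eff.day_patterns[
        rng.choice(len(eff.day_patterns), p=np.asarray(eff.day_pattern_probs))
    ]
    for d in pattern:
        if d in lfc:
            lfc[d] = sign * mag
    return lfc


_QUADRANT_SIGNS = {
    "both_up": (1, 1),
    "both_down": (-1, -1),
    "utr_up_pct_down": (1, -1),
    "utr_down_pct_up": (-1, 1),
}


def _assign_pair_effect(
    rng: np.random.Generator, eff: EffectConfig, days: Sequence[int]
) -> tuple[dict[int, float], dict[int, float], dict[int, str | None]]:
    utr_lfc = {d: 0.0 for d in days}
    pct_lfc = {d: 0.0 for d in days}
    quadrant: dict[int, str | None] = {d: None for d in days}
    for d in days:
        if rng.random() >= eff.pair_de_fraction:
            continue
        props = np.asarray(eff.quadrant_props.get(d, (0.25, 0.25, 0.25, 0.25)))
        total = props.sum()
        if rng.random() >= total:
            continue
        q = QUADRANTS[rng.choice(4, p=props / total)]
        su, sp = _QUADRANT_SIGNS[q]
        utr_lfc[d] = su * rng.uniform(*eff.pair_lfc_range)
        pct_lfc[d] = sp * rng.uniform(*eff.pair_lfc_range)
        quadrant[d] = q
    return utr_lfc, pct_lfc, quadrant


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_transcriptome(
    config: GeneratorConfig,
) -> tuple[list[Contig], list[TruthRecord], ReferenceBundle]:
    """Emit contigs, ground-truth records and the reference bundle.

    Guarantees: PCT contigs contain a complete ORF >= ``pct_orf_min`` nt;
    NOVEL_LNC (and non-CDS regions generally) contain no complete sense ORF
    >= ``lnc_orf_max`` nt; each UTR pair yields one contig overlapping only
    the CDS and one lying entirely inside the 3'UTR of a shared parent
    mRNA; all contigs are >= ``min_len`` nt.
    """
    rng = np.random.default_rng(config.seed)
    # independent streams per stage so adding a class never reshuffles others
    r_pct, r_fam, r_pair, r_lnc, r_eff, r_base, r_term = rng.spawn(7)

    contigs: list[Contig] = []
    truth: list[TruthRecord] = []
    proteins: list[tuple[str, str]] = []
    mrnas: list[tuple[str, str]] = []
    annotations: list[dict] = []
    protein_to_mrna: dict[str, str] = {}
    days = config.days

    # --- standalone protein-coding transcripts
    for i in range(config.n_pct):
        seq, orf_s, orf_e = _make_pct_contig(r_pct, config)
        cid = f"PCT{i:05d}"
        mid = f"mrna_{cid}"
        pid = f"prot_{cid}"
        contigs.append(Contig(cid, seq))
        truth.append(TruthRecord(cid, PCT))
        proteins.append((pid, translate(seq[orf_s - 1 : orf_e])))
        mrnas.append((mid, seq))
        annotations.append(
            {"mrna_id": mid, "cds_start": orf_s, "cds_end": orf_e, "length": len(seq)}
        )
        protein_to_mrna[pid] = mid

    # --- known ncRNA family members
    families = _make_family_models(r_fam, config)
    for i in range(config.n_known_nc):
        model = families[int(r_fam.integers(len(families)))] if families else None
        if model is None:
            raise ValueError("n_known_nc > 0 requires n_families > 0")
        L = _draw_length(r_fam, config.lnc_length_dist, config.min_len, config.max_len)
        cid = f"KNC{i:05d}"
        contigs.append(Contig(cid, _emit_family_member(r_fam, model, config, L)))
        truth.append(TruthRecord(cid, KNOWN_NC))

    # --- 3'UTR / PCT pairs cut from shared parent mRNAs
    for i in range(config.n_utr_pairs):
        mid = f"pairmrna_{i:05d}"
        parent = _make_parent_mrna(r_pair, config, mid)
        mrnas.append((mid, parent.seq))
        annotations.append(
            {
                "mrna_id": mid,
                "cds_start": parent.cds_start,
                "cds_end": parent.cds_end,
                "length": len(parent.seq),
            }
        )
        pid = f"prot_{mid}"
        proteins.append((pid, translate(parent.cds_seq)))
        protein_to_mrna[pid] = mid

        # coding member: a 5' tail plus the full CDS, never entering the 3'UTR
        tail = int(r_pair.integers(0, parent.cds_start))
        pct_seq = parent.seq[parent.cds_start - 1 - tail : parent.cds_end]
        pct_id = f"PAIRPCT{i:05d}"
        contigs.append(Contig(pct_id, pct_seq))
        truth.append(TruthRecord(pct_id, PCT, parent_mrna_id=mid))

        # 3'UTR member: a fragment entirely inside the 3'UTR
        u3s, u3e = parent.utr3_interval
        utr_len = u3e - u3s + 1
        frag_len = int(r_pair.integers(config.min_len, utr_len + 1))
        off = int(r_pair.integers(0, utr_len - frag_len + 1))
        utr_seq = parent.seq[u3s - 1 + off : u3s - 1 + off + frag_len]
        utr_id = f"UTR{i:05d}"
        contigs.append(Contig(utr_id, utr_seq))
        truth.append(TruthRecord(utr_id, UTR3, parent_mrna_id=mid))

    # --- novel lncRNAs
    for i in range(config.n_novel_lnc):
        cid = f"LNC{i:05d}"
        contigs.append(Contig(cid, _make_novel_lnc(r_lnc, config)))
        truth.append(TruthRecord(cid, NOVEL_LNC))

    # --- expression truth: base means and per-day effects
    pair_members: dict[str, dict[str, TruthRecord]] = {}
    for rec in truth:
        rec.base_mean = float(r_base.lognormal(*config.base_mean_dist))
        if rec.parent_mrna_id is not None:
            pair_members.setdefault(rec.parent_mrna_id, {})[rec.true_class] = rec
    for rec in truth:
        if rec.parent_mrna_id is None:
            rec.log2fc = _assign_single_effect(r_eff, config.effects, days)
            rec.quadrant = {d: None for d in days}
    for mid, members in sorted(pair_members.items()):
        utr_lfc, pct_lfc, quad = _assign_pair_effect(r_eff, config.effects, days)
        members[UTR3].log2fc = utr_lfc
        members[UTR3].quadrant = quad
        members[PCT].log2fc = pct_lfc
        members[PCT].quadrant = quad

    # --- term-annotation map over all reference mRNAs
    terms = [f"TERM:{k:04d}" for k in range(25)]
    term_rows = []
    for mid, _ in mrnas:
        for t in r_term.choice(
            terms, size=int(r_term.integers(1, 5)), replace=False
        ):
            term_rows.append({"mrna_id": mid, "term": t})
    term_map = pd.DataFrame(term_rows, columns=["mrna_id", "term"])

    bundle = ReferenceBundle(
        proteins=proteins,
        mrnas=mrnas,
        annotations=pd.DataFrame(
            annotations, columns=["mrna_id", "cds_start", "cds_end", "length"]
        ),
        protein_to_mrna=protein_to_mrna,
        families=families,
        term_map=term_map,
    )

    if config.redundancy_rate > 0:
        contigs, truth = inject_redundancy(
            contigs,
            config.redundancy_rate,
            config.redundancy_identity,
            seed=int(rng.integers(2**31)),
            truth=truth,
        )

    return contigs, truth, bundle


def simulate_counts(
    truth: Sequence[TruthRecord],
    config: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial count matrix (contig x sample) for the design.

    K_ij ~ NB(mean = s_j * mu_i * 2^lfc(day_j) when treated, dispersion
    alpha) with sample-specific size multipliers s_j ~ log-uniform
    [0.7, 1.4].  alpha = 0 gives the Poisson limit.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    design = config.design_frame()
    mu = np.array([rec.base_mean for rec in truth], dtype=float)
    if np.any(mu < 0):
        raise ValueError("base means must be non-negative")
    size_mult = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=len(design)))

    lfc = np.zeros((len(truth), len(design)))
    for j, row in design.iterrows():
        if row["condition"] == TREATED:
            lfc[:, j] = [rec.log2fc.get(int(row["day"]), 0.0) for rec in truth]

    mean = mu[:, None] * size_mult[None, :] * 2.0**lfc
    alpha = config.nb_dispersion
    if alpha > 0:
        r = 1.0 / alpha
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)
    return pd.DataFrame(
        counts,
        index=pd.Index([rec.contig_id for rec in truth], name="contig_id"),
        columns=design["sample_id"].tolist(),
    )


def inject_redundancy(
    contigs: Sequence[Contig],
    rate: float,
    identity_level: float = 0.95,
    seed: int = 0,
    truth: Sequence[TruthRecord] | None = None,
) -> tuple[list[Contig], list[TruthRecord]]:
    """Add ceil(rate*N) near-duplicate contigs by point-mutating donors.

    Each duplicate differs from its donor at ``round((1-identity_level) *
    length)`` positions and carries provenance in its truth record
    (``duplicate_of``).  Returns the augmented contig list and the
    augmented truth list (duplicates inherit the donor's class and
    expression truth, as redundant assemblies of the same transcript do).
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if not 0 < identity_level <= 1:
        raise ValueError("identity_level must be in (0, 1]")
    contigs = list(contigs)
    truth_by_id = {rec.contig_id: rec for rec in truth} if truth else {}
    out_truth = list(truth) if truth else []
    n_dup = math.ceil(rate * len(contigs))
    rng = np.random.default_rng(seed)
    if n_dup == 0:
        return contigs, out_truth
    donors = rng.choice(len(contigs), size=n_dup, replace=n_dup > len(contigs))
    out = list(contigs)
    for k, di in enumerate(sorted(int(d) for d in donors)):
        donor = contigs[di]
        seq = list(donor.seq)
        n_mut = int(round((1 - identity_level) * len(seq)))
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            alternatives = [b for b in BASES if b != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(3))]
        dup_id = f"{donor.contig_id}_dup{k}"
        out.append(Contig(dup_id, "".join(seq)))
        if truth:
            src = truth_by_id[donor.contig_id]
            out_truth.append(
                replace(
                    src,
                    contig_id=dup_id,
                    log2fc=dict(src.log2fc),
                    quadrant=dict(src.quadrant),
                    duplicate_of=donor.contig_id,
                )
            )
    return out, out_truth
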