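"""Co-expression analysis of autonomous 3'UTR / coding-partner pairs.

Per-day differential-expression quadrants (both members up, both down, or
opposing), a control-condition abundance-ratio test (is the 3'UTR fragment
or the coding fragment of the same mRNA more abundant in unchallenged
samples?), and hypergeometric term enrichment of pair categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import UtrPctPair
from .diffexpr import SizeFactors, _nb_irls, bh_adjust, estimate_dispersions
from .synthetic import QUADRANTS


@dataclass
class QuadrantReport:
    day: int
    counts: dict[str, int]  # over both-DE pairs, keys QUADRANTS
    percentages: dict[str, float]
    one_sided: int  # exactly one member DE (excluded from percentages)
    non_de: int
    total_pairs: int

    @property
    def both_de(self) -> int:
        return sum(self.counts.values())

    def conserves(self) -> bool:
        return self.both_de + self.one_sided + self.non_de == self.total_pairs


def quadrant_classify(
    pairs: list[UtrPctPair],
    de_utr: pd.DataFrame,
    de_pct: pd.DataFrame,
    day: int,
) -> QuadrantReport:
    """Assign each pair with both members DE to a sign quadrant.

    ``de_utr`` and ``de_pct`` are DE tables (indexed by contig id, with
    ``log2FoldChange`` and ``is_de``) covering the pair members.
    Percentages are over both-DE pairs only.
    """
    counts = {q: 0 for q in QUADRANTS}
    one_sided = 0
    non_de = 0
    for p in pairs:
        u = de_utr.loc[p.utr_contig]
        c = de_pct.loc[p.pct_contig]
        if bool(u["is_de"]) and bool(c["is_de"]):
            su = u["log2FoldChange"] > 0
            sc = c["log2FoldChange"] > 0
            if su and sc:
                counts["both_up"] += 1
            elif not su and not sc:
                counts["both_down"] += 1
            elif su:
                counts["utr_up_pct_down"] += 1
            else:
                counts["utr_down_pct_up"] += 1
        elif bool(u["is_de"]) or bool(c["is_de"]):
            one_sided += 1
        else:
            non_de += 1
    both = sum(counts.values())
    percentages = {
        q: (100.0 * n / both if both else 0.0) for q, n in counts.items()
    }
    return QuadrantReport(
        day=day,
        counts=counts,
        percentages=percentages,
        one_sided=one_sided,
        non_de=non_de,
        total_pairs=len(pairs),
    )


def control_ratio_analysis(
    pairs: list[UtrPctPair],
    counts: pd.DataFrame,
    sizefactors: SizeFactors,
    control_samples: list[str],
    padj_cut: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Which member of each pair is more abundant in control samples?

    Per pair, a paired NB Wald test across the same control samples with
    member identity as the condition (positive log2FC means the 3'UTR
    member is higher); BH correction across pairs.  Returns the per-pair
    table and summary fractions (utr_higher / pct_higher / no_difference
    at padj < 0.05).
    """
    if len(control_samples) < 2:
        raise ValueError("need >= 2 control samples")
    s = sizefactors.values.loc[control_samples].to_numpy()
    offset = np.tile(np.log(s), 2)
    x = np.repeat([0.0, 1.0], len(control_samples))  # 1 = UTR member

    member_ids = sorted(
        {p.utr_contig for p in pairs} | {p.pct_contig for p in pairs}
    )
    ctrl = counts.loc[member_ids, control_samples]
    disp = estimate_dispersions(
        ctrl,
        SizeFactors(sizefactors.values.loc[control_samples]),
        ["ctrl"] * len(control_samples),
    )

    rows = []
    ln2 = np.log(2.0)
    for p in pairs:
        y = np.concatenate(
            [
                counts.loc[p.pct_contig, control_samples].to_numpy(dtype=float),
                counts.loc[p.utr_contig, control_samples].to_numpy(dtype=float),
            ]
        )
        alpha = float(np.mean([disp[p.utr_contig], disp[p.pct_contig]]))
        if y.any():
            beta, se, ok = _nb_irls(y, x, offset, alpha)
            lfc = beta[1] / ln2
            pval = (
                2.0 * stats.norm.sf(abs(beta[1] / se[1]))
                if ok and np.isfinite(se[1]) and se[1] > 0
                else 1.0
            )
        else:
            lfc, pval = 0.0, 1.0
        rows.append(
            {
                "utr_contig": p.utr_contig,
                "pct_contig": p.pct_contig,
                "mrna_id": p.mrna_id,
                "log2_utr_over_pct": lfc,
                "pvalue": pval,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["padj"] = bh_adjust(table["pvalue"].to_numpy())
        sig = table["padj"] < padj_cut
        table["verdict"] = np.where(
            sig & (table["log2_utr_over_pct"] > 0),
            "utr_higher",
            np.where(
                sig & (table["log2_utr_over_pct"] < 0),
                "pct_higher",
                "no_difference",
            ),
        )
    else:
        table["padj"] = []
        table["verdict"] = []
    n = max(len(table), 1)
    summary = {
        "utr_higher": float((table["verdict"] == "utr_higher").sum() / n),
        "pct_higher": float((table["verdict"] == "pct_higher").sum() / n),
        "no_difference": float((table["verdict"] == "no_difference").sum() / n),
        "n_pairs": len(table),
    }
    return table, summary


@dataclass
class EnrichmentResult:
    term: str
    k: int  # hits in selection
    n: int  # selection size
    K: int  # hits in background
    N: int  # background size
    p_enrich: float  # P[X >= k]
    p_deplete: float  # P[X <= k]


def term_enrichment(
    selected: list[str],
    background: list[str],
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Exact hypergeometric enrichment/depletion of terms in a selection.

    ``term_map`` has columns (mrna_id, term); ``selected`` must be a
    subset of ``background``.  No multiplicity correction is applied (the
    emulated analysis reports raw p < 0.05); results are returned for all
    terms with either tail below ``alpha``, sorted by enrichment p.
    Terms never seen in the background are skipped with a warning.
    """
    bg = set(background)
    sel = set(selected)
    if not sel <= bg:
        raise ValueError("selected ids must be a subset of the background")
    N, n = len(bg), len(sel)
    results = []
    for term, sub in term_map.groupby("term"):
        members = set(sub["mrna_id"]) & bg
        if not members:
            warnings.warn(f"term {term} absent from background", RuntimeWarning)
            continue
        K = len(members)
        k = len(members & sel)
        p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
        results.append(
            EnrichmentResult(
                term=term, k=k, n=n, K=K, N=N,
                p_enrich=p_enrich, p_deplete=p_deplete,
            )
        )
    hits = [r for r in results if r.p_enrich < alpha or r.p_deplete < alpha]
    return sorted(hits, key=lambda r: r.p_enrich)
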