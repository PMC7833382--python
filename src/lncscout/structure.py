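"""Structural and statistical contrasts between transcript classes.

Welch's t on length-corrected MFE, GC and length between classes (with
per-class subsampling at 4000, matching the scale of the emulated
contrasts), plus the qPCR validation statistics: reference-normalized
relative expression, one-way ANOVA on log-transformed values and
Dunnett's many-to-one post hoc comparisons with Monte-Carlo critical
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .folding import FoldResult, fold_mfe
from .seqcore import gc_fraction
from .synthetic import Contig

SAMPLE_N = 4000


@dataclass
class WelchResult:
    t: float
    df: float
    pvalue: float
    ci_low: float
    ci_high: float
    mean_diff: float

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("Welch-Satterthwaite df must be positive")


def welch_t(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> WelchResult:
    """Welch's unequal-variance t from group summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom; the 95% CI of the mean difference comes from the
    t-quantile at that df.  Identical degenerate groups (both sd 0, equal
    means) give t = 0, p = 1.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = s1**2 / n1, s2**2 / n2
    diff = m1 - m2
    if v1 + v2 == 0:
        if diff == 0:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, 0.0, 0.0, 0.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t = diff / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * np.sqrt(v1 + v2)
    return WelchResult(float(t), float(df), float(p), float(diff - half), float(diff + half), float(diff))


def welch_from_samples(a: np.ndarray, b: np.ndarray) -> WelchResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return welch_t(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def fold_contigs(
    contigs: list[Contig], no_lonely_pairs: bool = False
) -> list[FoldResult]:
    return [
        fold_mfe(c.seq, contig_id=c.contig_id, no_lonely_pairs=no_lonely_pairs)
        for c in contigs
    ]


def feature_table(contigs: list[Contig], folds: list[FoldResult] | None = None) -> pd.DataFrame:
    """Per-contig structural features: gc, length and (optionally) MFE."""
    rows = {
        c.contig_id: {"gc": gc_fraction(c.seq), "length": c.length}
        for c in contigs
    }
    if folds is not None:
        for f in folds:
            rows[f.contig_id]["mfe"] = f.mfe
            rows[f.contig_id]["length_corrected_mfe"] = f.length_corrected_mfe
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "contig_id"
    return df


def compare_groups(
    features: pd.DataFrame,
    ids_a: list[str],
    ids_b: list[str],
    columns: tuple[str, ...] = ("length_corrected_mfe", "gc", "length"),
    sample_n: int = SAMPLE_N,
    seed: int = 0,
) -> dict[str, dict]:
    """Welch contrasts of class A vs class B per feature.

    Classes larger than ``sample_n`` are subsampled without replacement
    (seeded).  Returns per feature the WelchResult plus group summaries.
    """
    rng = np.random.default_rng(seed)

    def sample(ids: list[str]) -> list[str]:
        if len(ids) > sample_n:
            return list(rng.choice(ids, size=sample_n, replace=False))
        return list(ids)

    sel_a, sel_b = sample(ids_a), sample(ids_b)
    if len(sel_a) < 2 or len(sel_b) < 2:
        raise ValueError("each class needs >= 2 members after sampling")
    out: dict[str, dict] = {}
    for col in columns:
        a = features.loc[sel_a, col].to_numpy(dtype=float)
        b = features.loc[sel_b, col].to_numpy(dtype=float)
        res = welch_from_samples(a, b)
        out[col] = {
            "welch": res,
            "summary_a": {"mean": float(a.mean()), "sd": float(a.std(ddof=1)), "n": len(a)},
            "summary_b": {"mean": float(b.mean()), "sd": float(b.std(ddof=1)), "n": len(b)},
        }
    return out


# ---------------------------------------------------------------------------
# qPCR validation statistics
# ---------------------------------------------------------------------------


@dataclass
class QpcrPanel:
    """Cq values per (fish, transcript) with group labels per fish.

    ``cq`` is a DataFrame indexed by fish id with one column per
    transcript, including the reference transcript; ``groups`` maps fish
    id to its group label; ``control`` names the unchallenged group.
    """

    cq: pd.DataFrame
    groups: pd.Series
    reference: str
    control: str = "control"

    def __post_init__(self) -> None:
        if self.reference not in self.cq.columns:
            raise ValueError("reference transcript missing from panel")


def dunnett_critical_value(
    k: int,
    df: int,
    n_per_group: int,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 0,
) -> float:
    """Two-sided Dunnett critical value by Monte Carlo.

    Simulates the joint null distribution of the k many-to-one t statistics
    (shared control, pooled variance with ``df`` degrees of freedom) and
    returns the 1-alpha quantile of max |t|.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k + 1)) / np.sqrt(n_per_group)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    t = (z[:, 1:] - z[:, [0]]) / (s[:, None] * np.sqrt(2.0 / n_per_group))
    return float(np.quantile(np.abs(t).max(axis=1), 1 - alpha))


def _dunnett_pvalues(
    t_obs: np.ndarray,
    k: int,
    df: int,
    ns: np.ndarray,
    n_control: int,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo adjusted p per comparison: P(max_j |T_j| >= |t_i|)."""
    rng = np.random.default_rng(seed)
    zc = rng.standard_normal(n_draws) / np.sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    tmax = np.zeros(n_draws)
    for j in range(k):
        zj = rng.standard_normal(n_draws) / np.sqrt(ns[j])
        tj = (zj - zc) / (s * np.sqrt(1.0 / ns[j] + 1.0 / n_control))
        tmax = np.maximum(tmax, np.abs(tj))
    return np.array([(np.sum(tmax >= abs(t)) + 1) / (n_draws + 1) for t in t_obs])


def qpcr_analysis(
    panel: QpcrPanel,
    n_draws: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative expression, ANOVA and Dunnett post hoc per target transcript.

    Relative quantity per fish is 2^(Cq_ref - Cq_target) (amplification
    efficiency 2.0); group comparisons run on log2 relative quantities:
    one-way ANOVA across all groups, then Dunnett's many-to-one
    comparisons against the control with Monte-Carlo adjusted p-values.
    Fish without a reference Cq are dropped with a warning.
    """
    cq = panel.cq
    missing = cq[panel.reference].isna()
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} fish without reference Cq",
            RuntimeWarning,
        )
        cq = cq[~missing]
    groups = panel.groups.loc[cq.index]
    targets = [c for c in cq.columns if c != panel.reference]
    group_names = [panel.control] + sorted(
        g for g in groups.unique() if g != panel.control
    )
    if any((groups == g).sum() < 2 for g in group_names):
        raise ValueError("each group needs >= 2 fish")

    rows = []
    rng = np.random.default_rng(seed)
    for target in targets:
        rel = 2.0 ** (cq[panel.reference] - cq[target])
        logrel = np.log2(rel)
        by_group = [logrel[groups == g].to_numpy() for g in group_names]
        f_stat, f_p = stats.f_oneway(*by_group)

        ctrl = by_group[0]
        treats = by_group[1:]
        ns = np.array([len(t) for t in treats])
        n_all = sum(len(g) for g in by_group)
        df = n_all - len(by_group)
        pooled = np.sqrt(
            sum(((len(g) - 1) * np.var(g, ddof=1) for g in by_group)) / df
        )
        t_obs = np.array(
            [
                (t.mean() - ctrl.mean())
                / (pooled * np.sqrt(1.0 / len(t) + 1.0 / len(ctrl)))
                if pooled > 0
                else 0.0
                for t in treats
            ]
        )
        p_adj = _dunnett_pvalues(
            t_obs, len(treats), df, ns, len(ctrl), n_draws,
            seed=int(rng.integers(2**31)),
        )
        for g, t, p, grp_vals in zip(group_names[1:], t_obs, p_adj, treats):
            rows.append(
                {
                    "transcript": target,
                    "group": g,
                    "mean_log2_rel": float(np.mean(grp_vals)),
                    "control_mean_log2_rel": float(ctrl.mean()),
                    "anova_F": float(f_stat),
                    "anova_p": float(f_p),
                    "dunnett_t": float(t),
                    "dunnett_p": float(p),
                }
            )
    return pd.DataFrame(rows)
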