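"""Pre-classification filtering of assembled contigs.

Removes, in order: contigs shorter than the length floor, redundant
contigs (greedy identity clustering at 0.9, keeping the longest contig of
each cluster as representative), and contigs whose expression never
reaches FPKM 1.50 in any sample.  An audit report conserves totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import greedy_cluster
from .synthetic import Contig

FPKM_FLOOR = 1.50
IDENTITY_THRESHOLD = 0.9
MIN_LEN = 200


@dataclass
class ExpressionProfile:
    """FPKM per sample for one contig: count * 1e9 / (length * library size)."""

    contig_id: str
    fpkm: pd.Series
    max_fpkm: float


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM matrix (contig x sample).

    Library size is each sample's total assigned counts over the contigs in
    ``counts``.
    """
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size in at least one sample")
    return pd.DataFrame(
        counts.to_numpy(dtype=float)
        * 1e9
        / (lengths.to_numpy()[:, None] * lib.to_numpy()[None, :]),
        index=counts.index,
        columns=counts.columns,
    )


def expression_profiles(
    counts: pd.DataFrame, lengths: pd.Series
) -> list[ExpressionProfile]:
    fpkm = compute_fpkm(counts, lengths)
    return [
        ExpressionProfile(cid, fpkm.loc[cid], float(fpkm.loc[cid].max()))
        for cid in fpkm.index
    ]


@dataclass
class FilterAudit:
    input: int
    removed_short: int
    removed_redundant: int
    removed_low_expression: int
    kept: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    membership: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "removed_short": self.removed_short,
            "removed_redundant": self.removed_redundant,
            "removed_low_expression": self.removed_low_expression,
            "kept": self.kept,
        }

    def conserves(self) -> bool:
        return (
            self.input
            == self.kept
            + self.removed_short
            + self.removed_redundant
            + self.removed_low_expression
        )


def filter_assembly(
    contigs: list[Contig],
    counts: pd.DataFrame,
    identity_threshold: float = IDENTITY_THRESHOLD,
    fpkm_floor: float = FPKM_FLOOR,
    min_len: int = MIN_LEN,
) -> tuple[list[Contig], FilterAudit]:
    """Length -> redundancy -> expression filter.

    A contig survives the expression filter if its FPKM reaches the floor
    in at least one sample (the max-across-samples rule), so
    condition-specific transcripts are preserved for the DE stage.  Cluster
    member counts are not summed into representatives.
    """
    ids = {c.contig_id for c in contigs}
    missing = ids - set(counts.index)
    if missing:
        raise ValueError(f"counts missing for {len(missing)} contigs")

    long_enough = [c for c in contigs if c.length >= min_len]
    removed_short = [c.contig_id for c in contigs if c.length < min_len]

    _, membership = greedy_cluster(
        [(c.contig_id, c.seq) for c in long_enough], identity_threshold
    )
    representatives = [c for c in long_enough if membership[c.contig_id] == c.contig_id]
    removed_redundant = [
        c.contig_id for c in long_enough if membership[c.contig_id] != c.contig_id
    ]

    rep_ids = [c.contig_id for c in representatives]
    lengths = pd.Series({c.contig_id: c.length for c in representatives})
    fpkm = compute_fpkm(counts.loc[rep_ids], lengths)
    max_fpkm = fpkm.max(axis=1)
    kept = [c for c in representatives if max_fpkm[c.contig_id] >= fpkm_floor]
    removed_low = [
        c.contig_id for c in representatives if max_fpkm[c.contig_id] < fpkm_floor
    ]

    audit = FilterAudit(
        input=len(contigs),
        removed_short=len(removed_short),
        removed_redundant=len(removed_redundant),
        removed_low_expression=len(removed_low),
        kept=len(kept),
        removed_ids={
            "short": removed_short,
            "redundant": removed_redundant,
            "low_expression": removed_low,
        },
        membership=membership,
    )
    return kept, audit
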