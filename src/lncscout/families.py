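"""Position-weight-matrix models of non-coding RNA families.

These play the decision role of covariance-model family search: a known
ncRNA is a transcript that scores significantly against one of the packaged
family models.  Each model is a length-L x 4 matrix of log2 odds against a
uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
BASES = "ACGT"


@dataclass
class FamilyModel:
    family_id: str
    pwm: np.ndarray  # (L, 4) log2 odds vs background 0.25
    score_threshold: float | None = None  # None -> significance by shuffle

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("PWM must have shape (L, 4)")
        if not np.all(np.isfinite(self.pwm)):
            raise ValueError("PWM log-odds must be finite")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information (bits) of the implied probabilities."""
        p = 0.25 * 2.0**self.pwm
        p = p / p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        return 2.0 + h

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "pwm": self.pwm.tolist(),
            "score_threshold": self.score_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FamilyModel":
        return cls(
            family_id=d["family_id"],
            pwm=np.asarray(d["pwm"], dtype=float),
            score_threshold=d.get("score_threshold"),
        )


def encode(seq: str) -> np.ndarray:
    """Map a DNA/RNA string to integer codes (A=0, C=1, G=2, T/U=3)."""
    try:
        return np.fromiter(
            (BASE_INDEX[b] for b in seq.upper()), dtype=np.int8, count=len(seq)
        )
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol {exc.args[0]!r}") from exc


def pwm_scan_scores(pwm: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Log-odds score of the PWM at every window start of ``codes``.

    ``codes`` may be 1-D (one sequence) or 2-D (batch, length); a batch is
    scored in one vectorized pass.
    """
    W = pwm.shape[0]
    single = codes.ndim == 1
    if single:
        codes = codes[None, :]
    L = codes.shape[1]
    if L < W:
        out = np.full((codes.shape[0], 0), -np.inf)
        return out[0] if single else out
    nwin = L - W + 1
    scores = np.zeros((codes.shape[0], nwin))
    for w in range(W):
        scores += pwm[w][codes[:, w : w + nwin]]
    return scores[0] if single else scores


@njit(cache=True)
def _mark_exceeding(pwm, suffix_max, codes, threshold, out):  # pragma: no cover
    """Set out[b] where any window of codes[b] scores >= threshold.

    Branch-and-bound inner loop: a window is abandoned as soon as even the
    per-column maxima of the remaining PWM columns cannot lift it to the
    threshold.
    """
    B, L = codes.shape
    W = pwm.shape[0]
    nwin = L - W + 1
    for b in range(B):
        if out[b]:
            continue
        for i in range(nwin):
            s = 0.0
            for w in range(W):
                s += pwm[w, codes[b, i + w]]
                if s + suffix_max[w + 1] < threshold:
                    break
            if s >= threshold:
                out[b] = True
                break


def count_null_exceedances(
    models: list["FamilyModel"], codes_batch: np.ndarray, threshold: float
) -> int:
    """How many shuffled sequences reach ``threshold`` on any model/strand."""
    fwd = np.ascontiguousarray(codes_batch)
    rev = np.ascontiguousarray(codes_batch[:, ::-1] ^ 3)
    out = np.zeros(codes_batch.shape[0], dtype=np.bool_)
    for model in models:
        if model.length > codes_batch.shape[1]:
            continue
        suffix = np.zeros(model.length + 1)
        suffix[:-1] = np.cumsum(model.pwm.max(axis=1)[::-1])[::-1]
        for strand in (fwd, rev):
            _mark_exceeding(model.pwm, suffix, strand, threshold, out)
    return int(out.sum())
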