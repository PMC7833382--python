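"""Structural contrast of novel lncRNAs against coding transcripts.

Folds a random subsample of each class with the simplified base-pair
energy DP and compares length-corrected MFE, GC content and length by
Welch's t.  Writes distribution figures under results/figures/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from common import config_for, parse_args
from lncscout.io import read_tsv
from lncscout.pipeline import STAGES, run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = config_for(args)
    run_pipeline(cfg, stages=STAGES)
    out = Path(cfg.outdir)
    contrasts = json.loads((out / "contrasts.json").read_text())
    for feature, d in contrasts.items():
        print(
            f"{feature}: lncRNA mean {d['lnc']['mean']:.4g} vs PCT mean "
            f"{d['pct']['mean']:.4g}; Welch t = {d['t']:.2f} "
            f"(df {d['df']:.0f}, p = {d['p']:.2e})"
        )

    feats = read_tsv(out / "structure_features.tsv", index_col=0)
    classes = read_tsv(out / "classification.tsv", index_col=0)
    feats = feats.join(classes["final_class"])
    figdir = Path("results/figures")
    figdir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, col, label in zip(
        axes,
        ("length_corrected_mfe", "gc", "length"),
        ("MFE per nt (kcal/mol/nt)", "GC fraction", "length (nt)"),
    ):
        for cls, color in (("PCT", "tab:blue"), ("NOVEL_LNC", "tab:orange")):
            vals = feats.loc[feats["final_class"] == cls, col].dropna()
            ax.hist(vals, bins=30, alpha=0.6, label=cls, color=color, density=True)
        ax.set_xlabel(label)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "class_contrasts.png", dpi=150)
    print(f"Wrote {figdir / 'class_contrasts.png'}")


if __name__ == "__main__":
    main()
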