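"""Classify the filtered contigs.

Coding assessment (protein homology at E <= 1e-3 plus the hexamer/ORF
logistic score) splits coding from non-coding candidates; the decision
tree then separates known ncRNA families (PWM scan with shuffle null),
autonomous 3'UTR fragments paired to a coding partner of the same mRNA,
and novel lncRNAs.  Prints the confusion against ground truth.
"""

from pathlib import Path

import pandas as pd

from common import config_for, parse_args
from lncscout.io import read_tsv
from lncscout.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = config_for(args)
    run_pipeline(cfg, stages=("simulate", "filter", "classify"))
    out = Path(cfg.outdir)
    truth = read_tsv(out / "truth.tsv", index_col=0)
    classes = read_tsv(out / "classification.tsv", index_col=0)
    joined = truth.join(classes, how="inner")
    acc = (joined["true_class"] == joined["final_class"]).mean()
    print(f"Classified {len(joined)} contigs; {100 * acc:.1f}% received their "
          "ground-truth class.")
    print(pd.crosstab(joined["true_class"], joined["final_class"]).to_string())
    pairs = read_tsv(out / "pairs.tsv")
    print(f"{len(pairs)} autonomous-3'UTR/coding pairs share a parent mRNA.")


if __name__ == "__main__":
    main()
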