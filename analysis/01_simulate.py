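"""Generate the synthetic toxin-exposure study.

Emits the ground-truth transcriptome (protein-coding transcripts, known
ncRNA family members, autonomous-3'UTR/coding pairs, novel lncRNAs), the
reference bundle and the negative-binomial count matrix for the
2-arm x 3-day x 6-replicate design.
"""

import json
from pathlib import Path

from common import config_for, parse_args
from lncscout.io import read_tsv
from lncscout.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = config_for(args)
    manifest = run_pipeline(cfg, stages=("simulate",))
    info = manifest["stages"]["simulate"]["info"]
    truth = read_tsv(Path(cfg.outdir) / "truth.tsv", index_col=0)
    print(f"Simulated {info['n_contigs']} contigs x {info['n_samples']} samples "
          f"into {cfg.outdir} (seed {cfg.seed}).")
    print("Ground-truth class counts:")
    print(truth["true_class"].value_counts().to_string())


if __name__ == "__main__":
    main()
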