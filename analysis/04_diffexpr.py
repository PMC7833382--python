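"""Day-matched toxin-vs-vehicle differential expression.

Negative-binomial Wald tests per contig per day with median-of-ratios
size factors and trend-shrunk dispersions; calls at |log2FC| > 2 and
BH-adjusted p < 0.001.  Prints up/down counts per transcript class.
"""

import json
from pathlib import Path

from common import config_for, parse_args
from lncscout.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = config_for(args)
    run_pipeline(cfg, stages=("simulate", "filter", "classify", "de"))
    summary = json.loads((Path(cfg.outdir) / "de_summary.json").read_text())
    for day in sorted(summary, key=int):
        parts = [
            f"{cls}: {v['up']} up / {v['down']} down (of {v['n']})"
            for cls, v in sorted(summary[day].items())
            if v["up"] or v["down"]
        ]
        print(f"Day {day}: " + "; ".join(parts))


if __name__ == "__main__":
    main()
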