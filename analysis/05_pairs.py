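"""Co-expression of autonomous 3'UTRs and their coding partners.

Per-day quadrants of both-DE pairs (co-up, co-down, opposing), the
control-condition abundance ratio within each pair, and hypergeometric
term enrichment of the co-regulated categories.
"""

import json
from pathlib import Path

from common import config_for, parse_args
from lncscout.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = config_for(args)
    run_pipeline(cfg, stages=("simulate", "filter", "classify", "de", "pairs"))
    out = Path(cfg.outdir)
    quad = json.loads((out / "quadrants.json").read_text())
    for day in sorted(quad, key=int):
        rep = quad[day]
        p = rep["percentages"]
        print(
            f"Day {day}: of {sum(rep['counts'].values())} both-DE pairs "
            f"{p['both_up']:.0f}% co-up, {p['both_down']:.0f}% co-down, "
            f"{p['utr_up_pct_down'] + p['utr_down_pct_up']:.0f}% opposing "
            f"({rep['one_sided']} one-sided, {rep['non_de']} non-DE)."
        )
    ratio = json.loads((out / "control_ratio_summary.json").read_text())
    print(
        f"Control condition: 3'UTR member higher in {100 * ratio['utr_higher']:.0f}% "
        f"of pairs, coding member higher in {100 * ratio['pct_higher']:.0f}%, "
        f"no difference in {100 * ratio['no_difference']:.0f}%."
    )


if __name__ == "__main__":
    main()
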