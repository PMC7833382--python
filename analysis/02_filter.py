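"""Filter the assembly: length floor, greedy redundancy clustering at 0.9
identity, and the FPKM >= 1.50 expression floor.

Prints the removal audit; the totals always conserve the input count.
"""

from common import config_for, parse_args
from lncscout.pipeline import run_pipeline


def main() -> None:
    args = parse_args(__doc__)
    cfg = config_for(args)
    manifest = run_pipeline(cfg, stages=("simulate", "filter"))
    audit = manifest["stages"]["filter"]["info"]
    print(
        f"Filter audit: {audit['input']} in -> {audit['kept']} kept "
        f"({audit['removed_short']} short, {audit['removed_redundant']} redundant, "
        f"{audit['removed_low_expression']} low-expression)."
    )


if __name__ == "__main__":
    main()
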