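"""Shared command-line plumbing for the numbered analysis drivers.

Every driver operates on one run directory (default ``results/study``) so
the steps compose: later scripts resume from earlier artifacts.
"""

from __future__ import annotations

import argparse

from lncscout.pipeline import RunConfig


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--outdir", default="results/study")
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args()


def config_for(args: argparse.Namespace) -> RunConfig:
    return RunConfig(outdir=args.outdir, seed=args.seed)
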