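"""Shared fixtures: a full default-configuration pipeline run (session
scope, reused by acceptance and integration tests) and small simulated
datasets for unit tests."""

from __future__ import annotations

import json
import time
from pathlib import Path

import pytest

from lncscout.io import read_tsv
from lncscout.pipeline import RunConfig, run_pipeline
from lncscout.synthetic import GeneratorConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The default synthetic study (200 PCT, 50 known ncRNA, 100 pairs,
    150 novel lncRNA, seed 1) run through every pipeline stage."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(outdir=str(outdir), seed=1)
    t0 = time.monotonic()
    manifest = run_pipeline(cfg, resume=False)
    elapsed = time.monotonic() - t0
    return {
        "cfg": cfg,
        "outdir": outdir,
        "manifest": manifest,
        "elapsed": elapsed,
    }


@pytest.fixture(scope="session")
def default_truth_and_classes(default_run):
    outdir = default_run["outdir"]
    truth = read_tsv(outdir / "truth.tsv", index_col=0, keep_default_na=False)
    classes = read_tsv(outdir / "classification.tsv", index_col=0)
    return truth, classes


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully-formed synthetic dataset for unit tests."""
    cfg = GeneratorConfig(
        n_pct=60, n_known_nc=12, n_utr_pairs=20, n_novel_lnc=40, seed=7
    )
    contigs, truth, bundle = simulate_transcriptome(cfg)
    return cfg, contigs, truth, bundle
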