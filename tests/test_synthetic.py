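"""Generator tests: class composition guarantees, determinism, count-model
behavior (including the Poisson limit and effect recovery) and redundancy
injection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncscout.seqcore import find_orfs, gc_fraction, smith_waterman
from lncscout.synthetic import (
    CLASSES,
    GeneratorConfig,
    inject_redundancy,
    simulate_counts,
    simulate_transcriptome,
)


class TestSimulateTranscriptome:
    def test_empty_config_gives_empty_outputs(self):
        cfg = GeneratorConfig(n_pct=0, n_known_nc=0, n_utr_pairs=0, n_novel_lnc=0)
        contigs, truth, bundle = simulate_transcriptome(cfg)
        assert contigs == [] and truth == []
        assert bundle.proteins == [] and bundle.mrnas == []

    def test_same_seed_is_byte_identical(self, small_sim):
        cfg, contigs, _, _ = small_sim
        contigs2, _, _ = simulate_transcriptome(cfg)
        assert [(c.contig_id, c.seq) for c in contigs] == [
            (c.contig_id, c.seq) for c in contigs2
        ]

    def test_novel_lnc_gc_hits_target(self):
        cfg = GeneratorConfig(
            n_pct=0, n_known_nc=0, n_utr_pairs=0, n_novel_lnc=500,
            lnc_gc_target=0.39, seed=1,
        )
        contigs, _, _ = simulate_transcriptome(cfg)
        mean_gc = np.mean([gc_fraction(c.seq) for c in contigs])
        assert mean_gc == pytest.approx(0.39, abs=0.02)

    def test_classes_partition_contigs(self, small_sim):
        _, contigs, truth, _ = small_sim
        assert len(contigs) == len(truth)
        assert {r.contig_id for r in truth} == {c.contig_id for c in contigs}
        assert all(r.true_class in CLASSES for r in truth)

    def test_gc_and_length_contrasts(self, small_sim):
        _, contigs, truth, _ = small_sim
        by_class = {}
        truth_by_id = {r.contig_id: r for r in truth}
        for c in contigs:
            by_class.setdefault(truth_by_id[c.contig_id].true_class, []).append(c)
        gc_pct = np.mean([gc_fraction(c.seq) for c in by_class["PCT"]])
        gc_lnc = np.mean([gc_fraction(c.seq) for c in by_class["NOVEL_LNC"]])
        assert gc_pct - gc_lnc >= 0.04
        med_pct = np.median([c.length for c in by_class["PCT"]])
        med_lnc = np.median([c.length for c in by_class["NOVEL_LNC"]])
        assert med_pct > med_lnc

    def test_orf_guarantees(self, small_sim):
        cfg, contigs, truth, _ = small_sim
        truth_by_id = {r.contig_id: r for r in truth}
        for c in contigs:
            cls = truth_by_id[c.contig_id].true_class
            if cls == "PCT":
                orfs = find_orfs(c.seq, cfg.pct_orf_min, "sense")
                assert orfs and orfs[0].length >= cfg.pct_orf_min
            elif cls == "NOVEL_LNC":
                assert find_orfs(c.seq, cfg.lnc_orf_max, "sense") == []

    def test_utr_pairs_share_parent_with_exactly_one_pct(self, small_sim):
        _, _, truth, _ = small_sim
        pct_parents = [
            r.parent_mrna_id for r in truth
            if r.true_class == "PCT" and r.parent_mrna_id
        ]
        for r in truth:
            if r.true_class == "UTR3":
                assert r.parent_mrna_id is not None
                assert pct_parents.count(r.parent_mrna_id) == 1

    def test_min_len_respected(self, small_sim):
        cfg, contigs, _, _ = small_sim
        assert all(c.length >= cfg.min_len for c in contigs)

    def test_infeasible_length_config_raises(self):
        with pytest.raises(ValueError):
            GeneratorConfig(lnc_length_dist=(np.log(20.0), 0.1), min_len=200)

    def test_parent_mrna_invariants(self, small_sim):
        _, _, _, bundle = small_sim
        ann = bundle.annotations.set_index("mrna_id")
        seqs = dict(bundle.mrnas)
        for mid, row in ann.iterrows():
            s, e, L = int(row["cds_start"]), int(row["cds_end"]), int(row["length"])
            assert 1 <= s < e <= L == len(seqs[mid])
            cds = seqs[mid][s - 1 : e]
            assert cds.startswith("ATG") and len(cds) % 3 == 0
            assert cds[-3:] in ("TAA", "TAG", "TGA")

    def test_family_models_are_informative(self, small_sim):
        _, _, _, bundle = small_sim
        for fam in bundle.families:
            assert 60 <= fam.length <= 120
            assert fam.information_content().min() >= 1.0


class TestSimulateCounts:
    def _null_config(self, n=300):
        cfg = GeneratorConfig(
            n_pct=0, n_known_nc=0, n_utr_pairs=0, n_novel_lnc=n, seed=3
        )
        cfg.effects.de_fraction = 0.0
        cfg.effects.pair_de_fraction = 0.0
        return cfg

    def test_reproducible_bit_exact(self, small_sim):
        cfg, _, truth, _ = small_sim
        a = simulate_counts(truth, cfg, seed=5)
        b = simulate_counts(truth, cfg, seed=5)
        assert (a.values == b.values).all()

    def test_no_effect_means_ratio_near_one(self):
        cfg = self._null_config()
        _, truth, _ = simulate_transcriptome(cfg)
        counts = simulate_counts(truth, cfg, seed=9)
        design = cfg.design_frame()
        treated = design[design.condition == "MCLR"]["sample_id"]
        control = design[design.condition == "PBS"]["sample_id"]
        # size multipliers cancel in expectation across 18 samples per arm
        ratio = (counts[treated].mean(axis=1) + 1) / (counts[control].mean(axis=1) + 1)
        log2r = np.log2(ratio)
        assert np.mean(np.abs(log2r) < 1.0) >= 0.95

    def test_poisson_limit(self):
        cfg = self._null_config(n=200)
        cfg.nb_dispersion = 0.0
        cfg.base_mean_dist = (np.log(1000.0), 0.0)
        _, truth, _ = simulate_transcriptome(cfg)
        counts = simulate_counts(truth, cfg, seed=2)
        # divide out the per-sample size multipliers (estimated from column
        # means over 200 constant-mean contigs, so nearly noiseless)
        scale = counts.mean(axis=0)
        q = counts / scale * scale.mean()
        vm = q.var(axis=1, ddof=1) / q.mean(axis=1)
        assert np.median(vm) == pytest.approx(1.0, abs=0.25)

    def test_spiked_effect_recovered(self):
        cfg = GeneratorConfig(
            n_pct=0, n_known_nc=0, n_utr_pairs=0, n_novel_lnc=150,
            nb_dispersion=0.05, base_mean_dist=(np.log(300.0), 0.3), seed=4,
        )
        cfg.effects.de_fraction = 0.0
        _, truth, _ = simulate_transcriptome(cfg)
        spiked = [r.contig_id for r in truth[:75]]
        for r in truth[:75]:
            r.log2fc = {1: 3.0, 6: 0.0, 9: 0.0}
        counts = simulate_counts(truth, cfg, seed=8)
        design = cfg.design_frame()
        t = design[(design.day == 1) & (design.condition == "MCLR")]["sample_id"]
        c = design[(design.day == 1) & (design.condition == "PBS")]["sample_id"]
        # divide out the per-sample size multipliers, estimated from the
        # unspiked half of the transcriptome
        scale = counts.iloc[75:].mean(axis=0)
        norm = counts / scale
        log2r = np.log2(norm[t].mean(axis=1) / norm[c].mean(axis=1))
        mu = pd.Series({r.contig_id: r.base_mean for r in truth})
        sel = [cid for cid in spiked if mu[cid] >= 100]
        ok = np.abs(log2r[sel] - 3.0) <= 0.5
        assert ok.mean() >= 0.9

    def test_negative_base_mean_raises(self, small_sim):
        cfg, _, truth, _ = small_sim
        truth[0].base_mean = -1.0
        with pytest.raises(ValueError):
            simulate_counts(truth, cfg)
        truth[0].base_mean = 1.0


class TestInjectRedundancy:
    def test_rate_zero_is_identity(self, small_sim):
        _, contigs, truth, _ = small_sim
        out, out_truth = inject_redundancy(contigs, 0.0, truth=truth)
        assert out == contigs and len(out_truth) == len(truth)

    def test_identity_one_gives_exact_copies(self, small_sim):
        _, contigs, _, _ = small_sim
        out, _ = inject_redundancy(contigs, 0.1, identity_level=1.0, seed=3)
        by_id = {c.contig_id: c.seq for c in contigs}
        dups = out[len(contigs):]
        assert len(dups) == int(np.ceil(0.1 * len(contigs)))
        for d in dups:
            donor_id = d.contig_id.rsplit("_dup", 1)[0]
            assert d.seq == by_id[donor_id]

    def test_duplicates_align_above_093(self, small_sim):
        _, contigs, truth, _ = small_sim
        subset = contigs[:100]
        out, out_truth = inject_redundancy(
            subset, 0.1, identity_level=0.95, seed=5, truth=truth[:100]
        )
        dups = out[100:]
        assert len(dups) == 10
        by_id = {c.contig_id: c.seq for c in subset}
        for d, rec in zip(dups, out_truth[100:]):
            assert rec.duplicate_of is not None
            aln = smith_waterman(d.seq, by_id[rec.duplicate_of])
            assert aln.n_matches / min(d.length, len(by_id[rec.duplicate_of])) >= 0.93
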