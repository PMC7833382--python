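"""Decision-tree tests: family scanning with shuffle nulls, mRNA mapping
fractions, 3'UTR/PCT pairing rules and the full classification order."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncscout.classify import (
    UtrMapping,
    classify_transcripts,
    family_scan,
    map_to_mrna,
    pair_utr_with_pct,
)
from lncscout.coding import CodingVerdict
from lncscout.families import FamilyModel
from lncscout.seqcore import reverse_complement
from lncscout.synthetic import (
    Contig,
    GeneratorConfig,
    ReferenceBundle,
    simulate_transcriptome,
)


def _model(rng, L=80, fid="FAM"):
    consensus = rng.integers(0, 4, size=L)
    p = np.full((L, 4), 0.05)
    p[np.arange(L), consensus] = 0.85
    return FamilyModel(fid, np.log2(p / 0.25))


def _random_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class TestFamilyScan:
    def test_consensus_hits_with_minimal_p(self):
        rng = np.random.default_rng(0)
        model = _model(rng)
        hit = family_scan(model.consensus, [model], n_shuffles=1000, seed=1)
        assert hit is not None
        assert hit.pvalue == pytest.approx(1 / 1001)

    def test_reverse_complement_consensus_also_hits(self):
        rng = np.random.default_rng(0)
        model = _model(rng)
        hit = family_scan(
            reverse_complement(model.consensus), [model], n_shuffles=1000, seed=1
        )
        assert hit is not None and hit.strand == "-"

    def test_random_contig_rarely_hits(self):
        rng = np.random.default_rng(5)
        model = _model(rng, fid="OTHER")
        misses = 0
        for trial in range(20):
            seq = _random_seq(rng, 500)
            if family_scan(seq, [model], n_shuffles=1000, seed=trial) is None:
                misses += 1
        assert misses >= 19  # >= 99% expected; allow one fluke in 20

    def test_contig_shorter_than_pwm_is_no_hit(self):
        rng = np.random.default_rng(2)
        model = _model(rng, L=100)
        assert family_scan("ACGT" * 10, [model], n_shuffles=100) is None


@pytest.fixture(scope="module")
def paired_bundle():
    cfg = GeneratorConfig(
        n_pct=0, n_known_nc=0, n_utr_pairs=8, n_novel_lnc=0, seed=11
    )
    contigs, truth, bundle = simulate_transcriptome(cfg)
    return cfg, contigs, truth, bundle


class TestMapToMrna:
    def test_planted_utr_fragment_maps_cleanly(self, paired_bundle):
        _, contigs, truth, bundle = paired_bundle
        utr = next(
            c for c, r in zip(contigs, truth) if r.true_class == "UTR3"
        )
        m = map_to_mrna(utr.contig_id, utr.seq, bundle)
        assert m is not None
        assert m.f_utr3 == pytest.approx(1.0)
        assert m.is_utr3 and not m.overlaps_cds

    def test_cds_fragment_overlaps_cds(self, paired_bundle):
        _, _, _, bundle = paired_bundle
        mid, mseq = bundle.mrnas[0]
        cs, ce, _ = bundle.mrna_annotation(mid)
        frag = mseq[cs + 20 : ce - 21]  # strictly inside the CDS
        m = map_to_mrna("frag", frag, bundle)
        assert m is not None and m.mrna_id == mid
        assert m.f_cds == pytest.approx(1.0)
        assert m.overlaps_cds and not m.is_utr3

    def test_junction_spanner_is_not_utr3(self, paired_bundle):
        _, _, _, bundle = paired_bundle
        mid, mseq = bundle.mrnas[0]
        _, ce, length = bundle.mrna_annotation(mid)
        half = 120
        frag = mseq[ce - half : ce + half]  # 50/50 across the stop junction
        m = map_to_mrna("junction", frag, bundle)
        assert m is not None
        assert m.f_utr3 == pytest.approx(0.5, abs=0.05)
        assert not m.is_utr3

    def test_unrelated_sequence_has_no_hit(self, paired_bundle):
        _, _, _, bundle = paired_bundle
        rng = np.random.default_rng(3)
        assert map_to_mrna("x", _random_seq(rng, 400), bundle) is None


def _mapping(cid, mid, f_utr3=1.0, f_cds=0.0, ev=1e-20):
    return UtrMapping(cid, mid, 1, 100, f_utr3, f_cds, ev)


class TestPairing:
    def test_one_pair_per_parent(self):
        pairs, unpaired = pair_utr_with_pct(
            [_mapping("u1", "m1")], {"p1": ("m1", 1e-30)}
        )
        assert len(pairs) == 1 and not unpaired
        assert (pairs[0].utr_contig, pairs[0].pct_contig) == ("u1", "p1")

    def test_orphan_utr_is_unpaired(self):
        pairs, unpaired = pair_utr_with_pct(
            [_mapping("u1", "m1")], {"p1": ("m2", 1e-30)}
        )
        assert not pairs and unpaired == ["u1"]

    def test_two_utrs_share_one_pct(self):
        pairs, _ = pair_utr_with_pct(
            [_mapping("u1", "m1"), _mapping("u2", "m1")], {"p1": ("m1", 1e-30)}
        )
        assert len(pairs) == 2
        assert {p.pct_contig for p in pairs} == {"p1"}

    def test_best_evalue_pct_wins(self):
        pairs, _ = pair_utr_with_pct(
            [_mapping("u1", "m1")],
            {"pA": ("m1", 1e-10), "pB": ("m1", 1e-40)},
        )
        assert pairs[0].pct_contig == "pB"


def _verdict(cid, label="NCT_CANDIDATE", score=-5.0):
    return CodingVerdict(cid, label, None, None, score, np.zeros(3))


class TestClassifyTranscripts:
    def test_empty_candidates(self, paired_bundle):
        _, _, _, bundle = paired_bundle
        out, pairs = classify_transcripts([], [], bundle)
        assert out == [] and pairs == []

    def test_family_step_precedes_mrna_step(self, paired_bundle):
        _, _, _, bundle = paired_bundle
        # a contig that is both a family consensus AND a 3'UTR fragment
        mid, mseq = bundle.mrnas[0]
        _, ce, length = bundle.mrna_annotation(mid)
        utr_frag = mseq[ce : ce + 210]
        fam = FamilyModel("FAMX", np.log2(np.where(np.eye(4)[  # consensus = frag
            [("ACGT".index(b)) for b in utr_frag[:80]]
        ] > 0, 0.85, 0.05) / 0.25))
        bundle2 = ReferenceBundle(
            proteins=bundle.proteins,
            mrnas=bundle.mrnas,
            annotations=bundle.annotations,
            protein_to_mrna=bundle.protein_to_mrna,
            families=[fam],
            term_map=bundle.term_map,
        )
        contig = Contig("dual", utr_frag)
        out, _ = classify_transcripts(
            [contig], [_verdict("dual")], bundle2, seed=4
        )
        assert out[0].final_class == "KNOWN_NC"

    def test_short_contig_discarded(self, paired_bundle):
        _, _, _, bundle = paired_bundle
        out, _ = classify_transcripts(
            [Contig("tiny", "ACGT" * 30)], [_verdict("tiny")], bundle
        )
        assert out[0].final_class == "DISCARDED" and out[0].reason == "short"

    def test_coding_leak_discarded(self, paired_bundle):
        _, _, _, bundle = paired_bundle
        rng = np.random.default_rng(8)
        seq = _random_seq(rng, 400)
        out, _ = classify_transcripts(
            [Contig("leaky", seq)], [_verdict("leaky", score=2.0)], bundle, seed=1
        )
        assert out[0].final_class == "DISCARDED"
        assert out[0].reason == "coding_leak"

    def test_order_invariance_and_partition(self, paired_bundle):
        _, contigs, truth, bundle = paired_bundle
        cands = [c for c, r in zip(contigs, truth) if r.true_class == "UTR3"]
        rng = np.random.default_rng(1)
        extra = [Contig(f"rnd{i}", _random_seq(rng, 300)) for i in range(4)]
        cands = cands + extra
        verdicts = [_verdict(c.contig_id) for c in cands]
        # pairing partners come from the coding side's verdicts
        pct_verdicts = []
        for c, r in zip(contigs, truth):
            if r.true_class == "PCT":
                from lncscout.seqcore import LocalAlignment

                hit = LocalAlignment(
                    score=100, bit_score=50, evalue=1e-30, identity=1.0,
                    query_start=1, query_end=10, subject_start=1, subject_end=10,
                    subject_id=f"prot_{r.parent_mrna_id}",
                )
                pct_verdicts.append(
                    CodingVerdict(c.contig_id, "PCT", hit, None, 5.0, np.zeros(3))
                )
        out1, pairs1 = classify_transcripts(
            cands, verdicts + pct_verdicts, bundle, seed=2
        )
        out2, pairs2 = classify_transcripts(
            cands[::-1], verdicts + pct_verdicts, bundle, seed=2
        )
        assert len(out1) == len(cands)  # partition: one class per contig
        by_id1 = {o.contig_id: o.final_class for o in out1}
        by_id2 = {o.contig_id: o.final_class for o in out2}
        assert by_id1 == by_id2
        assert len(pairs1) == len(pairs2) == 8
        for o in out1:
            if o.contig_id.startswith("UTR"):
                assert o.final_class == "UTR3"
            if o.contig_id.startswith("rnd"):
                assert o.final_class == "NOVEL_LNC"
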