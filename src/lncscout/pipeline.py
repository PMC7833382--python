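"""Staged, resumable orchestration of the full synthetic-study pipeline.

Stages run in discovery-workflow order: simulate -> filter -> classify ->
de -> pairs -> structure.  Each stage reads its inputs from the output
directory, writes plain-text artifacts plus checksums, and is skipped on
resume when its outputs already exist and no upstream stage re-ran.  A
manifest records configuration hash, seeds, per-stage counts and
checksums; two runs with the same config produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly_filter, classify, coding, diffexpr, pairs as pairmod, structure
from .families import FamilyModel
from .io import read_fasta, read_json, read_tsv, write_fasta, write_json, write_tsv
from .synthetic import (
    CONTROL,
    Contig,
    GeneratorConfig,
    ReferenceBundle,
    TruthRecord,
    simulate_counts,
    simulate_transcriptome,
)

STAGES = ("simulate", "filter", "classify", "de", "pairs", "structure")

STAGE_OUTPUTS = {
    "simulate": [
        "contigs.fasta",
        "truth.tsv",
        "counts.tsv",
        "design.tsv",
        "proteins.fasta",
        "mrna.fasta",
        "mrna_annotation.tsv",
        "families.json",
        "terms.tsv",
    ],
    "filter": ["kept.fasta", "filter_audit.json"],
    "classify": ["coding_verdicts.tsv", "classification.tsv", "pairs.tsv"],
    "de": ["de_results.tsv", "de_summary.json"],
    "pairs": ["quadrants.json", "control_ratio.tsv", "control_ratio_summary.json", "enrichment.tsv"],
    "structure": ["structure_features.tsv", "contrasts.json"],
}


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    identity_threshold: float = 0.9
    fpkm_floor: float = 1.50
    evalue_cut: float = 1e-3
    min_len: int = 200
    lfc_threshold: float = 2.0
    padj_threshold: float = 0.001
    enrichment_alpha: float = 0.05
    family_shuffles: int = 1000
    family_p_cut: float = 0.001
    # contigs folded per class in the structure stage (classes are randomly
    # subsampled, mirroring the contrast against a random selection of PCTs)
    structure_sample_per_class: int = 200
    seed: int = 1
    outdir: str = "runs/default"

    def __post_init__(self) -> None:
        for name in (
            "identity_threshold",
            "fpkm_floor",
            "evalue_cut",
            "min_len",
            "lfc_threshold",
            "padj_threshold",
            "enrichment_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# artifact (de)serialization helpers
# ---------------------------------------------------------------------------


def _truth_frame(truth: list[TruthRecord], days) -> pd.DataFrame:
    rows = []
    for r in truth:
        row = {
            "contig_id": r.contig_id,
            "true_class": r.true_class,
            "parent_mrna_id": r.parent_mrna_id or "",
            "base_mean": r.base_mean,
            "duplicate_of": r.duplicate_of or "",
        }
        for d in days:
            row[f"log2fc_d{d}"] = r.log2fc.get(d, 0.0)
            row[f"quadrant_d{d}"] = r.quadrant.get(d) or ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("contig_id")


def read_truth(path: Path, days) -> list[TruthRecord]:
    df = read_tsv(path, index_col=0, keep_default_na=False)
    out = []
    for cid, row in df.iterrows():
        out.append(
            TruthRecord(
                contig_id=cid,
                true_class=row["true_class"],
                parent_mrna_id=row["parent_mrna_id"] or None,
                base_mean=float(row["base_mean"]),
                duplicate_of=row["duplicate_of"] or None,
                log2fc={d: float(row[f"log2fc_d{d}"]) for d in days},
                quadrant={d: (row[f"quadrant_d{d}"] or None) for d in days},
            )
        )
    return out


def load_bundle(outdir: Path) -> ReferenceBundle:
    return ReferenceBundle(
        proteins=read_fasta(outdir / "proteins.fasta"),
        mrnas=read_fasta(outdir / "mrna.fasta"),
        annotations=read_tsv(outdir / "mrna_annotation.tsv"),
        protein_to_mrna=read_json(outdir / "families.json")["protein_to_mrna"],
        families=[
            FamilyModel.from_dict(d)
            for d in read_json(outdir / "families.json")["families"]
        ],
        term_map=read_tsv(outdir / "terms.tsv"),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
    contigs, truth, bundle = simulate_transcriptome(gen)
    counts = simulate_counts(truth, gen, seed=cfg.seed + 1)
    design = gen.design_frame()

    write_fasta(outdir / "contigs.fasta", [(c.contig_id, c.seq) for c in contigs])
    write_tsv(_truth_frame(truth, gen.days), outdir / "truth.tsv")
    write_tsv(counts, outdir / "counts.tsv")
    write_tsv(design, outdir / "design.tsv", index=False)
    write_fasta(outdir / "proteins.fasta", bundle.proteins)
    write_fasta(outdir / "mrna.fasta", bundle.mrnas)
    write_tsv(bundle.annotations, outdir / "mrna_annotation.tsv", index=False)
    write_json(
        {
            "families": [f.to_dict() for f in bundle.families],
            "protein_to_mrna": bundle.protein_to_mrna,
        },
        outdir / "families.json",
    )
    write_tsv(bundle.term_map, outdir / "terms.tsv", index=False)
    return {"n_contigs": len(contigs), "n_samples": counts.shape[1]}


def stage_filter(cfg: RunConfig, outdir: Path) -> dict:
    contigs = [Contig(cid, seq) for cid, seq in read_fasta(outdir / "contigs.fasta")]
    counts = read_tsv(outdir / "counts.tsv", index_col=0)
    kept, audit = assembly_filter.filter_assembly(
        contigs,
        counts,
        identity_threshold=cfg.identity_threshold,
        fpkm_floor=cfg.fpkm_floor,
        min_len=cfg.min_len,
    )
    if not audit.conserves():
        raise StageError("filter", "conservation", "audit does not conserve totals")
    write_fasta(outdir / "kept.fasta", [(c.contig_id, c.seq) for c in kept])
    write_json(audit.to_dict(), outdir / "filter_audit.json")
    return audit.to_dict()


def train_model_from_bundle(
    bundle: ReferenceBundle, seed: int
) -> coding.CodingModel:
    """Coding model trained on reference CDSs vs composition-matched nulls.

    The noncoding class combines mononucleotide-shuffled CDS copies (same
    composition, codon structure destroyed) with random sequences of varied
    GC, so the logistic cannot lean on hexamer usage alone for sequences
    that carry no ORF.
    """
    ann = bundle.annotations.set_index("mrna_id")
    mrna_seqs = dict(bundle.mrnas)
    cds = [
        mrna_seqs[mid][int(row["cds_start"]) - 1 : int(row["cds_end"])]
        for mid, row in ann.iterrows()
    ]
    rng = np.random.default_rng(seed)
    noncoding = [s for seq in cds for s in coding.shuffled_copies(seq, 1, rng)]
    bases = np.array(list("ACGT"))
    for _ in range(max(len(cds) // 2, 50)):
        gc = rng.uniform(0.25, 0.60)
        L = int(rng.integers(200, 1000))
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        noncoding.append("".join(bases[rng.choice(4, size=L, p=p)]))
    return coding.train_coding_model(cds, noncoding)


def stage_classify(cfg: RunConfig, outdir: Path) -> dict:
    kept = [Contig(cid, seq) for cid, seq in read_fasta(outdir / "kept.fasta")]
    bundle = load_bundle(outdir)
    model = train_model_from_bundle(bundle, seed=cfg.seed + 11)

    ref_kmers = coding.build_ref_kmers(bundle.proteins)
    verdicts = [
        coding.assess_coding(
            c.contig_id, c.seq, bundle.proteins, model,
            evalue_cut=cfg.evalue_cut, seed=cfg.seed + 13, ref_kmers=ref_kmers,
        )
        for c in kept
    ]
    vframe = pd.DataFrame(
        {
            "contig_id": [v.contig_id for v in verdicts],
            "label": [v.label for v in verdicts],
            "coding_score": [v.coding_score for v in verdicts],
            "best_hit_id": [
                v.best_hit.subject_id if v.best_hit else "" for v in verdicts
            ],
            "best_hit_evalue": [
                v.best_hit.evalue if v.best_hit else np.nan for v in verdicts
            ],
        }
    ).set_index("contig_id")
    write_tsv(vframe, outdir / "coding_verdicts.tsv")

    candidates = [c for c, v in zip(kept, verdicts) if not v.is_coding]
    classified, found_pairs = classify.classify_transcripts(
        candidates,
        verdicts,
        bundle,
        min_len=cfg.min_len,
        e_cut=cfg.evalue_cut,
        n_shuffles=cfg.family_shuffles,
        p_cut=cfg.family_p_cut,
        seed=cfg.seed + 17,
    )
    rows = []
    for c, v in zip(kept, verdicts):
        if v.is_coding:
            rows.append(
                {"contig_id": c.contig_id, "final_class": "PCT", "reason": "coding"}
            )
    for ct in classified:
        rows.append(
            {
                "contig_id": ct.contig_id,
                "final_class": ct.final_class,
                "reason": ct.reason,
            }
        )
    cframe = pd.DataFrame(rows).set_index("contig_id")
    if len(cframe) != len(kept):
        raise StageError("classify", "conservation", "classes do not partition input")
    write_tsv(cframe, outdir / "classification.tsv")
    write_tsv(
        pd.DataFrame(
            [
                {
                    "utr_contig": p.utr_contig,
                    "pct_contig": p.pct_contig,
                    "mrna_id": p.mrna_id,
                }
                for p in found_pairs
            ],
            columns=["utr_contig", "pct_contig", "mrna_id"],
        ),
        outdir / "pairs.tsv",
        index=False,
    )
    return {
        "n_candidates": len(candidates),
        "n_pairs": len(found_pairs),
        "classes": cframe["final_class"].value_counts().to_dict(),
    }


def stage_de(cfg: RunConfig, outdir: Path) -> dict:
    counts = read_tsv(outdir / "counts.tsv", index_col=0)
    design = read_tsv(outdir / "design.tsv")
    classes = read_tsv(outdir / "classification.tsv", index_col=0)
    kept_ids = classes.index.tolist()
    per_day = diffexpr.run_per_day(counts.loc[kept_ids], design)

    frames = []
    for day, res in per_day.items():
        res = diffexpr.call_de(res, cfg.lfc_threshold, cfg.padj_threshold)
        res = res.join(classes["final_class"])
        frames.append(res)
    table = pd.concat(frames)
    write_tsv(table, outdir / "de_results.tsv")

    summary: dict = {}
    for day, res in table.groupby("day"):
        by_class = {}
        for cls, sub in res.groupby("final_class"):
            de = sub[sub["is_de"]]
            by_class[cls] = {
                "up": int((de["log2FoldChange"] > 0).sum()),
                "down": int((de["log2FoldChange"] < 0).sum()),
                "n": int(len(sub)),
            }
        summary[str(day)] = by_class
    write_json(summary, outdir / "de_summary.json")
    return {"days": list(summary)}


def stage_pairs(cfg: RunConfig, outdir: Path) -> dict:
    counts = read_tsv(outdir / "counts.tsv", index_col=0)
    design = read_tsv(outdir / "design.tsv")
    de_table = read_tsv(outdir / "de_results.tsv", index_col=0)
    pair_table = read_tsv(outdir / "pairs.tsv")
    bundle = load_bundle(outdir)
    found_pairs = [
        classify.UtrPctPair(r["utr_contig"], r["pct_contig"], r["mrna_id"])
        for _, r in pair_table.iterrows()
    ]

    quadrants = {}
    for day in sorted(design["day"].unique()):
        sub = de_table[de_table["day"] == day]
        report = pairmod.quadrant_classify(found_pairs, sub, sub, int(day))
        quadrants[str(int(day))] = {
            "counts": report.counts,
            "percentages": report.percentages,
            "one_sided": report.one_sided,
            "non_de": report.non_de,
            "total_pairs": report.total_pairs,
        }
    write_json(quadrants, outdir / "quadrants.json")

    sf = diffexpr.size_factors(counts)
    controls = design[design["condition"] == CONTROL]["sample_id"].tolist()
    ratio_table, ratio_summary = pairmod.control_ratio_analysis(
        found_pairs, counts, sf, controls
    )
    write_tsv(ratio_table, outdir / "control_ratio.tsv", index=False)
    write_json(ratio_summary, outdir / "control_ratio_summary.json")

    # enrichment of both-up pairs (per day) against all paired mRNAs
    background = sorted({p.mrna_id for p in found_pairs})
    enrich_rows = []
    for day in sorted(design["day"].unique()):
        sub = de_table[de_table["day"] == day]
        for quadrant_filter, name in (
            ((1, 1), "both_up"),
            ((-1, -1), "both_down"),
        ):
            selected = []
            for p in found_pairs:
                u, c = sub.loc[p.utr_contig], sub.loc[p.pct_contig]
                if bool(u["is_de"]) and bool(c["is_de"]):
                    if (
                        np.sign(u["log2FoldChange"]) == quadrant_filter[0]
                        and np.sign(c["log2FoldChange"]) == quadrant_filter[1]
                    ):
                        selected.append(p.mrna_id)
            if not selected:
                continue
            for r in pairmod.term_enrichment(
                sorted(set(selected)), background, bundle.term_map,
                alpha=cfg.enrichment_alpha,
            ):
                enrich_rows.append(
                    {
                        "day": int(day),
                        "category": name,
                        "term": r.term,
                        "k": r.k,
                        "n": r.n,
                        "K": r.K,
                        "N": r.N,
                        "p_enrich": r.p_enrich,
                        "p_deplete": r.p_deplete,
                    }
                )
    write_tsv(
        pd.DataFrame(
            enrich_rows,
            columns=["day", "category", "term", "k", "n", "K", "N", "p_enrich", "p_deplete"],
        ),
        outdir / "enrichment.tsv",
        index=False,
    )
    return {"n_pairs": len(found_pairs), "ratio_summary": ratio_summary}


def stage_structure(cfg: RunConfig, outdir: Path) -> dict:
    kept = {cid: seq for cid, seq in read_fasta(outdir / "kept.fasta")}
    classes = read_tsv(outdir / "classification.tsv", index_col=0)
    pct_ids = classes[classes["final_class"] == "PCT"].index.tolist()
    lnc_ids = classes[classes["final_class"] == "NOVEL_LNC"].index.tolist()
    rng = np.random.default_rng(cfg.seed + 19)
    cap = cfg.structure_sample_per_class
    pct_ids = sorted(
        rng.choice(pct_ids, cap, replace=False) if len(pct_ids) > cap else pct_ids
    )
    lnc_ids = sorted(
        rng.choice(lnc_ids, cap, replace=False) if len(lnc_ids) > cap else lnc_ids
    )
    contigs = [Contig(cid, kept[cid]) for cid in pct_ids + lnc_ids]
    folds = structure.fold_contigs(contigs)
    feats = structure.feature_table(contigs, folds)
    write_tsv(feats, outdir / "structure_features.tsv")

    contrasts = structure.compare_groups(
        feats, lnc_ids, pct_ids, seed=cfg.seed + 23
    )
    out = {}
    for col, d in contrasts.items():
        w = d["welch"]
        out[col] = {
            "t": w.t,
            "df": w.df,
            "p": w.pvalue,
            "ci": [w.ci_low, w.ci_high],
            "lnc": d["summary_a"],
            "pct": d["summary_b"],
        }
    write_json(out, outdir / "contrasts.json")
    return {k: v["t"] for k, v in out.items()}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "classify": stage_classify,
    "de": stage_de,
    "pairs": stage_pairs,
    "structure": stage_structure,
}


def run_pipeline(
    cfg: RunConfig,
    stages: tuple[str, ...] = STAGES,
    resume: bool = True,
) -> dict:
    """Run the pipeline, skipping up-to-date stages on resume.

    A stage is re-run when any of its outputs is missing, the recorded
    config hash changed, or an upstream stage re-ran.  Returns the
    manifest (also written to ``manifest.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    chash = cfg.config_hash()
    if manifest.get("config_hash") != chash:
        manifest = {"config_hash": chash, "seed": cfg.seed, "stages": {}}
    upstream_reran = False
    for stage in STAGES:
        if stage not in stages:
            continue
        outputs = [outdir / f for f in STAGE_OUTPUTS[stage]]
        up_to_date = (
            resume
            and not upstream_reran
            and stage in manifest["stages"]
            and all(o.exists() for o in outputs)
        )
        if up_to_date:
            continue
        t0 = time.time()
        try:
            info = _STAGE_FUNCS[stage](cfg, outdir)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, "failure", str(exc)) from exc
        manifest["stages"][stage] = {
            "info": info,
            "elapsed_s": round(time.time() - t0, 2),
            "outputs": {f: _sha256(outdir / f) for f in STAGE_OUTPUTS[stage]},
        }
        upstream_reran = True
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
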