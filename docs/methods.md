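# Methods

`lncscout` is a desk-scale reconstruction of a de novo non-coding-RNA
discovery study: a hepatotoxin-exposure RNA-seq design (vehicle vs toxin
arms at days 1, 6 and 9, six fish per arm) analysed from assembled contigs
and a count matrix, with every external tool of such a pipeline (CD-HIT,
BLAST, TransDecoder, CPC, Infernal, DESeq2, RNAfold) replaced by a
self-contained, testable implementation of the same decision role.
Because the original sequencing data are not reproducible at desk scale,
the package pairs the pipeline with a synthetic generator that emits
ground-truth-labelled transcriptomes, so every stage can be scored against
known classes and effects.

## The synthetic study

`synthetic.simulate_transcriptome` emits four contig classes:

* **PCT** — protein-coding transcripts carrying one complete ORF
  (ATG…stop, ≥ 300 nt, configurable) between scrubbed UTRs, GC target
  0.460;
* **KNOWN_NC** — noisy emissions of packaged ncRNA family PWMs (5 families,
  lengths 60–120 nt, information content ≥ 1 bit/column) inside AT-richer
  flanks;
* **UTR3 / paired PCT** — two contigs cut from one parent mRNA: a coding
  fragment covering the full CDS (never entering the 3'UTR) and a fragment
  lying entirely inside the 3'UTR. This is deliberately the clean case;
  junction-spanning fragments appear only in tests that construct them;
* **NOVEL_LNC** — random sequence at GC 0.393, log-normal lengths
  (median 450 nt vs 900 nt for PCTs), rejection-scrubbed of any complete
  sense ORF ≥ 150 nt.

GC targets (0.460 vs 0.393) and the shorter-lncRNA length contrast encode
the class differences the discovery methodology is meant to recover.
Non-CDS regions are scrubbed of ORFs ≥ 150 nt by planting in-frame stops,
so class membership is unambiguous by construction.

Counts are negative binomial, `K_ij ~ NB(mean = s_j · µ_i · 2^lfc,
var = µ + αµ²)` with a single dispersion α (default 0.1) per run,
log-normal base means (median 100) and per-sample size multipliers
log-uniform in [0.7, 1.4]. Effects are assigned per day: non-pair contigs
are affected with probability 0.35 with day patterns that make days 6 and
9 resemble each other more than day 1; each 3'UTR/coding pair draws a
per-day quadrant (co-up, co-down, or opposing) from per-day proportions —
day 1 dominated by co-upregulation (0.82/0.11/0.04/0.03), days 6/9
balanced with more opposing pairs. These proportions are the study
conditions, not free dials.

What the generator does **not** emulate: read-level error, isoforms,
positional coverage bias, GC-dependent library effects, partially
assembled ("junction") fragments, homology families shared between novel
lncRNAs, and genuinely continuous coding potential (pseudogenes,
short-ORF peptides). Passing tests therefore demonstrate that the
pipeline's logic recovers planted structure under its own assumptions,
not that it would reach the same accuracy on real assemblies, where the
discovery problem is much harder.

## Pipeline stages

**Filter** (`assembly_filter`): length floor 200 nt → greedy clustering
(longest-first, join the first representative with alignment identity
≥ 0.9, identity = matches / length of the shorter sequence; an 8-mer
prefilter skips hopeless comparisons) → expression floor FPKM 1.50.
"Below 1.50" is read as *below in every sample* (max-across-samples
rule), preserving condition-specific transcripts for the DE stage. The
audit report conserves totals exactly.

**Alignment kernel** (`seqcore`): local alignment with affine gaps
(nucleotide +2/−3, gap open 5 / extend 2, a gap of length L costs
5 + 2L), executed by Bio.Align.PairwiseAligner; significance by
Karlin–Altschul `E = K·m·n·exp(−λS)` with λ = 0.625, K = 0.41 for the
nucleotide scheme and BLOSUM62 with λ = 0.267, K = 0.041 for proteins,
using the whole-database length for n. Among co-optimal alignments the
smallest subject start, then query start, is reported.

**Coding assessment** (`coding`): a contig is coding iff a protein (or
domain) hit at E ≤ 1e-3 exists or a logistic coding score is positive.
The score's features are log10 best-ORF length, ORF coverage and mean
hexamer log-odds (in-frame for ORFs, all-frame otherwise; table built
with pseudocount 1). The model is trained per run on the reference CDSs
against mononucleotide-shuffled copies plus composition-varied random
sequences — the latter prevent the fit from leaning on hexamer usage
alone for ORF-less inputs (extreme-composition repeats would otherwise
leak). Separable fits are stabilized with a 1e-4 ridge; final weights
above |w| = 50 are rescaled, which leaves the score-0 boundary unchanged.
Minimum ORF is 150 nt and ORF search is sense-strand only (stranded
library), both configurable.

**Classification** (`classify`): (1) length < 200 → discarded; (2) PWM
family scan over both strands, significance by the empirical p of the
observed best score against ≤ 1000 mononucleotide shuffles scanned over
the same models and strands (minimum attainable p = 1/1001, cut 0.001) →
known ncRNA; (3) nucleotide search against the annotated mRNA reference —
a hit with ≥ 90% of aligned subject columns inside the 3'UTR is an
autonomous-3'UTR candidate and is kept only when a coding contig of the
same mRNA exists (best protein E-value wins when several claim one mRNA);
CDS-overlapping (> 10%) or partnerless or ambiguous hits are discarded
with reason codes; (4) the remainder are novel lncRNAs unless their
coding score is positive (discarded as coding leakage). The scan keeps
p ≤ 0.001 attainable only when `n_shuffles ≥ 999`; runs that lower the
shuffle count must lower `family_p_cut` with it.

**Differential expression** (`diffexpr`): median-of-ratios size factors
(geometric mean 1; total-count fallback with a warning when no contig is
all-positive); gene-wise method-of-moments dispersions on normalized
counts, shrunk on the log scale (weight 0.5) toward a robust
`a₁/µ + a₀` trend (Huber regression); per-contig NB log-link GLM
(intercept + condition, offsets ln s_j) fit by IRLS (tol 1e-8, max 100),
Wald z from expected Fisher information, two-sided normal p, BH
adjustment, calls at |log2FC| > 2 and padj < 0.001 (strict). Two
numerical notes: (i) the pooled variance is rescaled by
`dof / median(χ²_dof)` before the moments step — the robust trend and the
log-space blend both track the median of a right-skewed estimate, and
without centring it the dispersions run ~10% low at n = 6+6, drifting the
null type-I fraction above nominal; (ii) fits whose condition effect
pins at the |β| = 15 cap (an all-zero group) are reported at the cap with
their large standard error rather than flagged as failures. Contrasts
are day-matched (day-d toxin vs day-d vehicle).

**Pair analysis** (`pairs`): quadrants count both-DE pairs by fold-change
signs; percentages use both-DE pairs as the denominator, with one-sided
pairs counted separately. The control-condition ratio test reuses the NB
engine with member identity as the condition across the same control
samples (a pair-specific Wald test; dispersion = mean of the two members'
control-sample estimates), BH across pairs at 0.05. Term enrichment is
the exact hypergeometric tail (upper for enrichment, lower for
depletion), reported at raw p < 0.05 without multiplicity correction, at
the parent-mRNA level.

**Structure** (`structure`, `folding`): minimum free energy by an exact
Nussinov-style DP over pair energies GC/CG −3, AU/UA −2, GU/UG −1
kcal/mol, minimum hairpin loop 3; ties in the traceback prefer pairing
(outermost partner first) over leaving the 3' base unpaired. A flag
forbids lonely pairs by requiring each helix to be ≥ 2 pairs deep from
its outermost pair (slightly conservative relative to the usual noLP
convention). This model keeps an exhaustive-enumeration oracle feasible
and preserves the GC-dependence that drives the class contrast; its
absolute energies are *not* comparable to nearest-neighbor
(Turner-parameter) values, so only length-corrected comparisons between
classes are meaningful. Class contrasts use Welch's t (with
Welch–Satterthwaite df and t-based CIs) on per-class subsamples: the
pipeline folds up to 200 contigs per class (the contrast in the emulated
study is likewise against a random selection of coding transcripts), and
`compare_groups` caps at 4000 per class. qPCR panels are analysed as
2^(Cq_ref − Cq_target) relative quantities (efficiency 2.0 assumed),
log2-transformed, one-way ANOVA, then Dunnett many-to-one comparisons
whose adjusted p-values come from a seeded 200,000-draw Monte Carlo of
the joint null max-|t| distribution.

## Orchestration and determinism

`pipeline.run_pipeline` executes the stages in order, writes plain-text
artifacts with SHA-256 checksums into a manifest, and on resume re-runs a
stage only when an output is missing, the config hash changed, or an
upstream stage re-ran. One master seed fans out into per-stage streams
(`numpy` `default_rng` spawning inside the generator), so identical
configs reproduce byte-identical artifacts. The `lncscout` CLI exposes
one subcommand per stage plus `all`, a YAML config mirroring the run
configuration, and `--set key=value` overrides.

## Problem sizes

The default study is 200 standalone PCTs, 50 known ncRNAs, 100 pairs and
150 novel lncRNAs (600 contigs, 36 samples); DE calibration uses 2000
contigs at α = 0.2; quadrant recovery uses 200 affected pairs over a
500-contig non-DE background (median-of-ratios normalization presumes a
non-DE majority); kernel oracles use 500 sequences ≤ 10 nt (folding) and
200 pairs of 30-mers (alignment). These sizes were chosen so the full
study, test suite and acceptance script each complete in minutes on one
CPU while keeping every statistical check adequately powered.

## Known limitations

* Homology search is restricted to translated complete ORFs; a coding
  fragment without a stop codon would be judged by the score alone.
* The k-mer prefilters in clustering, protein search and mRNA mapping are
  heuristics in the same sense BLAST's word seeding is: a true hit with
  no shared k-mer would be missed (vanishingly unlikely at the identity
  levels that matter here).
* The Wald test's normal reference is mildly anticonservative at six
  replicates per arm (type-I ≈ 0.055 at nominal 0.05), as is the
  convention it reimplements.
* Single-factor contrasts only; no shrunken fold changes, likelihood-ratio
  tests, outlier handling or independent filtering.
* The spec-level invariant "rescaling one sample leaves log2FC unchanged"
  holds exactly for size factors but only to ~1% for the NB GLM, whose
  per-sample likelihood weights change with the counts.
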