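# lncscout

De novo discovery, classification and expression profiling of
polyadenylated non-coding transcripts from assembled transcriptomes —
built for the common situation in non-model organisms (here, a fish
hepatotoxicity study design) where no annotated genome exists and long
non-coding RNAs (lncRNAs) must be separated from protein-coding
transcripts (PCTs) by a sequence of filters rather than by annotation.

The package implements the full decision tree of such a study as a
self-contained, tested pipeline:

1. **Filter** the assembly: drop contigs < 200 nt, collapse redundant
   contigs by greedy clustering at 0.9 alignment identity, drop contigs
   never reaching FPKM 1.50;
2. **Split coding from non-coding**: local alignment of translated ORFs
   against reference proteins with Karlin–Altschul E-values (threshold
   1e-3), backed by a trained logistic coding-potential score over ORF
   length, ORF coverage and hexamer usage;
3. **Classify the non-coding candidates** into three non-overlapping
   groups: known ncRNA families (PWM scan with a mononucleotide-shuffle
   null), autonomous 3'UTR fragments paired with the coding transcript of
   the same parent mRNA, and novel lncRNAs;
4. **Differential expression** per exposure day (toxin vs vehicle, n = 6
   per arm) with a compact negative-binomial Wald engine — median-of-ratios
   size factors, trend-shrunk dispersions, calls at |log2FC| > 2 and
   Benjamini–Hochberg adjusted p < 0.001;
5. **Pair co-expression analysis**: per-day quadrants of 3'UTR/PCT pairs
   (both up, both down, opposing), control-condition abundance ratios
   within pairs, hypergeometric term enrichment;
6. **Structural contrasts**: minimum free energy by an exact
   base-pair-energy DP, with Welch's t on length-corrected MFE, GC and
   length between classes, plus qPCR ANOVA/Dunnett statistics.

Because such studies hinge on sequencing data that cannot be shipped, the
package includes a first-class synthetic generator
(`lncscout.synthetic`) that emits ground-truth-labelled contigs,
reference bundles and NB count matrices emulating the study design —
every stage is scored against known classes and planted effects.

## Worked example

Run the whole synthetic study (about four minutes on one CPU):

```bash
lncscout all -o results/study --seed 1
```

or step through it with the numbered drivers:

```bash
cd analysis
python 01_simulate.py   # 600 contigs x 36 samples, truth labels
python 03_classify.py   # coding split + decision tree
python 05_pairs.py      # 3'UTR/PCT quadrants and control ratios
```

`03_classify.py` prints the confusion against ground truth:

```
Classified 600 contigs; 99.8% received their ground-truth class.
final_class  DISCARDED  KNOWN_NC  NOVEL_LNC  PCT  UTR3
true_class
KNOWN_NC             0        50          0    0     0
NOVEL_LNC            0         0        150    0     0
PCT                  1         0          0  299     0
UTR3                 0         0          0    0   100
100 autonomous-3'UTR/coding pairs share a parent mRNA.
```

and `05_pairs.py` the co-expression quadrants — day 1 dominated by
co-upregulated pairs, days 6/9 balanced, exactly the regime the generator
plants:

```
Day 1: of 54 both-DE pairs 85% co-up, 13% co-down, 2% opposing (0 one-sided, 46 non-DE).
Day 6: of 70 both-DE pairs 34% co-up, 44% co-down, 21% opposing (0 one-sided, 30 non-DE).
Control condition: 3'UTR member higher in 32% of pairs, coding member higher in 54%, ...
```

`06_structure.py` reports the structural contrasts (novel lncRNAs have
higher length-corrected MFE, lower GC, shorter lengths than PCTs):

```
gc:     lncRNA mean 0.392 vs PCT mean 0.46;  Welch t = -24.18 (p = 4e-64)
length: lncRNA mean 539.7 vs PCT mean 828.6; Welch t = -9.92  (p = 1e-20)
length_corrected_mfe: lncRNA mean -0.884 vs PCT mean -0.918; t = 22.22 (p = 2e-59)
```

All artifacts are plain text (FASTA/TSV/JSON) under the run directory,
with a manifest of checksums; re-running the same config reproduces them
byte-for-byte, and deleting an artifact re-runs only that stage and its
dependents.

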