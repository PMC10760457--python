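# mirstruct

Plant genomes silence transposable elements (TEs) through RNA-directed
DNA methylation, and the incipient step is thought to be the folding of
transcripts into miRNA-like hairpins that Dicer-like enzymes cut into
small RNAs.  `mirstruct` is a toolkit for surveying that chain of events
on annotated genome features: it predicts miRNA-like secondary
structures in genes and TEs, and quantifies how those structures relate
to small-RNA mapping, CHH methylation, and expression variability across
genotypes.  It is aimed at regulatory/epigenomics researchers who want
the full analysis chain runnable, testable, and reproducible at desk
scale on synthetic genomes with planted truth.

## What it computes

**Structure annotation** (two complementary methods):

* *Window MFE scan* — 110-nt sliding windows (1-nt step) folded to
  minimum free energy; per feature minMFE and meanMFE; overlapping
  sub-threshold windows merged into **lowMFE regions**.  A feature is
  **RF-structured** when it has a sub-threshold window and its window
  MFEs are significantly lower than five composition-preserving shuffles
  (one-sided Wilcoxon, Benjamini–Hochberg across the cohort).
* *Partition function* — McCaskill-style ensemble per feature: partition
  sum Z, ensemble free energy Q = −RT ln Z, Q_norm = Q / length, and the
  base-pair probability matrix, from which **hairpins** are called as
  ≥ 21-nt runs of positions pairing with probability > 0.90, with ≤ 4
  mismatched nucleotides of which ≤ 2 in asymmetric bulges.

**Downstream analyses**: exact-match small-RNA species mapping
(21/22/24-nt classes, strand-agnostic, multi-mappers kept); the **skew**
statistic (d_in − d_out)/(d_in + d_out) of species density inside vs
outside miRNA-like regions, with zero-filters and signed-rank tests;
weighted-methylation metaprofiles (centre ± 2-kb flanks in 40 × 100-bp
windows) with matched random controls; 100-bin positional landscapes;
observed/expected overlap enrichment; expression contrasts, CV across
genotype lines, and CV ~ smRNA-density / CV ~ minMFE models.

A synthetic-data generator produces genomes, annotations, smRNA
libraries, methylomes and expression panels with planted, exhaustively
recorded truth, so every stage is testable without downloads.

Both folding engines are built in and share one energy model with a
brute-force enumeration oracle, which lets the test suite verify the
dynamic programs exactly.  Window MFEs and pair-probability matrices
computed by external folding tools can be imported through documented
TSV dialects instead (see `docs/methods.md`).

## Worked example

```python
from mirstruct import NucleotideSequence, fold_mfe, partition_function, window_scan

seq = NucleotideSequence("stem", "GGGGGAAAACCCCC")
res = fold_mfe(seq)
print(res.mfe, res.structure)          # -9.0 (((((....)))))

ens = partition_function(seq)
print(round(ens.q, 3))                 # -9.019   (ensemble free energy)
print(round(ens.pair_prob[0, 13], 4))  # 0.9773   (terminal pair probability)

prof = window_scan(NucleotideSequence("f", "ACGU" * 60))
print(prof.n_windows)                  # 131      (= 240 - 109)
```

The five-pair stem scores −12.0 from its four stacked GC pairs plus
+3.0 for the hairpin loop; the ensemble free energy is barely below the
MFE because that stem dominates the ensemble, and its terminal pair is
paired in ~98% of structures.

End-to-end on the packaged ~1-Mb synthetic demo (about 3 minutes on one
CPU):

```bash
mirstruct run-all --config configs/demo.yaml --seed 1 --out demo_out
```

`demo_out/report.json` from this run shows, among other things, a
calibrated lowMFE threshold of −51.5 kcal/mol, 100% of RLC elements with
hairpin calls (median arm span 25 nt — the planted stem length) versus
0% of the structure-free control features, mean 22-nt skew of +0.46 in
RLC and +0.07 in controls, a CHH metaprofile centre level of 0.23 over a
0.05 baseline (paired centre-vs-flank p ≈ 4e-32), and a 3.1-fold
enrichment of hairpins inside lowMFE regions.  Artifacts (window MFE and
pair-probability TSVs, BED tracks, skew/metaprofile/landscape tables)
land beside the report.

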