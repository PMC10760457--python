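# Methods

`mirstruct` annotates miRNA-like secondary structures in genomic features
(genes, transposable elements) and quantifies their association with
small-RNA production, RdDM-style CHH methylation, and cross-genotype
expression variability.  This note records the models, the parameters
that matter, and the deliberate design choices.

## Structure annotation

Two complementary annotations are produced per feature, mirroring the
two families of tools used for this kind of survey (window-based MFE
folding and whole-sequence partition functions).

**Window MFE scan.**  Each feature's sense-strand sequence is scanned
with 110-nt sliding windows at 1-nt step; every nucleotide except the
trailing 109 starts a window.  Features shorter than a window are folded
whole and flagged `short_feature`.  Per feature we keep the full window
vector plus minMFE (strongest window) and meanMFE.  Windows with MFE
below a stability threshold are merged (overlap, which at 1-nt step
subsumes bookended windows) into *lowMFE regions*; a region is therefore
always at least one window long.

**RF-structured classification.**  A feature is *RF-structured* when it
(a) contains at least one sub-threshold window and (b) folds
significantly more stably than its own base composition: the observed
window-MFE distribution is compared against the pooled window MFEs of
five composition-preserving shuffles with a one-sided Wilcoxon rank-sum
test, and p-values are Benjamini–Hochberg corrected once across the whole
feature cohort (alpha = 0.05).  An alternative `minmfe` mode compares the
observed minMFE against the five shuffle minima by empirical rank; with
five shuffles its smallest attainable p is 1/6, which is why the
window-distribution mode is the default.

**Hairpin calls.**  From the base-pair probability matrix, positions with
maximum pairing probability > 0.90 are *qualified* (argmax partner, ties
toward the smaller index).  Qualified positions are segmented into stem
arms: partners must strictly decrease along an arm, and a sign change of
(partner − position) marks the boundary between the two arms of a stem
(without this split the partner sequence decreases monotonically straight
across the loop, and a perfect stem would be mis-read as a single
interval whose loop counts as mismatches).  Blocks of unqualified
positions internal to an arm accumulate mismatches: a block of length g
between qualified neighbours whose partners differ by gap_p = q_prev −
q_next − 1 adds max(g, gap_p) mismatches, |g − gap_p| of them asymmetric.
A block that would push a candidate past the budget (≤ 4 mismatches, ≤ 2
asymmetric) closes the candidate before the block and restarts after it;
this keeps clean planted stems callable when serendipitous neighbouring
pairing would otherwise inflate a single over-budget segment.  Calls must
span ≥ 21 nt; both arms are emitted, cross-referencing each other.

## Folding engines

The energy model ("SIMPLE-NN v1") is intentionally small: stacking of
pair p2 on p1 scores −(w(p1) + w(p2))/2 with w(GC) = 3.0, w(AU) = 2.0,
w(GU) = 1.0 kcal/mol; hairpin closure +3.0; bulge/internal loop +2.0
(size-independent); multiloop +3.0; minimum loop 3 nt; RT = 0.6157
kcal/mol (310.15 K).  One model instance parameterizes all three engines
— the Zuker-style MFE recursion, the McCaskill-style partition function,
and a brute-force enumeration oracle (≤ 25 nt) — so the dynamic programs
can be validated against exhaustive enumeration *exactly*, which the test
suite does to 1e-9 relative error on Z and every pair probability.  The
model makes no claim of Turner-parameter fidelity; externally computed
window MFEs and pair-probability matrices can be supplied through the
TSV adapter dialects instead and flow through the callers unchanged.

Numerical choices: MFE traceback is deterministic and left-greedy (the
5'-most pairing decision wins among co-optimal structures).  The
partition function uses ViennaRNA-style per-nucleotide scaling with the
scale derived from the sequence MFE — the inside/outside recursions here
use inclusion–exclusion sums whose subtractions rule out pure log-space
arithmetic, and scaling keeps everything finite for sequences to ~20 kb.
The outside pass handles the multiloop context (which couples the two
sides of the closing pair) with row-wise accumulator arrays, keeping the
whole computation O(n³).  Kernels are numba-compiled.

Because the built-in energies are not Turner energies, the canonical
−40 kcal/mol lowMFE cutoff does not transfer: random-composition windows
under this model fold near −40.  Runs with the built-in engine therefore
calibrate the threshold from the data by default: the 0.5th percentile of
the pooled shuffled window-MFE distribution, so essentially no
composition-matched null window qualifies while planted stems (which sit
20+ kcal/mol below the null) do.  The −40 default remains in the
configuration for externally imported (Turner-scale) window MFEs.

## smRNA mapping and skew

Small-RNA *species* (distinct sequences, classes 21/22/24 nt) are mapped
by exact match on both strands, reporting all loci of multi-mappers; a
hash lookup is equivalent to a full aligner here because only perfect
alignments are retained.  Counting is per species per region (read
counts and hit multiplicity do not matter; a ≥ 1-nt overlap assigns a
species to a region).  Skew contrasts species-per-nucleotide densities
inside the union of a feature's miRNA-like regions against the
within-feature complement, (d_in − d_out)/(d_in + d_out) ∈ [−1, 1];
feature × library pairs with zero species in either compartment are
flagged and excluded from summaries, and a one-sided Wilcoxon
signed-rank test asks whether the median skew exceeds zero.  Model fits
use natural-log transforms log(x + 1): OLS of per-kb species counts
(summed across libraries) on a structure metric, and a mixed model
log(density + 1) ~ structured + (1 | feature) at region × library
resolution (statsmodels MixedLM).

## Methylation, landscapes, enrichment

Weighted methylation of a region is Σ meth_reads / Σ total_reads over
covered cytosines of one context (CG symmetric, CHG/CHH strand-specific);
uncovered regions are *missing*, never zero.  Metaprofiles take one
centre slot per region plus 2-kb flanks cut into 40 non-overlapping
100-bp windows, averaged unweighted across regions (missing slots
excluded); the centre-vs-flank contrast is a paired t-test of each
region's centre against the mean of its own flank windows.  Matched
controls are same-length random within-feature intervals that avoid the
miRNA-like regions; features more than half covered by such regions are
excluded since no fair control placement exists.  Positional landscapes
split each feature into 100 proportional bins (5'→3' via strand) and
count features whose regions touch each bin.  Overlap enrichment is
observed / expected with expected = n_items × (target bp / assayed bp),
i.e. a uniform-placement null, verified to be calibrated (mean fold
within [0.9, 1.1] over 1,000 replicates) in the test suite.

## Expression analyses

Cross-genotype variability is the per-gene CV (sample SD over mean,
n−1 denominator) across the genotype-line panel; zero-mean genes are
flagged invalid rather than dropped silently.  The structured-vs-
unstructured expression contrast uses Welch t-tests on log(expr + 1)
plus a label-permutation test of the group-mean difference (10,000
permutations by default) with optional equal-size down-sampling of the
larger group.  Expression ~ minMFE fits are per-group OLS with an
opposing-slope diagnostic; CV models regress CV on smRNA density and on
minMFE, and log(B73-like expression + 1) on CV.  Quartile summaries
split genes into four equal minMFE quartiles (stable-order ties) and
report mean smRNA counts per quartile.

## Synthetic data generator

The generator defines the study conditions for every recovery test; the
defaults are fixed and are not tuned per experiment.

* **Genome.**  i.i.d. background at GC 0.45 (composition-preserving
  shuffling is the structural null, so an i.i.d. background is a fair
  one; a dinucleotide-preserving background is deliberately out of
  scope).  Features (genes, RLC/RLG/DTM/DHH superfamilies, organellar-
  like controls) of 300–600 nt sit between configurable intergenic gaps;
  random strands exercise the coordinate logic.
* **Planted structure.**  25-bp stems with 4-nt loops (0 mismatches) at
  superfamily-typical positions: LTR-proximal (RLC/RLG), 3'-proximal
  (DHH), at a TIR end (DTM), uniform in genes (50% of genes structured);
  controls receive none.  The planted stem padded to 150 nt is recorded
  as the feature's true miRNA-like region — the scale a window-based
  caller actually reports.
* **smRNA libraries.**  Species arise at rate r = 0.05 per nt outside
  regions and r(1+s)/(1−s) inside, so the density contrast equals the
  target skew s exactly in expectation; draws are Poisson counts placed
  without replacement on distinct fully-inside starts, and sequences are
  the genomic subsequences (random strand), so exact-match mapping
  recovers them in place.  Autonomous elements add +0.3 to s.  Defaults
  give roughly 30–90 species per feature per class.  The ratio form of
  skew leaves a small Jensen bias (≈ −0.02 at s = 0) that sits well
  inside the ±0.05 recovery band.
* **Methylome.**  Per-cytosine binomial draws at context baselines
  (CG 0.80, CHG 0.60, CHH 0.05 — maize-like magnitudes) with Poisson
  coverage (mean 8); CHH rates rise to 0.30 at planted stems and decay
  exponentially (length 150 nt) into the flanks.
* **Expression.**  Log-normal gene means (tissue panel of 23, line panel
  of 26); structured genes' means scale by 1.5; line-to-line dispersion
  grows by 0.02 per 100 species/kb of simulated smRNA density, coupling
  smRNA load to CV.

What passing recovery tests show — and what they do not: the pipeline
recovers planted effects whose generative form matches its own model
(i.i.d. background, exact planted stems, Poisson species, binomial
methylomes).  Real genomes add dinucleotide structure, nested/truncated
TEs, mapping biases, bisulfite conversion artefacts and expression batch
structure that the generator deliberately omits, so recovery here
validates the *implementation*, not field performance.

## Problem sizes

The packaged demo configuration uses a ~1-Mb genome with 90 features
(300–600 nt) and 3 libraries × 3 length classes; recovery experiments use
100–300 features per condition, 200 regions for methylation profiles,
and 1,000 genes × 26 lines for the expression panel.  These sizes give
stable estimates (Monte-Carlo error well inside the asserted bands)
while keeping a full run on a single CPU in minutes.

## Known limitations

* The window-distribution Wilcoxon treats overlapping (strongly
  autocorrelated) windows as independent observations, so its null
  p-values are overdispersed rather than uniform and the cohort-wide BH
  correction controls FDR only nominally; this is inherent to testing
  per-window MFE distributions at 1-nt step.  The calibration tests
  bound the realized false-positive rate empirically.
* The built-in energy model is a structural toy: adequate for exact
  cross-validation and planted-structure recovery, not for quantitative
  thermodynamics; use the adapter seam for Turner-scale results.
* Hairpin arm pairing records partner intervals but does not classify
  loop types, and a partner-side-only bulge between adjacent qualified
  positions is accounted on the opposite arm's record only.
* Skew uses the union of a feature's miRNA-like regions (not per-region
  averaging) when several regions exist.
* Whether a hairpin whose two arms both pass should count once or twice
  in per-feature tallies is ambiguous; both arms are emitted and
  `n_hairpins` counts arms.
* The ensemble free energy Q = −RT ln Z is reported (not the raw
  partition sum), consistent with its positive correlation with meanMFE;
  `EnsembleResult.z` exposes the sum itself.
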