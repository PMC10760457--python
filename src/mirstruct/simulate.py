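"""Synthetic genomes with planted truth for end-to-end testing.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* a genome of i.i.d. background sequence at a configurable GC fraction,
  carrying gene / TE-superfamily / control features;
* planted inverted repeats (default 25-bp stem, 4-nt loop) at
  superfamily-typical positions — LTR-proximal for RLC/RLG, 3'-proximal
  for helitrons (DHH), at a terminal-inverted-repeat end for Mutator-like
  DTM elements, uniform within genes; control features receive none;
* small-RNA libraries whose species density inside planted regions versus
  outside realises a configured true skew exactly in expectation
  (outside rate r, inside rate r(1+s)/(1-s)), with an additive skew
  differential for autonomous elements;
* binomial methylomes at per-context baselines with a CHH boost centred
  on planted regions decaying exponentially into the flanks;
* expression panels (tissue panel and genotype-line panel) where
  structured genes have a scaled mean and line-to-line dispersion grows
  with simulated smRNA density.

Every output is a deterministic function of the master seed; the planted
truth is exhaustive, and nothing downstream reads it except tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import FeatureAnnotation
from .seqs import InputError, NucleotideSequence, reverse_complement

BASES = np.array(list("ACGU"))


@dataclass
class CategoryConfig:
    n: int = 20
    length_range: tuple[int, int] = (300, 600)
    structured_fraction: float = 1.0
    position_bias: str = "uniform"  # uniform | five_prime | three_prime | either_end
    true_skew: float = 0.5
    autonomous_fraction: float = 0.0


def _default_categories() -> dict[str, CategoryConfig]:
    return {
        "gene": CategoryConfig(n=20, structured_fraction=0.5,
                               position_bias="uniform", true_skew=0.8),
        "RLC": CategoryConfig(n=20, position_bias="five_prime",
                              true_skew=0.5),
        "RLG": CategoryConfig(n=20, position_bias="five_prime",
                              true_skew=0.5),
        "DTM": CategoryConfig(n=20, position_bias="either_end",
                              true_skew=0.5, autonomous_fraction=0.4),
        "DHH": CategoryConfig(n=20, position_bias="three_prime",
                              true_skew=0.6, autonomous_fraction=0.4),
        "control": CategoryConfig(n=20, structured_fraction=0.0,
                                  true_skew=0.0),
    }


@dataclass
class SyntheticConfig:
    seed: int = 0
    categories: dict[str, CategoryConfig] = field(
        default_factory=_default_categories)
    gc_fraction: float = 0.45
    intergenic_gap: tuple[int, int] = (500, 2000)
    # planted hairpins
    stem_length: int = 25
    loop_length: int = 4
    stem_mismatches: int = 0
    mirna_region_size: int = 150    # planted stem padded to this span
    # smRNA libraries
    n_libraries: int = 3
    length_classes: tuple[int, ...] = (21, 22, 24)
    species_rate: float = 0.05      # expected species per nt outside regions
    autonomous_skew_delta: float = 0.3
    # methylome
    baseline_rates: dict = field(default_factory=lambda: {
        "CG": 0.80, "CHG": 0.60, "CHH": 0.05})
    chh_boost: float = 0.30         # CHH rate at planted-region centre
    decay_length: float = 150.0     # nt, exponential decay into flanks
    coverage: float = 8.0           # mean per-cytosine read depth
    # expression
    n_tissues: int = 23
    n_lines: int = 26
    structured_multiplier: float = 1.5
    cv_coupling: float = 0.02       # sigma increase per 100 species/kb
    base_sigma: float = 0.3

    def validate(self) -> None:
        if not (0 < self.gc_fraction < 1):
            raise InputError("gc_fraction must lie in (0, 1)")
        for name, cat in self.categories.items():
            if not (-1 < cat.true_skew < 1):
                raise InputError(f"{name}: true_skew must lie in (-1, 1)")
            if not (0 <= cat.structured_fraction <= 1):
                raise InputError(f"{name}: bad structured_fraction")
            if self.stem_length * 2 + self.loop_length > cat.length_range[0]:
                raise InputError(
                    f"{name}: planted hairpin does not fit the minimum "
                    "feature length")
        for rate in self.baseline_rates.values():
            if not (0 <= rate <= 1):
                raise InputError("baseline methylation rates must be in [0,1]")
        if not (0 <= self.chh_boost <= 1):
            raise InputError("chh_boost must lie in [0, 1]")


@dataclass
class FeatureTruth:
    feature_id: str
    category: str
    chrom: str
    start: int
    end: int
    strand: str
    autonomy: str
    structured: bool
    planted_local: list  # [(start, end)] in feature-local sense coordinates
    planted_genomic: list
    mirna_local: list    # planted stems padded to the miRNA-region span
    mirna_genomic: list
    true_skew: float


@dataclass
class SyntheticTruth:
    features: dict[str, FeatureTruth]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({fid: asdict(t) for fid, t in self.features.items()},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({fid: FeatureTruth(**{
            **d, "planted_local": [tuple(x) for x in d["planted_local"]],
            "planted_genomic": [tuple(x) for x in d["planted_genomic"]],
            "mirna_local": [tuple(x) for x in d["mirna_local"]],
            "mirna_genomic": [tuple(x) for x in d["mirna_genomic"]],
        }) for fid, d in raw.items()})


@dataclass
class SyntheticDataset:
    genome: dict[str, str]          # chrom -> RNA-alphabet sequence
    features: list[FeatureAnnotation]
    truth: SyntheticTruth

    def feature_sequence(self, f: FeatureAnnotation) -> NucleotideSequence:
        """Sense-strand sequence of a feature."""
        s = self.genome[f.chrom][f.start:f.end]
        if f.strand == "-":
            s = reverse_complement(s)
        return NucleotideSequence(f.feature_id, s)


def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def plant_inverted_repeat(
    residues: np.ndarray,
    stem: int,
    loop: int,
    mismatches: int,
    position: int,
    rng,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Overwrite arm / loop / reverse-complement arm starting at
    ``position``; returns the modified array and the planted interval
    (covering both arms and the loop, half-open)."""
    total = 2 * stem + loop
    if position < 0 or position + total > len(residues):
        raise InputError("inverted repeat does not fit at this position")
    arm = residues[position:position + stem].copy()
    rc = np.array(list(reverse_complement("".join(arm))))
    if mismatches > 0:
        idx = rng.choice(stem, size=mismatches, replace=False)
        for i in idx:
            choices = [b for b in "ACGU" if b != rc[i]]
            rc[i] = choices[rng.integers(3)]
    residues[position + stem + loop:position + total] = rc
    return residues, (position, position + total)


def _plant_position(rng, cat: CategoryConfig, flen: int, total: int) -> int:
    margin = 10
    hi = flen - total - margin
    if hi <= margin:
        return max(0, (flen - total) // 2)
    if cat.position_bias == "five_prime":
        return int(rng.integers(margin, min(margin + 40, hi)))
    if cat.position_bias == "three_prime":
        return int(rng.integers(max(margin, hi - 40), hi))
    if cat.position_bias == "either_end":
        if rng.random() < 0.5:
            return int(rng.integers(margin, min(margin + 40, hi)))
        return int(rng.integers(max(margin, hi - 40), hi))
    return int(rng.integers(margin, hi))


def build_synthetic_genome(config: SyntheticConfig) -> SyntheticDataset:
    """Genome + annotations + exhaustive planted truth (deterministic)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom = "chr1"
    pieces: list[np.ndarray] = []
    features: list[FeatureAnnotation] = []
    truth: dict[str, FeatureTruth] = {}
    pos = 0
    total_ir = 2 * config.stem_length + config.loop_length
    plan = [(name, cat, i) for name, cat in config.categories.items()
            for i in range(cat.n)]
    for name, cat, i in plan:
        gap = int(rng.integers(*config.intergenic_gap))
        pieces.append(_random_seq(rng, gap, config.gc_fraction))
        pos += gap
        flen = int(rng.integers(cat.length_range[0], cat.length_range[1] + 1))
        seq = _random_seq(rng, flen, config.gc_fraction)
        structured = rng.random() < cat.structured_fraction
        planted_local: list[tuple[int, int]] = []
        if structured:
            p = _plant_position(rng, cat, flen, total_ir)
            seq, interval = plant_inverted_repeat(
                seq, config.stem_length, config.loop_length,
                config.stem_mismatches, p, rng)
            planted_local.append(interval)
        strand = "+" if rng.random() < 0.5 else "-"
        fid = f"{name}_{i:04d}"
        autonomy = "unknown"
        if cat.autonomous_fraction > 0:
            autonomy = "autonomous" if rng.random() < cat.autonomous_fraction \
                else "nonautonomous"
        skew = cat.true_skew
        if autonomy == "autonomous":
            skew = min(0.95, skew + config.autonomous_skew_delta)
        elif autonomy == "nonautonomous" and cat.autonomous_fraction > 0:
            skew = max(-0.95, skew - 0.0)
        feat = FeatureAnnotation(chrom, pos, pos + flen, strand, fid,
                                 name if name != "control" else "control",
                                 autonomy)
        genomic = [feat.to_genomic(s, e) for s, e in planted_local]
        mirna_local = []
        for s, e in planted_local:  # pad stems to the miRNA-region span
            pad = max(0, config.mirna_region_size - (e - s))
            ms = max(0, s - pad // 2)
            me = min(flen, ms + max(e - s, config.mirna_region_size))
            ms = max(0, me - max(e - s, config.mirna_region_size))
            mirna_local.append((ms, me))
        mirna_genomic = [feat.to_genomic(s, e) for s, e in mirna_local]
        if strand == "-":
            seq = np.array(list(reverse_complement("".join(seq))))
        pieces.append(seq)
        features.append(feat)
        truth[fid] = FeatureTruth(fid, name, chrom, pos, pos + flen, strand,
                                  autonomy, structured, planted_local,
                                  genomic, mirna_local, mirna_genomic,
                                  skew if structured else 0.0)
        pos += flen
    gap = int(rng.integers(*config.intergenic_gap))
    pieces.append(_random_seq(rng, gap, config.gc_fraction))
    genome = {chrom: "".join("".join(p) for p in pieces)}
    return SyntheticDataset(genome, features, SyntheticTruth(truth))


def simulate_smrna_libraries(
    dataset: SyntheticDataset,
    config: SyntheticConfig,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Collapsed read tables per (library, length class).

    For a feature with true skew s, species start positions arise at
    per-nucleotide rate r outside planted regions and r(1+s)/(1-s)
    inside, so the inside/outside density contrast realises s exactly in
    expectation.  Species sequences are the genomic subsequences at the
    sampled positions (random strand), so exact-match mapping recovers
    them in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for lib in range(config.n_libraries):
        lib_id = f"lib{lib + 1}"
        for k in config.length_classes:
            rows: list[tuple[str, int]] = []
            for feat in dataset.features:
                t = dataset.truth.features[feat.feature_id]
                regions = sorted(t.mirna_genomic)
                s = t.true_skew if t.structured else 0.0
                r_out = config.species_rate
                r_in = r_out * (1 + s) / (1 - s)
                compartments = []
                prev = feat.start
                for rs, re_ in regions:
                    if rs > prev:
                        compartments.append((prev, rs, r_out))
                    compartments.append((rs, re_, r_in))
                    prev = re_
                if feat.end > prev:
                    compartments.append((prev, feat.end, r_out))
                chrom_seq = dataset.genome[feat.chrom]
                for cs, ce, rate in compartments:
                    valid = ce - cs - k + 1
                    if valid < 1:
                        continue
                    n = min(int(rng.poisson(rate * (ce - cs))), valid)
                    if n == 0:
                        continue
                    starts = rng.choice(valid, size=n, replace=False) + cs
                    for st in starts:
                        sp = chrom_seq[st:st + k]
                        if rng.random() < 0.5:
                            sp = reverse_complement(sp)
                        rows.append((sp, 1 + int(rng.poisson(2))))
            df = pd.DataFrame(rows, columns=["sequence", "count"])
            df = df.groupby("sequence", as_index=False)["count"].sum()
            out[(lib_id, k)] = df
    return out


def simulate_methylome(
    dataset: SyntheticDataset,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Per-cytosine binomial methylome over the whole genome.

    CHH sites near planted regions are boosted from the baseline toward
    ``chh_boost`` with exponential decay of the configured length.
    Returns the long-form table (chrom, pos 0-based, strand, context,
    meth, total); zero-coverage sites are omitted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    frames = []
    for chrom, seq in dataset.genome.items():
        s = seq.upper().replace("U", "T")
        arr = np.frombuffer(s.encode(), dtype="S1")
        n = len(s)
        dist = np.full(n, np.inf)
        positions = np.arange(n)
        for t in dataset.truth.features.values():
            for rs, re_ in t.planted_genomic:
                d = np.maximum(0, np.maximum(rs - positions,
                                             positions - (re_ - 1)))
                np.minimum(dist, d, out=dist)
        for strand, base in (("+", b"C"), ("-", b"G")):
            pos = np.flatnonzero(arr == base)
            # vectorized context assignment (assign_context, elementwise)
            if strand == "+":
                pos = pos[pos + 1 < n]
                n1 = arr[pos + 1] == b"G"
                inner = pos + 2 < n
                n2 = np.zeros(len(pos), dtype=bool)
                n2[inner] = arr[pos[inner] + 2] == b"G"
            else:
                pos = pos[pos - 1 >= 0]
                n1 = arr[pos - 1] == b"C"
                inner = pos - 2 >= 0
                n2 = np.zeros(len(pos), dtype=bool)
                n2[inner] = arr[pos[inner] - 2] == b"C"
            ctx = np.where(n1, "CG", np.where(n2, "CHG", "CHH"))
            keep = n1 | inner  # CHG/CHH undecidable at the sequence edge
            pos, ctx = pos[keep], ctx[keep]
            rate = np.empty(len(pos))
            for c, r in config.baseline_rates.items():
                rate[ctx == c] = r
            chh = ctx == "CHH"
            base_chh = config.baseline_rates["CHH"]
            decay = np.exp(-dist[pos[chh]] / config.decay_length)
            rate[chh] = base_chh + (config.chh_boost - base_chh) * decay
            total = rng.poisson(config.coverage, size=len(pos))
            cov = total > 0
            meth = rng.binomial(total[cov], rate[cov])
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos[cov], "strand": strand,
                "context": ctx[cov], "meth": meth, "total": total[cov]}))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos"], kind="stable",
                          ignore_index=True)


def simulate_expression_panel(
    dataset: SyntheticDataset,
    config: SyntheticConfig,
    smrna_density_per_kb: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-panel and genotype-line-panel expression matrices for genes.

    Gene base expression is log-normal; structured genes' mean is scaled
    by ``structured_multiplier``; line-to-line dispersion sigma grows by
    ``cv_coupling`` per 100 species/kb of simulated smRNA density, which
    couples smRNA load to cross-genotype expression variability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = [f for f in dataset.features if f.category == "gene"]
    if not genes:
        raise InputError("dataset contains no genes")
    smrna_density_per_kb = smrna_density_per_kb or {}
    gene_ids = [g.feature_id for g in genes]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    structured = np.array(
        [dataset.truth.features[g.feature_id].structured for g in genes])
    base = base * np.where(structured, config.structured_multiplier, 1.0)
    density = np.array([smrna_density_per_kb.get(g, 0.0) for g in gene_ids])
    sigma = config.base_sigma + config.cv_coupling * density / 100.0
    tissue = base[:, None] * rng.lognormal(
        mean=0.0, sigma=0.25, size=(len(genes), config.n_tissues))
    line = base[:, None] * np.exp(
        rng.normal(0.0, 1.0, size=(len(genes), config.n_lines))
        * sigma[:, None])
    tissue_df = pd.DataFrame(
        tissue, index=gene_ids,
        columns=[f"tissue{t + 1}" for t in range(config.n_tissues)])
    line_df = pd.DataFrame(
        line, index=gene_ids,
        columns=[f"line{t + 1}" for t in range(config.n_lines)])
    return tissue_df, line_df
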