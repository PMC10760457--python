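"""Small-RNA species mapping, per-region densities, and the skew statistic.

A *species* is a distinct small-RNA sequence of one of the canonical
length classes (21, 22, 24 nt).  Species are mapped to the genome by exact
match only (the paper's pipeline kept only perfect alignments, which makes
a hash/dictionary lookup equivalent to a full aligner), on both strands,
reporting every locus of multi-mappers.  Counting is per species — a
species contributes once to a region no matter how many reads or hits it
has there.

Skew contrasts species density (species per nucleotide) inside miRNA-like
regions of a feature against the within-feature complement:

    skew = (d_in - d_out) / (d_in + d_out)   in [-1, 1]

Feature x library pairs with zero species in either compartment are
flagged ``dropped`` and excluded from skew summaries; significance of a
positive median skew uses a one-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqs import InputError, reverse_complement

LENGTH_CLASSES = (21, 22, 24)


@dataclass
class SpeciesTable:
    """Distinct read sequences (one length class) with read counts."""

    library_id: str
    length_class: int
    species: dict[str, int]  # sequence -> read count

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class SmrnaHit:
    species: str
    chrom: str
    start: int
    end: int
    strand: str  # recorded but ignored by all counting


@dataclass
class SkewRecord:
    feature_id: str
    library_id: str
    length_class: int
    d_hp: float
    d_non: float
    skew: float
    dropped: bool
    reason: str = ""


def collapse_species(reads, length_class: int,
                     library_id: str = "lib") -> SpeciesTable:
    """Deduplicate reads of exactly ``length_class`` nt into species."""
    species: dict[str, int] = {}
    for r in reads:
        r = str(r).upper().replace("T", "U")
        if len(r) != length_class:
            continue
        species[r] = species.get(r, 0) + 1
    return SpeciesTable(library_id, length_class, species)


def map_species_exact(table: SpeciesTable, genome) -> list[SmrnaHit]:
    """Every perfect-match locus of every species, on either strand.

    ``genome`` is a mapping chrom -> sequence string (RNA or DNA
    alphabet).  Matching is strand-agnostic: a species query hits a locus
    when the forward genomic k-mer equals the species (strand +) or its
    reverse complement (strand -).  Implemented as a single sliding pass
    per chromosome against a species dictionary.
    """
    k = table.length_class
    lookup: dict[str, list[tuple[str, str]]] = {}
    for sp in table.species:
        lookup.setdefault(sp, []).append((sp, "+"))
        rc = reverse_complement(sp)
        lookup.setdefault(rc, []).append((sp, "-"))
    hits: list[SmrnaHit] = []
    for chrom, seq in genome.items():
        s = str(seq).upper().replace("T", "U")
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            entries = lookup.get(kmer)
            if entries:
                for sp, strand in entries:
                    hits.append(SmrnaHit(sp, chrom, i, i + k, strand))
    return hits


def hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.species, h.chrom, h.start, h.end, h.strand) for h in hits],
        columns=["species", "chrom", "start", "end", "strand"],
    )


def count_species(hits, chrom: str, start: int, end: int) -> tuple[int, float]:
    """Distinct species with >= 1 nt overlap of [start, end); density/nt.

    A species counts once per region regardless of hit multiplicity.
    """
    if end - start < 1:
        raise InputError("zero-length region")
    seen = set()
    for h in hits:
        if h.chrom == chrom and h.start < end and h.end > start:
            seen.add(h.species)
    count = len(seen)
    return count, count / (end - start)


def _interval_union_length(intervals) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        else:
            total += max(0, e - last_end)
            last_end = max(last_end, e)
    return total


def compute_skew(
    feature_id: str,
    chrom: str,
    feature_start: int,
    feature_end: int,
    structured_regions,
    hits,
    library_id: str,
    length_class: int,
) -> SkewRecord:
    """Per feature x library x length-class skew of species density.

    ``structured_regions`` are genomic [start, end) intervals of the
    feature's miRNA-like regions; densities are computed over the union of
    those regions and over the within-feature complement.
    """
    regions = sorted((max(s, feature_start), min(e, feature_end))
                     for s, e in structured_regions)
    regions = [(s, e) for s, e in regions if e > s]
    if not regions:
        raise InputError(f"feature {feature_id} has no structured region")
    l_in = _interval_union_length(regions)
    l_out = (feature_end - feature_start) - l_in
    if l_out <= 0:
        return SkewRecord(feature_id, library_id, length_class,
                          float("nan"), float("nan"), float("nan"),
                          dropped=True, reason="regions cover entire feature")
    in_species: set[str] = set()
    out_species: set[str] = set()
    merged = []
    last = None
    for s, e in regions:  # merge for complement computation
        if last is None or s > last[1]:
            merged.append([s, e])
            last = merged[-1]
        else:
            last[1] = max(last[1], e)
    complement = []
    prev = feature_start
    for s, e in merged:
        if s > prev:
            complement.append((prev, s))
        prev = max(prev, e)
    if feature_end > prev:
        complement.append((prev, feature_end))
    for h in hits:
        if h.chrom != chrom or h.end <= feature_start or h.start >= feature_end:
            continue
        for s, e in merged:
            if h.start < e and h.end > s:
                in_species.add(h.species)
                break
        for s, e in complement:
            if h.start < e and h.end > s:
                out_species.add(h.species)
                break
    d_in = len(in_species) / l_in
    d_out = len(out_species) / l_out
    if d_in == 0.0 or d_out == 0.0:
        skew = float("nan") if (d_in == 0.0 and d_out == 0.0) else \
            (1.0 if d_out == 0.0 else -1.0)
        return SkewRecord(feature_id, library_id, length_class, d_in, d_out,
                          skew, dropped=True, reason="zero species in a compartment")
    skew = (d_in - d_out) / (d_in + d_out)
    return SkewRecord(feature_id, library_id, length_class, d_in, d_out,
                      skew, dropped=False)


def skew_sign_test(skews) -> float:
    """One-sided Wilcoxon signed-rank p for median skew > 0."""
    arr = np.asarray([s for s in skews if np.isfinite(s)], dtype=float)
    if arr.size == 0:
        raise InputError("no non-dropped skew records")
    if np.all(arr == 0):
        return 1.0
    res = stats.wilcoxon(arr, alternative="greater")
    return float(res.pvalue)


def skew_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.library_id, r.length_class, r.d_hp, r.d_non,
          r.skew, r.dropped) for r in records],
        columns=["feature_id", "library_id", "length_class", "d_hp",
                 "d_non", "skew", "dropped"],
    )


def fit_structure_smrna_models(
    feature_table: pd.DataFrame,
    metric: str = "min_mfe",
    response: str = "species_per_kb",
):
    """OLS of log(species per kb + 1) on a per-feature structure metric.

    ``feature_table`` needs one row per feature with columns ``metric``
    and ``response`` (species summed across libraries, per kb).
    Returns (slope, r_squared, p_value).
    """
    import statsmodels.api as sm

    df = feature_table.dropna(subset=[metric, response])
    if len(df) < 3:
        raise InputError("need at least 3 features for a model fit")
    y = np.log1p(df[response].to_numpy(dtype=float))
    x = df[metric].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise InputError("degenerate (constant) structure metric")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.rsquared), float(model.pvalues[1])


def fit_mixed_region_model(region_table: pd.DataFrame):
    """Mixed-effect model: log(species per kb + 1) ~ structured + (1|feature).

    ``region_table`` has one row per feature x library x region-compartment
    with columns feature_id, structured (0/1), species_per_kb.  Returns
    (fixed-effect estimate for 'structured', p-value).
    """
    import statsmodels.formula.api as smf

    df = region_table.copy()
    if len(df) < 3 or df["feature_id"].nunique() < 2:
        raise InputError("need >= 3 rows over >= 2 features")
    df["log_density"] = np.log1p(df["species_per_kb"].astype(float))
    md = smf.mixedlm("log_density ~ structured", df, groups=df["feature_id"])
    fit = md.fit(reml=True, method="lbfgs")
    return float(fit.fe_params["structured"]), float(fit.pvalues["structured"])
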