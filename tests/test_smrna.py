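import numpy as np
import pandas as pd
import pytest

from mirstruct.seqs import reverse_complement
from mirstruct.smrna import (SmrnaHit, SpeciesTable, collapse_species,
                             compute_skew, count_species,
                             fit_mixed_region_model,
                             fit_structure_smrna_models, map_species_exact,
                             skew_sign_test)
from mirstruct.seqs import InputError

from conftest import random_rna


def test_collapse_filters_length_and_counts_reads():
    reads = ["ACGUACGUACGUACGUACGUAC"] * 100 + ["ACGUACGUACGUACGUACGUA"]
    t = collapse_species(reads, 22)
    assert t.n_species == 1
    assert t.species["ACGUACGUACGUACGUACGUAC"] == 100
    assert collapse_species([], 22).n_species == 0


def test_exact_mapping_both_strands_and_multimappers(rng):
    sp = random_rna(rng, 21)
    genome = {"c1": "A" * 50 + sp + "A" * 50 + sp + "A" * 30,
              "c2": "G" * 40 + reverse_complement(sp) + "G" * 40}
    hits = map_species_exact(SpeciesTable("l", 21, {sp: 5}), genome)
    assert len(hits) == 3
    strands = sorted(h.strand for h in hits)
    assert strands == ["+", "+", "-"]


def test_one_mismatch_is_no_hit(rng):
    sp = "ACGUACGUACGUACGUACGUA"
    mutated = "ACGUACGUACGUACGUACGUU"
    genome = {"c1": "AAAA" + mutated + "AAAA"}
    assert map_species_exact(SpeciesTable("l", 21, {sp: 1}), genome) == []


def test_mapper_agrees_with_naive_scan_oracle(rng):
    """Exhaustive cross-check against per-position string comparison."""
    genome = {"chrA": random_rna(rng, 5000), "chrB": random_rna(rng, 5000)}
    species = {}
    for _ in range(300):
        chrom = "chrA" if rng.random() < 0.5 else "chrB"
        pos = int(rng.integers(0, 5000 - 21))
        s = genome[chrom][pos:pos + 21]
        species[s if rng.random() < 0.5 else reverse_complement(s)] = 1
    for _ in range(100):
        species[random_rna(rng, 21)] = 1
    hits = map_species_exact(SpeciesTable("l", 21, species), genome)
    expected = set()
    for sp in species:
        rc = reverse_complement(sp)
        for chrom, seq in genome.items():
            for i in range(len(seq) - 20):
                window = seq[i:i + 21]
                if window == sp:
                    expected.add((sp, chrom, i, "+"))
                if window == rc:
                    expected.add((sp, chrom, i, "-"))
    got = {(h.species, h.chrom, h.start, h.strand) for h in hits}
    assert got == expected


def test_species_counted_once_per_region():
    hits = [SmrnaHit("AAA", "c", 10, 31, "+"),
            SmrnaHit("AAA", "c", 50, 71, "+"),
            SmrnaHit("AAA", "c", 90, 111, "-"),
            SmrnaHit("CCC", "c", 20, 41, "+")]
    count, dens = count_species(hits, "c", 0, 500)
    assert count == 2
    assert dens * 1000 == pytest.approx(4.0)
    assert count_species(hits, "c", 400, 450)[0] == 0
    with pytest.raises(InputError):
        count_species(hits, "c", 5, 5)


def test_five_species_in_500nt_is_10_per_kb():
    hits = [SmrnaHit(f"S{i}", "c", 10 * i, 10 * i + 21, "+")
            for i in range(5)]
    count, dens = count_species(hits, "c", 0, 500)
    assert count == 5
    assert dens * 1000 == pytest.approx(10.0)


def _skew(hits_in, hits_out, l_feat=600, region=(100, 200)):
    hits = []
    for i in range(hits_in):
        hits.append(SmrnaHit(f"I{i}", "c", region[0] + i, region[0] + i + 1,
                             "+"))
    for i in range(hits_out):
        hits.append(SmrnaHit(f"O{i}", "c", 300 + i, 301 + i, "+"))
    return compute_skew("f", "c", 0, l_feat, [region], hits, "lib", 21)


def test_skew_zero_under_equal_density():
    # 10 species in 100 nt inside, 50 species in 500 nt outside
    rec = _skew(10, 50)
    assert rec.skew == pytest.approx(0.0)
    assert not rec.dropped


def test_skew_formula_and_antisymmetry():
    rec = _skew(3, 5)  # d_in = 3/100, d_out = 5/500 = 1/100 -> (3-1)/(3+1)
    assert rec.skew == pytest.approx(0.5)
    swapped = _skew(1, 15)  # d_in = 1/100, d_out = 3/100
    assert swapped.skew == pytest.approx(-0.5)


def test_zero_filter_drops_and_flags():
    rec = _skew(4, 0)
    assert rec.dropped
    assert rec.skew == pytest.approx(1.0)  # formula value pre-filter
    rec2 = _skew(0, 4)
    assert rec2.dropped and rec2.skew == pytest.approx(-1.0)


def test_regions_covering_feature_are_dropped():
    rec = compute_skew("f", "c", 0, 100, [(0, 100)], [], "lib", 21)
    assert rec.dropped
    assert "entire feature" in rec.reason


def test_sign_test_behaviour():
    assert skew_sign_test([0.5] * 100) < 1e-6
    sym = [x for v in np.linspace(0.05, 0.5, 25) for x in (v, -v)]
    assert 0.3 < skew_sign_test(sym) < 0.7
    assert skew_sign_test([0.4]) >= 0.5
    with pytest.raises(InputError):
        skew_sign_test([float("nan")])


def test_structure_model_exact_and_degenerate():
    x = np.linspace(-80, -20, 30)
    y = np.expm1(0.5 + 2.0 * x * 0.01)  # log1p(y) = 0.5 + 0.02 x exactly
    df = pd.DataFrame({"min_mfe": x, "species_per_kb": y})
    slope, r2, p = fit_structure_smrna_models(df)
    assert slope == pytest.approx(0.02)
    assert r2 == pytest.approx(1.0)
    flat = pd.DataFrame({"min_mfe": x, "species_per_kb": np.full(30, 7.0)})
    slope, r2, _ = fit_structure_smrna_models(flat)
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_mixed_model_recovers_planted_region_effect(rng):
    """Structured compartments simulated with higher species density must
    give a positive, significant fixed effect."""
    rows = []
    for f in range(120):
        base = rng.normal(3.0, 0.8)
        for lib in range(3):
            rows.append((f"f{f}", 1, np.expm1(
                max(0.0, base + 1.0 + rng.normal(0, 0.3)))))
            rows.append((f"f{f}", 0, np.expm1(
                max(0.0, base + rng.normal(0, 0.3)))))
    df = pd.DataFrame(rows, columns=["feature_id", "structured",
                                     "species_per_kb"])
    est, p = fit_mixed_region_model(df)
    assert est > 0.5
    assert p < 0.05
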