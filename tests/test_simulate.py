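import numpy as np
import pytest

from mirstruct.fold import fold_mfe
from mirstruct.seqs import InputError, NucleotideSequence, reverse_complement
from mirstruct.simulate import (CategoryConfig, SyntheticConfig,
                                build_synthetic_genome, plant_inverted_repeat,
                                simulate_expression_panel, simulate_methylome,
                                simulate_smrna_libraries)


def _small_config(seed=9, **kw):
    cfg = SyntheticConfig(seed=seed, **kw)
    cfg.categories = {
        "gene": CategoryConfig(n=6, structured_fraction=0.5, true_skew=0.8),
        "RLC": CategoryConfig(n=4, position_bias="five_prime", true_skew=0.5),
        "DHH": CategoryConfig(n=4, position_bias="three_prime",
                              true_skew=0.6, autonomous_fraction=0.5),
        "control": CategoryConfig(n=4, structured_fraction=0.0,
                                  true_skew=0.0),
    }
    cfg.intergenic_gap = (200, 400)
    return cfg


def test_same_seed_reproduces_genome_byte_for_byte():
    a = build_synthetic_genome(_small_config())
    b = build_synthetic_genome(_small_config())
    assert a.genome == b.genome
    assert [f.feature_id for f in a.features] == [f.feature_id
                                                  for f in b.features]
    c = build_synthetic_genome(_small_config(seed=10))
    assert c.genome != a.genome


def test_gc_fraction_realized():
    cfg = SyntheticConfig(seed=2)
    cfg.categories = {"control": CategoryConfig(
        n=2, structured_fraction=0.0, length_range=(400, 500))}
    cfg.intergenic_gap = (50_000, 50_001)
    cfg.gc_fraction = 0.5
    ds = build_synthetic_genome(cfg)
    seq = ds.genome["chr1"]
    assert len(seq) >= 100_000
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.5) <= 0.03


def test_planted_inverted_repeat_geometry(rng):
    seq = rng.choice(list("ACGU"), size=120)
    out, (s, e) = plant_inverted_repeat(seq.copy(), 25, 4, 0, 30, rng)
    assert (s, e) == (30, 30 + 54)
    arm = "".join(out[30:55])
    rc = "".join(out[59:84])
    assert rc == reverse_complement(arm)
    # 2 mismatches -> Hamming distance exactly 2
    out2, _ = plant_inverted_repeat(seq.copy(), 25, 4, 2, 30, rng)
    arm2 = "".join(out2[30:55])
    rc2 = "".join(out2[59:84])
    ham = sum(a != b for a, b in zip(rc2, reverse_complement(arm2)))
    assert ham == 2
    with pytest.raises(InputError):
        plant_inverted_repeat(seq.copy(), 60, 4, 0, 30, rng)


def test_planted_region_folds_below_background(rng, model):
    cfg = _small_config()
    ds = build_synthetic_genome(cfg)
    planted_mfes, background_mfes = [], []
    for f in ds.features:
        t = ds.truth.features[f.feature_id]
        seq = ds.feature_sequence(f)
        if t.structured:
            s, e = t.planted_local[0]
            planted_mfes.append(fold_mfe(seq.subsequence(s, e), model).mfe)
        else:
            background_mfes.append(
                fold_mfe(seq.subsequence(10, 64), model).mfe)
    assert np.mean(planted_mfes) < np.mean(background_mfes) - 20


def test_truth_is_exhaustive_and_positionally_biased():
    cfg = _small_config()
    ds = build_synthetic_genome(cfg)
    for f in ds.features:
        t = ds.truth.features[f.feature_id]
        assert t.category in ("gene", "RLC", "DHH", "control")
        for s, e in t.planted_local:
            assert 0 <= s < e <= f.length
        assert t.structured == bool(t.planted_local)
        if t.category == "control":
            assert not t.structured
        if t.category == "RLC" and t.structured:
            assert t.planted_local[0][0] <= 50  # LTR-proximal
        if t.category == "DHH" and t.structured:
            assert t.planted_local[0][1] >= f.length - 64  # 3'-proximal


def test_smrna_species_have_configured_length():
    cfg = _small_config()
    cfg.n_libraries = 1
    libs = simulate_smrna_libraries(build_synthetic_genome(cfg), cfg)
    for (lib, k), df in libs.items():
        assert (df["sequence"].str.len() == k).all()
        assert (df["count"] >= 1).all()


def test_methylome_counts_and_flat_under_zero_boost():
    cfg = _small_config()
    cfg.chh_boost = 0.05  # equal to the baseline -> flat profile
    ds = build_synthetic_genome(cfg)
    meth = simulate_methylome(ds, cfg)
    assert (meth["meth"] <= meth["total"]).all()
    assert set(meth["context"].unique()) <= {"CG", "CHG", "CHH"}
    chh = meth[meth["context"] == "CHH"]
    level = chh["meth"].sum() / chh["total"].sum()
    assert level == pytest.approx(0.05, abs=0.01)


def test_expression_panel_shapes_and_multiplier(rng):
    cfg = _small_config()
    cfg.categories["gene"] = CategoryConfig(
        n=400, structured_fraction=0.5, true_skew=0.8)
    cfg.structured_multiplier = 1.5
    ds = build_synthetic_genome(cfg)
    tissue, line = simulate_expression_panel(ds, cfg)
    assert tissue.shape[1] == 23
    assert line.shape[1] == 26
    structured = np.array([ds.truth.features[g].structured
                           for g in tissue.index])
    ratio = tissue.to_numpy()[structured].mean() / \
        tissue.to_numpy()[~structured].mean()
    assert ratio == pytest.approx(1.5, rel=0.25)


def test_config_validation():
    cfg = SyntheticConfig(gc_fraction=1.5)
    with pytest.raises(InputError):
        cfg.validate()
    cfg = SyntheticConfig()
    cfg.categories["gene"].true_skew = 1.0
    with pytest.raises(InputError):
        cfg.validate()
    cfg = SyntheticConfig(stem_length=200)
    with pytest.raises(InputError):
        cfg.validate()
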