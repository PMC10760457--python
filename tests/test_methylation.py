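import numpy as np
import pandas as pd
import pytest

from mirstruct.methylation import (MethylationData, assign_context,
                                   draw_control_window, feature_landscape,
                                   methylation_metaprofile,
                                   overlap_enrichment, weighted_methylation)
from mirstruct.seqs import InputError


def _meth(rows):
    return MethylationData(pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth", "total"]))


def test_weighted_level_is_read_weighted():
    m = _meth([("c", 5, "+", "CHH", 3, 10), ("c", 8, "+", "CHH", 1, 10)])
    assert weighted_methylation(m, "c", 0, 20, "CHH") == pytest.approx(0.2)


def test_fully_methylated_region_is_one():
    m = _meth([("c", 1, "+", "CG", 7, 7), ("c", 4, "-", "CG", 3, 3)])
    assert weighted_methylation(m, "c", 0, 10, "CG") == pytest.approx(1.0)


def test_uniform_coverage_equals_unweighted_mean():
    rows = [("c", i, "+", "CHH", i % 5, 10) for i in range(10)]
    m = _meth(rows)
    level = weighted_methylation(m, "c", 0, 10, "CHH")
    assert level == pytest.approx(np.mean([r[4] / 10 for r in rows]))


def test_uncovered_region_is_missing_not_zero():
    m = _meth([("c", 5, "+", "CG", 3, 10)])
    assert np.isnan(weighted_methylation(m, "c", 100, 200, "CG"))
    assert np.isnan(weighted_methylation(m, "c", 0, 20, "CHH"))


def test_meth_cannot_exceed_total():
    with pytest.raises(InputError):
        _meth([("c", 1, "+", "CG", 5, 3)])


@pytest.mark.parametrize("seq,pos,strand,expect", [
    ("ACGT", 1, "+", "CG"),
    ("ACAGT", 1, "+", "CHG"),
    ("ACAAT", 1, "+", "CHH"),
    ("ACGT", 2, "-", "CG"),      # G on forward = C on minus, CpG symmetric
    ("CAGAA", 2, "-", "CHG"),
    ("TAGAA", 2, "-", "CHH"),
    ("ACGT", 0, "+", None),      # not a C context query on A
    ("AAC", 2, "+", None),       # undecidable at the edge
])
def test_context_assignment(seq, pos, strand, expect):
    assert assign_context(seq, pos, strand) == expect


def test_metaprofile_has_40_flank_windows():
    rows = [("c", i, "+", "CHH", 1, 10) for i in range(0, 5000, 7)]
    m = _meth(rows)
    prof = methylation_metaprofile([("c", 2300, 2400)], m, {"c": 5000})
    assert prof.n_flank_windows == 40
    assert len(prof.slots) == 41
    assert prof.slots[20] == "center"


def test_metaprofile_detects_planted_center_boost(rng):
    rows = []
    regions = []
    for r in range(60):
        offset = r * 6000
        regions.append(("c", offset + 2500, offset + 2600))
        for p in range(offset, offset + 5200, 3):
            inside = offset + 2500 <= p < offset + 2600
            rate = 0.30 if inside else 0.05
            total = 10
            rows.append(("c", p, "+", "CHH", rng.binomial(total, rate), total))
    m = _meth(rows)
    prof = methylation_metaprofile(regions, m, {"c": 60 * 6000})
    center = prof.mean_level[20]
    flanks = np.delete(prof.mean_level, 20)
    assert center > np.nanmax(flanks)
    assert prof.center_vs_flank_p < 0.01


def test_metaprofile_truncates_at_sequence_ends():
    rows = [("c", i, "+", "CHH", 1, 4) for i in range(0, 600, 5)]
    m = _meth(rows)
    prof = methylation_metaprofile([("c", 100, 150)], m, {"c": 600})
    # only one region, close to the start: upstream windows beyond the
    # sequence are missing
    assert prof.n_regions[0] == 0    # up20 window would start at -1900
    assert prof.n_regions[20] == 1   # centre is covered


def test_control_window_properties():
    iv = draw_control_window(0, 1000, 450, 550, seed=5)
    assert iv is not None
    s, e = iv
    assert e - s == 100
    assert e <= 450 or s >= 550
    assert 0 <= s and e <= 1000
    assert draw_control_window(0, 1000, 450, 550, seed=5) == iv  # determinism


def test_control_window_refuses_majority_coverage():
    assert draw_control_window(0, 100, 20, 80, seed=1) is None
    # regions covering 60% of the feature in aggregate
    assert draw_control_window(0, 1000, 0, 100, seed=1,
                               all_regions=[(0, 300), (400, 700)]) is None


def test_landscape_examples():
    counts = feature_landscape([("f", 200, "+")], {"f": [(0, 50)]})
    assert counts[:25].tolist() == [1] * 25
    assert counts[25:].sum() == 0
    counts = feature_landscape([("f", 200, "+")], {"f": [(0, 200)]})
    assert counts.tolist() == [1] * 100
    # minus strand: a region at the genomic end maps to 5' bins
    counts = feature_landscape([("f", 200, "-")], {"f": [(150, 200)]})
    assert counts[:25].tolist() == [1] * 25
    assert counts[25:].sum() == 0


def test_landscape_counts_bounded_by_feature_number():
    feats = [(f"f{i}", 100, "+") for i in range(5)]
    regions = {f"f{i}": [(0, 100)] for i in range(5)}
    counts = feature_landscape(feats, regions)
    assert counts.max() == 5


def test_enrichment_fold_example():
    targets = [("c", 0, 10_000)]  # 10% of a 100-kb space
    items = [("c", 5, 6)] * 50 + [("c", 50_000, 50_001)] * 50
    res = overlap_enrichment(items, targets, {"c": 100_000})
    assert res.covered_fraction == pytest.approx(0.10)
    assert res.observed_overlapping == 50
    assert res.expected_overlapping == pytest.approx(10.0)
    assert res.fold == pytest.approx(5.0)


def test_enrichment_zero_items_fold_undefined():
    res = overlap_enrichment([], [("c", 0, 10)], {"c": 100})
    assert res.observed_overlapping == 0
    assert res.expected_overlapping == 0
    assert np.isnan(res.fold)
    with pytest.raises(InputError):
        overlap_enrichment([("c", 0, 1)], [], {"c": 0})
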