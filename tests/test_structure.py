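import numpy as np
import pytest

from mirstruct.ensemble import EnsembleResult
from mirstruct.fold import WindowProfile
from mirstruct.seqs import InputError
from mirstruct.structure import (HairpinCall, bh_adjust, call_lowmfe_regions,
                                 call_lp_hairpins, classify_feature, q_norm,
                                 rf_structured_test)


def _profile(mfes, wsize=110, fid="f"):
    mfes = np.asarray(mfes, dtype=float)
    return WindowProfile(fid, wsize, 1, np.arange(len(mfes)), mfes,
                         length=len(mfes) + wsize - 1)


# ----------------------------------------------------------- lowMFE regions

def test_lowmfe_merges_overlapping_windows():
    regs = call_lowmfe_regions(_profile([-45, -45, -20, -41]), threshold=-40)
    assert len(regs) == 1
    assert (regs[0].start, regs[0].end) == (0, 113)
    assert regs[0].min_window_mfe == -45


def test_lowmfe_empty_when_nothing_qualifies():
    assert call_lowmfe_regions(_profile([-10, -39.9, 0]), -40) == []


def test_lowmfe_single_window_region():
    mfes = np.zeros(20)
    mfes[7] = -41
    regs = call_lowmfe_regions(_profile(mfes), -40)
    assert [(r.start, r.end) for r in regs] == [(7, 117)]


def test_lowmfe_matches_per_position_coverage_oracle(rng):
    """Union of reported regions == naive per-position union of qualifying
    window intervals."""
    for _ in range(20):
        mfes = rng.uniform(-60, 0, size=rng.integers(5, 80))
        wsize = int(rng.integers(5, 30))
        prof = _profile(mfes, wsize=wsize)
        regs = call_lowmfe_regions(prof, threshold=-40)
        covered = np.zeros(len(mfes) + wsize - 1, dtype=bool)
        for s, m in enumerate(mfes):
            if m < -40:
                covered[s:s + wsize] = True
        reported = np.zeros_like(covered)
        for r in regs:
            assert r.end - r.start >= wsize
            reported[r.start:r.end] = True
        assert np.array_equal(covered, reported)


# ------------------------------------------------------- RF-structured test

def test_rf_test_complete_separation():
    obs = _profile(np.full(300, -50.0))
    shuf = [_profile(np.full(300, -10.0)) for _ in range(5)]
    assert rf_structured_test(obs, shuf) < 1e-6


def test_rf_test_exchangeable_null(rng):
    vals = rng.normal(-30, 5, size=300)
    obs = _profile(vals)
    shuf = [_profile(rng.permutation(vals)) for _ in range(5)]
    assert rf_structured_test(obs, shuf) >= 0.3


def test_rf_test_minmfe_mode_rank_formula():
    obs = _profile([-50, -60, -40])
    shuf = [_profile([-30 - k, -20, -10]) for k in range(5)]
    assert rf_structured_test(obs, shuf, mode="minmfe") == pytest.approx(1 / 6)


def test_rf_test_rejects_mismatched_window_counts():
    with pytest.raises(InputError):
        rf_structured_test(_profile([-1, -2]), [_profile([-1, -2, -3])])


# ------------------------------------------------------------ BH adjustment

def test_bh_stepup_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]),
                       [0.05] * 5)
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([0.001, 1.0]), [0.002, 1.0])


def test_bh_dominates_raw_and_validates(rng):
    p = rng.uniform(size=50)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    with pytest.raises(InputError):
        bh_adjust([0.5, 1.5])


def test_classification_requires_both_conditions():
    assert classify_feature(True, 0.01)
    assert not classify_feature(False, 1e-10)
    assert not classify_feature(True, 0.06)


def test_q_norm():
    assert q_norm(-100.0, 1000) == pytest.approx(-0.1)
    assert q_norm(0.0, 57) == 0.0
    assert q_norm(-3.3, 110) == pytest.approx(-0.03)
    with pytest.raises(InputError):
        q_norm(-1.0, 0)


# ------------------------------------------------------------- LP-hairpins

def _stem_matrix(n, pairs, prob=1.0):
    pp = np.zeros((n, n))
    for i, j in pairs:
        pp[i, j] = pp[j, i] = prob
    return EnsembleResult("hp", n, 0.0, pp)


def _perfect_stem(stem, loop=4):
    n = 2 * stem + loop
    pairs = [(i, n - 1 - i) for i in range(stem)]
    return _stem_matrix(n, pairs)


def test_perfect_25bp_stem_yields_two_arm_calls():
    calls = call_lp_hairpins(_perfect_stem(25))
    assert len(calls) == 2
    arms = sorted((c.start, c.end) for c in calls)
    assert arms == [(0, 25), (29, 54)]
    for c in calls:
        assert c.span == 25
        assert c.mismatch_total == 0
        assert c.asym_mismatch_total == 0
    # arms cross-reference each other
    a, b = sorted(calls, key=lambda c: c.start)
    assert (a.partner_start, a.partner_end) == (29, 54)
    assert (b.partner_start, b.partner_end) == (0, 25)


def test_20bp_stem_below_min_span_gives_no_calls():
    assert call_lp_hairpins(_perfect_stem(20)) == []


def test_symmetric_5nt_internal_loop_breaks_the_budget():
    # 24-bp stem interrupted after 12 bp by a 5-nt loop on both arms
    stem, gap = 24, 5
    n = 2 * (stem + gap) + 4
    pairs = []
    for i in range(12):
        pairs.append((i, n - 1 - i))
    for i in range(12, 24):
        pairs.append((i + gap, n - 1 - i - gap))
    calls = call_lp_hairpins(_stem_matrix(n, pairs))
    assert calls == []  # each clean half is only 12 nt, budget split rejects


def test_small_symmetric_loop_accumulates_mismatches():
    # 24-bp stem with a 2-nt symmetric interior loop: mismatch 2, asym 0
    stem, gap = 24, 2
    n = 2 * (stem + gap) + 4
    pairs = []
    for i in range(12):
        pairs.append((i, n - 1 - i))
    for i in range(12, 24):
        pairs.append((i + gap, n - 1 - i - gap))
    calls = call_lp_hairpins(_stem_matrix(n, pairs))
    assert len(calls) == 2
    assert all(c.mismatch_total == 2 and c.asym_mismatch_total == 0
               for c in calls)
    assert all(c.span == 26 for c in calls)


def test_no_confident_pairs_no_calls():
    ens = _stem_matrix(60, [(i, 59 - i) for i in range(25)], prob=0.5)
    assert call_lp_hairpins(ens, p_min=0.90) == []


def test_emitted_calls_satisfy_type_invariants(rng):
    """Re-assert every invariant post hoc from the matrix on noisy input."""
    n = 120
    pp = np.zeros((n, n))
    for i in range(30):
        pp[i, n - 1 - i] = pp[n - 1 - i, i] = rng.uniform(0.85, 1.0)
    ens = EnsembleResult("x", n, 0.0, pp)
    for c in call_lp_hairpins(ens):
        assert c.span >= 21
        assert c.mismatch_total <= 4
        assert c.asym_mismatch_total <= 2
        assert ens.pair_prob[c.start].max() > 0.90
        assert ens.pair_prob[c.end - 1].max() > 0.90
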