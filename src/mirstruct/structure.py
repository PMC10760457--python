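"""Turning folding output into structure annotations.

Three annotations are produced per feature:

* **lowMFE regions** — maximal merges of overlapping sliding windows whose
  MFE falls below a stability threshold (default -40 kcal/mol, the
  empirical cutoff below which pre-miRNA-sized windows typically fall);
* **RF-structured classification** — a feature is called structured when it
  both contains at least one sub-threshold window and its window-MFE
  distribution is significantly lower than that of composition-preserving
  shuffles (one-sided Wilcoxon rank-sum, Benjamini-Hochberg corrected
  across the cohort);
* **hairpin calls** — runs of confidently pairing bases (pairing
  probability > 0.90) at least 21 nt long, with miRNA-annotation mismatch
  tolerances: at most 4 mismatched nucleotides overall and at most 2 in
  asymmetric bulges.  Both arms of a stem are emitted, cross-referencing
  each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ensemble import EnsembleResult
from .fold import WindowProfile
from .seqs import InputError

DEFAULT_MFE_THRESHOLD = -40.0
DEFAULT_ALPHA = 0.05
DEFAULT_P_MIN = 0.90
DEFAULT_MIN_SPAN = 21
DEFAULT_MAX_MISMATCH = 4
DEFAULT_MAX_ASYM = 2


@dataclass(frozen=True)
class LowMFERegion:
    """Merged span of overlapping sub-threshold windows (feature-local,
    0-based half-open)."""

    feature_id: str
    start: int
    end: int
    min_window_mfe: float


@dataclass(frozen=True)
class HairpinCall:
    """One stem arm of a confidently pairing hairpin."""

    feature_id: str
    start: int
    end: int  # half-open
    mismatch_total: int
    asym_mismatch_total: int
    partner_start: int
    partner_end: int
    mean_pair_prob: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class StructureSummary:
    feature_id: str
    length: int
    min_mfe: float
    mean_mfe: float
    q: float
    q_norm: float
    has_low_window: bool
    p_raw: float
    p_adj: float = float("nan")
    rf_structured: bool = False
    n_lowmfe_regions: int = 0
    n_hairpins: int = 0
    category: str = ""


def call_lowmfe_regions(
    profile: WindowProfile,
    threshold: float = DEFAULT_MFE_THRESHOLD,
) -> list[LowMFERegion]:
    """Merge overlapping windows with MFE strictly below ``threshold``.

    Each qualifying window contributes [start, start + window_size);
    overlapping (and, at step 1, necessarily abutting) intervals merge.
    """
    if profile.n_windows == 0:
        raise InputError("empty window profile")
    wsize = profile.window_size if not profile.short_feature else profile.length
    mask = profile.window_mfes < threshold
    regions: list[LowMFERegion] = []
    cur_start = cur_end = None
    cur_min = 0.0
    for start, mfe in zip(profile.starts[mask], profile.window_mfes[mask]):
        s, e = int(start), int(start) + wsize
        if cur_start is None:
            cur_start, cur_end, cur_min = s, e, mfe
        elif s <= cur_end:  # overlap (or bookended) -> extend
            cur_end = max(cur_end, e)
            cur_min = min(cur_min, mfe)
        else:
            regions.append(LowMFERegion(profile.feature_id, cur_start,
                                        cur_end, float(cur_min)))
            cur_start, cur_end, cur_min = s, e, mfe
    if cur_start is not None:
        regions.append(LowMFERegion(profile.feature_id, cur_start, cur_end,
                                    float(cur_min)))
    return regions


def rf_structured_test(
    observed: WindowProfile,
    shuffled: list[WindowProfile],
    mode: str = "windows",
) -> float:
    """Raw one-sided p-value for 'observed folds lower than shuffles'.

    mode='windows' (default): Wilcoxon rank-sum of the observed window-MFE
    distribution against the pooled shuffled window MFEs (alternative:
    observed lower).  mode='minmfe': empirical rank of the observed minMFE
    among the k shuffle minima, p = (1 + #{shuffle min <= observed min})
    / (k + 1); with the canonical k = 5 this cannot fall below 1/6, which
    is why the window-distribution mode is the default.
    """
    if not shuffled:
        raise InputError("need at least one shuffled profile")
    for sh in shuffled:
        if sh.n_windows != observed.n_windows:
            raise InputError(
                "shuffled profile window count does not match the observed "
                f"profile ({sh.n_windows} vs {observed.n_windows})")
    if mode == "windows":
        pooled = np.concatenate([sh.window_mfes for sh in shuffled])
        if np.all(observed.window_mfes == pooled[0]) and np.all(pooled == pooled[0]):
            return 1.0
        res = stats.mannwhitneyu(observed.window_mfes, pooled,
                                 alternative="less")
        return float(res.pvalue)
    if mode == "minmfe":
        k = len(shuffled)
        n_le = sum(1 for sh in shuffled if sh.min_mfe <= observed.min_mfe)
        return (1 + n_le) / (k + 1)
    raise InputError(f"unknown mode {mode!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_feature(
    has_low_window: bool,
    p_adj: float,
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """RF-structured iff a sub-threshold window exists AND p_adj < alpha."""
    return bool(has_low_window) and (p_adj < alpha)


def q_norm(q: float, length: int) -> float:
    """Ensemble free energy per nucleotide (kcal/mol per nt)."""
    if length < 1:
        raise InputError("length must be >= 1")
    return q / length


def calibrate_mfe_threshold(
    shuffled_profiles: list[WindowProfile],
    quantile: float = 0.005,
) -> float:
    """Data-driven stability threshold for non-Turner energy models.

    The canonical -40 kcal/mol cutoff presumes Turner energies; for the
    built-in model a threshold is set at a low quantile of the pooled
    window-MFE distribution of composition-preserving shuffles, so that
    essentially no shuffled window qualifies while planted stems do.
    """
    pooled = np.concatenate([p.window_mfes for p in shuffled_profiles])
    return float(np.quantile(pooled, quantile))


def _segment_runs(qual: np.ndarray, partner: np.ndarray):
    """Split qualified positions into candidate arm segments.

    A segment extends while (a) partners strictly decrease along the arm
    and (b) the partner stays on the same side of the diagonal (a sign
    change of partner - position marks the loop between the two arms).
    """
    idx = np.flatnonzero(qual)
    segments: list[list[int]] = []
    cur: list[int] = []
    for pos in idx:
        if not cur:
            cur = [pos]
            continue
        prev = cur[-1]
        same_side = (partner[pos] > pos) == (partner[prev] > prev)
        if partner[pos] < partner[prev] and same_side:
            cur.append(pos)
        else:
            segments.append(cur)
            cur = [pos]
    if cur:
        segments.append(cur)
    return segments


def call_lp_hairpins(
    ensemble: EnsembleResult,
    p_min: float = DEFAULT_P_MIN,
    min_span: int = DEFAULT_MIN_SPAN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_asym: int = DEFAULT_MAX_ASYM,
) -> list[HairpinCall]:
    """Hairpin arms from the base-pair probability matrix.

    A position qualifies when its maximum pairing probability exceeds
    ``p_min`` (argmax partner; ties resolved toward the smaller index).
    Qualified positions are segmented into arms (strictly decreasing,
    same-side partners); internal blocks of unqualified positions between
    qualified neighbours accumulate mismatches: with flanking partners
    q_prev > q_next, the block of length g on this arm spans
    q_prev - q_next - 1 positions on the opposite arm, contributing
    max(g, gap_partner) mismatches of which |g - gap_partner| are
    asymmetric.  A gap that would push a candidate past
    ``max_mismatch`` / ``max_asym`` closes the candidate before the gap
    and restarts after it, so a clean stem flanked by noisy pairing
    context is still reported.  Calls must span >= ``min_span``.
    """
    pp = ensemble.pair_prob
    n = ensemble.length
    if pp.shape != (n, n):
        raise InputError("pair-probability matrix does not match length")
    if n == 0:
        return []
    maxp = pp.max(axis=1)
    partner = pp.argmax(axis=1)
    qual = maxp > p_min
    calls: list[HairpinCall] = []

    def emit(first, last, mismatch, asym):
        span = last - first + 1
        if span >= min_span:
            idx = [p for p in range(first, last + 1) if qual[p]]
            calls.append(HairpinCall(
                feature_id=ensemble.feature_id,
                start=int(first), end=int(last) + 1,
                mismatch_total=int(mismatch), asym_mismatch_total=int(asym),
                partner_start=int(partner[last]),
                partner_end=int(partner[first]) + 1,
                mean_pair_prob=float(maxp[idx].mean()),
            ))

    for seg in _segment_runs(qual, partner):
        cand_start = seg[0]
        mismatch = 0
        asym = 0
        prev = seg[0]
        for b in seg[1:]:
            gap_arm = b - prev - 1
            if gap_arm > 0:
                gap_partner = int(partner[prev]) - int(partner[b]) - 1
                add_mm = max(gap_arm, gap_partner)
                add_as = abs(gap_arm - gap_partner)
                if mismatch + add_mm > max_mismatch \
                        or asym + add_as > max_asym:
                    # budget exceeded: close the candidate before the gap
                    emit(cand_start, prev, mismatch, asym)
                    cand_start, mismatch, asym = b, 0, 0
                else:
                    mismatch += add_mm
                    asym += add_as
            prev = b
        emit(cand_start, prev, mismatch, asym)
    return calls


def summarize_structures(
    profiles: dict[str, WindowProfile],
    ensembles: dict[str, EnsembleResult],
    shuffled: dict[str, list[WindowProfile]],
    threshold: float = DEFAULT_MFE_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "windows",
    hairpin_params: dict | None = None,
) -> tuple[dict[str, StructureSummary], dict[str, list[LowMFERegion]],
           dict[str, list[HairpinCall]]]:
    """Cohort-level structure summary: p-values BH-corrected across ALL
    features in the run, as required for the structured/unstructured call."""
    hairpin_params = hairpin_params or {}
    ids = list(profiles)
    p_raw = np.array([
        rf_structured_test(profiles[fid], shuffled[fid], mode=mode)
        for fid in ids
    ])
    p_adj = bh_adjust(p_raw)
    summaries: dict[str, StructureSummary] = {}
    regions: dict[str, list[LowMFERegion]] = {}
    hairpins: dict[str, list[HairpinCall]] = {}
    for fid, pr, pa in zip(ids, p_raw, p_adj):
        prof = profiles[fid]
        regs = call_lowmfe_regions(prof, threshold)
        regions[fid] = regs
        ens = ensembles.get(fid)
        if ens is not None:
            hps = call_lp_hairpins(ens, **hairpin_params)
            qval = ens.q
            qn = q_norm(qval, ens.length)
        else:
            hps = []
            qval = float("nan")
            qn = float("nan")
        hairpins[fid] = hps
        has_low = bool(np.any(prof.window_mfes < threshold))
        summaries[fid] = StructureSummary(
            feature_id=fid, length=prof.length,
            min_mfe=prof.min_mfe, mean_mfe=prof.mean_mfe,
            q=qval, q_norm=qn, has_low_window=has_low,
            p_raw=float(pr), p_adj=float(pa),
            rf_structured=classify_feature(has_low, pa, alpha),
            n_lowmfe_regions=len(regs), n_hairpins=len(hps),
        )
    return summaries, regions, hairpins
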