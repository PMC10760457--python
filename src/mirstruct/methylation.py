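"""Weighted methylation levels, hairpin-centred metaprofiles, structure
landscapes, and observed-vs-expected overlap enrichment.

The weighted methylation level of a region is the read-weighted fraction
sum(methylated reads) / sum(total reads) over the region's cytosines of a
given context (CG symmetric; CHG/CHH strand-specific, H = A/C/T).  Regions
with no covered cytosine of the context yield a *missing* value, never 0.

Metaprofiles centre on miRNA-like regions: one centre slot plus 2-kb
flanks divided into 40 non-overlapping 100-bp windows (20 per side),
averaged (unweighted) across regions, with matched random same-size
within-feature control windows available for contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqs import InputError

DEFAULT_FLANK = 2000
DEFAULT_METH_WINDOW = 100
DEFAULT_BINS = 100
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class MethylationData:
    """Per-cytosine methylation calls in long form.

    Columns: chrom, pos (0-based), strand, context, meth, total.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "strand", "context", "meth", "total"}
        missing = need - set(self.frame.columns)
        if missing:
            raise InputError(f"methylation table missing columns {missing}")
        bad = self.frame["meth"] > self.frame["total"]
        if bad.any():
            raise InputError("meth read count exceeds total read count")
        self._index: dict = {}

    def _range_sums(self, chrom: str, context: str):
        """Sorted positions with meth/total prefix sums (lazy, cached)."""
        key = (chrom, context)
        if key not in self._index:
            df = self.frame
            sel = df[(df["chrom"] == chrom) & (df["context"] == context)
                     & (df["total"] > 0)]
            pos = sel["pos"].to_numpy(dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            meth = np.concatenate([[0], np.cumsum(
                sel["meth"].to_numpy(dtype=np.int64)[order])])
            total = np.concatenate([[0], np.cumsum(
                sel["total"].to_numpy(dtype=np.int64)[order])])
            self._index[key] = (pos, meth, total)
        return self._index[key]


def assign_context(sequence: str, pos: int, strand: str) -> str | None:
    """Sequence context (CG/CHG/CHH) of a cytosine from the reference.

    For strand '-', the cytosine appears as G on the forward reference and
    the context is read 3'->5' on the complement.
    """
    s = sequence.upper().replace("U", "T")
    n = len(s)
    if strand == "+":
        if s[pos] != "C":
            return None
        if pos + 1 < n and s[pos + 1] == "G":
            return "CG"
        if pos + 2 >= n:
            return None  # CHG vs CHH undecidable at the sequence edge
        return "CHG" if s[pos + 2] == "G" else "CHH"
    else:
        if s[pos] != "G":
            return None
        if pos - 1 >= 0 and s[pos - 1] == "C":
            return "CG"
        if pos - 2 >= 0 and s[pos - 2] == "C":
            return "CHG"
        return "CHH" if pos - 2 >= 0 else None


def weighted_methylation(
    meth: MethylationData,
    chrom: str,
    start: int,
    end: int,
    context: str = "CHH",
) -> float:
    """Read-weighted methylation level of [start, end); NaN when uncovered."""
    pos, meth_cum, total_cum = meth._range_sums(chrom, context)
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    if hi <= lo:
        return float("nan")
    total = total_cum[hi] - total_cum[lo]
    if total == 0:
        return float("nan")
    return float((meth_cum[hi] - meth_cum[lo]) / total)


@dataclass
class Metaprofile:
    """Mean methylation in the centre slot and the 40 flank windows."""

    slots: list[str]                # 'up20'...'up1', 'center', 'down1'...
    mean_level: np.ndarray
    n_regions: np.ndarray           # non-missing contributions per slot
    control_mean_level: np.ndarray | None = None
    center_vs_flank_p: float = float("nan")

    @property
    def n_flank_windows(self) -> int:
        return len(self.slots) - 1

    def frame(self) -> pd.DataFrame:
        d = {"slot": self.slots, "mean_level": self.mean_level,
             "n": self.n_regions}
        if self.control_mean_level is not None:
            d["control_mean_level"] = self.control_mean_level
        return pd.DataFrame(d)


def _region_profile(meth, chrom, start, end, chrom_len, flank, window,
                    context):
    n_side = flank // window
    vals = []
    for w in range(n_side, 0, -1):
        ws, we = start - w * window, start - (w - 1) * window
        vals.append(weighted_methylation(meth, chrom, ws, we, context)
                    if ws >= 0 else float("nan"))
    vals.append(weighted_methylation(meth, chrom, start, end, context))
    for w in range(1, n_side + 1):
        ws, we = end + (w - 1) * window, end + w * window
        vals.append(weighted_methylation(meth, chrom, ws, we, context)
                    if we <= chrom_len else float("nan"))
    return np.array(vals)


def methylation_metaprofile(
    regions,
    meth: MethylationData,
    chrom_lengths: dict[str, int],
    flank: int = DEFAULT_FLANK,
    window: int = DEFAULT_METH_WINDOW,
    context: str = "CHH",
    control_regions=None,
) -> Metaprofile:
    """Average methylation profile across regions (centre + flank windows).

    ``regions`` is an iterable of (chrom, start, end).  Windows running
    off a sequence end are missing for that region.  The paired
    centre-vs-flank t-test compares, per region, the centre level against
    the mean of that region's non-missing flank windows.
    """
    flank = int(flank)
    window = int(window)
    if flank % window != 0:
        raise InputError("flank must be a multiple of the window size")
    n_side = flank // window
    mat = np.array([
        _region_profile(meth, c, s, e, chrom_lengths[c], flank, window,
                        context)
        for c, s, e in regions
    ])
    if mat.size == 0:
        raise InputError("no regions supplied")
    slots = [f"up{w}" for w in range(n_side, 0, -1)] + ["center"] + \
        [f"down{w}" for w in range(1, n_side + 1)]
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_level = np.nanmean(mat, axis=0)
    n_regions = np.sum(~np.isnan(mat), axis=0)
    center_idx = n_side
    centers = mat[:, center_idx]
    flanks = np.delete(mat, center_idx, axis=1)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        flank_means = np.nanmean(flanks, axis=1)
    ok = ~np.isnan(centers) & ~np.isnan(flank_means)
    if ok.sum() >= 2 and np.ptp(centers[ok] - flank_means[ok]) > 0:
        p = float(stats.ttest_rel(centers[ok], flank_means[ok],
                                  alternative="greater").pvalue)
    else:
        p = float("nan")
    control_mean = None
    if control_regions is not None:
        ctrl = methylation_metaprofile(control_regions, meth, chrom_lengths,
                                       flank, window, context)
        control_mean = ctrl.mean_level
    return Metaprofile(slots, mean_level, n_regions, control_mean, p)


def draw_control_window(
    feature_start: int,
    feature_end: int,
    region_start: int,
    region_end: int,
    seed: int,
    all_regions=None,
) -> tuple[int, int]:
    """Random same-size within-feature interval not overlapping the region.

    Refuses (returns ``None``) when miRNA-like regions cover more than half
    of the feature, or when no non-overlapping placement exists.
    ``all_regions`` (if given) lists every miRNA-like interval of the
    feature for the >50% coverage rule.
    """
    size = region_end - region_start
    flen = feature_end - feature_start
    regions = list(all_regions) if all_regions is not None \
        else [(region_start, region_end)]
    covered = sum(min(e, feature_end) - max(s, feature_start)
                  for s, e in regions
                  if min(e, feature_end) > max(s, feature_start))
    if covered * 2 > flen:
        return None
    # legal start positions: window fully inside feature, no overlap
    starts = [s for s in range(feature_start, feature_end - size + 1)
              if s + size <= region_start or s >= region_end]
    if not starts:
        return None
    rng = np.random.default_rng(seed)
    s = int(starts[rng.integers(len(starts))])
    return s, s + size


def feature_landscape(
    features,
    regions_by_feature: dict[str, list[tuple[int, int]]],
    bins: int = DEFAULT_BINS,
) -> np.ndarray:
    """Positional bias of structured regions along features, 5'->3'.

    Each feature is split into ``bins`` equal proportional bins; a bin
    increments by 1 when >= 1 region overlaps it; counts are summed over
    features.  ``features`` is an iterable of (feature_id, length, strand)
    with regions in feature-local coordinates on the forward strand;
    minus-strand features are flipped so bin 1 is the biological 5' end.
    """
    counts = np.zeros(bins, dtype=np.int64)
    for feature_id, length, strand in features:
        regions = regions_by_feature.get(feature_id, [])
        if not regions:
            continue
        hit = np.zeros(bins, dtype=bool)
        for s, e in regions:
            s = max(0, s)
            e = min(length, e)
            if e <= s:
                continue
            b0 = int(s * bins // length)
            b1 = int(math.ceil(e * bins / length)) - 1
            hit[b0:b1 + 1] = True
        if strand == "-":
            hit = hit[::-1]
        counts += hit
    return counts


@dataclass(frozen=True)
class EnrichmentResult:
    n_items: int
    observed_overlapping: int
    expected_overlapping: float
    covered_fraction: float

    @property
    def fold(self) -> float:
        if self.expected_overlapping == 0:
            return float("nan")
        return self.observed_overlapping / self.expected_overlapping


def overlap_enrichment(items, target_regions, assayed_space) -> EnrichmentResult:
    """Observed vs expected overlap of items with target regions.

    ``items``: (chrom, start, end) intervals (points are 1-nt intervals).
    ``assayed_space``: dict chrom -> total assayed bp (or list of
    (chrom, start, end) intervals).  Expected = n_items x fraction of the
    assayed space covered by targets, i.e. the uniform-placement null.
    """
    targets = sorted((c, int(s), int(e)) for c, s, e in target_regions)
    if isinstance(assayed_space, dict):
        total_bp = sum(assayed_space.values())
    else:
        total_bp = sum(e - s for _, s, e in assayed_space)
    if total_bp <= 0:
        raise InputError("empty assayed space")
    # merge targets per chrom for covered bp
    covered = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in targets:
        by_chrom.setdefault(c, []).append((s, e))
    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, ivs in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        merged_by_chrom[c] = [(s, e) for s, e in merged]
        covered += sum(e - s for s, e in merged)
    items = [(c, int(s), int(e)) for c, s, e in items]
    observed = 0
    for c, s, e in items:
        for ts, te in merged_by_chrom.get(c, []):
            if s < te and e > ts:
                observed += 1
                break
    frac = covered / total_bp
    expected = len(items) * frac
    return EnrichmentResult(len(items), observed, expected, frac)
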