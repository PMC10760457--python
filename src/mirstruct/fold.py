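"""Minimum-free-energy folding and sliding-window scans.

The recursion is a Zuker-style loop decomposition specialised to the
built-in energy model: ``V(i,j)`` is the best energy given ``(i,j)`` pairs
(hairpin / stack / single-branch internal / multiloop cases), helper arrays
``B`` (>=1 branch) and ``M2`` (>=2 branches) carry the multiloop
decomposition, and an exterior pass assembles the final MFE.  The empty
structure (energy 0) is always admissible, so the MFE is never positive.

Kernels are numba-compiled; the per-window cost is O(w^3) in the window
size, which makes genome-feature scans at 1-nt step desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .energy import EnergyModel, pairs_to_dotbracket
from .seqs import InputError, NucleotideSequence

INF = 1e18

DEFAULT_WINDOW = 110
DEFAULT_STEP = 1


@dataclass(frozen=True)
class FoldResult:
    """MFE and one witnessing structure (deterministic traceback)."""

    mfe: float
    structure: str


@dataclass
class WindowProfile:
    """Per-window MFE vector for one feature.

    ``window_mfes[k]`` is the MFE of the window starting at
    ``starts[k]`` (0-based).  Features shorter than the window are folded
    as a single whole-sequence window and flagged ``short_feature``.
    """

    feature_id: str
    window_size: int
    step: int
    starts: np.ndarray
    window_mfes: np.ndarray
    short_feature: bool = False
    length: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.window_mfes)

    @property
    def min_mfe(self) -> float:
        return float(np.min(self.window_mfes))

    @property
    def mean_mfe(self) -> float:
        return float(np.mean(self.window_mfes))


def summarize_profile(profile: WindowProfile) -> tuple[float, float]:
    """(minMFE, meanMFE) of a window profile."""
    if profile.n_windows == 0:
        raise InputError("cannot summarize an empty window profile")
    return profile.min_mfe, profile.mean_mfe


@njit(cache=True)
def _fill_tables(codes, off, n, wpair, hp, bg, ml, min_loop, V, B, M2, W1):
    """Fill DP tables for codes[off:off+n]; tables are n x n, caller-owned."""
    for i in range(n):
        for j in range(n):
            V[i, j] = INF
            B[i, j] = INF
            M2[i, j] = INF
            W1[i, j] = INF
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            ci = codes[off + i]
            cj = codes[off + j]
            v = INF
            if wpair[ci, cj] > 0.0 and span - 1 >= min_loop:
                v = hp  # hairpin loop
                if span >= min_loop + 3:
                    cin = codes[off + i + 1]
                    cjn = codes[off + j - 1]
                    if wpair[cin, cjn] > 0.0 and V[i + 1, j - 1] < INF / 2:
                        st = -(wpair[ci, cj] + wpair[cin, cjn]) / 2.0
                        cand = st + V[i + 1, j - 1]
                        if cand < v:
                            v = cand
                if span >= 2 and W1[i + 1, j - 1] < INF / 2:
                    cand = bg + W1[i + 1, j - 1]
                    if cand < v:
                        v = cand
                if span >= 2 and M2[i + 1, j - 1] < INF / 2:
                    cand = ml + M2[i + 1, j - 1]
                    if cand < v:
                        v = cand
            V[i, j] = v
            # W1: best single helix anywhere inside [i, j]
            w1 = v
            if W1[i + 1, j] < w1:
                w1 = W1[i + 1, j]
            if W1[i, j - 1] < w1:
                w1 = W1[i, j - 1]
            W1[i, j] = w1
            # B (>=1 branch) and M2 (>=2 branches), unpaired bases free
            b = B[i, j - 1]
            m2 = M2[i, j - 1]
            for k in range(i, j - min_loop):
                vk = V[k, j]
                if vk < INF / 2:
                    if vk < b:
                        b = vk
                    if k > i and B[i, k - 1] < INF / 2:
                        cand = B[i, k - 1] + vk
                        if cand < b:
                            b = cand
                        if cand < m2:
                            m2 = cand
            B[i, j] = b
            M2[i, j] = m2


@njit(cache=True)
def _exterior(V, n, min_loop, W):
    """Exterior pass: W[j+1] = best energy over prefix [0, j]."""
    W[0] = 0.0
    for j in range(n):
        best = W[j]
        for k in range(0, j - min_loop):
            if V[k, j] < INF / 2:
                cand = W[k] + V[k, j]
                if cand < best:
                    best = cand
        W[j + 1] = best
    return W[n]


@njit(cache=True)
def _window_mfes(codes, starts, wsize, wpair, hp, bg, ml, min_loop):
    nw = len(starts)
    out = np.empty(nw, dtype=np.float64)
    V = np.empty((wsize, wsize), dtype=np.float64)
    B = np.empty((wsize, wsize), dtype=np.float64)
    M2 = np.empty((wsize, wsize), dtype=np.float64)
    W1 = np.empty((wsize, wsize), dtype=np.float64)
    W = np.empty(wsize + 1, dtype=np.float64)
    for w in range(nw):
        _fill_tables(codes, starts[w], wsize, wpair, hp, bg, ml, min_loop,
                     V, B, M2, W1)
        out[w] = _exterior(V, wsize, min_loop, W)
    return out


def _model_params(model: EnergyModel):
    return (model.weight_matrix, model.hairpin_penalty,
            model.bulge_internal_penalty, model.multiloop_penalty,
            model.min_loop)


def mfe_tables(seq: NucleotideSequence, model: EnergyModel | None = None):
    """DP tables (V, B, M2, W1, W) for a whole sequence; used by traceback
    and by the partition function's scaling heuristic."""
    model = model or EnergyModel()
    n = len(seq)
    wpair, hp, bg, ml, min_loop = _model_params(model)
    V = np.empty((n, n), dtype=np.float64)
    B = np.empty((n, n), dtype=np.float64)
    M2 = np.empty((n, n), dtype=np.float64)
    W1 = np.empty((n, n), dtype=np.float64)
    W = np.empty(n + 1, dtype=np.float64)
    codes = seq.codes
    _fill_tables(codes, 0, n, wpair, hp, bg, ml, min_loop, V, B, M2, W1)
    mfe = _exterior(V, n, min_loop, W)
    return V, B, M2, W1, W, float(mfe)


def _traceback(seq, model, V, B, M2, W1, W):
    """Deterministic left-greedy traceback: scanning 5'->3', prefer pairing,
    and among co-optimal cases prefer hairpin < stack < internal < multiloop."""
    res = seq.residues
    n = len(seq)
    min_loop = model.min_loop
    hp = model.hairpin_penalty
    bg = model.bulge_internal_penalty
    ml = model.multiloop_penalty
    wmat = model.weight_matrix
    codes = seq.codes
    pairs: list[tuple[int, int]] = []
    eps = 1e-9

    def trace_v(i, j):
        pairs.append((i, j))
        v = V[i, j]
        if abs(v - hp) < eps and j - i - 1 >= min_loop:
            return
        if j - i >= min_loop + 3 and wmat[codes[i + 1], codes[j - 1]] > 0:
            st = -(wmat[codes[i], codes[j]] + wmat[codes[i + 1], codes[j - 1]]) / 2.0
            if V[i + 1, j - 1] < INF / 2 and abs(v - (st + V[i + 1, j - 1])) < eps:
                trace_v(i + 1, j - 1)
                return
        if W1[i + 1, j - 1] < INF / 2 and abs(v - (bg + W1[i + 1, j - 1])) < eps:
            trace_w1(i + 1, j - 1, exclude_stack=(i, j))
            return
        if M2[i + 1, j - 1] < INF / 2 and abs(v - (ml + M2[i + 1, j - 1])) < eps:
            trace_m(i + 1, j - 1, need_two=True)
            return
        raise AssertionError("traceback failed in V")

    def trace_w1(i, j, exclude_stack=None):
        # find 5'-most (k, l) with V[k, l] == W1[i, j]
        target = W1[i, j]
        for k in range(i, j):
            for l in range(k + min_loop + 1, j + 1):
                if exclude_stack is not None and (k, l) == (
                        exclude_stack[0] + 1, exclude_stack[1] - 1):
                    continue
                if V[k, l] < INF / 2 and abs(V[k, l] - target) < eps:
                    trace_v(k, l)
                    return
        raise AssertionError("traceback failed in W1")

    def trace_m(i, j, need_two=False):
        # arrangement with >=1 (B) or >=2 (M2) branches on [i, j]
        target = M2[i, j] if need_two else B[i, j]
        # trailing unpaired bases first
        jj = j
        while jj > i:
            arr = M2 if need_two else B
            if arr[i, jj - 1] < INF / 2 and abs(arr[i, jj - 1] - target) < eps:
                jj -= 1
            else:
                break
        # rightmost branch (k, jj)
        for k in range(i, jj - min_loop):
            vk = V[k, jj]
            if vk >= INF / 2:
                continue
            if not need_two and abs(vk - target) < eps:
                trace_v(k, jj)
                return
            if k > i and B[i, k - 1] < INF / 2 and abs(
                    B[i, k - 1] + vk - target) < eps:
                trace_v(k, jj)
                trace_m(i, k - 1, need_two=False)
                return
        raise AssertionError("traceback failed in multiloop arrangement")

    def trace_ext(j):
        # W[j+1] over prefix [0, j]; prefer the 5'-most pairing decision
        while j >= min_loop + 1:
            paired = False
            for k in range(0, j - min_loop):
                if V[k, j] < INF / 2 and abs(W[k] + V[k, j] - W[j + 1]) < eps:
                    trace_v(k, j)
                    j = k - 1
                    paired = True
                    break
            if not paired:
                if abs(W[j + 1] - W[j]) < eps:
                    j -= 1
                else:
                    raise AssertionError("traceback failed in exterior")

    trace_ext(n - 1)
    return pairs


def fold_mfe(seq: NucleotideSequence, model: EnergyModel | None = None) -> FoldResult:
    """Global minimum free energy and one witnessing structure.

    Deterministic: co-optimal structures are resolved by a left-greedy
    traceback (the 5'-most pairing decision wins).
    """
    model = model or EnergyModel()
    n = len(seq)
    if n < model.min_loop + 2:
        return FoldResult(0.0, "." * n)
    V, B, M2, W1, W, mfe = mfe_tables(seq, model)
    if mfe >= -1e-12:
        return FoldResult(0.0, "." * n)
    pairs = _traceback(seq, model, V, B, M2, W1, W)
    return FoldResult(mfe, pairs_to_dotbracket(pairs, n))


def window_scan(
    seq: NucleotideSequence,
    model: EnergyModel | None = None,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> WindowProfile:
    """MFE of every sliding window (default 110 nt, 1-nt step).

    Every nucleotide except the trailing ``window_size - 1`` starts its own
    window.  A feature shorter than the window yields a single
    whole-sequence window flagged ``short_feature``.
    """
    model = model or EnergyModel()
    if window_size < model.min_loop + 2:
        raise InputError("window_size must be >= min_loop + 2")
    n = len(seq)
    wpair, hp, bg, ml, min_loop = _model_params(model)
    if n < window_size:
        _, _, _, _, _, mfe = mfe_tables(seq, model)
        return WindowProfile(
            feature_id=seq.identifier, window_size=window_size, step=step,
            starts=np.array([0]), window_mfes=np.array([mfe]),
            short_feature=True, length=n,
        )
    starts = np.arange(0, n - window_size + 1, step, dtype=np.int64)
    mfes = _window_mfes(seq.codes, starts, window_size, wpair, hp, bg, ml,
                        min_loop)
    return WindowProfile(
        feature_id=seq.identifier, window_size=window_size, step=step,
        starts=starts, window_mfes=mfes, short_feature=False, length=n,
    )
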