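"""McCaskill-style partition function and base-pair probabilities.

Inside pass: ``Zb(i,j)`` sums Boltzmann weights of all structures on
``[i, j]`` in which ``(i, j)`` pair, decomposed (like the MFE recursion)
into hairpin / stack / single-branch internal / multiloop cases, with
helper sums ``C`` (any single helix inside an interval, gap bases
weighted), ``Zm1`` (>=1 branch) and ``Zm2`` (>=2 branches).  An exterior
pass gives the total partition sum Z.

Outside pass: pair probabilities ``P(i,j)`` accumulate the exterior,
stacked, internal-loop and multiloop contexts of each pair.  The multiloop
context, which couples the closing pair's two sides, is handled with
row-wise accumulator arrays so the whole computation stays O(n^3).

To avoid overflow, every quantity over a region of length L is stored
divided by ``scale**L``, with the per-nucleotide scale derived from the
sequence MFE (the dominant Boltzmann weight); the reported ensemble free
energy Q = -RT ln Z is reconstructed exactly from the scaled total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .energy import EnergyModel
from .fold import mfe_tables
from .seqs import InputError, NucleotideSequence


@dataclass
class EnsembleResult:
    """Partition sum, ensemble free energy, and pairing probabilities."""

    feature_id: str
    length: int
    log_z: float
    pair_prob: np.ndarray  # symmetric (n, n)

    @property
    def z(self) -> float:
        try:
            return math.exp(self.log_z)
        except OverflowError:
            return math.inf

    @property
    def q(self) -> float:
        """Ensemble free energy -RT ln Z (kcal/mol), always <= 0."""
        return self._q

    @property
    def max_pair_prob(self) -> np.ndarray:
        return self.pair_prob.max(axis=1)

    @property
    def partner(self) -> np.ndarray:
        """Argmax pairing partner per position (smallest index on ties)."""
        return self.pair_prob.argmax(axis=1)


def _attach_q(res: EnsembleResult, rt: float) -> EnsembleResult:
    res._q = -rt * res.log_z
    return res


@njit(cache=True)
def _pf_inside(codes, n, wpair, hp, bg, ml, min_loop, rt, s1):
    """Scaled inside recursions. s1 = 1/scale (per-nucleotide factor)."""
    expn = np.empty(n + 2)
    expn[0] = 1.0
    for k in range(1, n + 2):
        expn[k] = expn[k - 1] * s1
    eh = math.exp(-hp / rt)
    ebg = math.exp(-bg / rt)
    eml = math.exp(-ml / rt)
    Zb = np.zeros((n, n))
    C = np.zeros((n, n))
    Zm1 = np.zeros((n, n))
    Zm2 = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            ci = codes[i]
            cj = codes[j]
            zb = 0.0
            if wpair[ci, cj] > 0.0 and span - 1 >= min_loop:
                zb = eh * expn[span + 1]  # hairpin
                if span >= min_loop + 3:
                    cin = codes[i + 1]
                    cjn = codes[j - 1]
                    if wpair[cin, cjn] > 0.0:
                        est = math.exp((wpair[ci, cj] + wpair[cin, cjn])
                                       / (2.0 * rt))
                        zb += est * Zb[i + 1, j - 1] * expn[2]
                if span >= 2:
                    zb += ebg * expn[2] * (C[i + 1, j - 1] - Zb[i + 1, j - 1])
                    zb += eml * expn[2] * Zm2[i + 1, j - 1]
            Zb[i, j] = zb
            # C(i,j) = sum over single helices (k,l) in [i,j], flanking
            # unpaired bases carrying the per-nt scale
            c = zb
            c += C[i + 1, j] * s1
            c += C[i, j - 1] * s1
            if span >= 2:
                c -= C[i + 1, j - 1] * s1 * s1
            C[i, j] = c
            # Zm1 / Zm2: multiloop component sums (rightmost-branch split)
            zm1 = Zm1[i, j - 1] * s1
            zm2 = Zm2[i, j - 1] * s1
            for k in range(i, j - min_loop):
                zbk = Zb[k, j]
                if zbk > 0.0:
                    if k == i:
                        zm1 += zbk
                    else:
                        zm1 += (expn[k - i] + Zm1[i, k - 1]) * zbk
                        zm2 += Zm1[i, k - 1] * zbk
            Zm1[i, j] = zm1
            Zm2[i, j] = zm2
    # exterior forward / backward sums
    fwd = np.empty(n + 1)
    fwd[0] = 1.0
    for j in range(n):
        acc = fwd[j] * s1
        for k in range(0, j - min_loop):
            if Zb[k, j] > 0.0:
                acc += fwd[k] * Zb[k, j]
        fwd[j + 1] = acc
    bwd = np.empty(n + 1)
    bwd[n] = 1.0
    for i in range(n - 1, -1, -1):
        acc = bwd[i + 1] * s1
        for l in range(i + min_loop + 1, n):
            if Zb[i, l] > 0.0:
                acc += Zb[i, l] * bwd[l + 1]
        bwd[i] = acc
    return Zb, C, Zm1, Zm2, fwd, bwd, expn


@njit(cache=True)
def _pf_outside(codes, n, wpair, hp, bg, ml, min_loop, rt, s1,
                Zb, Zm1, fwd, bwd, expn):
    ebg = math.exp(-bg / rt)
    eml = math.exp(-ml / rt)
    ztot = fwd[n]
    P = np.zeros((n, n))
    T = np.zeros((n, n))   # internal-loop outside weights
    U = np.zeros((n, n))   # multiloop outside weights
    A = np.zeros(n)        # internal accumulator, current row
    A_prev = np.zeros(n)
    ML0 = np.zeros(n)      # sum_h U(h,l) * expn[i-1-h]
    MLrow = np.zeros(n)
    for i in range(0, n):
        # internal accumulator A(i, j) from row i-1 (j descending)
        if i > 0:
            right = 0.0  # A(i, j+1) as we walk j downward
            for j in range(n - 1, -1, -1):
                a = A_prev[j] * s1 + right * s1
                if j + 1 < n:
                    a -= A_prev[j + 1] * s1 * s1
                    a += T[i - 1, j + 1] * s1 * s1
                A[j] = a
                right = a
            # ML0(i, l) update
            for l in range(n):
                ML0[l] = ML0[l] * s1 + U[i - 1, l]
        # MLrow(l) = sum_{h < i} U(h, l) * Zm1(h+1, i-1)
        for l in range(n):
            acc = 0.0
            for h in range(0, i - 1):
                u = U[h, l]
                if u > 0.0:
                    acc += u * Zm1[h + 1, i - 1]
            MLrow[l] = acc
        for j in range(i + min_loop + 1, n):
            zb = Zb[i, j]
            if zb <= 0.0:
                continue
            # exterior context
            p = fwd[i] * zb * bwd[j + 1] / ztot
            # stacked context
            if i > 0 and j + 1 < n and P[i - 1, j + 1] > 0.0:
                ci, cj = codes[i], codes[j]
                co, cjo = codes[i - 1], codes[j + 1]
                if wpair[co, cjo] > 0.0:
                    est = math.exp((wpair[co, cjo] + wpair[ci, cj])
                                   / (2.0 * rt))
                    p += (P[i - 1, j + 1] / Zb[i - 1, j + 1]) * est \
                        * zb * s1 * s1
            # internal-loop context (exclude the exact-stack configuration)
            a = A[j]
            if i > 0 and j + 1 < n:
                a -= T[i - 1, j + 1] * s1 * s1
            if a > 0.0:
                p += zb * a
            # multiloop context
            acc = 0.0
            for l in range(j + 1, n):
                mlv = MLrow[l]
                ml0 = ML0[l]
                if mlv > 0.0 or ml0 > 0.0:
                    zm1r = Zm1[j + 1, l - 1] if l - 1 >= j + 1 else 0.0
                    acc += mlv * expn[l - 1 - j] + (mlv + ml0) * zm1r
            p += zb * acc
            if p < 0.0:
                p = 0.0
            if p > 1.0:
                p = 1.0
            P[i, j] = p
            T[i, j] = ebg * p / zb
            U[i, j] = eml * expn[2] * p / zb
        tmp = A_prev
        A_prev = A
        A = tmp
    return P


def partition_function(
    seq: NucleotideSequence,
    model: EnergyModel | None = None,
    compute_pairs: bool = True,
) -> EnsembleResult:
    """Partition sum Z, ensemble free energy Q, and pair probabilities.

    The empty structure always contributes exp(0), so Z >= 1 and Q <= 0.
    """
    model = model or EnergyModel()
    n = len(seq)
    wpair = model.weight_matrix
    if n < model.min_loop + 2:
        res = EnsembleResult(seq.identifier, n, 0.0, np.zeros((n, n)))
        return _attach_q(res, model.rt)
    # per-nucleotide scale from the MFE (dominant term), slightly padded
    _, _, _, _, _, mfe = mfe_tables(seq, model)
    scale = math.exp(max(0.0, -1.05 * mfe / n) / model.rt)
    s1 = 1.0 / scale
    codes = seq.codes
    Zb, C, Zm1, Zm2, fwd, bwd, expn = _pf_inside(
        codes, n, wpair, model.hairpin_penalty, model.bulge_internal_penalty,
        model.multiloop_penalty, model.min_loop, model.rt, s1)
    log_z = math.log(fwd[n]) + n * math.log(scale)
    if log_z < 0 and log_z > -1e-9:
        log_z = 0.0
    if compute_pairs:
        P = _pf_outside(codes, n, wpair, model.hairpin_penalty,
                        model.bulge_internal_penalty, model.multiloop_penalty,
                        model.min_loop, model.rt, s1, Zb, Zm1, fwd, bwd, expn)
        P = np.maximum(P, P.T)
    else:
        P = np.zeros((n, n))
    res = EnsembleResult(seq.identifier, n, log_z, P)
    return _attach_q(res, model.rt)
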