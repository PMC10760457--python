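"""Brute-force enumeration of all secondary structures (verification oracle).

Enumerates every non-crossing, min-loop-respecting structure of a short
sequence, scoring each with the structural energy function.  Exponential in
sequence length, hence the hard cap; its only job is to cross-validate the
dynamic-programming kernels exactly.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .energy import EnergyModel, pairs_to_dotbracket, structure_energy
from .seqs import InputError, NucleotideSequence

DEFAULT_CAP = 25


def enumerate_structures(
    seq: NucleotideSequence,
    model: EnergyModel | None = None,
    cap: int = DEFAULT_CAP,
) -> list[tuple[str, float]]:
    """All (dot-bracket, energy) pairs, the empty structure included.

    Raises :class:`InputError` for sequences longer than ``cap`` — the
    combinatorics are exponential and anything past ~25 nt is not a sensible
    oracle workload.
    """
    model = model or EnergyModel()
    n = len(seq)
    if n > cap:
        raise InputError(
            f"sequence length {n} exceeds the enumeration cap of {cap} nt; "
            "use fold_mfe/partition_function for longer sequences"
        )
    res = seq.residues
    min_loop = model.min_loop

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        """All pair sets over the closed interval [i, j]."""
        if j - i < min_loop + 1:
            return ((),)
        out = list(structs(i, j - 1))  # j unpaired
        for k in range(i, j - min_loop):
            if model.can_pair(res[k], res[j]):
                for left in structs(i, k - 1) if k > i else ((),):
                    for inner in structs(k + 1, j - 1):
                        out.append(left + inner + (((k, j)),))
        return tuple(out)

    results = []
    for pairset in structs(0, n - 1):
        db = pairs_to_dotbracket(pairset, n)
        results.append((db, structure_energy(res, pairset, model)))
    return results


def boltzmann_oracle(
    seq: NucleotideSequence,
    model: EnergyModel | None = None,
    cap: int = DEFAULT_CAP,
):
    """Exact Boltzmann sums over the enumerated ensemble.

    Returns ``(Z, pair_prob)`` where ``pair_prob[i, j]`` is the probability
    that bases i and j pair, computed as a direct sum over all structures.
    """
    model = model or EnergyModel()
    n = len(seq)
    z = 0.0
    pp = np.zeros((n, n))
    for db, e in enumerate_structures(seq, model, cap=cap):
        w = math.exp(-e / model.rt)
        z += w
        for i, ch in enumerate(db):
            if ch == "(":
                depth = 0
                for j in range(i, n):
                    if db[j] == "(":
                        depth += 1
                    elif db[j] == ")":
                        depth -= 1
                        if depth == 0:
                            pp[i, j] += w
                            break
    pp = (pp + pp.T) / z
    return z, pp


def min_energy_structure(
    seq: NucleotideSequence,
    model: EnergyModel | None = None,
    cap: int = DEFAULT_CAP,
) -> tuple[str, float]:
    """Minimum over the enumerated ensemble (ties: empty-most first listed)."""
    best = min(enumerate_structures(seq, model, cap=cap), key=lambda se: se[1])
    return best
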