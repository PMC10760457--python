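"""The built-in nearest-neighbour-style energy model ("SIMPLE-NN v1").

A deliberately small model shared verbatim by the minimum-free-energy
recursion, the McCaskill-style partition function, and the brute-force
enumeration oracle, so that the three can be cross-validated exactly.

Energy of a secondary structure is the sum over its loops:

* a stacked pair ``(i, j)`` on ``(i+1, j-1)`` contributes
  ``-(w(i,j) + w(i+1,j-1)) / 2`` with ``w(GC) = 3.0``, ``w(AU) = 2.0``,
  ``w(GU) = 1.0`` kcal/mol;
* a hairpin loop costs ``+3.0``;
* a bulge or internal loop (one inner helix, not a stack) costs ``+2.0``,
  independent of its size;
* a multiloop (two or more inner helices) costs ``+3.0``;
* exterior (unenclosed) bases are free.

This is not the Turner parameter set and makes no claim of thermodynamic
fidelity; window MFEs and pair-probability matrices computed by external
folding tools can be imported through the adapter TSV dialect instead
(see :mod:`mirstruct.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import BASE_CODE, InputError

#: default pair strengths (kcal/mol); 0.0 means the pair is disallowed
DEFAULT_PAIR_WEIGHTS = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "U"): 2.0,
    ("U", "A"): 2.0,
    ("G", "U"): 1.0,
    ("U", "G"): 1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Single source of truth for all folding energetics."""

    pair_weights: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS))
    hairpin_penalty: float = 3.0
    bulge_internal_penalty: float = 2.0
    multiloop_penalty: float = 3.0
    min_loop: int = 3
    rt: float = 0.6157  # kcal/mol at 310.15 K

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise InputError("min_loop must be >= 3")
        for pen in (self.hairpin_penalty, self.bulge_internal_penalty,
                    self.multiloop_penalty):
            if pen < 0:
                raise InputError("loop penalties must be >= 0")
        for pair, w in self.pair_weights.items():
            if w < 0:
                raise InputError(f"pair weight for {pair} must be >= 0")

    @property
    def weight_matrix(self) -> np.ndarray:
        """5x5 matrix of pair strengths over the A,C,G,U,N encoding."""
        w = np.zeros((5, 5), dtype=np.float64)
        for (a, b), val in self.pair_weights.items():
            w[BASE_CODE[a], BASE_CODE[b]] = val
        return w

    def can_pair(self, a: str, b: str) -> bool:
        return self.pair_weights.get((a, b), 0.0) > 0

    def stack_energy(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        """Energy of stacking ``inner`` directly on ``outer`` (<= 0)."""
        wo = self.pair_weights.get(outer, 0.0)
        wi = self.pair_weights.get(inner, 0.0)
        if wo <= 0 or wi <= 0:
            raise InputError(f"stack on unpairable bases: {outer}/{inner}")
        return -(wo + wi) / 2.0


def pairs_to_dotbracket(pairs, length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise InputError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise InputError(f"bad dot-bracket character {ch!r}")
    if stack:
        raise InputError("unbalanced dot-bracket string")
    return sorted(pairs)


def structure_energy(residues: str, pairs, model: EnergyModel) -> float:
    """Loop-decomposition energy of an explicit structure.

    This walks the pair list structurally (no dynamic programming), so it
    serves as an independent energy oracle for the DP kernels.
    """
    pairs = sorted(pairs)
    n = len(residues)
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise InputError(f"pair ({i}, {j}) out of range")
        if j - i - 1 < model.min_loop:
            raise InputError(f"pair ({i}, {j}) violates min_loop")
        if not model.can_pair(residues[i], residues[j]):
            raise InputError(f"illegal pair {residues[i]}-{residues[j]} at ({i}, {j})")
    # parent of each pair via a stack over sorted pairs (non-crossing assumed)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    open_stack: list[tuple[int, int]] = []
    for p in pairs:
        while open_stack and open_stack[-1][1] < p[0]:
            open_stack.pop()
        if open_stack and not (open_stack[-1][0] < p[0] and p[1] < open_stack[-1][1]):
            raise InputError("crossing pairs")
        parent = open_stack[-1] if open_stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        open_stack.append(p)
    energy = 0.0
    for (i, j) in pairs:
        kids = children[(i, j)]
        if not kids:
            energy += model.hairpin_penalty
        elif len(kids) == 1:
            (k, l) = kids[0]
            if k == i + 1 and l == j - 1:
                energy += model.stack_energy(
                    (residues[i], residues[j]), (residues[k], residues[l])
                )
            else:
                energy += model.bulge_internal_penalty
        else:
            energy += model.multiloop_penalty
    return energy
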