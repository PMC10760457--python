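"""Nucleotide sequences and composition-preserving shuffles.

All folding code operates on RNA alphabet {A, C, G, U} plus ``N`` for
anything unresolvable.  DNA input is accepted transparently (``T`` maps to
``U``); lowercase is uppercased.  Ambiguity codes other than N are also
collapsed to N: they cannot participate in a base pair under the built-in
energy model, and treating them as unpairable loop residues is the
conservative choice for structure prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CANON = {c: c for c in "ACGUN"}
_CANON.update({"T": "U"})

# integer encoding used by the DP kernels
BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")


def canonicalize(residues: str) -> str:
    """Uppercase, map T->U, collapse non-ACGU codes to N."""
    out = []
    for ch in residues.upper():
        out.append(_CANON.get(ch, "N"))
    return "".join(out)


class InputError(ValueError):
    """Raised when an operation receives invalid input."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A canonicalized RNA sequence with an identifier.

    ``residues`` is guaranteed to contain only A, C, G, U, N.
    """

    identifier: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        canon = canonicalize(self.residues)
        object.__setattr__(self, "residues", canon)
        if len(canon) < 1:
            raise InputError(f"empty sequence for {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """Integer encoding (A=0, C=1, G=2, U=3, N=4) for the DP kernels."""
        return np.frombuffer(
            self.residues.encode().translate(
                bytes.maketrans(b"ACGUN", bytes([0, 1, 2, 3, 4]))
            ),
            dtype=np.int8,
        ).copy()

    def reverse_complement(self) -> "NucleotideSequence":
        rc = self.residues.translate(_COMPLEMENT)[::-1]
        return NucleotideSequence(self.identifier, rc)

    def subsequence(self, start: int, end: int, identifier: str | None = None):
        if not (0 <= start < end <= len(self)):
            raise InputError(f"bad slice [{start}, {end}) for {self.identifier!r}")
        return NucleotideSequence(
            identifier or f"{self.identifier}:{start}-{end}",
            self.residues[start:end],
        )


def reverse_complement(residues: str, alphabet: str = "rna") -> str:
    """Reverse complement of a plain string (RNA by default, 'dna' for T)."""
    table = _COMPLEMENT if alphabet == "rna" else _COMPLEMENT_DNA
    return residues.upper().translate(table)[::-1]


def shuffle_sequence(seq: NucleotideSequence, seed: int) -> NucleotideSequence:
    """Uniform random permutation of the residues (composition-preserving).

    The same seed always yields the same permutation; this is the null used
    to ask whether observed folding stability exceeds what base composition
    alone would produce.
    """
    rng = np.random.default_rng(seed)
    arr = np.array(list(seq.residues))
    rng.shuffle(arr)
    return NucleotideSequence(f"{seq.identifier}|shuffle{seed}", "".join(arr))
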