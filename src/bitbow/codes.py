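"""Binary Bitbow codes: representation, capacity math, string encoding, entropy.

A Bitbow code is an ordered binary vector over (compartment, fluorophore)
slots.  Each bit records whether one FRT-flanked fluorophore module
recombined into its ON orientation.  With five spectrally distinct
fluorophores targeted to one, two, or three subcellular compartments the
code length is 5, 10, or 15 bits and the pool of usable (nonzero) codes is
2**n - 1: the all-zero vector corresponds to an unlabeled, invisible cell.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "DEFAULT_FLUOROPHORES",
    "FLUOROPHORE_NAMES",
    "DEFAULT_COMPARTMENTS",
    "BitbowCode",
    "code_capacity",
    "encode",
    "decode",
    "shannon_entropy",
    "code_count_table",
]

#: One-letter fluorophore labels in fixed bit order within a compartment group.
DEFAULT_FLUOROPHORES: tuple[str, ...] = ("A", "T", "G", "O", "K")

#: Full names behind the one-letter labels.
FLUOROPHORE_NAMES: dict[str, str] = {
    "A": "mAmetrine",
    "T": "mTFP1",
    "G": "mNeonGreen",
    "O": "mKO2",
    "K": "tdKatushka2",
}

#: Compartment groups in fixed order (membrane -> nucleus -> golgi).
DEFAULT_COMPARTMENTS: tuple[str, ...] = ("membrane", "nucleus", "golgi")


def code_capacity(n_bits: int) -> int:
    """Number of distinct nonzero binary codes of length ``n_bits``.

    Each of the ``n_bits`` modules independently takes an ON or OFF state,
    so a transgenic animal carries ``2**n_bits`` states of which the
    all-OFF state is unobservable; capacity is ``2**n_bits - 1``.

    >>> code_capacity(5)
    31
    >>> code_capacity(15)
    32767
    """
    if not isinstance(n_bits, (int, np.integer)) or n_bits < 1:
        raise ValueError(f"n_bits must be a positive integer, got {n_bits!r}")
    return 2 ** int(n_bits) - 1


@dataclass(frozen=True, order=True)
class BitbowCode:
    """An ordered binary vector over (compartment, fluorophore) slots.

    Ordering (``<``, sorting) is lexicographic on the bit vector, which is
    the global tie-break used throughout the package.
    """

    bits: tuple[int, ...]
    fp_labels: tuple[str, ...] = field(default=DEFAULT_FLUOROPHORES, compare=False)
    compartment_labels: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("bits must be 0/1")
        n_fp = len(self.fp_labels)
        if n_fp < 1 or len(bits) == 0 or len(bits) % n_fp != 0:
            raise ValueError(
                f"bit length {len(bits)} is not a positive multiple of the "
                f"fluorophore count {n_fp}"
            )
        object.__setattr__(self, "bits", bits)
        if not self.compartment_labels:
            k = len(bits) // n_fp
            object.__setattr__(
                self, "compartment_labels", DEFAULT_COMPARTMENTS[:k] or ("membrane",)
            )

    @property
    def n_bits(self) -> int:
        return len(self.bits)

    @property
    def n_compartments(self) -> int:
        return len(self.bits) // len(self.fp_labels)

    @property
    def is_labeled(self) -> bool:
        """True unless all modules are OFF (all-zero = unlabeled cell)."""
        return any(self.bits)

    def __str__(self) -> str:
        return encode(self)


def encode(code: BitbowCode) -> str:
    """Render a code as groups of five 0/1 digits joined by ``-``.

    Digit order within a group is the fixed fluorophore order
    (A, T, G, O, K by default); group order is membrane, nucleus, golgi.

    >>> encode(BitbowCode((1, 0, 0, 0, 0)))
    '10000'
    """
    g = len(code.fp_labels)
    bits = code.bits
    return "-".join(
        "".join(str(b) for b in bits[i : i + g]) for i in range(0, len(bits), g)
    )


def decode(s: str, fp_labels: tuple[str, ...] = DEFAULT_FLUOROPHORES) -> BitbowCode:
    """Parse a grouped 0/1 code string back into a :class:`BitbowCode`.

    The all-zero string is accepted (it decodes to a code whose
    ``is_labeled`` is False).  Malformed input raises ``ValueError`` naming
    the offending character position.
    """
    g = len(fp_labels)
    groups = s.split("-")
    bits: list[int] = []
    pos = 0
    for group in groups:
        if len(group) != g:
            raise ValueError(
                f"group {group!r} at position {pos} has length {len(group)}, "
                f"expected {g}"
            )
        for ch in group:
            if ch not in "01":
                raise ValueError(f"invalid character {ch!r} at position {pos}")
            bits.append(int(ch))
            pos += 1
        pos += 1  # separator
    return BitbowCode(tuple(bits), fp_labels=fp_labels)


def code_count_table(codes: Iterable[str | BitbowCode]) -> dict[str, int]:
    """Tally an iterable of codes into a ``{code string: count}`` table."""
    counts: dict[str, int] = {}
    for c in codes:
        key = str(c)
        counts[key] = counts.get(key, 0) + 1
    return counts


def shannon_entropy(counts: Mapping[str | BitbowCode, int]) -> float:
    """Shannon entropy (bits) of an observed code-count table.

    H = -sum f_i * log2(f_i) with f_i = count_i / total.  Zero-count codes
    contribute nothing.  Used as a diagnostic of the information-carrying
    ability of a labeling experiment: H is maximal (log2 of the number of
    observed codes) when codes occur uniformly and shrinks as recombination
    bias concentrates mass on a few codes.
    """
    if not counts:
        raise ValueError("empty code-count table")
    values = np.asarray(list(counts.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    total = values.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    f = values[values > 0] / total
    return float(-(f * np.log2(f)).sum())
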