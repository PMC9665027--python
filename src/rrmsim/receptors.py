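"""Bit-string receptors and complementarity-based binding.

Receptors and antigen epitopes are fixed-length binary strings; the
affinity between two strings is the fraction of positions at which they
are complementary (a clonotype binds best the exact bit-complement of
its epitope, in the Celada–Seiden tradition).  Strings of length ``L``
are stored as unsigned integers in ``[0, 2**L)``, which makes affinity a
popcount of an XOR and lets whole repertoires be scored in one
vectorised call.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ReceptorSpaceMismatch",
    "affinity",
    "affinity_many",
    "binds",
    "binds_many",
    "random_receptors",
    "near_complement",
    "thymic_selection",
    "bits_to_int",
    "int_to_bits",
]


class ReceptorSpaceMismatch(ValueError):
    """Raised when two receptor strings come from different-length spaces."""


def bits_to_int(bits: str | list[int] | np.ndarray) -> int:
    """Pack a bit sequence (string like ``"1010"`` or list of 0/1) into an int."""
    if isinstance(bits, str):
        return int(bits, 2)
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


def int_to_bits(value: int, length: int) -> str:
    """Unpack an integer receptor into its bit-string representation."""
    return format(int(value), f"0{length}b")


def _popcount(x: np.ndarray | int) -> np.ndarray | int:
    if isinstance(x, (int, np.integer)):
        return int(x).bit_count()
    return np.bitwise_count(x.astype(np.uint64))


def affinity(a: int, b: int, length: int) -> float:
    """Fraction of complementary bit positions between two strings.

    Complementary means the bits differ, so the score is
    ``popcount(a XOR b) / L``: 1.0 for exact complements, 0.0 for
    identical strings.  Symmetric in its arguments.
    """
    space = 1 << length
    if not (0 <= a < space) or not (0 <= b < space):
        raise ReceptorSpaceMismatch(
            f"receptor outside the {length}-bit space: a={a}, b={b}"
        )
    return _popcount(a ^ b) / length


def affinity_many(receptors: np.ndarray, antigen: int, length: int) -> np.ndarray:
    """Vectorised :func:`affinity` of many receptors against one antigen."""
    x = np.asarray(receptors, dtype=np.uint64) ^ np.uint64(antigen)
    return _popcount(x) / length


def binds(a: int, b: int, length: int, threshold: float) -> bool:
    """True iff the affinity of ``a`` and ``b`` reaches ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return affinity(a, b, length) >= threshold


def binds_many(
    receptors: np.ndarray, antigen: int, length: int, threshold: float
) -> np.ndarray:
    """Vectorised binding test of many receptors against one antigen."""
    return affinity_many(receptors, antigen, length) >= threshold


def random_receptors(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Draw ``n`` receptors uniformly from the ``2**L`` string space."""
    return rng.integers(0, 1 << length, size=n, dtype=np.uint64)


def near_complement(
    rng: np.random.Generator, antigen: int, length: int, n: int, flips: int = 1
) -> np.ndarray:
    """Receptors at Hamming distance ``flips`` from the exact complement.

    Used to seed weakly self-reactive clonotypes (affinity
    ``(L - flips)/L`` to ``antigen``) that escape a perfect-complement
    negative-selection rule.
    """
    comp = np.uint64(((1 << length) - 1) ^ int(antigen))
    out = np.full(n, comp, dtype=np.uint64)
    for _ in range(flips):
        bit = rng.integers(0, length, size=n).astype(np.uint64)
        out ^= np.uint64(1) << bit
    return out


def thymic_selection(
    receptors: np.ndarray | int,
    self_antigens: list[int] | np.ndarray,
    length: int,
    neg_threshold: float,
) -> np.ndarray | bool:
    """Negative selection of T-lineage receptors against self epitopes.

    A receptor is rejected (``False``) when its affinity to *any* self
    antigen reaches ``neg_threshold``; survivors return ``True``.
    Accepts a scalar receptor or a whole cohort.
    """
    self_antigens = list(np.asarray(self_antigens, dtype=np.uint64).ravel())
    if not self_antigens:
        raise ValueError("self-antigen set must be non-empty")
    scalar = isinstance(receptors, (int, np.integer))
    recs = np.atleast_1d(np.asarray(receptors, dtype=np.uint64))
    accept = np.ones(recs.shape, dtype=bool)
    for ag in self_antigens:
        accept &= affinity_many(recs, int(ag), length) < neg_threshold
    return bool(accept[0]) if scalar else accept
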