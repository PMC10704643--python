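"""k-mer alphabets and encodings.

The hidden states of the basecalling model are k-mers: windows of ``k``
consecutive bases that dominate the pore current at a given instant.  A
:class:`KmerAlphabet` fixes a bijection between the ``|bases|**k`` length-k
strings and integer indices, using big-endian positional encoding with the
bases in their declared order (so with the default DNA bases, ``A=0, C=1,
G=2, T=3`` and e.g. ``"AC"`` -> 0*4+1 = 1 for k=2).

Alphabets over fewer (or more) than four symbols are supported so that
exhaustive test oracles stay enumerable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KmerAlphabet",
    "build_kmer_alphabet",
    "kmers_from_sequence",
    "sequence_from_kmers",
]

DNA_BASES = ("A", "C", "G", "T")


class AlphabetError(ValueError):
    """Invalid alphabet definition or encoding request."""


@dataclass(frozen=True)
class KmerAlphabet:
    """The k-mer state set: all length-``k`` strings over ``bases``."""

    k: int
    bases: tuple[str, ...] = DNA_BASES

    def __post_init__(self) -> None:
        if self.k < 1:
            raise AlphabetError(f"k must be >= 1, got {self.k}")
        if len(self.bases) < 2:
            raise AlphabetError("alphabet needs at least 2 bases")
        if len(set(self.bases)) != len(self.bases) or "" in self.bases:
            raise AlphabetError(f"bases must be distinct and non-empty: {self.bases}")
        object.__setattr__(self, "bases", tuple(self.bases))

    @property
    def n_bases(self) -> int:
        return len(self.bases)

    @property
    def size(self) -> int:
        """Number of k-mer states, ``|bases|**k``."""
        return self.n_bases**self.k

    def base_index(self, base: str) -> int:
        try:
            return self.bases.index(base)
        except ValueError:
            raise AlphabetError(f"unknown base {base!r}") from None

    def encode(self, kmer: str) -> int:
        """Index of a length-k string (big-endian base-``|bases|``)."""
        if len(kmer) != self.k:
            raise AlphabetError(f"expected a {self.k}-mer, got {kmer!r}")
        idx = 0
        for b in kmer:
            idx = idx * self.n_bases + self.base_index(b)
        return idx

    def decode(self, index: int) -> str:
        """Length-k string for an index; inverse of :meth:`encode`."""
        if not 0 <= index < self.size:
            raise AlphabetError(f"k-mer index {index} out of range [0, {self.size})")
        out = []
        for _ in range(self.k):
            out.append(self.bases[index % self.n_bases])
            index //= self.n_bases
        return "".join(reversed(out))

    def successors(self, index: int) -> np.ndarray:
        """Indices of the ``|bases|`` single-base-shift successors of a k-mer.

        K' succeeds K when the last k-1 bases of K equal the first k-1
        bases of K'.  For k=1 every k-mer succeeds every other.
        """
        prefix = (index % (self.n_bases ** (self.k - 1))) * self.n_bases
        return prefix + np.arange(self.n_bases)

    def shift_overlap_ok(self, a: int, b: int) -> bool:
        """True when k-mer ``b`` may follow ``a`` under single-base shifting."""
        return a % (self.n_bases ** (self.k - 1)) == b // self.n_bases


def build_kmer_alphabet(k: int, bases=DNA_BASES) -> KmerAlphabet:
    """Construct the k-mer state set over the given ordered bases."""
    return KmerAlphabet(k=k, bases=tuple(bases))


def kmers_from_sequence(seq: str, alphabet: KmerAlphabet) -> np.ndarray:
    """Encode a base string as its sequence of overlapping k-mer indices.

    Returns ``M = len(seq) - k + 1`` indices; consecutive indices satisfy
    the single-base-shift overlap by construction.
    """
    k = alphabet.k
    if len(seq) < k:
        raise AlphabetError(f"sequence of length {len(seq)} shorter than k={k}")
    codes = np.array([alphabet.base_index(b) for b in seq], dtype=np.int64)
    # correlation of base codes with big-endian positional weights
    weights = alphabet.n_bases ** np.arange(k, dtype=np.int64)
    return np.convolve(codes, weights, mode="valid")


def sequence_from_kmers(kmers, alphabet: KmerAlphabet) -> str:
    """Decode a k-mer index path back to a base string.

    The first k-mer contributes ``k`` bases and every subsequent k-mer one
    base (its last).  Consecutive k-mers must satisfy the (k-1)-overlap.
    """
    kmers = np.asarray(kmers, dtype=np.int64)
    if kmers.size == 0:
        return ""
    out = [alphabet.decode(int(kmers[0]))]
    for prev, cur in zip(kmers[:-1], kmers[1:]):
        if not alphabet.shift_overlap_ok(int(prev), int(cur)):
            raise AlphabetError(
                f"k-mers {alphabet.decode(int(prev))} -> {alphabet.decode(int(cur))} "
                "violate single-shift overlap"
            )
        out.append(alphabet.bases[int(cur) % alphabet.n_bases])
    return "".join(out)
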