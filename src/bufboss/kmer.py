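"""2-bit packed DNA k-mers and edgemer enumeration.

Edgemers (k-mers, the edges of an edge-centric de Bruijn graph) and nodemers
((k-1)-mers, the nodes) are packed two bits per character into a single
Python integer, with the first character in the most significant position.
With the alphabet fixed to ACGT and k capped at 32, every key fits in a
64-bit word, which is what makes hashing the addition buffer cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

ALPHABET = "ACGT"
MAX_K = 32

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CHAR = "ACGT"
_VALID = frozenset("ACGT")


class CodecError(ValueError):
    """A sequence contains characters outside the ACGT alphabet."""


class KmerLengthError(ValueError):
    """A k-mer length is outside the supported range."""


@dataclass(frozen=True, slots=True)
class PackedKmer:
    """An ACGT string of length <= 32 packed 2 bits per character.

    ``bits`` holds the characters with the first character in the highest
    2-bit slot, so the (k-1)-length prefix/suffix nodemers of an edgemer are
    single shift/mask operations.
    """

    bits: int
    length: int

    def __post_init__(self) -> None:
        if not 0 <= self.length <= MAX_K:
            raise KmerLengthError(f"k-mer length {self.length} not in [0, {MAX_K}]")
        if self.bits >> (2 * self.length):
            raise CodecError("bits set above 2*length")

    def __str__(self) -> str:
        return decode_kmer(self)

    def __len__(self) -> int:
        return self.length

    @property
    def first(self) -> str:
        """First character."""
        return _CHAR[(self.bits >> (2 * (self.length - 1))) & 3]

    @property
    def last(self) -> str:
        """Last character."""
        return _CHAR[self.bits & 3]

    def prefix(self) -> "PackedKmer":
        """Drop the last character."""
        return PackedKmer(self.bits >> 2, self.length - 1)

    def suffix(self) -> "PackedKmer":
        """Drop the first character."""
        mask = (1 << (2 * (self.length - 1))) - 1
        return PackedKmer(self.bits & mask, self.length - 1)


def encode_kmer(s: str) -> PackedKmer:
    """Pack an ACGT string (case-insensitive) into a :class:`PackedKmer`."""
    s = s.upper()
    if len(s) > MAX_K:
        raise KmerLengthError(f"k-mer longer than {MAX_K}: {len(s)}")
    bits = 0
    for ch in s:
        try:
            bits = (bits << 2) | _CODE[ch]
        except KeyError:
            raise CodecError(f"invalid character {ch!r} in k-mer") from None
    return PackedKmer(bits, len(s))


def decode_kmer(x: PackedKmer) -> str:
    """Unpack a :class:`PackedKmer` back to its ACGT string."""
    chars = []
    bits = x.bits
    for _ in range(x.length):
        chars.append(_CHAR[bits & 3])
        bits >>= 2
    return "".join(reversed(chars))


def reverse_complement(x: PackedKmer) -> PackedKmer:
    """Reverse complement; an involution (A<->T, C<->G, order reversed)."""
    bits = x.bits
    out = 0
    for _ in range(x.length):
        out = (out << 2) | (3 - (bits & 3))
        bits >>= 2
    return PackedKmer(out, x.length)


def reverse_complement_str(s: str) -> str:
    """Reverse complement of a plain ACGT string."""
    return str(reverse_complement(encode_kmer(s))) if s else ""


def canonical(x: PackedKmer) -> PackedKmer:
    """The smaller of a k-mer and its reverse complement.

    Canonical form is used only for reporting distinct-canonical-edgemer
    counts; the index itself stores both strands when asked to.
    """
    rc = reverse_complement(x)
    return x if x.bits <= rc.bits else rc


def split_on_invalid(seq: str) -> list[str]:
    """Split a sequence into maximal runs of A/C/G/T.

    Every non-ACGT character (N, IUPAC ambiguity codes, gaps, ...) acts as a
    split point. Input is upper-cased first.
    """
    seq = seq.upper()
    pieces: list[str] = []
    start = None
    for i, ch in enumerate(seq):
        if ch in _VALID:
            if start is None:
                start = i
        elif start is not None:
            pieces.append(seq[start:i])
            start = None
    if start is not None:
        pieces.append(seq[start:])
    return pieces


def _piece_edgemers(piece: str, k: int) -> Iterator[PackedKmer]:
    if len(piece) < k:
        return
    mask = (1 << (2 * k)) - 1
    bits = 0
    for i, ch in enumerate(piece):
        bits = ((bits << 2) | _CODE[ch]) & mask
        if i >= k - 1:
            yield PackedKmer(bits, k)


def check_k(k: int) -> None:
    """Validate the edgemer length parameter (2 <= k <= 32)."""
    if not isinstance(k, int) or not 2 <= k <= MAX_K:
        raise KmerLengthError(f"edgemer length k={k!r} must be an integer in [2, {MAX_K}]")


def enumerate_edgemers(seqs: Iterable[str], k: int, add_rc: bool = False) -> set[PackedKmer]:
    """All distinct length-k substrings of the ACGT pieces of ``seqs``.

    With ``add_rc`` the reverse complement of every sequence is processed as
    well, so both strands end up in the edgemer set.
    """
    check_k(k)
    out: set[PackedKmer] = set()
    for seq in seqs:
        for piece in split_on_invalid(seq):
            out.update(_piece_edgemers(piece, k))
            if add_rc:
                out.update(_piece_edgemers(reverse_complement_str(piece), k))
    return out
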