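"""Static bit vectors with rank/select support.

Plain precomputed directories (prefix sums and position lists) on numpy
arrays. All positions are 0-based and rank is over the half-open prefix
[0, i); select is 1-based (select1(j) is the position of the j-th set bit).
"""

from __future__ import annotations

import numpy as np


class RankSelectBits:
    """An immutable bit sequence with O(1)-ish rank and select."""

    def __init__(self, bits) -> None:
        self._bits = np.asarray(bits, dtype=bool)
        if self._bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        self._ones = np.flatnonzero(self._bits)
        self._zeros = np.flatnonzero(~self._bits)

    @classmethod
    def from_unary_degrees(cls, degrees) -> "RankSelectBits":
        """Concatenate the unary encodings 1·0^d of a degree sequence."""
        degrees = np.asarray(degrees, dtype=np.int64)
        n = len(degrees) + int(degrees.sum())
        bits = np.zeros(n, dtype=bool)
        if len(degrees) == 0:
            return cls(bits)
        # a 1 marks the start of each node's run of degree zeros
        starts = np.concatenate(([0], np.cumsum(degrees + 1)[:-1]))
        bits[starts] = True
        return cls(bits)

    def __len__(self) -> int:
        return len(self._bits)

    def __getitem__(self, i: int) -> int:
        return int(self._bits[i])

    def __eq__(self, other) -> bool:
        if not isinstance(other, RankSelectBits):
            return NotImplemented
        return len(self) == len(other) and bool(np.array_equal(self._bits, other._bits))

    def rank1(self, i: int) -> int:
        """Number of set bits in [0, i)."""
        return int(np.searchsorted(self._ones, i, side="left"))

    def rank0(self, i: int) -> int:
        """Number of clear bits in [0, i)."""
        return i - self.rank1(i)

    def select1(self, j: int) -> int:
        """Position of the j-th (1-based) set bit."""
        if not 1 <= j <= len(self._ones):
            raise IndexError(f"select1({j}) out of range")
        return int(self._ones[j - 1])

    def select0(self, j: int) -> int:
        """Position of the j-th (1-based) clear bit."""
        if not 1 <= j <= len(self._zeros):
            raise IndexError(f"select0({j}) out of range")
        return int(self._zeros[j - 1])

    def count1(self) -> int:
        return len(self._ones)

    def count0(self) -> int:
        return len(self._zeros)

    def to01(self) -> str:
        """The bit sequence as a '0'/'1' string."""
        return "".join("1" if b else "0" for b in self._bits)
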