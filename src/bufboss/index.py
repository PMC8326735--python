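"""The static BOSS / Wheeler-graph index of an edge-centric de Bruijn graph.

Nodes are (k-1)-mers (nodemers) plus a tree of dummy prefix nodes rooted at
the empty string, so that every non-root node has an incoming path of length
k-1 spelling its label. Nodes and edges are identified by their 1-based
colexicographic ranks; node labels shorter than k-1 compare as if left-padded
with '$' ($ < A < C < G < T). The index stores three components:

* ``ebwt`` — the single-character edge labels, grouped by origin node in
  colexicographic node order (label-sorted within a node, which makes the
  representation canonical and serialization bit-reproducible);
* the outdegree sequence (conceptually the bit vector O, degree d encoded
  as 1·0^d);
* the indegree sequence (bit vector I, same encoding).

Edge rank and ebwt position are linked by the classic last-to-first mapping:
the edge at ebwt position p with label c has colexicographic rank
C[c] + rank_c(p) + 1, where C[c] counts edges whose label precedes c.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .bitvectors import RankSelectBits
from .kmer import CodecError, PackedKmer, _CHAR, _CODE, decode_kmer

PAD = "$"


@dataclass(frozen=True, slots=True)
class NodeInterval:
    """A closed interval [lo, hi] of colexicographic node ranks."""

    lo: int
    hi: int

    @property
    def empty(self) -> bool:
        return self.lo > self.hi

    def width(self) -> int:
        return max(0, self.hi - self.lo + 1)


EMPTY_INTERVAL = NodeInterval(1, 0)


class BossIndex:
    """Static Wheeler-graph index supporting the eight navigation operations.

    Construct with :func:`bufboss.build.build_index`; the constructor takes
    the raw components (edge-label codes in ebwt order plus the degree
    sequences in colexicographic node order).
    """

    def __init__(self, k: int, ebwt_codes, outdeg, indeg, validate: bool = True):
        self.k = int(k)
        self._ebwt = np.ascontiguousarray(ebwt_codes, dtype=np.uint8)
        self._outdeg = np.ascontiguousarray(outdeg, dtype=np.int64)
        self._indeg = np.ascontiguousarray(indeg, dtype=np.int64)
        self.n_nodes = len(self._outdeg)
        self.n_edges = len(self._ebwt)

        # out_cum[v] = ebwt position one past the edges of nodes 1..v
        self._out_cum = np.concatenate(([0], np.cumsum(self._outdeg)))
        # in_cum[v] = number of in-edges of nodes 1..v == last in-edge rank of v
        self._in_cum = np.concatenate(([0], np.cumsum(self._indeg)))
        counts = np.bincount(self._ebwt, minlength=4) if self.n_edges else np.zeros(4, np.int64)
        self._C = np.concatenate(([0], np.cumsum(counts)))  # length 5
        self._occ = [np.flatnonzero(self._ebwt == c) for c in range(4)]

        if validate:
            self._validate()

    # -- basic consistency -------------------------------------------------

    def _validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("index must contain at least the root node")
        if len(self._indeg) != self.n_nodes:
            raise ValueError("outdegree and indegree sequences differ in length")
        if int(self._out_cum[-1]) != self.n_edges:
            raise ValueError("sum of outdegrees does not match ebwt length")
        if int(self._in_cum[-1]) != self.n_edges:
            raise ValueError("sum of indegrees does not match ebwt length")
        if self._indeg[0] != 0:
            raise ValueError("the root (rank 1) must have indegree 0")
        if self.n_edges and self._ebwt.max() > 3:
            raise ValueError("ebwt contains codes outside ACGT")

    # -- representations ---------------------------------------------------

    @property
    def ebwt(self) -> str:
        """The edge-label sequence as an ACGT string."""
        return "".join(_CHAR[c] for c in self._ebwt)

    @cached_property
    def O(self) -> RankSelectBits:  # noqa: E743 - field name from the structure
        """Outdegree bit vector (unary 1·0^d per node, colex order)."""
        return RankSelectBits.from_unary_degrees(self._outdeg)

    @cached_property
    def I(self) -> RankSelectBits:  # noqa: E743
        """Indegree bit vector (unary 1·0^d per node, colex order)."""
        return RankSelectBits.from_unary_degrees(self._indeg)

    def outdegree(self, v: int) -> int:
        self._check_node(v)
        return int(self._outdeg[v - 1])

    def indegree(self, v: int) -> int:
        self._check_node(v)
        return int(self._indeg[v - 1])

    @property
    def outdegrees(self) -> np.ndarray:
        return self._outdeg.copy()

    @property
    def indegrees(self) -> np.ndarray:
        return self._indeg.copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, BossIndex):
            return NotImplemented
        return (
            self.k == other.k
            and np.array_equal(self._ebwt, other._ebwt)
            and np.array_equal(self._outdeg, other._outdeg)
            and np.array_equal(self._indeg, other._indeg)
        )

    def __repr__(self) -> str:
        return f"BossIndex(k={self.k}, n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    @classmethod
    def empty(cls, k: int) -> "BossIndex":
        """The index of the empty edgemer set: the root alone."""
        return cls(k, np.zeros(0, np.uint8), [0], [0])

    # -- internal rank machinery --------------------------------------------

    def _check_node(self, v: int) -> None:
        if not 1 <= v <= self.n_nodes:
            raise IndexError(f"node rank {v} out of range [1, {self.n_nodes}]")

    def _rank_c(self, c: int, pos: int) -> int:
        """Occurrences of code c in ebwt[0:pos)."""
        return int(np.searchsorted(self._occ[c], pos, side="left"))

    def _edge_rank_at(self, pos: int) -> int:
        """Colexicographic rank of the edge stored at ebwt position pos."""
        c = int(self._ebwt[pos])
        return int(self._C[c]) + self._rank_c(c, pos) + 1

    def _node_of_edge(self, r: int) -> int:
        """The node whose in-edge interval contains edge rank r."""
        return int(np.searchsorted(self._in_cum, r, side="left"))

    def _label_of_edge(self, r: int) -> int:
        """The single-character code of the edge with colex rank r."""
        return int(np.searchsorted(self._C, r, side="left")) - 1

    def _origin_of_pos(self, pos: int) -> int:
        """The node from which the edge at ebwt position pos leaves."""
        return int(np.searchsorted(self._out_cum, pos, side="right"))

    @cached_property
    def _edge_dest(self) -> np.ndarray:
        """Destination node of the edge at each ebwt position (vectorized)."""
        ranks = np.empty(self.n_edges, dtype=np.int64)
        for c in range(4):
            occ = self._occ[c]
            ranks[occ] = self._C[c] + np.arange(1, len(occ) + 1)
        return np.searchsorted(self._in_cum, ranks, side="left")

    @cached_property
    def _edge_origin(self) -> np.ndarray:
        """Origin node of the edge at each ebwt position."""
        return np.repeat(np.arange(1, self.n_nodes + 1), self._outdeg)

    # -- navigation operations ----------------------------------------------

    def full_interval(self) -> NodeInterval:
        return NodeInterval(1, self.n_nodes)

    def update_interval(self, iv: NodeInterval, c: str) -> NodeInterval:
        """Destinations of all c-labeled edges leaving nodes in ``iv``."""
        if iv.empty:
            return EMPTY_INTERVAL
        code = _CODE.get(c)
        if code is None:
            raise CodecError(f"invalid character {c!r}")
        p_lo = int(self._out_cum[iv.lo - 1])
        p_hi = int(self._out_cum[iv.hi])
        n_before = self._rank_c(code, p_lo)
        n_upto = self._rank_c(code, p_hi)
        if n_upto == n_before:
            return EMPTY_INTERVAL
        e_lo = int(self._C[code]) + n_before + 1
        e_hi = int(self._C[code]) + n_upto
        return NodeInterval(self._node_of_edge(e_lo), self._node_of_edge(e_hi))

    def node_search(self, label) -> int | None:
        """Colexicographic rank of the node with this label, or None.

        Full nodemers (length k-1) are located by backward-search from the
        interval of all nodes; shorter (dummy) labels are located by walking
        the dummy tree down from the root.
        """
        if isinstance(label, PackedKmer):
            label = decode_kmer(label)
        if len(label) > self.k - 1:
            raise ValueError(f"node label longer than k-1={self.k - 1}: {label!r}")
        if label == "":
            return 1
        iv = self.full_interval() if len(label) == self.k - 1 else NodeInterval(1, 1)
        for ch in label:
            iv = self.update_interval(iv, ch)
            if iv.empty:
                return None
        return iv.lo

    def edge_search(self, e) -> int | None:
        """Colexicographic rank of the edge with edgemer label ``e``, or None."""
        if isinstance(e, str):
            if len(e) != self.k:
                raise ValueError(f"edge label must have length k={self.k}")
            prefix, last = e[:-1], e[-1]
        else:
            if e.length != self.k:
                raise ValueError(f"edge label must have length k={self.k}")
            prefix, last = decode_kmer(e.prefix()), e.last
        v = self.node_search(prefix)
        if v is None:
            return None
        return self.out_edge_rank(v, last)

    def out_labels(self, v: int) -> set[str]:
        """The set of single-character labels on edges leaving ``v``."""
        self._check_node(v)
        lo, hi = int(self._out_cum[v - 1]), int(self._out_cum[v])
        return {_CHAR[c] for c in self._ebwt[lo:hi]}

    def in_label(self, v: int) -> str | None:
        """The (unique) incoming edge label of ``v``; None if indegree 0."""
        self._check_node(v)
        if self._indeg[v - 1] == 0:
            return None
        first = int(self._in_cum[v - 1]) + 1
        return _CHAR[self._label_of_edge(first)]

    def out_edge_rank(self, v: int, c: str) -> int | None:
        """Colexicographic rank of the c-labeled edge leaving ``v``, or None."""
        self._check_node(v)
        code = _CODE.get(c)
        if code is None:
            raise CodecError(f"invalid character {c!r}")
        lo, hi = int(self._out_cum[v - 1]), int(self._out_cum[v])
        hits = np.flatnonzero(self._ebwt[lo:hi] == code)
        if len(hits) == 0:
            return None
        return self._edge_rank_at(lo + int(hits[0]))

    def forward(self, v: int, c: str) -> int:
        """Destination node of the c-labeled edge leaving ``v``."""
        r = self.out_edge_rank(v, c)
        if r is None:
            raise LookupError(f"node {v} has no outgoing edge labeled {c!r}")
        return self._node_of_edge(r)

    def forward_edge(self, r: int) -> int:
        """Destination node of the edge with colexicographic rank ``r``."""
        if not 1 <= r <= self.n_edges:
            raise IndexError(f"edge rank {r} out of range [1, {self.n_edges}]")
        return self._node_of_edge(r)

    def backward(self, v: int) -> int | None:
        """Some predecessor of ``v`` (the smallest-rank one); None if indegree 0."""
        self._check_node(v)
        if self._indeg[v - 1] == 0:
            return None
        r = int(self._in_cum[v - 1]) + 1  # smallest incoming edge rank
        c = self._label_of_edge(r)
        pos = int(self._occ[c][r - int(self._C[c]) - 1])
        return self._origin_of_pos(pos)

    def in_edge_interval(self, v: int) -> tuple[int, int]:
        """Closed interval of incoming edge ranks; (lo, hi) with lo > hi if empty."""
        self._check_node(v)
        return int(self._in_cum[v - 1]) + 1, int(self._in_cum[v])

    def node_label(self, v: int) -> str:
        """The nodemer label of ``v``, recovered by walking backward k-1 steps."""
        self._check_node(v)
        chars: list[str] = []
        u = v
        for _ in range(self.k - 1):
            c = self.in_label(u)
            if c is None:
                break
            chars.append(c)
            u = self.backward(u)
        return "".join(reversed(chars))

    def node_labels(self) -> list[str]:
        """All node labels in colexicographic order (mostly for inspection)."""
        return [self.node_label(v) for v in range(1, self.n_nodes + 1)]
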