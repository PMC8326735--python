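"""Dynamic layer: addition buffer, deletion buffer, node tokens.

The modified graph is G' = (V', E') with E' = (E ∪ A) ∖ D, where E is the
edge set of the static index, A the buffered additions and D the buffered
deletions. A lives in a hash map from nodemer to a pair of label bitsets
(incoming over $ACGT — the *first* character of the edgemer whose suffix
the nodemer is — and outgoing over ACGT, its last character). D is a single
bit per static edge, indexed by colexicographic edge rank, so deletions
never grow memory and never force a rebuild.

The buffers are kept synchronized so that A ∩ E = ∅, A ∩ D = ∅ and D ⊆ E
hold after any operation sequence. Traversal works on node tokens: the
static colex rank (if the nodemer is indexed), the buffer entry (if it is
buffered), and the label itself so the buffer can be re-probed after a
step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .index import BossIndex
from .kmer import PackedKmer, decode_kmer, encode_kmer, split_on_invalid

logger = logging.getLogger(__name__)

IN_ALPHABET = "$ACGT"
OUT_ALPHABET = "ACGT"


@dataclass
class AdditionEntry:
    """Incoming ($ACGT) and outgoing (ACGT) label indicator bits for one key."""

    in_bits: int = 0
    out_bits: int = 0

    def set_in(self, c: str) -> None:
        self.in_bits |= 1 << IN_ALPHABET.index(c)

    def clear_in(self, c: str) -> None:
        self.in_bits &= ~(1 << IN_ALPHABET.index(c))

    def has_in(self, c: str) -> bool:
        return bool(self.in_bits >> IN_ALPHABET.index(c) & 1)

    def set_out(self, c: str) -> None:
        self.out_bits |= 1 << OUT_ALPHABET.index(c)

    def clear_out(self, c: str) -> None:
        self.out_bits &= ~(1 << OUT_ALPHABET.index(c))

    def has_out(self, c: str) -> bool:
        return bool(self.out_bits >> OUT_ALPHABET.index(c) & 1)

    @property
    def empty(self) -> bool:
        return self.in_bits == 0 and self.out_bits == 0

    def out_chars(self) -> set[str]:
        return {c for i, c in enumerate(OUT_ALPHABET) if self.out_bits >> i & 1}

    def in_count(self) -> int:
        """Number of incoming edges recorded (a set $ counts its dummy edge)."""
        return bin(self.in_bits).count("1")

    def in_string(self) -> str:
        """5-character 0/1 indicator in alphabet order $ACGT."""
        return "".join("1" if self.in_bits >> i & 1 else "0" for i in range(5))

    def out_string(self) -> str:
        """4-character 0/1 indicator in alphabet order ACGT."""
        return "".join("1" if self.out_bits >> i & 1 else "0" for i in range(4))

    def copy(self) -> "AdditionEntry":
        return AdditionEntry(self.in_bits, self.out_bits)


@dataclass(frozen=True)
class NodeToken:
    """A node of G': static rank and/or buffer entry, plus the label."""

    rank: int | None
    entry: AdditionEntry | None
    label: str


def _as_edgemer(e, k: int) -> str:
    s = decode_kmer(e) if isinstance(e, PackedKmer) else str(e).upper()
    if len(s) != k:
        raise ValueError(f"edgemer must have length k={k}, got {len(s)}")
    encode_kmer(s)  # character validation
    return s


class BufBoss:
    """A static BOSS index made dynamic by addition/deletion buffers.

    ``track_marks`` enables an optional accelerator: a bit per static node
    that is set when the node may be affected by a buffered operation, so
    queries on unmarked nodes skip the buffer lookups entirely. Query
    results never depend on it.

    ``stats`` counts the elementary search steps performed: one
    ``char_steps`` per backward-search interval update (node/edge search)
    and one ``token_steps`` per token traversal step.
    """

    def __init__(self, boss: BossIndex, track_marks: bool = False):
        self.boss = boss
        self.ha: dict[str, AdditionEntry] = {}
        self.bd = np.zeros(boss.n_edges, dtype=bool)
        self.marks = np.zeros(boss.n_nodes, dtype=bool) if track_marks else None
        self.stats = {"char_steps": 0, "token_steps": 0}

    @property
    def k(self) -> int:
        return self.boss.k

    @property
    def n_deleted(self) -> int:
        return int(self.bd.sum())

    def reset_stats(self) -> None:
        self.stats = {"char_steps": 0, "token_steps": 0}

    # -- buffer bookkeeping -------------------------------------------------

    def _entry(self, label: str) -> AdditionEntry:
        e = self.ha.get(label)
        if e is None:
            e = self.ha[label] = AdditionEntry()
        return e

    def _drop_if_empty(self, label: str) -> None:
        e = self.ha.get(label)
        if e is not None and e.empty:
            del self.ha[label]

    def _mark_label(self, label: str) -> None:
        if self.marks is None:
            return
        r = self.boss.node_search(label) if len(label) <= self.k - 1 else None
        if r is not None:
            self.marks[r - 1] = True

    def _mark_rank(self, r: int) -> None:
        if self.marks is not None:
            self.marks[r - 1] = True

    def buffered(self, e) -> bool:
        """Is edgemer ``e`` fully recorded in the addition buffer?"""
        s = _as_edgemer(e, self.k)
        pre, suf = self.ha.get(s[:-1]), self.ha.get(s[1:])
        return (pre is not None and pre.has_out(s[-1])
                and suf is not None and suf.has_in(s[0]))

    # -- updates --------------------------------------------------------------

    def add_edgemer(self, e) -> None:
        """Record edgemer ``e`` for addition (no-op if already present)."""
        s = _as_edgemer(e, self.k)
        r = self.boss.edge_search(s)
        self.stats["char_steps"] += self.k
        if r is not None:
            # resynchronization: re-adding a deleted static edge only
            # clears the deletion mark, preserving A ∩ E = ∅
            if self.bd[r - 1]:
                self.bd[r - 1] = False
                self._mark_rank(self.boss.forward_edge(r))
            return
        self._entry(s[:-1]).set_out(s[-1])
        self._entry(s[1:]).set_in(s[0])
        self._mark_label(s[:-1])
        self._mark_label(s[1:])

    def delete_edgemer(self, e) -> None:
        """Record edgemer ``e`` for deletion (warning no-op if absent)."""
        s = _as_edgemer(e, self.k)
        if self.buffered(s):
            self.ha[s[:-1]].clear_out(s[-1])
            self.ha[s[1:]].clear_in(s[0])
            self._drop_if_empty(s[:-1])
            self._drop_if_empty(s[1:])
            return
        r = self.boss.edge_search(s)
        self.stats["char_steps"] += self.k
        if r is not None:
            self.bd[r - 1] = True
            v = self.boss.forward_edge(r)
            self._mark_rank(v)
            self._mark_label(s[:-1])
        else:
            logger.warning("delete of absent edgemer %s ignored", s)

    # -- tokens ----------------------------------------------------------------

    def make_token(self, label: str) -> NodeToken:
        """Token for a nodemer label (rank and entry each possibly absent)."""
        label = str(label).upper()
        rank = self.boss.node_search(label)
        self.stats["char_steps"] += len(label)
        return NodeToken(rank, self.ha.get(label), label)

    def _boss_edge_deleted(self, v: int, c: str) -> bool:
        r = self.boss.out_edge_rank(v, c)
        return r is not None and bool(self.bd[r - 1])

    def _unaffected(self, t: NodeToken) -> bool:
        """Mark-vector fast path: node certainly untouched by the buffers."""
        return (self.marks is not None and t.rank is not None
                and not self.marks[t.rank - 1] and t.entry is None)

    def token_exists(self, t: NodeToken) -> bool:
        """Does the node exist in G'?"""
        if t.entry is not None and not t.entry.empty:
            return True
        if t.rank is None:
            return False
        if self._unaffected(t):
            return self.boss.indegree(t.rank) + self.boss.outdegree(t.rank) > 0
        lo, hi = self.boss.in_edge_interval(t.rank)
        if lo <= hi and not self.bd[lo - 1:hi].all():
            return True
        return any(not self._boss_edge_deleted(t.rank, c)
                   for c in self.boss.out_labels(t.rank))

    def _out_labels(self, t: NodeToken) -> set[str]:
        labels: set[str] = set()
        if t.rank is not None:
            if self._unaffected(t):
                return self.boss.out_labels(t.rank)
            labels = {c for c in self.boss.out_labels(t.rank)
                      if not self._boss_edge_deleted(t.rank, c)}
        if t.entry is not None:
            labels |= t.entry.out_chars()
        return labels

    def token_out_labels(self, t: NodeToken) -> set[str]:
        """Outgoing single-character labels of the node in G'."""
        if not self.token_exists(t):
            raise LookupError(f"node {t.label!r} does not exist in the modified graph")
        return self._out_labels(t)

    def token_forward(self, t: NodeToken, c: str) -> NodeToken:
        """Traverse the c-labeled out-edge of ``t`` in G'."""
        if c not in self._out_labels(t):
            raise LookupError(f"node {t.label!r} has no outgoing label {c!r} in G'")
        return self._step(t, c)

    def _step(self, t: NodeToken, c: str) -> NodeToken:
        new_label = t.label[1:] + c
        self.stats["token_steps"] += 1
        if t.rank is not None and self.boss.out_edge_rank(t.rank, c) is not None:
            rank = self.boss.forward(t.rank, c)
        else:
            rank = self.boss.node_search(new_label)
            self.stats["char_steps"] += len(new_label)
        return NodeToken(rank, self.ha.get(new_label), new_label)

    # -- membership -----------------------------------------------------------

    def edgemer_present(self, e) -> bool:
        """Membership of ``e`` in E' = (E ∪ A) ∖ D."""
        s = _as_edgemer(e, self.k)
        r = self.boss.edge_search(s)
        self.stats["char_steps"] += self.k
        if r is not None:
            return not self.bd[r - 1]
        return self.buffered(s)

    def query_read(self, read: str) -> list[bool]:
        """Per-edgemer membership along a read, by graph traversal.

        A positive answer advances the previous token one step instead of
        searching the next edgemer from scratch, so an in-graph read of
        length m costs O(m) token steps rather than O(k·m) character steps.
        Windows containing non-ACGT characters are reported absent. The
        answers are identical to independent ``edgemer_present`` calls.
        """
        read = str(read).upper()
        k = self.k
        if len(read) < k:
            return []
        valid = np.frombuffer(read.encode(), dtype=np.uint8)
        ok = (valid == ord("A")) | (valid == ord("C")) | (valid == ord("G")) | (valid == ord("T"))
        window_ok = np.convolve(ok.astype(int), np.ones(k, int), "valid") == k
        result: list[bool] = []
        token: NodeToken | None = None
        for i in range(len(read) - k + 1):
            if not window_ok[i]:
                result.append(False)
                token = None
                continue
            if token is None:
                token = self.make_token(read[i:i + k - 1])
            c = read[i + k - 1]
            if c in self._out_labels(token):
                result.append(True)
                token = self._step(token, c)
            else:
                result.append(False)
                token = None
        return result

    def query_sequence(self, seq: str, mode: str = "read") -> list[bool]:
        """Per-edgemer membership for one query sequence.

        ``mode='read'`` uses graph traversal; ``mode='edgemer'`` searches
        every window independently.
        """
        if mode == "read":
            return self.query_read(seq)
        if mode != "edgemer":
            raise ValueError(f"unknown query mode {mode!r}")
        seq = str(seq).upper()
        k = self.k
        out = []
        for i in range(max(0, len(seq) - k + 1)):
            window = seq[i:i + k]
            try:
                out.append(self.edgemer_present(window))
            except ValueError:
                out.append(False)
        return out

    # -- flushing (delegates to the batch-update module) -----------------------

    def flush(self, cleanup: bool = True) -> None:
        from .update import flush

        flush(self, cleanup=cleanup)

    def flush_if_needed(self, t: float, force: bool = False, cleanup: bool = True) -> bool:
        from .update import flush_if_needed

        return flush_if_needed(self, t, force=force, cleanup=cleanup)
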