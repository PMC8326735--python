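"""Batched merge of the buffers into the static index.

Flushing runs four phases:

1. *Dummy preparation* — nodes about to lose every incoming edge (and
   buffer-only nodemers that never had one) get an incoming chain of dummy
   prefixes recorded in the addition buffer; the node itself records the
   chain with the $ incoming bit.
2. *Merge planning* — the buffered node labels, $-padded and sorted, are
   aligned against the (never materialized) matrix of static node labels by
   k-1 rounds of partition refinement; static columns are produced right to
   left by propagating in-edge labels forward through the graph.
3. *Merge execution* — the interval pairs are streamed in colexicographic
   order; every emitted node appends its label-sorted outgoing set and its
   indegree to the new ebwt/O/I, with deletions subtracted on the fly.
   Nodes left with no incident edge at all are not emitted (the root always
   is).
4. *Dummy cleanup* (optional, on by default) — chains that became redundant
   (their target gained a real in-edge, or lost every out-edge and thereby
   left the graph) are pruned bottom-up.

The result is bit-identical to building the index of (E ∪ A) ∖ D from
scratch, thanks to the canonical label-sorted tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamic import AdditionEntry, BufBoss
from .index import BossIndex, PAD
from .kmer import _CHAR, _CODE

DOLLAR = -1  # column code for the $ padding / no-in-edge marker


@dataclass(frozen=True)
class BufferRow:
    """One row of the buffer matrix: a padded label plus its buffer entry."""

    padded_label: str
    entry: AdditionEntry

    @property
    def label(self) -> str:
        return self.padded_label.lstrip(PAD)

    @property
    def is_root(self) -> bool:
        return set(self.padded_label) <= {PAD}

    @property
    def is_dummy(self) -> bool:
        return PAD in self.padded_label or self.padded_label == ""


@dataclass(frozen=True)
class IntervalPair:
    """Half-open row ranges into the BOSS matrix and the buffer matrix."""

    boss_lo: int
    boss_hi: int
    buf_lo: int
    buf_hi: int

    @property
    def boss_size(self) -> int:
        return self.boss_hi - self.boss_lo

    @property
    def buf_size(self) -> int:
        return self.buf_hi - self.buf_lo


# ---------------------------------------------------------------------------
# Phase 1: dummy preparation
# ---------------------------------------------------------------------------


def _surviving_out(state: BufBoss, v: int, label: str) -> bool:
    """Does node ``v`` keep at least one outgoing edge in G'?"""
    boss = state.boss
    for c in boss.out_labels(v):
        r = boss.out_edge_rank(v, c)
        if not state.bd[r - 1]:
            return True
    entry = state.ha.get(label)
    return entry is not None and entry.out_bits != 0


def _add_chain(state: BufBoss, label: str) -> None:
    """Record the incoming dummy chain of ``label`` in the addition buffer."""
    for i in range(len(label)):
        state._entry(label[:i]).set_out(label[i])
    state._entry(label).set_in(PAD)


def prepare_dummies(state: BufBoss) -> None:
    """Add incoming dummy chains for nodes left without in-edges.

    Two passes: (a) every static node whose in-edges are all marked for
    deletion and that has no buffered incoming edge; (b) every buffered
    full nodemer absent from the static index whose incoming bitset is
    empty. Nodes with no surviving outgoing edge vanish from G' entirely
    and get no chain.
    """
    boss, bd = state.boss, state.bd
    # pass (a): scan deletion-marked edges in colexicographic edge order
    for e in np.flatnonzero(bd) + 1:
        v = boss.forward_edge(int(e))
        lo, hi = boss.in_edge_interval(v)
        if not bd[lo - 1:hi].all():
            continue
        label = boss.node_label(v)
        entry = state.ha.get(label)
        if entry is not None and entry.in_bits != 0:
            continue  # buffered incoming edge (or chain already recorded)
        if not _surviving_out(state, v, label):
            continue  # node leaves the graph; no chain needed
        _add_chain(state, label)
    # pass (b): buffer-only nodemers that are prefixes but never suffixes
    for label in [x for x, ent in state.ha.items()
                  if len(x) == boss.k - 1 and ent.in_bits == 0]:
        if boss.node_search(label) is None:
            _add_chain(state, label)


# ---------------------------------------------------------------------------
# Phase 2: merge planning
# ---------------------------------------------------------------------------


def build_buffer_matrix(ha: dict[str, AdditionEntry], k: int) -> list[BufferRow]:
    """The buffered node labels, $-padded to width k-1, in colex order."""
    rows = [BufferRow(PAD * (k - 1 - len(x)) + x, ent) for x, ent in ha.items()]
    rows.sort(key=lambda r: r.padded_label[::-1])
    return rows


def _padded_codes(rows: list[BufferRow], k: int) -> np.ndarray:
    """Buffer matrix as an (n_buffer, k-1) array of codes, $ = -1."""
    mat = np.full((len(rows), k - 1), DOLLAR, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row.padded_label):
            if ch != PAD:
                mat[i, j] = _CODE[ch]
    return mat


def last_column(boss: BossIndex) -> np.ndarray:
    """The rightmost BOSS-matrix column: in-edge label per node, $ if none."""
    col = np.full(boss.n_nodes, DOLLAR, dtype=np.int8)
    for v in range(1, boss.n_nodes + 1):
        c = boss.in_label(v)
        if c is not None:
            col[v - 1] = _CODE[c]
    return col


def prev_column(boss: BossIndex, col: np.ndarray) -> np.ndarray:
    """Given column i of the BOSS matrix, produce column i-1.

    Labels are propagated forward along every edge (all in-edges of a node
    carry the same history, so the assignment is consistent); the root is
    forced to $.
    """
    if len(col) != boss.n_nodes:
        raise ValueError("column length does not match the number of nodes")
    new = np.full(boss.n_nodes, DOLLAR, dtype=np.int8)
    new[boss._edge_dest - 1] = col[boss._edge_origin - 1]
    new[0] = DOLLAR
    return new


def plan_merge(boss: BossIndex, rows: list[BufferRow], k: int) -> list[IntervalPair]:
    """k-1 rounds of partition refinement aligning buffer rows to BOSS rows.

    The returned pairs cover [1, n_boss+1) and [1, n_buffer+1) in order;
    after the final round every pair groups rows with identical padded
    labels, so pairs with both sides nonempty are exactly the shared nodes.
    """
    n_boss, n_buf = boss.n_nodes, len(rows)
    mbuf = _padded_codes(rows, k)
    col = last_column(boss)
    pairs = [IntervalPair(1, n_boss + 1, 1, n_buf + 1)]
    for t in range(1, k):
        refined: list[IntervalPair] = []
        bcol = mbuf[:, k - 1 - t] if n_buf else None
        for p in pairs:
            x, y = p.boss_lo, p.buf_lo
            for c in (DOLLAR, 0, 1, 2, 3):
                x2 = x
                while x2 < p.boss_hi and col[x2 - 1] == c:
                    x2 += 1
                y2 = y
                while y2 < p.buf_hi and bcol[y2 - 1] == c:
                    y2 += 1
                if x2 > x or y2 > y:
                    refined.append(IntervalPair(x, x2, y, y2))
                x, y = x2, y2
        pairs = refined
        if t < k - 1:
            col = prev_column(boss, col)
    return pairs


# ---------------------------------------------------------------------------
# Phase 3: merge execution
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates the new ebwt / outdegree / indegree streams."""

    def __init__(self) -> None:
        self.ebwt: list[int] = []
        self.outdeg: list[int] = []
        self.indeg: list[int] = []

    def add_node(self, out_labels: list[str], indegree: int) -> None:
        self.ebwt.extend(_CODE[c] for c in out_labels)
        self.outdeg.append(len(out_labels))
        self.indeg.append(indegree)


def _boss_survivors(boss: BossIndex, bd: np.ndarray, v: int) -> set[str]:
    return {c for c in boss.out_labels(v)
            if not bd[boss.out_edge_rank(v, c) - 1]}


def _boss_indeg_after(boss: BossIndex, bd: np.ndarray, v: int) -> int:
    lo, hi = boss.in_edge_interval(v)
    return boss.indegree(v) - int(bd[lo - 1:hi].sum())


def _buffer_in_count(row: BufferRow, shared: bool) -> int:
    """Indegree contributed by a buffer row to the merged node.

    Full nodemers contribute their recorded incoming edges (a $ bit is the
    new dummy chain edge). Dummy rows have exactly one parent edge, which
    already exists in the static index when the row is shared; the root has
    none.
    """
    if not row.is_dummy:
        return row.entry.in_count()
    if row.is_root or shared:
        return 0
    return 1


def execute_merge(boss: BossIndex, rows: list[BufferRow],
                  plan: list[IntervalPair], bd: np.ndarray) -> BossIndex:
    """Stream the interval pairs into the ebwt/O/I of the updated index."""
    b = _Builder()
    for p in plan:
        if p.boss_size == 1 and p.buf_size == 1:  # shared node
            v, row = p.boss_lo, rows[p.buf_lo - 1]
            out = sorted(_boss_survivors(boss, bd, v) | row.entry.out_chars())
            ind = _boss_indeg_after(boss, bd, v) + _buffer_in_count(row, shared=True)
            b.add_node(out, ind)
        elif p.boss_size == 0:  # buffer-only nodes
            for j in range(p.buf_lo, p.buf_hi):
                row = rows[j - 1]
                b.add_node(sorted(row.entry.out_chars()),
                           _buffer_in_count(row, shared=False))
        else:  # BOSS-only nodes
            for v in range(p.boss_lo, p.boss_hi):
                out = sorted(_boss_survivors(boss, bd, v))
                ind = _boss_indeg_after(boss, bd, v)
                if out or ind or v == 1:  # fully isolated nodes vanish; root stays
                    b.add_node(out, ind)
    return BossIndex(boss.k, np.asarray(b.ebwt, dtype=np.uint8), b.outdeg, b.indeg)


# ---------------------------------------------------------------------------
# Phase 4: dummy cleanup
# ---------------------------------------------------------------------------


def cleanup_dummies(boss: BossIndex) -> BossIndex:
    """Prune dummy chains that are no longer needed.

    Depth-first search of the dummy tree from the root. A leaf dummy's
    out-edge to a full node is redundant when the node has another incoming
    edge (indegree >= 2) or no outgoing edge (it is no longer the endpoint
    of any edgemer and leaves the graph). Dummy in-edges are marked
    bottom-up when every out-edge below was marked. The edgemer set is
    unchanged.
    """
    k = boss.k
    marked_pos: set[int] = set()
    indeg_loss = np.zeros(boss.n_nodes, dtype=np.int64)

    def dfs(v: int, depth: int) -> bool:
        """Mark below dummy node v; True if all of v's out-edges got marked."""
        all_marked = True
        lo, hi = int(boss._out_cum[v - 1]), int(boss._out_cum[v])
        for pos in range(lo, hi):
            u = int(boss._edge_dest[pos])
            if depth + 1 < k - 1:  # child is another dummy
                if dfs(u, depth + 1):
                    marked_pos.add(pos)
                    indeg_loss[u - 1] += 1
                else:
                    all_marked = False
            else:  # child is a full nodemer
                if boss.indegree(u) >= 2 or boss.outdegree(u) == 0:
                    marked_pos.add(pos)
                    indeg_loss[u - 1] += 1
                else:
                    all_marked = False
        return all_marked

    if boss.n_edges == 0:
        return boss
    dfs(1, 0)
    if not marked_pos:
        return boss

    b = _Builder()
    for v in range(1, boss.n_nodes + 1):
        lo, hi = int(boss._out_cum[v - 1]), int(boss._out_cum[v])
        out = [_CHAR[boss._ebwt[pos]] for pos in range(lo, hi) if pos not in marked_pos]
        ind = boss.indegree(v) - int(indeg_loss[v - 1])
        if out or ind or v == 1:
            b.add_node(out, ind)
    return BossIndex(k, np.asarray(b.ebwt, dtype=np.uint8), b.outdeg, b.indeg)


# ---------------------------------------------------------------------------
# Flushing policy
# ---------------------------------------------------------------------------


def flush(state: BufBoss, cleanup: bool = True) -> None:
    """Run the full four-phase update and clear both buffers."""
    prepare_dummies(state)
    rows = build_buffer_matrix(state.ha, state.boss.k)
    plan = plan_merge(state.boss, rows, state.boss.k)
    new = execute_merge(state.boss, rows, plan, state.bd)
    if cleanup:
        new = cleanup_dummies(new)
    state.boss = new
    state.ha = {}
    state.bd = np.zeros(new.n_edges, dtype=bool)
    if state.marks is not None:
        state.marks = np.zeros(new.n_nodes, dtype=bool)


def flush_if_needed(state: BufBoss, t: float, force: bool = False,
                    cleanup: bool = True) -> bool:
    """Flush when the buffer exceeds fraction ``t`` of the indexed edges.

    The trigger is |buffered nodemers| > t · n_edges (or ``force``).
    Deletions alone never trigger a flush: the deletion bit vector does not
    grow with the number of deletions.
    """
    if not 0 <= t <= 1:
        raise ValueError(f"flush threshold t={t} must be in [0, 1]")
    if force or len(state.ha) > t * state.boss.n_edges:
        flush(state, cleanup=cleanup)
        return True
    return False
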