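"""Brute-force reference implementation and synthetic-instance generators.

Everything here works on explicit Python strings, sets and dicts — no
packed integers, no rank/select — so it can serve as an independent ground
truth for the succinct index, the dynamic buffers and the batched update.
The package's worked reference example (the four strings ACGTA, ACACGT,
AGTA, GCGCGCGA at k=4, and the update that adds the edgemers of CGCACAGT
while deleting CGCG, CGTA, ACAC) ships as named constants used across the
test suite.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

PAD = "$"
ALPHABET = "ACGT"
_RC = str.maketrans("ACGT", "TGCA")

# The reference fixture: a 13-node Wheeler graph with a 4-node dummy tree.
G1_STRINGS = ("ACGTA", "ACACGT", "AGTA", "GCGCGCGA")
G1_K = 4
UPDATE_ADD_SEQUENCE = "CGCACAGT"
UPDATE_DELETE_EDGEMERS = ("CGCG", "CGTA", "ACAC")


def rc_str(s: str) -> str:
    return s.translate(_RC)[::-1]


def string_edgemers(seqs, k: int, add_rc: bool = False) -> set[str]:
    """Naive string-slicing edgemer enumeration (splits on non-ACGT)."""
    out: set[str] = set()
    todo = list(seqs)
    if add_rc:
        todo += [rc_str(s.upper()) for s in seqs if set(s.upper()) <= set(ALPHABET)]
        # for sequences with invalid characters, reverse-complement per piece
        todo += [rc_str(p) for s in seqs if not set(s.upper()) <= set(ALPHABET)
                 for p in _pieces(s)]
    for s in todo:
        for piece in _pieces(s):
            out.update(piece[i:i + k] for i in range(len(piece) - k + 1))
    return out


def _pieces(s: str) -> list[str]:
    s = s.upper()
    pieces, cur = [], []
    for ch in s:
        if ch in ALPHABET:
            cur.append(ch)
        elif cur:
            pieces.append("".join(cur))
            cur = []
    if cur:
        pieces.append("".join(cur))
    return pieces


def g1_edgemers() -> set[str]:
    return string_edgemers(G1_STRINGS, G1_K)


def reference_update_script() -> list[tuple[str, str]]:
    """The update script of the worked example, as (op, edgemer) pairs."""
    adds = sorted(string_edgemers([UPDATE_ADD_SEQUENCE], G1_K))
    return [("add", e) for e in adds] + [("del", e) for e in UPDATE_DELETE_EDGEMERS]


def colex_key(label: str, width: int) -> str:
    return (PAD * (width - len(label)) + label)[::-1]


@dataclass
class OracleGraph:
    """Explicit edge-centric de Bruijn graph with its dummy tree.

    Node labels are kept in colexicographic order of their $-padded forms;
    ``adjacency[u][c]`` is the destination label of the c-labeled edge out
    of u; edges are the strings ℓ(e) (the destination prefix for dummy
    edges, the full edgemer otherwise) in colexicographic order.
    """

    k: int
    labels: list[str]
    rank: dict[str, int]                    # label -> 1-based colex rank
    adjacency: dict[str, dict[str, str]]
    predecessors: dict[str, list[str]]
    edge_labels: list[str]                  # colex order of ℓ(e)
    edge_rank: dict[str, int]
    dummies: set[str] = field(default_factory=set)

    # ---- degree / label queries ----------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edge_labels)

    def outdegrees(self) -> list[int]:
        return [len(self.adjacency[u]) for u in self.labels]

    def indegrees(self) -> list[int]:
        return [len(self.predecessors[u]) for u in self.labels]

    def out_labels(self, label: str) -> set[str]:
        return set(self.adjacency[label])

    def in_label(self, label: str) -> str | None:
        return label[-1] if self.predecessors[label] else None

    def in_edge_interval(self, label: str) -> tuple[int, int]:
        ranks = sorted(self.edge_rank[self._edge_to(p, label)]
                       for p in self.predecessors[label])
        if not ranks:
            return (1, 0)
        return ranks[0], ranks[-1]

    def _edge_to(self, pred: str, label: str) -> str:
        """ℓ(e) for the edge pred -> label."""
        if len(pred) < self.k - 1:
            return label  # dummy edge: the destination prefix itself
        return pred + label[-1]

    def mboss(self) -> list[str]:
        """The node-label matrix: padded labels in colex order."""
        w = self.k - 1
        return [PAD * (w - len(u)) + u for u in self.labels]

    def ebwt(self) -> str:
        out = []
        for u in self.labels:
            out.extend(sorted(self.adjacency[u]))
        return "".join(out)

    def unary(self, degrees) -> str:
        return "".join("1" + "0" * d for d in degrees)


def oracle_graph(E, k: int) -> OracleGraph:
    """Materialize the graph of an edgemer set, dummy closure included."""
    E = {str(e) for e in E}
    if any(len(e) != k for e in E):
        raise ValueError("all edgemers must have length k")
    nodes = {e[:-1] for e in E} | {e[1:] for e in E} | {""}
    have_in = {e[1:] for e in E}
    dummies = {""}
    chain_edges: set[tuple[str, str]] = set()
    for x in nodes - have_in - {""}:
        for i in range(len(x)):
            dummies.add(x[:i])
            chain_edges.add((x[:i], x[: i + 1]))
    nodes |= dummies

    adjacency: dict[str, dict[str, str]] = {u: {} for u in nodes}
    predecessors: dict[str, list[str]] = {u: [] for u in nodes}
    for e in E:
        adjacency[e[:-1]][e[-1]] = e[1:]
        predecessors[e[1:]].append(e[:-1])
    for u, v in chain_edges:
        adjacency[u][v[-1]] = v
        predecessors[v].append(u)

    labels = sorted(nodes, key=lambda s: colex_key(s, k - 1))
    rank = {u: i + 1 for i, u in enumerate(labels)}
    edge_labels = sorted(
        [e for e in E] + [v for _, v in chain_edges],
        key=lambda s: colex_key(s, k),
    )
    edge_rank = {e: i + 1 for i, e in enumerate(edge_labels)}
    for u in nodes:
        predecessors[u].sort(key=rank.get)
    return OracleGraph(k, labels, rank, adjacency, predecessors,
                       edge_labels, edge_rank, dummies)


def oracle_dynamic(E, script) -> set[str]:
    """Plain-set semantics of an add/delete script: (E ∪ adds) ∖ deletes."""
    cur = {str(e) for e in E}
    for op, e in script:
        if op == "add":
            cur.add(e)
        elif op == "del":
            cur.discard(e)
        else:
            raise ValueError(f"unknown op {op!r}")
    return cur


# ---- synthetic instances ------------------------------------------------


def random_genome(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(length))


def random_reads(rng: random.Random, genome: str, n_reads: int, read_len: int) -> list[str]:
    reads = []
    read_len = min(read_len, len(genome))
    for _ in range(n_reads):
        i = rng.randrange(len(genome) - read_len + 1)
        reads.append(genome[i:i + read_len])
    return reads


def random_script(rng: random.Random, base: set[str], k: int,
                  n_ops: int = 20, strict: bool = True) -> list[tuple[str, str]]:
    """Interleaved adds/deletes; deletes are drawn from the current set.

    With ``strict`` a delete always targets a currently present edgemer;
    otherwise absent edgemers may be requested (exercising the warning
    path).
    """
    cur = set(base)
    script: list[tuple[str, str]] = []
    for _ in range(n_ops):
        if cur and rng.random() < 0.45:
            pool = sorted(cur)
            e = rng.choice(pool) if strict or rng.random() < 0.8 else \
                "".join(rng.choice(ALPHABET) for _ in range(k))
            script.append(("del", e))
            cur.discard(e)
        else:
            e = "".join(rng.choice(ALPHABET) for _ in range(k))
            script.append(("add", e))
            cur.add(e)
    return script


def random_instance(seed: int, genome_len: int = 200, n_reads: int = 20,
                    read_len: int = 40, k: int = 5, n_ops: int = 20,
                    strict: bool = True):
    """Reproducible (reads, script) pair for randomized testing."""
    rng = random.Random(seed)
    genome = random_genome(rng, genome_len)
    reads = random_reads(rng, genome, n_reads, read_len)
    base = string_edgemers(reads, k)
    script = random_script(rng, base, k, n_ops=n_ops, strict=strict)
    return reads, script
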