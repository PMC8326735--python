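"""Construction of a :class:`BossIndex` from a set of edgemers.

The pipeline mirrors the classic triple-sorting construction, entirely in
memory: every edgemer c1..ck contributes a right context (prefix nodemer,
ck) and a left context (suffix nodemer, c1); nodemers without any left
context receive an incoming chain of dummy prefix nodes down from the empty
root, with shared prefixes glued. Grouping the sorted contexts by nodemer
then yields, in colexicographic order, each node's outgoing label set and
indegree — exactly the information the index stores.

A left context '$' stands for the single incoming dummy edge of a node.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .index import BossIndex, PAD
from .kmer import PackedKmer, _CODE, check_k, decode_kmer, encode_kmer

RIGHT = "R"
LEFT = "L"

Context = tuple[str, str, str]  # (nodemer label, character, side)


def colex_key(label: str, width: int) -> str:
    """Sort key realizing colexicographic order of $-padded labels."""
    return (PAD * (width - len(label)) + label)[::-1]


def _as_strings(E: Iterable, k: int) -> list[str]:
    out = []
    for e in E:
        s = decode_kmer(e) if isinstance(e, PackedKmer) else str(e)
        if len(s) != k:
            raise ValueError(f"edgemer {s!r} does not have length k={k}")
        out.append(s)
    return out


def collect_contexts(E: Iterable, k: int) -> list[Context]:
    """Sorted, deduplicated (nodemer, character, side) triples of an edgemer set."""
    check_k(k)
    triples: set[Context] = set()
    for s in _as_strings(E, k):
        triples.add((s[:-1], s[-1], RIGHT))
        triples.add((s[1:], s[0], LEFT))
    return sorted(triples, key=lambda t: (colex_key(t[0], k - 1), t[2], t[1]))


def dummy_closure(contexts: list[Context], k: int) -> list[Context]:
    """Contexts for the dummy-prefix chains of nodemers with no left context.

    For every nodemer x lacking a left context, each proper prefix of x
    (including the empty root) gains a right context toward the next
    character; every non-root chain node, and x itself, gains a single '$'
    left context standing for its incoming dummy edge. Chains sharing a
    prefix are glued by deduplication.
    """
    has_left = {x for x, _, side in contexts if side == LEFT}
    nodemers = {x for x, _, _ in contexts}
    extra: set[Context] = set()
    for x in sorted(nodemers - has_left):
        for i in range(len(x)):
            extra.add((x[:i], x[i], RIGHT))
            if i > 0:
                extra.add((x[:i], PAD, LEFT))
        extra.add((x, PAD, LEFT))
    return sorted(extra, key=lambda t: (colex_key(t[0], k - 1), t[2], t[1]))


def build_index(E: Iterable, k: int) -> BossIndex:
    """Build the Wheeler-graph index (with dummy tree) over an edgemer set.

    Deterministic: edges within a node are label-sorted. The empty root is
    always materialized, so rank 1 is stable even for fully cyclic graphs;
    an empty edgemer set yields the root-only index.
    """
    check_k(k)
    contexts = collect_contexts(E, k)
    contexts = contexts + dummy_closure(contexts, k)

    out_chars: dict[str, set[str]] = {"": set()}
    in_chars: dict[str, set[str]] = {"": set()}
    for x, c, side in contexts:
        out_chars.setdefault(x, set())
        in_chars.setdefault(x, set())
        (out_chars if side == RIGHT else in_chars)[x].add(c)

    labels = sorted(out_chars, key=lambda s: colex_key(s, k - 1))
    ebwt_codes: list[int] = []
    outdeg = np.empty(len(labels), dtype=np.int64)
    indeg = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        outs = sorted(out_chars[lab])
        ebwt_codes.extend(_CODE[c] for c in outs)
        outdeg[i] = len(outs)
        indeg[i] = len(in_chars[lab])
    return BossIndex(k, np.asarray(ebwt_codes, dtype=np.uint8), outdeg, indeg)


def build_from_sequences(seqs: Iterable[str], k: int, add_rc: bool = False) -> BossIndex:
    """Convenience: enumerate the edgemers of ``seqs`` and build the index."""
    from .kmer import enumerate_edgemers

    return build_index(enumerate_edgemers(seqs, k, add_rc=add_rc), k)
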