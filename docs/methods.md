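# Methods

This note records what `bufboss` computes, how, and which design choices
were made where a contract had to be fixed.

## 1. Graph model

Given an alphabet Σ = {A, C, G, T} and an order k (2 ≤ k ≤ 32), the
edge-centric de Bruijn graph of an edgemer set E ⊆ Σ^k has:

- one node per nodemer (length-(k−1) substring occurring as a prefix or
  suffix of some edgemer),
- one edge u → v per edgemer e with u = e[1..k−1], v = e[2..k], labeled
  with the single character e[k].

To make backward search total, a **dummy tree** is added: for every node
with indegree 0, all of its proper prefixes (down to the empty string ε)
become nodes, connected in a chain; chains sharing a prefix are glued. ε
is *always* materialized, even for fully cyclic graphs, so colex rank 1 is
stable.

Nodes are ordered colexicographically with labels shorter than k−1
compared as if left-padded with `$`, where `$ < A < C < G < T`. Edges are
ordered colexicographically by their string label ℓ(e) (the full edgemer,
or the destination prefix for dummy edges).

## 2. Static index (BOSS)

The index stores, in colexicographic node order:

- `ebwt` — one character per edge, grouped by origin node, **label-sorted
  within each node**. The underlying construction allows breaking these
  ties arbitrarily; fixing them by label makes the representation
  canonical, so independently built or merged indexes can be compared
  bit-for-bit.
- `O`, `I` — out-/indegree sequences, conceptually unary bit vectors
  `1·0^d` with rank/select support.
- `C` — per-character cumulative counts of `ebwt`, linking an `ebwt`
  position p with label c to the edge's colex rank `C[c] + rank_c(p) + 1`
  (the last-to-first mapping).

Navigation (all ranks 1-based): `node_search` runs backward search —
full-length labels start from the interval of all nodes, shorter (dummy)
labels walk down from the root interval. `forward`, `backward`,
`out_labels`, `in_label`, `out_edge_rank`, `in_edge_interval` and
`node_label` are standard rank/select arithmetic on the three sequences.
`backward` returns the smallest-rank predecessor (any would be valid).

Rank/select is implemented with plain precomputed position directories on
numpy arrays (`bufboss.bitvectors`): O(log n) binary search per query,
which is ample at the scales this package targets. Compressed or
constant-time structures are deliberately out of scope.

**Construction** (`bufboss.build`) is the in-memory triple-sort: every
edgemer contributes a (prefix-nodemer, last-char, out) and a
(suffix-nodemer, first-char, in) context; the dummy closure adds chain
contexts with `$` marking each chain node's single in-edge; grouping the
colex-sorted contexts yields `ebwt`, `O`, `I` directly. External-memory
k-mer counting and disk sorting, used by large-scale tools, are replaced
by hash sets and `sorted()` — same output contract.

## 3. Dynamic layer

`BufBoss` holds the static index plus:

- **HA** (addition buffer): nodemer → (incoming bitset over `$ACGT`,
  outgoing bitset over `ACGT`). Adding edgemer e sets the out-bit of
  e[1..k−1] and the in-bit of e[2..k]. The `$` in-bit marks an incoming
  dummy-chain edge and is recorded lazily by the update algorithm, not on
  every add.
- **BD** (deletion buffer): one bit per static edge, indexed by colex edge
  rank. Deletions never grow memory.

Synchronization invariants maintained by every operation: A ∩ E = ∅,
A ∩ D = ∅, D ⊆ E. Two branches are worth noting: re-adding a
deleted-but-indexed edgemer only clears its BD bit (never touches HA), and
deleting an absent edgemer is a warning-level no-op.

Traversal uses **node tokens** `(rank, entry, label)`: the static colex
rank if the nodemer is indexed, the HA entry if buffered, and the label
itself so the buffer can be re-probed after a step. A token's rank is
*canonical*: it is present exactly when the nodemer exists in the static
index, even if the step that produced it crossed a buffer-only edge.

`query_read` advances a token per window on a hit and re-searches only
after a miss, so an in-graph read with m windows costs m token steps plus
one initial (k−1)-character search, versus k·m searched characters for
independent window queries. The package asserts these operation counts
with instrumented counters rather than timing hardware.

An optional **mark vector** (one bit per static node, set when a buffered
operation may affect the node) lets queries on unmarked nodes skip buffer
checks. It is off by default and never changes results — verified
bit-for-bit in the tests.

## 4. Batched merge

`flush` merges the buffers into the static index in four phases:

1. **Dummy preparation.** Scan BD in colex edge order; a node whose
   incoming edges are all marked for deletion, and that has no buffered
   incoming edge, gets a new incoming dummy chain recorded in HA (proper
   prefixes gain out-bits, the node gains the `$` in-bit). Two refinements
   were needed beyond the obvious scan: (a) a node that also loses every
   outgoing edge vanishes from the new graph and must *not* get a chain;
   (b) buffer-only nodemers that occur as prefixes of added edgemers but
   never as suffixes need a chain too, so a second pass covers full-length
   HA keys with empty in-bitsets that are absent from the index.
2. **Merge planning.** The HA keys, `$`-padded to width k−1 and colex
   sorted, form the buffer matrix. k−1 rounds of partition refinement
   align it with the static node-label matrix, which is never
   materialized: its rightmost column is each node's in-label, and
   `prev_column` derives column i−1 from column i by pushing labels
   forward along every edge (all in-edges of a node spell the same
   history). The result is a stream of interval pairs covering both
   matrices; after the last round each pair groups rows with identical
   padded labels, so 1/1 pairs are exactly the shared nodes.
3. **Merge execution.** Stream the pairs in order; every emitted node
   appends its label-sorted surviving out-edges (BD subtracted) and its
   indegree (BD-marked in-edges subtracted, buffered in-edges added) to
   the new `ebwt`/`O`/`I`. A buffer row's indegree contribution is the
   popcount of its in-bitset for full nodemers; dummy rows contribute 1
   when buffer-only (their single parent chain edge), 0 when shared or at
   the root. Nodes left with no incident edge are not emitted (the root
   always is).
4. **Dummy cleanup** (default on, CLI `--no-cleanup` to skip). DFS over
   the dummy tree; a leaf dummy's out-edge is redundant when its full-node
   target has another in-edge (indegree ≥ 2) *or* no out-edge (the node
   left the graph); interior chain edges are pruned bottom-up when
   everything below was pruned.

**Correctness contract:** flushing yields an index bit-identical
(`ebwt`, `O`, `I`) to `build_index((E ∪ A) ∖ D)`. This is the central
property of the package and is enforced on the worked fixture and on
hundreds of seeded random scripts with interleaved adds, deletes and
flushes at several thresholds.

**Flush policy:** flush when |HA| > t · n_edges, with t = 0.025 by
default. Deletions alone never trigger a flush (BD does not grow), with
one pragmatic exception: the CLI's `update -t 0` force-flushes pending
deletions so that "keep nothing buffered" means what it says.

## 5. Input handling and CLI

FASTA/FASTQ (multi-line FASTA, qualities ignored) are parsed with
Biopython; gzip is detected by magic bytes. Non-ACGT characters split
sequences into valid pieces; lowercase is upper-cased. The CLI indexes
both strands by default (`--rc`); the library API leaves reverse
complements off so the reference fixture is reproducible verbatim.
Canonical k-mers (min of the strand pair) are *not* used internally; the
helper exists only for reporting.

Serialization is a single-file container: magic `BUFBOSS\x01`, a JSON
manifest, a fixed little-endian payload (`ebwt` bytes, degree arrays,
packed BD bits, HA entries as 2-bit-packed labels plus bitsets) and a
CRC-32 trailer. Round trips are bit-exact; corruption and truncation fail
loudly.

## 6. Parameters and scope

| Parameter | Default | Why |
|---|---|---|
| k | user-set, 2–32 | 32 keeps a nodemer in one 64-bit word; k=2 is the smallest well-defined edge-centric graph |
| t (flush fraction) | 0.025 | balances buffer memory against merge frequency; any value in [0, 1] is accepted |
| rc (CLI) | on | genomic convention of indexing both strands |
| cleanup | on | keeps the index minimal; off mirrors merge output exactly |

All experiments in the test suite are synthetic: random genomes up to
500 bp, reads sampled from them, and random update scripts (these sizes
are this package's own choice — large-scale genome benchmarks are out of
scope, and wall-clock performance is asserted nowhere; complexity claims
are checked by operation counting). Correctness at larger scales follows
from the same code paths; the data-structure constants are simply not
tuned for them (Python dict/numpy rather than succinct hash maps and
compressed bit vectors).

## 7. Known limitations

- Single-threaded, in-memory only; no disk-streamed construction.
- Node sets are implicit; explicit node insertion/deletion is not
  supported (nodes appear and disappear with their edges).
- Alphabet is fixed to ACGT; other IUPAC codes act as sequence breaks.
- `BD` marks persist until a flush; a long deletions-only workload keeps
  the static index size constant rather than shrinking it.
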