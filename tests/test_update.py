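"""Batched merge: column recovery, merge planning, rebuild equivalence."""

import numpy as np
import pytest

from bufboss import BossIndex, BufBoss, build_index
from bufboss.kmer import _CHAR
from bufboss.oracle import (
    reference_update_script,
    oracle_dynamic,
    oracle_graph,
    random_instance,
    string_edgemers,
)
from bufboss.update import (
    DOLLAR,
    build_buffer_matrix,
    cleanup_dummies,
    execute_merge,
    flush,
    flush_if_needed,
    last_column,
    plan_merge,
    prepare_dummies,
    prev_column,
)

from conftest import apply_script


def _decode_col(col):
    return "".join("$" if c == DOLLAR else _CHAR[c] for c in col)


# -- columns of the node-label matrix -----------------------------------------


def test_prev_column_recovers_every_column(g1_boss, g1_oracle):
    m = g1_oracle.mboss()
    k = g1_boss.k
    col = last_column(g1_boss)
    assert _decode_col(col) == "".join(row[k - 2] for row in m)
    for j in range(k - 3, -1, -1):
        col = prev_column(g1_boss, col)
        assert _decode_col(col) == "".join(row[j] for row in m)


def test_prev_column_random_graphs():
    for seed in range(30):
        reads, _ = random_instance(seed)
        E = string_edgemers(reads, 5)
        boss = build_index(E, 5)
        m = oracle_graph(E, 5).mboss()
        col = last_column(boss)
        for j in range(boss.k - 2, -1, -1):
            assert _decode_col(col) == "".join(row[j] for row in m)
            if j:
                col = prev_column(boss, col)


def test_prev_column_length_check(g1_boss):
    with pytest.raises(ValueError):
        prev_column(g1_boss, np.zeros(3, dtype=np.int8))


# -- merge planning -------------------------------------------------------------


def _check_plan_properties(boss, rows, pairs, mboss):
    k = boss.k
    mbuf = [r.padded_label for r in rows]
    # property 1: both sides cover [1, n+1) contiguously and in order
    assert pairs[0].boss_lo == 1 and pairs[0].buf_lo == 1
    assert pairs[-1].boss_hi == boss.n_nodes + 1
    assert pairs[-1].buf_hi == len(rows) + 1
    for a, b in zip(pairs, pairs[1:]):
        assert b.boss_lo == a.boss_hi and b.buf_lo == a.buf_hi
    for p in pairs:
        boss_rows = [mboss[v - 1] for v in range(p.boss_lo, p.boss_hi)]
        buf_rows = [mbuf[j - 1] for j in range(p.buf_lo, p.buf_hi)]
        # property 2: every row in the pair has the same (full) padded label
        assert len(set(boss_rows) | set(buf_rows)) <= 1
    # properties 3 and 4: parts are maximal on each side
    for a, b in zip(pairs, pairs[1:]):
        if a.boss_size and b.boss_size:
            assert mboss[a.boss_lo - 1] != mboss[b.boss_lo - 1]
        if a.buf_size and b.buf_size:
            assert mbuf[a.buf_lo - 1] != mbuf[b.buf_lo - 1]


def test_plan_merge_properties_on_reference_update(g1_boss, g1_oracle, g1_state):
    apply_script(g1_state, reference_update_script())
    prepare_dummies(g1_state)
    rows = build_buffer_matrix(g1_state.ha, 4)
    pairs = plan_merge(g1_boss, rows, 4)
    _check_plan_properties(g1_boss, rows, pairs, g1_oracle.mboss())
    # shared nodes come out as 1/1 pairs with matching labels
    shared = [p for p in pairs if p.boss_size == 1 and p.buf_size == 1]
    assert shared, "the reference update shares nodes with the static index"


def test_plan_merge_properties_random():
    for seed in range(25):
        reads, script = random_instance(seed, n_ops=25)
        E = string_edgemers(reads, 5)
        state = BufBoss(build_index(E, 5))
        apply_script(state, script)
        prepare_dummies(state)
        rows = build_buffer_matrix(state.ha, 5)
        pairs = plan_merge(state.boss, rows, 5)
        _check_plan_properties(state.boss, rows, pairs, oracle_graph(E, 5).mboss())


def test_buffer_matrix_is_colex_sorted(g1_state):
    apply_script(g1_state, reference_update_script())
    prepare_dummies(g1_state)
    rows = build_buffer_matrix(g1_state.ha, 4)
    keys = [r.padded_label[::-1] for r in rows]
    assert keys == sorted(keys)
    assert all(len(r.padded_label) == 3 for r in rows)


# -- dummy preparation ------------------------------------------------------------


def test_prepare_dummies_adds_chain_for_orphaned_node(g1_state):
    """Deleting CGCG leaves GCG without in-edges; it needs a fresh chain."""
    apply_script(g1_state, reference_update_script())
    assert "G" not in g1_state.ha and "GC" not in g1_state.ha
    prepare_dummies(g1_state)
    assert g1_state.ha[""].has_out("G")
    assert g1_state.ha["G"].has_out("C")
    assert g1_state.ha["GC"].has_out("G")
    assert g1_state.ha["GCG"].has_in("$")


def test_prepare_dummies_skips_vanishing_nodes(g1_boss):
    """A node losing all in- AND out-edges leaves G' and gets no chain."""
    state = BufBoss(g1_boss)
    state.delete_edgemer("AGTA")  # GTA keeps its in-edge from CGTA
    state.delete_edgemer("CGTA")  # now GTA is fully isolated in G'
    prepare_dummies(state)
    assert "GTA" not in state.ha
    assert state.ha == {}


def test_prepare_dummies_covers_buffer_only_prefix_nodes():
    """A buffer-only nodemer that is never a suffix needs a chain too."""
    state = BufBoss(BossIndex.empty(4))
    state.add_edgemer("ACGT")
    prepare_dummies(state)
    assert state.ha["ACG"].has_in("$")
    assert state.ha[""].has_out("A")
    assert state.ha["A"].has_out("C")
    assert state.ha["AC"].has_out("G")


# -- merge execution and cleanup ----------------------------------------------------


def test_execute_merge_identity_on_empty_buffers(g1_boss):
    rows = build_buffer_matrix({}, 4)
    plan = plan_merge(g1_boss, rows, 4)
    new = execute_merge(g1_boss, rows, plan, np.zeros(g1_boss.n_edges, bool))
    assert new == g1_boss


def test_flush_identity_on_empty_buffers(g1_boss):
    state = BufBoss(g1_boss)
    flush(state)
    assert state.boss == g1_boss


def test_cleanup_is_identity_on_direct_builds(g1_boss):
    assert cleanup_dummies(g1_boss) == g1_boss
    for seed in range(20):
        reads, _ = random_instance(seed)
        boss = build_index(string_edgemers(reads, 5), 5)
        assert cleanup_dummies(boss) == boss


def test_cleanup_preserves_edgemer_set():
    for seed in range(25):
        reads, script = random_instance(seed, n_ops=25)
        E = string_edgemers(reads, 5)
        state = BufBoss(build_index(E, 5))
        apply_script(state, script)
        target = oracle_dynamic(E, script)
        flush(state, cleanup=False)
        raw = state.boss
        cleaned = cleanup_dummies(raw)
        for e in target:
            assert raw.edge_search(e) is not None
            assert cleaned.edge_search(e) is not None
        # cleanup only removes nodes/edges, never adds
        assert cleaned.n_nodes <= raw.n_nodes
        assert cleaned.n_edges <= raw.n_edges
        assert cleaned == build_index(target, 5)


# -- the worked update example -------------------------------------------------------


def test_reference_update_equals_direct_rebuild(g1_state, g1_set):
    script = reference_update_script()
    apply_script(g1_state, script)
    target = oracle_dynamic(g1_set, script)
    assert len(target) == 10
    g1_state.flush()
    direct = build_index(target, 4)
    assert g1_state.boss == direct
    assert g1_state.boss.ebwt == direct.ebwt
    assert g1_state.boss.O.to01() == direct.O.to01()
    assert g1_state.boss.I.to01() == direct.I.to01()
    # the new dummy chain toward GCG survives cleanup (GCG has no other in-edge)
    assert g1_state.boss.node_search("G") is not None
    assert g1_state.boss.node_search("GC") is not None
    assert g1_state.boss.in_label(g1_state.boss.node_search("GCG")) == "G"
    # buffers are cleared
    assert g1_state.ha == {} and g1_state.n_deleted == 0


# -- rebuild equivalence on random scripts ---------------------------------------------


@pytest.mark.parametrize("threshold", [0.0, 0.2, 1.0])
def test_rebuild_equivalence_random_scripts(threshold):
    for seed in range(20):
        k = 2 + seed % 7
        reads, script = random_instance(seed, k=k, n_ops=30, strict=False)
        E = string_edgemers(reads, k)
        state = BufBoss(build_index(E, k), track_marks=(seed % 3 == 0))
        cur = set(E)
        for i, (op, e) in enumerate(script):
            if op == "add":
                state.add_edgemer(e); cur.add(e)
            else:
                state.delete_edgemer(e); cur.discard(e)
            flush_if_needed(state, threshold)
            if i % 7 == 0:
                assert state.edgemer_present(e) == (e in cur)
        state.flush()
        assert state.boss == build_index(cur, k), (seed, threshold)


def test_flush_to_empty_graph(g1_state, g1_set):
    for e in sorted(g1_set):
        g1_state.delete_edgemer(e)
    g1_state.flush()
    assert g1_state.boss == BossIndex.empty(4)


# -- flushing policy ---------------------------------------------------------------


def test_flush_trigger_semantics(g1_state):
    with pytest.raises(ValueError):
        flush_if_needed(g1_state, -0.1)
    with pytest.raises(ValueError):
        flush_if_needed(g1_state, 1.5)
    # deletions alone never trigger a flush
    g1_state.delete_edgemer("ACGT")
    assert not flush_if_needed(g1_state, 0.0)
    assert g1_state.n_deleted == 1
    # additions trigger once the buffer exceeds t * n_edges
    g1_state.add_edgemer("TTTT")
    assert not flush_if_needed(g1_state, 1.0)  # 1 buffered key <= 13 edges
    assert flush_if_needed(g1_state, 0.0)
    assert g1_state.ha == {} and g1_state.n_deleted == 0
    # force flushes regardless of the threshold
    g1_state.delete_edgemer("AGTA")
    assert flush_if_needed(g1_state, 1.0, force=True)
    assert g1_state.n_deleted == 0


def test_never_flush_and_always_flush_answer_identically(g1_set, g1_boss):
    script = reference_update_script()
    lazy = BufBoss(g1_boss)
    eager = BufBoss(g1_boss)
    probes = sorted(g1_set | {e for _, e in script} | {"TTTT", "AAAA"})
    for op, e in script:
        for st, t in ((lazy, 1.0), (eager, 0.0)):
            if op == "add":
                st.add_edgemer(e)
            else:
                st.delete_edgemer(e)
            st.flush_if_needed(t, force=(t == 0.0))
        for x in probes:
            assert lazy.edgemer_present(x) == eager.edgemer_present(x)
        read = "CGCACAGT"
        assert lazy.query_read(read) == eager.query_read(read)
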