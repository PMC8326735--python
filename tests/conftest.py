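import pytest

from bufboss import BufBoss, build_index
from bufboss import oracle as oracle_mod
from bufboss.oracle import G1_K, g1_edgemers, oracle_graph


@pytest.fixture(scope="session")
def g1_set():
    """Edgemer set of the 13-node reference fixture (k=4)."""
    return g1_edgemers()


@pytest.fixture(scope="session")
def g1_boss(g1_set):
    return build_index(g1_set, G1_K)


@pytest.fixture(scope="session")
def g1_oracle(g1_set):
    return oracle_graph(g1_set, G1_K)


@pytest.fixture()
def g1_state(g1_boss):
    """A fresh dynamic state over the reference index."""
    return BufBoss(g1_boss)


@pytest.fixture()
def empty_state():
    from bufboss import BossIndex

    return BufBoss(BossIndex.empty(G1_K))


def apply_script(state, script):
    for op, e in script:
        if op == "add":
            state.add_edgemer(e)
        else:
            state.delete_edgemer(e)
    return state


@pytest.fixture(scope="session")
def oracle():
    return oracle_mod
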