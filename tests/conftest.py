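import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kinrates as kr

# property tests run derandomized so the suite is reproducible everywhere
settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_tree():
    """((A:100,B:100):50,C:150); -- 3-leaf ultrametric toy, lengths in years."""
    import dendropy

    return dendropy.Tree.get(
        data="((A:100,B:100):50,C:150);", schema="newick", rooting="default-rooted"
    )


@pytest.fixture(scope="session")
def tree47():
    """47-leaf ultrametric Yule tree rooted at 8,700 years."""
    return kr.simulate_tree(47, 8700.0, seed=11)


def brute_force_loglik(tree, character, pi, mu):
    """Independent likelihood oracle: exhaustive sum over all internal-state
    assignments, using closed-form F81 transition probabilities."""
    import itertools

    k = len(pi)
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if n.child_nodes()]
    leaves = [n for n in nodes if not n.child_nodes()]

    def p(i, j, t):
        e = np.exp(-mu * t)
        return pi[j] + ((1.0 if i == j else 0.0) - pi[j]) * e

    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        states = {id(n): s for n, s in zip(internal, assign)}
        prob = pi[states[id(tree.seed_node)]]
        ok = True
        for n in nodes:
            if n is tree.seed_node:
                continue
            parent_state = states[id(n.parent_node)]
            if n.child_nodes():
                prob *= p(parent_state, states[id(n)], n.edge.length)
            else:
                s = character.states.get(n.taxon.label)
                if s is None:
                    continue  # missing tip: sums to 1 over its states
                prob *= p(parent_state, s, n.edge.length)
            if prob == 0.0:
                ok = False
                break
        if ok:
            total += prob
    return np.log(total) if total > 0 else -np.inf


@pytest.fixture(scope="session")
def loglik_oracle():
    return brute_force_loglik
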