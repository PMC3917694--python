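import itertools

import numpy as np
import pytest

from divtime.likelihood import compile_kernels
from divtime.trees import TimeTree


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    compile_kernels()


def balanced_quartet(ages=(1.0, 1.5, 2.0)) -> TimeTree:
    """((a,b),(c,d)) with internal ages (ab, cd, root)."""
    parent = np.array([4, 4, 5, 5, 6, 6, -1])
    children = np.array([[-1, -1]] * 4 + [[0, 1], [2, 3], [4, 5]])
    node_ages = np.array([0.0, 0.0, 0.0, 0.0, ages[0], ages[1], ages[2]])
    return TimeTree(["a", "b", "c", "d"], parent, children, node_ages)


def caterpillar(taxa, ages) -> TimeTree:
    """(((t0,t1),t2),...) with internal ages from youngest cherry to root."""
    n = len(taxa)
    parent = np.full(2 * n - 1, -1, dtype=int)
    children = np.full((2 * n - 1, 2), -1, dtype=int)
    node_ages = np.zeros(2 * n - 1)
    prev = 0
    for k in range(n - 1):
        node = n + k
        tip = k + 1
        children[node] = (prev, tip)
        parent[prev] = node
        parent[tip] = node
        node_ages[node] = ages[k]
        prev = node
    return TimeTree(list(taxa), parent, children, node_ages)


def brute_force_site_likelihood(tree, blens, model, column):
    """Exhaustive enumeration over internal-state assignments and rate
    categories; the independent oracle for the pruning algorithm."""
    from divtime.alignment import IUPAC_STATES

    bases = "ACGT"
    cat_rates = model.category_rates()
    pi = model.freqs
    internals = list(tree.internal_nodes())
    tipsets = [IUPAC_STATES[column[i]] for i in range(tree.n_tips)]

    def edge_prob(P, parent_state, child_node, assignment):
        if tree.is_tip(child_node):
            return sum(
                P[parent_state, bases.index(s)] for s in tipsets[child_node]
            )
        return P[parent_state, assignment[child_node]]

    var_lik = 0.0
    for cat in range(model.ncat):
        P = {
            node: model.transition_matrices(np.array([blens[node] * cat_rates[cat]]))[0]
            for node in range(tree.n_nodes)
            if tree.parent[node] >= 0
        }
        for combo in itertools.product(range(4), repeat=len(internals)):
            assignment = dict(zip(internals, combo))
            lik = pi[assignment[tree.root]]
            for node in range(tree.n_nodes):
                p = tree.parent[node]
                if p < 0:
                    continue
                if tree.is_tip(node):
                    lik *= edge_prob(P[node], assignment[p], node, assignment)
                else:
                    lik *= P[node][assignment[p], assignment[node]]
            var_lik += lik
    var_lik /= model.ncat
    const = sum(pi["ACGT".index(b)] for b in bases if all(b in ts for ts in tipsets))
    return model.p_inv * const + (1.0 - model.p_inv) * var_lik
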