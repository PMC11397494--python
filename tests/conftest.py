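"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive quantities by exhaustive enumeration (internal
substitution states, HMM state paths, haplotype pairs) and are deliberately
written against the public model interfaces only, never against the pruning /
dynamic-programming code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import cneaccel as ca
from cneaccel.hmm import _log_initial, _log_transition  # noqa: F401 (oracle use)

CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@pytest.fixture(scope="session")
def jc():
    return ca.HKYModel.jc69()


@pytest.fixture(scope="session")
def hky():
    return ca.HKYModel([0.35, 0.15, 0.2, 0.3], kappa=3.1)


@pytest.fixture(scope="session")
def four_leaf_tree():
    return ca.parse_newick("((A:0.13,B:0.3):0.21,(C:0.09,D:0.4):0.17);")


@pytest.fixture(scope="session")
def eleven_taxon():
    from cneaccel.simulate import DEFAULT_TREE_NEWICK

    return ca.parse_newick(DEFAULT_TREE_NEWICK)


def brute_force_column_loglik(tree, model, column, scales=None):
    """Sum over all internal-state assignments of the column probability."""
    sa = tree.scale_array(scales) if scales is None or isinstance(scales, dict) else np.asarray(scales)
    leaves = {i: column[tree.names[i]] for i in tree.leaf_nodes()}
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    pmats = {
        i: model.transition_matrix(float(tree.lengths[i] * sa[i]))
        for i in range(tree.n_nodes)
        if i != tree.root
    }
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        st = dict(zip(internal, assign))
        pr = model.freqs[st[tree.root]]
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            ps = st[int(tree.parent[i])]
            if tree.is_leaf(i):
                sym = leaves[i]
                pr *= pmats[i][ps, CODE[sym]] if sym in CODE else 1.0
            else:
                pr *= pmats[i][ps, st[i]]
        total += pr
    return np.log(total)


def enumerate_forward(emissions, mu, nu):
    """HMM total likelihood by summation over all 2^L state paths."""
    em = np.asarray(emissions)
    init = np.exp(_log_initial(mu, nu))
    T = np.exp(_log_transition(mu, nu))
    total = 0.0
    for path in itertools.product([0, 1], repeat=len(em)):
        pr = init[path[0]] * np.exp(em[0, path[0]])
        for i in range(1, len(em)):
            pr *= T[path[i - 1], path[i]] * np.exp(em[i, path[i]])
        total += pr
    return np.log(total)


def enumerate_viterbi(emissions, mu, nu):
    """Best path by enumeration; nonconserved-leaning tie-break."""
    em = np.asarray(emissions)
    init = _log_initial(mu, nu)
    T = _log_transition(mu, nu)
    best, bestp = -np.inf, None
    for path in itertools.product([1, 0], repeat=len(em)):
        pr = init[path[0]] + em[0, path[0]]
        for i in range(1, len(em)):
            pr += T[path[i - 1], path[i]] + em[i, path[i]]
        if pr > best:
            best, bestp = pr, np.array(path)
    return best, bestp


def random_tree(rng, n_leaves, labels=None):
    """Random rooted binary tree via sequential pair-joining; lengths U(0.01,0.5)."""
    if labels is None:
        labels = [f"L{i}" for i in range(n_leaves)]
    parts = [f"{lab}:{rng.uniform(0.01, 0.5):.6f}" for lab in labels]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.01, 0.5):.6f}")
    return ca.parse_newick(f"({parts[0]},{parts[1]});")
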