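"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

import gerppy as g


@pytest.fixture(scope="session")
def model():
    """HKY85 with kappa=2 and mildly unequal frequencies."""
    return g.SubstitutionModel(2.0, (0.295, 0.205, 0.205, 0.295))


@pytest.fixture(scope="session")
def uniform_model():
    return g.SubstitutionModel(1.0, (0.25, 0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def four_leaf_tree():
    return g.parse_newick("((A:0.21,B:0.37):0.11,(C:0.08,D:0.5):0.14);")


@pytest.fixture(scope="session")
def big_tree():
    """The 16-leaf, scope-5.8 simulation phylogeny."""
    return g.default_tree()


def brute_force_likelihood(tree, codes, model, r):
    """Column likelihood by exhaustive summation over internal states.

    `codes` maps leaf label -> base index 0..3.  Independent of the
    pruning recursion: enumerates every assignment of states to
    internal nodes and sums path probabilities.
    """
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for i in range(tree.n_nodes):
            if tree.is_leaf(i):
                state[i] = codes[tree.labels[i]]
        p = model.frequencies[state[tree.root]]
        for node in range(tree.n_nodes):
            for child in tree.children[node]:
                pm = model.transition_matrix(r * tree.lengths[child])
                p *= pm[state[node], state[child]]
        total += p
    return total


def brute_force_tail(probs, offset, length, score_idx):
    """Pr(sum of `length` draws >= score_idx) by exhaustive enumeration."""
    values = offset + np.arange(len(probs))
    total = 0.0
    for combo in itertools.product(range(len(probs)), repeat=length):
        if values[list(combo)].sum() >= score_idx:
            total += np.prod(probs[list(combo)])
    return total


def all_rooted_topologies(labels):
    """All rooted binary tree shapes over `labels`, as nested tuples
    compatible with NeutralTree.from_nested (lengths filled later)."""
    if len(labels) == 1:
        yield labels[0]
        return
    # split into every unordered bipartition, rooted recursively
    seen = set()
    n = len(labels)
    for bits in range(1, (1 << n) - 1):
        left = tuple(labels[i] for i in range(n) if bits & (1 << i))
        right = tuple(labels[i] for i in range(n) if not bits & (1 << i))
        key = frozenset((left, right))
        if key in seen or labels[0] not in left:
            continue
        seen.add(key)
        for lt in all_rooted_topologies(list(left)):
            for rt in all_rooted_topologies(list(right)):
                yield (lt, rt)


def attach_lengths(shape, rng, lo=0.05, hi=0.8):
    """Turn a nested shape into NeutralTree nested form with random
    branch lengths."""
    def walk(node):
        if isinstance(node, str):
            return (node, float(rng.uniform(lo, hi)))
        left, right = node
        return ([walk(left), walk(right)], float(rng.uniform(lo, hi)))

    payload = walk(shape)
    return (payload[0], 0.0) if isinstance(payload[0], list) else payload
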