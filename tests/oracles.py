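"""Independent brute-force oracles used only by the tests.

These deliberately avoid the pruning recursion, the coordinate-ascent
optimiser and the Fitch bookkeeping they are used to check.
"""

import itertools

import numpy as np

from gapml.likelihood import jc_edge_transition

NUCS = "ACGT"


def brute_force_column_likelihood(tree, column):
    """Column likelihood by explicit summation over every node-state assignment.

    P(column) = sum over full assignments of 1/4 (root) times the product of
    per-edge transition probabilities, with gapped leaves free (summed over).
    """
    nodes = list(tree.nodes())
    splits = tree.edge_splits()
    mats = {
        (u, v): jc_edge_transition(tree.edge_params[splits[(u, v)]])
        for (u, v) in tree.edges()
    }
    root = nodes[0]
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(nodes)):
        state = dict(zip(nodes, assign))
        ok = True
        for n in nodes:
            if tree.is_leaf(n):
                c = column[tree.leaf_label(n)]
                if c != "-" and NUCS.index(c) != state[n]:
                    ok = False
                    break
        if not ok:
            continue
        p = 0.25
        for (u, v) in tree.edges():
            p *= mats[(u, v)][state[u], state[v]]
        total += p
    return total


def brute_force_binary_parsimony(tree, char):
    """Minimum state changes of a binary character by trying every internal labelling."""
    internal = [n for n in tree.nodes() if not tree.is_leaf(n)]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for n in tree.nodes():
            if tree.is_leaf(n):
                state[n] = char[tree.leaf_label(n)]
        changes = sum(1 for (u, v) in tree.edges() if state[u] != state[v])
        best = changes if best is None else min(best, changes)
    return best


def grid_search_max_loglik(tl, step=0.025, chunk=400_000):
    """Dense grid search over [0, 3/4]^|E| using the compiled evaluator's
    batched entry point (the search itself is exhaustive, not iterative)."""
    values = np.arange(0.0, 0.75 + step / 2, step)
    n_edges = len(tl.splits)
    best = -np.inf
    combos = itertools.product(values, repeat=n_edges)
    while True:
        block = np.array(list(itertools.islice(combos, chunk)))
        if block.size == 0:
            break
        scores = tl.multi_log_likelihood(block)
        best = max(best, float(np.max(scores)))
    return best
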