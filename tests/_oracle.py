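"""Independent brute-force oracles used to check the production code paths.

These deliberately avoid the package's pruning/kernel machinery: transition
matrices come straight from ``scipy.linalg.expm`` and the likelihood is an
exhaustive sum over all internal-state assignments.
"""

from itertools import product
from math import inf, log

import numpy as np
from scipy.linalg import expm


def enumeration_loglik(tree, leaf_states: dict, q: np.ndarray,
                       pi: np.ndarray, mu: dict, rate: float = 1.0) -> float:
    """Sum the joint probability over every internal-state assignment."""
    a = q.shape[0]
    internal = [n for n in tree.postorder() if not n.is_leaf]
    edges = [(n, expm(q * n.length * mu[n.category] * rate))
             for n in tree.postorder() if n.parent is not None]
    total = 0.0
    for assign in product(range(a), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assign)}
        for leaf in tree.leaves():
            state[id(leaf)] = leaf_states[leaf.name]
        p = pi[state[id(tree.root)]]
        for node, pmat in edges:
            p *= pmat[state[id(node.parent)], state[id(node)]]
        total += p
    return log(total) if total > 0 else -inf
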