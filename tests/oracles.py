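"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration, separate
from the package's implementations.
"""

import itertools
import math

import numpy as np

UNCERTAIN = -1


def mve_oracle_2d(X, inclusion):
    """Enumerate every 3-point subset of a 2-D point set, scale each
    subset covariance to cover h points, return the minimal sqrt(det)
    of the scaled shape (proportional to the ellipse area)."""
    n, d = X.shape
    h = math.ceil(inclusion * n)
    best = np.inf
    for subset in itertools.combinations(range(n), d + 1):
        pts = X[list(subset)]
        m = pts.mean(axis=0)
        C = np.cov(pts, rowvar=False)
        det = np.linalg.det(C)
        if det <= 1e-12:
            continue
        inv = np.linalg.inv(C)
        md2 = np.sort([(x - m) @ inv @ (x - m) for x in X])
        s = md2[h - 1]
        best = min(best, np.sqrt(np.linalg.det(s * C)))
    return best


def mve_oracle_1d_halfwidth(xs, h):
    """Smallest half-width over all h-point windows of sorted values."""
    xs = np.sort(np.asarray(xs, dtype=float))
    return min((xs[i + h - 1] - xs[i]) / 2 for i in range(len(xs) - h + 1))


def parsimony_oracle(tree, tip_states):
    """Exhaustive minimum-change enumeration over all internal labelings
    of a binary character; uncertain tips may take either state for
    free. Only feasible for small trees."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    free_tips = [l for l in tree.leaf_node_iter()
                 if tip_states[l.taxon.label] == UNCERTAIN]
    best = np.inf
    for assign in itertools.product([0, 1], repeat=len(internals)):
        lab = {n: s for n, s in zip(internals, assign)}
        for tip_assign in itertools.product([0, 1], repeat=len(free_tips)):
            for l, s in zip(free_tips, tip_assign):
                lab[l] = s
            for l in tree.leaf_node_iter():
                if tip_states[l.taxon.label] != UNCERTAIN:
                    lab[l] = tip_states[l.taxon.label]
            cost = sum(1 for n in tree.preorder_node_iter()
                       if n.parent_node is not None
                       and lab[n] != lab[n.parent_node])
            best = min(best, cost)
    return best
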