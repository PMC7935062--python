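"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: the dip
oracle minimizes the sup-distance over unimodal step CDFs by linear
programming, and the Mk oracles sum over every internal-node state
assignment explicitly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

import scipy.linalg


def dip_bruteforce(x) -> float:
    """Exact dip by LP over mode-at-point unimodal CDFs.

    A unimodal CDF is convex below its mode and concave above, with an
    atom allowed at the mode; modes between data points reduce to one of
    the flanking data-point modes once junction slopes are accounted for.
    The mode point is split into left/right limits matched against the
    CDF's left/right values there.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    hi = np.cumsum(counts) / n
    lo = np.concatenate(([0.0], hi[:-1]))
    m = u.size
    if m == 1:
        return 0.0
    best = np.inf
    for j in range(m):
        # variables g_0..g_{m-1} (g_j = left limit), gp (right limit), t
        nv = m + 2
        GP, T = m, m + 1
        c = np.zeros(nv)
        c[T] = 1.0
        A, b = [], []

        def le(row, rhs):  # row . v <= rhs
            A.append(row)
            b.append(rhs)

        for i in range(m):
            tgt_lo, tgt_hi = (lo[i], lo[i]) if i == j else (hi[i], lo[i])
            r = np.zeros(nv); r[i] = -1.0; r[T] = -1.0
            le(r, -tgt_lo)                       # g_i >= tgt_lo - t
            r = np.zeros(nv); r[i] = 1.0; r[T] = -1.0
            le(r, tgt_hi)                        # g_i <= tgt_hi + t
        r = np.zeros(nv); r[GP] = -1.0; r[T] = -1.0
        le(r, -hi[j])
        r = np.zeros(nv); r[GP] = 1.0; r[T] = -1.0
        le(r, hi[j])
        # monotone, with gm <= gp at the mode
        for i in range(m - 1):
            r = np.zeros(nv)
            r[GP if i == j else i] = 1.0
            r[i + 1] = -1.0
            le(r, 0.0)
        r = np.zeros(nv); r[j] = 1.0; r[GP] = -1.0
        le(r, 0.0)
        # convex second differences on 0..j, concave on j..m-1
        for i in range(j - 1):
            d1, d2 = u[i + 1] - u[i], u[i + 2] - u[i + 1]
            r = np.zeros(nv)
            r[i] = -1.0 / d1
            r[i + 1] = 1.0 / d1 + 1.0 / d2
            r[i + 2] = -1.0 / d2
            le(r, 0.0)
        for i in range(j, m - 2):
            d1, d2 = u[i + 1] - u[i], u[i + 2] - u[i + 1]
            r = np.zeros(nv)
            r[GP if i == j else i] += 1.0 / d1
            r[i + 1] += -1.0 / d1 - 1.0 / d2
            r[i + 2] += 1.0 / d2
            le(r, 0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0.0, 1.0)] * (m + 1) + [(0.0, None)],
                      method="highs")
        if res.success:
            best = min(best, res.fun)
    return float(best)


def _node_lists(tree):
    tips = [nd for nd in tree.leaf_node_iter()]
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    return tips, internals


def mk_likelihood_enumeration(tree, tip_states: dict, Q, root_prior) -> float:
    """Log-likelihood by explicit sum over internal-node state assignments."""
    Q = np.asarray(Q, dtype=float)
    prior = np.asarray(root_prior, dtype=float)
    tips, internals = _node_lists(tree)
    P = {nd: scipy.linalg.expm(Q * max(nd.edge.length or 0.0, 1e-8))
         for nd in tree.preorder_node_iter() if nd.parent_node is not None}
    total = 0.0
    for combo in itertools.product(range(3), repeat=len(internals)):
        state = {nd: s for nd, s in zip(internals, combo)}
        for nd in tips:
            state[nd] = tip_states[nd.taxon.label]
        prob = prior[state[tree.seed_node]]
        for nd in state:
            if nd.parent_node is not None:
                prob *= P[nd][state[nd.parent_node], state[nd]]
        total += prob
    return float(np.log(total))


def mk_marginals_enumeration(tree, tip_states: dict, Q, root_prior) -> dict:
    """P(node = s | tips) for every node, by enumeration."""
    Q = np.asarray(Q, dtype=float)
    prior = np.asarray(root_prior, dtype=float)
    tips, internals = _node_lists(tree)
    P = {nd: scipy.linalg.expm(Q * max(nd.edge.length or 0.0, 1e-8))
         for nd in tree.preorder_node_iter() if nd.parent_node is not None}
    marg = {nd: np.zeros(3) for nd in internals}
    total = 0.0
    for combo in itertools.product(range(3), repeat=len(internals)):
        state = {nd: s for nd, s in zip(internals, combo)}
        for nd in tips:
            state[nd] = tip_states[nd.taxon.label]
        prob = prior[state[tree.seed_node]]
        for nd in state:
            if nd.parent_node is not None:
                prob *= P[nd][state[nd.parent_node], state[nd]]
        total += prob
        for nd in internals:
            marg[nd][state[nd]] += prob
    out = {}
    for nd in internals:
        out[nd.label] = marg[nd] / total
    for nd in tips:
        v = np.zeros(3)
        v[tip_states[nd.taxon.label]] = 1.0
        out[nd.taxon.label] = v
    return out
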