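"""3-state Mk model: likelihood, rate fitting, ancestral states, origins.

The plumage character takes one of three states — sexually monochromic,
sexually dichromic, or female-limited polymorphic (FLP) — and evolves on a
rooted, time-calibrated phylogeny under a continuous-time Markov chain with
instantaneous rate matrix Q.  Three nested parameterizations are supported:

* ``ER``  — equal rates, one free parameter;
* ``SYM`` — symmetric rates, q_ij = q_ji, three free parameters;
* ``ARD`` — all rates different, six free parameters.

Likelihoods use Felsenstein's pruning algorithm with per-node rescaling;
ancestral states are marginal probabilities from the standard down-pass /
up-pass (rerooting-equivalent) recursion.  Model choice is by AICc with the
conventional "within 2 units" equivalence set.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from . import trees
from .errors import (InsufficientDataError, InvalidArgumentError,
                     MissingDataError, NonConvergenceError)

__all__ = [
    "STATES", "QMatrix", "MkFit", "ASRResult",
    "build_rate_matrix", "validate_q", "transition_probabilities",
    "mk_log_likelihood", "fit_mk_model", "aicc", "select_models",
    "marginal_asr", "count_independent_origins", "root_state_resampling",
    "prune_to_data",
]

STATES = ("monochromic", "dichromic", "FLP")
N_STATES = 3
UNIFORM_PRIOR = np.full(N_STATES, 1.0 / N_STATES)

#: free-parameter count per model
MODEL_K = {"ER": 1, "SYM": 3, "ARD": 6}

# off-diagonal index order for the free-rate vector
_SYM_PAIRS = [(0, 1), (0, 2), (1, 2)]
_ARD_CELLS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]

RATE_LOWER, RATE_UPPER = 1e-9, 100.0

prune_to_data = trees.prune_to_data


@dataclasses.dataclass
class QMatrix:
    """Instantaneous rate matrix under a named rate model."""

    matrix: np.ndarray
    model: str
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        validate_q(self.matrix)


@dataclasses.dataclass
class MkFit:
    model: str
    theta: np.ndarray
    q: QMatrix
    log_likelihood: float
    k: int
    n_tips: int
    aicc: float
    converged: bool
    at_lower_bound: bool = False


@dataclasses.dataclass
class ASRResult:
    """Marginal state probabilities per node.

    ``probs`` is indexed by node label (tips by taxon label, internal nodes
    by their deterministic ``nd*`` label) with one probability per state.
    """

    probs: pd.DataFrame
    root_prior: np.ndarray
    root_label: str

    def node(self, label: str) -> np.ndarray:
        return self.probs.loc[label, list(STATES)].to_numpy(dtype=float)


def validate_q(Q: np.ndarray) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES) or not np.all(np.isfinite(Q)):
        raise InvalidArgumentError("Q must be a finite 3x3 matrix")
    off = Q[~np.eye(N_STATES, dtype=bool)]
    if (off < 0).any():
        raise InvalidArgumentError("off-diagonal rates must be >= 0")
    if np.abs(Q.sum(axis=1)).max() > 1e-8 * max(1.0, np.abs(Q).max()):
        raise InvalidArgumentError("rows of Q must sum to 0")


def build_rate_matrix(model: str, theta) -> QMatrix:
    """Assemble Q from the free-rate vector of a named model.

    ER fills every off-diagonal with the single rate; SYM uses one rate per
    unordered state pair (order (0,1), (0,2), (1,2)); ARD one per ordered
    pair (row-major).  Diagonals are set to minus the row sums.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if model not in MODEL_K:
        raise InvalidArgumentError(f"unknown model {model!r}")
    if theta.size != MODEL_K[model]:
        raise InvalidArgumentError(
            f"{model} needs {MODEL_K[model]} rates, got {theta.size}")
    if (theta <= 0).any() or not np.all(np.isfinite(theta)):
        raise InvalidArgumentError("rates must be positive and finite")
    Q = np.zeros((N_STATES, N_STATES))
    if model == "ER":
        Q[:] = theta[0]
    elif model == "SYM":
        for r, (i, j) in zip(theta, _SYM_PAIRS):
            Q[i, j] = Q[j, i] = r
    else:
        for r, (i, j) in zip(theta, _ARD_CELLS):
            Q[i, j] = r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return QMatrix(Q, model, theta)


def transition_probabilities(Q, t: float) -> np.ndarray:
    """P(t) = exp(Q t), rows summing to 1, entries clamped to [0, 1]."""
    Q = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise InvalidArgumentError("Q must be finite")
    if t < 0:
        raise InvalidArgumentError("t must be >= 0")
    P = scipy.linalg.expm(Q * t)
    return np.clip(P, 0.0, 1.0)


def _edge_prob_stack(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q t) for every edge length at once, via eigendecomposition.

    Falls back to per-edge ``expm`` when the eigenbasis is ill-conditioned
    (possible for strongly asymmetric ARD matrices).
    """
    lengths = np.maximum(lengths, 1e-8)  # zero branches perturbed
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) < 1e8:
            E = np.exp(np.outer(lengths, w))
            P = np.einsum("ij,ej,jk->eik", U, E, Uinv)
            P = np.real(P)
            if np.abs(P.sum(axis=2) - 1.0).max() < 1e-8:
                return np.clip(P, 0.0, 1.0)
    except np.linalg.LinAlgError:
        pass
    return np.stack([np.clip(scipy.linalg.expm(Q * t), 0.0, 1.0)
                     for t in lengths])


class _TreeIndex:
    """Flat postorder arrays for fast repeated likelihood evaluation."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {nd: i for i, nd in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[nd.parent_node] if nd.parent_node else -1
             for nd in self.nodes])
        self.lengths = np.array(
            [nd.edge.length or 0.0 for nd in self.nodes])
        self.is_tip = np.array([nd.is_leaf() for nd in self.nodes])
        self.labels = [nd.taxon.label if nd.is_leaf() else nd.label
                       for nd in self.nodes]
        self.children = [[] for _ in self.nodes]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.root = len(self.nodes) - 1

    def tip_matrix(self, tip_states: Mapping, ambiguous_ok: bool) -> np.ndarray:
        """One row per node: observation mask (1 for allowed states)."""
        L = np.ones((len(self.nodes), N_STATES))
        for i in np.flatnonzero(self.is_tip):
            label = self.labels[i]
            if label not in tip_states:
                if ambiguous_ok:
                    continue
                raise MissingDataError(f"no state for tip {label!r}")
            s = tip_states[label]
            mask = np.zeros(N_STATES)
            if isinstance(s, (set, frozenset, list, tuple)):
                for si in s:
                    mask[_state_index(si)] = 1.0
            else:
                mask[_state_index(s)] = 1.0
            L[i] = mask
        return L


def _state_index(s) -> int:
    if isinstance(s, (int, np.integer)):
        if not 0 <= int(s) < N_STATES:
            raise InvalidArgumentError(f"state index {s} out of range")
        return int(s)
    try:
        return STATES.index(s)
    except ValueError:
        raise InvalidArgumentError(f"unknown state {s!r}") from None


def _postorder_conditionals(ti: _TreeIndex, tipL: np.ndarray,
                            P: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescaled conditional likelihoods and accumulated log scale."""
    L = tipL.copy()
    log_scale = 0.0
    for i, kids in enumerate(ti.children):
        if not kids:
            continue
        acc = L[i].copy()  # starts at ones for internal nodes
        for c in kids:
            acc = acc * (P[c] @ L[c])
        m = acc.max()
        if m <= 0:
            return L, -np.inf
        L[i] = acc / m
        log_scale += np.log(m)
    return L, log_scale


def mk_log_likelihood(tree: dendropy.Tree, tip_states: Mapping, Q,
                      root_prior=None, *, ambiguous_ok: bool = False) -> float:
    """Log-likelihood of tip states under Q via Felsenstein pruning.

    ``tip_states`` maps tip label -> state (name, index, or a set of
    allowed states for ambiguity).  Missing tips raise unless
    ``ambiguous_ok`` treats them as fully ambiguous.
    """
    Qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, dtype=float)
    validate_q(Qm)
    prior = UNIFORM_PRIOR if root_prior is None else np.asarray(root_prior, float)
    if abs(prior.sum() - 1.0) > 1e-8:
        raise InvalidArgumentError("root_prior must sum to 1")
    ti = _TreeIndex(tree)
    tipL = ti.tip_matrix(tip_states, ambiguous_ok)
    P = _edge_prob_stack(Qm, ti.lengths)
    L, log_scale = _postorder_conditionals(ti, tipL, P)
    if not np.isfinite(log_scale):
        return -np.inf
    lik = float(prior @ L[ti.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion, n = number of tips."""
    if n <= k + 1:
        raise InvalidArgumentError("need n > k + 1 for the AICc correction")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mk_model(tree: dendropy.Tree, tip_states: Mapping, model: str,
                 restarts: int = 5, seed: int | None = None,
                 root_prior=None) -> MkFit:
    """Maximum-likelihood rates for one model by multi-start L-BFGS-B.

    Optimizes over log-rates with bounds [1e-9, 100]; starts are seeded
    log-uniform draws on [1e-2, 10].  The best converged restart wins.
    """
    k = MODEL_K.get(model)
    if k is None:
        raise InvalidArgumentError(f"unknown model {model!r}")
    observed = {_state_index(s) for s in tip_states.values()
                if not isinstance(s, (set, frozenset, list, tuple))}
    if len(observed) < 2:
        warnings.warn("fewer than 2 distinct observed states: rates are "
                      "unidentifiable and will run to the lower bound",
                      stacklevel=2)
    prior = UNIFORM_PRIOR if root_prior is None else np.asarray(root_prior, float)
    ti = _TreeIndex(tree)
    tipL = ti.tip_matrix(tip_states, ambiguous_ok=False)
    n_tips = int(ti.is_tip.sum())

    def nll(log_theta: np.ndarray) -> float:
        q = build_rate_matrix(model, np.exp(log_theta))
        P = _edge_prob_stack(q.matrix, ti.lengths)
        L, log_scale = _postorder_conditionals(ti, tipL, P)
        lik = float(prior @ L[ti.root])
        if not np.isfinite(log_scale) or lik <= 0:
            return 1e10
        return -(np.log(lik) + log_scale)

    rng = np.random.default_rng(None if seed is None else [int(seed), 0x_F17])
    bounds = [(np.log(RATE_LOWER), np.log(RATE_UPPER))] * k
    best = None
    for r in range(max(1, restarts)):
        x0 = np.log(rng.uniform(1e-2, 10.0, k)) if r else np.zeros(k)
        res = scipy.optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise NonConvergenceError(
            f"all {restarts} restarts failed for model {model}")
    theta = np.exp(best.x)
    q = build_rate_matrix(model, theta)
    logL = -float(best.fun)
    return MkFit(
        model=model, theta=theta, q=q, log_likelihood=logL, k=k,
        n_tips=n_tips, aicc=aicc(logL, k, n_tips), converged=bool(best.success),
        at_lower_bound=bool((theta <= RATE_LOWER * 1.01).any()),
    )


def select_models(fits: Iterable[MkFit]) -> tuple[list[MkFit], list[MkFit]]:
    """Rank fits by AICc; return (ranked, best set with delta-AICc < 2).

    Ties in AICc break toward fewer parameters.
    """
    fits = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    if not fits:
        raise NonConvergenceError("no converged fit to select from")
    ranked = sorted(fits, key=lambda f: (f.aicc, f.k))
    best = ranked[0].aicc
    return ranked, [f for f in ranked if f.aicc - best < 2.0]


def marginal_asr(tree: dendropy.Tree, tip_states: Mapping, Q,
                 root_prior=None, *, ambiguous_ok: bool = False) -> ASRResult:
    """Marginal ancestral state probabilities at every node.

    Down-pass conditionals from pruning are combined with up-pass partial
    likelihoods (the information in the rest of the tree), which is
    equivalent to rerooting at each node.  Observed tips keep unit mass on
    their observed state.
    """
    Qm = Q.matrix if isinstance(Q, QMatrix) else np.asarray(Q, dtype=float)
    validate_q(Qm)
    prior = UNIFORM_PRIOR if root_prior is None else np.asarray(root_prior, float)
    ti = _TreeIndex(tree)
    tipL = ti.tip_matrix(tip_states, ambiguous_ok)
    P = _edge_prob_stack(Qm, ti.lengths)
    L, log_scale = _postorder_conditionals(ti, tipL, P)
    if not np.isfinite(log_scale):
        raise InvalidArgumentError("data have zero likelihood under Q")

    # up-pass: U[i] = likelihood of everything outside the clade of i,
    # as a function of the state at node i
    U = np.ones_like(L)
    U[ti.root] = prior
    # messages from child c to parent p: M[c] = P[c] @ L[c]
    M = np.einsum("eij,ej->ei", P, L)
    for p in reversed(range(len(ti.nodes))):
        kids = ti.children[p]
        for c in kids:
            sib = U[p].copy()
            for c2 in kids:
                if c2 != c:
                    sib = sib * M[c2]
            U[c] = P[c].T @ sib
    post = U * L
    Z = post.sum(axis=1, keepdims=True)
    Z[Z == 0] = 1.0
    post = post / Z
    df = pd.DataFrame(post, index=ti.labels, columns=list(STATES))
    df.index.name = "node"
    df.insert(0, "is_tip", ti.is_tip)
    return ASRResult(probs=df, root_prior=prior,
                     root_label=ti.labels[ti.root])


def count_independent_origins(tree: dendropy.Tree, asr: ASRResult,
                              focal_state: str = "FLP",
                              threshold: float = 0.5) -> int:
    """Number of independent gains of ``focal_state`` on the tree.

    Each node is called focal iff its marginal probability of the focal
    state exceeds ``threshold`` (tips by their observed/reconstructed
    state mass).  An origin is an edge whose child is focal and whose
    parent is not; a focal root contributes one origin.
    """
    if not 0.5 <= threshold <= 1.0:
        raise InvalidArgumentError("threshold must be in [0.5, 1]")
    si = _state_index(focal_state)
    focal: dict[dendropy.Node, bool] = {}
    count = 0
    for nd in tree.preorder_node_iter():
        label = nd.taxon.label if nd.is_leaf() else nd.label
        try:
            p = float(asr.probs.loc[label, STATES[si]])
        except KeyError:
            raise InvalidArgumentError(
                f"ASR table lacks node {label!r}") from None
        focal[nd] = p > threshold
        parent = nd.parent_node
        if focal[nd] and (parent is None or not focal[parent]):
            count += 1
    return count


def root_state_resampling(tree: dendropy.Tree, tip_states: Mapping,
                          model: str = "ER", drop_frac: float = 0.10,
                          reps: int = 1000, seed: int | None = None,
                          refit: bool = True,
                          full_fit: MkFit | None = None) -> pd.DataFrame:
    """Stability of root-state likelihoods under random tip pruning.

    Each replicate removes ``floor(drop_frac * n)`` random tips, refits the
    rate model (or re-evaluates at the full-data rates when ``refit`` is
    False), and records the root marginals.  Returns per-state mean and SD.
    """
    if not 0.0 < drop_frac < 0.5:
        raise InvalidArgumentError("drop_frac must be in (0, 0.5)")
    if reps < 2:
        raise InvalidArgumentError("reps must be >= 2")
    labels = [lb for lb in trees.tip_labels(tree) if lb in tip_states]
    n_drop = int(np.floor(drop_frac * len(labels)))
    if len(labels) - n_drop < 3:
        raise InvalidArgumentError("pruning would leave < 3 tips")
    if not refit and full_fit is None:
        full_fit = fit_mk_model(tree, tip_states, model, seed=seed)
    rng = np.random.default_rng(None if seed is None else [int(seed), 0x_D609])
    rows = []
    for _ in range(reps):
        keep = list(labels)
        if n_drop:
            drop = set(rng.choice(len(labels), n_drop, replace=False))
            keep = [lb for i, lb in enumerate(labels) if i not in drop]
        sub = trees.prune_to_data(tree, keep)
        sub_states = {lb: tip_states[lb] for lb in keep}
        if refit:
            fit = fit_mk_model(sub, sub_states, model, restarts=2,
                               seed=int(rng.integers(2 ** 31)))
        else:
            fit = full_fit
        asr = marginal_asr(sub, sub_states, fit.q)
        rows.append(asr.node(asr.root_label))
    arr = np.array(rows)
    return pd.DataFrame(
        {"state": list(STATES), "mean": arr.mean(axis=0),
         "sd": arr.std(axis=0, ddof=1)})
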