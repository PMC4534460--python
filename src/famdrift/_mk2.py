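"""Low-level two-state CTMC kernels.

Trees are flattened to postorder arrays once per tree; the pruning
likelihood and the Metropolis random-walk chain run as compiled kernels so
that parameter-recovery and calibration simulations at hundreds of tips and
thousands of likelihood evaluations stay cheap.

State coding at the tips: 0, 1, 2 = polymorphic (partial likelihood 1 for
both states, i.e. an uncertainty rather than an extra trial), -1 = internal.
Root prior codes: 0 = stationary distribution of the rate matrix,
1 = uniform (1/2, 1/2).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ROOT_STATIONARY = 0
ROOT_UNIFORM = 1

# hard rate bounds on the log scale (per unit branch length)
LOG_RATE_MIN = math.log(1e-6)
LOG_RATE_MAX = math.log(100.0)


class TreeArrays:
    """Postorder-flattened rooted tree (children before parents, root last)."""

    __slots__ = ("child_ptr", "child_idx", "blen", "tipstate", "n_tips")

    def __init__(self, child_ptr, child_idx, blen, tipstate):
        self.child_ptr = child_ptr
        self.child_idx = child_idx
        self.blen = blen
        self.tipstate = tipstate
        self.n_tips = int((tipstate >= 0).sum())


def compile_tree(family_tree) -> TreeArrays:
    """Flatten a :class:`~famdrift.corpus.FamilyTree` into kernel arrays."""
    tree = family_tree.tree
    states = family_tree.tip_states
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    blen = np.zeros(n)
    tipstate = np.full(n, -1, dtype=np.int64)
    ptr = np.zeros(n + 1, dtype=np.int64)
    kids: list[int] = []
    for i, node in enumerate(nodes):
        if node.edge.length is not None:
            blen[i] = float(node.edge.length)
            if blen[i] < 0:
                raise ValueError(f"negative branch length {blen[i]}")
        children = node.child_nodes()
        if not children:
            s = states[node.taxon.label]
            tipstate[i] = 2 if s == "polymorphic" else int(s)
        kids.extend(index[id(c)] for c in children)
        ptr[i + 1] = len(kids)
    return TreeArrays(ptr, np.asarray(kids, dtype=np.int64), blen, tipstate)


@njit(cache=True)
def _trans(q01, q10, t):
    """Closed-form 2x2 transition matrix entries (P00, P01, P10, P11)."""
    q = q01 + q10
    if q <= 0.0 or t <= 0.0:
        return 1.0, 0.0, 0.0, 1.0
    pi1 = q01 / q
    pi0 = q10 / q
    e = math.exp(-q * t)
    return pi0 + pi1 * e, pi1 * (1.0 - e), pi0 * (1.0 - e), pi1 + pi0 * e


@njit(cache=True)
def pruning_loglik(child_ptr, child_idx, blen, tipstate, q01, q10, root_prior):
    """Log-likelihood of the tip states by postorder pruning.

    Polytomies are handled natively (product over all children); partials
    are rescaled at every internal node so deep trees do not underflow.
    """
    n = len(tipstate)
    L0 = np.empty(n)
    L1 = np.empty(n)
    logscale = 0.0
    for v in range(n):
        s = tipstate[v]
        if s == 0:
            L0[v] = 1.0
            L1[v] = 0.0
        elif s == 1:
            L0[v] = 0.0
            L1[v] = 1.0
        elif s == 2:
            L0[v] = 1.0
            L1[v] = 1.0
        else:
            a = 1.0
            b = 1.0
            for j in range(child_ptr[v], child_ptr[v + 1]):
                c = child_idx[j]
                p00, p01, p10, p11 = _trans(q01, q10, blen[c])
                a *= p00 * L0[c] + p01 * L1[c]
                b *= p10 * L0[c] + p11 * L1[c]
            m = a if a > b else b
            if m > 0.0 and m != 1.0:
                a /= m
                b /= m
                logscale += math.log(m)
            L0[v] = a
            L1[v] = b
    root = n - 1
    q = q01 + q10
    if root_prior == ROOT_STATIONARY and q > 0.0:
        pi0 = q10 / q
        pi1 = q01 / q
    else:
        pi0 = 0.5
        pi1 = 0.5
    lik = pi0 * L0[root] + pi1 * L1[root]
    if lik <= 0.0:
        return -np.inf
    return math.log(lik) + logscale


@njit(cache=True)
def _log_target(ll, logq, k, beta):
    """beta-tempered posterior density on the log-rate scale.

    Prior: independent Exponential(mean 1) on each rate; on the log scale the
    density picks up a Jacobian q, giving log q - q per parameter.
    """
    lp = beta * ll
    for i in range(k):
        lp += logq[i] - math.exp(logq[i])
    return lp


@njit(cache=True)
def rw_chain(
    child_ptr,
    child_idx,
    blen,
    tipstate,
    root_prior,
    logq_init,
    steps,
    logu,
    beta,
    equal_rates,
):
    """Metropolis random walk on log-rates.

    ``steps`` holds pre-drawn Gaussian proposal increments (n_iter x k) and
    ``logu`` pre-drawn log-uniforms, so the chain is reproducible from the
    caller's generator.  ``beta`` tempers the likelihood (beta = 0 samples
    the prior; beta = 1 the posterior).  Returns the sampled log-rates, the
    *untempered* log-likelihood at every kept state, and the acceptance
    count.
    """
    n_iter, k = steps.shape
    cur = logq_init.copy()
    if equal_rates:
        cur_ll = pruning_loglik(
            child_ptr, child_idx, blen, tipstate,
            math.exp(cur[0]), math.exp(cur[0]), root_prior,
        )
    else:
        cur_ll = pruning_loglik(
            child_ptr, child_idx, blen, tipstate,
            math.exp(cur[0]), math.exp(cur[1]), root_prior,
        )
    cur_lp = _log_target(cur_ll, cur, k, beta)
    samples = np.empty((n_iter, k))
    logliks = np.empty(n_iter)
    n_accept = 0
    for i in range(n_iter):
        ok = True
        prop = cur.copy()
        for j in range(k):
            prop[j] = cur[j] + steps[i, j]
            if prop[j] < LOG_RATE_MIN or prop[j] > LOG_RATE_MAX:
                ok = False
        if ok:
            if equal_rates:
                ll = pruning_loglik(
                    child_ptr, child_idx, blen, tipstate,
                    math.exp(prop[0]), math.exp(prop[0]), root_prior,
                )
            else:
                ll = pruning_loglik(
                    child_ptr, child_idx, blen, tipstate,
                    math.exp(prop[0]), math.exp(prop[1]), root_prior,
                )
            lp = _log_target(ll, prop, k, beta)
            if logu[i] < lp - cur_lp:
                cur = prop
                cur_ll = ll
                cur_lp = lp
                n_accept += 1
        samples[i] = cur
        logliks[i] = cur_ll
    return samples, logliks, n_accept
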