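"""Tree-based bias detection: a two-state CTMC on the family tree.

The trait (ergative marker present/absent) evolves along the family tree as
a continuous-time Markov chain with a gain rate (0 -> 1) and a loss rate
(1 -> 0) per unit branch length.  Strongly unequal rates indicate a directed
bias: loss > gain is a bias against the trait, gain > loss a bias towards
it.  Two engines evaluate the evidence for unequal rates:

* maximum likelihood with a likelihood-ratio test (chi-square, 1 df,
  alpha = .05 by default), and
* Bayesian MCMC with a stepping-stone marginal-likelihood estimate and a
  log Bayes factor > 2 positive-evidence criterion.

Languages whose grammatical subsystems disagree enter as polymorphic tips
(uncertainties, not extra trials).  The method needs variation: a family in
which every language is fully ergative or fully non-ergative carries no
information about transition rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from ._mk2 import (
    LOG_RATE_MAX,
    LOG_RATE_MIN,
    ROOT_STATIONARY,
    ROOT_UNIFORM,
    TreeArrays,
    compile_tree,
    pruning_loglik,
    rw_chain,
)
from .corpus import FamilyDataset, FamilyTree, build_family_tree
from .setbias import AGAINST, NONE, TOWARD, BiasEstimate, family_bias_binomial

_ROOT_CODES = {"stationary": ROOT_STATIONARY, "uniform": ROOT_UNIFORM}


class InapplicableMethodError(ValueError):
    """The family shows no variation; transition rates are unidentifiable."""


@dataclass
class RateModel:
    """Fitted CTMC gain/loss rates with their log-likelihood."""

    q_gain: float
    q_loss: float
    loglik: float
    constrained_equal: bool
    root_prior: str = "stationary"

    def __post_init__(self):
        if self.q_gain < 0 or self.q_loss < 0:
            raise ValueError("rates must be nonnegative")
        if self.constrained_equal and self.q_gain != self.q_loss:
            raise ValueError("constrained model requires equal rates")


@dataclass
class ModelComparison:
    """Outcome of the unequal-vs-equal rates comparison for one family."""

    method: str  # ml_lrt | mcmc_bf
    statistic: float  # LRT chi-square or logBF
    threshold: float
    favored: str  # unequal | equal
    direction_if_unequal: str  # A | E | none
    p_value: float | None = None
    unequal_model: RateModel | None = None
    equal_model: RateModel | None = None


@dataclass
class MCMCResult:
    """Posterior sample of (q_gain, q_loss) with chain diagnostics."""

    rates: np.ndarray  # (n_kept, 2)
    logliks: np.ndarray
    acceptance_rate: float
    ess: np.ndarray  # per-parameter effective sample size
    step_size: float


def _tree_arrays(tree: FamilyTree | TreeArrays) -> TreeArrays:
    return tree if isinstance(tree, TreeArrays) else compile_tree(tree)


def _check_variation(arr: TreeArrays) -> None:
    tips = arr.tipstate[arr.tipstate >= 0]
    if 2 in tips:  # a polymorphic tip is variation by itself
        return
    if tips.min() == tips.max():
        raise InapplicableMethodError(
            "all tips share one state; rate estimation is inapplicable"
        )


def mk2_loglik(
    tree: FamilyTree | TreeArrays,
    q_gain: float,
    q_loss: float,
    root_prior: str = "stationary",
) -> float:
    """Exact log-likelihood of the tip states under the two-state CTMC.

    Computed by postorder pruning; polymorphic tips contribute partial
    likelihood 1 for both states, polytomies are products over all children,
    and the root is closed with the chosen prior (stationary distribution of
    the rate matrix, or uniform).
    """
    if q_gain < 0 or q_loss < 0:
        raise ValueError("rates must be nonnegative")
    arr = _tree_arrays(tree)
    if not (arr.tipstate >= 0).any():
        raise ValueError("tree has no tips with states")
    return pruning_loglik(
        arr.child_ptr, arr.child_idx, arr.blen, arr.tipstate,
        float(q_gain), float(q_loss), _ROOT_CODES[root_prior],
    )


def fit_ml(
    tree: FamilyTree | TreeArrays,
    constrained_equal: bool = False,
    root_prior: str = "stationary",
    n_starts: int = 5,
    seed: int = 0,
) -> RateModel:
    """Maximum-likelihood rates by bounded multi-start search on log-rates."""
    arr = _tree_arrays(tree)
    _check_variation(arr)
    code = _ROOT_CODES[root_prior]
    rng = np.random.default_rng(seed)

    def nll2(x):
        return -pruning_loglik(
            arr.child_ptr, arr.child_idx, arr.blen, arr.tipstate,
            math.exp(x[0]), math.exp(x[1]), code,
        )

    def nll1(x):
        q = math.exp(x)
        return -pruning_loglik(
            arr.child_ptr, arr.child_idx, arr.blen, arr.tipstate, q, q, code
        )

    if constrained_equal:
        best = None
        # scalar problem: one bounded search suffices, but keep jittered
        # restarts for rugged small-tree surfaces
        for _ in range(max(1, n_starts // 2)):
            x0 = rng.uniform(math.log(0.01), math.log(3.0))
            res = minimize_scalar(
                nll1, bounds=(LOG_RATE_MIN, LOG_RATE_MAX), method="bounded",
                options={"xatol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        q = math.exp(best.x)
        return RateModel(q, q, -best.fun, True, root_prior)

    best = None
    for _ in range(n_starts):
        x0 = rng.uniform(math.log(0.01), math.log(3.0), size=2)
        res = minimize(
            nll2, x0, method="L-BFGS-B",
            bounds=[(LOG_RATE_MIN, LOG_RATE_MAX)] * 2,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    qg, ql = np.exp(best.x)
    return RateModel(qg, ql, -best.fun, False, root_prior)


def lrt_unequal_rates(
    tree: FamilyTree | TreeArrays,
    alpha: float = 0.05,
    root_prior: str = "stationary",
    seed: int = 0,
    _tol: float = 1e-6,
) -> ModelComparison:
    """Likelihood-ratio test of unequal vs equal gain/loss rates.

    The statistic 2*(ll_unequal - ll_equal) is referred to chi-square with
    1 df (no boundary correction; both rates are interior under the null).
    """
    arr = _tree_arrays(tree)
    full = fit_ml(arr, constrained_equal=False, root_prior=root_prior, seed=seed)
    null = fit_ml(arr, constrained_equal=True, root_prior=root_prior, seed=seed)
    stat = 2.0 * (full.loglik - null.loglik)
    if stat < -_tol:
        # optimizer missed the unconstrained optimum; retry harder
        full = fit_ml(arr, False, root_prior, n_starts=20, seed=seed + 1)
        stat = 2.0 * (full.loglik - null.loglik)
        if stat < -_tol:
            raise RuntimeError(
                f"unconstrained fit below constrained fit (delta={stat/2:.3g})"
            )
    stat = max(stat, 0.0)
    p = chi2.sf(stat, df=1)
    crit = chi2.isf(alpha, df=1)
    if p <= alpha:
        favored = "unequal"
        direction = AGAINST if full.q_loss > full.q_gain else TOWARD
    else:
        favored = "equal"
        direction = NONE
    return ModelComparison(
        method="ml_lrt", statistic=stat, threshold=crit, favored=favored,
        direction_if_unequal=direction, p_value=p,
        unequal_model=full, equal_model=null,
    )


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    n = len(x)
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return float(n)
    tau = 1.0
    for lag in range(1, n // 2):
        rho = (x[:-lag] @ x[lag:]) / (n * var)
        if rho <= 0.0:
            break
        tau += 2.0 * rho
    return n / tau


def _run_chain(arr, code, rng, logq0, step, n_iter, beta, equal):
    k = len(logq0)
    steps = rng.normal(0.0, step, size=(n_iter, k))
    logu = np.log(rng.uniform(size=n_iter))
    return rw_chain(
        arr.child_ptr, arr.child_idx, arr.blen, arr.tipstate, code,
        np.asarray(logq0, dtype=float), steps, logu, float(beta), equal,
    )


def mcmc_rates(
    tree: FamilyTree | TreeArrays,
    n_iter: int = 5000,
    burn_in: int = 500,
    seed: int = 0,
    step_size: float = 0.5,
    root_prior: str = "stationary",
    constrained_equal: bool = False,
    beta: float = 1.0,
) -> MCMCResult:
    """Posterior sample of the rates by Metropolis random walk on log-rates.

    Priors are independent Exponential(mean 1) on the rates.  The step size
    adapts during burn-in toward ~30% acceptance; the post-burn-in chain is
    fixed-step so the kept sample is a valid Metropolis chain.  ``beta = 0``
    disables the likelihood and samples the prior (sampler check).
    """
    if n_iter < 10 * burn_in:
        raise ValueError("n_iter must be at least 10x burn_in")
    arr = _tree_arrays(tree)
    if beta > 0:
        _check_variation(arr)
    code = _ROOT_CODES[root_prior]
    rng = np.random.default_rng(seed)
    k = 1 if constrained_equal else 2
    logq = np.full(k, math.log(0.5))
    step = step_size
    # adaptation: tune during burn-in in blocks
    block = max(50, burn_in // 5)
    done = 0
    while done < burn_in:
        m = min(block, burn_in - done)
        samples, _, n_acc = _run_chain(arr, code, rng, logq, step, m, beta, constrained_equal)
        logq = samples[-1]
        acc = n_acc / m
        step *= math.exp(acc - 0.3)
        step = min(max(step, 0.01), 5.0)
        done += m
    samples, logliks, n_acc = _run_chain(
        arr, code, rng, logq, step, n_iter - burn_in, beta, constrained_equal
    )
    acc = n_acc / len(samples)
    if not 0.05 <= acc <= 0.8:
        warnings.warn(f"MCMC acceptance rate {acc:.2f} outside [0.05, 0.8]")
    rates = np.exp(samples)
    if constrained_equal:
        rates = np.column_stack([rates[:, 0], rates[:, 0]])
    ess = np.array([_ess(rates[:, j]) for j in range(rates.shape[1])])
    return MCMCResult(rates=rates, logliks=logliks, acceptance_rate=acc,
                      ess=ess, step_size=step)


def stepping_stone_logml(
    tree: FamilyTree | TreeArrays,
    constrained_equal: bool,
    seed: int = 0,
    n_steps: int = 32,
    iter_per_step: int = 600,
    burn_per_step: int = 100,
    step_size: float = 0.6,
    root_prior: str = "stationary",
    alpha_spacing: float = 0.3,
) -> tuple[float, float]:
    """Log marginal likelihood by stepping-stone sampling.

    Power posteriors at beta_k = (k/K)^(1/alpha_spacing) (prior-heavy
    spacing), chains warm-started from the previous rung.  Returns the
    log marginal likelihood and the summed per-rung variance of the
    log-ratio estimates (an instability diagnostic).
    """
    arr = _tree_arrays(tree)
    code = _ROOT_CODES[root_prior]
    rng = np.random.default_rng(seed)
    k = 1 if constrained_equal else 2
    betas = (np.arange(n_steps + 1) / n_steps) ** (1.0 / alpha_spacing)
    logq = np.full(k, math.log(0.5))
    logml = 0.0
    var_sum = 0.0
    for j in range(n_steps):
        b_lo, b_hi = betas[j], betas[j + 1]
        _, _, _ = (None, None, None)
        warm, _, _ = _run_chain(arr, code, rng, logq, step_size, burn_per_step, b_lo, constrained_equal)
        logq = warm[-1]
        samples, logliks, _ = _run_chain(
            arr, code, rng, logq, step_size, iter_per_step, b_lo, constrained_equal
        )
        logq = samples[-1]
        w = (b_hi - b_lo) * logliks
        m = w.max()
        contrib = m + math.log(np.mean(np.exp(w - m)))
        logml += contrib
        var_sum += float(np.var(np.exp(w - m)) / len(w))
    return logml, var_sum


def bayes_factor_unequal(
    tree: FamilyTree | TreeArrays,
    seed: int = 0,
    threshold: float = 2.0,
    n_steps: int = 32,
    iter_per_step: int = 600,
    root_prior: str = "stationary",
    posterior_iter: int = 3000,
) -> ModelComparison:
    """Log Bayes factor for unequal vs equal rates via stepping stone.

    logBF = log ML(unequal) - log ML(equal); logBF > 2 counts as positive
    evidence for a directed bias, with the direction read off the posterior
    mean rates.
    """
    arr = _tree_arrays(tree)
    _check_variation(arr)
    ml_uneq, v1 = stepping_stone_logml(
        arr, False, seed=seed, n_steps=n_steps, iter_per_step=iter_per_step,
        root_prior=root_prior,
    )
    ml_eq, v2 = stepping_stone_logml(
        arr, True, seed=seed + 1, n_steps=n_steps, iter_per_step=iter_per_step,
        root_prior=root_prior,
    )
    if v1 + v2 > 0.5:
        warnings.warn("stepping-stone estimate unstable; consider more steps")
    logbf = ml_uneq - ml_eq
    post = mcmc_rates(
        arr, n_iter=posterior_iter, burn_in=posterior_iter // 10,
        seed=seed + 2, root_prior=root_prior,
    )
    qg, ql = post.rates.mean(axis=0)
    if logbf > threshold:
        favored = "unequal"
        direction = AGAINST if ql > qg else TOWARD
    else:
        favored = "equal"
        direction = NONE
    return ModelComparison(
        method="mcmc_bf", statistic=logbf, threshold=threshold,
        favored=favored, direction_if_unequal=direction,
    )


def classify_large_families_tree(
    families: Sequence[FamilyDataset],
    engine: str = "ml",
    trees: dict[str, FamilyTree] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> list[BiasEstimate]:
    """Classify large families by the tree-based engine.

    Families without variation (all trials one value) are unclassifiable by
    rate estimation and fall back to the set-based binomial test; the
    ``method`` field of each estimate records which path produced it.
    Strength is always the empirical majority proportion of the trials, so
    the downstream deviation probability is commensurable across engines.
    """
    if engine not in ("ml", "mcmc"):
        raise ValueError(f"unknown engine {engine!r}")
    out = []
    for i, fam in enumerate(families):
        if not fam.is_large:
            raise ValueError(f"family {fam.family_id!r} is not large")
        k = sum(fam.trials)
        n = fam.n_trials
        strength = max(k, n - k) / n
        if not fam.is_variable:
            est = family_bias_binomial(fam.trials, alpha=alpha)
            est.family_id = fam.family_id
            est.area, est.taxonomy = fam.area, fam.taxonomy
            out.append(est)
            continue
        if fam.n_languages == 2:
            warnings.warn(
                f"family {fam.family_id!r}: two-tip variable family is "
                "low-information for rate estimation"
            )
        tree = (trees or {}).get(fam.family_id) or build_family_tree(fam)
        if engine == "ml":
            cmp_ = lrt_unequal_rates(tree, alpha=alpha, seed=seed + i)
            evidence = cmp_.p_value
            method = "tree_ml"
        else:
            cmp_ = bayes_factor_unequal(tree, seed=seed + i, **(mcmc_kwargs or {}))
            evidence = cmp_.statistic
            method = "tree_mcmc"
        out.append(
            BiasEstimate(
                family_id=fam.family_id, method=method,
                direction=cmp_.direction_if_unequal,
                strength=strength, evidence=evidence, n_trials=n,
                area=fam.area, taxonomy=fam.taxonomy,
            )
        )
    return out
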