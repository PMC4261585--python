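"""Maximum-likelihood estimation of evolutionary rates.

Free quantities — the per-branch-category rate ``mu``, relative rates of the
transition template, the root prior and the gamma shape — are optimized on
unconstrained scales (logs; additive log-ratio for the root-prior simplex)
with a bounded quasi-Newton routine (L-BFGS-B).  One relative-rate parameter
is pinned to 1 because only rate ratios survive calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .char_matrix import CharacterMatrix, compress_patterns, simplify_to_binary
from .likelihood import NEG_INF, LikelihoodConfig, total_loglik
from .rate_models import (GammaRates, discrete_gamma, make_model_spec,
                          uniform_prior)
from .tree_io import Tree, midpoint_root

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "LrtResult", "fit", "fit_per_site",
           "likelihood_ratio_test", "MU_BOUNDS", "ALPHA_BOUNDS", "REL_BOUNDS"]

MU_BOUNDS = (1e-8, 1e4)
ALPHA_BOUNDS = (1e-3, 1e3)
REL_BOUNDS = (1e-6, 1e6)
_ALR_BOUND = 30.0
_PENALTY = 1e12


@dataclass
class FitResult:
    """Estimates and diagnostics from one maximization."""

    mu: np.ndarray  # one rate per branch category, index = category - 1
    rel_rates: np.ndarray  # full relative-rate vector (first entry pinned)
    pi_hat: Optional[np.ndarray]
    alpha_hat: Optional[float]
    loglik: float
    n_params: int
    converged: bool
    n_iterations: int
    model: str
    a: int
    per_site_mu: Optional[np.ndarray] = None
    per_site_flags: Optional[list[str]] = None
    boundary_hits: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "a": self.a,
            "mu": [float(x) for x in np.atleast_1d(self.mu)],
            "rel_rates": [float(x) for x in np.atleast_1d(self.rel_rates)],
            "pi": None if self.pi_hat is None else [float(x) for x in self.pi_hat],
            "alpha": None if self.alpha_hat is None else float(self.alpha_hat),
            "loglik": float(self.loglik),
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "boundary_hits": list(self.boundary_hits),
            "per_site_mu": (None if self.per_site_mu is None
                            else [float(x) for x in self.per_site_mu]),
            "per_site_flags": self.per_site_flags,
        }


@dataclass
class LrtResult:
    two_delta: float
    df: int
    p_value: float


class _ParamPack:
    """Layout of the transformed (unconstrained) parameter vector."""

    def __init__(self, n_cats: int, n_rel: int, a: int,
                 estimate_pi: bool, estimate_alpha: bool):
        self.n_cats = n_cats
        self.n_rel_free = max(n_rel - 1, 0)  # first relative rate pinned to 1
        self.a = a
        self.estimate_pi = estimate_pi
        self.estimate_alpha = estimate_alpha
        self.n_rel = n_rel

        self.sl_mu = slice(0, n_cats)
        k = n_cats
        self.sl_rel = slice(k, k + self.n_rel_free)
        k += self.n_rel_free
        self.sl_pi = slice(k, k + (a - 1 if estimate_pi else 0))
        k += a - 1 if estimate_pi else 0
        self.sl_alpha = slice(k, k + (1 if estimate_alpha else 0))
        self.size = k + (1 if estimate_alpha else 0)

    def start(self) -> np.ndarray:
        return np.zeros(self.size)

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = []
        b += [(np.log(MU_BOUNDS[0]), np.log(MU_BOUNDS[1]))] * self.n_cats
        b += [(np.log(REL_BOUNDS[0]), np.log(REL_BOUNDS[1]))] * self.n_rel_free
        if self.estimate_pi:
            b += [(-_ALR_BOUND, _ALR_BOUND)] * (self.a - 1)
        if self.estimate_alpha:
            b += [(np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1]))]
        return b

    def unpack(self, x: np.ndarray):
        mu = np.exp(x[self.sl_mu])
        rel = np.concatenate([[1.0], np.exp(x[self.sl_rel])]) \
            if self.n_rel else np.empty(0)
        if self.estimate_pi:
            y = np.concatenate([x[self.sl_pi], [0.0]])
            y = y - y.max()
            pi = np.exp(y)
            pi /= pi.sum()
        else:
            pi = None
        alpha = float(np.exp(x[self.sl_alpha][0])) if self.estimate_alpha else None
        return mu, rel, pi, alpha

    def boundary_hits(self, x: np.ndarray) -> list[str]:
        """Parameters pinned at (or on the flat approach to) a bound."""
        hits = []
        labels = ([f"mu[{i + 1}]" for i in range(self.n_cats)]
                  + [f"rel_rate[{i + 2}]" for i in range(self.n_rel_free)]
                  + ([f"pi_alr[{i}]" for i in range(self.a - 1)]
                     if self.estimate_pi else [])
                  + (["alpha"] if self.estimate_alpha else []))
        for xi, (lo, hi), lab in zip(x, self.bounds(), labels):
            tol = max(1e-6, 0.1 * (hi - lo))
            if xi - lo < tol or hi - xi < tol:
                hits.append(lab)
        return hits


def _prepare(tree: Tree, m: CharacterMatrix, model: str, *,
             custom_template, simplify, rootprobability, reversible,
             messages: list[str]):
    model = model.upper()
    if model == "GTR":
        # GTR == SYM with forced reversibility and estimated root prior
        model, reversible, rootprobability = "SYM", True, True
        messages.append("expanded GTR to SYM + reversible + rootprobability")
    if simplify:
        m = simplify_to_binary(m)
    spec = make_model_spec(model, m.a, custom_template)
    if reversible and not spec.symmetric:
        raise ValueError(f"reversible=True is incompatible with the "
                         f"non-symmetric model {spec.name}")

    tree_leaves = set(tree.leaf_names)
    if tree_leaves != set(m.taxa):
        raise ValueError(
            f"taxa mismatch between tree and matrix: only in tree "
            f"{sorted(tree_leaves - set(m.taxa))}, only in matrix "
            f"{sorted(set(m.taxa) - tree_leaves)}")

    irreversible = (not spec.symmetric) or (rootprobability and not reversible)
    if irreversible and not tree.is_rooted:
        tree = midpoint_root(tree)
        messages.append("unrooted tree midpoint-rooted for irreversible analysis")
        logger.info("midpoint rooting applied before irreversible analysis")
    m = m.reorder(tree.leaf_names)
    return tree, m, spec, rootprobability, reversible


def fit(tree: Tree, m: CharacterMatrix, model: str = "ER", *,
        custom_template: Optional[np.ndarray] = None,
        alpha: bool = False, ncat: int = 4,
        rootprobability: bool = False, reversible: bool = False,
        zerocorrection: bool = False, simplify: bool = False,
        n_restarts: int = 0, seed: int = 0) -> FitResult:
    """Maximize the likelihood of ``m`` on ``tree`` under a preset model.

    Returns the best point over the fixed default start plus ``n_restarts``
    jittered starts (seeded, so the whole procedure is deterministic).
    """
    messages: list[str] = []
    tree, m, spec, rootprobability, reversible = _prepare(
        tree, m, model, custom_template=custom_template, simplify=simplify,
        rootprobability=rootprobability, reversible=reversible,
        messages=messages)

    cats = tree.categories
    patterns = compress_patterns(m)
    pack = _ParamPack(len(cats), spec.free_params, spec.a,
                      rootprobability, alpha)
    uniform = uniform_prior(spec.a)
    n_total = float(patterns.weights.sum())

    # per-site scaling keeps gradients O(1) so the first quasi-Newton step
    # stays inside the region where the surface is informative
    def objective(x: np.ndarray) -> float:
        mu, rel, pi, alph = pack.unpack(x)
        config = LikelihoodConfig(
            model=spec, rel_rates=rel,
            mu={c: mu[i] for i, c in enumerate(cats)},
            root_prior=uniform if pi is None else pi,
            reversible=reversible,
            gamma=discrete_gamma(alph, ncat) if alph is not None else None,
            zerocorrection=zerocorrection)
        try:
            ll = total_loglik(tree, patterns, config)
        except (ValueError, FloatingPointError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll / n_total

    starts = [pack.start()]
    if n_restarts:
        rng = np.random.default_rng(seed)
        starts += [pack.start() + rng.normal(scale=1.0, size=pack.size)
                   for _ in range(n_restarts)]

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=pack.bounds(),
                       options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    res = best

    mu, rel, pi, alph = pack.unpack(res.x)
    loglik = -float(res.fun) * n_total
    converged = bool(res.success) and loglik > -_PENALTY / 2
    if not converged:
        messages.append(f"optimizer did not converge: {res.message}")
        logger.warning("fit did not converge: %s", res.message)
    return FitResult(
        mu=mu, rel_rates=rel, pi_hat=pi, alpha_hat=alph, loglik=loglik,
        n_params=pack.size, converged=converged,
        n_iterations=int(res.nit), model=spec.name, a=spec.a,
        boundary_hits=pack.boundary_hits(res.x), messages=messages)


def fit_per_site(tree: Tree, m: CharacterMatrix, model: str = "ER", *,
                 custom_template: Optional[np.ndarray] = None,
                 alpha: bool = False, ncat: int = 4,
                 rootprobability: bool = False, reversible: bool = False,
                 zerocorrection: bool = False, simplify: bool = False,
                 seed: int = 0) -> FitResult:
    """Independent rate estimation for every site (shared model shape).

    Identical site columns share one maximization.  Sites whose estimate hits
    a bound are flagged; gamma shape, if requested, is fitted per site as well
    (weakly identified on one column, flagged accordingly).
    """
    if alpha:
        logger.warning("gamma rate variation across a single site is weakly "
                       "identified")
    work = simplify_to_binary(m) if simplify else m
    patterns = compress_patterns(work)

    n_sites = work.n_sites
    per_pattern: list[FitResult] = []
    for row in patterns.patterns:
        sub = CharacterMatrix(list(work.taxa), row[:, None].copy(), work.a)
        per_pattern.append(fit(
            tree, sub, model, custom_template=custom_template, alpha=alpha,
            ncat=ncat, rootprobability=rootprobability, reversible=reversible,
            zerocorrection=zerocorrection, simplify=False, seed=seed))

    cats_n = len(per_pattern[0].mu)
    per_site_mu = np.empty(n_sites)
    flags: list[str] = []
    total = 0.0
    for s in range(n_sites):
        r = per_pattern[patterns.site_index[s]]
        per_site_mu[s] = float(np.mean(r.mu)) if cats_n > 1 else float(r.mu[0])
        total += r.loglik
        flag = []
        if any(h.startswith("mu") for h in r.boundary_hits):
            flag.append("at_bound")
        if not r.converged:
            flag.append("not_converged")
        if alpha:
            flag.append("alpha_weakly_identified")
        flags.append(",".join(flag) if flag else "ok")

    ref = per_pattern[0]
    return FitResult(
        mu=np.array([float(np.mean([r.mu for r in per_pattern]))]),
        rel_rates=ref.rel_rates, pi_hat=ref.pi_hat, alpha_hat=ref.alpha_hat,
        loglik=total, n_params=ref.n_params * patterns.n_patterns,
        converged=all(r.converged for r in per_pattern),
        n_iterations=sum(r.n_iterations for r in per_pattern),
        model=ref.model, a=ref.a, per_site_mu=per_site_mu,
        per_site_flags=flags,
        messages=[m_ for r in per_pattern for m_ in r.messages][:5])


def likelihood_ratio_test(loglik0: float, loglik1: float, df: int,
                          tolerance: float = 0.5) -> LrtResult:
    """Chi-square likelihood-ratio test of nested fits.

    ``loglik0`` is the restricted (null) model.  ``2 * (lnL1 - lnL0)`` is
    referred to the upper tail of a chi-square with ``df`` degrees of freedom.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    two_delta = 2.0 * (loglik1 - loglik0)
    if two_delta < -tolerance:
        raise ValueError(
            f"2*deltaLnL = {two_delta:.4f} < 0: the richer model fits worse, "
            "which signals an optimization failure")
    two_delta = max(two_delta, 0.0)
    return LrtResult(two_delta=two_delta, df=df,
                     p_value=float(chi2.sf(two_delta, df)))
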