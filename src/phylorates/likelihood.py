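"""Phylogenetic log-likelihood of discrete characters: pruning, transition
kernels, gamma mixtures, branch-category rate multipliers and the
unobservable-pattern (zero) correction.

The likelihood of a site pattern is computed by the pruning algorithm:
conditional (partial) likelihood vectors are propagated from the leaves to the
root through branch transition matrices ``P = exp(Q * nu)`` with
``nu = branch_length * mu_category * gamma_rate``, then weighted by the root
prior.  With ``zerocorrection`` the per-site likelihood is conditioned on the
pattern being observable by dividing by ``1 - L_minus``, where ``L_minus`` is
the likelihood of the all-zero (all-absent) pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import eigh, expm
from scipy.special import logsumexp

from .char_matrix import PatternSet
from .rate_models import (GammaRates, ModelSpec, assemble_q, calibrate_q,
                          uniform_prior, validate_prior)
from .tree_io import Tree

logger = logging.getLogger(__name__)

__all__ = [
    "LikelihoodConfig",
    "TransitionKernel",
    "transition_probs",
    "pattern_loglik",
    "unobservable_loglik",
    "total_loglik",
    "NEG_INF",
]

NEG_INF = float("-inf")


@dataclass
class LikelihoodConfig:
    """Everything needed to evaluate the likelihood on a tree."""

    model: ModelSpec
    rel_rates: np.ndarray
    mu: Mapping[int, float]  # branch category -> rate multiplier
    root_prior: np.ndarray
    reversible: bool = False
    gamma: Optional[GammaRates] = None
    zerocorrection: bool = False

    def __post_init__(self) -> None:
        self.root_prior = validate_prior(self.root_prior, self.model.a)
        self.rel_rates = np.asarray(self.rel_rates, dtype=float)
        self.mu = dict(self.mu)
        if any(v < 0 for v in self.mu.values()):
            raise ValueError("mu must be nonnegative")

    def build_q(self) -> np.ndarray:
        q = assemble_q(self.model, self.rel_rates, self.root_prior,
                       self.reversible)
        return calibrate_q(q, self.root_prior)


class TransitionKernel:
    """Repeated evaluation of ``P(nu) = exp(Q * nu)`` for one generator.

    Reversible generators (detailed balance with respect to ``pi``) are
    diagonalized once through the symmetric similarity transform
    ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``; other generators fall back to
    scaling-and-squaring (``scipy.linalg.expm``) per call.
    """

    def __init__(self, q: np.ndarray, pi: Optional[np.ndarray] = None):
        self.q = np.asarray(q, dtype=float)
        self._eig = None
        if pi is not None and (pi > 0).all():
            d = np.sqrt(pi)
            b = d[:, None] * self.q / d[None, :]
            if np.allclose(b, b.T, atol=1e-10):
                w, u = eigh((b + b.T) / 2.0)
                self._eig = (w, u, d)

    def probs(self, nu: float) -> np.ndarray:
        if not (np.isfinite(nu) and nu >= 0):
            raise ValueError(f"branch rate-distance nu must be >= 0, got {nu}")
        if nu == 0.0:
            return np.eye(self.q.shape[0])
        if self._eig is not None:
            w, u, d = self._eig
            p = (u * np.exp(w * nu)) @ u.T
            p = p / d[:, None] * d[None, :]
        else:
            p = expm(self.q * nu)
        return np.clip(p, 0.0, 1.0)


def transition_probs(q: np.ndarray, nu: float) -> np.ndarray:
    """One-shot ``exp(Q * nu)`` with entries clipped to ``[0, 1]``."""
    return TransitionKernel(q).probs(nu)


def _leaf_index(tree: Tree) -> dict[str, int]:
    return {name: i for i, name in enumerate(tree.leaf_names)}


def _pattern_logliks(tree: Tree, patterns: np.ndarray, q: np.ndarray,
                     pi: np.ndarray, mu: Mapping[int, float],
                     rate: float = 1.0) -> np.ndarray:
    """Vectorized pruning over a batch of patterns.

    ``patterns`` has one column per leaf in ``tree.leaf_names`` order.
    Returns natural-log likelihoods (``-inf`` for impossible patterns).
    Partial vectors are rescaled per node to avoid underflow on large trees.
    """
    a = q.shape[0]
    if patterns.size and patterns.max() >= a:
        raise ValueError("pattern contains states outside the model alphabet")
    kernel = TransitionKernel(q, pi)
    idx = _leaf_index(tree)
    n_pat = patterns.shape[0]
    eye = np.eye(a)
    logscale = np.zeros(n_pat)
    partial: dict[int, np.ndarray] = {}

    for node in tree.postorder():
        if node.is_leaf:
            f = eye[patterns[:, idx[node.name]]]
        else:
            f = np.ones((n_pat, a))
            for child in node.children:
                p = kernel.probs(child.length * mu[child.category] * rate)
                f = f * (partial.pop(id(child)) @ p.T)
            peak = f.max(axis=1)
            alive = peak > 0
            logscale[alive] += np.log(peak[alive])
            f = f / np.where(alive, peak, 1.0)[:, None]
        partial[id(node)] = f

    site_l = partial[id(tree.root)] @ pi
    with np.errstate(divide="ignore"):
        out = np.where(site_l > 0, np.log(np.maximum(site_l, 1e-320)), NEG_INF)
    return out + logscale


def _mu_for_tree(tree: Tree, config: LikelihoodConfig) -> dict[int, float]:
    cats = tree.categories
    missing = [c for c in cats if c not in config.mu]
    if missing:
        raise ValueError(f"no mu supplied for branch categories {missing}")
    return {c: float(config.mu[c]) for c in cats}


def pattern_loglik(tree: Tree, pattern: Mapping[str, int] | Sequence[int],
                   config: LikelihoodConfig, gamma_rate: float = 1.0) -> float:
    """Log-likelihood of a single site pattern at one gamma rate."""
    names = tree.leaf_names
    if isinstance(pattern, Mapping):
        missing = set(names) - set(pattern)
        if missing:
            raise ValueError(f"pattern missing leaves {sorted(missing)}")
        row = np.array([[pattern[n] for n in names]], dtype=int)
    else:
        if len(pattern) != len(names):
            raise ValueError("pattern length does not match the leaf count")
        row = np.array([list(pattern)], dtype=int)
    q = config.build_q()
    mu = _mu_for_tree(tree, config)
    return float(_pattern_logliks(tree, row, q, config.root_prior, mu,
                                  gamma_rate)[0])


def unobservable_loglik(tree: Tree, config: LikelihoodConfig,
                        gamma_rate: float = 1.0) -> float:
    """Log-likelihood of the all-zero pattern (every taxon in state 0)."""
    zeros = np.zeros(len(tree.leaf_names), dtype=int)
    return pattern_loglik(tree, zeros, config, gamma_rate)


def total_loglik(tree: Tree, patterns: PatternSet,
                 config: LikelihoodConfig) -> float:
    """Weighted log-likelihood over a pattern set.

    Per site the gamma mixture averages the K category likelihoods with equal
    weights; the zero-correction then divides the *mixed* site likelihood by
    ``1 - L_minus`` (with ``L_minus`` also gamma-mixed), so corrected site
    probabilities form a proper distribution over observable patterns.
    """
    q = config.build_q()
    pi = config.root_prior
    mu = _mu_for_tree(tree, config)
    rates = config.gamma.rates if config.gamma is not None else np.array([1.0])

    cols = patterns.patterns
    if patterns.taxa is not None:
        names = tree.leaf_names
        if set(patterns.taxa) != set(names):
            raise ValueError("pattern taxa do not match the tree leaves")
        order = [patterns.taxa.index(n) for n in names]
        cols = cols[:, order]

    per_cat = np.stack([
        _pattern_logliks(tree, cols, q, pi, mu, r) for r in rates
    ])  # (K, n_patterns)
    site_log = logsumexp(per_cat, axis=0) - np.log(len(rates))

    if config.zerocorrection:
        zeros = np.zeros((1, patterns.patterns.shape[1]), dtype=int)
        zero_log = logsumexp(
            [_pattern_logliks(tree, zeros, q, pi, mu, r)[0] for r in rates]
        ) - np.log(len(rates))
        l_minus = float(np.exp(zero_log))
        if 1.0 - l_minus <= 0.0:
            raise FloatingPointError(
                "zero-correction failed: unobservable-pattern likelihood >= 1")
        site_log = site_log - np.log1p(-l_minus)

    dead = ~np.isfinite(site_log)
    if dead.any():
        k = int(np.flatnonzero(dead)[0])
        logger.warning("pattern %s has zero likelihood; log-likelihood is -inf",
                       patterns.patterns[k].tolist())
        return NEG_INF
    return float(patterns.weights @ site_log)
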