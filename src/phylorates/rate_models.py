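"""Constrained instantaneous rate matrices, calibration, forced
reversibility, root priors and the discrete-gamma rate distribution.

Preset model templates tie the off-diagonal entries of the a x a generator to
shared positive relative-rate parameters.  A template is an integer grid where
entry ``k >= 1`` means "off-diagonal cell uses parameter k" and ``0`` is a
structural zero.  The birth-and-death (BD) family allows transitions only
between neighbouring states ``n <-> n+1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gamma as _gamma_dist

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "GammaRates",
    "make_model_spec",
    "assemble_q",
    "calibrate_q",
    "discrete_gamma",
    "uniform_prior",
    "validate_prior",
]

MODEL_NAMES = ("ER", "SYM", "ARD", "BDER", "BDSYM", "BDISYM", "BDARD", "CUSTOM")


@dataclass(frozen=True)
class ModelSpec:
    """A symmetry/neighbour constraint class on the generator."""

    name: str
    a: int
    template: np.ndarray  # (a, a) int grid; 0 = structural zero, k = param k
    free_params: int
    symmetric: bool
    neighbor_only: bool

    def __post_init__(self) -> None:
        t = self.template
        if t.shape != (self.a, self.a):
            raise ValueError("template must be a x a")
        if (t < 0).any():
            raise ValueError("template indices must be nonnegative")
        if np.diag(t).any():
            raise ValueError("template diagonal must be zero")


def uniform_prior(a: int) -> np.ndarray:
    return np.full(a, 1.0 / a)


def validate_prior(pi: Sequence[float], a: int) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (a,):
        raise ValueError(f"root prior must have length {a}")
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0, atol=1e-12):
        raise ValueError("root prior entries must be >= 0 and sum to 1")
    return pi


def make_model_spec(name: str, a: int,
                    custom_template: Optional[np.ndarray] = None) -> ModelSpec:
    """Build a preset (or custom) model template for ``a`` states.

    Free-parameter counts: ER and BDER 1; SYM ``a(a-1)/2``; ARD ``a(a-1)``;
    BDSYM ``a-1``; BDISYM 2 (requires ``a >= 3``); BDARD ``2(a-1)``.
    """
    name = name.upper()
    if a < 2:
        raise ValueError("need a >= 2 character states")
    t = np.zeros((a, a), dtype=int)

    if name == "ER":
        t[~np.eye(a, dtype=bool)] = 1
        return ModelSpec(name, a, t, 1, True, False)
    if name == "SYM":
        p = 0
        for i in range(a):
            for j in range(i + 1, a):
                p += 1
                t[i, j] = t[j, i] = p
        return ModelSpec(name, a, t, p, True, False)
    if name == "ARD":
        p = 0
        for i in range(a):
            for j in range(a):
                if i != j:
                    p += 1
                    t[i, j] = p
        return ModelSpec(name, a, t, p, False, False)
    if name == "BDER":
        for i in range(a - 1):
            t[i, i + 1] = t[i + 1, i] = 1
        return ModelSpec(name, a, t, 1, True, True)
    if name == "BDSYM":
        for i in range(a - 1):
            t[i, i + 1] = t[i + 1, i] = i + 1
        return ModelSpec(name, a, t, a - 1, True, True)
    if name == "BDISYM":
        if a < 3:
            raise ValueError("BDISYM requires a >= 3 (it degenerates to BDSYM "
                             "at a=2; use BDSYM instead)")
        t[0, 1] = t[1, 0] = 1
        for i in range(1, a - 1):
            t[i, i + 1] = t[i + 1, i] = 2
        return ModelSpec(name, a, t, 2, True, True)
    if name == "BDARD":
        # births first (n -> n+1), then deaths (n+1 -> n)
        for i in range(a - 1):
            t[i, i + 1] = i + 1
        for i in range(a - 1):
            t[i + 1, i] = a - 1 + i + 1
        return ModelSpec(name, a, t, 2 * (a - 1), False, True)
    if name == "CUSTOM":
        if custom_template is None:
            raise ValueError("CUSTOM requires a template grid")
        t = np.asarray(custom_template, dtype=int)
        if (t < 0).any():
            raise ValueError("custom template indices must be nonnegative")
        spec = ModelSpec("CUSTOM", a, t, int(t.max()),
                         bool((t == t.T).all()), False)
        _warn_if_reducible(spec)
        return spec
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _warn_if_reducible(spec: ModelSpec) -> None:
    """Structural zeros may disconnect states; warn, don't fail."""
    reach = (spec.template + spec.template.T) > 0
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(reach[i]):
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    if len(seen) < spec.a:
        logger.warning("custom template leaves the state graph disconnected; "
                       "some states are unreachable")


def assemble_q(spec: ModelSpec, rel_rates: Sequence[float],
               pi: Optional[Sequence[float]] = None,
               reversible: bool = False) -> np.ndarray:
    """Fill the template with relative rates; not yet calibrated.

    With ``reversible=True`` (symmetric templates only) each off-diagonal
    entry is additionally multiplied by the destination-state root
    probability, which enforces detailed balance ``pi_i q_ij = pi_j q_ji``.
    """
    rel = np.asarray(rel_rates, dtype=float)
    if rel.shape != (spec.free_params,):
        raise ValueError(f"{spec.name} expects {spec.free_params} relative "
                         f"rates, got {rel.shape}")
    if (rel <= 0).any():
        raise ValueError("relative rates must be positive")
    if reversible and not spec.symmetric:
        raise ValueError(
            f"reversible=True requires a symmetric template (ER/SYM/BD*SYM); "
            f"{spec.name} is not symmetric")

    lookup = np.concatenate([[0.0], rel])
    q = lookup[spec.template]
    if reversible:
        pi = validate_prior(uniform_prior(spec.a) if pi is None else pi, spec.a)
        q = q * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def calibrate_q(q: np.ndarray, pi: Sequence[float]) -> np.ndarray:
    """Rescale so the expected number of transitions per site per time unit
    is 1, i.e. ``-sum_i pi_i q_ii = 1``."""
    q = np.asarray(q, dtype=float)
    pi = validate_prior(pi, q.shape[0])
    rate = -float(pi @ np.diag(q))
    if rate <= 1e-300:
        raise ValueError("calibration impossible: expected transition rate is "
                         "zero under this root prior")
    return q / rate


@dataclass(frozen=True)
class GammaRates:
    """K equal-probability rate categories of a mean-1 gamma distribution."""

    alpha: float
    K: int
    rates: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.rates.mean(), 1.0, atol=1e-9):
            raise ValueError("category rates must average 1")
        if (np.diff(self.rates) < -1e-12).any():
            raise ValueError("category rates must be nondecreasing")


def discrete_gamma(alpha: float, K: int) -> GammaRates:
    """Discretize Gamma(shape=alpha, mean=1) into K equal-probability
    categories, each represented by its conditional mean (so the discretized
    mean is exactly 1).
    """
    if not (alpha > 0 and np.isfinite(alpha)):
        raise ValueError("gamma shape must be a positive finite number")
    if K < 1:
        raise ValueError("need at least one rate category")
    if K == 1:
        return GammaRates(alpha, 1, np.array([1.0]))
    # mean-1 gamma: shape=alpha, scale=1/alpha
    edges = _gamma_dist.ppf(np.arange(1, K) / K, alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X | bin] * P(bin) = mean * (F_{alpha+1}(hi) - F_{alpha+1}(lo))
    cdf_up = _gamma_dist.cdf(edges, alpha + 1.0, scale=1.0 / alpha)
    rates = K * np.diff(cdf_up)
    rates = rates / rates.mean()  # remove residual quadrature error
    return GammaRates(alpha, K, rates)
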