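"""Objective heavy-tailed priors built from the score zero-set.

The positive-axis prior is ``q(x) = a/(a+x)^2`` — a Lomax distribution
with scale ``a`` and shape 1, hence proper but with no finite mean — and
its symmetric extension to the real line is ``q(x) = (1/2) a/(|x|+a)^2``.
Both solve ``S = 0`` for the score generated by ``alpha(u) = u^-2``
(see :mod:`scoreprior.score_engine`).

The scale constant defaults to ``a = 1``: the positive-axis prior is
invariant under the reciprocal map ``phi = 1/x`` (which swaps, e.g.,
variance and precision) iff ``a = 1``, since the pushforward density is
``a/(a*phi+1)^2``.

Improper comparison priors (Jeffreys ``1/sigma`` for a scale, flat for a
location) are represented only as log-kernels and are refused as sampling
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .score_engine import DensityTriplet, DomainError

__all__ = [
    "PriorSpec",
    "InverseGammaPrior",
    "SCORE_POSITIVE",
    "SCORE_REAL",
    "JEFFREYS_SCALE",
    "FLAT",
    "score_prior_pdf",
    "score_prior_logpdf",
    "score_prior_cdf",
    "score_prior_quantile",
    "score_prior_sample",
    "comparison_log_prior",
    "log_prior",
    "reciprocal_pushforward",
    "triplet",
]

_KINDS = ("score_positive", "score_real", "jeffreys_scale", "flat")


@dataclass(frozen=True)
class PriorSpec:
    """One prior in the comparison set.

    ``a`` is the scale constant of the score priors (ignored by the
    improper comparison kernels).  ``proper`` is derived, not stored.
    """

    kind: str
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not (self.a > 0):
            raise ValueError(f"scale constant a must be positive, got {self.a!r}")

    @property
    def proper(self) -> bool:
        return self.kind in ("score_positive", "score_real")


@dataclass(frozen=True)
class InverseGammaPrior:
    """IG(eps, eps) prior on a variance, the sparse comparison choice."""

    eps: float = 1.0

    def __post_init__(self) -> None:
        if not (self.eps > 0):
            raise ValueError("eps must be positive")

    def log_density(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                v > 0,
                -(self.eps + 1.0) * np.log(np.where(v > 0, v, 1.0))
                - self.eps / np.where(v > 0, v, 1.0),
                -np.inf,
            )
        return out


SCORE_POSITIVE = PriorSpec("score_positive")
SCORE_REAL = PriorSpec("score_real")
JEFFREYS_SCALE = PriorSpec("jeffreys_scale")
FLAT = PriorSpec("flat")


def _require_score(spec: PriorSpec) -> None:
    if spec.kind not in ("score_positive", "score_real"):
        raise ValueError(f"operation defined only for score priors, got {spec.kind!r}")


def score_prior_pdf(x, spec: PriorSpec = SCORE_POSITIVE):
    """Density a/(a+x)^2 on (0, inf), or (1/2) a/(|x|+a)^2 on R."""
    _require_score(spec)
    x = np.asarray(x, dtype=float)
    a = spec.a
    if spec.kind == "score_positive":
        if np.any(x < 0):
            raise DomainError("x must be >= 0 for the positive-axis prior")
        out = a / (a + x) ** 2
    else:
        out = 0.5 * a / (np.abs(x) + a) ** 2
    return out if out.ndim else float(out)


def score_prior_logpdf(x, spec: PriorSpec = SCORE_POSITIVE):
    _require_score(spec)
    x = np.asarray(x, dtype=float)
    a = spec.a
    if spec.kind == "score_positive":
        if np.any(x < 0):
            raise DomainError("x must be >= 0 for the positive-axis prior")
        out = math.log(a) - 2.0 * np.log(a + x)
    else:
        out = math.log(a / 2.0) - 2.0 * np.log(np.abs(x) + a)
    return out if np.ndim(out) else float(out)


def score_prior_cdf(x, spec: PriorSpec = SCORE_POSITIVE):
    """Closed-form cdf: x/(a+x) on (0, inf); symmetric reflection on R."""
    _require_score(spec)
    x = np.asarray(x, dtype=float)
    a = spec.a
    if spec.kind == "score_positive":
        if np.any(x < 0):
            raise DomainError("x must be >= 0 for the positive-axis prior")
        out = x / (a + x)
    else:
        t = np.abs(x)
        out = 0.5 + np.sign(x) * 0.5 * t / (a + t)
    return out if out.ndim else float(out)


def score_prior_quantile(p, spec: PriorSpec = SCORE_POSITIVE):
    """Inverse cdf; p = 1 (or 0 on the real line) has no finite quantile."""
    _require_score(spec)
    p = np.asarray(p, dtype=float)
    a = spec.a
    if np.any(p >= 1.0):
        raise ValueError("quantile undefined at p >= 1 (the prior has no mean)")
    if spec.kind == "score_positive":
        if np.any(p < 0.0):
            raise ValueError("p must lie in [0, 1)")
        out = a * p / (1.0 - p)
    else:
        if np.any(p <= 0.0):
            raise ValueError("p must lie in (0, 1) on the real line")
        s = np.sign(p - 0.5)
        t = np.abs(2.0 * p - 1.0)      # cdf of |x|
        out = s * a * t / (1.0 - t)
    return out if out.ndim else float(out)


def score_prior_sample(n: int, seed, spec: PriorSpec = SCORE_POSITIVE) -> np.ndarray:
    """Inverse-cdf sampling; the real-line prior draws a magnitude from the
    positive-axis prior and attaches an independent fair sign."""
    _require_score(spec)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    mag = spec.a * u / (1.0 - u)
    if spec.kind == "score_positive":
        return mag
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    return sign * mag


def comparison_log_prior(x, kind: str):
    """Unnormalised log-kernels of the improper comparison priors."""
    x = np.asarray(x, dtype=float)
    if kind == "jeffreys_scale":
        if np.any(x <= 0):
            raise DomainError("Jeffreys scale prior requires x > 0")
        out = -np.log(x)
    elif kind == "flat":
        out = np.zeros_like(x)
    else:
        raise ValueError(f"unknown comparison prior {kind!r}")
    return out if out.ndim else float(out)


def log_prior(x, spec: PriorSpec):
    """Unified log-density / log-kernel, -inf off support (array-safe).

    This is the form the posterior kernels consume: proper score priors
    return true log-densities, the improper kinds return log-kernels.
    """
    x = np.asarray(x, dtype=float)
    a = spec.a
    with np.errstate(divide="ignore", invalid="ignore"):
        if spec.kind == "score_positive":
            safe = np.where(x >= 0, x, 0.0)
            out = np.where(x >= 0, math.log(a) - 2.0 * np.log(a + safe), -np.inf)
        elif spec.kind == "score_real":
            out = math.log(a / 2.0) - 2.0 * np.log(np.abs(x) + a)
        elif spec.kind == "jeffreys_scale":
            safe = np.where(x > 0, x, 1.0)
            out = np.where(x > 0, -np.log(safe), -np.inf)
        else:  # flat
            out = np.zeros_like(x)
    return out if out.ndim else float(out)


def reciprocal_pushforward(
    spec: PriorSpec,
    grid=(0.1, 0.5, 1.0, 2.0, 10.0),
    rtol: float = 1e-12,
) -> tuple[Callable[[np.ndarray], np.ndarray], bool]:
    """Density of phi = 1/x under the positive-axis prior, and whether it
    coincides with the original density on ``grid`` (true iff a = 1).

    The pushforward has the closed form a/(a*phi + 1)^2: applying it twice
    returns the original family member, so the map is an involution on
    this family.
    """
    if spec.kind != "score_positive":
        raise ValueError("reciprocal pushforward is defined for the positive-axis prior")
    a = spec.a

    def pushed(phi):
        phi = np.asarray(phi, dtype=float)
        out = a / (a * phi + 1.0) ** 2
        return out if out.ndim else float(out)

    g = np.asarray(grid, dtype=float)
    invariant = bool(np.allclose(pushed(g), score_prior_pdf(g, spec), rtol=rtol, atol=0.0))
    return pushed, invariant


def triplet(spec: PriorSpec, x: float) -> DensityTriplet:
    """Analytic (q, q', q'') of a score prior at x, for the score engine."""
    _require_score(spec)
    a = spec.a
    if spec.kind == "score_positive":
        if x < 0:
            raise DomainError("x must be >= 0")
        s = a + x
        return DensityTriplet(x=x, q=a / s ** 2, q1=-2.0 * a / s ** 3, q2=6.0 * a / s ** 4)
    # real line: differentiable except at 0
    if x == 0:
        raise DomainError("the real-line prior is not differentiable at 0")
    s = abs(x) + a
    sgn = math.copysign(1.0, x)
    return DensityTriplet(
        x=x, q=0.5 * a / s ** 2, q1=-sgn * a / s ** 3, q2=3.0 * a / s ** 4
    )
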