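"""MCMC machinery: random-walk Metropolis and Metropolis-within-Gibbs.

Three samplers, matching the three model classes in the validation
studies:

* :func:`rw_metropolis` — scalar random-walk Metropolis-Hastings with a
  normal proposal, for the 1-D scale / location posteriors;
* :func:`mixture_mwg` — Metropolis-within-Gibbs for a k-component Gaussian
  mixture: latent allocations, conjugate Dirichlet weight updates, and
  componentwise random-walk updates of means (real-line score prior) and
  standard deviations (positive-axis score prior);
* :func:`schools_mwg` — the two-level hierarchical (eight-schools) model
  with known per-group standard errors, Gibbs updates for the grand mean
  and the group effects, and either a conjugate inverse-gamma draw or a
  log-scale Metropolis step (with Jacobian) for the between-group
  variance.

Proposal scales are pilot-tuned per parameter during burn-in to an
acceptance rate in [0.2, 0.5] and then frozen, so post-burn-in chains are
valid Metropolis chains.  All randomness flows through explicitly seeded
``numpy.random.Generator`` objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .priors import (
    FLAT,
    InverseGammaPrior,
    JEFFREYS_SCALE,
    PriorSpec,
    SCORE_POSITIVE,
    SCORE_REAL,
    log_prior,
)

__all__ = [
    "MCMCConfig",
    "Chain",
    "MixtureSpec",
    "SchoolsData",
    "rw_metropolis",
    "rw_metropolis_ensemble",
    "normal_scale_log_posterior",
    "lognormal_location_log_posterior",
    "mixture_mwg",
    "mixture_log_likelihood",
    "relabel_components",
    "schools_mwg",
]

_ADAPT_WINDOW = 50
_ADAPT_LO, _ADAPT_HI = 0.2, 0.5
_ADAPT_SHRINK, _ADAPT_GROW = 0.7, 1.4


@dataclass(frozen=True)
class MCMCConfig:
    """Iteration schedule and proposal settings for one run."""

    n_iter: int
    burn_in: int = 0
    thin: int = 1
    proposal_sd: float = 1.0
    seed: int = 0
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ValueError("n_iter must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (self.proposal_sd > 0):
            raise ValueError("proposal_sd must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class Chain:
    """Post-burn-in, thinned draws with acceptance diagnostics."""

    draws: np.ndarray            # (retained, n_params)
    names: list[str]
    acceptance: dict[str, float]
    config: MCMCConfig

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[1] != len(self.names):
            raise ValueError("draws width does not match names")

    def __len__(self) -> int:
        return self.draws.shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        qs = np.quantile(self.draws, [lo, 0.5, hi], axis=0)
        return pd.DataFrame(
            {
                "mean": self.mean(),
                "sd": self.draws.std(axis=0, ddof=1) if len(self) > 1 else 0.0,
                f"q{lo:g}": qs[0],
                "median": qs[1],
                f"q{hi:g}": qs[2],
            },
            index=self.names,
        )


@dataclass(frozen=True)
class MixtureSpec:
    """Truth (k, weights, means, sds) of a finite Gaussian mixture."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.weights)
        if not (len(self.means) == len(self.sds) == k) or k < 1:
            raise ValueError("weights, means, sds must share length k >= 1")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class SchoolsData:
    """Group-level observed effects with known standard errors."""

    labels: tuple[str, ...]
    y: tuple[float, ...]
    se: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.y) == len(self.se)):
            raise ValueError("labels, y, se must share length")
        if any(s <= 0 for s in self.se):
            raise ValueError("standard errors must be positive")

    @property
    def J(self) -> int:
        return len(self.y)


# --------------------------------------------------------------------------
# scalar and ensemble random-walk Metropolis
# --------------------------------------------------------------------------


def _record_mask(cfg: MCMCConfig, t: int) -> bool:
    # record the thin-th, 2*thin-th, ... post-burn-in iterates: length floor((n-b)/thin)
    return t >= cfg.burn_in and (t - cfg.burn_in + 1) % cfg.thin == 0


def rw_metropolis(
    log_target: Callable[[float], float],
    init: float,
    cfg: MCMCConfig,
    name: str = "x",
) -> Chain:
    """Scalar symmetric random-walk Metropolis-Hastings.

    Proposals where the target is -inf (off support) are rejected.  The
    reported acceptance rate covers post-burn-in iterations only.
    """
    lp = float(log_target(float(init)))
    if not math.isfinite(lp):
        raise ValueError(f"log_target not finite at init = {init!r}")
    rng = np.random.default_rng(cfg.seed)
    x = float(init)
    sd = float(cfg.proposal_sd)
    draws = np.empty(cfg.n_retained)
    k = 0
    acc_post = 0
    acc_win = 0
    for t in range(cfg.n_iter):
        prop = x + sd * rng.standard_normal()
        lpp = float(log_target(prop))
        if lpp - lp > math.log(rng.random()):
            x, lp = prop, lpp
            acc_win += 1
            if t >= cfg.burn_in:
                acc_post += 1
        if cfg.adapt and t < cfg.burn_in and (t + 1) % _ADAPT_WINDOW == 0:
            rate = acc_win / _ADAPT_WINDOW
            if rate < _ADAPT_LO:
                sd *= _ADAPT_SHRINK
            elif rate > _ADAPT_HI:
                sd *= _ADAPT_GROW
            acc_win = 0
        if _record_mask(cfg, t):
            draws[k] = x
            k += 1
    n_post = cfg.n_iter - cfg.burn_in
    return Chain(
        draws=draws[:k, None],
        names=[name],
        acceptance={name: acc_post / n_post},
        config=cfg,
    )


def rw_metropolis_ensemble(
    log_target: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    cfg: MCMCConfig,
    proposal_sd: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """R independent scalar RW-Metropolis chains advanced in lockstep.

    ``log_target`` maps a state vector (R,) to a log-density vector (R,);
    chain r targets component r.  Used by the replication studies, where
    one chain per replicate dataset turns a table cell into vector
    arithmetic.  Returns (draws (retained, R), acceptance rates (R,)).
    """
    x = np.array(init, dtype=float)
    R = x.shape[0]
    lp = np.asarray(log_target(x), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("log_target not finite at some init")
    rng = np.random.default_rng(cfg.seed)
    sd = np.full(R, float(cfg.proposal_sd)) if proposal_sd is None else np.array(
        proposal_sd, dtype=float
    )
    draws = np.empty((cfg.n_retained, R))
    k = 0
    acc_post = np.zeros(R)
    acc_win = np.zeros(R)
    for t in range(cfg.n_iter):
        prop = x + sd * rng.standard_normal(R)
        lpp = np.asarray(log_target(prop), dtype=float)
        accept = lpp - lp > np.log(rng.random(R))
        x = np.where(accept, prop, x)
        lp = np.where(accept, lpp, lp)
        acc_win += accept
        if t >= cfg.burn_in:
            acc_post += accept
        if cfg.adapt and t < cfg.burn_in and (t + 1) % _ADAPT_WINDOW == 0:
            rate = acc_win / _ADAPT_WINDOW
            sd = sd * np.where(
                rate < _ADAPT_LO, _ADAPT_SHRINK, np.where(rate > _ADAPT_HI, _ADAPT_GROW, 1.0)
            )
            acc_win[:] = 0.0
        if _record_mask(cfg, t):
            draws[k] = x
            k += 1
    n_post = cfg.n_iter - cfg.burn_in
    return draws[:k], acc_post / n_post


# --------------------------------------------------------------------------
# 1-D posterior kernels
# --------------------------------------------------------------------------


def normal_scale_log_posterior(
    data: Sequence[float], prior: PriorSpec
) -> Callable[[np.ndarray], np.ndarray]:
    """Kernel of sigma for N(0, sigma^2) data: -n log s - (sum x^2)/(2 s^2) + log prior."""
    y = np.asarray(data, dtype=float)
    if y.size == 0:
        raise ValueError("data must be non-empty")
    if prior.kind not in ("score_positive", "jeffreys_scale"):
        raise ValueError("scale posterior expects a score_positive or jeffreys_scale prior")
    n = y.size
    s2 = float(np.sum(y * y))

    def logpost(sigma):
        sig = np.asarray(sigma, dtype=float)
        safe = np.where(sig > 0, sig, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                sig > 0,
                -n * np.log(safe) - s2 / (2.0 * safe ** 2) + log_prior(safe, prior),
                -np.inf,
            )
        return out if out.ndim else float(out)

    return logpost


def lognormal_location_log_posterior(
    data: Sequence[float], prior: PriorSpec
) -> Callable[[np.ndarray], np.ndarray]:
    """Kernel of mu for log-normal(mu, 1) data: -(1/2) sum (log x - mu)^2 + log prior."""
    y = np.asarray(data, dtype=float)
    if y.size == 0:
        raise ValueError("data must be non-empty")
    if np.any(y <= 0):
        raise ValueError("log-normal data must be positive")
    if prior.kind not in ("score_real", "flat"):
        raise ValueError("location posterior expects a score_real or flat prior")
    z = np.log(y)
    n = z.size
    s1 = float(z.sum())
    s2 = float(np.sum(z * z))

    def logpost(mu):
        m = np.asarray(mu, dtype=float)
        out = -0.5 * (s2 - 2.0 * m * s1 + n * m * m) + log_prior(m, prior)
        return out if out.ndim else float(out)

    return logpost


# --------------------------------------------------------------------------
# Gaussian mixture: Metropolis-within-Gibbs
# --------------------------------------------------------------------------


def mixture_parameter_names(k: int) -> list[str]:
    return (
        [f"w{l}" for l in range(1, k + 1)]
        + [f"mu{l}" for l in range(1, k + 1)]
        + [f"sigma{l}" for l in range(1, k + 1)]
    )


def mixture_mwg(
    data: Sequence[float],
    k: int,
    cfg: MCMCConfig,
    prior_a: float = 1.0,
) -> Chain:
    """Metropolis-within-Gibbs for a k-component Gaussian mixture.

    One sweep:

    1. latent allocations ``z_i ~ Categorical(prop. to w_l N(y_i | mu_l, sigma_l^2))``;
    2. weights from the conjugate ``Dirichlet(1 + n_1, ..., 1 + n_k)``
       (symmetric unit-concentration Dirichlet prior);
    3. for each component, a random-walk Metropolis update of ``mu_l``
       under the real-line score prior and of ``sigma_l`` under the
       positive-axis score prior (off-support proposals rejected).

    Likelihood factors are evaluated through per-component sufficient
    statistics (count, sum, sum of squares), so each sweep is O(n k).
    """
    y = np.asarray(data, dtype=float)
    n = y.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the sample size n = {n}")
    rng = np.random.default_rng(cfg.seed)
    mu_prior = PriorSpec("score_real", a=prior_a)
    sd_prior = PriorSpec("score_positive", a=prior_a)

    # moment-based initialisation: means at interior quantiles, common sd
    w = np.full(k, 1.0 / k)
    mu = np.quantile(y, (np.arange(k) + 0.5) / k)
    sig = np.full(k, max(y.std() / max(k, 1), 1e-3))
    sd_mu = np.full(k, max(y.std() / 5.0, 1e-2))
    sd_sig = np.full(k, 0.3)

    names = mixture_parameter_names(k)
    draws = np.empty((cfg.n_retained, 3 * k))
    kept = 0
    acc = np.zeros(2 * k)       # mu then sigma
    acc_win = np.zeros(2 * k)
    n_post = cfg.n_iter - cfg.burn_in
    log2pi = math.log(2.0 * math.pi)

    def comp_loglik(nl, sl, ssl, m, s):
        # sum over members of -log s - (y - m)^2 / (2 s^2), dropping const
        return -nl * math.log(s) - (ssl - 2.0 * m * sl + nl * m * m) / (2.0 * s * s)

    for t in range(cfg.n_iter):
        # 1. allocations (Gumbel-max on the log scale; stable for small densities)
        logp = (
            np.log(np.maximum(w, 1e-300))[None, :]
            - np.log(sig)[None, :]
            - 0.5 * ((y[:, None] - mu[None, :]) / sig[None, :]) ** 2
        )
        z = np.argmax(logp + rng.gumbel(size=(n, k)), axis=1)
        counts = np.bincount(z, minlength=k).astype(float)
        sums = np.bincount(z, weights=y, minlength=k)
        sumsq = np.bincount(z, weights=y * y, minlength=k)

        # 2. conjugate weight update
        w = rng.dirichlet(1.0 + counts)

        # 3. componentwise random-walk updates
        zn = rng.standard_normal(2 * k)
        zu = rng.random(2 * k)
        for l in range(k):
            nl, sl, ssl = counts[l], sums[l], sumsq[l]
            # mu_l
            prop = mu[l] + sd_mu[l] * zn[l]
            cur = comp_loglik(nl, sl, ssl, mu[l], sig[l]) + log_prior(mu[l], mu_prior)
            new = comp_loglik(nl, sl, ssl, prop, sig[l]) + log_prior(prop, mu_prior)
            if new - cur > math.log(zu[l]):
                mu[l] = prop
                acc_win[l] += 1
                if t >= cfg.burn_in:
                    acc[l] += 1
            # sigma_l (raw-scale proposal, off-support rejected)
            prop = sig[l] + sd_sig[l] * zn[k + l]
            if prop > 0:
                cur = comp_loglik(nl, sl, ssl, mu[l], sig[l]) + log_prior(sig[l], sd_prior)
                new = comp_loglik(nl, sl, ssl, mu[l], prop) + log_prior(prop, sd_prior)
                if new - cur > math.log(zu[k + l]):
                    sig[l] = prop
                    acc_win[k + l] += 1
                    if t >= cfg.burn_in:
                        acc[k + l] += 1

        if cfg.adapt and t < cfg.burn_in and (t + 1) % _ADAPT_WINDOW == 0:
            rate = acc_win / _ADAPT_WINDOW
            for arr, j0 in ((sd_mu, 0), (sd_sig, k)):
                r = rate[j0 : j0 + k]
                arr *= np.where(r < _ADAPT_LO, _ADAPT_SHRINK, np.where(r > _ADAPT_HI, _ADAPT_GROW, 1.0))
            acc_win[:] = 0.0

        if _record_mask(cfg, t):
            draws[kept, :k] = w
            draws[kept, k : 2 * k] = mu
            draws[kept, 2 * k :] = sig
            kept += 1

    rates = {}
    for l in range(k):
        rates[f"mu{l + 1}"] = acc[l] / n_post
        rates[f"sigma{l + 1}"] = acc[k + l] / n_post
    return Chain(draws=draws[:kept], names=names, acceptance=rates, config=cfg)


def mixture_log_likelihood(params: np.ndarray, data: np.ndarray, k: int) -> float:
    """Log-likelihood of one (w, mu, sigma) parameter row for the mixture."""
    params = np.asarray(params, dtype=float)
    y = np.asarray(data, dtype=float)
    w, mu, sig = params[:k], params[k : 2 * k], params[2 * k : 3 * k]
    if np.any(sig <= 0) or np.any(w < 0):
        return -np.inf
    logp = (
        np.log(np.maximum(w, 1e-300))[None, :]
        - np.log(sig)[None, :]
        - 0.5 * ((y[:, None] - mu[None, :]) / sig[None, :]) ** 2
        - 0.5 * math.log(2.0 * math.pi)
    )
    m = logp.max(axis=1)
    return float(np.sum(m + np.log(np.sum(np.exp(logp - m[:, None]), axis=1))))


def relabel_components(chain: Chain, k: int, by: str = "mu_mean") -> Chain:
    """Resolve label switching by one global permutation of the components.

    ``by="mu_mean"`` orders components by the posterior mean of their
    location (ascending); ``by="weight_desc"`` by descending posterior
    mean weight (the convention for reporting the velocity-mixture
    table).
    """
    if chain.draws.shape[1] != 3 * k:
        raise ValueError("chain does not look like a k-component mixture chain")
    means = chain.draws.mean(axis=0)
    if by == "mu_mean":
        order = np.argsort(means[k : 2 * k])
    elif by == "weight_desc":
        order = np.argsort(-means[:k])
    else:
        raise ValueError(f"unknown relabeling rule {by!r}")
    idx = np.concatenate([order, k + order, 2 * k + order])
    names = mixture_parameter_names(k)
    acc = {}
    for new, old in enumerate(order):
        for stem in ("mu", "sigma"):
            key = f"{stem}{old + 1}"
            if key in chain.acceptance:
                acc[f"{stem}{new + 1}"] = chain.acceptance[key]
    return Chain(
        draws=chain.draws[:, idx], names=names, acceptance=acc, config=chain.config
    )


# --------------------------------------------------------------------------
# hierarchical (eight-schools) model
# --------------------------------------------------------------------------


def schools_mwg(
    data: SchoolsData,
    variance_prior: PriorSpec | InverseGammaPrior,
    cfg: MCMCConfig,
) -> Chain:
    """Metropolis-within-Gibbs for y_j ~ N(mu + alpha_j, se_j^2),
    alpha_j ~ N(0, sigma_alpha^2), flat prior on mu.

    The between-group variance is updated by a conjugate inverse-gamma
    draw when ``variance_prior`` is :class:`InverseGammaPrior`, or by a
    random-walk Metropolis step on ``log sigma_alpha^2`` (with Jacobian)
    when it is the positive-axis score prior — the score posterior spans
    orders of magnitude, so the log scale is what mixes.
    """
    if data.J < 2:
        raise ValueError("need at least 2 groups to identify the between-group variance")
    if isinstance(variance_prior, PriorSpec) and variance_prior.kind != "score_positive":
        raise ValueError("variance_prior must be score_positive or InverseGammaPrior")
    y = np.asarray(data.y, dtype=float)
    se2 = np.asarray(data.se, dtype=float) ** 2
    J = data.J
    rng = np.random.default_rng(cfg.seed)
    conjugate = isinstance(variance_prior, InverseGammaPrior)

    mu = float(y.mean())
    alpha = np.zeros(J)
    v = max(float(np.var(y, ddof=1)), 1e-2)     # sigma_alpha^2
    t_sd = float(cfg.proposal_sd) if not conjugate else 0.0
    names = ["mu"] + [f"alpha_{lab}" for lab in data.labels] + ["sigma_alpha2"]
    draws = np.empty((cfg.n_retained, J + 2))
    kept = 0
    acc = 0
    acc_win = 0
    n_post = cfg.n_iter - cfg.burn_in

    def log_post_v(vv: float) -> float:
        if vv <= 0:
            return -np.inf
        lp = float(log_prior(vv, variance_prior)) if not conjugate else 0.0
        return lp - 0.5 * J * math.log(vv) - float(np.sum(alpha ** 2)) / (2.0 * vv)

    for t in range(cfg.n_iter):
        # mu | alpha, y  (flat prior)
        w = 1.0 / se2
        W = w.sum()
        mu = rng.normal((w * (y - alpha)).sum() / W, math.sqrt(1.0 / W))
        # alpha_j | mu, v, y
        prec = 1.0 / se2 + 1.0 / v
        mean = ((y - mu) / se2) / prec
        alpha = mean + rng.standard_normal(J) / np.sqrt(prec)
        # v
        if conjugate:
            shape = variance_prior.eps + 0.5 * J
            scale = variance_prior.eps + 0.5 * float(np.sum(alpha ** 2))
            v = scale / rng.gamma(shape)
        else:
            lt = math.log(v)
            prop = lt + t_sd * rng.standard_normal()
            # target on t = log v includes the Jacobian e^t
            cur = log_post_v(v) + lt
            new = log_post_v(math.exp(prop)) + prop
            if new - cur > math.log(rng.random()):
                v = math.exp(prop)
                acc_win += 1
                if t >= cfg.burn_in:
                    acc += 1
            if cfg.adapt and t < cfg.burn_in and (t + 1) % _ADAPT_WINDOW == 0:
                rate = acc_win / _ADAPT_WINDOW
                if rate < _ADAPT_LO:
                    t_sd *= _ADAPT_SHRINK
                elif rate > _ADAPT_HI:
                    t_sd *= _ADAPT_GROW
                acc_win = 0
        if _record_mask(cfg, t):
            draws[kept, 0] = mu
            draws[kept, 1 : J + 1] = alpha
            draws[kept, J + 1] = v
            kept += 1

    rates = {"sigma_alpha2": 1.0 if conjugate else acc / n_post}
    return Chain(draws=draws[:kept], names=names, acceptance=rates, config=cfg)
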