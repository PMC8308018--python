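"""Repeated-sampling validation studies, DIC model selection, summaries.

Each study is a grid of (prior, true value, sample size) cells.  A cell
draws ``reps`` replicate datasets, samples the posterior for each, and
aggregates the posterior-mean estimator into

* ``nrmse`` — root mean squared error divided by the true value,
* ``rmse`` / ``mse`` — the un-normalised root/raw mean squared error
  (the location tables print the raw MSE, which is also the only option
  when the truth is 0),
* ``coverage`` — the fraction of 95% equal-tailed credible intervals
  containing the truth.

Within a cell the replicate chains are advanced in lockstep as a numpy
ensemble (one Metropolis chain per replicate; identical algorithm to the
scalar sampler).  Seeds derive deterministically from the study seed and
the cell coordinates, so every cell is independently reproducible and
data are shared across priors within a cell (a paired comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .priors import PriorSpec, log_prior
from .samplers import (
    Chain,
    MCMCConfig,
    MixtureSpec,
    mixture_log_likelihood,
    mixture_mwg,
    relabel_components,
    rw_metropolis_ensemble,
)
from .data_io import generate_mixture

__all__ = [
    "StudyResult",
    "nrmse",
    "credible_interval",
    "run_scale_study",
    "run_location_study",
    "run_mixture_repeats",
    "dic",
    "run_dic_scan",
]

_STUDY_CODES = {"scale": 11, "location": 12, "mixture_repeats": 13, "dic": 14}


@dataclass
class StudyResult:
    """Per-cell error and coverage summaries plus the seed schedule."""

    table: pd.DataFrame
    reps: int
    seed: int
    config: MCMCConfig

    def cell(self, prior: str, truth: float, n: int) -> pd.Series:
        t = self.table
        m = (t["prior"] == prior) & (t["truth"] == truth) & (t["n"] == n)
        if not m.any():
            raise KeyError(f"no cell ({prior}, {truth}, {n})")
        return t[m].iloc[0]


def nrmse(estimates: Sequence[float], truth: float) -> float:
    """sqrt(mean (estimate - truth)^2) / truth; undefined at truth = 0."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one replicate")
    if truth == 0:
        raise ValueError("nrmse undefined at truth = 0 (use the raw MSE)")
    return float(np.sqrt(np.mean((est - truth) ** 2)) / truth)


def credible_interval(draws: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed interval from empirical (linear-interpolated) quantiles."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    d = np.asarray(draws, dtype=float)
    if d.size < 100:
        raise ValueError("need at least 100 draws for a stable interval")
    lo, hi = np.quantile(d, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def _cell_seed(seed: int, study: str, *coords: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, _STUDY_CODES[study], *coords])


def _run_cell(
    data: np.ndarray,
    target_factory: Callable[[np.ndarray], Callable],
    init: np.ndarray,
    proposal_sd: np.ndarray,
    cfg: MCMCConfig,
    sampler_seed: int,
    truth: float,
    level: float = 0.95,
) -> dict:
    """One (truth, n, prior) cell: ensemble MH over the replicate axis."""
    cfg_cell = replace(cfg, seed=sampler_seed)
    logpost = target_factory(data)
    draws, acc = rw_metropolis_ensemble(logpost, init, cfg_cell, proposal_sd=proposal_sd)
    post_mean = draws.mean(axis=0)
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
    covered = (lo <= truth) & (truth <= hi)
    sq = (post_mean - truth) ** 2
    return {
        "nrmse": float(np.sqrt(sq.mean()) / truth) if truth != 0 else float("nan"),
        "rmse": float(np.sqrt(sq.mean())),
        "mse": float(sq.mean()),
        "coverage": float(covered.mean()),
        "mean_acceptance": float(acc.mean()),
        "post_means": post_mean,
    }


def run_scale_study(
    sigmas: Sequence[float],
    ns: Sequence[int],
    reps: int,
    priors: Sequence[PriorSpec],
    cfg: MCMCConfig,
    seed: int = 0,
    keep_estimates: bool = False,
) -> StudyResult:
    """Normal-scale grid: data N(0, sigma^2), posterior of sigma per prior."""
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rows = []
    estimates = {}
    for i, sigma in enumerate(sigmas):
        for j, n in enumerate(ns):
            rng = np.random.default_rng(_cell_seed(seed, "scale", i, j))
            data = rng.normal(0.0, sigma, size=(reps, n))
            s2 = np.sum(data * data, axis=1)
            init = np.sqrt(s2 / n)
            prop_sd = init / math.sqrt(2.0 * n) * 2.5
            for p_idx, prior in enumerate(priors):
                sseed = int(
                    _cell_seed(seed, "scale", i, j, p_idx + 1).generate_state(1, np.uint32)[0]
                )

                def factory(_d, _n=n, _s2=s2, _prior=prior):
                    def logpost(sig):
                        sig = np.asarray(sig, dtype=float)
                        safe = np.where(sig > 0, sig, 1.0)
                        with np.errstate(divide="ignore", invalid="ignore"):
                            return np.where(
                                sig > 0,
                                -_n * np.log(safe)
                                - _s2 / (2.0 * safe ** 2)
                                + log_prior(safe, _prior),
                                -np.inf,
                            )

                    return logpost

                cell = _run_cell(data, factory, init, prop_sd, cfg, sseed, sigma)
                est = cell.pop("post_means")
                if keep_estimates:
                    estimates[(prior.kind, sigma, n)] = est
                rows.append(
                    {"study": "scale", "prior": prior.kind, "truth": sigma, "n": n,
                     "reps": reps, **cell}
                )
    result = StudyResult(table=pd.DataFrame(rows), reps=reps, seed=seed, config=cfg)
    if keep_estimates:
        result.estimates = estimates
    return result


def run_location_study(
    mus: Sequence[float],
    ns: Sequence[int],
    reps: int,
    priors: Sequence[PriorSpec],
    cfg: MCMCConfig,
    seed: int = 0,
    keep_estimates: bool = False,
) -> StudyResult:
    """Log-normal-location grid: data LN(mu, 1), posterior of mu per prior."""
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rows = []
    estimates = {}
    for i, mu in enumerate(mus):
        for j, n in enumerate(ns):
            rng = np.random.default_rng(_cell_seed(seed, "location", i, j))
            logdata = rng.normal(mu, 1.0, size=(reps, n))
            s1 = logdata.sum(axis=1)
            s2 = np.sum(logdata * logdata, axis=1)
            init = s1 / n
            prop_sd = np.full(reps, 2.5 / math.sqrt(n))
            for p_idx, prior in enumerate(priors):
                sseed = int(
                    _cell_seed(seed, "location", i, j, p_idx + 1).generate_state(1, np.uint32)[0]
                )

                def factory(_d, _n=n, _s1=s1, _s2=s2, _prior=prior):
                    def logpost(m):
                        m = np.asarray(m, dtype=float)
                        return (
                            -0.5 * (_s2 - 2.0 * m * _s1 + _n * m * m)
                            + log_prior(m, _prior)
                        )

                    return logpost

                cell = _run_cell(logdata, factory, init, prop_sd, cfg, sseed, mu)
                est = cell.pop("post_means")
                if keep_estimates:
                    estimates[(prior.kind, mu, n)] = est
                rows.append(
                    {"study": "location", "prior": prior.kind, "truth": mu, "n": n,
                     "reps": reps, **cell}
                )
    result = StudyResult(table=pd.DataFrame(rows), reps=reps, seed=seed, config=cfg)
    if keep_estimates:
        result.estimates = estimates
    return result


def run_mixture_repeats(
    models: Sequence[MixtureSpec],
    ns: Sequence[int],
    M: int,
    cfg: MCMCConfig,
    seed: int = 0,
    prior_a: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated-sampling study over mixture truths.

    For each (model, n, replicate): simulate, fit by Metropolis-within-
    Gibbs, relabel components by ascending posterior-mean location, and
    record the posterior means of every mu_l and sigma_l.  Returns the
    replicate-level tidy frame and a per-parameter summary (median,
    quartiles, whiskers) of the boxplot kind.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rows = []
    for im, model in enumerate(models):
        k = model.k
        order = np.argsort(model.means)
        for jn, n in enumerate(ns):
            for rep in range(M):
                ss = _cell_seed(seed, "mixture_repeats", im, jn, rep)
                state = ss.generate_state(2, np.uint32)
                data = generate_mixture(model, n, np.random.default_rng(int(state[0])))
                chain = mixture_mwg(data, k, replace(cfg, seed=int(state[1])), prior_a=prior_a)
                chain = relabel_components(chain, k, by="mu_mean")
                means = chain.mean()
                for pos, comp in enumerate(order):
                    rows.append(
                        {"k": k, "n": n, "rep": rep, "component": pos + 1,
                         "param": "mu", "truth": model.means[comp],
                         "post_mean": means[k + pos]}
                    )
                    rows.append(
                        {"k": k, "n": n, "rep": rep, "component": pos + 1,
                         "param": "sigma", "truth": model.sds[comp],
                         "post_mean": means[2 * k + pos]}
                    )
    tidy = pd.DataFrame(rows)

    def box(g: pd.DataFrame) -> pd.Series:
        v = g["post_mean"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        return pd.Series(
            {"median": med, "q1": q1, "q3": q3, "whisker_lo": lo, "whisker_hi": hi,
             "iqr": iqr, "truth": g["truth"].iloc[0]}
        )

    summary = (
        tidy.groupby(["k", "n", "param", "component"])[["post_mean", "truth"]]
        .apply(box)
        .reset_index()
    )
    return tidy, summary


def dic(chain: Chain, loglik: Callable[[np.ndarray, np.ndarray], float], data) -> float:
    """Deviance Information Criterion D-bar + pD, pD = D-bar - D(theta-bar).

    ``theta-bar`` is the vector of per-parameter posterior means; for
    mixtures the chain should be relabeled first so the plug-in mean is
    meaningful.
    """
    y = np.asarray(data, dtype=float)
    devs = np.array([-2.0 * loglik(row, y) for row in chain.draws])
    if not np.all(np.isfinite(devs)):
        bad = int(np.argmax(~np.isfinite(devs)))
        raise ValueError(f"non-finite log-likelihood at retained draw {bad}")
    d_bar = float(devs.mean())
    d_hat = -2.0 * loglik(chain.mean(), y)
    if not math.isfinite(d_hat):
        raise ValueError("non-finite log-likelihood at the posterior mean")
    p_d = d_bar - d_hat
    return d_bar + p_d


def run_dic_scan(
    data: Sequence[float],
    ks: Sequence[int],
    cfg: MCMCConfig,
    seed: int = 0,
    prior_a: float = 1.0,
) -> pd.DataFrame:
    """Fit the mixture for each k and tabulate DIC; flags the argmin."""
    y = np.asarray(data, dtype=float)
    if y.size <= max(ks):
        raise ValueError("data length must exceed max(ks)")
    rows = []
    for k in ks:
        sseed = int(_cell_seed(seed, "dic", k).generate_state(1, np.uint32)[0])
        chain = mixture_mwg(y, k, replace(cfg, seed=sseed), prior_a=prior_a)
        chain = relabel_components(chain, k, by="weight_desc")
        rows.append(
            {"k": k, "dic": dic(chain, lambda p, d, _k=k: mixture_log_likelihood(p, d, _k), y)}
        )
    out = pd.DataFrame(rows)
    out["best"] = out["dic"] == out["dic"].min()
    return out
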