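"""Posterior sampling and convergence diagnostics for the hierarchical model.

All group parameters and person effects are sampled jointly by a
Metropolis-within-Gibbs scheme built for this likelihood:

* Given the caution side, the accretion side is a linear-Gaussian hierarchy
  (``theta_n * u_n - v_n ~ Normal(0, 1)`` with ``u = y`` or ``1/y`` depending
  on the likelihood form), so person accretion rates, condition deviations
  ``delta_v`` and regression weights ``beta_v`` are drawn from their *exact*
  full conditionals.
* Caution-side blocks (person thresholds, ``delta_theta``) and the
  random-effect scales are updated by univariate stepping-out slice sampling
  (Neal 2003), which is rejection-free and needs no step-size tuning.

Every conditional is evaluated through per-(person x condition-cell)
sufficient statistics (trial count, sum and sum of squares of ``u``), so the
cost of one sweep is independent of the number of trials.  The trial-level
rate realisations ``z`` are marginalised analytically and never sampled.

Convergence is monitored with the split-chain Gelman-Rubin statistic
(each chain halved, between/within variance ratio), the classic variant
rather than the rank-normalised one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelConfig
from .preprocess import PreparedDataset

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "ParameterSummary",
    "sample_posterior",
    "sample_accretion_fixed_caution",
    "rhat",
    "summarize",
    "summary_table",
    "slice_sample",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class SamplerConfig:
    """MCMC run settings.

    Defaults mirror a standard desk run of this model: six chains of 2,000
    iterations each with the first 1,000 discarded as burn-in, leaving 6,000
    retained draws.  At least two chains are required for the Gelman-Rubin
    diagnostic.
    """

    n_chains: int = 6
    n_iterations: int = 2000
    n_burnin: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("n_burnin must satisfy 0 <= n_burnin < n_iterations")


@dataclass
class ParameterSummary:
    """Marginal posterior summary: mean, SD, central 95% interval, R-hat."""

    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    rhat: float


@dataclass
class PosteriorDraws:
    """Retained posterior samples indexed (chain, iteration, parameter)."""

    samples: np.ndarray
    names: list
    config: SamplerConfig
    model_config: ModelConfig
    person_ids: list
    covariate_names: list

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_retained(self) -> int:
        return self.samples.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter as a (chains, iterations) array."""
        if name not in self._index:
            raise KeyError(
                f"unknown parameter {name!r}; available: {', '.join(self.names)}"
            )
        return self.samples[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        """Draws for one parameter pooled across chains (1-D)."""
        return self.get(name).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (chain, iteration, parameter, value)."""
        C, T, _ = self.samples.shape
        chains = np.repeat(np.arange(C), T * len(self.names))
        iters = np.tile(np.repeat(np.arange(T), len(self.names)), C)
        params = np.tile(np.array(self.names, dtype=object), C * T)
        return pd.DataFrame(
            {
                "chain": chains,
                "iteration": iters,
                "parameter": params,
                "value": self.samples.reshape(-1),
            }
        )


# ---------------------------------------------------------------------------
# slice sampler


def slice_sample(x0, logp, rng, width=1.0, max_steps=100):
    """One univariate stepping-out + shrinkage slice-sampling update.

    ``logp`` may return ``-inf`` outside the support; ``x0`` must have finite
    log-density.
    """
    f0 = logp(x0)
    if not np.isfinite(f0):
        raise ValueError("slice_sample requires a starting point with finite logp")
    level = f0 - rng.exponential()
    u = rng.uniform(0.0, width)
    left, right = x0 - u, x0 + u
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logp(left) > level:
        left -= width
        j -= 1
    while k > 0 and logp(right) > level:
        right += width
        k -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logp(x1) > level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


# ---------------------------------------------------------------------------
# sufficient statistics

_N_CELLS = 4


def _suffstats(prepared: PreparedDataset, form: str):
    """Per-(person, cell) trial count and first two moments of u.

    u = rt for the direct form, 1/rt for the reciprocal form; either way the
    likelihood kernel is theta_n*u_n - v_n ~ N(0,1), so (N, sum u, sum u^2)
    per person/cell carry all the information the conditionals need.
    """
    u = prepared.rt if form == "direct" else 1.0 / prepared.rt
    flat = prepared.person_idx * _N_CELLS + prepared.cond_idx
    size = prepared.n_persons * _N_CELLS
    N = np.bincount(flat, minlength=size).reshape(-1, _N_CELLS).astype(float)
    S1 = np.bincount(flat, weights=u, minlength=size).reshape(-1, _N_CELLS)
    S2 = np.bincount(flat, weights=u * u, minlength=size).reshape(-1, _N_CELLS)
    return N, S1, S2


def _data_log_density_suffstats(N, S1, S2, v, th, delta_v, delta_theta,
                                form: str, rt=None) -> float:
    """Data log-density computed from sufficient statistics.

    Equals the sum of trial log-densities; used to verify the sampler's view
    of the likelihood against the direct per-trial evaluation.
    """
    dvt = np.concatenate([[0.0], np.asarray(delta_v, float)])
    dtht = np.concatenate([[0.0], np.asarray(delta_theta, float)])
    th_pc = th[:, None] + dtht[None, :]
    v_pc = v[:, None] + dvt[None, :]
    present = N > 0
    if np.any(th_pc[present] <= 0):
        return -np.inf
    log_th = np.where(present, np.log(np.where(th_pc > 0, th_pc, 1.0)), 0.0)
    total = float(
        np.sum(
            N * log_th
            - 0.5 * (th_pc**2 * S2 - 2.0 * th_pc * v_pc * S1 + N * v_pc**2)
        )
    )
    total -= N.sum() * _LOG_SQRT_2PI
    if form == "reciprocal":
        if rt is None:
            raise ValueError("reciprocal form needs rt for the Jacobian term")
        total -= 2.0 * float(np.sum(np.log(rt)))
    return total


# ---------------------------------------------------------------------------
# Gibbs sweep


class _ChainState:
    __slots__ = ("v", "th", "dv", "dth", "bv", "bth", "sv", "sth", "rho")

    def __init__(self, v, th, dv, dth, bv, bth, sv, sth, rho=0.0):
        self.v, self.th = v, th
        self.dv, self.dth = dv, dth
        self.bv, self.bth = bv, bth
        self.sv, self.sth = sv, sth
        self.rho = rho


def _init_state(N, S1, S2, X, cfg: ModelConfig, rng) -> _ChainState:
    """Moment-based starting values, jittered per chain.

    For either form, u has mean v/theta and SD 1/theta per cell, so
    theta ~= 1/sd(u) and v ~= mean(u)*theta person by person.  Starting from
    prior means is not possible here: a zero caution intercept lies outside
    the likelihood support.
    """
    n_p = N.sum(axis=1)
    mean_u = S1.sum(axis=1) / np.maximum(n_p, 1.0)
    var_u = S2.sum(axis=1) / np.maximum(n_p, 1.0) - mean_u**2
    sd_u = np.sqrt(np.clip(var_u, 1e-6, None))
    th = np.clip(1.0 / sd_u, 0.3, 30.0) * np.exp(rng.normal(0.0, 0.05, size=len(n_p)))
    v = mean_u * th + rng.normal(0.0, 0.05, size=len(n_p))
    dv = rng.normal(0.0, 0.01, size=3)
    dth = rng.normal(0.0, 0.01, size=3)
    bv, *_ = np.linalg.lstsq(X, v, rcond=None)
    bth, *_ = np.linalg.lstsq(X, th, rcond=None)
    sv = max(float(np.std(v - X @ bv)), 0.05) * np.exp(rng.normal(0.0, 0.1))
    sth = max(float(np.std(th - X @ bth)), 0.05) * np.exp(rng.normal(0.0, 0.1))
    return _ChainState(v, th, dv, dth, bv, bth, sv, sth)


def _draw_mvn_coefficients(X, target, noise_var, loc, scale, rng):
    """Conjugate draw of regression weights: target ~ N(X b, noise_var)."""
    K1 = X.shape[1]
    prec = X.T @ X / noise_var + np.eye(K1) / scale**2
    lin = X.T @ target / noise_var + loc / scale**2
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin)
    z = rng.standard_normal(K1)
    return mean + np.linalg.solve(chol.T, z)


def _sweep(state: _ChainState, N, S1, S2, X, cfg: ModelConfig, rng,
           present, rt_jacobian=0.0):
    """One full Gibbs sweep over all parameter blocks, in place."""
    P = X.shape[0]
    dvt = np.concatenate([[0.0], state.dv])
    dtht = np.concatenate([[0.0], state.dth])
    mu_v = X @ state.bv
    mu_th = X @ state.bth
    corr = cfg.correlated_effects
    rho = state.rho if corr else 0.0

    # ---- accretion side: exact conjugate draws -------------------------
    th_pc = state.th[:, None] + dtht[None, :]
    n_p = N.sum(axis=1)
    if corr and rho != 0.0:
        cond_mu_v = mu_v + rho * (state.sv / state.sth) * (state.th - mu_th)
        cond_var_v = state.sv**2 * (1.0 - rho**2)
    else:
        cond_mu_v, cond_var_v = mu_v, state.sv**2
    lin = (th_pc * S1).sum(axis=1) - N @ dvt
    post_prec = n_p + 1.0 / cond_var_v
    post_mean = (lin + cond_mu_v / cond_var_v) / post_prec
    state.v = post_mean + rng.standard_normal(P) / np.sqrt(post_prec)

    for c in range(1, _N_CELLS):  # the three deviation cells are disjoint
        Nc = N[:, c].sum()
        lin_c = float((th_pc[:, c] * S1[:, c] - N[:, c] * state.v).sum())
        prec_c = Nc + 1.0 / cfg.delta_scale**2
        mean_c = (lin_c + cfg.delta_loc / cfg.delta_scale**2) / prec_c
        state.dv[c - 1] = mean_c + rng.standard_normal() / np.sqrt(prec_c)
    dvt = np.concatenate([[0.0], state.dv])

    target_v = state.v
    noise_var_v = state.sv**2
    if corr and rho != 0.0:
        target_v = state.v - rho * (state.sv / state.sth) * (state.th - mu_th)
        noise_var_v = state.sv**2 * (1.0 - rho**2)
    state.bv = _draw_mvn_coefficients(
        X, target_v, noise_var_v, cfg.beta_loc, cfg.beta_scale, rng
    )
    mu_v = X @ state.bv

    # ---- random-effect scales (and optional correlation): slice --------
    ev = state.v - mu_v
    eth = state.th - mu_th

    if corr:
        def biv_logp(sv, sth, r):
            if sv <= 0 or sth <= 0 or not -0.999 < r < 0.999:
                return -np.inf
            det = 1.0 - r * r
            quad = ((ev / sv) ** 2 - 2 * r * (ev / sv) * (eth / sth)
                    + (eth / sth) ** 2) / det
            return (
                -0.5 * float(quad.sum())
                - P * (np.log(sv) + np.log(sth) + 0.5 * np.log(det))
                - 0.5 * (sv / cfg.sigma_scale) ** 2
                - 0.5 * (sth / cfg.sigma_scale) ** 2
            )

        state.sv = slice_sample(
            state.sv, lambda s: biv_logp(s, state.sth, rho), rng, width=0.25
        )
        state.sth = slice_sample(
            state.sth, lambda s: biv_logp(state.sv, s, rho), rng, width=0.25
        )
        state.rho = slice_sample(
            rho, lambda r: biv_logp(state.sv, state.sth, r), rng, width=0.25
        )
    else:
        ss_v = float((ev * ev).sum())

        def logp_sv(s):
            if s <= 0:
                return -np.inf
            return -P * np.log(s) - ss_v / (2 * s * s) - 0.5 * (s / cfg.sigma_scale) ** 2

        state.sv = slice_sample(state.sv, logp_sv, rng, width=0.25)

    # ---- caution side: slice updates -----------------------------------
    rho = state.rho if corr else 0.0
    if corr and rho != 0.0:
        cond_mu_th = mu_th + rho * (state.sth / state.sv) * (state.v - mu_v)
        cond_sd_th = state.sth * np.sqrt(1.0 - rho**2)
    else:
        cond_mu_th, cond_sd_th = mu_th, np.full(P, state.sth)
        cond_sd_th = np.broadcast_to(cond_sd_th, (P,))

    dtht = np.concatenate([[0.0], state.dth])
    v_pc = state.v[:, None] + dvt[None, :]
    for p in range(P):
        pres = present[p]
        Np, S1p, S2p, vp = N[p], S1[p], S2[p], v_pc[p]
        m_p, sd_p = float(np.asarray(cond_mu_th)[p]), float(np.asarray(cond_sd_th)[p])

        def logp_th(t):
            tc = t + dtht
            if np.any(tc[pres] <= 0):
                return -np.inf
            log_tc = np.where(pres, np.log(np.where(tc > 0, tc, 1.0)), 0.0)
            ll = float(
                np.sum(Np * log_tc - 0.5 * tc**2 * S2p + tc * vp * S1p)
            )
            return ll - 0.5 * ((t - m_p) / sd_p) ** 2

        state.th[p] = slice_sample(state.th[p], logp_th, rng, width=0.5)

    for c in range(1, _N_CELLS):
        mask = present[:, c]
        if not mask.any():
            continue
        th_m = state.th[mask]
        N_m, S1_m, S2_m = N[mask, c], S1[mask, c], S2[mask, c]
        v_m = state.v[mask] + dvt[c]

        def logp_dth(d):
            tc = th_m + d
            if np.any(tc <= 0):
                return -np.inf
            ll = float(
                np.sum(N_m * np.log(tc) - 0.5 * tc**2 * S2_m + tc * v_m * S1_m)
            )
            return ll - 0.5 * ((d - cfg.delta_loc) / cfg.delta_scale) ** 2

        state.dth[c - 1] = slice_sample(state.dth[c - 1], logp_dth, rng, width=0.1)

    target_th = state.th
    noise_var_th = state.sth**2
    if corr and rho != 0.0:
        target_th = state.th - rho * (state.sth / state.sv) * (state.v - mu_v)
        noise_var_th = state.sth**2 * (1.0 - rho**2)
    state.bth = _draw_mvn_coefficients(
        X, target_th, noise_var_th, cfg.beta_loc, cfg.beta_scale, rng
    )
    mu_th = X @ state.bth

    if not corr:
        eth = state.th - mu_th
        ss_th = float((eth * eth).sum())

        def logp_sth(s):
            if s <= 0:
                return -np.inf
            return (
                -P * np.log(s) - ss_th / (2 * s * s) - 0.5 * (s / cfg.sigma_scale) ** 2
            )

        state.sth = slice_sample(state.sth, logp_sth, rng, width=0.25)


def _parameter_names(covariate_names, person_ids, correlated):
    names = [f"beta_v[{c}]" for c in covariate_names]
    names += [f"beta_theta[{c}]" for c in covariate_names]
    names += ["sigma_v", "sigma_theta"]
    names += [f"delta_v[{c}]" for c in (1, 2, 3)]
    names += [f"delta_theta[{c}]" for c in (1, 2, 3)]
    names += [f"v[{p}]" for p in person_ids]
    names += [f"theta[{p}]" for p in person_ids]
    if correlated:
        names.append("rho")
    return names


def _pack(state: _ChainState, correlated: bool) -> np.ndarray:
    parts = [state.bv, state.bth, [state.sv, state.sth], state.dv, state.dth,
             state.v, state.th]
    if correlated:
        parts.append([state.rho])
    return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


def sample_posterior(
    prepared: PreparedDataset,
    model_config: ModelConfig | None = None,
    sampler_config: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Draw posterior samples of all group parameters and person effects.

    Chains run sequentially; the seed in ``sampler_config`` drives both the
    per-chain initial jitter and the sampling noise, so identical settings
    reproduce identical draws.
    """
    cfg = model_config or ModelConfig()
    scfg = sampler_config or SamplerConfig()
    if prepared.n_trials == 0:
        raise ValueError("cannot sample from an empty dataset")
    if prepared.n_persons < 2:
        raise ValueError(
            "need at least 2 persons to identify group-level variances; "
            "see sample_accretion_fixed_caution for single-person reductions"
        )

    N, S1, S2 = _suffstats(prepared, cfg.form)
    present = N > 0
    X = prepared.X
    names = _parameter_names(
        prepared.covariate_names, prepared.person_ids, cfg.correlated_effects
    )
    n_keep = scfg.n_iterations - scfg.n_burnin
    out = np.empty((scfg.n_chains, n_keep, len(names)))

    seed_seq = np.random.SeedSequence(scfg.seed)
    child_seqs = seed_seq.spawn(scfg.n_chains)
    for c, sub in enumerate(child_seqs):
        rng = np.random.default_rng(sub)
        state = _init_state(N, S1, S2, X, cfg, rng)
        if not np.all(np.isfinite(_pack(state, cfg.correlated_effects))):
            raise RuntimeError(
                "chain initialization failed: non-finite starting values in the "
                "person-effect block"
            )
        for it in range(scfg.n_iterations):
            _sweep(state, N, S1, S2, X, cfg, rng, present)
            if it >= scfg.n_burnin:
                out[c, it - scfg.n_burnin] = _pack(state, cfg.correlated_effects)
        if not np.all(np.isfinite(out[c])):
            bad = [names[i] for i in np.unique(np.argwhere(~np.isfinite(out[c]))[:, 1])]
            raise RuntimeError(f"sampler produced non-finite draws for: {bad}")

    return PosteriorDraws(
        samples=out,
        names=names,
        config=scfg,
        model_config=cfg,
        person_ids=list(prepared.person_ids),
        covariate_names=list(prepared.covariate_names),
    )


def sample_accretion_fixed_caution(
    rt,
    theta: float,
    prior_mean: float,
    prior_sd: float,
    n_draws: int = 20000,
    seed: int | None = None,
    form: str = "direct",
) -> np.ndarray:
    """MCMC draws of a single person's accretion rate with caution fixed.

    Slice-samples the exact posterior of ``v`` given trials ``rt`` and a
    Normal(prior_mean, prior_sd**2) prior.  With ``theta`` fixed this model is
    conjugate, so the output can be checked against the closed-form Gaussian
    posterior (mean ``(sum(theta*u) + m0/s0^2) / (n + 1/s0^2)``, variance
    ``1/(n + 1/s0^2)``) — a direct oracle for the sampling machinery.
    """
    rt = np.asarray(rt, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("latencies must be positive")
    if theta <= 0:
        raise ValueError("caution must be positive")
    u = rt if form == "direct" else 1.0 / rt
    w = theta * u
    sw = float(w.sum())
    n = float(w.size)

    def logp(v):
        return (
            v * sw - 0.5 * n * v * v - 0.5 * ((v - prior_mean) / prior_sd) ** 2
        )

    rng = np.random.default_rng(seed)
    v = sw / max(n, 1.0)
    draws = np.empty(n_draws)
    for i in range(n_draws):
        v = slice_sample(v, logp, rng, width=1.0)
        draws[i] = v
    return draws


# ---------------------------------------------------------------------------
# diagnostics and summaries


def rhat(chains) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is halved, then R-hat = sqrt(((n-1)/n * W + B/n) / W) with W
    the mean within-half variance and B/n the variance of the half means.
    Returns NaN (with a warning) when all halves have zero variance.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    m, n = arr.shape
    if m < 2 or n < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    half = n // 2
    split = np.concatenate([arr[:, :half], arr[:, n - half :]], axis=0)
    W = float(split.var(axis=1, ddof=1).mean())
    if W == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined", stacklevel=2)
        return float("nan")
    b_over_n = float(split.mean(axis=1).var(ddof=1))
    var_plus = (half - 1) / half * W + b_over_n
    return float(np.sqrt(var_plus / W))


def summarize(draws: PosteriorDraws, parameter: str) -> ParameterSummary:
    """Posterior mean, SD, central 95% interval and R-hat for one parameter."""
    chains = draws.get(parameter)
    pooled = chains.reshape(-1)
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    if pooled.std(ddof=0) == 0.0 or chains.shape[1] < 4:
        r = float("nan")  # constant or too short to diagnose
    else:
        r = rhat(chains)
    return ParameterSummary(
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        ci_lower=float(lo),
        ci_upper=float(hi),
        rhat=r,
    )


def summary_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Summaries for every sampled parameter, one row each.

    Columns mirror the usual reporting layout: posterior mean, posterior SD,
    95% credible interval bounds, and R-hat (4 decimals is the reporting
    precision; the value itself is unrounded).
    """
    rows = []
    for name in draws.names:
        s = summarize(draws, name)
        rows.append((name, s.mean, s.sd, s.ci_lower, s.ci_upper, s.rhat))
    return pd.DataFrame(
        rows,
        columns=["parameter", "mean", "sd", "ci_2.5", "ci_97.5", "rhat"],
    ).set_index("parameter")
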