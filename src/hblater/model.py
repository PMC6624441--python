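"""Core probability model for the hierarchical LATER reaction-time process.

The LATER (Linear Approach to Threshold with Ergodic Rate) model describes a
single go-decision as a signal that rises linearly from a starting point at a
trial-random rate until it crosses a threshold, at which point the response is
emitted.  Two latent quantities characterise each person:

* **accretion** ``v`` — the mean rate of information accumulation; on trial
  ``i`` the realised rate is ``z_i ~ Normal(v, 1)``;
* **caution** ``theta`` — the threshold amount of accumulated information
  required before responding (``theta > 0``).

Under the *direct* likelihood form the latency itself is Gaussian,

    y = z / theta  ~  Normal(v / theta, 1 / theta**2),

so a person with accretion 1 and caution 4 responds in 250 ms on average.
Under the *reciprocal* (classic recinormal) form the reciprocal latency is
Gaussian instead, ``1/y ~ Normal(v/theta, 1/theta**2)``, and latency densities
carry the change-of-variables Jacobian.  Both forms are first-class; they are
linked by ``u = y`` (direct) versus ``u = 1/y`` (reciprocal) feeding the same
Gaussian kernel ``theta * u - v ~ Normal(0, 1)``.

The hierarchy places each person's ``(v_p, theta_p)`` around covariate-driven
group means, ``v_p = x_p @ beta_v + eps``, and lets dummy-coded experimental
conditions shift both parameters additively on each trial:
``v_n = v_p + g_n @ delta_v`` and ``theta_n = theta_p + g_n @ delta_theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SESSIONS",
    "TRIAL_TYPES",
    "GroupParameters",
    "PersonEffects",
    "ModelConfig",
    "compose_trial_accretion",
    "compose_trial_caution",
    "expected_latency",
    "trial_log_density",
    "person_level_mean",
    "joint_log_posterior",
]

#: Session levels: smoking as usual vs. >=12 h verified abstinence.
SESSIONS = ("smoke_as_usual", "abstinent")
#: Trial types of the incentivised Go/No-Go runs modelled here.
TRIAL_TYPES = ("neutral", "reward")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class PersonEffects:
    """Latent person-specific parameters for a set of persons.

    Attributes
    ----------
    v : ndarray, shape (n_persons,)
        Accretion rates (mean information-accumulation rate per person).
    theta : ndarray, shape (n_persons,)
        Caution thresholds; strictly positive.
    """

    v: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.v.shape != self.theta.shape:
            raise ValueError("v and theta must have the same shape")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("accretion rates must be finite")
        if np.any(self.theta <= 0):
            raise ValueError("caution thresholds must be strictly positive")

    @property
    def n_persons(self) -> int:
        return self.v.shape[0]


@dataclass
class GroupParameters:
    """Group-level estimands of the hierarchical model.

    ``beta_v`` / ``beta_theta`` are regression weights of the person-level
    covariates (first element = intercept) on accretion / caution;
    ``sigma_v`` / ``sigma_theta`` are the residual random-effect SDs; and
    ``delta_v`` / ``delta_theta`` are the three dummy-coded condition
    deviations from the smoke-as-usual/neutral baseline, ordered
    (neutral–abstinent, reward–smoke-as-usual, reward–abstinent).
    """

    beta_v: np.ndarray
    beta_theta: np.ndarray
    sigma_v: float
    sigma_theta: float
    delta_v: np.ndarray
    delta_theta: np.ndarray
    rho: float = 0.0  # correlation between accretion and caution residuals

    def __post_init__(self) -> None:
        self.beta_v = np.atleast_1d(np.asarray(self.beta_v, dtype=float))
        self.beta_theta = np.atleast_1d(np.asarray(self.beta_theta, dtype=float))
        self.delta_v = np.atleast_1d(np.asarray(self.delta_v, dtype=float))
        self.delta_theta = np.atleast_1d(np.asarray(self.delta_theta, dtype=float))
        if self.beta_v.shape != self.beta_theta.shape:
            raise ValueError("beta_v and beta_theta must have equal length")
        if self.delta_v.shape != (3,) or self.delta_theta.shape != (3,):
            raise ValueError("delta vectors must have length 3")
        # zero is allowed for degenerate (no-heterogeneity) simulation
        if self.sigma_v < 0 or self.sigma_theta < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")


@dataclass
class ModelConfig:
    """Likelihood form and prior specification.

    Priors are weakly informative by default: Normal(0, beta_scale**2) on every
    regression weight and condition deviation, half-Normal(0, sigma_scale**2)
    on both random-effect SDs.  ``correlated_effects`` switches on a bivariate
    normal for the (accretion, caution) residual pair with a Uniform(-1, 1)
    prior on the correlation; off by default, matching the separate residual
    terms of the model statement.
    """

    form: str = "direct"
    beta_loc: float = 0.0
    beta_scale: float = 10.0
    delta_loc: float = 0.0
    delta_scale: float = 10.0
    sigma_scale: float = 5.0
    correlated_effects: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("direct", "reciprocal"):
            raise ValueError(
                f"unknown likelihood form {self.form!r}; use 'direct' or 'reciprocal'"
            )
        if min(self.beta_scale, self.delta_scale, self.sigma_scale) <= 0:
            raise ValueError("prior scales must be positive")


def compose_trial_accretion(v_p, g, delta_v):
    """Trial-level accretion ``v_n = v_p + g @ delta_v``.

    ``g`` is the length-3 condition-indicator vector (all zeros at baseline,
    at most one element set); broadcasting over arrays of trials is allowed.
    """
    g = np.asarray(g, dtype=float)
    delta_v = np.asarray(delta_v, dtype=float)
    return np.asarray(v_p, dtype=float) + g @ delta_v


def compose_trial_caution(theta_p, g, delta_theta):
    """Trial-level caution ``theta_n = theta_p + g @ delta_theta``.

    The additive composition can leave ``theta_n <= 0`` for extreme parameter
    values; callers (the likelihood, the simulator) are responsible for
    rejecting that region.
    """
    g = np.asarray(g, dtype=float)
    delta_theta = np.asarray(delta_theta, dtype=float)
    return np.asarray(theta_p, dtype=float) + g @ delta_theta


def expected_latency(v, theta, form: str = "direct"):
    """Mean latency (seconds) implied by accretion ``v`` and caution ``theta``.

    form="direct" returns ``v / theta``, the mean of the Gaussian latency
    distribution; form="reciprocal" returns ``theta / v``, the latency at the
    mean accumulation rate.  Both give 0.25 s for (v=1, theta=4).
    """
    v = np.asarray(v, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("caution threshold must be strictly positive")
    if form == "direct":
        return v / theta
    if form == "reciprocal":
        if np.any(v == 0):
            raise ValueError("accretion must be nonzero for the reciprocal form")
        return theta / v
    raise ValueError(f"unknown likelihood form {form!r}")


def trial_log_density(y, v, theta, form: str = "direct"):
    """Log-density of a single latency ``y`` (seconds) given trial parameters.

    direct:      y ~ Normal(v/theta, 1/theta**2)
                 log f = log(theta) - (theta*y - v)**2 / 2 - log(sqrt(2*pi))
    reciprocal:  1/y ~ Normal(v/theta, 1/theta**2), so the density of y itself
                 includes the Jacobian |d(1/y)/dy| = 1/y**2:
                 log f = log(theta) - (theta/y - v)**2 / 2 - log(sqrt(2*pi))
                         - 2*log(y)

    Non-positive ``theta`` yields ``-inf`` (excluded parameter region, soft
    rejection for samplers); non-positive ``y`` is a data error and raises.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(y <= 0):
        raise ValueError("latencies must be strictly positive")
    u = y if form == "direct" else 1.0 / y
    if form not in ("direct", "reciprocal"):
        raise ValueError(f"unknown likelihood form {form!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            theta > 0,
            np.log(np.where(theta > 0, theta, 1.0))
            - 0.5 * (theta * u - v) ** 2
            - _LOG_SQRT_2PI,
            -np.inf,
        )
    if form == "reciprocal":
        out = out - 2.0 * np.log(y)
    if out.ndim == 0:
        return float(out)
    return out


def person_level_mean(x, beta):
    """Group-level mean ``x @ beta`` of a person's accretion or caution."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape[-1] != beta.shape[-1]:
        raise ValueError(
            f"covariate vector length {x.shape[-1]} does not match "
            f"coefficient length {beta.shape[-1]}"
        )
    return x @ beta


def _halfnormal_logpdf(s, scale):
    if s <= 0:
        return -np.inf
    return (
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (s / scale) ** 2
    )


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -0.5 * z**2 - np.log(scale) - _LOG_SQRT_2PI


def joint_log_posterior(data, group: GroupParameters, effects: PersonEffects,
                        config: ModelConfig | None = None,
                        include_priors: bool = True) -> float:
    """Unnormalised joint log-posterior of the hierarchical LATER model.

    Sums (a) the trial log-densities with trial parameters composed from the
    person effects and condition indicators, (b) the person-effect densities
    around their covariate-predicted group means, and (c) the prior densities
    from ``config`` (dropped when ``include_priors=False``).

    ``data`` is a :class:`~hblater.preprocess.PreparedDataset` (duck-typed: it
    needs ``rt``, ``person_idx``, ``G`` and ``X``).  Any trial-level caution
    ``theta_n <= 0`` returns ``-inf`` instead of raising, so samplers can use
    this as a soft rejection.
    """
    config = config or ModelConfig()
    rt = np.asarray(data.rt, dtype=float)
    pidx = np.asarray(data.person_idx)
    G = np.asarray(data.G, dtype=float)
    X = np.asarray(data.X, dtype=float)

    if effects.n_persons != X.shape[0]:
        raise ValueError("effects and covariate matrix disagree on person count")

    v_n = compose_trial_accretion(effects.v[pidx], G, group.delta_v)
    th_n = compose_trial_caution(effects.theta[pidx], G, group.delta_theta)
    if rt.size and np.any(th_n <= 0):
        return -np.inf
    total = 0.0
    if rt.size:
        total += float(np.sum(trial_log_density(rt, v_n, th_n, config.form)))

    mu_v = X @ group.beta_v
    mu_th = X @ group.beta_theta
    ev = effects.v - mu_v
    eth = effects.theta - mu_th
    if config.correlated_effects and group.rho != 0.0:
        rho, sv, sth = group.rho, group.sigma_v, group.sigma_theta
        det = 1.0 - rho**2
        quad = (
            (ev / sv) ** 2 - 2 * rho * (ev / sv) * (eth / sth) + (eth / sth) ** 2
        ) / det
        total += float(
            np.sum(-0.5 * quad)
            - effects.n_persons
            * (np.log(sv) + np.log(sth) + 0.5 * np.log(det) + 2 * _LOG_SQRT_2PI)
        )
    else:
        total += float(np.sum(_normal_logpdf(ev, 0.0, group.sigma_v)))
        total += float(np.sum(_normal_logpdf(eth, 0.0, group.sigma_theta)))

    if include_priors:
        total += float(
            np.sum(_normal_logpdf(group.beta_v, config.beta_loc, config.beta_scale))
        )
        total += float(
            np.sum(_normal_logpdf(group.beta_theta, config.beta_loc, config.beta_scale))
        )
        total += float(
            np.sum(_normal_logpdf(group.delta_v, config.delta_loc, config.delta_scale))
        )
        total += float(
            np.sum(
                _normal_logpdf(group.delta_theta, config.delta_loc, config.delta_scale)
            )
        )
        total += _halfnormal_logpdf(group.sigma_v, config.sigma_scale)
        total += _halfnormal_logpdf(group.sigma_theta, config.sigma_scale)
        # rho prior is Uniform(-1, 1): constant, omitted.
    return total
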