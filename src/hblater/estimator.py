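"""Scikit-learn style estimator wrapping preprocessing and posterior sampling."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .inference import PosteriorDraws, SamplerConfig, sample_posterior, summary_table
from .model import ModelConfig, trial_log_density
from .ppc import PPCResult, generate_replicates
from .preprocess import PreparedDataset, prepare_dataset

__all__ = ["HierarchicalLater"]


class HierarchicalLater(BaseEstimator):
    """Hierarchical Bayesian LATER model for go-trial reaction times.

    Fits the rise-to-threshold latency model with person-level accretion and
    caution random effects (regressed on person covariates) and dummy-coded
    session-by-trial-type condition deviations, by MCMC.

    Parameters
    ----------
    form : {"direct", "reciprocal"}
        Likelihood form: latency Gaussian (default) or reciprocal-latency
        Gaussian (classic recinormal) with the transform Jacobian.
    covariates : DataFrame, optional
        ``person_id`` plus numeric covariate columns; standardized internally
        when ``standardize=True``.  Without it the model is intercept-only.
    n_chains, n_iterations, n_burnin
        MCMC run shape (defaults 6 chains x 2,000 iterations, 1,000 burn-in).
    beta_scale, delta_scale, sigma_scale
        Weakly informative prior scales: Normal(0, scale^2) on regression
        weights and condition deviations, half-Normal on random-effect SDs.
    correlated_effects : bool
        Model the accretion/caution residual pair as bivariate normal with an
        estimated correlation (off by default).
    min_rt, max_rt, max_rt_policy, rt_unit
        Preprocessing: premature-response threshold (seconds; below is
        excluded), response-window upper bound, and how to treat rts above it.
    seed : int, optional
        Drives chain initialization and sampling; same seed, same draws.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Retained samples, (chain, iteration, parameter).
    summary_ : DataFrame
        Posterior mean / SD / 95% CrI / R-hat for every parameter.
    prepared_ : PreparedDataset
        The validated, encoded dataset the model was fitted to.
    max_rhat_ : float
        Largest R-hat across parameters (< 1.1 indicates convergence).

    Examples
    --------
    >>> from hblater import HierarchicalLater, make_study_fixture
    >>> prepared, truth = make_study_fixture(seed=7)
    >>> est = HierarchicalLater(n_iterations=400, n_burnin=200, seed=7)
    >>> est.fit(prepared.trials, covariates=None)  # doctest: +SKIP
    """

    def __init__(
        self,
        form: str = "direct",
        covariates: pd.DataFrame | None = None,
        n_chains: int = 6,
        n_iterations: int = 2000,
        n_burnin: int = 1000,
        beta_scale: float = 10.0,
        delta_scale: float = 10.0,
        sigma_scale: float = 5.0,
        correlated_effects: bool = False,
        standardize: bool = True,
        min_rt: float = 0.150,
        max_rt: float = 0.800,
        max_rt_policy: str = "error",
        rt_unit: str = "s",
        seed: int | None = None,
    ):
        self.form = form
        self.covariates = covariates
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.beta_scale = beta_scale
        self.delta_scale = delta_scale
        self.sigma_scale = sigma_scale
        self.correlated_effects = correlated_effects
        self.standardize = standardize
        self.min_rt = min_rt
        self.max_rt = max_rt
        self.max_rt_policy = max_rt_policy
        self.rt_unit = rt_unit
        self.seed = seed

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            form=self.form,
            beta_scale=self.beta_scale,
            delta_scale=self.delta_scale,
            sigma_scale=self.sigma_scale,
            correlated_effects=self.correlated_effects,
        )

    def _sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            n_burnin=self.n_burnin,
            seed=self.seed,
        )

    def fit(self, X, y=None, covariates: pd.DataFrame | None = None):
        """Fit the model to a long-format trial table.

        ``X`` is a DataFrame with columns ``person_id``, ``session``,
        ``trial_type`` and — unless ``y`` is given separately — ``rt``.
        ``covariates`` overrides the constructor-level covariate table.
        """
        X = pd.DataFrame(X).copy()
        if y is not None:
            X["rt"] = np.asarray(y, dtype=float)
        cov = covariates if covariates is not None else self.covariates
        self.prepared_ = prepare_dataset(
            X,
            cov,
            rt_unit=self.rt_unit,
            min_rt=self.min_rt,
            max_rt=self.max_rt,
            max_rt_policy=self.max_rt_policy,
            standardize=self.standardize,
        )
        self.model_config_ = self._model_config()
        self.draws_ = sample_posterior(
            self.prepared_, self.model_config_, self._sampler_config()
        )
        self.summary_ = summary_table(self.draws_)
        self.max_rhat_ = float(np.nanmax(self.summary_["rhat"].to_numpy()))
        self.n_parameters_ = len(self.draws_.names)
        return self

    # ------------------------------------------------------------------
    def _trial_params(self, X: pd.DataFrame):
        """Per-draw composed (v_n, theta_n) arrays for the rows of X."""
        check_is_fitted(self, "draws_")
        from .preprocess import condition_cell_index

        d = self.draws_
        pidx = np.array(
            [d.person_ids.index(p) for p in X["person_id"]], dtype=np.int64
        )
        cells = np.array(
            [
                condition_cell_index(s, t)
                for s, t in zip(X["session"], X["trial_type"])
            ],
            dtype=np.int64,
        )
        from .preprocess import _G_BY_CELL

        G = _G_BY_CELL[cells]
        v_cols = np.stack([d.pooled(f"v[{p}]") for p in d.person_ids], axis=1)
        th_cols = np.stack([d.pooled(f"theta[{p}]") for p in d.person_ids], axis=1)
        dv = np.stack([d.pooled(f"delta_v[{c}]") for c in (1, 2, 3)], axis=1)
        dth = np.stack([d.pooled(f"delta_theta[{c}]") for c in (1, 2, 3)], axis=1)
        v_n = v_cols[:, pidx] + dv @ G.T  # (draws, trials)
        th_n = th_cols[:, pidx] + dth @ G.T
        return v_n, th_n

    def predict(self, X) -> np.ndarray:
        """Posterior-mean expected latency (seconds) for each trial row.

        Averages the per-draw model-implied mean latency — ``v_n/theta_n``
        (direct) or ``theta_n/v_n`` (reciprocal) — over the retained draws.
        """
        X = pd.DataFrame(X)
        v_n, th_n = self._trial_params(X)
        if self.form == "direct":
            return (v_n / th_n).mean(axis=0)
        return (th_n / v_n).mean(axis=0)

    def score(self, X, y=None) -> float:
        """Mean trial log-density at the posterior-mean parameters."""
        X = pd.DataFrame(X).copy()
        if y is not None:
            X["rt"] = np.asarray(y, dtype=float)
        v_n, th_n = self._trial_params(X)
        ll = trial_log_density(
            X["rt"].to_numpy(dtype=float), v_n.mean(axis=0), th_n.mean(axis=0),
            self.form,
        )
        return float(np.mean(ll))

    def posterior_predictive_check(
        self, n_rep: int = 100, seed=None, window: tuple | None = None
    ) -> PPCResult:
        """Run PPCs against the fitted dataset (see :func:`hblater.ppc.generate_replicates`)."""
        check_is_fitted(self, "draws_")
        return generate_replicates(
            self.draws_, self.prepared_, n_rep=n_rep, seed=seed, window=window
        )

    def converged(self, threshold: float = 1.1) -> bool:
        """True when every parameter's split R-hat is below ``threshold``."""
        check_is_fitted(self, "max_rhat_")
        return bool(self.max_rhat_ < threshold)
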