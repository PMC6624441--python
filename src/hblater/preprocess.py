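"""Ingestion, validation and design construction for trial/covariate tables.

Applies the study's exclusion rule (reaction times below 150 ms are premature
responses, not reactions to the stimulus), encodes the 2x2 session-by-trial-type
design into dummy indicators, and standardises person covariates for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SESSIONS, TRIAL_TYPES

__all__ = [
    "CONDITION_CELLS",
    "PreparedDataset",
    "encode_condition",
    "condition_cell_index",
    "filter_min_rt",
    "standardize_covariates",
    "prepare_dataset",
]

# Cell order: baseline first, then the dummy-coded deviations in the order
# (neutral-abstinent, reward-smoke-as-usual, reward-abstinent).
CONDITION_CELLS = (
    ("smoke_as_usual", "neutral"),
    ("abstinent", "neutral"),
    ("smoke_as_usual", "reward"),
    ("abstinent", "reward"),
)

# Row c of this matrix is the indicator vector g for cell c.
_G_BY_CELL = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
    ],
    dtype=float,
)

_CELL_INDEX = {cell: i for i, cell in enumerate(CONDITION_CELLS)}


def condition_cell_index(session: str, trial_type: str) -> int:
    """Index 0..3 of the design cell; 0 is the smoke-as-usual/neutral baseline."""
    key = (session, trial_type)
    if key not in _CELL_INDEX:
        raise ValueError(
            f"unknown condition ({session!r}, {trial_type!r}); "
            f"session must be one of {SESSIONS}, trial_type one of {TRIAL_TYPES}"
        )
    return _CELL_INDEX[key]


def encode_condition(session: str, trial_type: str) -> np.ndarray:
    """Dummy indicator vector g (length 3) for one session/trial-type cell.

    Baseline (smoke_as_usual, neutral) maps to (0,0,0); the three deviations
    are g1=neutral-abstinent, g2=reward-smoke-as-usual, g3=reward-abstinent.
    """
    return _G_BY_CELL[condition_cell_index(session, trial_type)].copy()


def filter_min_rt(trials: pd.DataFrame, threshold: float = 0.150):
    """Drop trials with rt strictly below ``threshold`` seconds.

    Returns ``(retained, n_excluded)``; input order is preserved and retained
    rows are not mutated.  Missing or non-positive rt values are data errors
    and raise with the offending row label.
    """
    rt = trials["rt"]
    bad = rt.isna() | (rt <= 0)
    if bad.any():
        row = trials.index[bad][0]
        raise ValueError(f"non-positive or missing rt at row {row}")
    keep = rt >= threshold
    return trials.loc[keep].copy(), int((~keep).sum())


def standardize_covariates(X: pd.DataFrame):
    """Centre and scale covariate columns to mean 0, sample SD 1 (ddof=1).

    A column named ``intercept`` (or constant-1) is left untouched.  Returns
    ``(X_std, means, scales)``; the transform parameters allow coefficients to
    be mapped back to the raw scale.  Constant columns cannot be scaled and
    raise.
    """
    X_std = X.copy()
    means: dict[str, float] = {}
    scales: dict[str, float] = {}
    for col in X.columns:
        vals = X[col].astype(float)
        if col == "intercept":
            means[col], scales[col] = 0.0, 1.0
            continue
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"covariate column {col!r} is constant; cannot scale")
        means[col] = float(vals.mean())
        scales[col] = float(sd)
        X_std[col] = (vals - means[col]) / scales[col]
    return X_std, means, scales


@dataclass
class PreparedDataset:
    """Fitting-ready view of a trial table plus person covariates.

    Arrays are aligned: ``rt[n]`` belongs to person ``person_ids[person_idx[n]]``
    in design cell ``cond_idx[n]`` with indicator row ``G[n]``.  ``X`` is the
    persons-by-(K+1) covariate matrix with a leading intercept column.
    """

    trials: pd.DataFrame
    rt: np.ndarray
    person_idx: np.ndarray
    cond_idx: np.ndarray
    G: np.ndarray
    X: np.ndarray
    person_ids: list
    covariate_names: list
    exclusion_log: dict = field(default_factory=dict)
    covariate_means: dict | None = None
    covariate_scales: dict | None = None

    @property
    def n_trials(self) -> int:
        return int(self.rt.shape[0])

    @property
    def n_persons(self) -> int:
        return int(self.X.shape[0])


def prepare_dataset(
    trials: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    rt_unit: str = "s",
    min_rt: float = 0.150,
    max_rt: float = 0.800,
    max_rt_policy: str = "error",
    standardize: bool = True,
) -> PreparedDataset:
    """Validate, filter and encode a long-format trial table for fitting.

    Parameters
    ----------
    trials
        Columns ``person_id``, ``session``, ``trial_type``, ``rt``.
    covariates
        Optional table with ``person_id`` plus numeric covariate columns; an
        intercept column is added internally.  Without it the model is
        intercept-only.
    rt_unit
        ``"s"`` or ``"ms"``; milliseconds are converted to seconds.
    min_rt
        Exclusion threshold in seconds; rts strictly below are dropped
        (rt == threshold is retained).
    max_rt, max_rt_policy
        Trials above the response window are impossible under the task design:
        policy ``"error"`` raises, ``"warn"`` drops them with a log entry.
    """
    required = {"person_id", "session", "trial_type", "rt"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials = trials.copy()
    if rt_unit == "ms":
        trials["rt"] = trials["rt"].astype(float) / 1000.0
    elif rt_unit != "s":
        raise ValueError(f"rt_unit must be 's' or 'ms', got {rt_unit!r}")
    trials["rt"] = trials["rt"].astype(float)

    exclusion_log: dict[str, int] = {}
    trials, n_low = filter_min_rt(trials, threshold=min_rt)
    exclusion_log["below_min_rt"] = n_low

    over = trials["rt"] > max_rt
    if over.any():
        if max_rt_policy == "error":
            row = trials.index[over][0]
            raise ValueError(
                f"rt above the {max_rt*1000:.0f}-ms response window at row "
                f"{row!r}; pass max_rt_policy='warn' to drop instead"
            )
        if max_rt_policy != "warn":
            raise ValueError("max_rt_policy must be 'error' or 'warn'")
        import warnings

        warnings.warn(
            f"dropping {int(over.sum())} trial(s) above the response window",
            stacklevel=2,
        )
        trials = trials.loc[~over].copy()
    exclusion_log["above_window"] = int(over.sum())

    cond_idx = np.array(
        [
            condition_cell_index(s, t)
            for s, t in zip(trials["session"], trials["trial_type"])
        ],
        dtype=np.int64,
    )
    G = _G_BY_CELL[cond_idx]

    person_ids = sorted(trials["person_id"].unique())
    if covariates is not None:
        cov = covariates.set_index("person_id")
        missing_p = [p for p in person_ids if p not in cov.index]
        if missing_p:
            raise ValueError(f"persons missing from covariate table: {missing_p}")
        cov = cov.loc[person_ids].astype(float)
        if cov.isna().any().any():
            raise ValueError("covariate table contains missing values")
        means = scales = None
        if standardize:
            cov, means, scales = standardize_covariates(cov)
        X = np.column_stack([np.ones(len(person_ids)), cov.to_numpy()])
        covariate_names = ["intercept"] + list(cov.columns)
    else:
        X = np.ones((len(person_ids), 1))
        covariate_names = ["intercept"]
        means = scales = None

    pmap = {p: i for i, p in enumerate(person_ids)}
    person_idx = trials["person_id"].map(pmap).to_numpy(dtype=np.int64)

    return PreparedDataset(
        trials=trials.reset_index(drop=True),
        rt=trials["rt"].to_numpy(dtype=float),
        person_idx=person_idx,
        cond_idx=cond_idx,
        G=G,
        X=X,
        person_ids=list(person_ids),
        covariate_names=covariate_names,
        exclusion_log=exclusion_log,
        covariate_means=means,
        covariate_scales=scales,
    )
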