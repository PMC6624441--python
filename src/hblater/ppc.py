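"""Posterior predictive checks: replicate datasets and overlay diagnostics.

Replicates are generated under the fitted model — one retained posterior draw
of all person effects and condition deviations per replicate, then new trial
noise with the observed design shape — and compared to the observed data via
summary statistics and smoothed-density overlays at whole-dataset and
per-person level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .inference import PosteriorDraws
from .model import ModelConfig
from .preprocess import PreparedDataset

__all__ = ["PPCResult", "generate_replicates", "ppc_overlay_export", "plot_ppc"]

_DATASET_STATS = ("mean", "sd", "q10", "q25", "median", "q75", "q90")


def _stats_row(rt: np.ndarray) -> dict:
    q10, q25, q50, q75, q90 = np.percentile(rt, [10, 25, 50, 75, 90])
    return {
        "mean": float(rt.mean()),
        "sd": float(rt.std(ddof=1)),
        "q10": float(q10),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "q90": float(q90),
    }


@dataclass
class PPCResult:
    """Replicated datasets plus summary-statistic comparison to observed data."""

    replicate_stats: pd.DataFrame
    observed_stats: pd.Series
    coverage: dict
    replicate_rts: list
    observed_rt: np.ndarray
    person_idx: np.ndarray
    person_ids: list
    n_rep: int
    draw_indices: np.ndarray


def generate_replicates(
    draws: PosteriorDraws,
    data: PreparedDataset,
    n_rep: int = 100,
    seed=None,
    window: tuple | None = None,
) -> PPCResult:
    """Generate ``n_rep`` replicate datasets from the posterior.

    Parameter draws are taken equally spaced across the pooled retained draws
    (deterministic given the fit), so the seed only governs trial-level noise.
    Each replicate reuses the observed design exactly: the same persons, the
    same condition cell, and the same trial count for every observed trial.
    ``window`` optionally redraws replicate latencies into an observable
    interval, mimicking a response window.

    Summary statistics (mean, SD, quantiles of rt, and per-person means) are
    computed per replicate and for the observed data; ``coverage`` flags
    whether each observed statistic falls inside the central 95% interval of
    its replicate distribution.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be at least 2")
    total = draws.n_chains * draws.n_retained
    if n_rep > total:
        raise ValueError(f"n_rep={n_rep} exceeds the {total} retained draws")
    rng = np.random.default_rng(seed)
    idx = np.linspace(0, total - 1, n_rep).round().astype(int)

    pidx = data.person_idx
    G = data.G
    form = draws.model_config.form

    v_cols = np.stack(
        [draws.pooled(f"v[{p}]") for p in draws.person_ids], axis=1
    )  # (total, P)
    th_cols = np.stack([draws.pooled(f"theta[{p}]") for p in draws.person_ids], axis=1)
    dv_cols = np.stack([draws.pooled(f"delta_v[{c}]") for c in (1, 2, 3)], axis=1)
    dth_cols = np.stack([draws.pooled(f"delta_theta[{c}]") for c in (1, 2, 3)], axis=1)

    rep_rows = []
    rep_rts = []
    for r, d in enumerate(idx):
        v_n = v_cols[d][pidx] + G @ dv_cols[d]
        th_n = th_cols[d][pidx] + G @ dth_cols[d]
        if np.any(th_n <= 0):
            raise RuntimeError(
                "posterior draw implies non-positive trial caution; cannot replicate"
            )
        y = _draw_latencies(v_n, th_n, form, rng)
        if window is not None:
            lo, hi = window
            bad = (y < lo) | (y > hi) | ~np.isfinite(y)
            guard = 0
            while bad.any():
                guard += 1
                if guard > 1000:
                    raise RuntimeError("replicate window redraw did not terminate")
                y[bad] = _draw_latencies(v_n[bad], th_n[bad], form, rng)
                bad = (y < lo) | (y > hi) | ~np.isfinite(y)
        row = _stats_row(y)
        for i, p in enumerate(data.person_ids):
            row[f"person_mean[{p}]"] = float(y[pidx == i].mean())
        rep_rows.append(row)
        rep_rts.append(y)

    replicate_stats = pd.DataFrame(rep_rows)
    obs_row = _stats_row(data.rt)
    for i, p in enumerate(data.person_ids):
        obs_row[f"person_mean[{p}]"] = float(data.rt[pidx == i].mean())
    observed_stats = pd.Series(obs_row)

    coverage = {}
    for stat in replicate_stats.columns:
        lo, hi = np.percentile(replicate_stats[stat], [2.5, 97.5])
        coverage[stat] = bool(lo <= observed_stats[stat] <= hi)

    return PPCResult(
        replicate_stats=replicate_stats,
        observed_stats=observed_stats,
        coverage=coverage,
        replicate_rts=rep_rts,
        observed_rt=np.asarray(data.rt, dtype=float),
        person_idx=np.asarray(pidx),
        person_ids=list(data.person_ids),
        n_rep=n_rep,
        draw_indices=idx,
    )


def _draw_latencies(v_n, th_n, form, rng):
    z = rng.normal(v_n, 1.0)
    if form == "direct":
        return z / th_n
    with np.errstate(divide="ignore"):
        return th_n / z


def ppc_overlay_export(
    result: PPCResult,
    level: str = "dataset",
    person_id=None,
    n_bins: int = 40,
    grid_size: int = 128,
) -> pd.DataFrame:
    """Plot-ready overlay table: observed histogram + replicate densities.

    Returns a table on a common latency grid with the observed histogram
    counts (summing to the retained trial count) and one Gaussian-kernel
    smoothed density column per replicate (Silverman bandwidth), each
    integrating to ~1 over the grid.  ``level="person"`` restricts both
    observed and replicated data to one participant.
    """
    if level not in ("dataset", "person"):
        raise ValueError("level must be 'dataset' or 'person'")
    if level == "person":
        if person_id is None:
            raise ValueError("person-level export requires person_id")
        if person_id not in result.person_ids:
            raise ValueError(
                f"unknown person {person_id!r}; known: {result.person_ids}"
            )
        sel = result.person_idx == result.person_ids.index(person_id)
    else:
        sel = slice(None)

    obs = result.observed_rt[sel]
    pool = np.concatenate([obs] + [y[sel] for y in result.replicate_rts])
    lo, hi = float(pool.min()), float(pool.max())
    pad = 0.05 * (hi - lo) if hi > lo else 0.05
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(obs, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    cols = {
        "rt": grid,
        "observed_count": np.interp(grid, centers, counts, left=0.0, right=0.0),
    }
    hist = pd.DataFrame({"bin_center": centers, "count": counts})
    for r, y in enumerate(result.replicate_rts):
        kde = gaussian_kde(y[sel], bw_method="silverman")
        cols[f"rep_{r:03d}"] = kde(grid)
    out = pd.DataFrame(cols)
    out.attrs["observed_histogram"] = hist
    out.attrs["n_observed"] = int(obs.size)
    return out


def plot_ppc(result: PPCResult, level: str = "dataset", person_id=None, ax=None):
    """Overlay figure: observed histogram (bars) under replicate densities."""
    import matplotlib.pyplot as plt

    table = ppc_overlay_export(result, level=level, person_id=person_id)
    hist = table.attrs["observed_histogram"]
    if ax is None:
        _, ax = plt.subplots()
    width = hist["bin_center"].diff().median()
    dens = hist["count"] / (hist["count"].sum() * width)
    ax.bar(hist["bin_center"], dens, width=width, color="firebrick", alpha=0.6,
           label="observed")
    rep_cols = [c for c in table.columns if c.startswith("rep_")]
    for c in rep_cols:
        ax.plot(table["rt"], table[c], color="steelblue", alpha=0.15, lw=0.8)
    ax.set_xlabel("reaction time (s)")
    ax.set_ylabel("density")
    ax.legend(loc="upper right")
    return ax
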