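"""Fit-visualization summaries: quantile binning of the stimulus axis
and posterior-predictive group curves with bootstrap uncertainty bands.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .inference import PosteriorSamples
from .params import ModelSpec
from .simulate import Dataset, sample_responses
from .tasks import TaskSpec, task_a, task_b

__all__ = ["quantile_bins", "binned_statistic", "summarize_fit"]


def quantile_bins(task: TaskSpec, n_bins: int) -> np.ndarray:
    """Interior bin edges splitting the mixture stimulus distribution
    p(s) = Σ_c p(C=c) p(s|C=c) into ``n_bins`` equal-mass bins."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    qs = np.arange(1, n_bins) / n_bins
    lo = min(task.mu) - 10 * max(task.sigma_cat)
    hi = max(task.mu) + 10 * max(task.sigma_cat)
    return np.array([optimize.brentq(lambda s: task.stimulus_cdf(s) - q, lo, hi)
                     for q in qs])


def binned_statistic(s: np.ndarray, values: np.ndarray,
                     edges: np.ndarray) -> np.ndarray:
    """Mean of ``values`` per stimulus bin (edges are interior; bins are
    (-inf, e1], ..., (e_{k-1}, inf))."""
    idx = np.searchsorted(edges, s)
    n_bins = len(edges) + 1
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            out[b] = values[m].mean()
    return out


def _dataset_curve(trials: pd.DataFrame, edges_by_task: Dict[str, np.ndarray],
                   column: str = "response") -> pd.Series:
    parts = {}
    for tid, grp in trials.groupby("task"):
        curve = binned_statistic(grp["orientation_deg"].to_numpy(),
                                 grp[column].to_numpy(dtype=float),
                                 edges_by_task[tid])
        for b, v in enumerate(curve):
            parts[(tid, b)] = v
    return pd.Series(parts)


def summarize_fit(model: ModelSpec, samples_per_dataset: Sequence[PosteriorSamples],
                  datasets: Sequence[Dataset], n_param_draws: int = 20,
                  n_group_boot: int = 1000,
                  rng: Optional[np.random.Generator] = None,
                  n_bins: int = 6, column: str = "response",
                  tasks: Optional[Dict[str, TaskSpec]] = None) -> pd.DataFrame:
    """Posterior-predictive group curves.

    For each dataset, ``n_param_draws`` synthetic datasets are simulated
    from distinct posterior parameter draws on the original stimuli;
    ``n_group_boot`` synthetic groups are then assembled by sampling one
    synthetic dataset per subject, and the per-bin mean of ``column`` is
    summarized by its mean ± s.d. across groups, next to the observed
    group mean ± s.e.m.
    """
    if len(samples_per_dataset) != len(datasets):
        raise ValueError("need one PosteriorSamples per dataset")
    rng = rng or np.random.default_rng(0)
    tasks = tasks or {"A": task_a(), "B": task_b()}
    present = sorted({t for ds in datasets for t in ds.testing()["task"].unique()})
    edges = {t: quantile_bins(tasks[t], n_bins) for t in present}

    obs_curves = []
    synth_curves: List[List[pd.Series]] = []
    for ds, samp in zip(datasets, samples_per_dataset):
        trials = ds.testing()
        obs_curves.append(_dataset_curve(trials, edges, column))
        n_avail = len(samp.draws)
        if n_avail < n_param_draws:
            warnings.warn("fewer posterior draws than requested; sampling "
                          "with replacement", RuntimeWarning)
            draw_idx = rng.integers(0, n_avail, size=n_param_draws)
        else:
            draw_idx = rng.choice(n_avail, size=n_param_draws, replace=False)
        per_ds = []
        for di in draw_idx:
            pv = samp.param_vector(int(di))
            sim = trials.copy()
            resp = np.empty(len(sim), dtype=int)
            for tid, grp in sim.groupby("task"):
                r = sample_responses(model, pv, tasks[tid],
                                     grp["orientation_deg"].to_numpy(),
                                     grp["reliability_value"].to_numpy(), rng)
                resp[grp.index.to_numpy()] = r
            sim["response"] = resp
            from .responses import response_to_choice, response_to_confidence
            sim["chosen_category"] = response_to_choice(resp)
            sim["confidence"] = response_to_confidence(resp)
            per_ds.append(_dataset_curve(sim, edges, column))
        synth_curves.append(per_ds)

    obs = pd.concat(obs_curves, axis=1)
    obs_mean = obs.mean(axis=1)
    obs_sem = obs.std(axis=1, ddof=1) / np.sqrt(obs.shape[1]) \
        if obs.shape[1] > 1 else obs_mean * np.nan

    n_subj = len(datasets)
    boots = np.empty((n_group_boot, len(obs_mean)))
    for b in range(n_group_boot):
        picks = [synth_curves[s][rng.integers(len(synth_curves[s]))]
                 for s in range(n_subj)]
        boots[b] = pd.concat(picks, axis=1).mean(axis=1).to_numpy()
    fit_mean = boots.mean(axis=0)
    fit_sd = boots.std(axis=0, ddof=1) if n_group_boot > 1 else np.full_like(
        fit_mean, np.nan)

    out = pd.DataFrame({
        "task": [k[0] for k in obs_mean.index],
        "bin": [k[1] for k in obs_mean.index],
        "obs_mean": obs_mean.to_numpy(),
        "obs_sem": obs_sem.to_numpy(),
        "fit_mean": fit_mean,
        "fit_sd": fit_sd,
    })
    return out
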