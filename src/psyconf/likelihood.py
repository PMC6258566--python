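"""Trial-level response probabilities and dataset log likelihood.

For the boundary families the probability of response ``r`` on a trial
with stimulus ``s`` and measurement noise ``σ`` is the probability mass
of the measurement distribution N(s, σ²) between the model's
measurement-space boundaries (Task A), or over the mirrored pair of
|x| intervals (Task B).  The linear-neural family integrates the normal
approximation of the population readout z between its criteria, and the
precision-hybrid family intersects the category half-line on the
decision axis with the confidence bands of its mixed decision variable.
The core vector is then mixed with three lapse processes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import observers as obs
from .params import ModelSpec, ParamVector, PriorSpec
from .tasks import TaskSpec, task_a, task_b

__all__ = [
    "LapseParams",
    "PreparedTrials",
    "apply_lapses",
    "core_response_probabilities",
    "response_probabilities",
    "dataset_log_likelihood",
    "log_posterior",
]

_TASKS = {"A": task_a(), "B": task_b()}


def _task_for(task_id: str, tasks: Optional[dict] = None) -> TaskSpec:
    return (tasks or _TASKS)[task_id]


# ---------------------------------------------------------------------------
# Gaussian interval masses

def _interval_mass(lo, hi, mu, sigma):
    """P(lo < X < hi) for X ~ N(mu, sigma²), evaluated through the
    complementary tail when the interval lies above the mean to avoid
    catastrophic cancellation; empty (lo >= hi) intervals give 0."""
    with np.errstate(invalid="ignore"):
        z_lo = (lo - mu) / sigma
        z_hi = (hi - mu) / sigma
        upper = z_lo + z_hi > 0
    m = np.where(upper, ndtr(-z_lo) - ndtr(-z_hi), ndtr(z_hi) - ndtr(z_lo))
    return np.maximum(m, 0.0)


def _edge_masses(edges: np.ndarray, mu, sigma) -> np.ndarray:
    """Masses of N(mu, sigma²) between consecutive edges (..., E).

    The CDF is evaluated once per edge on its well-conditioned side
    (the nearer tail, ndtr(-|z|)), so masses of far-tail intervals never
    suffer catastrophic cancellation.
    """
    with np.errstate(invalid="ignore"):
        z = (edges - mu) / sigma
    tail = ndtr(-np.abs(z))          # P(X beyond the edge, nearer tail)
    t_lo, t_hi = tail[..., :-1], tail[..., 1:]
    z_lo, z_hi = z[..., :-1], z[..., 1:]
    # edges sorted: both above mean -> difference of upper tails; both
    # below -> lower tails; straddling -> 1 - both tails
    m = np.where(z_lo >= 0, t_lo - t_hi,
                 np.where(z_hi <= 0, t_hi - t_lo, 1.0 - t_lo - t_hi))
    return np.maximum(m, 0.0)


def _absx_mass(lo, hi, mu, sigma):
    """P(lo < |X| < hi) for X ~ N(mu, sigma²), lo, hi >= 0."""
    return (_interval_mass(lo, hi, mu, sigma)
            + _interval_mass(-hi, -lo, mu, sigma))


def _masses_from_boundaries(b: np.ndarray, s: np.ndarray, sigma: np.ndarray,
                            task_id: str) -> np.ndarray:
    """Response masses given sorted boundaries b (..., K) per trial."""
    mu = s.reshape(s.shape + (1,) * (b.ndim - s.ndim))
    sg = sigma.reshape(sigma.shape + (1,) * (b.ndim - sigma.ndim))
    if task_id == "A":
        # only the K interior edges need the CDF; the outer edges are ±inf
        with np.errstate(invalid="ignore"):
            z = (b - mu) / sg
        tail = ndtr(-np.abs(z))
        out = np.empty(b.shape[:-1] + (b.shape[-1] + 1,))
        lo_half = z <= 0
        out[..., 0] = np.where(lo_half[..., 0], tail[..., 0],
                               1.0 - tail[..., 0])
        out[..., -1] = np.where(lo_half[..., -1], 1.0 - tail[..., -1],
                                tail[..., -1])
        t_lo, t_hi = tail[..., :-1], tail[..., 1:]
        out[..., 1:-1] = np.where(
            z[..., :-1] >= 0, t_lo - t_hi,
            np.where(z[..., 1:] <= 0, t_hi - t_lo, 1.0 - t_lo - t_hi))
        return np.maximum(out, 0.0, out=out)
    n_edge = b.shape[-1] + 2
    edges = np.empty(b.shape[:-1] + (n_edge,))
    edges[..., 0] = 0.0
    edges[..., 1:-1] = b
    edges[..., -1] = np.inf
    return _edge_masses(edges, mu, sg) + _edge_masses(-edges[..., ::-1], mu,
                                                      sg)[..., ::-1]


# ---------------------------------------------------------------------------
# Lapses

@dataclass(frozen=True)
class LapseParams:
    """Mixture weights of the three lapse processes.

    ``lambda_full``: category random, confidence drawn from the
    (λ₁, λ₄)-interpolated distribution; ``lambda_conf``: category kept,
    confidence uniform; ``lambda_repeat``: the previous response is
    repeated.  The three events are mutually exclusive per trial.
    """

    lambda_full: float = 0.0
    lambda_1: float = 0.25
    lambda_4: float = 0.25
    lambda_conf: float = 0.0
    lambda_repeat: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_full", "lambda_1", "lambda_4", "lambda_conf",
                     "lambda_repeat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lambda_full + self.lambda_conf + self.lambda_repeat > 1.0:
            raise ValueError("lapse probabilities must sum to at most 1")

    @classmethod
    def from_params(cls, pv: ParamVector) -> "LapseParams":
        if pv.model.response_mode == "choice_only":
            return cls(lambda_full=pv.get("lambda_full"),
                       lambda_repeat=pv.get("lambda_repeat"))
        return cls(lambda_full=pv.get("lambda_full"),
                   lambda_1=pv.get("lambda_1"), lambda_4=pv.get("lambda_4"),
                   lambda_conf=pv.get("lambda_conf"),
                   lambda_repeat=pv.get("lambda_repeat"))

    def confidence_weights(self) -> np.ndarray:
        """Full-lapse distribution over confidence levels 1..4: endpoints
        λ₁ and λ₄ with linear interpolation, renormalized to sum 1."""
        lam1, lam4 = self.lambda_1, self.lambda_4
        w = np.array([lam1 + j * (lam4 - lam1) / 3.0 for j in range(4)])
        total = w.sum()
        if total <= 0:
            return np.full(4, 0.25)
        return w / total

    def full_lapse_distribution(self, n_responses: int = 8) -> np.ndarray:
        if n_responses == 2:
            return np.array([0.5, 0.5])
        w = self.confidence_weights()
        out = np.empty(8)
        out[:4] = 0.5 * w[::-1]   # responses 1..4 = category 1, confidence 4..1
        out[4:] = 0.5 * w         # responses 5..8 = category 2, confidence 1..4
        return out


def apply_lapses(core_probs: np.ndarray, lapses: LapseParams,
                 previous_response=None) -> np.ndarray:
    """Mix the core response vector(s) with the lapse processes.

    ``previous_response`` holds response codes, with 0 (or None) marking
    trials without a predecessor; on those trials the repeat mass is
    redistributed proportionally over the remaining mixture components.
    """
    core = np.asarray(core_probs, dtype=float)
    squeeze = core.ndim == 1
    core = np.atleast_2d(core)
    n, K = core.shape
    lam_f, lam_c, lam_r = (lapses.lambda_full, lapses.lambda_conf,
                           lapses.lambda_repeat)
    rem = 1.0 - lam_f - lam_c - lam_r
    if rem < -1e-12:
        raise ValueError("lapse probabilities exceed 1")
    base = core * rem
    if lam_f > 0:
        base += lam_f * lapses.full_lapse_distribution(K)
    if lam_c > 0 and K == 8:
        marg = core.reshape(n, 2, 4).sum(axis=2) * (lam_c / 4.0)
        base += np.repeat(marg, 4, axis=1)
    elif lam_c > 0:
        base += lam_c * core
    if previous_response is None:
        prev = np.zeros(n, dtype=int)
    else:
        prev = np.atleast_1d(np.asarray(previous_response)).astype(int)
        if prev.shape == (1,) and n > 1:
            prev = np.full(n, prev[0])
    out = np.empty_like(base)
    has_prev = prev > 0
    if lam_r > 0:
        out[~has_prev] = base[~has_prev] / (1.0 - lam_r)
        out[has_prev] = base[has_prev]
        rows = np.nonzero(has_prev)[0]
        out[rows, prev[rows] - 1] += lam_r
    else:
        out[:] = base
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Core (lapse-free) response probabilities

def _linear_neural_probs(model: ModelSpec, pv: ParamVector, task: TaskSpec,
                         s: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    mean_z, var_z = obs.linear_neural_moments(s, sigma, pv.get("a"),
                                              pv.get("sigma_tc"))
    sd = np.sqrt(var_z)
    t = task.task_id
    idx = (4,) if model.response_mode == "choice_only" else range(1, 8)
    k = pv.get_array([f"k{t}_{j}" for j in idx])
    if t == "B":
        k = np.maximum(k, 0.0)
    k = np.sort(k)
    b = np.broadcast_to(k, sigma.shape + k.shape)
    return _masses_from_boundaries(b, mean_z, sd, t)


def _hybrid_probs(model: ModelSpec, pv: ParamVector, task: TaskSpec,
                  s: np.ndarray, sigma_m: np.ndarray, sigma_i: np.ndarray,
                  eta: float = 0.0) -> np.ndarray:
    """Precision-hybrid responses: category from the sign of d relative to
    the category criterion, confidence from v = ω/σ² + logistic(|d|)."""
    beliefs = obs.CategoryBeliefs.from_params(pv, task)
    lp = beliefs.log_prior_ratio
    omega = pv.get("omega")
    k4 = pv.get("k_4") - eta
    tid = task.task_id
    s2 = sigma_i ** 2

    if tid == "A":
        coef = (s2 + beliefs.sigma_cat[0] ** 2) / (2.0 * beliefs.mu[0])

        def inv(v):  # x where d = v; decreasing in v (mu_1 < 0)
            with np.errstate(invalid="ignore"):
                return (v - lp) * coef
    else:
        sig1sq, sig2sq = beliefs.sigma_cat[0] ** 2, beliefs.sigma_cat[1] ** 2
        v1, v2 = s2 + sig1sq, s2 + sig2sq
        amp = 0.5 * np.log(v2 / v1)
        denom = (sig2sq - sig1sq) / (2.0 * v1 * v2)

        def inv(v):  # |x| where d = v; decreasing in v
            with np.errstate(invalid="ignore"):
                return np.sqrt(np.maximum(0.0, (amp + lp - v) / denom))

    bc = inv(np.broadcast_to(k4, sigma_i.shape))  # category boundary

    if model.response_mode == "choice_only":
        if tid == "A":
            p1 = _interval_mass(-np.inf, bc, s, sigma_m)
        else:
            p1 = _absx_mass(0.0, bc, s, sigma_m)
        return np.stack([p1, 1.0 - p1], axis=-1)

    t = obs.hybrid_thresholds(pv.get_array(["k_1", "k_2", "k_3"]), sigma_i, omega)
    t = np.sort(t, axis=1)  # crossing confidence criteria resolved by sorting
    n = len(s)
    T = np.concatenate([np.zeros((n, 1)), t, np.full((n, 1), np.inf)], axis=1)
    out = np.zeros((n, 8))
    for lev in range(1, 5):
        # d-axis bands of confidence level `lev`: (T_{lev-1}, T_lev) and its mirror
        pieces = (((T[:, lev - 1] - eta), (T[:, lev] - eta)),
                  ((-T[:, lev] - eta), (-T[:, lev - 1] - eta)))
        for a, bnd in pieces:
            with np.errstate(invalid="ignore"):
                lo, hi = inv(bnd), inv(a)  # decision axis decreasing in d
            if tid == "A":
                p_c1 = _interval_mass(lo, np.minimum(hi, bc), s, sigma_m)
                p_c2 = _interval_mass(np.maximum(lo, bc), hi, s, sigma_m)
            else:
                p_c1 = _absx_mass(lo, np.minimum(hi, bc), s, sigma_m)
                p_c2 = _absx_mass(np.maximum(lo, bc), hi, s, sigma_m)
            out[:, 5 - lev - 1] += p_c1
            out[:, 4 + lev - 1] += p_c2
    return out


class PreparedTrials:
    """Pre-extracted trial arrays for fast repeated likelihood evaluation
    (one extraction from the DataFrame, plus a memo for the trial noise
    s.d.s keyed by the noise-parameter values)."""

    def __init__(self, model: ModelSpec, trials: pd.DataFrame,
                 tasks: Optional[dict] = None):
        self.model = model
        self.n = len(trials)
        task_col = trials["task"].to_numpy()
        present = set(task_col)
        if not present <= set(model.tasks):
            raise ValueError(
                f"dataset contains task(s) {sorted(present - set(model.tasks))} "
                f"outside the model's fit scope {model.fit_scope}")
        self.groups = []
        for tid in model.tasks:
            mask = task_col == tid
            if not mask.any():
                continue
            task = _task_for(tid, tasks)
            self.groups.append({
                "task": task,
                "mask": mask,
                "s": trials.loc[mask, "orientation_deg"].to_numpy(dtype=float),
                "c": trials.loc[mask, "reliability_value"].to_numpy(dtype=float),
                "sigma_memo": {},
            })
        col = ("chosen_category" if model.response_mode == "choice_only"
               else "response")
        r = trials[col].to_numpy(dtype=int)
        self.observed = r - 1
        self.prev = np.empty_like(r)
        self.prev[0] = 0
        self.prev[1:] = r[:-1]

    def sigmas(self, pv: ParamVector, grp: dict, believed: bool) -> np.ndarray:
        np_ = obs.NoiseParams.from_params(pv, grp["task"], believed=believed)
        key = np_
        memo = grp["sigma_memo"]
        if key not in memo:
            if len(memo) > 16:
                memo.clear()
            sig = obs.sigma_of(np_, grp["c"], grp["s"])
            memo[key] = np.ascontiguousarray(
                np.broadcast_to(np.asarray(sig, float), grp["s"].shape))
        return memo[key]


def core_response_probabilities(model: ModelSpec, pv: ParamVector,
                                trials,
                                tasks: Optional[dict] = None) -> np.ndarray:
    """Lapse-free response probability vectors, one row per trial.

    ``trials`` is a DataFrame with columns ``task``, ``orientation_deg``
    and ``reliability_value`` (or a :class:`PreparedTrials`).  Returns
    shape (n, 8), or (n, 2) for choice-only models.
    """
    prepared = (trials if isinstance(trials, PreparedTrials)
                else PreparedTrials(model, trials, tasks))
    K = 2 if model.response_mode == "choice_only" else 8
    out = np.empty((prepared.n, K))
    for grp in prepared.groups:
        task = grp["task"]
        tid = task.task_id
        mask = grp["mask"]
        s = grp["s"]
        sigma_m = prepared.sigmas(pv, grp, believed=False)
        sigma_i = (prepared.sigmas(pv, grp, believed=True)
                   if pv.model.noise_split else sigma_m)

        fam = model.family
        if fam == "linear_neural":
            p = _linear_neural_probs(model, pv, task, s, sigma_m)
        elif fam == "precision_hybrid":
            if model.d_noise:
                eta, w = obs.dnoise_grid(pv.get("sigma_d"))
                p = np.zeros((mask.sum(), K))
                for e, wi in zip(eta, w):
                    p += wi * _hybrid_probs(model, pv, task, s, sigma_m,
                                            sigma_i, eta=e)
            else:
                p = _hybrid_probs(model, pv, task, s, sigma_m, sigma_i)
        elif model.is_bayes and model.d_noise:
            eta, w = obs.dnoise_grid(pv.get("sigma_d"))
            crit = obs.d_criteria(model, pv, tid)
            beliefs = obs.CategoryBeliefs.from_params(pv, task)
            b = obs.bayes_boundaries(task, crit[None, :] - eta[:, None],
                                     sigma_i[:, None], beliefs)  # (n, E, K-1...)
            masses = _masses_from_boundaries(b, s[:, None], sigma_m[:, None], tid)
            p = np.einsum("neK,e->nK", masses, w)
        else:
            b = obs.measurement_boundaries(model, pv, task, sigma_i)
            p = _masses_from_boundaries(b, s, sigma_m, tid)
        out[mask] = p
    return out


def response_probabilities(model: ModelSpec, pv: ParamVector,
                           trials,
                           tasks: Optional[dict] = None) -> np.ndarray:
    """Full (lapse-mixed) response probabilities per trial, in row order."""
    prepared = (trials if isinstance(trials, PreparedTrials)
                else PreparedTrials(model, trials, tasks))
    core = core_response_probabilities(model, pv, prepared)
    lapses = LapseParams.from_params(pv)
    return apply_lapses(core, lapses, prepared.prev)


def _previous_responses(model: ModelSpec, trials: pd.DataFrame) -> np.ndarray:
    col = ("chosen_category" if model.response_mode == "choice_only"
           else "response")
    r = trials[col].to_numpy(dtype=int)
    prev = np.empty_like(r)
    prev[0] = 0
    prev[1:] = r[:-1]
    return prev


def _observed_index(model: ModelSpec, trials: pd.DataFrame) -> np.ndarray:
    col = ("chosen_category" if model.response_mode == "choice_only"
           else "response")
    return trials[col].to_numpy(dtype=int) - 1


def dataset_log_likelihood(model: ModelSpec, pv: ParamVector, dataset,
                           return_pointwise: bool = False,
                           tasks: Optional[dict] = None):
    """Σ_i log p(r_i | s_i, σ_i, θ) over the testing trials.

    ``dataset`` is a trial DataFrame, a :class:`PreparedTrials`, or any
    object with a ``testing()`` method returning a DataFrame.  A trial
    with probability 0 yields −inf with a diagnostic naming the trial
    rows.
    """
    if isinstance(dataset, PreparedTrials):
        prepared = dataset
    else:
        trials_df = dataset.testing() if hasattr(dataset, "testing") else dataset
        if len(trials_df) == 0:
            raise ValueError("dataset has no testing trials")
        prepared = PreparedTrials(model, trials_df, tasks)
    trials = prepared
    probs = response_probabilities(model, pv, prepared)
    p_obs = probs[np.arange(prepared.n), prepared.observed]
    zero = p_obs <= 0.0
    if zero.any():
        idx = np.nonzero(zero)[0][:10]
        warnings.warn(f"zero response probability at trial row(s) {idx.tolist()}",
                      RuntimeWarning)
        pointwise = np.full(prepared.n, -np.inf)
        pointwise[~zero] = np.log(p_obs[~zero])
    else:
        pointwise = np.log(p_obs)
    total = float(pointwise.sum()) if not zero.any() else -np.inf
    return (total, pointwise) if return_pointwise else total


def log_posterior(model: ModelSpec, values, dataset, priors: PriorSpec,
                  tasks: Optional[dict] = None) -> float:
    """Log posterior of a sampling-scale parameter vector: log likelihood
    plus the (constant inside the box) log prior; −inf outside the box."""
    values = np.asarray(values, dtype=float)
    lp = priors.log_pdf(values)
    if not np.isfinite(lp):
        return -np.inf
    pv = ParamVector(model, values)
    ll = dataset_log_likelihood(model, pv, dataset, tasks=tasks)
    return ll + lp
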