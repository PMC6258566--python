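"""Decision variables and measurement-space decision boundaries.

Every observer family maps a noisy measurement ``x`` (and, for the
probabilistic families, the trial-level uncertainty ``σ``) to one of
eight category-and-confidence responses.  This module provides the
building blocks: the reliability-dependent noise function, the log
posterior ratio ``d`` of the Bayesian observer, closed-form inversions
of ``d``-space criteria into measurement-space boundaries, the
lookup-table MAP orientation estimator, the linear neural readout
moments, and the heuristic (Fixed/Lin/Quad) boundary rules.

Orientation convention: degrees, 0° horizontal; category 1 is the
leftward (Task A) or narrow (Task B) category, so ``d > 0`` favors
category 1 and corresponds to negative ``x`` in Task A and small ``|x|``
in Task B.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from .params import ModelSpec, ParamVector
from .tasks import TaskSpec

__all__ = [
    "NoiseParams",
    "CategoryBeliefs",
    "sigma_of",
    "category_likelihood",
    "log_posterior_ratio",
    "prob_correct",
    "bayes_boundaries",
    "d_criteria",
    "dnoise_grid",
    "heuristic_boundaries",
    "linear_neural_moments",
    "hybrid_decision_variable",
    "hybrid_thresholds",
    "OrientationEstimator",
    "orientation_estimator",
    "map_orientation_estimate",
    "measurement_boundaries",
]


# ---------------------------------------------------------------------------
# Measurement noise

@dataclass(frozen=True)
class NoiseParams:
    """Reliability → measurement-noise mapping for one observer.

    In parametric mode the noise variance interpolates between
    ``sigma_low²`` (at the lowest reliability ``c_lo``) and
    ``sigma_high²`` (at the highest, ``c_hi``) along a power law in the
    reliability with curvature ``beta``.  In nonparametric mode each of
    the six reliability levels carries its own s.d.  ``psi`` adds
    orientation-dependent noise peaking at oblique orientations.
    """

    mode: str                     # parametric | nonparametric
    psi: float = 0.0
    sigma_low: Optional[float] = None
    sigma_high: Optional[float] = None
    beta: Optional[float] = None
    sigma_per_level: Optional[Tuple[float, ...]] = None
    levels: Optional[Tuple[float, ...]] = None   # physical reliability values
    c_lo: Optional[float] = None
    c_hi: Optional[float] = None

    @classmethod
    def from_params(cls, pv: ParamVector, task: TaskSpec,
                    believed: bool = False) -> "NoiseParams":
        sfx = "_inf" if (believed and pv.model.noise_split) else ""
        psi = pv.get(f"psi{sfx}") if f"psi{sfx}" in pv else 0.0
        rv = task.reliability_values
        if pv.model.nonparam_sigma:
            return cls(mode="nonparametric", psi=psi,
                       sigma_per_level=tuple(pv.get(f"sigma_rel_{i}{sfx}")
                                             for i in range(1, 7)),
                       levels=tuple(rv))
        return cls(mode="parametric", psi=psi,
                   sigma_low=pv.get(f"sigma_low{sfx}"),
                   sigma_high=pv.get(f"sigma_high{sfx}"),
                   beta=pv.get(f"beta{sfx}"),
                   c_lo=rv[0], c_hi=rv[-1])


def sigma_of(noise: NoiseParams, reliability_value, orientation):
    """Measurement-noise s.d. at reliability ``c`` and orientation ``s``.

    Parametric mode:  σ(c,s) = sqrt(σ_L² + (σ_L²−σ_H²)(c^−β − c_L^−β)
    /(c_L^−β − c_H^−β)) + ψ·|sin(πs/90)|, exactly σ_L at the lowest and
    σ_H at the highest calibrated reliability.
    """
    c = np.asarray(reliability_value, dtype=float)
    s = np.asarray(orientation, dtype=float)
    if noise.mode == "parametric":
        if np.any(c < noise.c_lo - 1e-12) or np.any(c > noise.c_hi + 1e-12):
            raise ValueError(
                f"reliability outside calibrated range [{noise.c_lo}, {noise.c_hi}]")
        b = noise.beta
        num = c ** (-b) - noise.c_lo ** (-b)
        den = noise.c_lo ** (-b) - noise.c_hi ** (-b)
        var = noise.sigma_low ** 2 + (noise.sigma_low ** 2
                                      - noise.sigma_high ** 2) * num / den
        base = np.sqrt(var)
    else:
        lv = np.asarray(noise.levels, dtype=float)
        idx = np.argmin(np.abs(c[..., None] - lv), axis=-1)
        matched = lv[idx]
        if np.any(~np.isclose(matched, c, rtol=1e-6, atol=1e-12)):
            raise ValueError("reliability value not among the calibrated levels")
        base = np.asarray(noise.sigma_per_level, dtype=float)[idx]
    out = base + noise.psi * np.abs(np.sin(np.pi * s / 90.0))
    return out[()]


# ---------------------------------------------------------------------------
# The Bayesian decision variable

@dataclass(frozen=True)
class CategoryBeliefs:
    """The observer's assumed category parameters (defaults: the true design)."""

    mu: Tuple[float, float]
    sigma_cat: Tuple[float, float]
    log_prior_ratio: float = 0.0

    @classmethod
    def from_params(cls, pv: ParamVector, task: TaskSpec) -> "CategoryBeliefs":
        if not pv.model.free_category_params:
            return cls(task.mu, task.sigma_cat, task.log_prior_ratio)
        if task.task_id == "A":
            sc = pv.get("sigma_c_a")
            sig = (sc, sc)
        else:
            sig = (pv.get("sigma_1_b"), pv.get("sigma_2_b"))
        return cls(task.mu, sig, pv.get("prior_log_ratio"))


def category_likelihood(x, sigma, mu_c, sigma_c):
    """p(x|C): Normal density of x with mean μ_C and variance σ² + σ_C²
    (the stimulus marginalized out)."""
    x = np.asarray(x, dtype=float)
    var = np.asarray(sigma, dtype=float) ** 2 + float(sigma_c) ** 2
    return np.exp(-0.5 * (x - mu_c) ** 2 / var) / np.sqrt(2 * np.pi * var)


def log_posterior_ratio(task: TaskSpec, x, sigma,
                        beliefs: Optional[CategoryBeliefs] = None):
    """Log posterior ratio d = log p(C=1|x)/p(C=2|x)."""
    b = beliefs or CategoryBeliefs(task.mu, task.sigma_cat, task.log_prior_ratio)
    x = np.asarray(x, dtype=float)
    s2 = np.asarray(sigma, dtype=float) ** 2
    if task.task_id == "A":
        d = 2.0 * x * b.mu[0] / (s2 + b.sigma_cat[0] ** 2)
    else:
        v1 = s2 + b.sigma_cat[0] ** 2
        v2 = s2 + b.sigma_cat[1] ** 2
        d = 0.5 * np.log(v2 / v1) - (b.sigma_cat[1] ** 2 - b.sigma_cat[0] ** 2) \
            / (2.0 * v1 * v2) * x ** 2
    return d + b.log_prior_ratio


def prob_correct(d):
    """Posterior probability of category 1, logistic in d; the probability
    of the *chosen* category is the logistic of |d|."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-d))


def bayes_boundaries(task: TaskSpec, criteria, sigma,
                     beliefs: Optional[CategoryBeliefs] = None) -> np.ndarray:
    """Measurement-space boundaries for d-space criteria, closed form.

    ``criteria`` broadcasts against ``sigma[..., None]``; the returned
    array is sorted nondecreasing along the last axis.  Task A boundaries
    are signed x values (affine in σ²); Task B boundaries act on |x|,
    with unreachable criteria collapsing to 0.
    """
    b = beliefs or CategoryBeliefs(task.mu, task.sigma_cat, task.log_prior_ratio)
    k = np.asarray(criteria, dtype=float)
    s2 = np.asarray(sigma, dtype=float)[..., None] ** 2
    lp = b.log_prior_ratio
    if task.task_id == "A":
        out = (k - lp) * (s2 + b.sigma_cat[0] ** 2) / (2.0 * b.mu[0])
    else:
        sig1sq, sig2sq = b.sigma_cat[0] ** 2, b.sigma_cat[1] ** 2
        if sig1sq == sig2sq:
            raise ValueError("Task B boundary inversion undefined when the "
                             "believed category s.d.s are equal")
        v1, v2 = s2 + sig1sq, s2 + sig2sq
        amp = 0.5 * np.log(v2 / v1)
        denom = (sig2sq - sig1sq) / (2.0 * v1 * v2)
        out = np.sqrt(np.maximum(0.0, (amp + lp - k) / denom))
    return np.sort(out, axis=-1)


def d_criteria(model: ModelSpec, pv: ParamVector, task_id: str) -> np.ndarray:
    """The full d-space criterion vector (k_1..k_7, or just k_4 in
    choice-only mode) for a Bayes-family model, expanding symmetric sets."""
    fam = model.family
    if fam == "bayes_ultrastrong":
        prefix = "k"
    elif fam == "bayes_strong":
        prefix = f"k{task_id}"
    elif fam == "bayes_weak":
        prefix = f"k{task_id}"
    else:
        raise ValueError(f"{fam} has no d-space criteria")
    if model.response_mode == "choice_only":
        return np.array([pv.get(f"{prefix}_4")])
    if fam == "bayes_weak" and task_id == "B":
        return pv.get_array([f"{prefix}_{j}" for j in range(1, 8)])
    k = pv.get_array([f"{prefix}_{j}" for j in (1, 2, 3, 4)])
    k4 = k[3]
    return np.concatenate([k, 2 * k4 - k[2::-1]])


def dnoise_grid(sigma_d: float, n_draws: int = 101,
                span: float = 5.0) -> Tuple[np.ndarray, np.ndarray]:
    """Evenly spaced draws of the decision noise η_d spanning ±span·σ_d,
    with normalized Gaussian weights."""
    if sigma_d <= 0:
        raise ValueError("sigma_d must be positive")
    if n_draws % 2 == 0:
        raise ValueError("n_draws must be odd so the grid includes 0")
    eta = np.linspace(-span * sigma_d, span * sigma_d, n_draws)
    w = np.exp(-0.5 * (eta / sigma_d) ** 2)
    return eta, w / w.sum()


# ---------------------------------------------------------------------------
# Heuristic families

def heuristic_boundaries(family: str, k, m, sigma, task_id: str) -> np.ndarray:
    """Fixed / Lin / Quad measurement boundaries b(σ).

    Fixed: b = k.  Lin: b = k + mσ.  Quad: b = k + mσ².  Task B
    boundaries act on |x| and are clipped at 0; the output is sorted
    nondecreasing per σ so that crossing boundaries never produce
    negative response masses.
    """
    k = np.asarray(k, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if family == "fixed":
        out = np.broadcast_to(k, sigma.shape + k.shape).copy()
    elif family == "lin":
        out = k + np.asarray(m, float) * sigma[..., None]
    elif family == "quad":
        out = k + np.asarray(m, float) * sigma[..., None] ** 2
    else:
        raise ValueError(f"unknown heuristic family {family!r}")
    if task_id == "B":
        out = np.maximum(out, 0.0)
    return np.sort(out, axis=-1)


def linear_neural_moments(s, sigma, a: float, sigma_tc: float):
    """Mean and variance of the linear population readout z.

    A homogeneous population with Gaussian tuning (width σ_TC), gain
    g = 1/σ², independent Poisson spiking and weights w = a·s̃ linear in
    the preferred orientation yields E[z] = Σ_j w_j f_j(s) =
    a·g·s·sqrt(2π σ_TC²) and Var[z] = Σ_j w_j² f_j(s) =
    a²·g·sqrt(2π σ_TC²)·(σ_TC² + s²); the quadratic weight enters the
    variance twice (verified against direct simulation of the Poisson
    population).
    """
    if a <= 0 or sigma_tc <= 0:
        raise ValueError("a and sigma_tc must be positive")
    s = np.asarray(s, dtype=float)
    g = 1.0 / np.asarray(sigma, dtype=float) ** 2
    amp = a * g * math.sqrt(2 * math.pi * sigma_tc ** 2)
    return amp * s, a * amp * (sigma_tc ** 2 + s ** 2)


def hybrid_decision_variable(d, sigma, omega: float):
    """v = ω/σ² + logistic(|d|): weighted mix of precision and the
    perceived probability of a correct choice."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    return omega / np.asarray(sigma, float) ** 2 + prob_correct(np.abs(d))


def hybrid_thresholds(k_v, sigma, omega: float) -> np.ndarray:
    """|d|-thresholds implied by v-criteria at uncertainty σ.

    A criterion below the attainable range (v ≥ ω/σ² + 0.5) maps to 0;
    one above it (v < ω/σ² + 1) maps to +inf.
    """
    p = np.asarray(k_v, dtype=float) - omega / np.asarray(sigma, float)[..., None] ** 2
    out = np.full(p.shape, np.inf)
    out[p <= 0.5] = 0.0
    mid = (p > 0.5) & (p < 1.0)
    out[mid] = np.log(p[mid] / (1.0 - p[mid]))
    return out


# ---------------------------------------------------------------------------
# MAP orientation estimation

class OrientationEstimator:
    """Lookup-table MAP estimate of orientation under the mixture prior
    p(s) ∝ p(s|C=1) + p(s|C=2), with linear interpolation in (x, log σ).

    The mixture prior is symmetric about 0° in both tasks, so the
    estimate is odd in x and only x ≥ 0 is tabulated.
    """

    def __init__(self, mu: Tuple[float, float], sigma_cat: Tuple[float, float],
                 n_x: int = 500, n_sigma: int = 50,
                 x_max: float = 150.0, sigma_range: Tuple[float, float] = (0.05, 80.0),
                 n_s_grid: int = 1501):
        self.mu = mu
        self.sigma_cat = sigma_cat
        self.x_grid = np.linspace(0.0, x_max, n_x)
        self.log_sigma_grid = np.linspace(math.log(sigma_range[0]),
                                          math.log(sigma_range[1]), n_sigma)
        s_grid = np.linspace(-x_max - 30.0, x_max + 30.0, n_s_grid)
        log_prior = np.log(
            np.exp(-0.5 * (s_grid - mu[0]) ** 2 / sigma_cat[0] ** 2) / sigma_cat[0]
            + np.exp(-0.5 * (s_grid - mu[1]) ** 2 / sigma_cat[1] ** 2) / sigma_cat[1])
        self.s_grid = s_grid
        self.log_prior = log_prior
        table = np.empty((n_sigma, n_x))
        ds = s_grid[1] - s_grid[0]
        for i, lsig in enumerate(self.log_sigma_grid):
            sig2 = math.exp(2 * lsig)
            lp = log_prior[None, :] - 0.5 * (s_grid[None, :]
                                             - self.x_grid[:, None]) ** 2 / sig2
            j = np.argmax(lp, axis=1)
            # quadratic refinement around the grid argmax
            j = np.clip(j, 1, n_s_grid - 2)
            f0, f1, f2 = (lp[np.arange(n_x), j - 1], lp[np.arange(n_x), j],
                          lp[np.arange(n_x), j + 1])
            denom = f0 - 2 * f1 + f2
            shift = np.where(np.abs(denom) > 1e-300,
                             0.5 * (f0 - f2) / denom, 0.0)
            table[i] = s_grid[j] + np.clip(shift, -1.0, 1.0) * ds
        self.table = table
        # monotone cubic over the log-sigma axis: much faster convergence
        # with grid resolution than linear interpolation
        from scipy.interpolate import PchipInterpolator
        self._sigma_interp = PchipInterpolator(self.log_sigma_grid, table,
                                               axis=0, extrapolate=False)

    def _row(self, sigma: float) -> np.ndarray:
        """ŝ(x_grid) at σ, interpolated over the log-σ axis."""
        ls = float(np.clip(math.log(sigma), self.log_sigma_grid[0],
                           self.log_sigma_grid[-1]))
        return self._sigma_interp(ls)

    def estimate(self, x, sigma):
        """MAP estimate ŝ(x, σ); odd in x."""
        x = np.asarray(x, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        out = np.empty(np.broadcast_shapes(x.shape, sigma.shape))
        xb, sb = np.broadcast_arrays(x, sigma)
        for sig in np.unique(sb):
            row = self._row(float(sig))
            mask = sb == sig
            out[mask] = np.sign(xb[mask]) * np.interp(np.abs(xb[mask]),
                                                      self.x_grid, row)
        return out[()]

    def exact_estimate(self, x: float, sigma: float) -> float:
        """ŝ at a single (x, σ) by dense-grid maximization with quadratic
        refinement (no lookup-table interpolation)."""
        lp = self.log_prior - 0.5 * (self.s_grid - x) ** 2 / sigma ** 2
        j = int(np.argmax(lp))
        j = min(max(j, 1), len(lp) - 2)
        f0, f1, f2 = lp[j - 1], lp[j], lp[j + 1]
        denom = f0 - 2 * f1 + f2
        ds = self.s_grid[1] - self.s_grid[0]
        shift = 0.5 * (f0 - f2) / denom if abs(denom) > 1e-300 else 0.0
        return float(self.s_grid[j] + np.clip(shift, -1.0, 1.0) * ds)

    def invert(self, k, sigma: float, refine: bool = True) -> np.ndarray:
        """x values where ŝ(x, σ) crosses the criteria ``k``.

        The tabulated profile brackets each crossing (nearest crossing,
        with a warning, if it is not monotone); bisection on the exact
        estimate then refines it, which keeps boundaries accurate even
        across the discontinuous jumps of a bimodal posterior.
        """
        k = np.atleast_1d(np.asarray(k, dtype=float))
        row = self._row(float(sigma))
        if np.any(np.diff(row) < -1e-6):
            warnings.warn("non-monotone orientation-estimate profile; using "
                          "nearest crossing", RuntimeWarning)
        mono = np.maximum.accumulate(row)
        top = mono[-1]
        out = np.empty_like(k)
        pos = k >= 0
        out[pos] = np.interp(k[pos], mono, self.x_grid)
        out[~pos] = -np.interp(-k[~pos], mono, self.x_grid)
        # linear extrapolation beyond the tabulated estimate range
        slope_inv = ((self.x_grid[-1] - self.x_grid[-2])
                     / max(mono[-1] - mono[-2], 1e-12))
        big = np.abs(k) > top
        out[big] = np.sign(k[big]) * (self.x_grid[-1]
                                      + (np.abs(k[big]) - top) * slope_inv)
        if not refine:
            return out
        h = 2.0 * (self.x_grid[1] - self.x_grid[0])
        for i in range(len(k)):
            if np.abs(k[i]) > top:
                continue  # tail extrapolation region; negligible mass
            lo, hi = out[i] - h, out[i] + h
            f_lo = self.exact_estimate(lo, sigma) - k[i]
            f_hi = self.exact_estimate(hi, sigma) - k[i]
            for _ in range(6):  # expand until the crossing is bracketed
                if f_lo <= 0.0 <= f_hi:
                    break
                if f_lo > 0.0:
                    lo -= h
                    f_lo = self.exact_estimate(lo, sigma) - k[i]
                if f_hi < 0.0:
                    hi += h
                    f_hi = self.exact_estimate(hi, sigma) - k[i]
            if not f_lo <= 0.0 <= f_hi:
                continue
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if self.exact_estimate(mid, sigma) < k[i]:
                    lo = mid
                else:
                    hi = mid
            out[i] = 0.5 * (lo + hi)
        return out


#: default lookup-table resolution (x points, log-sigma points); halving
#: either changes dataset log likelihoods by well under 0.1
OE_DEFAULT_RESOLUTION = (500, 50)


@lru_cache(maxsize=8)
def _cached_estimator(mu, sigma_cat, n_x, n_sigma) -> OrientationEstimator:
    return OrientationEstimator(mu, sigma_cat, n_x=n_x, n_sigma=n_sigma)


def orientation_estimator(task: TaskSpec,
                          beliefs: Optional[CategoryBeliefs] = None,
                          n_x: Optional[int] = None,
                          n_sigma: Optional[int] = None) -> OrientationEstimator:
    b = beliefs or CategoryBeliefs(task.mu, task.sigma_cat, task.log_prior_ratio)
    n_x = n_x if n_x is not None else OE_DEFAULT_RESOLUTION[0]
    n_sigma = n_sigma if n_sigma is not None else OE_DEFAULT_RESOLUTION[1]
    return _cached_estimator(tuple(b.mu), tuple(b.sigma_cat), n_x, n_sigma)


def map_orientation_estimate(x, sigma, task: TaskSpec,
                             beliefs: Optional[CategoryBeliefs] = None):
    """MAP orientation estimate ŝ(x, σ) under the task's mixture prior."""
    return orientation_estimator(task, beliefs).estimate(x, sigma)


# ---------------------------------------------------------------------------
# Unified boundary dispatch (all families whose rule reduces to sorted
# measurement-space boundaries; the hybrid and linear-neural families are
# handled by the likelihood module directly)

def measurement_boundaries(model: ModelSpec, pv: ParamVector, task: TaskSpec,
                           sigma, eta: float = 0.0) -> np.ndarray:
    """Sorted response boundaries in measurement space at uncertainty σ.

    For Task A these are signed x boundaries; for Task B boundaries on
    |x|.  ``eta`` shifts d-space criteria (decision noise).  Shape:
    ``sigma.shape + (n_boundaries,)``.
    """
    sigma = np.asarray(sigma, dtype=float)
    fam = model.family
    if model.is_bayes:
        crit = d_criteria(model, pv, task.task_id) - eta
        beliefs = CategoryBeliefs.from_params(pv, task)
        return bayes_boundaries(task, crit, sigma, beliefs)
    if fam in ("fixed", "lin", "quad"):
        t = task.task_id
        idx = (4,) if model.response_mode == "choice_only" else range(1, 8)
        k = pv.get_array([f"k{t}_{j}" for j in idx])
        m = (pv.get_array([f"m{t}_{j}" for j in idx])
             if fam in ("lin", "quad") else None)
        return heuristic_boundaries(fam, k, m, sigma, t)
    if fam == "orientation_estimation":
        t = task.task_id
        idx = (4,) if model.response_mode == "choice_only" else range(1, 8)
        k = pv.get_array([f"k{t}_{j}" for j in idx])
        beliefs = CategoryBeliefs.from_params(pv, task)
        est = orientation_estimator(task, beliefs)
        flat_sigma = np.atleast_1d(sigma)
        out = np.empty(flat_sigma.shape + (len(k),))
        uniq, inv = np.unique(flat_sigma, return_inverse=True)
        rows = np.stack([est.invert(k, float(sig)) for sig in uniq])
        out = rows[inv].reshape(sigma.shape + (len(k),))
        if t == "B":
            out = np.maximum(out, 0.0)
        return np.sort(out, axis=-1)
    raise ValueError(f"{fam} does not use measurement-space boundaries")
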