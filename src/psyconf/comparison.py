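"""Model-comparison metrics and aggregation.

Point-estimate criteria (AIC, BIC, AICc) are computed from the best
sampled draw; WAIC and PSIS-LOO use the full per-draw per-trial
log-likelihood matrix.  PSIS smooths the largest 20% of importance
ratios with a generalized-Pareto fit (probability-weighted-moments
estimator) and reports the tail-shape diagnostic k-hat per trial.
Scores are aggregated across datasets with a bootstrap over summed
differences from a reference model, and the recovery harness checks
that the generating model wins its own data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .inference import PosteriorSamples, fit_mle
from .params import ModelSpec, ParamVector, PriorSpec, subject_like_params
from .simulate import generate_dataset

__all__ = [
    "information_criteria",
    "waic",
    "psis_loo",
    "score_fit",
    "bootstrap_summed_differences",
    "metric_agreement",
    "RecoveryResult",
    "run_model_recovery",
]


def information_criteria(loglik_at_mle: float, n_params: int,
                         n_trials: int) -> Dict[str, float]:
    """AIC = −2ll + 2n; BIC = −2ll + n log t; AICc adds the small-sample
    correction (undefined, reported as NaN, when t ≤ n + 1)."""
    ll, n, t = float(loglik_at_mle), int(n_params), int(n_trials)
    aic = -2.0 * ll + 2.0 * n
    bic = -2.0 * ll + n * math.log(t)
    if t > n + 1:
        aicc = aic + 2.0 * n * (n + 1) / (t - n - 1)
    else:
        aicc = math.nan
    return {"AIC": aic, "BIC": bic, "AICc": aicc}


def waic(pointwise_ll: np.ndarray) -> Tuple[float, float]:
    """WAIC on the cross-validation scale: lppd − p_waic, with the
    variance-based effective-parameter penalty.  Returns (WAIC, p_waic)."""
    ll = np.asarray(pointwise_ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws x trials) matrix with at least 2 draws")
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(S)))
    p = float(np.sum(ll.var(axis=0, ddof=1)))
    return lppd - p, p


def _gpd_fit_pwm(excess: np.ndarray) -> Tuple[float, float]:
    """Generalized-Pareto (shape xi, scale sigma) fit by probability
    weighted moments (Hosking & Wallis)."""
    x = np.sort(excess)
    n = len(x)
    b0 = x.mean()
    j = np.arange(1, n + 1)
    b1 = np.mean(x * (n - j) / max(n - 1, 1))
    denom = b0 - 2.0 * b1
    if denom <= 0 or b0 <= 0:
        return 0.5, max(b0, 1e-300)  # degenerate tail; heavy-ish fallback
    r = b0 / denom
    k_hw = r - 2.0
    sigma = b0 * (1.0 + k_hw)
    if sigma <= 0:
        return 0.5, max(b0, 1e-300)
    return -k_hw, sigma  # xi = -k in the Hosking-Wallis convention


def _gpd_quantile(p: np.ndarray, xi: float, sigma: float) -> np.ndarray:
    if abs(xi) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / xi * ((1.0 - p) ** (-xi) - 1.0)


def psis_loo(pointwise_ll: np.ndarray,
             khat_warn: float = 0.7) -> Tuple[float, np.ndarray]:
    """PSIS-LOO: leave-one-out log predictive density via Pareto-smoothed
    importance sampling.  Returns (LOO, per-trial k-hat)."""
    ll = np.asarray(pointwise_ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws x trials) matrix with at least 2 draws")
    if not np.all(np.isfinite(ll)):
        bad = np.nonzero(~np.all(np.isfinite(ll), axis=0))[0]
        raise ValueError(f"non-finite log likelihoods for trial(s) {bad[:10].tolist()}")
    S, t = ll.shape
    if S < 100:
        warnings.warn("fewer than 100 posterior draws; PSIS-LOO may be "
                      "unreliable", RuntimeWarning)
    M = int(np.ceil(min(0.2 * S, 3.0 * math.sqrt(S))))
    loo_i = np.empty(t)
    khat = np.empty(t)
    for i in range(t):
        lw = -ll[:, i]
        lw = lw - lw.max()
        order = np.argsort(lw)
        tail_idx = order[-M:]
        cutoff = math.exp(lw[order[-M - 1]]) if M < S else 0.0
        w_tail = np.exp(lw[tail_idx])
        excess = w_tail - cutoff
        if np.all(excess <= 1e-12):
            khat[i] = -np.inf
            lw_s = lw
        else:
            xi, sigma = _gpd_fit_pwm(excess)
            khat[i] = xi
            p = (np.arange(1, M + 1) - 0.5) / M
            smooth = cutoff + _gpd_quantile(p, xi, sigma)
            lw_s = lw.copy()
            lw_s[tail_idx[np.argsort(w_tail)]] = np.log(np.maximum(smooth, 1e-300))
        # truncate smoothed weights at S^{3/4} times the mean weight
        cap = math.log(S) * 0.75 + logsumexp(lw_s) - math.log(S)
        lw_s = np.minimum(lw_s, cap)
        loo_i[i] = logsumexp(lw_s + ll[:, i]) - logsumexp(lw_s)
    n_bad = int(np.sum(khat > khat_warn))
    if n_bad:
        warnings.warn(f"{n_bad} trial(s) with Pareto k-hat above {khat_warn}",
                      RuntimeWarning)
    return float(loo_i.sum()), khat


def score_fit(samples: PosteriorSamples) -> Dict[str, float]:
    """All comparison scores for one fitted model/dataset combination.

    The draw with the highest total log likelihood stands in for the
    MLE when computing AIC/BIC/AICc, as in the original analysis.
    """
    if samples.pointwise_ll is None:
        raise ValueError("PosteriorSamples lacks the pointwise log-likelihood "
                         "matrix")
    ll_draws = samples.pointwise_ll.sum(axis=1)
    ll_best = float(ll_draws.max())
    n_params = samples.draws.shape[1]
    n_trials = samples.pointwise_ll.shape[1]
    out = information_criteria(ll_best, n_params, n_trials)
    w, _ = waic(samples.pointwise_ll)
    loo, khat = psis_loo(samples.pointwise_ll)
    out.update({"WAIC": w, "LOO": loo, "max_khat": float(np.max(khat)),
                "n_params": n_params, "n_trials": n_trials})
    return out


def bootstrap_summed_differences(score_table: pd.DataFrame,
                                 reference_model: str,
                                 n_boot: int = 10_000,
                                 rng: Optional[np.random.Generator] = None,
                                 score: str = "LOO") -> pd.DataFrame:
    """Bootstrap of summed score differences versus a reference model.

    ``score_table`` has one row per (dataset, model) with a score column;
    differences are reference − model (positive = worse than reference).
    Datasets are resampled with replacement ``n_boot`` times and the
    per-resample sums summarized by their median and central 95% CI.
    """
    rng = rng or np.random.default_rng(0)
    wide = score_table.pivot(index="dataset", columns="model", values=score)
    if reference_model not in wide.columns:
        raise ValueError(f"reference model {reference_model!r} not in table")
    if wide.isna().any().any():
        missing = [(d, m) for d in wide.index for m in wide.columns
                   if pd.isna(wide.loc[d, m])]
        raise ValueError(f"missing scores for pairs: {missing[:10]}")
    diffs = wide[reference_model].to_numpy()[:, None] - wide.to_numpy()
    n = len(wide)
    idx = rng.integers(0, n, size=(n_boot, n))
    sums = diffs[idx].sum(axis=1)        # (n_boot, n_models)
    med = np.median(sums, axis=0)
    lo, hi = np.percentile(sums, [2.5, 97.5], axis=0)
    return pd.DataFrame({"model": wide.columns, "median": med,
                         "ci_low": lo, "ci_high": hi}).set_index("model")


def metric_agreement(score_table: pd.DataFrame,
                     metrics: Sequence[str] = ("AIC", "BIC", "AICc", "WAIC", "LOO")
                     ) -> pd.DataFrame:
    """Spearman rank correlation between every pair of comparison metrics
    over all (dataset, model) rows.  Information criteria are put on the
    −IC/2 scale so that higher is better for every metric."""
    if score_table["model"].nunique() < 3:
        raise ValueError("need at least 3 models for metric agreement")
    cols = {}
    for m in metrics:
        v = score_table[m].to_numpy(dtype=float)
        cols[m] = -0.5 * v if m in ("AIC", "BIC", "AICc") else v
    out = pd.DataFrame(np.eye(len(metrics)), index=metrics, columns=metrics)
    names = list(metrics)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = spearmanr(cols[a], cols[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


@dataclass
class RecoveryResult:
    """Confusion matrix of a model-recovery run: generators as rows,
    fitters as columns, cells holding mean ΔAIC from the row minimum."""

    mean_delta_aic: pd.DataFrame
    selection_rate: float
    n_datasets: int
    n_failed: int = 0
    raw_scores: Optional[pd.DataFrame] = None

    def diagonal_dominant(self) -> bool:
        m = self.mean_delta_aic
        return all(m.loc[g, g] <= m.loc[g].min() + 1e-9 for g in m.index)


def _embedded_start(fitter: ModelSpec, base: Optional[ParamVector],
                    rng: np.random.Generator) -> ParamVector:
    """Warm start for a measurement-space fitter from a nested fit:
    shared parameters copied, slopes zeroed, the rest subject-like."""
    from .params import param_specs
    sub = subject_like_params(fitter, rng).natural_dict()
    base_vals = base.natural_dict() if base is not None else {}
    vals = {}
    for p in param_specs(fitter):
        if p.block == "slope":
            vals[p.name] = 0.0
        elif p.name in base_vals:
            vals[p.name] = base_vals[p.name]
        else:
            vals[p.name] = sub[p.name]
    return ParamVector.from_dict(fitter, vals)


def run_model_recovery(model_set: Sequence[ModelSpec],
                       parameter_source: Optional[Callable] = None,
                       n_datasets_per_model: int = 4,
                       structure=None, tasks=None, seed: int = 0,
                       n_restarts: int = 2, maxiter: int = 150,
                       priors: Optional[Dict[str, PriorSpec]] = None
                       ) -> RecoveryResult:
    """Generate datasets from each model, fit every model to every
    dataset by maximum likelihood, score with AIC, and tabulate whether
    the generating model wins its own data.

    Measurement-space boundary families are fitted in nested order
    (Fixed before Lin/Quad) so the constant-boundary solution warm-starts
    its supermodels; this equalizes optimization quality across fitters.
    """
    from .tasks import SessionStructure, task_a, task_b

    structure = structure or SessionStructure()
    if tasks is None:
        tasks = [task_a(), task_b()]
    parameter_source = parameter_source or subject_like_params
    rng = np.random.default_rng(seed)
    meas_fams = ("fixed", "lin", "quad")
    fit_order = sorted(model_set,
                       key=lambda m: (m.family != "fixed", m.family))
    records = []
    n_failed = 0
    for gen in model_set:
        for rep in range(n_datasets_per_model):
            pv = parameter_source(gen, rng)
            ds = generate_dataset(tasks, structure, gen, pv,
                                  seed=int(rng.integers(2 ** 31)),
                                  subject_id=f"{gen.name}-{rep}")
            fixed_mle: Optional[ParamVector] = None
            for fitter in fit_order:
                pr = (priors or {}).get(fitter.name) or PriorSpec.for_model(fitter)
                if fitter.family in meas_fams and fixed_mle is not None:
                    # supermodels of Fixed: the nested warm start alone is
                    # a better use of the budget than extra random starts
                    starts = [_embedded_start(fitter, fixed_mle, rng).values]
                else:
                    starts = [subject_like_params(fitter, rng).values
                              for _ in range(n_restarts)]
                try:
                    mle, ll = fit_mle(fitter, ds, bounds=pr, starts=starts,
                                      maxiter=maxiter, rng=rng)
                except RuntimeError as exc:
                    warnings.warn(f"fit of {fitter.name} to {ds.subject_id} "
                                  f"failed: {exc}", RuntimeWarning)
                    n_failed += 1
                    continue
                if fitter.family == "fixed":
                    fixed_mle = mle
                n_p = len(mle.values)
                aic = information_criteria(ll, n_p, len(ds.testing()))["AIC"]
                records.append({"dataset": ds.subject_id, "generator": gen.name,
                                "fitter": fitter.name, "AIC": aic, "ll": ll,
                                "n_params": n_p})
    raw = pd.DataFrame(records)
    mean_aic = raw.pivot_table(index="generator", columns="fitter",
                               values="AIC", aggfunc="mean")
    delta = mean_aic.sub(mean_aic.min(axis=1), axis=0)
    wins = 0
    total = 0
    for ds_id, grp in raw.groupby("dataset"):
        if len(grp) < len(model_set):
            continue
        total += 1
        best = grp.loc[grp["AIC"].idxmin(), "fitter"]
        if best == grp["generator"].iloc[0]:
            wins += 1
    rate = wins / total if total else float("nan")
    return RecoveryResult(mean_delta_aic=delta, selection_rate=rate,
                          n_datasets=total, n_failed=n_failed, raw_scores=raw)
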