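"""Synthetic behavioral datasets with the experiments' session structure.

A generated dataset reproduces the block arithmetic of the experiments
(category-training, confidence-training and testing blocks per task per
session) and draws every testing trial from the full generative model:
category → stimulus → reliability → noisy measurement → observer
response with lapses.  Responses come from any registered observer
model, so the simulator and the analytic likelihood can be checked
against each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import observers as obs
from .likelihood import LapseParams
from .params import ModelSpec, ParamVector
from .responses import choice_confidence_to_response, response_to_choice, \
    response_to_confidence
from .tasks import SessionStructure, TaskSpec, structure_counts

__all__ = ["Dataset", "generate_dataset", "sample_responses", "CSV_COLUMNS"]

CSV_COLUMNS = ["subject_id", "experiment", "phase", "session", "block", "trial",
               "task", "true_category", "orientation_deg", "reliability_level",
               "reliability_value", "response", "chosen_category", "confidence"]


@dataclass
class Dataset:
    """Ordered trials of one subject plus provenance when synthetic."""

    trials: pd.DataFrame
    subject_id: str = "S1"
    experiment_id: int = 1
    provenance: Optional[dict] = None

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")

    def testing(self) -> pd.DataFrame:
        """Testing-phase trials (the unit of all likelihood evaluation;
        training trials are never analyzed)."""
        df = self.trials
        return df[df["phase"] == "testing"].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.trials)

    def to_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        self.trials.to_csv(path, index=False)
        if self.provenance is not None:
            sidecar = path.with_suffix(".provenance.json")
            sidecar.write_text(json.dumps(self.provenance, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else None
        subject = str(df["subject_id"].iloc[0]) if len(df) else "S1"
        exp = int(df["experiment"].iloc[0]) if len(df) else 1
        return cls(df, subject_id=subject, experiment_id=exp, provenance=prov)


def sample_responses(model: ModelSpec, pv: ParamVector, task: TaskSpec,
                     s: np.ndarray, reliability_values: np.ndarray,
                     rng: np.random.Generator, prev_response: int = 0
                     ) -> np.ndarray:
    """Sample response codes for given stimuli and reliabilities.

    Draws, in order: the measurement x ~ N(s, σ(c,s)²), the decision
    noise (d-noise families), and the lapse mixture.  Returns codes in
    1..8 (choice-only models emit confidence level 1, i.e. codes 4/5).
    """
    s = np.asarray(s, dtype=float)
    c = np.asarray(reliability_values, dtype=float)
    n = len(s)
    sigma_m = np.broadcast_to(np.asarray(
        obs.sigma_of(obs.NoiseParams.from_params(pv, task), c, s), float), s.shape)
    if model.noise_split:
        sigma_i = np.broadcast_to(np.asarray(obs.sigma_of(
            obs.NoiseParams.from_params(pv, task, believed=True), c, s),
            float), s.shape)
    else:
        sigma_i = sigma_m

    x = rng.normal(s, sigma_m)
    tid = task.task_id
    fam = model.family
    choice_only = model.response_mode == "choice_only"

    if fam == "linear_neural":
        mean_z, var_z = obs.linear_neural_moments(s, sigma_m, pv.get("a"),
                                                  pv.get("sigma_tc"))
        z = rng.normal(mean_z, np.sqrt(var_z))
        idx = (4,) if choice_only else range(1, 8)
        k = pv.get_array([f"k{tid}_{j}" for j in idx])
        if tid == "B":
            k = np.maximum(k, 0.0)
        k = np.sort(k)
        v = np.abs(z) if tid == "B" else z
        core = np.sum(v[:, None] > k[None, :], axis=1) + 1
        if choice_only:
            core = np.where(core == 1, 4, 5)
    elif fam == "precision_hybrid":
        beliefs = obs.CategoryBeliefs.from_params(pv, task)
        d = obs.log_posterior_ratio(task, x, sigma_i, beliefs)
        if model.d_noise:
            d = d + rng.normal(0.0, pv.get("sigma_d"), size=n)
        cat = np.where(d > pv.get("k_4"), 1, 2)
        if choice_only:
            conf = np.ones(n, dtype=int)
        else:
            t = obs.hybrid_thresholds(pv.get_array(["k_1", "k_2", "k_3"]),
                                      sigma_i, pv.get("omega"))
            conf = 1 + np.sum(np.abs(d)[:, None] > t, axis=1)
        core = choice_confidence_to_response(cat, conf)
    else:
        if model.is_bayes and model.d_noise:
            eta = rng.normal(0.0, pv.get("sigma_d"), size=n)
            crit = obs.d_criteria(model, pv, tid)
            beliefs = obs.CategoryBeliefs.from_params(pv, task)
            b = obs.bayes_boundaries(task, crit[None, :] - eta[:, None],
                                     sigma_i, beliefs)
        else:
            b = obs.measurement_boundaries(model, pv, task, sigma_i)
        v = np.abs(x) if tid == "B" else x
        core = np.sum(v[:, None] > b, axis=1) + 1
        if choice_only:
            core = np.where(core == 1, 4, 5)  # category only, confidence 1

    return _sample_lapses(model, pv, core.astype(int), rng, prev_response)


def _sample_lapses(model: ModelSpec, pv: ParamVector, core: np.ndarray,
                   rng: np.random.Generator, prev_response: int) -> np.ndarray:
    lp = LapseParams.from_params(pv)
    n = len(core)
    u = rng.random(n)
    cat_rand = rng.integers(1, 3, size=n)
    conf_full = rng.choice(4, size=n, p=lp.confidence_weights()) + 1
    conf_rand = rng.integers(1, 5, size=n)

    choice_only = model.response_mode == "choice_only"
    lam_f, lam_c, lam_r = lp.lambda_full, lp.lambda_conf, lp.lambda_repeat
    out = core.copy()
    if choice_only:
        full_resp = np.where(cat_rand == 1, 4, 5)
    else:
        full_resp = choice_confidence_to_response(cat_rand, conf_full)
        conf_resp = choice_confidence_to_response(response_to_choice(core),
                                                  conf_rand)
    # components: [0, lam_f) full, [lam_f, lam_f+lam_c) confidence,
    # [lam_f+lam_c, lam_f+lam_c+lam_r) repeat, rest core
    is_full = u < lam_f
    is_conf = (~is_full) & (u < lam_f + lam_c) & (not choice_only)
    is_rep = (~is_full) & (u < lam_f + lam_c + lam_r) & ~is_conf
    if prev_response == 0 and n > 0 and is_rep[0]:
        # no predecessor: redistribute the repeat mass proportionally
        u0 = (u[0] - lam_f - lam_c) / max(lam_r, 1e-300) * (1.0 - lam_r)
        is_rep[0] = False
        is_full[0] = u0 < lam_f
        if not choice_only:
            is_conf[0] = (not is_full[0]) and u0 < lam_f + lam_c
    out[is_full] = full_resp[is_full]
    if not choice_only:
        out[is_conf] = conf_resp[is_conf]
    if is_rep.any():
        prev = prev_response
        for i in range(n):
            if is_rep[i]:
                out[i] = prev if prev > 0 else out[i]
            prev = out[i]
    return out


def _block_order(structure: SessionStructure):
    """Within-session block sequence per task: category training and
    testing alternate; confidence training follows the first category
    training block."""
    n_ct, ct_len = structure.category_training_blocks
    n_cf, cf_len = structure.confidence_training_blocks
    n_te, te_len = structure.testing_blocks
    seq = []
    n_pairs = max(n_ct, n_te)
    for i in range(n_pairs):
        if i < n_ct:
            seq.append(("category_training", ct_len))
        if i == 0:
            seq += [("confidence_training", cf_len)] * n_cf
        if i < n_te:
            seq.append(("testing", te_len))
    return seq


def generate_dataset(task_or_tasks, structure: SessionStructure,
                     model: ModelSpec, params: ParamVector,
                     seed: Union[int, np.random.Generator],
                     subject_id: str = "S1", experiment_id: int = 1) -> Dataset:
    """Simulate one subject: structure-faithful training and testing
    blocks, responses from the given observer model.  Reproducible given
    the seed (bitwise on the CSV serialization)."""
    if params.model != model:
        raise ValueError("params were built for a different model")
    params.validate()
    if isinstance(task_or_tasks, TaskSpec):
        tasks = {task_or_tasks.task_id: task_or_tasks}
    else:
        tasks = {t.task_id: t for t in task_or_tasks}
    for tid in structure.tasks_per_session:
        if tid not in tasks:
            raise ValueError(f"structure references task {tid!r} not provided")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    rows = []
    trial_no = 0
    prev_response = 0
    for session in range(1, structure.n_sessions + 1):
        for tid in structure.tasks_per_session:
            task = tasks[tid]
            rv = np.asarray(task.reliability_values, dtype=float)
            for block_idx, (phase, n) in enumerate(_block_order(structure), 1):
                cat = np.where(rng.random(n) < task.prior_c1, 1, 2)
                mu = np.asarray(task.mu)[cat - 1]
                sd = np.asarray(task.sigma_cat)[cat - 1]
                s = rng.normal(mu, sd)
                if phase == "category_training":
                    level = np.full(n, 6)
                else:
                    level = rng.integers(1, 7, size=n)
                c = rv[level - 1]
                resp = sample_responses(model, params, task, s, c, rng,
                                        prev_response)
                prev_response = int(resp[-1]) if n else prev_response
                block = pd.DataFrame({
                    "subject_id": subject_id,
                    "experiment": experiment_id,
                    "phase": phase,
                    "session": session,
                    "block": block_idx,
                    "trial": np.arange(trial_no + 1, trial_no + n + 1),
                    "task": tid,
                    "true_category": cat,
                    "orientation_deg": s,
                    "reliability_level": level,
                    "reliability_value": c,
                    "response": resp,
                    "chosen_category": response_to_choice(resp),
                    "confidence": response_to_confidence(resp),
                })
                rows.append(block)
                trial_no += n
    df = pd.concat(rows, ignore_index=True)[CSV_COLUMNS]

    counts = structure_counts(structure)
    got = df["phase"].value_counts().to_dict()
    for phase, expect in counts.items():
        if got.get(phase, 0) != expect:
            raise RuntimeError(f"{phase} count {got.get(phase, 0)} != {expect}")

    provenance = {
        "model": model.name,
        "params": params.natural_dict(),
        "seed": int(seed) if not isinstance(seed, np.random.Generator) else None,
    }
    return Dataset(df, subject_id=subject_id, experiment_id=experiment_id,
                   provenance=provenance)
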