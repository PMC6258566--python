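"""Observer-model specifications, parameter vectors, and priors.

Every observer model is described by a :class:`ModelSpec` (family plus
structural flags) which deterministically expands into an ordered list
of :class:`ParamSpec` entries — the free parameters, their blocks, prior
ranges and sampling scales.  Standard-deviation-like parameters are
sampled in log space and exponentiated when the likelihood is evaluated,
so every prior is uniform on the sampling scale and the prior box is a
simple hyper-rectangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIES",
    "BAYES_FAMILIES",
    "ModelSpec",
    "ParamSpec",
    "ParamVector",
    "PriorSpec",
    "param_specs",
    "parameter_table",
    "get_model",
    "MODEL_REGISTRY",
    "subject_like_params",
]

FAMILIES: Tuple[str, ...] = (
    "bayes_ultrastrong",
    "bayes_strong",
    "bayes_weak",
    "fixed",
    "lin",
    "quad",
    "orientation_estimation",
    "linear_neural",
    "precision_hybrid",
)

#: Families whose decision variable is the log posterior ratio d.
BAYES_FAMILIES = ("bayes_ultrastrong", "bayes_strong", "bayes_weak")

# default prior ranges (natural scale); "log" parameters are sampled as log(value)
_SD_RANGE = (0.1, 50.0)          # degrees, all s.d.-like parameters
_K_BAYES = (-20.0, 20.0)         # criteria on d
_K_MEAS = (-90.0, 90.0)          # criteria / slopes in measurement space (degrees)
_K_Z = (-1.0e4, 1.0e4)           # criteria on the neural readout z
_K_V = (0.0, 1.0e3)              # criteria on the hybrid decision variable v
_BETA_RANGE = (0.1, 10.0)        # power-law curvature
_PSI_RANGE = (0.0, 10.0)         # orientation-dependent noise amplitude (degrees)
_SIGMA_D_RANGE = (0.01, 10.0)    # s.d. of decision noise on d (log-sampled)
_OMEGA_RANGE = (0.0, 100.0)      # precision weight in the hybrid model
_A_RANGE = (0.01, 100.0)         # neural readout weight scale (log-sampled)
_LAPSE_RANGE = (0.0, 0.3)
_ENDPOINT_RANGE = (0.0, 1.0)
_LOG_PRIOR_RANGE = (-3.0, 3.0)


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one observer model."""

    family: str
    d_noise: bool = False
    free_category_params: bool = False
    noise_split: bool = False
    nonparam_sigma: bool = False
    fit_scope: str = "jointAB"                # jointAB | taskA | taskB
    response_mode: str = "choice_confidence"  # choice_confidence | choice_only

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.fit_scope not in ("jointAB", "taskA", "taskB"):
            raise ValueError(f"invalid fit_scope {self.fit_scope!r}")
        if self.response_mode not in ("choice_confidence", "choice_only"):
            raise ValueError(f"invalid response_mode {self.response_mode!r}")
        if self.d_noise and self.family not in BAYES_FAMILIES + ("precision_hybrid",):
            raise ValueError("d_noise is only valid for Bayes families and "
                             "precision_hybrid")
        if self.free_category_params and self.family in (
                "fixed", "lin", "quad", "linear_neural"):
            raise ValueError("free_category_params requires a model that uses the "
                             "category distributions")

    @property
    def tasks(self) -> Tuple[str, ...]:
        return {"jointAB": ("A", "B"), "taskA": ("A",), "taskB": ("B",)}[self.fit_scope]

    @property
    def is_bayes(self) -> bool:
        return self.family in BAYES_FAMILIES

    @property
    def name(self) -> str:
        """Canonical registry name, e.g. ``bayes_weak_dn``."""
        parts = [self.family]
        if self.d_noise:
            parts.append("dn")
        if self.free_category_params:
            parts.append("freecat")
        if self.noise_split:
            parts.append("split")
        if self.nonparam_sigma:
            parts.append("nonparam")
        if self.response_mode == "choice_only":
            parts.append("choice")
        if self.fit_scope == "taskA":
            parts.append("taska")
        elif self.fit_scope == "taskB":
            parts.append("taskb")
        return "_".join(parts)

    def n_boundary_params(self) -> int:
        return sum(1 for p in param_specs(self) if p.block in ("boundary", "slope"))

    def to_json(self) -> str:
        import json
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "ModelSpec":
        import json
        return cls(**json.loads(payload))


@dataclass(frozen=True)
class ParamSpec:
    """One free parameter: prior range on the natural scale plus sampling scale."""

    name: str
    block: str
    low: float
    high: float
    scale: str = "uniform"  # uniform | log

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: lower bound must be below upper")
        if self.scale not in ("uniform", "log"):
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log-scale parameters need low > 0")

    @property
    def sampling_bounds(self) -> Tuple[float, float]:
        if self.scale == "log":
            return math.log(self.low), math.log(self.high)
        return self.low, self.high

    def to_natural(self, u: float) -> float:
        return math.exp(u) if self.scale == "log" else u

    def to_sampling(self, v: float) -> float:
        return math.log(v) if self.scale == "log" else v


def _noise_specs(model: ModelSpec, suffix: str = "") -> list:
    specs = []
    if model.nonparam_sigma:
        for lev in range(1, 7):
            specs.append(ParamSpec(f"sigma_rel_{lev}{suffix}", "noise",
                                   *_SD_RANGE, "log"))
    else:
        specs.append(ParamSpec(f"sigma_low{suffix}", "noise", *_SD_RANGE, "log"))
        specs.append(ParamSpec(f"sigma_high{suffix}", "noise", *_SD_RANGE, "log"))
        specs.append(ParamSpec(f"beta{suffix}", "noise", *_BETA_RANGE))
    if model.family != "precision_hybrid":
        # orientation-dependent noise is used by all families except the hybrid
        specs.append(ParamSpec(f"psi{suffix}", "noise", *_PSI_RANGE))
    return specs


def _boundary_specs(model: ModelSpec) -> list:
    fam, tasks = model.family, model.tasks
    specs: list = []
    choice_only = model.response_mode == "choice_only"

    def meas(prefix: str, rng=_K_MEAS) -> list:
        idx = (4,) if choice_only else range(1, 8)
        return [ParamSpec(f"{prefix}_{j}", "boundary", *rng) for j in idx]

    if fam == "bayes_ultrastrong" or fam == "precision_hybrid":
        if fam == "precision_hybrid":
            if not choice_only:
                specs += [ParamSpec(f"k_{j}", "boundary", *_K_V) for j in (1, 2, 3)]
            specs.append(ParamSpec("k_4", "boundary", *_K_BAYES))
        else:
            idx = (4,) if choice_only else (1, 2, 3, 4)
            specs += [ParamSpec(f"k_{j}", "boundary", *_K_BAYES) for j in idx]
    elif fam == "bayes_strong":
        for t in tasks:
            idx = (4,) if choice_only else (1, 2, 3, 4)
            specs += [ParamSpec(f"k{t}_{j}", "boundary", *_K_BAYES) for j in idx]
    elif fam == "bayes_weak":
        if "A" in tasks:
            idx = (4,) if choice_only else (1, 2, 3, 4)
            specs += [ParamSpec(f"kA_{j}", "boundary", *_K_BAYES) for j in idx]
        if "B" in tasks:
            idx = (4,) if choice_only else range(1, 8)
            specs += [ParamSpec(f"kB_{j}", "boundary", *_K_BAYES) for j in idx]
    elif fam in ("fixed", "lin", "quad", "orientation_estimation"):
        for t in tasks:
            specs += meas(f"k{t}")
        if fam in ("lin", "quad"):
            for t in tasks:
                idx = (4,) if choice_only else range(1, 8)
                specs += [ParamSpec(f"m{t}_{j}", "slope", *_K_MEAS) for j in idx]
    elif fam == "linear_neural":
        for t in tasks:
            specs += meas(f"k{t}", _K_Z)
    return specs


def _lapse_specs(model: ModelSpec) -> list:
    if model.response_mode == "choice_only":
        return [ParamSpec("lambda_full", "lapse", *_LAPSE_RANGE),
                ParamSpec("lambda_repeat", "lapse", *_LAPSE_RANGE)]
    return [ParamSpec("lambda_full", "lapse", *_LAPSE_RANGE),
            ParamSpec("lambda_1", "lapse", *_ENDPOINT_RANGE),
            ParamSpec("lambda_4", "lapse", *_ENDPOINT_RANGE),
            ParamSpec("lambda_conf", "lapse", *_LAPSE_RANGE),
            ParamSpec("lambda_repeat", "lapse", *_LAPSE_RANGE)]


def param_specs(model: ModelSpec) -> Tuple[ParamSpec, ...]:
    """Ordered free-parameter list for one model."""
    specs = _noise_specs(model)
    if model.noise_split:
        specs += _noise_specs(model, suffix="_inf")
    specs += _boundary_specs(model)
    if model.free_category_params:
        if "A" in model.tasks:
            specs.append(ParamSpec("sigma_c_a", "category_beliefs", *_SD_RANGE, "log"))
        if "B" in model.tasks:
            specs.append(ParamSpec("sigma_1_b", "category_beliefs", *_SD_RANGE, "log"))
            specs.append(ParamSpec("sigma_2_b", "category_beliefs", *_SD_RANGE, "log"))
        specs.append(ParamSpec("prior_log_ratio", "category_beliefs",
                               *_LOG_PRIOR_RANGE))
    if model.d_noise:
        specs.append(ParamSpec("sigma_d", "extra", *_SIGMA_D_RANGE, "log"))
    if model.family == "precision_hybrid":
        specs.append(ParamSpec("omega", "extra", *_OMEGA_RANGE))
    if model.family == "linear_neural":
        specs.append(ParamSpec("a", "extra", *_A_RANGE, "log"))
        specs.append(ParamSpec("sigma_tc", "extra", *_SD_RANGE, "log"))
    specs += _lapse_specs(model)
    return tuple(specs)


def parameter_table(model: ModelSpec) -> pd.DataFrame:
    """Export the parameter list (name, block, prior range, scale) as a table."""
    rows = [{"name": p.name, "block": p.block, "lower": p.low,
             "upper": p.high, "scale": p.scale} for p in param_specs(model)]
    return pd.DataFrame(rows, columns=["name", "block", "lower", "upper", "scale"])


class PriorSpec:
    """Factorized box prior: uniform per parameter on its sampling scale
    (log-uniform on the natural scale for log-sampled parameters)."""

    def __init__(self, specs: Sequence[ParamSpec]):
        self.specs = tuple(specs)
        bounds = np.array([p.sampling_bounds for p in self.specs], dtype=float)
        self.low = bounds[:, 0]
        self.high = bounds[:, 1]
        self._log_const = float(-np.sum(np.log(self.high - self.low)))

    @classmethod
    def for_model(cls, model: ModelSpec,
                  overrides: Optional[Mapping[str, Tuple[float, float]]] = None
                  ) -> "PriorSpec":
        specs = param_specs(model)
        if overrides:
            specs = tuple(
                replace(p, low=overrides[p.name][0], high=overrides[p.name][1])
                if p.name in overrides else p
                for p in specs)
        return cls(specs)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(p.name for p in self.specs)

    def contains(self, values: np.ndarray) -> bool:
        v = np.asarray(values, dtype=float)
        return bool(np.all(v >= self.low) and np.all(v <= self.high))

    def log_pdf(self, values: np.ndarray) -> float:
        """Log prior density of a sampling-scale parameter vector."""
        return self._log_const if self.contains(values) else -np.inf

    def sample(self, rng: np.random.Generator, n: Optional[int] = None) -> np.ndarray:
        size = (len(self.specs),) if n is None else (n, len(self.specs))
        return rng.uniform(self.low, self.high, size=size)


@dataclass
class ParamVector:
    """Free-parameter values for one model, stored on the sampling scale."""

    model: ModelSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.specs = param_specs(self.model)
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.shape != (len(self.specs),):
            raise ValueError(
                f"expected {len(self.specs)} values for {self.model.name}, "
                f"got shape {self.values.shape}")
        self._index = {p.name: i for i, p in enumerate(self.specs)}

    @classmethod
    def from_dict(cls, model: ModelSpec, mapping: Mapping[str, float],
                  natural: bool = True) -> "ParamVector":
        specs = param_specs(model)
        missing = [p.name for p in specs if p.name not in mapping]
        if missing:
            raise ValueError(f"missing parameters for {model.name}: {missing}")
        extra = set(mapping) - {p.name for p in specs}
        if extra:
            raise ValueError(f"unknown parameters for {model.name}: {sorted(extra)}")
        vals = np.array([
            p.to_sampling(mapping[p.name]) if natural else mapping[p.name]
            for p in specs])
        return cls(model, vals)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def get(self, name: str) -> float:
        """Natural-scale value of one parameter."""
        i = self._index[name]
        return self.specs[i].to_natural(self.values[i])

    def get_array(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.get(n) for n in names])

    def natural_dict(self) -> Dict[str, float]:
        return {p.name: self.get(p.name) for p in self.specs}

    def with_values(self, values: np.ndarray) -> "ParamVector":
        return ParamVector(self.model, values)

    def validate(self, priors: Optional[PriorSpec] = None) -> None:
        """Raise ValueError naming the offending block(s) if any parameter
        falls outside its prior range."""
        priors = priors or PriorSpec(self.specs)
        bad = [(p.name, p.block) for p, v, lo, hi in
               zip(self.specs, self.values, priors.low, priors.high)
               if not (lo <= v <= hi) or not np.isfinite(v)]
        if bad:
            blocks = sorted({b for _, b in bad})
            names = [n for n, _ in bad]
            raise ValueError(
                f"parameters outside prior range in block(s) {blocks}: {names}")


# ---------------------------------------------------------------------------
# Registry

def _spec(**kw) -> ModelSpec:
    return ModelSpec(**kw)


MODEL_REGISTRY: Dict[str, ModelSpec] = {}
for _fam in FAMILIES:
    MODEL_REGISTRY[_fam] = _spec(family=_fam)
for _fam in BAYES_FAMILIES + ("precision_hybrid",):
    MODEL_REGISTRY[_fam + "_dn"] = _spec(family=_fam, d_noise=True)
MODEL_REGISTRY["bayes"] = MODEL_REGISTRY["bayes_weak"]
MODEL_REGISTRY["bayes_dn"] = MODEL_REGISTRY["bayes_weak_dn"]

_SUFFIX_FLAGS = {
    "dn": {"d_noise": True},
    "freecat": {"free_category_params": True},
    "split": {"noise_split": True},
    "nonparam": {"nonparam_sigma": True},
    "choice": {"response_mode": "choice_only"},
    "taska": {"fit_scope": "taskA"},
    "taskb": {"fit_scope": "taskB"},
}


def get_model(name: str, **overrides) -> ModelSpec:
    """Resolve a canonical model name (e.g. ``quad``, ``bayes_weak_dn``,
    ``lin_choice_taskb``) to a :class:`ModelSpec`."""
    key = name.lower()
    if key in MODEL_REGISTRY and not overrides:
        return MODEL_REGISTRY[key]
    tokens = key.split("_")
    flags: Dict[str, object] = {}
    while tokens and tokens[-1] in _SUFFIX_FLAGS:
        flags.update(_SUFFIX_FLAGS[tokens.pop()])
    base = "_".join(tokens)
    if base in MODEL_REGISTRY:
        base_spec = MODEL_REGISTRY[base]
        kw = {**base_spec.__dict__, **flags, **overrides}
        return ModelSpec(**kw)
    raise KeyError(f"unknown model name {name!r}")


# ---------------------------------------------------------------------------
# Behaviorally plausible generating parameters

def subject_like_params(model: ModelSpec, rng: np.random.Generator) -> ParamVector:
    """Draw generating parameters from narrow, behaviorally plausible ranges.

    Used by the model-recovery harness and the simulation oracles: values
    resemble those recovered from trained human observers (noise of a few
    degrees falling with reliability, ordered criteria spanning the
    stimulus range, lapse rates of a few percent) rather than arbitrary
    points of the much wider prior box.
    """
    vals: Dict[str, float] = {}
    jit = lambda lo, hi: float(rng.uniform(lo, hi))

    def noise_block(suffix: str) -> None:
        s_lo, s_hi = jit(4.0, 8.0), jit(0.8, 2.0)
        if model.nonparam_sigma:
            levels = np.exp(np.linspace(np.log(s_lo), np.log(s_hi), 6))
            for lev in range(1, 7):
                vals[f"sigma_rel_{lev}{suffix}"] = float(levels[lev - 1])
        else:
            vals[f"sigma_low{suffix}"] = s_lo
            vals[f"sigma_high{suffix}"] = s_hi
            vals[f"beta{suffix}"] = jit(0.5, 2.0)
        if model.family != "precision_hybrid":
            vals[f"psi{suffix}"] = jit(0.0, 0.5)

    noise_block("")
    if model.noise_split:
        noise_block("_inf")

    choice_only = model.response_mode == "choice_only"

    def d_criteria(prefix: str, symmetric: bool) -> None:
        k4 = float(rng.normal(0.0, 0.3))
        if choice_only:
            vals[f"{prefix}_4"] = k4
            return
        t = np.sort(rng.uniform(0.2, 3.0, size=3))
        vals[f"{prefix}_4"] = k4
        for j, tj in zip((3, 2, 1), t):
            vals[f"{prefix}_{j}"] = k4 - tj
        if not symmetric:
            t2 = np.sort(rng.uniform(0.2, 3.0, size=3))
            for j, tj in zip((5, 6, 7), t2):
                vals[f"{prefix}_{j}"] = k4 + tj

    def meas_criteria_a(prefix: str, scale: float = 1.0, center_sd: float = 1.0) -> None:
        c4 = float(rng.normal(0.0, center_sd))
        if choice_only:
            vals[f"{prefix}_4"] = c4
            return
        off = np.sort(rng.uniform(1.5, 4.5, size=3)).cumsum() * scale
        vals[f"{prefix}_4"] = c4
        for j, oj in zip((3, 2, 1), off):
            vals[f"{prefix}_{j}"] = c4 - oj
        off2 = np.sort(rng.uniform(1.5, 4.5, size=3)).cumsum() * scale
        for j, oj in zip((5, 6, 7), off2):
            vals[f"{prefix}_{j}"] = c4 + oj

    def meas_criteria_b(prefix: str, scale: float = 1.0) -> None:
        if choice_only:
            vals[f"{prefix}_4"] = jit(4.0, 7.0) * scale
            return
        ks = np.sort(rng.uniform(1.0, 16.0, size=7)) * scale
        for j in range(1, 8):
            vals[f"{prefix}_{j}"] = float(ks[j - 1])

    fam = model.family
    if fam in ("bayes_ultrastrong",):
        d_criteria("k", symmetric=True)
    elif fam == "bayes_strong":
        for t in model.tasks:
            d_criteria(f"k{t}", symmetric=True)
    elif fam == "bayes_weak":
        if "A" in model.tasks:
            d_criteria("kA", symmetric=True)
        if "B" in model.tasks:
            d_criteria("kB", symmetric=False)
    elif fam == "precision_hybrid":
        vals["omega"] = jit(0.0, 2.0)
        if not choice_only:
            kv = np.sort(rng.uniform(0.55, 1.4, size=3))
            for j in (1, 2, 3):
                vals[f"k_{j}"] = float(kv[j - 1])
        vals["k_4"] = float(rng.normal(0.0, 0.2))
    elif fam in ("fixed", "lin", "quad", "orientation_estimation"):
        if "A" in model.tasks:
            meas_criteria_a("kA")
        if "B" in model.tasks:
            meas_criteria_b("kB")
        if fam in ("lin", "quad"):
            unit = 0.4 if fam == "lin" else 0.06
            idx = (4,) if choice_only else range(1, 8)
            for t in model.tasks:
                for j in idx:
                    if t == "A":
                        sign = (j - 4) if j != 4 else rng.uniform(-0.6, 0.6)
                    else:
                        sign = max(j, 1)
                    vals[f"m{t}_{j}"] = float(sign * rng.uniform(0.2, 1.0) * unit)
    elif fam == "linear_neural":
        vals["a"] = jit(0.5, 2.0)
        vals["sigma_tc"] = jit(5.0, 20.0)
        # typical z scale at mid reliability for these draws
        z0 = vals["a"] * 0.25 * math.sqrt(2 * math.pi * vals["sigma_tc"] ** 2)
        if "A" in model.tasks:
            meas_criteria_a("kA", scale=z0 / 2.0, center_sd=z0)
        if "B" in model.tasks:
            meas_criteria_b("kB", scale=z0 / 2.0)

    if model.free_category_params:
        if "A" in model.tasks:
            vals["sigma_c_a"] = 5.0 * jit(0.8, 1.25)
        if "B" in model.tasks:
            vals["sigma_1_b"] = 3.0 * jit(0.8, 1.25)
            vals["sigma_2_b"] = 12.0 * jit(0.8, 1.25)
        vals["prior_log_ratio"] = float(rng.normal(0.0, 0.1))
    if model.d_noise:
        vals["sigma_d"] = jit(0.3, 1.2)

    if choice_only:
        vals["lambda_full"] = jit(0.005, 0.05)
        vals["lambda_repeat"] = jit(0.0, 0.03)
    else:
        vals["lambda_full"] = jit(0.005, 0.03)
        vals["lambda_1"] = jit(0.3, 0.7)
        vals["lambda_4"] = jit(0.1, 0.4)
        vals["lambda_conf"] = jit(0.005, 0.05)
        vals["lambda_repeat"] = jit(0.0, 0.03)
    return ParamVector.from_dict(model, vals)
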