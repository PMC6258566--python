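"""Task specifications for the two orientation-categorization tasks.

Two equiprobable categories generate stimulus orientations (degrees;
0° = horizontal, positive = rightward tilt).  In Task A the categories
differ in mean (±4°, common s.d. 5°); category 1 is the leftward
category.  In Task B they share a mean of 0° and differ in spread
(3° vs 12°); category 1 is the narrow category.  Stimulus reliability
(Gabor contrast or ellipse elongation) takes one of six physical values
per trial and controls measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "TaskSpec",
    "SessionStructure",
    "task_a",
    "task_b",
    "GABOR_CONTRASTS",
    "ELLIPSE_ECCENTRICITIES",
    "experiment1_structure",
    "structure_counts",
    "draw_stimulus",
    "ideal_accuracy",
]

#: Six physical reliability values, lowest to highest.
GABOR_CONTRASTS: Tuple[float, ...] = (0.004, 0.008, 0.017, 0.033, 0.067, 0.135)
ELLIPSE_ECCENTRICITIES: Tuple[float, ...] = (0.15, 0.28, 0.41, 0.54, 0.67, 0.8)


@dataclass(frozen=True)
class TaskSpec:
    """Category-defining stimulus distributions for one task.

    ``mu[c-1]`` and ``sigma_cat[c-1]`` give the mean and s.d. of the
    orientation distribution of category ``c`` (both Gaussian).
    """

    task_id: Literal["A", "B"]
    mu: Tuple[float, float]
    sigma_cat: Tuple[float, float]
    reliability_values: Tuple[float, ...] = GABOR_CONTRASTS
    prior_c1: float = 0.5

    def __post_init__(self) -> None:
        if self.task_id not in ("A", "B"):
            raise ValueError(f"task_id must be 'A' or 'B', got {self.task_id!r}")
        if len(self.reliability_values) != 6:
            raise ValueError("reliability_values must have length 6")
        rv = np.asarray(self.reliability_values, dtype=float)
        if not np.all(np.diff(rv) > 0):
            raise ValueError("reliability_values must be strictly increasing")
        if not 0.0 < self.prior_c1 < 1.0:
            raise ValueError("prior_c1 must be strictly inside (0, 1)")
        if any(s < 0 for s in self.sigma_cat):
            raise ValueError("category standard deviations must be >= 0")

    @property
    def log_prior_ratio(self) -> float:
        """log p(C=1)/p(C=2) implied by the design prior."""
        return math.log(self.prior_c1 / (1.0 - self.prior_c1))

    def with_reliabilities(self, values: Sequence[float]) -> "TaskSpec":
        return replace(self, reliability_values=tuple(float(v) for v in values))

    def stimulus_pdf(self, s):
        """Mixture stimulus density p(s) = Σ_c p(C=c) p(s|C=c)."""
        s = np.asarray(s, dtype=float)
        w = (self.prior_c1, 1.0 - self.prior_c1)
        out = np.zeros_like(s, dtype=float)
        for c in (0, 1):
            out += w[c] * stats.norm.pdf(s, self.mu[c], self.sigma_cat[c])
        return out

    def stimulus_cdf(self, s):
        s = np.asarray(s, dtype=float)
        w = (self.prior_c1, 1.0 - self.prior_c1)
        out = np.zeros_like(s, dtype=float)
        for c in (0, 1):
            out += w[c] * stats.norm.cdf(s, self.mu[c], self.sigma_cat[c])
        return out


def task_a(reliability_values: Sequence[float] = GABOR_CONTRASTS) -> TaskSpec:
    """Task A: mean-separated categories, Normal(∓4°, 5°)."""
    return TaskSpec("A", mu=(-4.0, 4.0), sigma_cat=(5.0, 5.0),
                    reliability_values=tuple(reliability_values))


def task_b(reliability_values: Sequence[float] = GABOR_CONTRASTS) -> TaskSpec:
    """Task B: spread-separated categories, Normal(0°, 3°) vs Normal(0°, 12°)."""
    return TaskSpec("B", mu=(0.0, 0.0), sigma_cat=(3.0, 12.0),
                    reliability_values=tuple(reliability_values))


@dataclass(frozen=True)
class SessionStructure:
    """Block structure of one experiment, per subject.

    Counts are (number of blocks, trials per block) per task per session.
    """

    n_sessions: int = 5
    tasks_per_session: Tuple[str, ...] = ("A", "B")
    category_training_blocks: Tuple[int, int] = (3, 96)
    confidence_training_blocks: Tuple[int, int] = (1, 24)
    testing_blocks: Tuple[int, int] = (3, 144)

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be positive")
        if not self.tasks_per_session:
            raise ValueError("tasks_per_session must be non-empty")
        for name in ("category_training_blocks", "confidence_training_blocks",
                     "testing_blocks"):
            n, m = getattr(self, name)
            if n < 0 or m < 1:
                raise ValueError(f"{name} counts must be positive")


def experiment1_structure() -> SessionStructure:
    """The experiment-1 design: 5 sessions × both tasks, 3×96 category
    training, 1×24 confidence training, 3×144 testing blocks."""
    return SessionStructure()


def structure_counts(structure: SessionStructure) -> dict:
    """Total trial counts per phase across all sessions and tasks."""
    mult = structure.n_sessions * len(structure.tasks_per_session)
    return {
        "category_training": mult * structure.category_training_blocks[0]
        * structure.category_training_blocks[1],
        "confidence_training": mult * structure.confidence_training_blocks[0]
        * structure.confidence_training_blocks[1],
        "testing": mult * structure.testing_blocks[0] * structure.testing_blocks[1],
    }


def draw_stimulus(task: TaskSpec, category: int, rng: np.random.Generator,
                  size=None):
    """Draw stimulus orientation(s) from the category distribution."""
    if category not in (1, 2):
        raise ValueError(f"category must be 1 or 2, got {category}")
    return rng.normal(task.mu[category - 1], task.sigma_cat[category - 1], size=size)


def ideal_accuracy(task: TaskSpec) -> float:
    """Proportion correct of the noiseless optimal observer.

    With zero measurement noise the observer sees ``s`` itself and applies
    the likelihood-ratio rule.  Task A reduces to a sign rule at the
    category midpoint: accuracy Φ(|μ₂ − μ₁| / (2σ_C)).  Task B reduces to
    a two-criterion rule on |s| at the point where the two category
    densities are equal.
    """
    mu1, mu2 = task.mu
    s1, s2 = task.sigma_cat
    if task.task_id == "A":
        if s1 != s2:
            raise ValueError("Task A closed form assumes equal category s.d.s")
        # equal-prior midpoint rule
        return float(stats.norm.cdf(abs(mu2 - mu1) / (2.0 * s1)))
    # Task B: solve N(s; 0, s1^2) = N(s; 0, s2^2) for |s|
    if s1 == s2:
        raise ValueError("Task B requires distinct category s.d.s")
    lo, hi = sorted((s1, s2))
    s_star = math.sqrt(2.0 * math.log(hi / lo) / (1.0 / lo**2 - 1.0 / hi**2))
    p_narrow = 2.0 * stats.norm.cdf(s_star / lo) - 1.0
    p_wide = 2.0 * (1.0 - stats.norm.cdf(s_star / hi))
    w_narrow = task.prior_c1 if s1 < s2 else 1.0 - task.prior_c1
    return float(w_narrow * p_narrow + (1.0 - w_narrow) * p_wide)
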