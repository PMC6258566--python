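"""Response-code conventions.

A single button press encodes category and confidence as an integer
``r`` in 1..8: responses 1–4 are category 1 with confidence 4 ("very
high") down to 1 ("very low"); responses 5–8 are category 2 with
confidence 1 up to 4.  Response codes are therefore ordered along the
decision axis: in Task A from strongly leftward to strongly rightward
measurements, in Task B from small to large |measurement|.
"""

from __future__ import annotations

import numpy as np

__all__ = ["response_to_choice", "response_to_confidence", "choice_confidence_to_response"]


def response_to_choice(r):
    """Chosen category (1 or 2) for response code(s) ``r``."""
    r = np.asarray(r)
    _check(r)
    return np.where(r <= 4, 1, 2)[()]


def response_to_confidence(r):
    """Confidence level (1..4) for response code(s) ``r``."""
    r = np.asarray(r)
    _check(r)
    return np.where(r <= 4, 5 - r, r - 4)[()]


def choice_confidence_to_response(choice, confidence):
    """Inverse mapping; bijective with (response_to_choice, response_to_confidence)."""
    choice = np.asarray(choice)
    confidence = np.asarray(confidence)
    if np.any((choice < 1) | (choice > 2)):
        raise ValueError("choice must be 1 or 2")
    if np.any((confidence < 1) | (confidence > 4)):
        raise ValueError("confidence must be in 1..4")
    return np.where(choice == 1, 5 - confidence, 4 + confidence)[()]


def _check(r) -> None:
    if np.any((r < 1) | (r > 8)):
        raise ValueError("response codes must be in 1..8")
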