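"""Expanding probability-window schedule and sample selection.

Two selectors act on the pool of unlabeled samples, each looking at the class
probabilities from the current classifier:

* the *self-training* (SSL) selector takes high-confidence samples, those with
  probability within ``gamma`` of 0 or 1;
* the *active-learning* (AL) selector takes uncertain samples, those with
  probability strictly within ``alpha`` of the 0.5 decision boundary.

Both half-widths grow linearly over iterations.  With step size ``SZ`` and
``C = 1/SZ`` iterations, the half-widths at iteration ``t`` are
``gamma_t = alpha_t = t * SZ / 4``, so the total probability mass covered per
iteration is ``t * SZ`` and at ``t = C`` the two windows partition all of
(0, 1): every pool sample becomes selectable by exactly one selector.  For
SZ = 0.2 the first iteration selects prob <= 0.05 or >= 0.95 (SSL) and
0.45 < prob < 0.55 (AL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Schedule",
    "WindowPair",
    "windows_at",
    "select_confident",
    "select_uncertain",
    "assign_pseudo_labels",
]

_SCHEDULE_TOL = 1e-12


@dataclass(frozen=True)
class Schedule:
    """Step size SZ and iteration cap C of the expanding-window schedule.

    Invariant: ``step_size * max_iterations == 1`` (the windows exhaust the
    whole probability range exactly at the final iteration).
    """

    step_size: float = 0.1
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.step_size <= 1):
            raise ValueError("step_size must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if abs(self.step_size * self.max_iterations - 1.0) > _SCHEDULE_TOL:
            raise ValueError(
                f"step_size * max_iterations must equal 1, got "
                f"{self.step_size} * {self.max_iterations}"
            )

    @classmethod
    def from_step_size(cls, step_size: float) -> "Schedule":
        c = round(1.0 / step_size)
        return cls(1.0 / c, c)

    @classmethod
    def from_max_iterations(cls, max_iterations: int) -> "Schedule":
        return cls(1.0 / max_iterations, max_iterations)


@dataclass(frozen=True)
class WindowPair:
    """Half-widths of the SSL confidence window and the AL uncertainty window."""

    ssl_halfwidth: float
    al_halfwidth: float

    def __post_init__(self) -> None:
        if not (0 <= self.ssl_halfwidth <= 0.25 + _SCHEDULE_TOL):
            raise ValueError("ssl_halfwidth must lie in [0, 0.25]")
        if not (0 <= self.al_halfwidth <= 0.25 + _SCHEDULE_TOL):
            raise ValueError("al_halfwidth must lie in [0, 0.25]")
        if self.ssl_halfwidth + self.al_halfwidth > 0.5 + _SCHEDULE_TOL:
            raise ValueError("windows overlap: halfwidths sum beyond 0.5")


def windows_at(schedule: Schedule, iteration: int) -> WindowPair:
    """Window half-widths at a 1-based iteration: both equal ``t * SZ / 4``."""
    if not (1 <= iteration <= schedule.max_iterations):
        raise ValueError(
            f"iteration {iteration} outside 1..{schedule.max_iterations}"
        )
    hw = iteration * schedule.step_size / 4.0
    return WindowPair(ssl_halfwidth=hw, al_halfwidth=hw)


def select_confident(probs: np.ndarray, gamma: float) -> np.ndarray:
    """Indices of high-confidence samples: ``prob <= gamma`` or ``prob >= 1 - gamma``."""
    probs = np.asarray(probs, dtype=float)
    return np.flatnonzero((probs <= gamma) | (probs >= 1.0 - gamma))


def select_uncertain(probs: np.ndarray, alpha: float) -> np.ndarray:
    """Indices of uncertain samples: ``0.5 - alpha < prob < 0.5 + alpha`` (strict)."""
    probs = np.asarray(probs, dtype=float)
    return np.flatnonzero((probs > 0.5 - alpha) & (probs < 0.5 + alpha))


def assign_pseudo_labels(probs: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Classifier-assigned labels for the selected samples: 1 iff prob > 0.5.

    A probability of exactly 0.5 gets class 0; such a sample sits in the AL
    window and is re-examined by the update mechanism on later iterations, so
    any fixed tie rule works, but it must be fixed.
    """
    probs = np.asarray(probs, dtype=float)
    indices = np.asarray(indices, dtype=int)
    return (probs[indices] > 0.5).astype(int)
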