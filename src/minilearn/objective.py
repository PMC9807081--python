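"""Differentiable proxy losses for matching scorer and template assignments.

The asymmetric distance

    D_DM(f, g) = sum_i (1 - g_i) (f_i - g_i)^2 + lambda * sum_i (f_i - 1)^2

weights each position-wise matching term by 1 - g_i, enforcing a stronger
matching preference around the template minima (where g_i is low) and leaving
slack elsewhere; the lambda term pushes scorer outputs toward 1 wherever
possible, preventing the trivial solution where both assignments collapse to
zero. Its gradient with respect to f has the closed form

    a_i = 2 (1 - g_i) (f_i - g_i) + 2 lambda (f_i - 1).

The symmetric l2 distance sum_i (f_i - g_i)^2 is provided as a baseline; it
over-constrains the match and trains markedly worse.

These forms are written in the MIN-selection convention (low score = selected).
The max-pool convention is the documented mirror f -> 1-f, g -> 1-g.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ObjectiveConfig",
    "dm_distance",
    "dm_gradient_constants",
    "dm_gradient_template",
    "l2_distance",
    "l2_gradients",
    "mirror",
]


@dataclasses.dataclass(frozen=True)
class ObjectiveConfig:
    """Loss configuration: trade-off weight lambda, metric, and convention."""

    lam: float = 1.0
    metric: str = "dm"
    convention: str = "min"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.metric not in ("dm", "l2"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.convention not in ("min", "max"):
            raise ValueError(f"unknown convention {self.convention!r}")


def _check(f: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape or f.ndim != 1:
        raise ValueError(f"f and g must be equal-length vectors, got {f.shape} vs {g.shape}")
    return f, g


def mirror(scores: np.ndarray) -> np.ndarray:
    """The min/max convention flip s -> 1 - s."""
    return 1.0 - np.asarray(scores, dtype=np.float64)


def dm_distance(f: np.ndarray, g: np.ndarray, lam: float = 1.0,
                convention: str = "min") -> float:
    """Asymmetric template-matching distance (see module docstring)."""
    f, g = _check(f, g)
    if convention == "max":
        f, g = mirror(f), mirror(g)
    return float(np.sum((1.0 - g) * (f - g) ** 2) + lam * np.sum((f - 1.0) ** 2))


def dm_gradient_constants(f: np.ndarray, g: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """a_i = 2 (1 - g_i)(f_i - g_i) + 2 lambda (f_i - 1) = d D_DM / d f_i."""
    f, g = _check(f, g)
    return 2.0 * (1.0 - g) * (f - g) + 2.0 * lam * (f - 1.0)


def dm_gradient_template(f: np.ndarray, g: np.ndarray, lam: float = 1.0,
                         detach_weight: bool = False) -> np.ndarray:
    """Template-side gradient of the asymmetric distance.

    The full derivative is d D_DM / d g_i = -(f_i-g_i)^2 - 2(1-g_i)(f_i-g_i).
    With ``detach_weight`` the matching weight (1-g_i) is treated as a
    constant for the template update, dropping the -(f-g)^2 term. That term
    rewards the template for raising its own scores to switch the matching
    off, which drives the amplitude parameters toward the degenerate constant
    template; detaching it leaves only the pull toward the scorer, keeping the
    template periodic throughout training. Training uses the detached form.
    """
    f, g = _check(f, g)
    pull = -2.0 * (1.0 - g) * (f - g)
    if detach_weight:
        return pull
    return -((f - g) ** 2) + pull


def l2_distance(f: np.ndarray, g: np.ndarray) -> float:
    """Symmetric squared-error baseline sum_i (f_i - g_i)^2."""
    f, g = _check(f, g)
    return float(np.sum((f - g) ** 2))


def l2_gradients(f: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(d/df, d/dg) of the l2 distance."""
    f, g = _check(f, g)
    d = 2.0 * (f - g)
    return d, -d
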