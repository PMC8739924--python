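"""Multiscale sample entropy of pulse recordings.

The signal is coarse-grained by non-overlapping block averaging: at scale
``s`` the j-th coarse sample is the mean of the original samples over the
block ``((j-1)s, js]``, so the coarse series has ``floor(N/s)`` points and
scale 1 returns the input unchanged. Sample entropy of each coarse series
is ``-ln(A/B)`` where ``B`` counts pairs of length-``m`` templates within
Chebyshev distance ``r`` (self-matches excluded) and ``A`` the same for
length ``m+1``. The tolerance ``r`` is fixed from the *original* signal's
standard deviation across all scales, following the original multiscale
convention; defaults are ``m=2`` and ``r = 0.15 × SD``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ParameterError

__all__ = [
    "MSEFeatures",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
]


@dataclass(frozen=True)
class MSEFeatures:
    """Entropy per scale (NaN where no template pair matched), with config echo."""

    values: tuple[float, ...]
    m: int
    r_factor: float
    n_used: int

    def as_dict(self) -> dict[str, float]:
        out = {f"mse{i + 1}": v for i, v in enumerate(self.values)}
        out["mse_m"] = float(self.m)
        out["mse_r_factor"] = self.r_factor
        return out


def coarse_grain(u: np.ndarray, s: int) -> np.ndarray:
    """Block-average ``u`` at scale ``s``; the trailing remainder is discarded."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ParameterError("input series must be a non-empty 1-D array")
    if int(s) != s or s < 1:
        raise ParameterError(f"scale factor must be an integer >= 1, got {s}")
    s = int(s)
    if u.size < s:
        raise ParameterError(f"series of length {u.size} is shorter than scale {s}")
    n_blocks = u.size // s
    return u[: n_blocks * s].reshape(n_blocks, s).mean(axis=1)


def _template_matrix(y: np.ndarray, length: int, count: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(y, length)[:count]


def _count_pairs(templates: np.ndarray, r: float) -> int:
    tree = cKDTree(templates)
    ordered = tree.count_neighbors(tree, r, p=np.inf)
    return int(ordered - len(templates)) // 2


def sample_entropy(y: np.ndarray, m: int = 2, r_absolute: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` with an absolute Chebyshev tolerance.

    Returns NaN when either template count is zero (the conditional
    probability is undefined) rather than an infinite value.
    """
    y = np.asarray(y, dtype=float)
    if m < 1:
        raise ParameterError(f"embedding length m must be >= 1, got {m}")
    if len(y) <= m + 1:
        raise ParameterError(
            f"series of length {len(y)} too short for m={m} (need > m + 1)"
        )
    if r_absolute is None or not r_absolute > 0:
        raise ParameterError("tolerance r_absolute must be a positive number")
    # N - m templates for both lengths m and m+1, the standard convention
    n_templates = len(y) - m
    b = _count_pairs(_template_matrix(y, m, n_templates), r_absolute)
    a = _count_pairs(_template_matrix(y, m + 1, n_templates), r_absolute)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def multiscale_entropy(
    u: np.ndarray,
    max_scale: int = 5,
    m: int = 2,
    r_factor: float = 0.15,
) -> MSEFeatures:
    """Sample entropy of the coarse-grained series at scales 1..``max_scale``."""
    u = np.asarray(u, dtype=float)
    if max_scale < 1:
        raise ParameterError("max_scale must be >= 1")
    if len(u) < max_scale * (m + 2):
        raise ParameterError(
            f"series of length {len(u)} too short for max_scale={max_scale}, m={m}"
        )
    sd = float(np.std(u, ddof=1))
    if not sd > 0:
        raise ParameterError("signal has zero variance; tolerance r would be 0")
    r = r_factor * sd
    values = tuple(
        sample_entropy(coarse_grain(u, s), m, r) for s in range(1, max_scale + 1)
    )
    return MSEFeatures(values=values, m=m, r_factor=r_factor, n_used=len(u))
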