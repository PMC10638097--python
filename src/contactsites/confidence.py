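"""Per-voxel statistical confidence for the windowed Spearman response.

Two gates derived from the Fisher z-transform of the correlation, with
the Spearman-specific standard error sqrt(1.06 / (n - 3)):

* significance — two-sided p-value of each window's correlation;
* detectability — the minimum correlation magnitude observable at level
  ``alpha`` with the requested power given the window sample size.  A
  125-voxel window (w = 2) at alpha = 0.05 and power 0.95 cannot resolve
  correlations weaker than about 0.32; as alpha tends to 0 this bound
  tends to 1 and no voxel survives.

No multiple-testing correction is applied across voxels: the confidence
map is a per-voxel filter, not an inferential claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .response import ResponseMap
from .volume_io import DetectParams

#: variance inflation of the Fisher z of a Spearman correlation
SPEARMAN_VAR = 1.06


@dataclass
class ConfidenceMap:
    p_value: np.ndarray
    rho_min: float
    pass_mask: np.ndarray


def _se_factor(n: int, plain_variance: bool) -> float:
    var = 1.0 if plain_variance else SPEARMAN_VAR
    return np.sqrt(var / (n - 3))


def spearman_significance(
    rho: np.ndarray | float, n: int, plain_variance: bool = False
) -> np.ndarray | float:
    """Two-sided p-value of a Spearman correlation via the Fisher z-test.

    z = atanh(rho) * sqrt((n - 3) / 1.06); p = 2 * (1 - Phi(|z|)).
    |rho| is clamped to 1 - 1e-12 before atanh.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    rho_arr = np.clip(np.asarray(rho, dtype=np.float64), -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(rho_arr) / _se_factor(n, plain_variance)
    p = 2.0 * norm.sf(np.abs(z))
    return float(p) if np.isscalar(rho) else p


def min_detectable_rho(
    n: int, alpha: float, power: float, plain_variance: bool = False
) -> float:
    """Smallest |rho| detectable at level ``alpha`` with ``power``.

    tanh((z_{1-alpha/2} + z_power) * sqrt(1.06 / (n - 3))) under the
    Fisher-z approximation.  Monotone decreasing in n; tends to 1 as
    alpha -> 0 (at full confidence nothing is observable).
    """
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must be in (0, 1), got {power}")
    z = norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power)
    return float(np.tanh(z * _se_factor(n, plain_variance)))


def confidence_map(resp: ResponseMap, params: DetectParams) -> ConfidenceMap:
    """Evaluate both gates on a response map without modifying it."""
    p = spearman_significance(resp.rho_lap, resp.n_window, params.plain_variance)
    rho_min = min_detectable_rho(
        resp.n_window, params.alpha, params.power, params.plain_variance
    )
    pass_mask = (
        (resp.magnitude > 0)
        & (p <= params.alpha)
        & (np.abs(resp.rho_lap) >= rho_min)
    )
    return ConfidenceMap(p_value=p, rho_min=rho_min, pass_mask=pass_mask)


def apply_confidence(resp: ResponseMap, params: DetectParams) -> ResponseMap:
    """Zero the response wherever p > alpha or |rho_lap| < rho_min.

    A pure masking operation: output magnitude <= input magnitude
    voxel-wise, and the retained count is non-increasing as alpha
    decreases or power increases.
    """
    cm = confidence_map(resp, params)
    return resp.copy_with_magnitude(np.where(cm.pass_mask, resp.magnitude, 0.0))
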