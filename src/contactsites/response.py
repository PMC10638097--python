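"""Windowed rank-correlation response: the raw contact signal.

At every voxel, the Spearman correlation of the two channels' negative
Laplacians is computed over a centred ``(2w+1)**3`` cube.  Two adjacent
objects blurred by the PSF produce *anti*-correlated curvature across
their interface, so the contact signal is the magnitude of the negative
correlation, gated by the intensity correlation also being negative (this
rejects low-intensity signal colocalising with high-intensity signal —
and trivially rejects self-overlap, where intensities correlate
positively).

The default half-width ``w = 2`` gives a 125-voxel window spanning
roughly 350 nm at 25 x 25 x 100 nm voxels; larger windows detect fainter
correlations but risk mixing opposing interaction patterns and cost
cubically more time (overall O(N * M log M), M the window size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from . import diffgeom
from .volume_io import DetectParams, DimensionError, VolumePair


@dataclass
class ResponseMap:
    """Per-voxel correlation fields and the retained response magnitude.

    ``magnitude`` is ``-rho_lap`` where both ``rho_lap`` and ``rho_int``
    are negative, else 0; it lives in [0, 1].  ``n_window`` is the sample
    count per window, ``(2w+1)**3``.
    """

    rho_lap: np.ndarray
    rho_int: np.ndarray
    magnitude: np.ndarray
    n_window: int
    params: DetectParams

    def __post_init__(self) -> None:
        if self.n_window != (2 * self.params.w + 1) ** 3:
            raise ValueError(
                f"n_window {self.n_window} != (2w+1)^3 for w={self.params.w}"
            )

    def copy_with_magnitude(self, magnitude: np.ndarray) -> "ResponseMap":
        return ResponseMap(
            self.rho_lap, self.rho_int, magnitude, self.n_window, self.params
        )


def windowed_spearman(
    field_a: np.ndarray,
    field_b: np.ndarray,
    w: int,
    slab: int = 4,
) -> np.ndarray:
    """Per-voxel Spearman correlation over centred ``(2w+1)**3`` cubes.

    Ties receive average ranks (standard Spearman).  Windows in which
    either field has zero variance are defined as correlation 0 — an
    all-constant background must never respond.  The ``w``-voxel outer
    shell, where the window would overhang the volume, is 0.

    Processing is chunked into z-slabs of ``slab`` output planes to bound
    memory; results are independent of ``slab``.
    """
    a = np.asarray(field_a, dtype=np.float64)
    b = np.asarray(field_b, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"field shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 3:
        raise DimensionError(f"expected 3D fields, got {a.ndim}D")
    side = 2 * w + 1
    if side > min(a.shape):
        raise ValueError(
            f"window of side {side} exceeds smallest axis of volume {a.shape}"
        )
    nz, ny, nx = a.shape
    out = np.zeros(a.shape, dtype=np.float64)
    m = side**3
    for z0 in range(w, nz - w, slab):
        z1 = min(z0 + slab, nz - w)
        wa = sliding_window_view(a[z0 - w : z1 + w], (side, side, side))
        wb = sliding_window_view(b[z0 - w : z1 + w], (side, side, side))
        shape = wa.shape[:3]
        ra = rankdata(wa.reshape(-1, m), axis=1)
        rb = rankdata(wb.reshape(-1, m), axis=1)
        ra -= ra.mean(axis=1, keepdims=True)
        rb -= rb.mean(axis=1, keepdims=True)
        num = np.einsum("ij,ij->i", ra, rb)
        den = np.sqrt(
            np.einsum("ij,ij->i", ra, ra) * np.einsum("ij,ij->i", rb, rb)
        )
        rho = np.zeros_like(num)
        np.divide(num, den, out=rho, where=den > 0)
        out[z0:z1, w : ny - w, w : nx - w] = rho.reshape(shape)
    return np.clip(out, -1.0, 1.0)


def contact_response(pair: VolumePair, params: DetectParams) -> ResponseMap:
    """Compute the raw contact response for a registered channel pair.

    ``rho_lap`` correlates the negative parts of the channel Laplacians;
    ``rho_int`` correlates the raw intensities.  The retained magnitude is
    ``-rho_lap`` where both are strictly negative.
    """
    spacing = pair.spacing if params.physical_units else None
    nla = diffgeom.negative_part(
        diffgeom.laplacian_3d(pair.channel_a, spacing=spacing, source_channel="a")
    )
    nlb = diffgeom.negative_part(
        diffgeom.laplacian_3d(pair.channel_b, spacing=spacing, source_channel="b")
    )
    rho_lap = windowed_spearman(nla.values, nlb.values, params.w)
    rho_int = windowed_spearman(pair.channel_a, pair.channel_b, params.w)
    magnitude = np.where((rho_lap < 0) & (rho_int < 0), -rho_lap, 0.0)
    return ResponseMap(
        rho_lap=rho_lap,
        rho_int=rho_int,
        magnitude=magnitude,
        n_window=params.n_window,
        params=params,
    )
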