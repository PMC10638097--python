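"""Discrete differential operators on 3D intensity fields.

The detection statistic correlates local curvature of the two channels,
approximated by the 6-neighbour Laplacian (second central difference per
axis, summed).  Its negative part peaks inside bright objects; the
third-derivative magnitude (gradient of the Laplacian) feeds the shadow
filter.

Operators work in voxel units by default: the downstream statistic is a
rank correlation comparing the two channels voxel-wise with identical
stencils, so a common image-space stencil is consistent.  A physical-units
mode (stencil scaled by 1/spacing^2 per axis) is available via
``spacing``.  Boundaries use replicate-edge padding; the response stage
additionally zeroes the window-width outer shell, so padding never
creates contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import DimensionError

MIN_AXIS = 8


@dataclass
class DifferentialField:
    """A derivative field with the same shape as its source channel."""

    values: np.ndarray
    order: int  # 2 = Laplacian, 3 = third-derivative magnitude
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("differential field contains non-finite values")


def _check_field(field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 3:
        raise DimensionError(f"expected a 3D field, got {field.ndim}D")
    if min(field.shape) < MIN_AXIS:
        raise DimensionError(
            f"field must be >= {MIN_AXIS} voxels per axis, got {field.shape}"
        )
    return field


def laplacian_3d(
    channel: np.ndarray,
    spacing: tuple[float, float, float] | None = None,
    source_channel: str = "",
) -> DifferentialField:
    """6-neighbour Laplacian: sum of per-axis second central differences.

    ``spacing`` (nm per axis) switches on physical units, dividing each
    axis term by its squared spacing; default is unit voxel spacing.
    """
    field = _check_field(channel)
    padded = np.pad(field, 1, mode="edge")
    scale = (1.0, 1.0, 1.0) if spacing is None else tuple(1.0 / s**2 for s in spacing)
    lap = np.zeros_like(field)
    c = padded[1:-1, 1:-1, 1:-1]
    lap += scale[0] * (padded[2:, 1:-1, 1:-1] + padded[:-2, 1:-1, 1:-1] - 2 * c)
    lap += scale[1] * (padded[1:-1, 2:, 1:-1] + padded[1:-1, :-2, 1:-1] - 2 * c)
    lap += scale[2] * (padded[1:-1, 1:-1, 2:] + padded[1:-1, 1:-1, :-2] - 2 * c)
    return DifferentialField(lap, order=2, source_channel=source_channel)


def negative_part(lap: DifferentialField) -> DifferentialField:
    """max(-v, 0) voxel-wise; nonnegative, zero wherever the Laplacian is >= 0."""
    if lap.order != 2:
        raise ValueError(f"negative_part expects an order-2 field, got {lap.order}")
    return DifferentialField(
        np.maximum(-lap.values, 0.0), order=2, source_channel=lap.source_channel
    )


def third_derivative(
    channel: np.ndarray,
    spacing: tuple[float, float, float] | None = None,
    source_channel: str = "",
) -> DifferentialField:
    """Magnitude of the finite-difference gradient of the Laplacian.

    Euclidean norm over the three central first differences of the
    Laplacian field (replicate-edge boundaries).
    """
    lap = laplacian_3d(channel, spacing=spacing).values
    padded = np.pad(lap, 1, mode="edge")
    gz = 0.5 * (padded[2:, 1:-1, 1:-1] - padded[:-2, 1:-1, 1:-1])
    gy = 0.5 * (padded[1:-1, 2:, 1:-1] - padded[1:-1, :-2, 1:-1])
    gx = 0.5 * (padded[1:-1, 1:-1, 2:] - padded[1:-1, 1:-1, :-2])
    mag = np.sqrt(gz**2 + gy**2 + gx**2)
    return DifferentialField(mag, order=3, source_channel=source_channel)


def zero_tolerance(d3: DifferentialField) -> float:
    """Numerical 'zero' threshold for a third-derivative magnitude field.

    Exact zeros are fragile in floating point; a value counts as zero when
    it is <= 1e-8 times the field's 99th percentile.
    """
    if d3.order != 3:
        raise ValueError(f"zero_tolerance expects an order-3 field, got {d3.order}")
    return 1e-8 * float(np.percentile(d3.values, 99.0))
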