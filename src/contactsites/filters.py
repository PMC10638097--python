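"""Artifact-removal stages applied to the raw contact response.

Three confounders of the differential correlation are handled here, in
the fixed pipeline order (bleed-through -> gating -> confidence -> shadow
-> labelling -> vesicle filter); every stage is a pure mask, so the
retained response never grows.

* bleed-through: the anisotropic PSF spills intensity across z-planes,
  creating false inter-channel correlation at low intensity.  Voxels must
  exceed a z-score threshold of their channel's intensity distribution
  (computed over nonzero voxels, keeping the statistic meaningful in
  mostly-empty volumes) in BOTH channels.
* shadow: low SNR and pixelation can produce a spurious response band
  parallel to a true interface, offset by a few voxels.  Where the
  third derivative of intensity is zero for exactly one channel the voxel
  cannot be a contact (it may be zero for a valid contact, but only if
  both are); such voxels are masked out.
* vesicle filter: contacts whose only adjacent mitochondria-channel
  component is a small, dim (vesicle-like) structure are excluded, so
  reported contacts involve whole mitochondria.  Thresholds: ln(size in
  voxels) >= 9 and mean [0,1]-rescaled intensity >= 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .diffgeom import DifferentialField, zero_tolerance
from .response import ResponseMap

#: 26-connectivity structuring element, also the 1-voxel adjacency radius
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def bleedthrough_mask(channel: np.ndarray, z_filter: float) -> np.ndarray:
    """Mask of voxels whose intensity z-score is >= ``z_filter``.

    The z-score is a pivotal quantity: it adapts to each channel's
    distribution, so the same threshold transfers across channels and
    acquisitions.  Mean and standard deviation are computed over the
    channel's nonzero voxels.  A degenerate (zero-variance) channel
    yields an all-false mask with a warning.
    """
    channel = np.asarray(channel, dtype=np.float64)
    nz = channel[channel != 0]
    if nz.size == 0:
        warnings.warn("channel is all zero; bleed-through mask is empty", stacklevel=2)
        return np.zeros(channel.shape, dtype=bool)
    mu, sd = float(nz.mean()), float(nz.std())
    if sd == 0:
        warnings.warn(
            "channel intensity has zero variance; bleed-through mask is empty",
            stacklevel=2,
        )
        return np.zeros(channel.shape, dtype=bool)
    return (channel - mu) / sd >= z_filter


def apply_bleedthrough(
    resp: ResponseMap, channel_a: np.ndarray, channel_b: np.ndarray, z_filter: float
) -> ResponseMap:
    """Retain response only where BOTH channels pass the z-score mask."""
    keep = bleedthrough_mask(channel_a, z_filter) & bleedthrough_mask(
        channel_b, z_filter
    )
    return resp.copy_with_magnitude(np.where(keep, resp.magnitude, 0.0))


def shadow_filter(
    resp: ResponseMap, d3_a: DifferentialField, d3_b: DifferentialField
) -> ResponseMap:
    """Remove voxels where exactly one channel's third derivative is zero.

    "Zero" is assessed against each field's numerical tolerance (1e-8 of
    its 99th percentile).  Voxels where both are zero, or both nonzero,
    pass.
    """
    for d3 in (d3_a, d3_b):
        if d3.order != 3:
            raise ValueError("shadow_filter expects order-3 differential fields")
        if d3.values.shape != resp.magnitude.shape:
            raise ValueError("third-derivative field shape differs from response")
    zero_a = d3_a.values <= zero_tolerance(d3_a)
    zero_b = d3_b.values <= zero_tolerance(d3_b)
    keep = ~(zero_a ^ zero_b)
    return resp.copy_with_magnitude(np.where(keep, resp.magnitude, 0.0))


@dataclass
class MitoComponents:
    """Labelled mitochondria-channel components with filter statistics.

    ``table`` has one row per component: label, size (voxels), ln_size,
    mean_intensity (on the [0,1]-rescaled channel) and keep_flag.
    """

    labels: np.ndarray
    table: pd.DataFrame

    @property
    def kept_mask(self) -> np.ndarray:
        kept = self.table.loc[self.table.keep_flag, "label"].to_numpy()
        return np.isin(self.labels, kept) & (self.labels > 0)

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


def segment_mito_components(
    channel: np.ndarray,
    mito_ln_size: float = 9.0,
    mito_min_intensity: float = 0.2,
) -> MitoComponents:
    """Threshold, label and characterise mitochondria-channel structures.

    Contact detection itself needs no segmentation; this minimal
    thresholding exists only to support the vesicle filter, which needs
    per-component size/intensity statistics.  Foreground is an Otsu
    threshold on the [0,1] min-max rescaled channel; components are
    26-connected.
    """
    channel = np.asarray(channel, dtype=np.float64)
    lo, hi = float(channel.min()), float(channel.max())
    if hi > lo:
        rescaled = (channel - lo) / (hi - lo)
    else:
        rescaled = np.zeros_like(channel)
    cols = ["label", "size", "ln_size", "mean_intensity", "keep_flag"]
    empty = pd.DataFrame(columns=cols)
    if hi == lo:
        warnings.warn("mitochondria channel is constant; no components", stacklevel=2)
        return MitoComponents(np.zeros(channel.shape, dtype=np.int32), empty)
    fg = rescaled >= threshold_otsu(rescaled)
    if not fg.any():
        warnings.warn("empty mitochondria foreground; no components", stacklevel=2)
        return MitoComponents(np.zeros(channel.shape, dtype=np.int32), empty)
    labels, n = ndimage.label(fg, structure=STRUCT_26)
    sizes = np.bincount(labels.ravel())[1:]
    means = ndimage.mean(rescaled, labels=labels, index=np.arange(1, n + 1))
    ln_sizes = np.log(sizes.astype(np.float64))
    table = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "size": sizes,
            "ln_size": ln_sizes,
            "mean_intensity": means,
            "keep_flag": (ln_sizes >= mito_ln_size) & (means >= mito_min_intensity),
        }
    )
    return MitoComponents(labels.astype(np.int32), table)


def vesicle_filter(
    contact_labels: np.ndarray, mito: MitoComponents
) -> tuple[np.ndarray, np.ndarray]:
    """Drop contact components not adjacent to any kept mitochondrion.

    A contact is adjacent to a component if any contact voxel lies within
    the 1-voxel 26-neighbourhood dilation of that component.  Contacts
    touching only below-threshold (vesicle-like) components, or no
    mitochondria-channel component at all, are removed.

    Returns the filtered label field (original label ids preserved) and
    the array of surviving label ids.
    """
    contact_labels = np.asarray(contact_labels)
    if contact_labels.shape != mito.labels.shape:
        raise ValueError("contact and mitochondria label fields differ in shape")
    kept = mito.kept_mask
    if kept.any():
        near_kept = ndimage.binary_dilation(kept, structure=STRUCT_26)
    else:
        near_kept = np.zeros(kept.shape, dtype=bool)
    ids = np.unique(contact_labels)
    ids = ids[ids > 0]
    survivors = np.array(
        [lab for lab in ids if near_kept[contact_labels == lab].any()],
        dtype=contact_labels.dtype,
    )
    out = np.where(np.isin(contact_labels, survivors), contact_labels, 0)
    return out, survivors
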