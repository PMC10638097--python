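"""Volume and result I/O.

Axis convention is fixed to ``(z, y, x)`` with z the slow (anisotropic,
axial) axis, matching the page order of a multi-page TIFF stack.  Voxel
spacing is carried in nanometres as ``(z, y, x)``; the default of
(100, 25, 25) nm reflects typical deconvolved 3D STED acquisitions.

Intensities are used raw throughout the pipeline — normalising the input
channels can destroy the differential reconstruction and is never needed,
because the detection statistic is a rank correlation.  The only internal
rescaling is a [0, 1] min–max map used by the mitochondria/vesicle filter,
whose mean-intensity threshold is unit-free.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

DEFAULT_SPACING_NM = (100.0, 25.0, 25.0)  # (z, y, x)


class DimensionError(ValueError):
    """Raised when volumes have incompatible or unsupported shapes."""


@dataclass
class DetectParams:
    """Every tunable of the detection pipeline, serialized with results.

    Attributes
    ----------
    w : int
        Window half-width in voxels; the correlation window is a
        ``(2w+1)**3`` cube (125 voxels at the default ``w=2``).
    alpha : float
        Two-sided significance level for the per-voxel correlation test.
    beta : float
        Type-II error rate; statistical power is ``1 - beta`` unless
        ``power_literal`` is set, in which case ``beta`` is read as the
        power itself (a degenerate but selectable interpretation).
    z_filter : float
        Bleed-through mask threshold in intensity z-score units.
    quant_k : int
        Quantification cube parameter; cubes are ``5k x 5k`` lateral by
        ``k`` axial voxels, a physical cube under 4:1 axial anisotropy.
    min_contact_voxels : int
        Minimum surviving contact volume; components smaller than this
        (default 3, i.e. size <= 2) are below the diffraction limit and
        removed.
    mito_ln_size : float
        ln(voxel count) threshold below which a mitochondria-channel
        component is treated as a vesicle-like fragment.
    mito_min_intensity : float
        Mean intensity threshold on the [0, 1]-rescaled mitochondria
        channel for the same filter.
    large_contact_voxels : int
        Cutoff (voxels) defining "large" contacts in the summary.
    seed : int
        RNG seed for any stochastic step.
    physical_units : bool
        If True the Laplacian stencil is scaled by the physical spacing;
        default is voxel units, consistent with image-space operators.
    plain_variance : bool
        If True the Fisher-z standard error uses 1/(n-3) instead of the
        Spearman correction 1.06/(n-3).
    """

    w: int = 2
    alpha: float = 0.05
    beta: float = 0.05
    power_literal: bool = False
    z_filter: float = 3.0
    quant_k: int = 5
    min_contact_voxels: int = 3
    mito_ln_size: float = 9.0
    mito_min_intensity: float = 0.2
    large_contact_voxels: int = 500
    seed: int = 0
    physical_units: bool = False
    plain_variance: bool = False
    height_from_eigenvalue: bool = False

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError(f"window half-width w must be >= 1, got {self.w}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if self.z_filter < 0:
            raise ValueError(f"z_filter must be >= 0, got {self.z_filter}")
        if self.quant_k < 1:
            raise ValueError(f"quant_k must be >= 1, got {self.quant_k}")
        if self.min_contact_voxels < 1:
            raise ValueError(
                f"min_contact_voxels must be >= 1, got {self.min_contact_voxels}"
            )

    @property
    def power(self) -> float:
        """Statistical power used by the minimum-detectable-correlation bound."""
        return self.beta if self.power_literal else 1.0 - self.beta

    @property
    def n_window(self) -> int:
        return (2 * self.w + 1) ** 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass
class VolumePair:
    """Two co-registered 3D intensity channels plus physical voxel spacing.

    ``channel_a`` conventionally holds the reticular/tubular marker (ER)
    and ``channel_b`` the organelle marker (mitochondria).  Registration
    of the two channels is a precondition, not a feature: misaligned
    channels induce false differential responses.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=np.float64)
        self.channel_b = np.asarray(self.channel_b, dtype=np.float64)
        if self.channel_a.ndim != 3 or self.channel_b.ndim != 3:
            raise DimensionError(
                f"channels must be 3D, got {self.channel_a.ndim}D and "
                f"{self.channel_b.ndim}D"
            )
        if self.channel_a.shape != self.channel_b.shape:
            raise DimensionError(
                f"channel shapes differ: {self.channel_a.shape} vs "
                f"{self.channel_b.shape}"
            )
        for ch, name in ((self.channel_a, "a"), (self.channel_b, "b")):
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel_{name} contains non-finite values")
            if ch.min() < 0:
                raise ValueError(f"channel_{name} contains negative intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channel_a.shape

    def swapped(self) -> "VolumePair":
        return VolumePair(self.channel_b, self.channel_a, self.spacing)


def read_volume(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as a float64 (z, y, x) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise DimensionError(f"{path}: expected a 3D stack, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_volume(path: str | Path, volume: np.ndarray, dtype=np.float32) -> Path:
    """Write a 3D array as a multi-page TIFF (32-bit float by default)."""
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(volume).astype(dtype))
    return path


def read_volume_pair(
    path_a: str | Path,
    path_b: str | Path,
    spacing: Optional[tuple[float, float, float]] = None,
    transposed: bool = False,
) -> VolumePair:
    """Read two single-channel TIFF stacks into a :class:`VolumePair`.

    Parameters
    ----------
    spacing : (z, y, x) voxel size in nm.  Defaults to (100, 25, 25)
        with a warning, since TIFF metadata is not relied upon.
    transposed : set True if the stacks are stored (x, y, z) rather than
        the package convention (z, y, x).
    """
    a = read_volume(path_a)
    b = read_volume(path_b)
    if a.shape != b.shape:
        raise DimensionError(
            f"channel stacks differ in shape: {path_a} is {a.shape}, "
            f"{path_b} is {b.shape}"
        )
    if transposed:
        a = np.ascontiguousarray(a.transpose(2, 1, 0))
        b = np.ascontiguousarray(b.transpose(2, 1, 0))
    if spacing is None:
        warnings.warn(
            "no voxel spacing given; assuming (100, 25, 25) nm (z, y, x)",
            stacklevel=2,
        )
        spacing = DEFAULT_SPACING_NM
    return VolumePair(a, b, spacing)


def write_outputs(
    out_dir: str | Path,
    params: DetectParams,
    magnitude: Optional[np.ndarray] = None,
    contact_mask: Optional[np.ndarray] = None,
    contacts_table=None,
    windows_table=None,
    summary: Optional[dict] = None,
) -> dict:
    """Write detection results; returns a manifest of written files.

    Writes the response magnitude (32-bit float TIFF), the binary contact
    mask (8-bit TIFF), per-contact and per-window CSV tables, and a JSON
    summary that always embeds the full parameter set for provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"out_dir": str(out_dir), "files": {}}
    if magnitude is not None:
        p = write_volume(out_dir / "response_magnitude.tif", magnitude, np.float32)
        manifest["files"]["response_magnitude"] = str(p)
    if contact_mask is not None:
        p = write_volume(
            out_dir / "contact_mask.tif", (np.asarray(contact_mask) > 0), np.uint8
        )
        manifest["files"]["contact_mask"] = str(p)
    if contacts_table is not None:
        p = out_dir / "contacts.csv"
        contacts_table.to_csv(p, index=False, lineterminator="\r\n")
        manifest["files"]["contacts"] = str(p)
    if windows_table is not None:
        p = out_dir / "windows.csv"
        windows_table.to_csv(p, index=False, lineterminator="\r\n")
        manifest["files"]["windows"] = str(p)
    summary = dict(summary or {})
    summary["params"] = params.to_dict()
    p = out_dir / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    manifest["files"]["summary"] = str(p)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
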