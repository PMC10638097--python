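"""Synthetic microscopy phantoms with voxel-level ground truth.

Two generators cover every stage of the pipeline without any external
data:

* a two-sphere phantom — one sphere per channel, separated by a
  controllable edge-to-edge gap, imaged with an anisotropic Gaussian PSF.
  Sweeping the gap from direct interaction up to the system resolution
  reproduces the sub-resolution interface regime the detector targets.
* a whole-volume cell phantom — an ER-like tubular channel and a
  mitochondria-like ellipsoid channel with designated sub-resolution
  contact interfaces, plus optional small dim "vesicle" ellipsoids that
  sit below the mitochondria filter thresholds, and decoy tubes touching
  them.

The PSF is an anisotropic Gaussian specified by FWHM in nm per axis
(default 120 nm lateral, 250 nm axial — the resolution regime of 3D STED)
and converted to voxels through the spacing.  Phantom generation is a
pure function of (spec, seed).

Ground truth is geometric: the true contact mask marks gap voxels close
to both object surfaces (there is no physical voxel-level ground truth
for a sub-resolution interface, so recall/precision tolerances measured
against this mask are artifact-level choices).  For the two-sphere
phantom the mask is defined empty when the separation exceeds the system
resolution — beyond resolution there is no contact to reconstruct — while
``interface_region`` always marks the geometric mid-gap region for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume_io import DEFAULT_SPACING_NM, VolumePair

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


class GeometryError(ValueError):
    """Raised when phantom objects do not fit the grid or overlap illegally."""


@dataclass
class PhantomSpec:
    """Geometry, optics and noise of a synthetic phantom.

    ``shape``/``spacing`` follow the (z, y, x) convention.  Lengths are
    in nm unless suffixed ``_vox``.  ``separation_nm`` is the
    edge-to-edge gap between paired objects.  Defaults model the STED
    regime: 25 x 25 x 100 nm voxels, 120/250 nm lateral/axial FWHM.
    """

    shape: tuple[int, int, int] = (28, 96, 184)
    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM
    psf_fwhm_nm: tuple[float, float, float] = (250.0, 120.0, 120.0)
    resolution_nm: float = 120.0
    separation_nm: float = 0.0
    radius_nm: float = 1000.0
    intensities: tuple[float, float] = (1.0, 1.0)
    noise_sigma: float = 0.0
    poisson_scale: float = 0.0
    # cell-phantom geometry
    n_mito: int = 2
    mito_radii_vox: tuple[int, int, int] = (6, 14, 44)
    mito_intensity: float = 0.9
    mito_membrane_label: bool = True
    tube_radius_vox: int = 3
    tube_z_radius_vox: int = 1
    n_contacts: int = 2
    contact_gap_vox: int = 1
    contact_plate_radii_vox: tuple[int, int, int] = (2, 2, 14)
    noise_smooth_vox: float = 1.0
    n_vesicles: int = 5
    vesicle_radii_vox: tuple[int, int, int] = (1, 2, 2)
    vesicle_intensity: float = 0.1
    n_background_tubes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.psf_fwhm_nm):
            raise ValueError("psf_fwhm_nm must be positive per axis")
        if self.separation_nm < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sigma < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def psf_sigma_vox(self) -> tuple[float, float, float]:
        return tuple(
            f * FWHM_TO_SIGMA / s for f, s in zip(self.psf_fwhm_nm, self.spacing)
        )


@dataclass
class GroundTruth:
    """Voxel-level truth accompanying a phantom volume pair."""

    contact_mask: np.ndarray
    object_labels_a: np.ndarray
    object_labels_b: np.ndarray
    interface_region: np.ndarray
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------- geometry

def _grid(shape):
    return np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]


def _ellipsoid(shape, center, radii) -> np.ndarray:
    zz, yy, xx = _grid(shape)
    cz, cy, cx = center
    rz, ry, rx = radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + (
        (xx - cx) / rx
    ) ** 2 <= 1.0


def _tube_x(shape, z, y, x0, x1, r_lat, r_z) -> np.ndarray:
    """Tube along the x axis with elliptical (z, y) cross-section."""
    zz, yy, xx = _grid(shape)
    cross = ((zz - z) / r_z) ** 2 + ((yy - y) / r_lat) ** 2 <= 1.0
    return cross & (xx >= x0) & (xx <= x1)


def _check_bounds(mask: np.ndarray, what: str) -> None:
    if not mask.any():
        raise GeometryError(f"{what} is empty (out of grid bounds?)")
    shell = np.zeros(mask.shape, dtype=bool)
    shell[0, :, :] = shell[-1, :, :] = True
    shell[:, 0, :] = shell[:, -1, :] = True
    shell[:, :, 0] = shell[:, :, -1] = True
    if (mask & shell).any():
        raise GeometryError(f"{what} touches the grid boundary")


def _lateral_edt(outside: np.ndarray, spacing) -> np.ndarray:
    """Distance (in lateral-voxel units) from each voxel to a solid."""
    aniso = spacing[0] / spacing[2]
    return ndimage.distance_transform_edt(outside, sampling=(aniso, 1.0, 1.0))


def _gap_interface(solid_a, solid_b, spacing, sep_vox) -> np.ndarray:
    """True-interface voxels between two solids separated by ``sep_vox``.

    Voxels outside both solids, within one lateral voxel of the
    equidistant mid-gap surface (|dA - dB| <= 1), and where the local
    surface-to-surface gap is within one voxel of the nominal separation
    (dA + dB <= sep + 3, absorbing grid quantization and diagonal
    adjacency).  This is robust to
    the voxel quantization of fractional separations, including
    separation 0 where no pure gap voxel may exist on the grid.
    """
    da = _lateral_edt(~solid_a, spacing)
    db = _lateral_edt(~solid_b, spacing)
    return (
        (~solid_a)
        & (~solid_b)
        & (np.abs(da - db) <= 1.0)
        & (da + db <= sep_vox + 3.0)
    )


def _render(solid_intensity: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Blur a solid intensity field with the anisotropic Gaussian PSF."""
    return ndimage.gaussian_filter(
        solid_intensity, sigma=spec.psf_sigma_vox, mode="constant", truncate=4.0
    )


def _acquire(
    solid_intensity: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """PSF blur plus the phantom's acquisition-noise model.

    The pipeline's intended input is *deconvolved* data, whose residual
    noise is weak and spatially correlated; the Gaussian noise field is
    therefore smoothed by ``noise_smooth_vox`` voxels before being added
    (0 gives white noise).  Poisson noise, if enabled, acts on the
    blurred intensity at ``poisson_scale`` expected photons per unit.
    """
    img = _render(solid_intensity, spec)
    if spec.poisson_scale > 0:
        img = (
            rng.poisson(np.clip(img, 0, None) * spec.poisson_scale)
            / spec.poisson_scale
        )
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, img.shape)
        if spec.noise_smooth_vox > 0:
            noise = ndimage.gaussian_filter(noise, spec.noise_smooth_vox)
        img = img + noise
    return np.clip(img, 0.0, None)


def add_noise(
    volume: np.ndarray,
    gaussian_sigma: float = 0.0,
    poisson_scale: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Seeded acquisition noise: optional Poisson stage, then Gaussian, clip at 0.

    ``poisson_scale`` is the expected photon count at unit intensity; 0
    disables the Poisson stage.  ``gaussian_sigma`` is additive read
    noise in intensity units.  With both parameters 0 this is the
    identity.
    """
    if gaussian_sigma < 0 or poisson_scale < 0:
        raise ValueError("noise parameters must be >= 0")
    out = np.asarray(volume, dtype=np.float64)
    if gaussian_sigma == 0 and poisson_scale == 0:
        return out.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sigma > 0:
        out = out + rng.normal(0.0, gaussian_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------- phantoms

def make_two_object_phantom(spec: PhantomSpec) -> tuple[VolumePair, GroundTruth]:
    """Two spheres, one per channel, separated along x by ``separation_nm``.

    Each channel is the indicator of its sphere times its intensity,
    convolved with the Gaussian PSF, plus noise if requested.  The
    default radius (1000 nm) makes the interface locally planar at the
    scale of the correlation window, the regime of a real organelle
    contact.  The true contact mask marks mid-gap voxels adjacent to both
    sphere surfaces — and is empty when the separation exceeds
    ``resolution_nm``, where no contact exists to reconstruct.
    """
    nz, ny, nx = spec.shape
    r_vox = (
        spec.radius_nm / spec.spacing[0],
        spec.radius_nm / spec.spacing[1],
        spec.radius_nm / spec.spacing[2],
    )
    sep_vox = spec.separation_nm / spec.spacing[2]
    cz, cy = (nz - 1) / 2, (ny - 1) / 2
    half = r_vox[2] + sep_vox / 2
    ca = ((nx - 1) / 2 - half, cy, cz)
    cb = ((nx - 1) / 2 + half, cy, cz)
    solid_a = _ellipsoid(spec.shape, (cz, cy, ca[0]), r_vox)
    solid_b = _ellipsoid(spec.shape, (cz, cy, cb[0]), r_vox)
    _check_bounds(solid_a, "sphere A")
    _check_bounds(solid_b, "sphere B")
    rng = np.random.default_rng(spec.seed)
    chan_a = _acquire(solid_a * spec.intensities[0], spec, rng)
    chan_b = _acquire(solid_b * spec.intensities[1], spec, rng)
    interface = _gap_interface(solid_a, solid_b, spec.spacing, sep_vox)
    contact = (
        interface
        if spec.separation_nm <= spec.resolution_nm
        else np.zeros(spec.shape, dtype=bool)
    )
    gt = GroundTruth(
        contact_mask=contact,
        object_labels_a=solid_a.astype(np.int32),
        object_labels_b=solid_b.astype(np.int32),
        interface_region=interface,
        info={
            "separation_nm": spec.separation_nm,
            "resolution_nm": spec.resolution_nm,
            "radius_nm": spec.radius_nm,
        },
    )
    return VolumePair(chan_a, chan_b, spec.spacing), gt


def separation_sweep(
    spec: PhantomSpec, separations_nm
) -> list[tuple[float, VolumePair, GroundTruth]]:
    """Two-object phantom series over a list of edge-to-edge separations."""
    out = []
    for s in separations_nm:
        pair, gt = make_two_object_phantom(replace(spec, separation_nm=float(s)))
        out.append((float(s), pair, gt))
    return out


def make_cell_phantom(spec: PhantomSpec) -> tuple[VolumePair, GroundTruth]:
    """Whole-volume phantom: ER-like tubes, mitochondria, vesicle decoys.

    Layout (deterministic given the spec):

    * ``n_mito`` ellipsoids in the mid z-plane, spread along y, long axis
      along x, sized above the vesicle-filter thresholds;
    * one ER sheet per designated contact — a plate hugging the
      mitochondrion flank at an edge-to-edge lateral gap of
      ``contact_gap_vox``, thin along y and extended along z and x so the
      interface is locally planar (alternating flanks for > n_mito
      contacts);
    * ``n_vesicles`` small dim ellipsoids below both filter thresholds,
      strung along a decoy tube in a distant z-plane, each at contact
      distance from it;
    * ``n_background_tubes`` ER tubes far (>> resolution) from all
      mitochondria.

    Ground truth: contact mask with exactly ``n_contacts`` components,
    true mitochondria/vesicle labels with sizes and intensity scales.
    """
    nz, ny, nx = spec.shape
    if spec.n_mito < 1:
        raise GeometryError("cell phantom needs at least one mitochondrion")
    if spec.n_contacts > 2 * spec.n_mito:
        raise GeometryError("at most two contact tubes per mitochondrion")
    rz, ry, rx = spec.mito_radii_vox
    z_mid = nz // 2
    ys = np.linspace(0, ny, spec.n_mito + 2, dtype=int)[1:-1]
    # ensure neighbouring mitochondria leave room for tubes on both sides
    min_pitch = 2 * (ry + spec.contact_gap_vox + 2 * spec.tube_radius_vox) + 4
    if spec.n_mito > 1 and np.min(np.diff(ys)) < min_pitch:
        raise GeometryError("mitochondria too close to route contact tubes")

    mito_solids, mito_labels = [], np.zeros(spec.shape, dtype=np.int32)
    for i, y in enumerate(ys):
        solid = _ellipsoid(spec.shape, (z_mid, y, nx // 2), (rz, ry, rx))
        _check_bounds(solid, f"mitochondrion {i}")
        mito_solids.append(solid)
        mito_labels[solid] = i + 1

    tube_masks, contact_components = [], []
    r_t, r_tz = spec.tube_radius_vox, spec.tube_z_radius_vox
    prz, pry, prx = spec.contact_plate_radii_vox
    for c in range(spec.n_contacts):
        i = c % spec.n_mito
        side = 1 if c < spec.n_mito else -1
        # ER sheet hugging the mitochondrion flank: thin along y, extended
        # along z and x, so the interface is locally planar at window scale
        y_plate = ys[i] + side * (ry + spec.contact_gap_vox + pry)
        x0, x1 = nx // 2 - prx, nx // 2 + prx
        plate = _tube_x(spec.shape, z_mid, y_plate, x0, x1, pry, prz)
        _check_bounds(plate, f"contact sheet {c}")
        tube_masks.append(plate)
        contact_components.append(
            _gap_interface(mito_solids[i], plate, spec.spacing,
                           spec.contact_gap_vox)
        )

    # vesicles + decoy tube in a far z-plane
    vesicle_labels = np.zeros(spec.shape, dtype=np.int32)
    if spec.n_vesicles > 0:
        z_ves = max(spec.vesicle_radii_vox[0] + 5, nz // 8)
        if z_mid - z_ves < 8:
            raise GeometryError("volume too thin to isolate the vesicle plane")
        y_ves = ny // 2
        vrz, vry, vrx = spec.vesicle_radii_vox
        y_decoy = y_ves + vry + spec.contact_gap_vox + r_t
        xs = np.linspace(0, nx, spec.n_vesicles + 2, dtype=int)[1:-1]
        for j, xv in enumerate(xs):
            ves = _ellipsoid(spec.shape, (z_ves, y_ves, xv), (vrz, vry, vrx))
            _check_bounds(ves, f"vesicle {j}")
            vesicle_labels[ves] = j + 1
        decoy = _tube_x(
            spec.shape, z_ves, y_decoy, xs[0] - 2 * r_t, xs[-1] + 2 * r_t, r_t, r_tz
        )
        _check_bounds(decoy, "decoy tube")
        tube_masks.append(decoy)

    for b in range(spec.n_background_tubes):
        z_bg = nz - 1 - max(r_tz + 3, nz // 8) if b % 2 == 0 else max(r_tz + 3, nz // 8)
        y_bg = ny // 3 if b % 2 == 0 else 2 * ny // 3
        tube_masks.append(
            _tube_x(spec.shape, z_bg, y_bg, nx // 8, nx - nx // 8, r_t, r_tz)
        )

    er_solid = np.zeros(spec.shape, dtype=bool)
    for t in tube_masks:
        er_solid |= t
    if (er_solid & (mito_labels > 0)).any() or (er_solid & (vesicle_labels > 0)).any():
        raise GeometryError("ER tubes overlap mitochondria/vesicle solids")

    mito_mask = mito_labels > 0
    if spec.mito_membrane_label:
        # outer-membrane marker: intensity on a surface shell (~2 lateral,
        # 1 axial voxel thick), as with TOM20-style labelling; peak signal
        # then sits at the surface, where contacts form
        struct = _ellipsoid((3, 5, 5), (1, 2, 2), (1.2, 2.2, 2.2))
        mito_mask = mito_mask & ~ndimage.binary_erosion(mito_mask, structure=struct)
    mito_field = mito_mask * spec.mito_intensity + (
        vesicle_labels > 0
    ) * spec.vesicle_intensity
    rng = np.random.default_rng(spec.seed)
    chan_a = _acquire(er_solid * spec.intensities[0], spec, rng)
    chan_b = _acquire(mito_field.astype(np.float64), spec, rng)

    contact_mask = np.zeros(spec.shape, dtype=bool)
    for comp in contact_components:
        if not comp.any():
            raise GeometryError("a designated contact produced no interface voxels")
        contact_mask |= comp
    labels_b = mito_labels.copy()
    labels_b[vesicle_labels > 0] = spec.n_mito + vesicle_labels[vesicle_labels > 0]
    gt = GroundTruth(
        contact_mask=contact_mask,
        object_labels_a=er_solid.astype(np.int32),
        object_labels_b=labels_b,
        interface_region=contact_mask.copy(),
        info={
            "n_contacts": spec.n_contacts,
            "mito_sizes_vox": [int(s.sum()) for s in mito_solids],
            "mito_intensity": spec.mito_intensity,
            "vesicle_sizes_vox": [
                int((vesicle_labels == j + 1).sum()) for j in range(spec.n_vesicles)
            ],
            "vesicle_intensity": spec.vesicle_intensity,
            "contact_gap_vox": spec.contact_gap_vox,
        },
    )
    return VolumePair(chan_a, chan_b, spec.spacing), gt


def cell_phantom_spec(**overrides) -> PhantomSpec:
    """The standard whole-cell phantom study conditions.

    A 48 x 160 x 192 voxel volume (4.8 x 4 x 4.8 um at STED spacing) with
    two membrane-labelled mitochondria, two designated sheet contacts,
    five sub-threshold vesicles strung along a decoy tube, background ER
    tubes, and weak correlated acquisition noise (sigma 0.01, smoothed
    over 1 voxel) emulating deconvolved data.
    """
    base = dict(shape=(48, 160, 192), noise_sigma=0.01)
    base.update(overrides)
    return PhantomSpec(**base)
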