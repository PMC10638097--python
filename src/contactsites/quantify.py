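"""Contact morphometrics and cell-level statistics.

Detected contacts follow a strongly long-tailed size distribution, so
they are quantified two ways: per contact (volume, response strength,
eigenvalue shape features) and by a non-overlapping sliding cube over the
mitochondria surface (local coverage and contact counts), which keeps the
visually dominant large contacts from being undercounted.

Shape features use the linear/planar/spherical decomposition of the
response-weighted coordinate covariance eigenvalues l1 >= l2 >= l3:

    anisotropy = (l1 - l2) / l1   (linear)
    planarity  = (l2 - l3) / l1   (planar)
    sphericity = l3 / l1          (spherical)

which sum to one for every contact.  Coordinates are physical (nm), so
the anisotropic axial spacing is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu

from .filters import STRUCT_26, MitoComponents
from .response import ResponseMap


@dataclass
class ContactSet:
    """26-connected contact components surviving all filters.

    Labels are positive integers over background 0; every component has
    at least ``min_contact_voxels`` voxels.
    """

    labels: np.ndarray
    volumes: pd.DataFrame  # columns: label, volume

    @property
    def n_contacts(self) -> int:
        return len(self.volumes)

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def subset(self, keep_labels: np.ndarray) -> "ContactSet":
        labels = np.where(np.isin(self.labels, keep_labels), self.labels, 0)
        vols = self.volumes[self.volumes.label.isin(keep_labels)].reset_index(
            drop=True
        )
        return ContactSet(labels, vols)


def label_contacts(magnitude: np.ndarray, min_contact_voxels: int = 3) -> ContactSet:
    """Label the positive-response support and drop sub-resolution specks.

    Components with fewer than ``min_contact_voxels`` voxels (default 3,
    i.e. size <= 2) are below the diffraction limit and removed.
    Connectivity is 26 (face, edge and corner neighbours).
    """
    support = np.asarray(magnitude) > 0
    labels, n = ndimage.label(support, structure=STRUCT_26)
    if n == 0:
        return ContactSet(
            labels.astype(np.int32), pd.DataFrame(columns=["label", "volume"])
        )
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_contact_voxels) + 1
    labels = np.where(np.isin(labels, keep), labels, 0).astype(np.int32)
    vols = pd.DataFrame({"label": keep, "volume": sizes[keep - 1]})
    return ContactSet(labels, vols.reset_index(drop=True))


def contact_features(
    contacts: ContactSet,
    resp: ResponseMap,
    spacing: tuple[float, float, float],
) -> pd.DataFrame:
    """Per-contact morphometric feature table.

    For each contact: volume (voxels), geometric mean of the per-voxel
    response magnitude, centroid (voxel coordinates), eigenvalues of the
    response-weighted physical-coordinate covariance (nm^2), the
    sphericity/planarity/anisotropy decomposition, and height — physical
    axial extent (max z - min z + 1 voxel) * axial spacing, in nm.
    Degenerate (collinear) contacts have l2 = l3 = 0, hence planarity 0
    and anisotropy 1.
    """
    rows = []
    mag = resp.magnitude
    sp = np.asarray(spacing, dtype=np.float64)
    for row in contacts.volumes.itertuples():
        coords = np.argwhere(contacts.labels == row.label)
        wts = mag[tuple(coords.T)]
        if np.any(wts <= 0):
            raise ValueError(
                f"contact {row.label} has voxels with non-positive response"
            )
        phys = coords * sp  # (n, 3) in nm
        wsum = wts.sum()
        mean = (wts[:, None] * phys).sum(axis=0) / wsum
        centred = phys - mean
        cov = (wts[:, None] * centred).T @ centred / wsum
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        evals = np.clip(evals, 0.0, None)
        l1, l2, l3 = evals
        if l1 > 0:
            aniso, plan, sphe = (l1 - l2) / l1, (l2 - l3) / l1, l3 / l1
        else:  # single-point mass: convention — perfectly spherical
            aniso, plan, sphe = 0.0, 0.0, 1.0
        if resp.params.height_from_eigenvalue:
            height = 2.0 * np.sqrt(l1)
        else:
            height = (coords[:, 0].max() - coords[:, 0].min() + 1) * sp[0]
        cz, cy, cx = coords.mean(axis=0)
        rows.append(
            {
                "label": row.label,
                "volume": row.volume,
                "gm_spearman": float(np.exp(np.mean(np.log(wts)))),
                "centroid_z": cz,
                "centroid_y": cy,
                "centroid_x": cx,
                "lambda1": l1,
                "lambda2": l2,
                "lambda3": l3,
                "sphericity": sphe,
                "planarity": plan,
                "anisotropy": aniso,
                "height_nm": height,
            }
        )
    cols = [
        "label", "volume", "gm_spearman", "centroid_z", "centroid_y", "centroid_x",
        "lambda1", "lambda2", "lambda3", "sphericity", "planarity", "anisotropy",
        "height_nm",
    ]
    return pd.DataFrame(rows, columns=cols)


def mito_surface(mito: MitoComponents) -> np.ndarray:
    """Boundary voxels (26-neighbourhood) of the kept mitochondria components."""
    kept = mito.kept_mask
    if not kept.any():
        return np.zeros(kept.shape, dtype=bool)
    return kept & ~ndimage.binary_erosion(kept, structure=STRUCT_26)


def sliding_window_stats(
    contacts: ContactSet,
    mito: MitoComponents,
    quant_k: int = 5,
) -> pd.DataFrame:
    """Coverage and contact counts per non-overlapping sampling cube.

    The volume is tiled with cubes of ``5k x 5k`` lateral by ``k`` axial
    voxels (a physical cube under the 4:1 axial anisotropy; 25 x 25 x 5
    at the default k = 5; partial edge tiles are included).  Per cube:
    the number of kept-mitochondria surface voxels, how many of those lie
    within the 1-voxel adjacency radius of a contact voxel, their ratio,
    and the number of distinct contact components adjacent to the cube's
    surface voxels.  Cubes without surface are excluded.
    """
    if quant_k < 1:
        raise ValueError(f"quant_k must be >= 1, got {quant_k}")
    surface = mito_surface(mito)
    cols = [
        "iz", "iy", "ix", "mito_surface_voxels", "covered_surface_voxels",
        "coverage_ratio", "n_contacts",
    ]
    if not surface.any():
        import warnings

        warnings.warn("no kept mitochondria components; window table is empty",
                      stacklevel=2)
        return pd.DataFrame(columns=cols)
    cmask = contacts.mask()
    covered = surface & ndimage.binary_dilation(cmask, structure=STRUCT_26)
    nz, ny, nx = surface.shape
    dz, dy, dx = quant_k, 5 * quant_k, 5 * quant_k
    # per-contact: cubes whose surface shell its 1-voxel dilation touches
    adj_labels = _adjacent_label_cubes(contacts, surface, (dz, dy, dx))
    rows = []
    for iz, z0 in enumerate(range(0, nz, dz)):
        for iy, y0 in enumerate(range(0, ny, dy)):
            for ix, x0 in enumerate(range(0, nx, dx)):
                sl = (
                    slice(z0, z0 + dz),
                    slice(y0, y0 + dy),
                    slice(x0, x0 + dx),
                )
                n_surf = int(surface[sl].sum())
                if n_surf == 0:
                    continue
                n_cov = int(covered[sl].sum())
                rows.append(
                    {
                        "iz": iz, "iy": iy, "ix": ix,
                        "mito_surface_voxels": n_surf,
                        "covered_surface_voxels": n_cov,
                        "coverage_ratio": n_cov / n_surf,
                        "n_contacts": len(adj_labels.get((iz, iy, ix), ())),
                    }
                )
    return pd.DataFrame(rows, columns=cols)


def _adjacent_label_cubes(
    contacts: ContactSet, surface: np.ndarray, cube: tuple[int, int, int]
) -> dict[tuple[int, int, int], set[int]]:
    """Map cube index -> set of contact labels adjacent to its surface voxels."""
    out: dict[tuple[int, int, int], set[int]] = {}
    dz, dy, dx = cube
    for row in contacts.volumes.itertuples():
        comp = contacts.labels == row.label
        near = ndimage.binary_dilation(comp, structure=STRUCT_26)
        touched = np.argwhere(near & surface)
        for z, y, x in touched:
            key = (z // dz, y // dy, x // dx)
            out.setdefault(key, set()).add(int(row.label))
    return out


def match_against_truth(
    detected: np.ndarray, truth: np.ndarray, tol_vox: float = 2.0
) -> tuple[float, float]:
    """Voxel recall and precision of a detected mask against ground truth.

    A truth voxel is recalled if a detected voxel lies within ``tol_vox``
    voxels (index space); a detected voxel is a true positive if a truth
    voxel lies within the same tolerance.  The default tolerance equals
    the correlation window half-width: a windowed statistic cannot
    localize an interface more sharply than its own window.
    """
    detected = np.asarray(detected) > 0
    truth = np.asarray(truth) > 0
    if not truth.any():
        return (1.0 if not detected.any() else 0.0), (
            0.0 if detected.any() else 1.0
        )
    if not detected.any():
        return 0.0, 1.0
    d_det = ndimage.distance_transform_edt(~detected)
    d_tru = ndimage.distance_transform_edt(~truth)
    recall = float((d_det[truth] <= tol_vox).mean())
    precision = float((d_tru[detected] <= tol_vox).mean())
    return recall, precision


def window_summary(windows: pd.DataFrame) -> dict:
    """Cell-level means over cubes containing mitochondria surface."""
    if len(windows) == 0:
        return {"mean_coverage_ratio": 0.0, "mean_n_contacts": 0.0, "n_cubes": 0}
    return {
        "mean_coverage_ratio": float(windows.coverage_ratio.mean()),
        "mean_n_contacts": float(windows.n_contacts.mean()),
        "n_cubes": int(len(windows)),
    }


def q95_summary(contacts: ContactSet, large_contact_voxels: int = 500) -> dict:
    """Large-contact summary: per-cell 95th volume quantile and counts.

    The quantile uses linear interpolation between order statistics
    (numpy's default convention).  ``count_large`` counts contacts with
    volume strictly above ``large_contact_voxels``.
    """
    vols = contacts.volumes.volume.to_numpy(dtype=np.float64)
    if vols.size == 0:
        return {"n_contacts": 0, "q95_volume": 0.0, "labels_above_q95": [],
                "count_large": 0}
    q95 = float(np.quantile(vols, 0.95))
    above = contacts.volumes.loc[contacts.volumes.volume > q95, "label"]
    return {
        "n_contacts": int(vols.size),
        "q95_volume": q95,
        "labels_above_q95": [int(v) for v in above],
        "count_large": int((vols > large_contact_voxels).sum()),
    }


def compare_groups(
    group_a: pd.DataFrame, group_b: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Two-sided Mann–Whitney comparison of per-cell summary features.

    Each row of a group is one cell (tests are always computed on
    per-cell aggregates, never on pooled contacts, to respect
    independence).  No outlier removal and no multiple-testing correction
    are performed.  Requires at least 3 cells per group.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError(
            f"need >= 3 cells per group, got {len(group_a)} and {len(group_b)}"
        )
    if features is None:
        features = [
            c
            for c in group_a.columns
            if c in group_b.columns and np.issubdtype(group_a[c].dtype, np.number)
        ]
    rows = []
    for feat in features:
        a = group_a[feat].to_numpy(dtype=np.float64)
        b = group_b[feat].to_numpy(dtype=np.float64)
        res = mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "feature": feat,
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "u_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)
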