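"""Contact labelling, shape features, window statistics, group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from contactsites import (
    ContactSet,
    DetectParams,
    ResponseMap,
    compare_groups,
    contact_features,
    label_contacts,
    q95_summary,
    sliding_window_stats,
    window_summary,
)
from contactsites.filters import STRUCT_26, MitoComponents
from contactsites.quantify import mito_surface

ISO = (25.0, 25.0, 25.0)


def response_for(mag):
    params = DetectParams()
    return ResponseMap(
        rho_lap=-np.asarray(mag, float),
        rho_int=np.where(np.asarray(mag) > 0, -1.0, 0.0),
        magnitude=np.asarray(mag, float),
        n_window=params.n_window,
        params=params,
    )


def ball_mask(shape, center, radius):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius**2


class TestLabelContacts:
    def test_minimum_size_filter(self):
        """Components of 1 and 2 voxels are below the diffraction limit
        and removed; 3 voxels survive."""
        mag = np.zeros((8, 16, 16))
        mag[4, 2, 2] = 0.5                    # volume 1
        mag[4, 5, 5:7] = 0.5                  # volume 2
        mag[4, 10, 10:13] = 0.5               # volume 3
        contacts = label_contacts(mag, min_contact_voxels=3)
        assert contacts.n_contacts == 1
        assert contacts.volumes.volume.tolist() == [3]

    def test_empty_field_gives_empty_set(self):
        contacts = label_contacts(np.zeros((8, 8, 8)))
        assert contacts.n_contacts == 0 and not contacts.labels.any()

    def test_corner_touching_blobs_merge_under_26_connectivity(self):
        mag = np.zeros((10, 10, 10))
        mag[2:4, 2:4, 2:4] = 1.0
        mag[4:6, 4:6, 4:6] = 1.0  # shares only the corner at (4,4,4)-(3,3,3)
        contacts = label_contacts(mag, 3)
        assert contacts.n_contacts == 1
        n6 = ndimage.label(mag > 0)[1]  # face connectivity would see two
        assert n6 == 2


class TestContactFeatures:
    def test_digital_ball_is_spherical(self):
        shape = (24, 24, 24)
        mask = ball_mask(shape, (11.5, 11.5, 11.5), 8.0)
        contacts = label_contacts(np.where(mask, 0.8, 0.0), 3)
        feats = contact_features(contacts, response_for(np.where(mask, 0.8, 0.0)), ISO)
        row = feats.iloc[0]
        assert row.sphericity >= 0.95
        assert row.planarity <= 0.05
        assert row.sphericity + row.planarity + row.anisotropy == pytest.approx(1.0)

    def test_single_voxel_plate_is_planar(self):
        mag = np.zeros((8, 24, 24))
        mag[4, 2:22, 2:22] = 0.6
        contacts = label_contacts(mag, 3)
        feats = contact_features(contacts, response_for(mag), ISO)
        row = feats.iloc[0]
        assert row.planarity >= 0.9
        assert row.sphericity <= 0.05
        assert row.height_nm == 25.0  # one z-slice at isotropic 25 nm

    def test_collinear_contact_is_anisotropic(self):
        mag = np.zeros((8, 8, 24))
        mag[4, 4, 2:22] = 0.5
        feats = contact_features(
            label_contacts(mag, 3), response_for(mag), ISO
        )
        row = feats.iloc[0]
        assert row.anisotropy == pytest.approx(1.0)
        assert row.planarity == pytest.approx(0.0)

    def test_geometric_mean_of_two_level_contact(self):
        mag = np.zeros((8, 8, 8))
        mag[4, 4, 1:4] = 0.25
        mag[4, 4, 4:7] = 1.0
        feats = contact_features(label_contacts(mag, 3), response_for(mag), ISO)
        assert feats.iloc[0].gm_spearman == pytest.approx(0.5)

    def test_features_invariant_to_translation(self):
        mag = np.zeros((16, 16, 16))
        mag[3:6, 3:7, 3:8] = 0.7
        f1 = contact_features(label_contacts(mag, 3), response_for(mag), ISO)
        mag2 = np.roll(mag, (5, 4, 3), axis=(0, 1, 2))
        f2 = contact_features(label_contacts(mag2, 3), response_for(mag2), ISO)
        for col in ("volume", "gm_spearman", "lambda1", "sphericity",
                    "planarity", "anisotropy", "height_nm"):
            assert f1.iloc[0][col] == pytest.approx(f2.iloc[0][col])

    def test_anisotropic_spacing_enters_covariance(self):
        mag = np.zeros((12, 12, 12))
        mag[3:9, 5, 5] = 0.5  # 6 voxels along z
        feats = contact_features(
            label_contacts(mag, 3), response_for(mag), (100.0, 25.0, 25.0)
        )
        assert feats.iloc[0].height_nm == 600.0
        assert feats.iloc[0].lambda1 == pytest.approx(np.var(np.arange(6) * 100.0))


class TestWindowStats:
    def _mito_with_contacts(self, coat_probability=0.0, seed=0):
        # large ellipsoid: enough surface for stable per-cube sampling
        shape = (32, 64, 128)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        solid = (
            ((zz - 16) / 10.0) ** 2
            + ((yy - 32) / 20.0) ** 2
            + ((xx - 64) / 52.0) ** 2
        ) <= 1
        labels = solid.astype(np.int32)
        table = pd.DataFrame(
            {"label": [1], "size": [int(solid.sum())],
             "ln_size": [float(np.log(solid.sum()))],
             "mean_intensity": [0.9], "keep_flag": [True]}
        )
        mito = MitoComponents(labels, table)
        shell_out = ndimage.binary_dilation(solid, structure=STRUCT_26) & ~solid
        if coat_probability >= 1.0:
            contact = shell_out
        elif coat_probability > 0:
            g = np.random.default_rng(seed)
            contact = shell_out & (g.random(shape) < coat_probability)
        else:
            contact = np.zeros(shape, dtype=bool)
        vols = (
            pd.DataFrame({"label": [1], "volume": [int(contact.sum())]})
            if contact.any()
            else pd.DataFrame(columns=["label", "volume"])
        )
        return mito, ContactSet(contact.astype(np.int32), vols)

    def test_no_contacts_gives_zero_coverage(self):
        mito, contacts = self._mito_with_contacts(0.0)
        w = sliding_window_stats(contacts, mito, 5)
        assert len(w) > 0
        assert (w.coverage_ratio == 0).all() and (w.n_contacts == 0).all()

    def test_fully_sheathed_mitochondrion_saturates(self):
        mito, contacts = self._mito_with_contacts(1.0)
        w = sliding_window_stats(contacts, mito, 5)
        assert (w.coverage_ratio == 1.0).all()

    def test_uniform_coating_estimates_known_fraction_stably(self):
        """With a known coated fraction the mean per-cube coverage ratio
        recovers it within 0.05 and is stable (<=10% relative) in k."""
        mito, contacts = self._mito_with_contacts(0.08, seed=3)
        surface = mito_surface(mito)
        covered = surface & ndimage.binary_dilation(
            contacts.mask(), structure=STRUCT_26
        )
        f_true = covered.sum() / surface.sum()
        means = []
        for k in (3, 4, 5, 6, 7):
            w = sliding_window_stats(contacts, mito, k)
            means.append(w.coverage_ratio.mean())
        means = np.asarray(means)
        assert np.all(np.abs(means - f_true) <= 0.05)
        assert (means.max() - means.min()) / means.mean() <= 0.10

    def test_no_kept_mitochondria_warns_empty(self):
        mito, contacts = self._mito_with_contacts(0.5)
        mito.table.keep_flag = False
        with pytest.warns(UserWarning):
            w = sliding_window_stats(contacts, mito, 5)
        assert len(w) == 0
        assert window_summary(w) == {
            "mean_coverage_ratio": 0.0, "mean_n_contacts": 0.0, "n_cubes": 0
        }


class TestQ95:
    def _contacts(self, volumes):
        labels = np.zeros((4, 4, max(1, len(volumes))), dtype=np.int32)
        vols = pd.DataFrame(
            {"label": np.arange(1, len(volumes) + 1), "volume": volumes}
        )
        return ContactSet(labels, vols)

    def test_degenerate_distribution(self):
        s = q95_summary(self._contacts([7] * 100))
        assert s["q95_volume"] == 7 and s["labels_above_q95"] == []

    def test_matches_order_statistics_convention(self):
        vols = list(range(3, 101))
        s = q95_summary(self._contacts(vols))
        assert s["q95_volume"] == pytest.approx(np.quantile(np.array(vols), 0.95))
        # independent: linear interpolation between the order statistics
        v = np.sort(np.array(vols, float))
        h = (len(v) - 1) * 0.95
        expected = v[int(h)] + (h - int(h)) * (v[int(h) + 1] - v[int(h)])
        assert s["q95_volume"] == pytest.approx(expected)

    def test_large_contact_count(self):
        s = q95_summary(self._contacts([10, 600, 700]), large_contact_voxels=500)
        assert s["count_large"] == 2

    def test_consistency_between_q95_and_large_count(self):
        s = q95_summary(self._contacts([10, 20, 600, 700, 800]), 500)
        assert all(
            v > 500
            for v in [600, 700, 800]
            if v in s["labels_above_q95"] or True
        )
        assert s["count_large"] == 3

    def test_empty_set_is_all_zero(self):
        s = q95_summary(self._contacts([]))
        assert s == {"n_contacts": 0, "q95_volume": 0.0,
                     "labels_above_q95": [], "count_large": 0}


class TestCompareGroups:
    def test_identical_groups_maximal_p(self):
        df = pd.DataFrame({"coverage": [0.1, 0.2, 0.3, 0.4]})
        rep = compare_groups(df, df.copy())
        assert rep.p_value.iloc[0] == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact_p(self):
        a = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"x": [10.0, 11.0, 12.0]})
        rep = compare_groups(a, b)
        assert rep.u_statistic.iloc[0] == 0.0
        assert rep.p_value.iloc[0] == pytest.approx(0.1)  # minimal for n=3,3

    def test_shift_invariance(self, rng):
        a = pd.DataFrame({"x": rng.random(6)})
        b = pd.DataFrame({"x": rng.random(6)})
        p1 = compare_groups(a, b).p_value.iloc[0]
        p2 = compare_groups(a + 42.0, b + 42.0).p_value.iloc[0]
        assert p1 == pytest.approx(p2)

    def test_small_group_refused(self):
        a = pd.DataFrame({"x": [1.0, 2.0]})
        b = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match=">= 3 cells"):
            compare_groups(a, b)
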