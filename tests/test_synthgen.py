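"""Generator contracts: geometry of rendered pores, hard-core placement,
gold placement, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poremark.morphometry import radial_profile
from poremark.synthgen import (
    LARGE_PORE,
    GeometryError,
    PoreClassMix,
    PoreModel,
    SheetScene,
    noise_sigma_for_snr,
    place_gold,
    rectangle_mask,
    render_pore_patch,
    render_sheet,
)


class TestPoreModel:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"d_plug": 20.0, "d_inner": 17.5, "d_outer": 33.5},  # ordering
            {"n_fold": 0},
            {"subunit_amplitude": 1.5},
            {"ring_width_outer": 0.0},
            {"tilt_deg": 60.0},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            PoreModel(**kwargs)

    def test_mix_proportions_must_sum_to_one(self):
        with pytest.raises(GeometryError):
            PoreClassMix(((LARGE_PORE, 0.5), (LARGE_PORE, 0.2)))


class TestRenderPorePatch:
    def test_ring_ridges_at_half_the_printed_diameters(self, large_patch_noiseless):
        """Noiseless default render: radial-profile extrema at the ridge
        radii 16.75 nm (dark outer ring) and 8.75 nm (bright inner ring),
        and plug half-contrast radius 4.75 nm."""
        prof = radial_profile(large_patch_noiseless)
        r, p = prof.bin_centers_nm, prof.mean_intensity
        tail = p[-5:].mean()
        # outer ring = global minimum beyond the plug region
        beyond = r > 12.0
        r_outer = r[beyond][np.argmin(p[beyond])]
        assert r_outer == pytest.approx(16.75, abs=prof.bin_width_nm)
        # inner ring = global maximum
        r_inner = r[np.argmax(p)]
        assert r_inner == pytest.approx(8.75, abs=prof.bin_width_nm)
        # plug half-contrast radius
        c0 = tail - p[0]
        inside = r < 8.0
        below = inside & ((tail - p) < c0 / 2)
        r_half = r[below].min()
        assert r_half == pytest.approx(4.75, abs=prof.bin_width_nm)

    def test_zero_amplitude_patch_is_rotation_invariant(self, circular_patch_noiseless):
        from scipy.ndimage import rotate

        img = circular_patch_noiseless.pixels
        rot = rotate(img, 37.0, reshape=False, order=3, mode="nearest")
        n = img.shape[0]
        rr = np.hypot(*np.mgrid[0:n, 0:n] - (n - 1) / 2.0)
        inside = rr < n // 2 - 2
        assert np.max(np.abs(img[inside] - rot[inside])) < 0.01

    def test_outer_ring_modulation_has_dominant_harmonic_8(self, large_patch_noiseless):
        """Angular profile on the outer-ring band has period 45 deg: the
        dominant non-DC Fourier harmonic is index 8."""
        m = large_patch_noiseless
        n = m.pixels.shape[0]
        c = (n - 1) / 2.0
        angles = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
        r_px = 16.75 / m.pixel_size
        rows = c + r_px * np.sin(angles)
        cols = c + r_px * np.cos(angles)
        from scipy.ndimage import map_coordinates

        prof = map_coordinates(m.pixels, [rows, cols], order=1)
        spec = np.abs(np.fft.rfft(prof - prof.mean()))
        assert np.argmax(spec[1:]) + 1 == 8

    def test_patch_too_small_rejected(self):
        with pytest.raises(GeometryError, match="patch_radius"):
            render_pore_patch(LARGE_PORE, patch_radius=10.0)

    def test_metadata_echoes_ground_truth(self, large_patch_snr3):
        md = large_patch_snr3.provenance["model"]
        assert md["d_outer"] == 33.5 and md["n_fold"] == 8
        assert large_patch_snr3.provenance["seed"] == 42

    def test_noiseless_center_is_on_plug_minimum_plateau(self, large_patch_noiseless):
        """Ground-truth/image consistency: the central pixel sits on the
        dark plug plateau (within 1e-3 of the minimum over the plug
        region) and the plug region is darker than the local background."""
        m = large_patch_noiseless
        img = m.pixels
        n = img.shape[0]
        rr = np.hypot(*np.mgrid[0:n, 0:n] - (n - 1) / 2.0) * m.pixel_size
        plug = rr <= 4.75
        assert img[(n - 1) // 2, (n - 1) // 2] <= img[plug].min() + 1e-3
        assert img[plug].max() < 0.5


class TestRenderSheet:
    def test_pore_count_and_hardcore_at_lysed_density(self):
        """2 um x 2 um at 87 pores/um^2: exactly round(87*4) pores, all
        pairwise distances >= min_separation (brute-force all pairs)."""
        scene = SheetScene(mask=rectangle_mask(2000.0, 2000.0), density=87.0, noise_sigma=0.0, seed=5)
        _, truth = render_sheet(scene)
        assert len(truth.pores) == round(87.0 * scene.mask.area_um2)
        xy = truth.pores[["x_nm", "y_nm"]].to_numpy()
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= scene.min_separation

    def test_zero_density_gives_background_only(self):
        scene = SheetScene(mask=rectangle_mask(300.0, 300.0), density=0.0, noise_sigma=0.01, seed=1)
        img, truth = render_sheet(scene)
        assert len(truth.pores) == 0
        assert img.pixels.mean() == pytest.approx(0.5, abs=0.01)

    def test_dense_packing_succeeds(self):
        """200 /um^2 with 35 nm hard core (packing fraction ~0.19)."""
        scene = SheetScene(mask=rectangle_mask(1000.0, 1000.0), density=200.0, noise_sigma=0.0, seed=2)
        _, truth = render_sheet(scene)
        xy = truth.pores[["x_nm", "y_nm"]].to_numpy()
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert len(truth.pores) == 200 and d.min() >= 35.0

    def test_infeasible_packing_rejected_by_invariant(self):
        with pytest.raises(GeometryError, match="packing"):
            SheetScene(mask=rectangle_mask(500.0, 500.0), density=600.0, min_separation=35.0)

    def test_determinism_bitwise(self):
        mk = lambda: render_sheet(
            SheetScene(mask=rectangle_mask(500.0, 500.0), density=100.0, noise_sigma=0.05, seed=9)
        )
        img1, t1 = mk()
        img2, t2 = mk()
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1.pores.equals(t2.pores)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), density=st.floats(20.0, 150.0))
    def test_hardcore_property_random_scenes(self, seed, density):
        scene = SheetScene(mask=rectangle_mask(600.0, 600.0), density=density, noise_sigma=0.0, seed=seed)
        _, truth = render_sheet(scene)
        xy = truth.pores[["x_nm", "y_nm"]].to_numpy()
        if len(xy) > 1:
            d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() >= scene.min_separation
        assert all(scene.mask.contains(x, y) for x, y in xy)


@pytest.fixture(scope="module")
def sheet_truth():
    scene = SheetScene(mask=rectangle_mask(1200.0, 1200.0), density=87.0, noise_sigma=0.0, seed=4)
    _, truth = render_sheet(scene)
    return scene, truth


class TestPlaceGold:

    def _edge_dists(self, truth, pts):
        pores = truth.pores
        d = np.hypot(
            pts[:, None, 0] - pores["x_nm"].to_numpy()[None, :],
            pts[:, None, 1] - pores["y_nm"].to_numpy()[None, :],
        )
        return np.maximum(0.0, d - pores["r_outer_nm"].to_numpy()[None, :]).min(axis=1)

    def test_all_associated_when_fraction_one(self, sheet_truth):
        scene, truth = sheet_truth
        t = place_gold(truth, scene.mask, 1.0, threshold=20.0, n_particles=50, seed=1)
        pts = t.gold[["x_nm", "y_nm"]].to_numpy()
        assert (self._edge_dists(truth, pts) <= 20.0).all()

    def test_realized_count_matches_rounding(self, sheet_truth):
        """frac 0.9 of 440 particles -> exactly 396 within the 20 nm rule."""
        scene, truth = sheet_truth
        t = place_gold(truth, scene.mask, 0.9, threshold=20.0, n_particles=440, seed=2)
        d = self._edge_dists(truth, t.gold[["x_nm", "y_nm"]].to_numpy())
        assert (d <= 20.0).sum() == 396
        assert t.gold.intended_associated.sum() == 396

    def test_non_associated_strictly_beyond_threshold(self, sheet_truth):
        scene, truth = sheet_truth
        t = place_gold(truth, scene.mask, 0.0, threshold=20.0, n_particles=30, seed=3)
        d = self._edge_dists(truth, t.gold[["x_nm", "y_nm"]].to_numpy())
        assert (d > 20.0).all()


def test_noise_sigma_for_snr_definition():
    assert noise_sigma_for_snr(LARGE_PORE, 5.0) == pytest.approx(abs(LARGE_PORE.contrast_outer) / 5.0)
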