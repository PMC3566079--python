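import math

import numpy as np
import pytest

import oracles
from facetwear.surface_io import HeightMap, HeightMapError
from facetwear.texture import (
    ALL_PARAMETERS,
    ConstantSurfaceError,
    ConstantSurfaceWarning,
    compute_all,
    feature_params,
    functional_params,
    height_params,
    hybrid_params,
    segment_motifs,
    spatial_params,
)
from conftest import cosine_surface


def isclose(a, b, rel=1e-9, abs_tol=1e-12):
    return math.isclose(a, b, rel_tol=rel, abs_tol=abs_tol)


class TestHeightParams:
    def test_flat_surface(self):
        hm = HeightMap(np.full((8, 8), 2.0), 1.0, 1.0)
        with pytest.warns(ConstantSurfaceWarning):
            hp = height_params(hm)
        for key in ("Sa", "Sq", "Sp", "Sv", "Sz"):
            assert hp[key] == 0.0
        assert math.isnan(hp["Ssk"]) and math.isnan(hp["Sku"])

    def test_cosine_closed_forms(self):
        hp = height_params(cosine_surface(amplitude=2.0))
        assert hp["Sq"] == pytest.approx(2.0 / np.sqrt(2), rel=0.005)
        assert hp["Sa"] == pytest.approx(2.0 * 2 / np.pi, rel=0.005)
        assert hp["Ssk"] == pytest.approx(0.0, abs=0.005)
        assert hp["Sku"] == pytest.approx(1.5, rel=0.005)
        assert hp["Sz"] == pytest.approx(4.0, rel=0.005)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            z = rng.normal(0, 1.3, size=(16, 16))
            hm = HeightMap(z, dx=0.7, dy=0.4)
            got = height_params(hm)
            want = oracles.height_params(z, 0.7, 0.4)
            for key, v in want.items():
                assert isclose(got[key], v), key


class TestSpatialParams:
    def test_white_noise_isotropic(self, rng):
        hm = HeightMap(rng.normal(size=(128, 128)), 1.0, 1.0)
        sp = spatial_params(hm)
        assert sp["Str"] > 0.9
        assert sp["Sal"] <= 2.0

    def test_groove_field_direction_and_anisotropy(self):
        n = 256
        x = np.arange(n)
        X, Y = np.meshgrid(x, x)
        th = np.deg2rad(30.0)
        perp = -X * np.sin(th) + Y * np.cos(th)
        hm = HeightMap(np.sin(2 * np.pi * perp / 12.0), 1.0, 1.0)
        sp = spatial_params(hm)
        assert sp["Std"] == pytest.approx(30.0, abs=2.0)
        assert sp["Str"] < 0.3

    def test_rotation_by_90_degrees(self, rng):
        z = rng.normal(size=(128, 128))
        # anisotropic texture: smooth along rows only
        z = np.cumsum(z, axis=1)
        z -= z.mean()
        hm = HeightMap(z, 1.0, 1.0)
        rot = HeightMap(np.rot90(z).copy(), 1.0, 1.0)
        a = spatial_params(hm)
        b = spatial_params(rot)
        assert b["Std"] == pytest.approx((a["Std"] + 90.0) % 180.0, abs=2.0)
        assert b["Sal"] == pytest.approx(a["Sal"], rel=0.01)
        assert b["Str"] == pytest.approx(a["Str"], rel=0.01)


class TestHybridParams:
    def test_flat(self):
        hp = hybrid_params(HeightMap(np.full((8, 8), 1.0), 1.0, 1.0))
        assert hp["Sdq"] == 0.0 and hp["Sdr"] == 0.0

    def test_tilted_plane_closed_form(self):
        x = np.arange(32.0) * 0.5
        X, Y = np.meshgrid(x, x)
        hm = HeightMap(0.3 * X + 0.4 * Y, dx=0.5, dy=0.5)
        hp = hybrid_params(hm)
        assert hp["Sdq"] == pytest.approx(0.5, abs=1e-12)
        assert hp["Sdr"] == pytest.approx((np.sqrt(1.25) - 1) * 100, abs=1e-9)

    def test_sinusoid_rms_gradient(self):
        lam, A, n = 64.0, 1.0, 512
        x = np.arange(n)
        z = A * np.sin(2 * np.pi * x / lam)
        hm = HeightMap(np.tile(z, (16, 1)), 1.0, 1.0)
        hp = hybrid_params(hm)
        assert hp["Sdq"] == pytest.approx(2 * np.pi * A / lam / np.sqrt(2),
                                          rel=0.01)

    def test_matches_brute_force_oracle(self, rng):
        z = rng.normal(size=(16, 16))
        got = hybrid_params(HeightMap(z, dx=0.3, dy=0.9))
        want = oracles.hybrid_params(z, 0.3, 0.9)
        assert isclose(got["Sdq"], want["Sdq"])
        assert isclose(got["Sdr"], want["Sdr"])


class TestFunctionalParams:
    def test_flat_degenerate_curve(self):
        hm = HeightMap(np.zeros((8, 8)), 1.0, 1.0)
        fp = functional_params(hm)
        assert fp["Smr"] == 100.0
        assert fp["Vv"] == 0.0
        assert fp["Sxp"] == 0.0

    def test_two_level_step_surface_matches_oracle(self):
        d = 2.0
        z = np.zeros((10, 10))
        z[:5] = d / 2
        z[5:] = -d / 2
        hm = HeightMap(z, 1.0, 1.0)
        got = functional_params(hm)
        want = oracles.functional_params(z, 1.0, 1.0)
        for key, v in want.items():
            assert isclose(got[key], v), key
        # the step concentrates all void volume below the valley ratio
        assert got["Vvv"] > 0 and got["Vv"] > got["Vvv"]

    def test_matches_brute_force_oracle_random(self, rng):
        for _ in range(5):
            z = rng.normal(0, 2.0, size=(16, 16))
            got = functional_params(HeightMap(z, 0.5, 0.5))
            want = oracles.functional_params(z, 0.5, 0.5)
            for key, v in want.items():
                assert isclose(got[key], v), key

    def test_volume_monotonicity(self, rng):
        from facetwear.texture import mean_plane_residual, _height_at_mr
        z = mean_plane_residual(HeightMap(rng.normal(size=(20, 20)), 1, 1))
        zr = z.ravel()
        ps = [5.0, 10.0, 25.0, 50.0, 80.0, 95.0]
        heights = [_height_at_mr(zr, p) for p in ps]
        assert heights == sorted(heights, reverse=True)
        vms = [np.mean(np.clip(zr - h, 0, None)) for h in heights]
        vvs = [np.mean(np.clip(h - zr, 0, None)) for h in heights]
        assert vms == sorted(vms)                  # Vm non-decreasing in p
        assert vvs == sorted(vvs, reverse=True)    # Vv non-increasing in p


def _pitted_plane(centers, depth=3.0, sigma=3.0, n=96):
    x = np.arange(n)
    X, Y = np.meshgrid(x, x)
    z = np.zeros((n, n))
    for cx, cy in centers:
        z -= depth * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))
    return z


class TestSegmentation:
    def test_three_pits_three_dales(self):
        z = _pitted_plane([(20, 20), (70, 30), (40, 75)])
        motifs = segment_motifs(HeightMap(z, 1.0, 1.0))
        assert len(motifs.dales) == 3

    def test_single_bump_single_hill(self):
        z = -_pitted_plane([(48, 48)])
        motifs = segment_motifs(HeightMap(z, 1.0, 1.0))
        assert len(motifs.hills) == 1
        fp = feature_params(motifs, HeightMap(z, 1.0, 1.0))
        assert fp["Spd"] == pytest.approx(1.0 / motifs.evaluated_area_um2)

    def test_pruning_removes_shallow_noise(self, rng):
        z = _pitted_plane([(20, 20), (70, 30), (40, 75)])
        hm_clean = HeightMap(z, 1.0, 1.0)
        prune_h = 0.05 * (z.max() - z.min())
        noisy = z + rng.uniform(-0.3, 0.3, z.shape) * prune_h
        hm_noisy = HeightMap(noisy, 1.0, 1.0)
        unpruned = segment_motifs(hm_noisy, pruning_fraction=0.0)
        pruned = segment_motifs(hm_noisy, pruning_fraction=0.05)
        assert len(unpruned.dales) > 3
        assert len(pruned.dales) == 3

    def test_constant_surface_rejected(self):
        with pytest.raises(ConstantSurfaceError):
            segment_motifs(HeightMap(np.zeros((8, 8)), 1.0, 1.0))

    def test_three_identical_pits_volume(self):
        # equilateral arrangement about the grid centre, so the pits do
        # not tilt the reference mean plane
        depth, sigma = 3.0, 3.0
        r = 28.0
        c = 47.5
        centers = [(c, c + r),
                   (c - r * np.sin(np.pi / 3), c - r / 2),
                   (c + r * np.sin(np.pi / 3), c - r / 2)]
        z = _pitted_plane(centers, depth, sigma)
        hm = HeightMap(z, 1.0, 1.0)
        motifs = segment_motifs(hm)
        fp = feature_params(motifs, hm)
        # volume of one Gaussian pit = depth * 2 pi sigma^2
        v_one = depth * 2 * np.pi * sigma**2
        assert fp["Sdv"] == pytest.approx(v_one, rel=0.02)

    def test_spherical_cap_curvature(self):
        R = 200.0
        n = 64
        x = np.arange(n) - n / 2
        X, Y = np.meshgrid(x, x)
        cap = np.clip(R**2 - X**2 - Y**2, 0, None)
        z = np.sqrt(cap) - R + 5.0 * np.exp(-(X**2 + Y**2) / (2 * 400.0))
        # pure spherical cap (the added broad bump guarantees one motif)
        z = np.sqrt(np.clip(R**2 - X**2 - Y**2, 0, None))
        hm = HeightMap(z, 1.0, 1.0)
        motifs = segment_motifs(hm)
        fp = feature_params(motifs, hm)
        assert fp["Spc"] == pytest.approx(1.0 / R, rel=0.05)


class TestComputeAll:
    def test_all_parameters_present(self, rng):
        hm = HeightMap(rng.normal(size=(64, 64)), 1.0, 1.0, stage="raw")
        ps = compute_all(hm)
        assert tuple(ps.values) == ALL_PARAMETERS
        assert ps.conditions["Sal_s"] == 0.2
        assert ps.conditions["Smr_c_um"] == 1.0

    def test_headline_subset_is_emitted(self, rng):
        ps = compute_all(HeightMap(rng.normal(size=(32, 32)), 1.0, 1.0))
        assert {"S5v", "Sda", "Sdq", "Sdr", "Sdv", "Sp", "Ssk", "Sxp",
                "Sz", "Vvv"} <= set(ps.values)

    def test_height_identities(self, rng):
        ps = compute_all(HeightMap(rng.normal(size=(48, 48)), 1.0, 1.0))
        assert ps["Sz"] == pytest.approx(ps["Sp"] + ps["Sv"], abs=1e-12)
        assert ps["S10z"] == pytest.approx(ps["S5p"] + ps["S5v"], abs=1e-12)
        assert ps["Sq"] >= ps["Sa"] >= 0
        assert 0 < ps["Str"] <= 1
        assert 0 <= ps["Std"] < 180

    def test_scaling_homogeneity(self, rng):
        z = rng.normal(size=(48, 48))
        a = compute_all(HeightMap(z, 1.0, 1.0))
        b = compute_all(HeightMap(2 * z, 1.0, 1.0))
        for key in ("Sa", "Sq", "Sp", "Sv", "Sz", "S5p", "S5v", "S10z",
                    "Smc", "Sxp"):
            assert b[key] == pytest.approx(2 * a[key], rel=1e-6), key
        for key in ("Ssk", "Sku", "Str"):
            assert b[key] == pytest.approx(a[key], rel=1e-6), key

    def test_deterministic(self, rng):
        z = rng.normal(size=(32, 32))
        a = compute_all(HeightMap(z, 1.0, 1.0))
        b = compute_all(HeightMap(z.copy(), 1.0, 1.0))
        for key in ALL_PARAMETERS:
            assert a[key] == b[key] or (
                math.isnan(a[key]) and math.isnan(b[key]))
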