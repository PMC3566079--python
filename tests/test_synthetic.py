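import numpy as np
import pytest

from facetwear.surface_io import HeightMap
from facetwear.synthetic import (
    DietGroupConfig,
    SurfaceFeature,
    default_group_configs,
    generate_counting_features,
    generate_group_sample,
    generate_surface,
    render_feature,
)


def small_config(**kw):
    base = dict(label="G", n_animals=2, silica_mg_g=11.96, scratch_rate=10.0,
                pit_rate=10.0, orientation_kappa=4.0, depth_scale_um=1.5,
                between_animal_cv=0.1, target_Np=10.0, target_Ls_um=50.0,
                micro_relief_rate=0.0, extent_um=80.0, n_points=128)
    base.update(kw)
    return DietGroupConfig(**base)


class TestDefaultConfigs:
    def test_group_sizes_and_silica_anchors(self):
        cfgs = {c.label: c for c in default_group_configs()}
        assert [cfgs[k].n_animals for k in ("G", "GO", "LO", "L")] == [7, 6, 7, 6]
        assert cfgs["G"].silica_mg_g == pytest.approx(11.96)
        assert cfgs["L"].silica_mg_g == pytest.approx(0.10)

    def test_monotone_silica_coupling(self):
        cfgs = sorted(default_group_configs(), key=lambda c: c.silica_mg_g)
        sc = [c.silica_mg_g for c in cfgs]
        assert sc == sorted(sc)
        for attr, increasing in (("scratch_rate", True),
                                 ("orientation_kappa", True),
                                 ("between_animal_cv", False),
                                 ("pit_rate", False)):
            vals = [getattr(c, attr) for c in cfgs]
            assert vals == sorted(vals, reverse=not increasing), attr

    def test_np_ls_anchors(self):
        cfgs = {c.label: c for c in default_group_configs()}
        assert cfgs["G"].target_Np == pytest.approx(21.7)
        assert cfgs["L"].target_Np == pytest.approx(45.9)
        assert cfgs["G"].target_Ls_um == pytest.approx(59.1)
        assert cfgs["L"].target_Ls_um == pytest.approx(38.9)


class TestRenderFeature:
    def test_pit_depth_at_center(self):
        hm = HeightMap(np.zeros((101, 101)), 1.0, 1.0)
        f = SurfaceFeature("pit", 50.0, 50.0, 10.0, 8.0, 2.0, 0.0)
        out = render_feature(f, hm)
        assert out.heights.min() == pytest.approx(-2.0, abs=1e-6)
        r, c = np.unravel_index(out.heights.argmin(), out.heights.shape)
        assert (r, c) == (50, 50)

    def test_scratch_orientation_via_moments(self):
        hm = HeightMap(np.zeros((201, 201)), 1.0, 1.0)
        f = SurfaceFeature("scratch", 100.0, 100.0, 80.0, 6.0, 2.0, 30.0)
        out = render_feature(f, hm)
        ind = out.heights < -0.2            # indicator of the depression
        ys, xs = np.nonzero(ind)
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        cov = np.cov(np.stack([xs, ys]))
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, np.argmax(evals)]
        angle = np.degrees(np.arctan2(v[1], v[0])) % 180.0
        assert angle == pytest.approx(30.0, abs=2.0)

    def test_disjoint_features_commute(self):
        hm = HeightMap(np.zeros((120, 120)), 1.0, 1.0)
        f1 = SurfaceFeature("pit", 20.0, 20.0, 6.0, 5.0, 1.0, 0.0)
        f2 = SurfaceFeature("pit", 100.0, 100.0, 6.0, 5.0, 1.5, 0.0)
        ab = render_feature(f2, render_feature(f1, hm))
        ba = render_feature(f1, render_feature(f2, hm))
        assert np.array_equal(ab.heights, ba.heights)

    def test_far_field_unchanged(self):
        hm = HeightMap(np.zeros((120, 120)), 1.0, 1.0)
        f = SurfaceFeature("pit", 20.0, 20.0, 6.0, 5.0, 1.0, 0.0)
        out = render_feature(f, hm)
        assert np.all(out.heights[:, 60:] == 0.0)

    def test_center_outside_rejected(self):
        hm = HeightMap(np.zeros((50, 50)), 1.0, 1.0)
        f = SurfaceFeature("pit", 200.0, 10.0, 6.0, 5.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="extent"):
            render_feature(f, hm)


class TestFeatureInvariants:
    def test_pit_aspect_guard(self):
        with pytest.raises(ValueError, match="aspect"):
            SurfaceFeature("pit", 0, 0, 40.0, 5.0, 1.0, 0.0)

    def test_dimension_ordering_enforced(self):
        with pytest.raises(ValueError):
            SurfaceFeature("pit", 0, 0, 4.0, 5.0, 1.0, 0.0)


class TestGenerateSurface:
    def test_deterministic(self):
        cfg = small_config()
        hm1, f1 = generate_surface(cfg, 0, 42)
        hm2, f2 = generate_surface(cfg, 0, 42)
        assert np.array_equal(hm1.heights, hm2.heights, equal_nan=True)
        assert np.array_equal(hm1.mask, hm2.mask)
        assert len(f1) == len(f2)
        assert all(a.center_x == b.center_x and a.depth_um == b.depth_um
                   for a, b in zip(f1, f2))

    def test_different_animals_differ(self):
        cfg = small_config()
        hm1, _ = generate_surface(cfg, 0, 42)
        hm2, _ = generate_surface(cfg, 1, 42)
        assert not np.array_equal(hm1.heights, hm2.heights, equal_nan=True)

    def test_no_features_gives_form_plus_waviness(self):
        cfg = small_config(scratch_rate=0.0, pit_rate=0.0,
                           noise_sd_um=0.0, dropout_fraction=0.0,
                           between_animal_cv=0.0)
        hm, feats = generate_surface(cfg, 0, 7)
        assert feats == []
        assert hm.mask.all()
        # smooth: the highpassed content of a form+waviness surface is tiny
        z = hm.heights
        rough = z - np.mean(z)
        assert np.abs(np.diff(z, axis=1)).max() < 0.5   # no sharp edges

    def test_dropout_below_ceiling(self):
        hm, _ = generate_surface(small_config(), 0, 3)
        assert hm.measured_fraction > 0.80

    def test_mean_scratch_count_matches_rate(self):
        cfg = small_config(between_animal_cv=0.0, pit_rate=0.0,
                           micro_relief_rate=0.0)
        counts = [len([f for f in generate_counting_features(cfg, i, 5)])
                  for i in range(200)]
        # counting-field rate: scratch_rate per counting square, with the
        # 1.2x margin the expected field count is rate * 1.44
        expect = cfg.scratch_rate * 1.44
        assert np.mean(counts) == pytest.approx(expect, rel=0.10)


class TestGroupSample:
    def test_bundle_shape_and_reproducibility(self):
        bundle = generate_group_sample(master_seed=11)
        assert len(bundle) == 26
        groups = {}
        for s in bundle:
            groups.setdefault(s.group, 0)
            groups[s.group] += 1
        assert groups == {"G": 7, "GO": 6, "LO": 7, "L": 6}
        again = generate_group_sample(master_seed=11)
        for a, b in zip(bundle, again):
            assert a.animal_id == b.animal_id
            assert np.array_equal(a.surface.heights, b.surface.heights,
                                  equal_nan=True)
            assert a.silica_mg_g == b.silica_mg_g

    def test_silica_covariate_near_group_values(self):
        bundle = generate_group_sample(master_seed=2)
        sil = {}
        for s in bundle:
            sil.setdefault(s.group, []).append(s.silica_mg_g)
        assert np.mean(sil["G"]) == pytest.approx(11.96, rel=0.10)
        assert np.mean(sil["L"]) == pytest.approx(0.10, rel=0.10)

    def test_duplicate_labels_rejected(self):
        cfgs = [small_config(), small_config()]
        with pytest.raises(ValueError, match="duplicate"):
            generate_group_sample(cfgs, 0)

    def test_matches_standalone_generators(self):
        cfg = small_config(label="LO", n_animals=1)
        bundle = generate_group_sample([cfg], master_seed=9)
        hm, feats = generate_surface(cfg, 0, 9)
        assert np.array_equal(bundle[0].surface.heights, hm.heights,
                              equal_nan=True)
        f2d = generate_counting_features(cfg, 0, 9)
        assert len(bundle[0].features_2d) == len(f2d)
        assert all(a.center_x == b.center_x
                   for a, b in zip(bundle[0].features_2d, f2d))


class TestOrientationConcentration:
    def test_circular_variance_decreases_with_kappa(self):
        variances = []
        for kappa in (0.0, 2.0, 8.0):
            cfg = small_config(orientation_kappa=kappa, pit_rate=0.0,
                               scratch_rate=40.0, between_animal_cv=0.0)
            angles = []
            for i in range(30):
                angles += [f.orientation_deg
                           for f in generate_counting_features(cfg, i, 13)]
            theta = np.deg2rad(np.array(angles) * 2.0)
            R = np.abs(np.mean(np.exp(1j * theta)))
            variances.append(1.0 - R)
        assert variances[0] > variances[1] > variances[2]
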