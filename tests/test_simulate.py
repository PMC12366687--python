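import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spcryolm as sp
from spcryolm.simulate import BlinkKinetics, equilateral_vertices


class TestSamplePopulation:
    def test_class_fractions_match_weights(self):
        pop = sp.sample_population(1000, (0.21, 0.51, 0.28), (9.0, 19.0, 34.0), seed=1)
        labels = [p.class_label for p in pop]
        for lab, w in zip(("i", "ii", "iii"), (0.21, 0.51, 0.28)):
            assert abs(labels.count(lab) / 1000 - w) < 0.04

    def test_sides_follow_class_and_triangles_equilateral(self):
        pop = sp.sample_population(50, seed=3)
        side_of = dict(zip(("i", "ii", "iii"), (9.0, 19.0, 34.0)))
        for p in pop:
            assert p.side_length == side_of[p.class_label]
            v = p.vertex_positions_3d
            d = [np.linalg.norm(v[i] - v[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
            assert np.allclose(d, p.side_length, atol=1e-9)
            assert np.allclose(v.mean(axis=0), 0.0, atol=1e-9)

    def test_degenerate_weights(self):
        pop = sp.sample_population(30, (1.0, 0.0, 0.0), seed=0)
        assert all(p.class_label == "i" for p in pop)

    def test_empty_population(self):
        assert sp.sample_population(0, seed=0) == []

    def test_seeded_runs_reproducible(self):
        a = sp.sample_population(20, seed=42)
        b = sp.sample_population(20, seed=42)
        assert all(
            x.orientation == y.orientation and x.dipole_azimuths == y.dipole_azimuths
            for x, y in zip(a, b)
        )

    @pytest.mark.parametrize(
        "weights,sides",
        [
            ((-0.1, 0.6, 0.5), (9, 19, 34)),
            ((0.3, 0.3, 0.3), (9, 19, 34)),
            ((0.21, 0.51, 0.28), (9, -19, 34)),
        ],
    )
    def test_invalid_parameters(self, weights, sides):
        with pytest.raises(ValueError):
            sp.sample_population(10, weights, sides, seed=0)

    def test_off_on_ratio_invariant(self):
        kin = BlinkKinetics()
        assert kin.off_on_ratio == pytest.approx(10.0)


class TestOrientationSampling:
    def test_large_concentration_is_in_plane(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            yaw, pitch, roll = sp.sample_orientation("in_plane_biased", 1e6, seed=rng)
            assert pitch < 0.01 and roll < 0.01

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            sp.sample_orientation("sideways", 1.0, seed=0)

    def test_biased_pitch_mode_at_zero(self):
        rng = np.random.default_rng(1)
        pitch = [
            sp.sample_orientation("in_plane_biased", 9.0, seed=rng)[1]
            for _ in range(2000)
        ]
        hist, _ = np.histogram(pitch, bins=np.arange(0, 95, 5))
        assert hist.argmax() == 0

    def test_uniform_max_side_matches_view_grid_oracle(self):
        # oracle: project along a quasi-uniform grid of view directions and
        # compare the max-side distributions by Kolmogorov-Smirnov distance
        side = 19.0
        rng = np.random.default_rng(2)
        quat = rng.normal(size=(20000, 4))
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        from scipy.spatial.transform import Rotation

        euler = Rotation.from_quat(quat).as_euler("ZXY", degrees=True)
        sampled = np.sort(sp.max_projected_side(side, euler))

        verts = equilateral_vertices(side)
        k = np.arange(20000)
        phi = np.arccos(1 - 2 * (k + 0.5) / len(k))  # Fibonacci sphere
        lam = np.pi * (1 + 5**0.5) * k
        views = np.column_stack(
            [np.sin(phi) * np.cos(lam), np.sin(phi) * np.sin(lam), np.cos(phi)]
        )
        oracle = []
        for v in views:
            proj = verts - np.outer(verts @ v, v)
            d = [np.linalg.norm(proj[i] - proj[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
            oracle.append(max(d))
        oracle = np.sort(oracle)
        grid = np.linspace(side * 0.85, side, 400)
        cdf_a = np.searchsorted(sampled, grid) / len(sampled)
        cdf_b = np.searchsorted(oracle, grid) / len(oracle)
        assert np.abs(cdf_a - cdf_b).max() < 0.02


class TestProjection:
    def test_in_plane_projection_is_identity(self):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (33.0, 0.0, 0.0), (0, 0, 0))
        pts = sp.project_particle(p)
        d = [np.linalg.norm(pts[i] - pts[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        assert np.allclose(d, 19.0, atol=1e-9)

    def test_vertex_axis_rotation_closed_form(self):
        # rotating by 90 deg about the in-plane symmetry axis through a vertex
        # collapses the triangle to a segment of length sqrt(3)/2 * side
        p = sp.GroundTruthParticle(0, "ii", 1.0, (0.0, 0.0, 90.0), (0, 0, 0))
        pts = sp.project_particle(p)
        d = [np.linalg.norm(pts[i] - pts[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        assert max(d) == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    @given(
        yaw=st.floats(0, 360),
        pitch=st.floats(-90, 90),
        roll=st.floats(-180, 180),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_projection_is_a_contraction(self, yaw, pitch, roll):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (yaw, pitch, roll), (0, 0, 0))
        pts = sp.project_particle(p)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            assert np.linalg.norm(pts[i] - pts[j]) <= 19.0 + 1e-9


class TestBlinkingAndEvents:
    def test_dwell_ratio_and_photon_budget(self):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (0, 0, 0), (30, 60, 80))
        sch = sp.simulate_blinking(p, 100_000, 0.014, seed=5)
        on = np.concatenate([np.asarray(d) for d in sch.on_dwells])
        off = np.concatenate([np.asarray(d) for d in sch.off_dwells])
        assert abs(off.mean() / on.mean() - 10.0) / 10.0 < 0.15
        photons = sch.photons[sch.on]
        assert abs(photons.mean() - 70.0) / 70.0 < 0.10

    def test_channel_split_follows_malus_law(self):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (0, 0, 0), (0.0, 45.0, 90.0))
        sch = sp.simulate_blinking(p, 20_000, seed=7)
        ev = sp.emit_events(p, sch, 0.0, seed=8)
        for f, expected in ((0, 1.0), (1, 0.5), (2, 0.0)):
            sub = ev[ev.fluorophore_index == f]
            frac = sub.counts_ch1.sum() / (sub.counts_ch1 + sub.counts_ch2).sum()
            assert frac == pytest.approx(expected, abs=0.02)

    def test_counts_conserve_drawn_photons(self):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (0, 0, 0), (30, 60, 80))
        sch = sp.simulate_blinking(p, 2000, seed=1)
        ev = sp.emit_events(p, sch, 10.0, seed=2)
        for f in range(3):
            sub = ev[ev.fluorophore_index == f]
            totals = (sub.counts_ch1 + sub.counts_ch2).to_numpy()
            drawn = sch.photons[f, sub.frame.to_numpy()]
            assert (totals == drawn).all()

    def test_zero_noise_events_identical(self):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (0, 0, 0), (30, 60, 80))
        sch = sp.simulate_blinking(p, 2000, seed=3)
        ev = sp.emit_events(p, sch, 0.0, seed=4)
        for f in range(3):
            sub = ev[ev.fluorophore_index == f]
            assert sub.x_nm.nunique() == 1 and sub.y_nm.nunique() == 1

    def test_event_noise_sd_recovered(self):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (0, 0, 0), (30, 60, 80))
        sch = sp.simulate_blinking(p, 8000, seed=9)
        ev = sp.emit_events(p, sch, 10.0, seed=10)
        sub = ev[ev.fluorophore_index == 0]
        assert len(sub) > 100
        assert abs(sub.x_nm.std() - 10.0) / 10.0 < 0.15

    def test_events_only_during_on_frames(self):
        p = sp.GroundTruthParticle(0, "ii", 19.0, (0, 0, 0), (30, 60, 80))
        sch = sp.simulate_blinking(p, 2000, seed=11)
        ev = sp.emit_events(p, sch, 10.0, seed=12)
        for f in range(3):
            frames = ev[ev.fluorophore_index == f].frame.to_numpy()
            assert sch.on[f, frames].all()


def test_event_table_roundtrip(tmp_path):
    from spcryolm import io

    ds = sp.simulate_dataset(5, seed=13)
    path = tmp_path / "events.tsv"
    io.write_events(ds.events, path)
    back = io.read_events(path)
    assert len(back) == len(ds.events)
    assert np.allclose(back.x_nm, ds.events.x_nm)
    io.write_truth(ds.truth, tmp_path / "truth.tsv")
    truth = io.read_truth(tmp_path / "truth.tsv")
    assert list(truth.class_label) == list(ds.truth.class_label)
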