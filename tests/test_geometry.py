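import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spcryolm as sp
from spcryolm.blades import BladeModel, trimer_probe_positions


class TestRadiusFromDistance:
    @pytest.mark.parametrize(
        "d,expected",
        [(9.0, 6.06), (19.0, 11.84), (34.0, 20.50), (24.0, 14.72), (0.0, 0.866)],
    )
    def test_known_values(self, d, expected):
        assert sp.radius_from_distance(d).value == pytest.approx(expected, abs=0.01)

    def test_af2_model_composition(self):
        # predicted interblade distance 19.5 nm maps onto in-plane radius ~12 nm
        assert sp.radius_from_distance(19.5).value == pytest.approx(12.12, abs=0.01)

    def test_propagated_uncertainty(self):
        assert sp.radius_from_distance(19.0).error == pytest.approx(2.3 / np.sqrt(3), abs=1e-9)

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            sp.radius_from_distance(-1.0)

    @given(d1=st.floats(0, 100), d2=st.floats(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_affine(self, d1, d2):
        r1 = sp.radius_from_distance(d1).value
        r2 = sp.radius_from_distance(d2).value
        if d1 + 1e-12 < d2:
            assert r1 < r2
        # affine: equal increments give equal radius increments
        assert sp.radius_from_distance(d1 + 1).value - r1 == pytest.approx(
            sp.radius_from_distance(d2 + 1).value - r2, abs=1e-9
        )


class TestCurvatureRadius:
    def test_highly_curved_state(self):
        assert sp.curvature_radius(6.0, 5.5) == pytest.approx(6.02, abs=0.01)

    def test_nearly_flat_state(self):
        assert sp.curvature_radius(20.0, 1.0) == pytest.approx(200.5, abs=0.01)

    def test_hemisphere_limit(self):
        assert sp.curvature_radius(7.0, 7.0) == pytest.approx(7.0)

    def test_minimum_at_hemisphere(self):
        # R >= r whenever 0 < h <= r, with equality only at h = r
        for h in (1.0, 3.0, 5.0, 7.0):
            assert sp.curvature_radius(7.0, h) >= 7.0 - 1e-12

    def test_flat_membrane_raises(self):
        with pytest.raises(ValueError):
            sp.curvature_radius(6.0, 0.0)


class TestMedianCurvature:
    def test_intermediate_class_median(self):
        res = sp.median_curvature(12.0, h_max=5.0, n_samples=100_000, seed=1)
        # R(h) is monotone decreasing for h < r, so the median sits at h = 2.5
        assert res.median == pytest.approx(30.05, abs=0.2)
        assert res.lo < res.median < res.hi

    def test_degenerate_height_range(self):
        res = sp.median_curvature(12.0, h_max=2.5, h_min=2.5, n_samples=1000, seed=2)
        assert res.median == pytest.approx(sp.curvature_radius(12.0, 2.5), abs=1e-9)

    def test_monotone_median_when_radius_dominates(self):
        res = sp.median_curvature(5.0, h_max=5.0, n_samples=100_000, seed=3)
        assert res.median == pytest.approx(sp.curvature_radius(5.0, 2.5), abs=0.1)

    def test_seeded_reproducibility(self):
        a = sp.median_curvature(12.0, seed=7, n_samples=10_000)
        b = sp.median_curvature(12.0, seed=7, n_samples=10_000)
        assert a == b

    def test_invalid_radius_raises(self):
        with pytest.raises(ValueError):
            sp.median_curvature(-1.0)


def straight_arm_model(n=21, arm_length=20.0, pivot_index=8):
    """Colinear toy blade along +x, N-terminal probe at the outer tip.

    Residue 0 is the labeled tip (mobile), the pivot sits partway along the
    arm, and the chain continues inward to the trimer axis at the origin."""
    x = np.linspace(arm_length, 0.0, n)
    coords = np.column_stack([x, np.zeros(n), np.zeros(n)])
    return BladeModel(coords=coords, pivot_index=pivot_index, probe_index=0)


class TestRigidBodyScan:
    def test_zero_angle_is_identity(self):
        model = straight_arm_model()
        scan = sp.rigid_body_scan(model, angles=[0.0])
        probes = trimer_probe_positions(model.coords, model.probe_index)
        assert scan.interblade_nm[0] == pytest.approx(
            np.linalg.norm(probes[0] - probes[1])
        )

    def test_in_plane_scan_matches_law_of_cosines(self):
        model = straight_arm_model()
        c = model.coords[model.pivot_index, 0]  # pivot radius from trimer axis
        a = model.coords[model.probe_index, 0] - c  # probe arm beyond the pivot
        scan = sp.rigid_body_scan(model, angles=np.arange(0.0, 181.0, 5.0), axis="in-plane")
        for angle, d in zip(scan.angle_deg, scan.interblade_nm):
            rho2 = c**2 + a**2 + 2 * c * a * np.cos(np.deg2rad(angle))
            assert d == pytest.approx(np.sqrt(3.0 * rho2), abs=1e-6)

    def test_out_of_plane_right_angle_shrinks_to_pivot_radius(self):
        model = straight_arm_model()
        c = model.coords[model.pivot_index, 0]
        scan = sp.rigid_body_scan(model, angles=[90.0], axis="out-of-plane")
        assert scan.interblade_nm[0] == pytest.approx(np.sqrt(3.0) * c, abs=1e-6)

    def test_rigidity_and_fixed_pivot(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 5, (15, 3)) + [10.0, 0.0, 0.0]
        model = BladeModel(coords=coords, pivot_index=7, probe_index=14)
        rotated = sp.rotate_mobile(model, 73.0, axis="out-of-plane")
        mob = model.mobile_indices
        orig = coords[mob]
        new = rotated[mob]
        d_orig = np.linalg.norm(orig[:, None] - orig[None], axis=-1)
        d_new = np.linalg.norm(new[:, None] - new[None], axis=-1)
        assert np.allclose(d_orig, d_new, atol=1e-6)
        assert np.allclose(rotated[model.pivot_index], coords[model.pivot_index], atol=1e-12)

    def test_distances_continuous_in_angle(self):
        model = straight_arm_model()
        scan = sp.rigid_body_scan(model, angles=np.arange(0.0, 181.0, 5.0))
        assert np.abs(np.diff(scan.interblade_nm)).max() < 5.0

    def test_pivot_outside_chain_raises(self):
        with pytest.raises(IndexError):
            BladeModel(coords=np.zeros((5, 3)), pivot_index=10, probe_index=1)

    def test_angstrom_units_converted(self):
        coords_a = np.column_stack([np.linspace(0, 200, 11), np.zeros(11), np.zeros(11)])
        model = BladeModel(coords=coords_a, pivot_index=4, probe_index=10, unit="angstrom")
        assert model.coords[10, 0] == pytest.approx(20.0)
        with pytest.raises(ValueError):
            BladeModel(coords=coords_a, pivot_index=4, probe_index=10, unit="furlong")


_SYNTHETIC_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   4      11.400   0.000   0.000  1.00  0.00           C
ATOM      5  CA  ALA A   5      15.200   0.000   0.000  1.00  0.00           C
END
"""


def test_load_chain_ca_from_synthetic_pdb(tmp_path):
    # synthetic five-residue straight chain, written as a plain PDB text file
    path = tmp_path / "synthetic_arm.pdb"
    path.write_text(_SYNTHETIC_PDB)
    df = sp.load_chain_ca(path)
    assert len(df) == 5
    assert df.x_nm.iloc[-1] == pytest.approx(1.52)
    model = BladeModel(
        coords=df[["x_nm", "y_nm", "z_nm"]].to_numpy() + [1.0, 0.0, 0.0],
        pivot_index=2,
        probe_index=0,
    )
    scan = sp.rigid_body_scan(model, angles=[0.0, 90.0, 180.0])
    assert (scan.interblade_nm > 0).all()
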