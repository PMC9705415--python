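"""Screw decomposition, symmetry expansion, and helix build/fit round-trips."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from formindock import (
    HelixSpec, RigidTransform, ScrewParameters, StructureError, UnitCell,
    axis_angle, build_helix, expand, fit_helix, relating_transform,
    screw_decompose,
)
from formindock.symmetry_helix import find_screw_operator
from formindock.structures import SymOp
from conftest import chain_set, random_transform


def random_screw(rng) -> ScrewParameters:
    axis = rng.normal(0, 1, 3)
    axis /= np.linalg.norm(axis)
    return ScrewParameters(axis, rng.normal(0, 15, 3), float(rng.uniform(1, 179)),
                           float(rng.uniform(0, 40)))


PROBE_CUBE = np.array([[x, y, z] for x in (-20.0, 20.0)
                       for y in (-20.0, 20.0) for z in (-20.0, 20.0)])


class TestScrewDecompose:
    def test_constructed_two_fold_screw(self):
        # Rot(z, 180) about the line x=5, y=0, composed with 27.5 along z
        R = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        point = np.array([5.0, 0.0, 0.0])
        t = point - R @ point + np.array([0.0, 0.0, 27.5])
        sp = screw_decompose(RigidTransform(R, t))
        assert sp.angle == pytest.approx(180.0, abs=1e-9)
        assert sp.translation == pytest.approx(27.5, abs=1e-9)
        np.testing.assert_allclose(sp.axis, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(sp.point, [5, 0, 0], atol=1e-8)

    def test_pure_translation_degenerate(self):
        sp = screw_decompose(RigidTransform(np.eye(3), np.array([0.0, 0.0, 27.5])))
        assert sp.degenerate
        assert sp.angle == 0.0
        assert sp.translation == pytest.approx(27.5)
        np.testing.assert_allclose(sp.axis, [0, 0, 1])

    def test_identity_raises(self):
        with pytest.raises(StructureError):
            screw_decompose(RigidTransform.identity())

    def test_roundtrip_on_probe_cube_100_random_screws(self, rng):
        for _ in range(100):
            sp = random_screw(rng)
            t = sp.to_transform()
            back = screw_decompose(t).to_transform()
            assert np.abs(back.apply(PROBE_CUBE) - t.apply(PROBE_CUBE)).max() < 1e-6

    def test_roundtrip_includes_crystal_two_fold_case(self):
        sp = ScrewParameters(np.array([0.0, 0.0, 1.0]), np.zeros(3), 180.0, 27.5)
        back = screw_decompose(sp.to_transform())
        assert back.angle == pytest.approx(180.0, abs=1e-9)
        assert back.translation == pytest.approx(27.5, abs=1e-12)

    def test_sign_convention_translation_nonnegative(self, rng):
        for _ in range(20):
            sp = random_screw(rng)
            flipped = ScrewParameters(-sp.axis, sp.point, -sp.angle, sp.translation)
            # decomposing a screw built with negative-axis convention still
            # reports translation >= 0
            back = screw_decompose(flipped.to_transform())
            assert back.translation >= 0


class TestScrewPropertyBased:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(angle=st.floats(1.0, 179.0), trans=st.floats(0.0, 50.0),
           ax=st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(0.1, 1)))
    def test_decompose_recovers_any_screw(angle, trans, ax):
        axis = np.array(ax) / np.linalg.norm(ax)
        sp = ScrewParameters(axis, np.array([3.0, -7.0, 2.0]), angle, trans)
        back = screw_decompose(sp.to_transform())
        assert back.angle == pytest.approx(angle, abs=1e-6)
        assert back.translation == pytest.approx(trans, abs=1e-6)
        assert float(back.axis @ axis) == pytest.approx(1.0, abs=1e-6)


class TestAxisAngle:
    def test_parallel_and_antiparallel_are_zero(self):
        z = np.array([0.0, 0.0, 1.0])
        assert axis_angle(z, z) == 0.0
        assert axis_angle(z, -z) == pytest.approx(0.0, abs=1e-6)

    def test_constructed_13_degrees(self):
        b = np.array([np.sin(np.deg2rad(13)), 0.0, np.cos(np.deg2rad(13))])
        assert axis_angle([0, 0, 1], b) == pytest.approx(13.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(StructureError):
            axis_angle([0, 0, 0], [0, 0, 1])


class TestExpand:
    def test_identity_operator_duplicates_with_new_ids(self, small_subunit):
        out = expand(small_subunit, RigidTransform.identity())
        assert len(out.chains) == 2
        a, b = out.chains
        assert a.chain_id != b.chain_id
        np.testing.assert_array_equal(
            np.array([at.coords for r in a.residues for at in r.atoms]),
            np.array([at.coords for r in b.residues for at in r.atoms]))

    def test_synthetic_screw_operator_roundtrip(self, small_subunit):
        sp = ScrewParameters(np.array([0.0, 0.0, 1.0]), np.zeros(3), 180.0, 27.5)
        out = expand(small_subunit, sp.to_transform())
        a, b = out.chain_ids
        rel = relating_transform(chain_set(out, a, atom_names=None),
                                 chain_set(out, b, atom_names=None))
        back = screw_decompose(rel.transform)
        assert back.angle == pytest.approx(180.0, abs=1e-6)
        assert back.translation == pytest.approx(27.5, abs=1e-6)

    def test_fractional_operator_through_cell(self, small_subunit):
        s = small_subunit.copy()
        s.cell = UnitCell(50, 60, 70)
        out = expand(s, "-x,-y,z+1/2")          # 2_1 along c: rise c/2 = 35
        sp = find_screw_operator(out, *out.chain_ids)
        assert sp.angle == pytest.approx(180.0, abs=1e-6)
        assert sp.translation == pytest.approx(35.0, abs=1e-6)

    def test_space_group_operator_screw_params_recovered(self, small_subunit):
        # expand with a P212121 operator, then measure it back from the copies
        s = small_subunit.copy()
        s.cell = UnitCell(40, 50, 60)
        op = SymOp.from_triplet("x+1/2,-y+1/2,-z")    # 2_1 along a: rise 20
        out = expand(s, op)
        sp = find_screw_operator(out, *out.chain_ids)
        assert sp.angle == pytest.approx(180.0, abs=1e-6)
        assert sp.translation == pytest.approx(20.0, abs=1e-6)
        np.testing.assert_allclose(np.abs(sp.axis), [1, 0, 0], atol=1e-6)

    def test_fractional_operator_without_cell_rejected(self, small_subunit):
        with pytest.raises(StructureError, match="cell"):
            expand(small_subunit, "-x,-y,z+1/2")


class TestRelatingTransform:
    def test_noiseless_recovery_is_exact(self, small_subunit, rng):
        t = random_transform(rng)
        X = chain_set(small_subunit, "A", atom_names=None)
        Y = X.with_coords(t.apply(X.coords))
        res = relating_transform(X, Y)
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.transform.rotation, t.rotation, atol=1e-9)


class TestHelix:
    def test_translation_stack_trivial(self, small_subunit):
        spec = HelixSpec(rise=10.0, twist=0.0, n_subunits=3)
        fil = build_helix(small_subunit, spec)
        assert len(fil.chains) == 3
        a, b = fil.chain_ids[:2]
        rel = relating_transform(chain_set(fil, a), chain_set(fil, b))
        sp = screw_decompose(rel.transform)
        assert sp.degenerate and sp.translation == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("rise", [5.0, 27.5, 100.0])
    @pytest.mark.parametrize("twist", [-179.0, -166.7, 0.5, 90.0])
    def test_build_fit_roundtrip_noiseless(self, small_subunit, rise, twist):
        fil = build_helix(small_subunit, HelixSpec(rise=rise, twist=twist,
                                                   n_subunits=4))
        spec = fit_helix(fil)
        assert spec.rise == pytest.approx(rise, abs=1e-6)
        assert spec.twist == pytest.approx(twist, abs=1e-6)

    def test_actin_like_helix_recovery_tight(self, subunit):
        fil = build_helix(subunit, HelixSpec(rise=27.5, twist=-166.7, n_subunits=6))
        spec = fit_helix(fil)
        assert spec.rise == pytest.approx(27.5, abs=1e-6)
        assert spec.twist == pytest.approx(-166.7, abs=1e-6)
        np.testing.assert_allclose(np.abs(spec.axis), [0, 0, 1], atol=1e-9)

    def test_too_few_subunits_rejected(self, small_subunit):
        fil = build_helix(small_subunit, HelixSpec(rise=27.5, twist=-166.7,
                                                   n_subunits=2))
        with pytest.raises(StructureError, match="3 consecutive"):
            fit_helix(fil)

    def test_irregular_stack_rejected(self, small_subunit, rng):
        fil = build_helix(small_subunit, HelixSpec(rise=27.5, twist=-166.7,
                                                   n_subunits=4))
        # scramble one subunit's orientation: no longer a regular helix
        t = random_transform(rng)
        last = fil.chains[-1]
        for r in last.residues:
            for a in r.atoms:
                a.coords = t.apply(a.coords)
        with pytest.raises(StructureError):
            fit_helix(fil)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            HelixSpec(rise=-1.0, twist=10.0)
        with pytest.raises(ValueError):
            HelixSpec(rise=10.0, twist=10.0, n_subunits=1)
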