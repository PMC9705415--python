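"""Seeded synthetic-structure generators with attached ground truth.

The generators produce rigid, chiral pseudo-protein subunits and arrange them
with exactly known geometry — screw pairs, helical filaments, hinged
two-domain pairs, Gaussian coordinate noise — so every measurement in the
pipeline can be checked against the truth that generated its input.  Fixtures
are geometric, not chemical: atoms carry backbone names (N, CA, C, O) so real
selections apply, but bond lengths/angles are not protein-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import (
    Atom, Chain, CoreDefinition, Residue, Structure, StructureError,
)
from .superpose import RigidTransform, apply_transform
from .symmetry_helix import HelixSpec, ScrewParameters, build_helix

_BACKBONE_NAMES = ("N", "CA", "C", "O")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


@dataclass
class SyntheticTruth:
    seed: int
    subunit_atoms: int
    transform_truth: RigidTransform | None = None
    helix_truth: HelixSpec | None = None
    hinge_truth: float | None = None
    noise_sigma: float = 0.0
    core_small: CoreDefinition | None = None
    core_large: CoreDefinition | None = None


def _structure_from_coords(coords: np.ndarray, chain_id: str = "A",
                           first_residue: int = 1, sid: str = "synthetic") -> Structure:
    if len(coords) % 4 != 0:
        raise StructureError("synthetic subunits use 4 atoms per pseudo-residue")
    chain = Chain(chain_id)
    serial = 1
    for i in range(0, len(coords), 4):
        seq = first_residue + i // 4
        res = Residue(chain_id, seq, "", "ALA")
        for j, name in enumerate(_BACKBONE_NAMES):
            res.atoms.append(Atom(serial, name, _ELEMENTS[name], "",
                                  coords[i + j].copy(), 1.0, 0.0))
            serial += 1
        chain.residues.append(res)
    return Structure(sid, [chain])


def make_subunit(n_atoms: int, seed: int, spread: float = 12.0,
                 chain_id: str = "A") -> Structure:
    """A rigid, chiral, non-degenerate pseudo-subunit.

    Gaussian point cloud (sd ``spread`` A) grouped into 4-atom pseudo-residues;
    redraws (bounded) until the inertia tensor has well-separated eigenvalues,
    which guarantees a unique superposition fit.
    """
    if n_atoms < 12:
        raise StructureError("need >= 12 atoms for a non-degenerate subunit")
    if n_atoms % 4 != 0:
        raise StructureError("n_atoms must be a multiple of 4 (pseudo-residues)")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        coords = rng.normal(0.0, spread, size=(n_atoms, 3))
        coords -= coords.mean(axis=0)
        inertia = coords.T @ coords
        ev = np.sort(np.linalg.eigvalsh(inertia))
        if np.min(np.diff(ev)) > 1e-3 * ev[-1]:
            return _structure_from_coords(coords, chain_id,
                                          sid=f"synthetic_subunit_s{seed}")
    raise StructureError("could not draw a non-degenerate subunit")  # pragma: no cover


def perturb(s: Structure, sigma: float, seed: int) -> Structure:
    """Add i.i.d. Gaussian noise (sd sigma, per coordinate) to every atom."""
    if sigma < 0:
        raise StructureError("sigma must be >= 0")
    out = s.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for _, _, atom in out.iter_atoms():
        atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)
    return out


def make_filament(subunit: Structure, rise: float, twist: float, n: int,
                  noise_sigma: float = 0.0, seed: int = 0,
                  axis=(0.0, 0.0, 1.0), origin=(0.0, 0.0, 0.0)
                  ) -> tuple[Structure, SyntheticTruth]:
    """Helical stack of ``n`` subunit copies, optionally noise-perturbed."""
    spec = HelixSpec(rise=rise, twist=twist, axis=np.asarray(axis, float),
                     origin=np.asarray(origin, float), n_subunits=n)
    filament = build_helix(subunit, spec)
    truth = SyntheticTruth(seed=seed, subunit_atoms=subunit.n_atoms,
                           helix_truth=spec, noise_sigma=noise_sigma)
    if noise_sigma > 0:
        noisy = perturb(filament, noise_sigma, seed)
        noisy.meta.update(filament.meta)
        filament = noisy
    filament.meta["truth"] = truth
    return filament, truth


def make_screw_pair(subunit: Structure, angle: float, translation: float,
                    axis=(0.0, 0.0, 1.0), point=(0.0, 0.0, 0.0), seed: int = 0,
                    noise_sigma: float = 0.0) -> tuple[Structure, SyntheticTruth]:
    """Subunit plus its screw-transformed copy (e.g. 180°/27.5 A, the
    crystal 2₁ relation between the two FH2-bound actins)."""
    screw = ScrewParameters(np.asarray(axis, float), np.asarray(point, float),
                            angle, translation)
    transform = screw.to_transform()
    pair = subunit.copy(f"synthetic_screw_pair_s{seed}")
    copy = subunit.chains[0].copy()
    new_id = pair.free_chain_ids(1)[0]
    copy.chain_id = new_id
    for res in copy.residues:
        res.chain_id = new_id
        for a in res.atoms:
            a.coords = transform.apply(a.coords)
    pair.chains.append(copy)
    truth = SyntheticTruth(seed=seed, subunit_atoms=subunit.n_atoms,
                           transform_truth=transform, noise_sigma=noise_sigma)
    if noise_sigma > 0:
        pair = perturb(pair, noise_sigma, seed)
    pair.meta["truth"] = truth
    pair.meta["screw_truth"] = screw
    return pair, truth


def make_hinged_pair(core_small_atoms: int, core_large_atoms: int,
                     hinge_deg: float, hinge_axis=(0.0, 1.0, 0.0), seed: int = 0
                     ) -> tuple[Structure, Structure, SyntheticTruth]:
    """A two-domain subunit and a copy with the large domain rotated.

    The rotation axis passes through the midpoint between the two domain
    centroids (the "hinge").  Residues 1..ns form the small core and
    ns+1..ns+nl the large core; the matching :class:`CoreDefinition` pair is
    attached to the truth so shear measurements can address them.
    """
    if not (0.0 <= hinge_deg <= 60.0):
        raise StructureError("hinge angle must be in [0, 60] degrees")
    for n in (core_small_atoms, core_large_atoms):
        if n < 12 or n % 4 != 0:
            raise StructureError("each core needs >= 12 atoms, multiple of 4")
    rng = np.random.default_rng(seed)
    small = rng.normal(0.0, 8.0, size=(core_small_atoms, 3)) + np.array([-14.0, 0.0, 0.0])
    large = rng.normal(0.0, 8.0, size=(core_large_atoms, 3)) + np.array([14.0, 0.0, 0.0])
    coords = np.vstack([small, large])
    x = _structure_from_coords(coords, "A", sid=f"synthetic_hinged_x_s{seed}")

    hinge_point = 0.5 * (small.mean(axis=0) + large.mean(axis=0))
    screw = ScrewParameters(np.asarray(hinge_axis, float), hinge_point,
                            hinge_deg, 0.0)
    rot = screw.to_transform()
    coords_y = coords.copy()
    coords_y[core_small_atoms:] = rot.apply(coords_y[core_small_atoms:])
    y = _structure_from_coords(coords_y, "A", sid=f"synthetic_hinged_y_s{seed}")

    ns = core_small_atoms // 4
    nl = core_large_atoms // 4
    truth = SyntheticTruth(
        seed=seed, subunit_atoms=core_small_atoms + core_large_atoms,
        hinge_truth=hinge_deg,
        core_small=CoreDefinition("synthetic_small", ((1, ns),)),
        core_large=CoreDefinition("synthetic_large", ((ns + 1, ns + nl),)))
    x.meta["truth"] = truth
    y.meta["truth"] = truth
    return x, y, truth


def make_translated_pair(subunit: Structure, direction, distance: float,
                         seed: int = 0) -> tuple[Structure, SyntheticTruth]:
    """Pure-translation pair: the zero-dispersion (coplanar) reference case."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = RigidTransform(np.eye(3), distance * direction)
    pair = subunit.copy(f"synthetic_translated_pair_s{seed}")
    copy = subunit.chains[0].copy()
    new_id = pair.free_chain_ids(1)[0]
    copy.chain_id = new_id
    for res in copy.residues:
        res.chain_id = new_id
        for a in res.atoms:
            a.coords = t.apply(a.coords)
    pair.chains.append(copy)
    truth = SyntheticTruth(seed=seed, subunit_atoms=subunit.n_atoms,
                           transform_truth=t)
    pair.meta["truth"] = truth
    return pair, truth
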