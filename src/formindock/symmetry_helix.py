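"""Crystallographic symmetry expansion, screw-axis decomposition, and ideal
helical filament construction/fitting.

A two-fold screw (2₁) crystal axis — 180° rotation plus a translation along
the axis — is the symmetry that relates the two bound actin molecules in
FH2–actin co-crystals; an actin filament is the general case, a screw of
~27.5 Å rise and ~-166.7° twist per subunit.  Everything here reduces to the
algebra of such screws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import (
    BACKBONE, AtomSet, Selection, Structure, StructureError, SymOp,
    pair_atoms, resolve_selection,
)
from .superpose import RigidTransform, SuperpositionResult, kabsch_fit

_DEGENERATE_ANGLE_DEG = 0.1


@dataclass
class ScrewParameters:
    """Axis-angle-translation form of a rigid motion.

    ``angle`` is in degrees in (-180, 180]; ``translation`` is the signed
    displacement along ``axis`` (oriented so translation >= 0; for a pure
    rotation the axis is oriented so the angle is positive).  ``point`` is the
    axis point closest to the origin.  ``degenerate`` marks (near-)pure
    translations, whose axis direction comes from the translation instead of
    the rotation.
    """
    axis: np.ndarray
    point: np.ndarray
    angle: float
    translation: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.point = np.asarray(self.point, dtype=float)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("screw axis must be non-zero")
            self.axis = self.axis / n

    def to_transform(self) -> RigidTransform:
        R = Rotation.from_rotvec(np.deg2rad(self.angle) * self.axis).as_matrix()
        t = self.point - R @ self.point + self.translation * self.axis
        return RigidTransform(R, t)


def screw_decompose(t: RigidTransform) -> ScrewParameters:
    """Decompose a rigid motion into screw parameters (Chasles' theorem)."""
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rotvec)))
    if angle < _DEGENERATE_ANGLE_DEG:
        tnorm = float(np.linalg.norm(t.translation))
        if tnorm < 1e-9:
            raise StructureError("identity transform has no screw decomposition")
        return ScrewParameters(t.translation / tnorm, np.zeros(3), 0.0, tnorm,
                               degenerate=True)
    axis = rotvec / np.linalg.norm(rotvec)
    d = float(axis @ t.translation)
    t_perp = t.translation - d * axis
    # (I - R) p = t_perp; singular along the axis -> least squares, then take
    # the axis point closest to the origin.
    point, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    point = point - (point @ axis) * axis
    if d < -1e-9:
        axis, angle, d = -axis, -angle, -d
    elif abs(d) <= 1e-9:
        d = 0.0
        if angle < 0:
            axis, angle = -axis, -angle
    if angle <= -180.0 + 1e-9:
        angle = 180.0
    return ScrewParameters(axis, point, angle, d)


def axis_angle(a, b) -> float:
    """Angle in degrees between two axes (directionless: result in [0, 90])."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise StructureError("zero vector has no direction")
    c = abs(float(a @ b) / (na * nb))
    return float(np.rad2deg(np.arccos(min(c, 1.0))))


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------

def operator_to_transform(op: SymOp, structure: Structure,
                          lattice_shift=(0, 0, 0)) -> RigidTransform:
    """Convert a fractional space-group operator (plus an optional lattice
    translation) to a Cartesian rigid transform through the structure's cell."""
    if structure.cell is None:
        raise StructureError("fractional operator needs a unit cell")
    M = structure.cell.orthogonalization_matrix()
    Minv = np.linalg.inv(M)
    R = M @ op.rot @ Minv
    t = M @ (op.tran + np.asarray(lattice_shift, dtype=float))
    # orthonormalize against cell round-off
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        raise StructureError(f"operator {op.triplet!r} is improper")
    return RigidTransform(R, t)


def expand(s: Structure, op, lattice_shift=(0, 0, 0)) -> Structure:
    """Return the structure plus a symmetry copy with renamed chains.

    ``op`` may be a :class:`RigidTransform` (Cartesian), a :class:`SymOp`, or
    a triplet string like ``"-x,y+1/2,-z"`` (fractional; requires a cell).
    The chain-id mapping of the copy is recorded in ``meta['expand_map']``.
    """
    if isinstance(op, str):
        op = SymOp.from_triplet(op)
    if isinstance(op, SymOp):
        transform = operator_to_transform(op, s, lattice_shift)
    elif isinstance(op, RigidTransform):
        transform = op
    else:
        raise StructureError(f"cannot interpret operator {op!r}")

    out = s.copy()
    new_ids = out.free_chain_ids(len(s.chains))
    mapping = {}
    for chain, new_id in zip(s.chains, new_ids):
        copy = chain.copy()
        copy.chain_id = new_id
        for res in copy.residues:
            res.chain_id = new_id
            for a in res.atoms:
                a.coords = transform.apply(a.coords)
        out.chains.append(copy)
        mapping[chain.chain_id] = new_id
    out.meta["expand_map"] = mapping
    out.meta["expand_transform"] = transform.as_flat()
    return out


def relating_transform(X: AtomSet, Y: AtomSet) -> SuperpositionResult:
    """Fit the rigid transform relating two copies of the same entity.

    Pairs by author numbering; a fit RMSD above 0.5 A is flagged in the
    result (``reflection_flagged`` is unrelated — check ``rmsd``) since the
    relation is then not rigid.
    """
    pairing = pair_atoms(X, Y, "by_author_number")
    return kabsch_fit(X, Y, pairing)


def find_screw_operator(s: Structure, chain_a: str, chain_b: str,
                        atom_names=BACKBONE) -> ScrewParameters:
    """Screw parameters of the relation between two chains of one structure."""
    X = resolve_selection(s, Selection(chain_id=chain_a, intervals=None,
                                       atom_names=atom_names))
    Y = resolve_selection(s, Selection(chain_id=chain_b, intervals=None,
                                       atom_names=atom_names))
    return screw_decompose(relating_transform(X, Y).transform)


# ---------------------------------------------------------------------------
# helices
# ---------------------------------------------------------------------------

@dataclass
class HelixSpec:
    """Ideal helix: rise (A/subunit), twist (deg/subunit; negative =
    left-handed one-start), axis direction, a point on the axis, and length."""
    rise: float
    twist: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_subunits: int = 2
    rise_sd: float = 0.0
    twist_sd: float = 0.0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("helix axis must be non-zero")
        self.axis = self.axis / n
        if self.rise <= 0:
            raise ValueError("helix rise must be positive")
        if self.n_subunits < 2:
            raise ValueError("a helix needs at least 2 subunits")

    def step_transform(self) -> RigidTransform:
        return ScrewParameters(self.axis, self.origin - (self.origin @ self.axis) * self.axis,
                               self.twist, self.rise).to_transform()


def build_helix(template: Structure, spec: HelixSpec) -> Structure:
    """Stack ``n_subunits`` screw-related copies of the template.

    Subunit i is screw^i(template); chains are renamed serially.  The spec is
    attached as ground truth in ``meta['helix_truth']``.
    """
    if template.n_atoms == 0:
        raise StructureError("empty template")
    step = spec.step_transform()
    out = Structure(f"{template.id}_helix{spec.n_subunits}", [],
                    template.cell, template.space_group,
                    list(template.operators) if template.operators else None)
    ids = iter(Structure("tmp").free_chain_ids(spec.n_subunits * len(template.chains)))
    subunit_chains = []
    current = RigidTransform.identity()
    for i in range(spec.n_subunits):
        ids_i = []
        for chain in template.chains:
            copy = chain.copy()
            copy.chain_id = next(ids)
            ids_i.append(copy.chain_id)
            for res in copy.residues:
                res.chain_id = copy.chain_id
                for a in res.atoms:
                    a.coords = current.apply(a.coords)
            out.chains.append(copy)
        subunit_chains.append(ids_i)
        current = step.compose(current)
    out.meta["helix_truth"] = spec
    out.meta["subunit_chains"] = subunit_chains
    return out


def fit_helix(filament: Structure, chains: list[str] | None = None,
              atom_names=BACKBONE, max_twist_sd: float = 5.0) -> HelixSpec:
    """Recover helical parameters from >= 3 consecutive subunits.

    Each consecutive-subunit relation is fitted and screw-decomposed; rise and
    twist are the means over steps (axes sign-aligned first), with standard
    deviations reported on the spec.  A twist s.d. above ``max_twist_sd``
    means the stack is not a regular helix and raises.
    """
    groups: list[list[str]]
    if chains is None:
        sub = filament.meta.get("subunit_chains")
        groups = sub if sub else [[cid] for cid in filament.chain_ids]
    else:
        groups = [[c] if isinstance(c, str) else list(c) for c in chains]
    if len(groups) < 3:
        raise StructureError("helix fitting needs >= 3 consecutive subunits")

    def subunit_set(group: list[str]) -> AtomSet:
        sets = [resolve_selection(filament, Selection(chain_id=cid, intervals=None,
                                                      atom_names=atom_names))
                for cid in group]
        sites = [s_ for a in sets for s_ in a.sites]
        coords = np.vstack([a.coords for a in sets])
        return AtomSet(sites, coords)

    def cross_pairing(A: AtomSet, B: AtomSet):
        keyed = {(s.seq_number, s.insertion_code, s.atom_name, s.chain_id): i
                 for i, s in enumerate(B.sites)}
        # chain ids differ between subunits; match by position within subunit
        if len(A) != len(B):
            raise StructureError("subunits differ in atom count; cannot fit helix")
        idx = np.arange(len(A))
        from .structures import AtomPairing
        return AtomPairing(idx, idx.copy(), "by_author_number")

    sets = [subunit_set(g) for g in groups]
    screws: list[ScrewParameters] = []
    for A, B in zip(sets[:-1], sets[1:]):
        res = kabsch_fit(A, B, cross_pairing(A, B))
        screws.append(screw_decompose(res.transform))

    ref = screws[0].axis
    axes, angles, rises, points = [], [], [], []
    for sp in screws:
        ax, ang, d = sp.axis, sp.angle, sp.translation
        if ax @ ref < 0:
            ax, ang, d = -ax, -ang, -d
        axes.append(ax)
        angles.append(ang)
        rises.append(d)
        points.append(sp.point)
    rise = float(np.mean(rises))
    twist = float(np.mean(angles))
    if rise < 0:
        rise, twist = -rise, -twist
        axes = [-a for a in axes]
    twist_sd = float(np.std(angles, ddof=1)) if len(angles) > 1 else 0.0
    rise_sd = float(np.std(rises, ddof=1)) if len(rises) > 1 else 0.0
    if twist_sd > max_twist_sd:
        raise StructureError(f"inconsistent steps (twist sd {twist_sd:.2f} deg): "
                             "not a regular helix")
    mean_axis = np.mean(axes, axis=0)
    mean_axis = mean_axis / np.linalg.norm(mean_axis)
    origin = np.mean(points, axis=0)
    return HelixSpec(rise, twist, mean_axis, origin, len(groups),
                     rise_sd=rise_sd, twist_sd=twist_sd)
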