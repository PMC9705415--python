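"""Least-squares rigid superposition (Kabsch), RMSD, and transform algebra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import AtomPairing, AtomSet, Structure, StructureError, identity_pairing


@dataclass
class RigidTransform:
    """A proper rotation plus translation: x -> R @ x + t."""
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det -1): reflections are not rigid "
                             "motions of a chiral molecule")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other:  x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform.identity()
        base = self if n >= 0 else self.inverse()
        for _ in range(abs(n)):
            out = base.compose(out)
        return out

    def as_flat(self) -> list[float]:
        """Row-major rotation followed by translation (12 numbers)."""
        return [*self.rotation.reshape(-1).tolist(), *self.translation.tolist()]

    @classmethod
    def from_flat(cls, values) -> "RigidTransform":
        v = np.asarray(values, dtype=float)
        return cls(v[:9].reshape(3, 3), v[9:12])


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    pairing: AtomPairing | None = None
    reflection_flagged: bool = field(default=False)


def _coords(X) -> np.ndarray:
    if isinstance(X, AtomSet):
        return X.coords
    return np.asarray(X, dtype=float)


def _paired(X, Y, pairing: AtomPairing | None):
    xc, yc = _coords(X), _coords(Y)
    if pairing is None:
        if len(xc) != len(yc):
            raise StructureError("unequal sizes and no pairing given")
        return xc, yc
    return xc[pairing.x_indices], yc[pairing.y_indices]


def rmsd(X, Y, pairing: AtomPairing | None = None) -> float:
    """Root-mean-square deviation of paired positions, compared as-is (no fit)."""
    xc, yc = _paired(X, Y, pairing)
    if len(xc) == 0:
        raise StructureError("no atom pairs to compare")
    return float(np.sqrt(np.mean(np.sum((xc - yc) ** 2, axis=1))))


def kabsch_fit(X, Y, pairing: AtomPairing | None = None) -> SuperpositionResult:
    """Optimal proper rotation + translation moving X onto Y (least squares).

    The reflection branch of the SVD is corrected so only proper rotations are
    returned; if the unconstrained optimum would be a reflection the result is
    flagged but still a proper rotation.
    """
    xc, yc = _paired(X, Y, pairing)
    n = len(xc)
    if n < 3:
        raise StructureError(f"need >= 3 paired atoms, got {n}")
    x0, y0 = xc.mean(axis=0), yc.mean(axis=0)
    A = (yc - y0).T @ (xc - x0)
    U, S, Vt = np.linalg.svd(A)
    # collinearity: rank < 2 leaves the rotation underdetermined
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise StructureError("paired atoms are (near-)collinear; fit is degenerate")
    d = np.sign(np.linalg.det(U @ Vt))
    flagged = d < 0
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = y0 - R @ x0
    transform = RigidTransform(R, t)
    fitted = transform.apply(xc)
    value = float(np.sqrt(np.mean(np.sum((fitted - yc) ** 2, axis=1))))
    return SuperpositionResult(transform, value, n, pairing, flagged)


def apply_transform(obj, t: RigidTransform):
    """Apply a rigid transform to a Structure or AtomSet, returning a new object."""
    if isinstance(obj, Structure):
        out = obj.copy()
        for _, _, atom in out.iter_atoms():
            atom.coords = t.apply(atom.coords)
        return out
    if isinstance(obj, AtomSet):
        return obj.with_coords(t.apply(obj.coords))
    return t.apply(np.asarray(obj, dtype=float))


def fit_onto(X: AtomSet, Y: AtomSet, method: str = "by_author_number") -> SuperpositionResult:
    """Convenience: pair then fit."""
    from .structures import pair_atoms
    pairing = identity_pairing(X) if X is Y else pair_atoms(X, Y, method)
    return kabsch_fit(X, Y, pairing)
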