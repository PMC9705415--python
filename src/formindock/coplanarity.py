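"""Direction-cosine coplanarity statistics and the small/large-domain shear
decomposition.

Two subunits related by (near-)pure translation are "coplanar": every line
connecting matched atoms then points the same way, so the direction cosines
of those lines have (near-)zero dispersion.  Given the two-fold screw symmetry
of the polymerase and the filament rise, exact coplanarity fixes the angle
triple to (90°, β, arccos(−sin β)) — (90°, 13°, 103°) at β = 13°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import (
    AtomPairing, AtomSet, CoreDefinition, LARGE_CORE, SMALL_CORE, Selection,
    Structure, StructureError, pair_atoms, resolve_selection,
)
from .superpose import RigidTransform, kabsch_fit


@dataclass
class DirectionCosineStats:
    """Per-axis mean ± sd of the direction cosines of atom-connecting lines.

    ``frame`` holds the three orthonormal reference axes as rows (labelled
    a, b, c).  ``sd_cos`` is the sample s.d. (ddof=1); the population s.d. is
    kept alongside since printed values rarely say which was used.
    """
    frame: np.ndarray
    n_lines: int
    mean_cos: np.ndarray
    sd_cos: np.ndarray
    sd_cos_population: np.ndarray
    n_dropped: int = 0

    @property
    def angles(self) -> np.ndarray:
        """(alpha, beta, gamma) in degrees = arccos of the mean cosines."""
        return np.rad2deg(np.arccos(np.clip(self.mean_cos, -1.0, 1.0)))

    @property
    def pooled_variance(self) -> float:
        """Mean of the three per-component variances (sample)."""
        return float(np.mean(self.sd_cos ** 2))


def _orthonormal_frame(frame) -> np.ndarray:
    F = np.asarray(frame, dtype=float)
    if F.shape != (3, 3):
        raise StructureError("frame must be three 3-vectors (rows)")
    if not np.allclose(F @ F.T, np.eye(3), atol=1e-9):
        raise StructureError("frame axes must be orthonormal")
    return F


def connecting_line_stats(X: AtomSet, Y: AtomSet,
                          pairing: AtomPairing | None = None,
                          frame=np.eye(3), flip: bool = False) -> DirectionCosineStats:
    """Direction-cosine statistics of the lines x_i -> y_i.

    Each line's unit vector u_i = (y_i - x_i)/|y_i - x_i| satisfies
    sum(cos²) = 1 against any orthonormal frame.  Coincident pairs
    (|y - x| <= 1e-6 A) are dropped and counted.  ``flip`` reverses the line
    direction convention (X toward Y by default).
    """
    F = _orthonormal_frame(frame)
    if pairing is None:
        if len(X) != len(Y):
            raise StructureError("unequal sizes and no pairing given")
        xc, yc = X.coords, Y.coords
    else:
        xc = X.coords[pairing.x_indices]
        yc = Y.coords[pairing.y_indices]
    if len(xc) < 10:
        raise StructureError(f"need >= 10 atom pairs, got {len(xc)}")
    d = yc - xc
    if flip:
        d = -d
    norms = np.linalg.norm(d, axis=1)
    keep = norms > 1e-6
    n_dropped = int(np.sum(~keep))
    if not np.any(keep):
        raise StructureError("all atom pairs coincide; lines are undefined")
    u = d[keep] / norms[keep, None]
    comps = u @ F.T
    mean = comps.mean(axis=0)
    n = len(u)
    sd = comps.std(axis=0, ddof=1) if n > 1 else np.zeros(3)
    sd_pop = comps.std(axis=0, ddof=0)
    return DirectionCosineStats(F, n, mean, sd, sd_pop, n_dropped)


def exact_coplanarity_reference(beta: float) -> tuple[float, float, float]:
    """Angle triple (alpha, beta, gamma) for exact coplanarity at tilt beta.

    alpha = 90° (lines perpendicular to the first axis), and gamma =
    arccos(-sin beta), the negative-third-cosine solution of
    cos²alpha + cos²beta + cos²gamma = 1.
    """
    if not (0.0 <= beta <= 90.0):
        raise StructureError("beta must be in [0, 90] degrees")
    gamma = float(np.rad2deg(np.arccos(-np.sin(np.deg2rad(beta)))))
    return (90.0, float(beta), gamma)


@dataclass
class ShearDecomposition:
    """Separate rigid fits of the small and large structural cores and the
    relative rotation between them (the shear-plane rotation)."""
    rotation_small: RigidTransform
    rotation_large: RigidTransform
    relative_angle: float
    rmsd_small: float
    rmsd_large: float
    n_small: int = 0
    n_large: int = 0


def _rotation_angle_deg(R: np.ndarray) -> float:
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def shear_decomposition(x: Structure, y: Structure,
                        small: CoreDefinition = SMALL_CORE,
                        large: CoreDefinition = LARGE_CORE,
                        chain_x: str = "*", chain_y: str = "*",
                        atom_names=("N", "CA", "C", "O")) -> ShearDecomposition:
    """Fit the small and large cores independently; report the relative
    rotation angle between the two fitted rotations (R_small · R_largeᵀ)."""
    results = {}
    for core in (small, large):
        try:
            Xs = resolve_selection(x, core.selection(chain_x, atom_names))
            Ys = resolve_selection(y, core.selection(chain_y, atom_names))
        except StructureError as exc:
            raise StructureError(
                f"cannot resolve core {core.name!r} ({core.intervals}): {exc}") from exc
        pairing = pair_atoms(Xs, Ys, "by_author_number")
        results[core.name] = kabsch_fit(Xs, Ys, pairing)
    rs = results[small.name]
    rl = results[large.name]
    rel = _rotation_angle_deg(rs.transform.rotation @ rl.transform.rotation.T)
    return ShearDecomposition(rs.transform, rl.transform, rel,
                              rs.rmsd, rl.rmsd, rs.n_atoms, rl.n_atoms)


def variance_ratio(stats_small: DirectionCosineStats,
                   stats_combined: DirectionCosineStats) -> float:
    """Percent increase of pooled direction-cosine variance when the large
    domains are included: 100 · (pooled_combined / pooled_small − 1)."""
    if not np.allclose(stats_small.frame, stats_combined.frame, atol=1e-9):
        raise StructureError("statistics were computed in different frames")
    ps = stats_small.pooled_variance
    if ps <= 0:
        raise StructureError("small-core variance is zero; ratio undefined")
    return 100.0 * (stats_combined.pooled_variance / ps - 1.0)
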