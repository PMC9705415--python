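"""Model-building recipes: dock a helical filament onto a polymerase-bound
actin, graft a profilin-actin complex onto an FH2-bound actin, and build/dock
the flat ribbon oligomer from profilin-actin crystal packing.

All recipes are pure rigid-body superpositions of refined structures; nothing
is minimized or repacked, so every output is a strain-free composite of its
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import (
    BACKBONE, CoreDefinition, SMALL_CORE, Selection, Structure,
    StructureError, pair_atoms, resolve_selection,
)
from .superpose import RigidTransform, apply_transform, kabsch_fit
from .symmetry_helix import (
    HelixSpec, axis_angle, expand, fit_helix, operator_to_transform,
    screw_decompose,
)


@dataclass
class DockResult:
    model: Structure
    filament_transform: RigidTransform
    filament_axis: np.ndarray | None
    reference_axis: np.ndarray | None
    tilt: float | None
    anchor: str
    fit_rmsd: float
    chain_map: dict[str, str] = field(default_factory=dict)


def _merge_renamed(model: Structure, incoming: Structure,
                   new_id: str | None = None) -> tuple[Structure, dict[str, str]]:
    out = model.copy(new_id or model.id)
    new_ids = out.free_chain_ids(len(incoming.chains))
    mapping = {}
    for chain, nid in zip(incoming.chains, new_ids):
        copy = chain.copy()
        copy.chain_id = nid
        for res in copy.residues:
            res.chain_id = nid
        out.chains.append(copy)
        mapping[chain.chain_id] = nid
    return out, mapping


def _core_set(s: Structure, chain_id: str, core: CoreDefinition | None,
              atom_names=BACKBONE):
    intervals = core.intervals if core is not None else None
    return resolve_selection(s, Selection(chain_id=chain_id, intervals=intervals,
                                          atom_names=atom_names))


def dock_filament(model: Structure, anchor_chain: str, filament: Structure,
                  filament_chain: str, core: CoreDefinition | None = SMALL_CORE,
                  reference_axis=None, reference_chains: tuple[str, str] | None = None,
                  atom_names=BACKBONE, max_fit_rmsd: float = 3.0) -> DockResult:
    """Superpose one filament subunit onto an anchor actin and carry the
    whole filament along; measure the filament-axis tilt against a reference
    axis (typically the crystal two-fold screw axis of the model).

    The reference axis may be given directly, or derived from two model
    chains related by the crystal screw (``reference_chains``).
    """
    X = _core_set(filament, filament_chain, core, atom_names)
    Y = _core_set(model, anchor_chain, core, atom_names)
    pairing = pair_atoms(X, Y, "by_author_number")
    fit = kabsch_fit(X, Y, pairing)
    if fit.rmsd > max_fit_rmsd:
        raise StructureError(
            f"filament subunit does not fit the anchor (RMSD {fit.rmsd:.2f} A "
            f"> {max_fit_rmsd} A): wrong anchor or subunit?")
    moved = apply_transform(filament, fit.transform)
    moved.meta.update(filament.meta)

    filament_axis = None
    try:
        spec = fit_helix(moved)
        filament_axis = spec.axis
    except StructureError:
        pass

    ref = None
    if reference_axis is not None:
        ref = np.asarray(reference_axis, dtype=float)
        ref = ref / np.linalg.norm(ref)
    elif reference_chains is not None:
        from .symmetry_helix import find_screw_operator
        ref = find_screw_operator(model, *reference_chains,
                                  atom_names=atom_names).axis
    tilt = None
    if ref is not None and filament_axis is not None:
        tilt = axis_angle(filament_axis, ref)

    combined, mapping = _merge_renamed(model, moved, f"{model.id}+{filament.id}")
    combined.meta["dock_transform"] = fit.transform.as_flat()
    return DockResult(combined, fit.transform, filament_axis, ref, tilt,
                      anchor_chain, fit.rmsd, mapping)


@dataclass
class GraftResult:
    model: Structure
    per_site_rmsd: list[float]
    grafted_chains: list[dict[str, str]] = field(default_factory=list)

    @property
    def mean_rmsd(self) -> float:
        return float(np.mean(self.per_site_rmsd))


def graft_profilin_actin(model: Structure, target_chains: list[str],
                         pa_complex: Structure, actin_chain: str,
                         profilin_chain: str, atom_names=BACKBONE,
                         pairing_method: str = "by_alignment",
                         min_pair_fraction: float = 0.5) -> GraftResult:
    """Replace FH2-bound actin chain(s) with the actin of a profilin-actin
    complex, carrying profilin along rigidly.

    The complex's actin is fitted onto each target by backbone pairing
    (sequence alignment by default, for cross-isoform grafts); the target
    chain is then removed and the fitted actin + profilin inserted.  The
    per-site backbone RMSD is the fit RMSD at each target.
    """
    if isinstance(target_chains, str):
        target_chains = [target_chains]
    pa_actin = resolve_selection(pa_complex, Selection(
        chain_id=actin_chain, intervals=None, atom_names=atom_names))
    out = model.copy(f"{model.id}_grafted")
    per_site: list[float] = []
    grafted: list[dict[str, str]] = []
    for i, target in enumerate(target_chains):
        target_set = resolve_selection(out, Selection(
            chain_id=target, intervals=None, atom_names=atom_names))
        pairing = pair_atoms(pa_actin, target_set, pairing_method)
        n_target_res = len({(s.seq_number, s.insertion_code) for s in target_set.sites})
        n_paired_res = len({(pa_actin.sites[k].seq_number,
                             pa_actin.sites[k].insertion_code)
                            for k in pairing.x_indices})
        if n_paired_res < min_pair_fraction * n_target_res:
            raise StructureError(
                f"only {n_paired_res}/{n_target_res} residues pair with target "
                f"{target!r}; below the {min_pair_fraction:.0%} threshold")
        fit = kabsch_fit(pa_actin, target_set, pairing)
        per_site.append(fit.rmsd)
        moved_pa = apply_transform(
            pa_complex.subset([actin_chain, profilin_chain]), fit.transform)
        out = out.without_chains([target])
        actin_copy = moved_pa.chain(actin_chain).copy()
        actin_copy.chain_id = target
        for res in actin_copy.residues:
            res.chain_id = target
        prof_copy = moved_pa.chain(profilin_chain).copy()
        prof_id = f"P{i}" if f"P{i}" not in out.chain_ids else out.free_chain_ids(1)[0]
        prof_copy.chain_id = prof_id
        for res in prof_copy.residues:
            res.chain_id = prof_id
        out.chains.extend([actin_copy, prof_copy])
        grafted.append({"target": target, "actin": target, "profilin": prof_id})
    out.meta["graft"] = grafted
    return GraftResult(out, per_site, grafted)


def build_ribbon_oligomer(pa_crystal: Structure, n_units: int,
                          contact_chain: str | None = None,
                          sasa_points: int = 120) -> Structure:
    """Generate the contiguous ribbon of profilin-actin units from crystal
    packing.

    Among the space-group operators (with lattice shifts), the generator is
    chosen as the symmetry copy burying the largest actin-actin interface
    against the input unit.  Unit i is generator^i(unit 0).
    """
    if n_units < 1:
        raise StructureError("n_units must be >= 1")
    if n_units == 1:
        return pa_crystal.copy()
    if pa_crystal.cell is None or not pa_crystal.operators:
        raise StructureError("ribbon construction needs a cell and space-group "
                             "operators")
    from .contacts import VDW_RADII, buried_area

    chain_id = contact_chain or pa_crystal.chains[0].chain_id
    base = resolve_selection(pa_crystal, Selection(chain_id=chain_id,
                                                   intervals=None, atom_names=None))
    best = None
    for op in pa_crystal.operators:
        for shift in _lattice_shifts():
            if np.allclose(op.rot, np.eye(3)) and np.allclose(
                    op.tran + np.asarray(shift, float), 0.0):
                continue  # identity
            t = operator_to_transform(op, pa_crystal, shift)
            moved = base.with_coords(t.apply(base.coords))
            dmin = _min_distance(base.coords, moved.coords)
            if dmin > 5.0 or dmin < 0.5:     # no contact / self-overlapping copy
                continue
            area = buried_area(base, moved, points_per_atom=sasa_points).buried
            if best is None or area > best[0]:
                best = (area, t)
    if best is None:
        raise StructureError("no packing neighbor makes an actin-actin contact")
    generator = best[1]

    out = pa_crystal.copy(f"{pa_crystal.id}_ribbon{n_units}")
    current = generator
    units = [list(pa_crystal.chain_ids)]
    for _ in range(1, n_units):
        moved = apply_transform(pa_crystal, current)
        out, mapping = _merge_renamed(out, moved)
        units.append([mapping[c] for c in pa_crystal.chain_ids])
        current = generator.compose(current)
    out.meta["ribbon_units"] = units
    out.meta["ribbon_generator"] = generator.as_flat()
    return out


def _lattice_shifts():
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                yield (i, j, k)


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    d, _ = cKDTree(b).query(a, k=1)
    return float(np.min(d))


def dock_ribbon(model: Structure, anchor_chain: str, ribbon: Structure,
                ribbon_chain: str, core: CoreDefinition | None = None,
                atom_names=BACKBONE, pairing_method: str = "by_author_number",
                max_fit_rmsd: float = 3.0) -> DockResult:
    """Place the ribbon oligomer by superposing one of its actin subunits
    onto the anchor actin (the penultimate subunit of the polymerase model);
    the remaining units become the bridging and incoming actins."""
    X = _core_set(ribbon, ribbon_chain, core, atom_names)
    Y = _core_set(model, anchor_chain, core, atom_names)
    pairing = pair_atoms(X, Y, pairing_method)
    fit = kabsch_fit(X, Y, pairing)
    if fit.rmsd > max_fit_rmsd:
        raise StructureError(
            f"ribbon subunit does not fit the anchor (RMSD {fit.rmsd:.2f} A)")
    moved = apply_transform(ribbon, fit.transform)
    moved.meta.update(ribbon.meta)
    combined, mapping = _merge_renamed(model, moved, f"{model.id}+{ribbon.id}")
    combined.meta["dock_transform"] = fit.transform.as_flat()
    return DockResult(combined, fit.transform, None, None, None,
                      anchor_chain, fit.rmsd, mapping)
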