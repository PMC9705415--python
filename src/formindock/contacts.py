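"""Steric clash detection, residue-level contacts/salt bridges, and buried
solvent-accessible interface area.

SASA is computed by Shrake-Rupley sphere sampling with a deterministic
golden-spiral point set (default probe 1.4 A, 960 points per atom).  Only the
geometric buried area is computed; no interface free-energy model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import AtomSet, AtomSite, StructureError

#: Van-der-Waals radii (A), a single published heavy-atom set.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "H": 1.20, "D": 1.20,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "MN": 1.97, "FE": 1.94,
    "K": 2.75, "NA": 2.27,
}

_BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_SIDECHAIN_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def _radii_for(sites: list[AtomSite], radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(sites))
    for i, s in enumerate(sites):
        el = _element_of(s)
        r = radii.get(el)
        if r is None:
            raise StructureError(
                f"no van-der-Waals radius for element {el!r} "
                f"(atom {s.atom_name} in {s.res_name} {s.chain_id}{s.seq_number})")
        out[i] = r
    return out


def _element_of(site: AtomSite) -> str:
    # atom sets carry names, not elements; standard PDB naming puts the
    # element first (CA -> C, OD1 -> O, NZ -> N, SG -> S, SE in MSE)
    name = site.atom_name.strip()
    if site.res_name.upper() == "MSE" and name == "SE":
        return "SE"
    if name[:1].isdigit():
        name = name[1:]
    return name[:1].upper()


@dataclass
class ClashRecord:
    atom_i: AtomSite
    atom_j: AtomSite
    distance: float
    overlap: float


def clashes(A: AtomSet, B: AtomSet, radii: dict[str, float] = VDW_RADII,
            min_overlap: float = 0.0,
            exclude_pairs: set[tuple[int, int]] | None = None) -> list[ClashRecord]:
    """All heavy-atom pairs between A and B whose van-der-Waals spheres
    overlap by more than ``min_overlap`` A, sorted by overlap descending."""
    ra = _radii_for(A.sites, radii)
    rb = _radii_for(B.sites, radii)
    max_cut = float(ra.max() + rb.max()) - min_overlap
    tree = cKDTree(B.coords)
    records: list[ClashRecord] = []
    for i, neighbors in enumerate(tree.query_ball_point(A.coords, max_cut)):
        for j in neighbors:
            if exclude_pairs and (i, j) in exclude_pairs:
                continue
            d = float(np.linalg.norm(A.coords[i] - B.coords[j]))
            overlap = ra[i] + rb[j] - d
            if overlap > min_overlap:
                records.append(ClashRecord(A.sites[i], B.sites[j], d, overlap))
    records.sort(key=lambda r: -r.overlap)
    return records


@dataclass
class ContactRecord:
    residue_i: tuple[str, int, str, str]   # chain, seq, icode, res_name
    residue_j: tuple[str, int, str, str]
    min_distance: float
    kind: str                              # salt_bridge | polar | other


def residue_contacts(A: AtomSet, B: AtomSet, cutoff: float = 4.0,
                     polar_cutoff: float = 3.5,
                     salt_bridge_cutoff: float = 4.0) -> list[ContactRecord]:
    """Residue pairs with minimum heavy-atom distance <= cutoff.

    A pair is a salt bridge when a basic sidechain nitrogen (Arg/Lys/His, or
    an N-terminal amine) lies within ``salt_bridge_cutoff`` of an acidic
    sidechain oxygen (Asp/Glu, or a C-terminal carboxylate OXT); polar when
    any N/O–N/O pair is within ``polar_cutoff``; other otherwise.
    """
    def group(aset: AtomSet) -> dict[tuple, list[int]]:
        out: dict[tuple, list[int]] = {}
        for i, s in enumerate(aset.sites):
            out.setdefault((s.chain_id, s.seq_number, s.insertion_code,
                            s.res_name), []).append(i)
        return out

    ga, gb = group(A), group(B)
    tree = cKDTree(B.coords)
    pairs_by_res: dict[tuple[tuple, tuple], list[tuple[int, int]]] = {}
    rev_b = {i: key for key, idxs in gb.items() for i in idxs}
    rev_a = {i: key for key, idxs in ga.items() for i in idxs}
    for i, neighbors in enumerate(tree.query_ball_point(A.coords, cutoff)):
        for j in neighbors:
            pairs_by_res.setdefault((rev_a[i], rev_b[j]), []).append((i, j))

    def is_basic(site: AtomSite) -> bool:
        names = _BASIC_SIDECHAIN_N.get(site.res_name.upper(), set())
        return site.atom_name in names

    def is_acidic(site: AtomSite) -> bool:
        names = _ACIDIC_SIDECHAIN_O.get(site.res_name.upper(), set())
        return site.atom_name in names or site.atom_name == "OXT"

    records = []
    for (ka, kb), idx_pairs in pairs_by_res.items():
        dists = [float(np.linalg.norm(A.coords[i] - B.coords[j]))
                 for i, j in idx_pairs]
        min_d = min(dists)
        kind = "other"
        for (i, j), d in zip(idx_pairs, dists):
            sa, sb = A.sites[i], B.sites[j]
            ea, eb = _element_of(sa), _element_of(sb)
            charged = ((is_basic(sa) and is_acidic(sb)) or
                       (is_acidic(sa) and is_basic(sb)))
            if charged and d <= salt_bridge_cutoff:
                kind = "salt_bridge"
                break
            if ea in ("N", "O") and eb in ("N", "O") and d <= polar_cutoff:
                kind = "polar"
        records.append(ContactRecord(ka, kb, min_d, kind))
    records.sort(key=lambda r: r.min_distance)
    return records


# ---------------------------------------------------------------------------
# SASA / buried interface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         points_per_atom: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    extended = radii + probe
    pts = _sphere_points(points_per_atom)
    tree = cKDTree(coords)
    max_r = extended.max()
    areas = np.empty(n)
    for i in range(n):
        ri = extended[i]
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + max_r)
                     if j != i]
        surface = coords[i] + ri * pts
        if neighbors:
            nb = np.array(neighbors, dtype=int)
            d2 = ((surface[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried_mask = (d2 < (extended[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried_mask.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri * ri
    return areas


@dataclass
class InterfaceArea:
    sasa_A: float
    sasa_B: float
    sasa_AB: float
    probe: float

    @property
    def buried(self) -> float:
        return self.sasa_A + self.sasa_B - self.sasa_AB


def buried_area(A: AtomSet, B: AtomSet, probe: float = 1.4,
                points_per_atom: int = 960,
                radii: dict[str, float] = VDW_RADII) -> InterfaceArea:
    """Buried interface area: SASA(A) + SASA(B) − SASA(A∪B)."""
    ra = _radii_for(A.sites, radii)
    rb = _radii_for(B.sites, radii)
    sa = float(sasa(A.coords, ra, probe, points_per_atom).sum())
    sb = float(sasa(B.coords, rb, probe, points_per_atom).sum())
    both_coords = np.vstack([A.coords, B.coords])
    both_radii = np.concatenate([ra, rb])
    sab = float(sasa(both_coords, both_radii, probe, points_per_atom).sum())
    return InterfaceArea(sa, sb, sab, probe)
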