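"""Hierarchical macromolecular structure container, PDB/mmCIF I/O, selections
and cross-structure atom pairing.

The container is deliberately light: chains -> residues -> atoms, addressed by
*author* residue numbering (the numbering crystallographers print in papers,
e.g. actin Y169 or formin K1410), plus the unit cell and space-group operators
needed for crystallographic symmetry expansion.  Parsing and writing of the
standard formats is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

BACKBONE: tuple[str, ...] = ("N", "CA", "C", "O")

#: Chain identifiers used when renaming symmetry/graft copies, in order.
CHAIN_ID_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

# Actin small/large domain structural cores (author numbering of the mature
# actin sequence).  The small domain spans subdomains 1+2, the large domain
# subdomains 3+4, on either side of the nucleotide cleft.
SMALL_CORE_INTERVALS = ((1, 38), (68, 135), (335, 350), (352, 375))
LARGE_CORE_INTERVALS = ((150, 195), (209, 232), (245, 320))

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "HIC": "H",
}


class StructureError(ValueError):
    """Raised for malformed input or selections that resolve to nothing."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    coords: np.ndarray          # (3,) Cartesian, Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_number, self.insertion_code,
                       self.res_name, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def orthogonalization_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix, PDB convention (a along x, b in xy)."""
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        return np.array(g.orth.mat.tolist(), dtype=float)


@dataclass
class SymOp:
    """Space-group operator: fractional rotation matrix + fractional translation."""
    rot: np.ndarray    # (3,3)
    tran: np.ndarray   # (3,)
    triplet: str = ""

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymOp":
        den = float(op.DEN)
        return cls(np.array(op.rot, dtype=float) / den,
                   np.array(op.tran, dtype=float) / den,
                   op.triplet())

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        return cls.from_gemmi(gemmi.Op(triplet))


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    cell: UnitCell | None = None
    space_group: str | None = None
    operators: list[SymOp] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.operators and self.cell is None:
            raise StructureError("operators require a unit cell")

    # -- hierarchy helpers -------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"structure {self.id!r} has no chain {chain_id!r}")

    def iter_atoms(self):
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for _, _, a in self.iter_atoms()], dtype=float)

    def copy(self, new_id: str | None = None) -> "Structure":
        return Structure(new_id or self.id, [c.copy() for c in self.chains],
                         self.cell, self.space_group,
                         list(self.operators) if self.operators else None,
                         dict(self.meta))

    def without_chains(self, chain_ids) -> "Structure":
        drop = set(chain_ids)
        s = self.copy()
        s.chains = [c for c in s.chains if c.chain_id not in drop]
        return s

    def subset(self, chain_ids) -> "Structure":
        keep = list(chain_ids)
        s = self.copy()
        s.chains = [c for c in s.chains if c.chain_id in keep]
        s.chains.sort(key=lambda c: keep.index(c.chain_id))
        return s

    def free_chain_ids(self, n: int) -> list[str]:
        used = set(self.chain_ids)
        out = [cid for cid in CHAIN_ID_POOL if cid not in used][:n]
        if len(out) < n:
            # two-character ids (mmCIF only)
            for pair in itertools.product(CHAIN_ID_POOL, repeat=2):
                cid = "".join(pair)
                if cid not in used:
                    out.append(cid)
                if len(out) == n:
                    break
        return out

    def sequence_one_letter(self, chain_id: str) -> str:
        return "".join(_THREE_TO_ONE.get(r.res_name.upper(), "X")
                       for r in self.chain(chain_id).residues)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclass
class Selection:
    """Atom selection over author numbering.

    ``chain_id`` may be ``"*"`` (all chains); ``intervals`` of ``None`` selects
    every residue; ``atom_names`` of ``None`` selects every heavy atom.
    """
    chain_id: str = "*"
    intervals: tuple[tuple[int, int], ...] | None = None
    atom_names: tuple[str, ...] | None = BACKBONE
    altloc_policy: str = "highest_occupancy"   # or "first"

    def __post_init__(self) -> None:
        if self.atom_names is not None and len(self.atom_names) == 0:
            raise StructureError("atom_names must be non-empty (or None for all heavy atoms)")
        if self.altloc_policy not in ("first", "highest_occupancy"):
            raise StructureError(f"unknown altloc policy {self.altloc_policy!r}")
        if self.intervals is not None:
            self.intervals = normalize_intervals(self.intervals)

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse e.g. ``"A:1-38,68-135@N,CA,C,O"``; chain ``*`` is a wildcard."""
        atom_names: tuple[str, ...] | None = BACKBONE
        if "@" in text:
            text, atoms = text.split("@", 1)
            atom_names = tuple(a.strip() for a in atoms.split(",")) if atoms != "*" else None
        chain_id, intervals = "*", None
        if ":" in text:
            chain_id, rest = text.split(":", 1)
        else:
            rest = text
        chain_id = chain_id.strip() or "*"
        rest = rest.strip()
        if rest and rest != "*":
            ivs = []
            for piece in rest.split(","):
                piece = piece.strip()
                if "-" in piece[1:]:
                    lo, hi = piece.rsplit("-", 1)
                    ivs.append((int(lo), int(hi)))
                else:
                    ivs.append((int(piece), int(piece)))
            intervals = tuple(ivs)
        return cls(chain_id=chain_id, intervals=intervals, atom_names=atom_names)


def normalize_intervals(intervals) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(lo), int(hi)) for lo, hi in intervals)
    merged: list[tuple[int, int]] = []
    for lo, hi in ivs:
        if lo > hi:
            raise StructureError(f"interval {lo}-{hi} is empty")
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return tuple(merged)


@dataclass(frozen=True)
class CoreDefinition:
    """A named set of author-numbering residue intervals (a structural core)."""
    name: str
    intervals: tuple[tuple[int, int], ...]

    def selection(self, chain_id: str = "*",
                  atom_names: tuple[str, ...] | None = BACKBONE) -> Selection:
        return Selection(chain_id=chain_id, intervals=self.intervals,
                         atom_names=atom_names)

    def union(self, other: "CoreDefinition", name: str | None = None) -> "CoreDefinition":
        return CoreDefinition(name or f"{self.name}+{other.name}",
                              normalize_intervals(self.intervals + other.intervals))

    @property
    def n_residues(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.intervals)


SMALL_CORE = CoreDefinition("small", SMALL_CORE_INTERVALS)
LARGE_CORE = CoreDefinition("large", LARGE_CORE_INTERVALS)


@dataclass(frozen=True)
class AtomSite:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atom_name: str


@dataclass
class AtomSet:
    """An ordered, resolved set of atoms: parallel site metadata + coordinates."""
    sites: list[AtomSite]
    coords: np.ndarray                     # (n, 3)
    skipped_residues: list[tuple[str, int]] = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.sites)

    def subset(self, indices) -> "AtomSet":
        idx = np.asarray(indices, dtype=int)
        return AtomSet([self.sites[i] for i in idx], self.coords[idx],
                       list(self.skipped_residues), self.source_id)

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise StructureError("replacement coordinates have wrong shape")
        return AtomSet(list(self.sites), coords, list(self.skipped_residues),
                       self.source_id)


def _pick_altloc(atoms: list[Atom], policy: str) -> Atom:
    if len(atoms) == 1:
        return atoms[0]
    if policy == "first":
        return atoms[0]
    return max(atoms, key=lambda a: (a.occupancy, -ord(a.altloc or "~")))


def resolve_selection(s: Structure, sel: Selection) -> AtomSet:
    """Resolve a :class:`Selection` to an :class:`AtomSet` in author order.

    Residues requested but absent from the model (disordered loops, e.g. the
    actin D-loop 40-51 in many crystals) are skipped silently and reported in
    ``skipped_residues``.  Hydrogens never enter a default selection.
    """
    if sel.chain_id != "*":
        chains = [s.chain(sel.chain_id)]
    else:
        chains = s.chains
    sites: list[AtomSite] = []
    coords: list[np.ndarray] = []
    skipped: list[tuple[str, int]] = []
    for chain in chains:
        present = set()
        for res in chain.residues:
            if sel.intervals is not None and not any(
                    lo <= res.seq_number <= hi for lo, hi in sel.intervals):
                continue
            present.add(res.seq_number)
            by_name: dict[str, list[Atom]] = {}
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                if sel.atom_names is not None and a.name not in sel.atom_names:
                    continue
                by_name.setdefault(a.name, []).append(a)
            order = sel.atom_names if sel.atom_names is not None else sorted(by_name)
            for name in order:
                if name not in by_name:
                    continue
                atom = _pick_altloc(by_name[name], sel.altloc_policy)
                sites.append(AtomSite(chain.chain_id, res.seq_number,
                                      res.insertion_code, res.res_name, name))
                coords.append(atom.coords)
        if sel.intervals is not None:
            for lo, hi in sel.intervals:
                for num in range(lo, hi + 1):
                    if num not in present:
                        skipped.append((chain.chain_id, num))
    if not sites:
        raise StructureError(f"selection matched nothing in structure {s.id!r}")
    return AtomSet(sites, np.array(coords, dtype=float), skipped, s.id)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

@dataclass
class AtomPairing:
    x_indices: np.ndarray
    y_indices: np.ndarray
    method: str
    n_dropped_x: int = 0
    n_dropped_y: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.x_indices)


def _align_sequences(seq_x: str, seq_y: str) -> list[tuple[int, int]]:
    """Global alignment (match +1, mismatch -1, gap open -5) over one-letter codes."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -5.0
    aln = aligner.align(seq_x, seq_y)[0]
    pairs: list[tuple[int, int]] = []
    for (xs, xe), (ys, ye) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend(zip(range(xs, xe), range(ys, ye)))
    return pairs


def pair_atoms(X: AtomSet, Y: AtomSet, method: str = "by_author_number") -> AtomPairing:
    """One-to-one pairing of two atom sets.

    ``by_author_number`` matches on (seq_number, insertion_code, atom_name) —
    appropriate for two copies of the same entity.  ``by_alignment`` globally
    aligns the residue sequences first (for isoform grafts, e.g. skeletal
    alpha-actin onto cytoplasmic beta-actin) and then matches atom names
    within aligned residue pairs.  Unpaired atoms are dropped and counted.
    """
    if len({s.chain_id for s in X.sites}) > 1 or len({s.chain_id for s in Y.sites}) > 1:
        raise StructureError("pair_atoms expects single-chain atom sets")
    if method == "by_author_number":
        keyed_y = {(s.seq_number, s.insertion_code, s.atom_name): i
                   for i, s in enumerate(Y.sites)}
        xi, yi = [], []
        for i, s in enumerate(X.sites):
            j = keyed_y.get((s.seq_number, s.insertion_code, s.atom_name))
            if j is not None:
                xi.append(i)
                yi.append(j)
    elif method == "by_alignment":
        res_x: list[tuple[tuple, str]] = []
        res_y: list[tuple[tuple, str]] = []
        idx_x: dict[tuple, dict[str, int]] = {}
        idx_y: dict[tuple, dict[str, int]] = {}
        for sites, res_list, idx in ((X.sites, res_x, idx_x), (Y.sites, res_y, idx_y)):
            for i, s in enumerate(sites):
                key = (s.seq_number, s.insertion_code)
                if key not in idx:
                    idx[key] = {}
                    res_list.append((key, _THREE_TO_ONE.get(s.res_name.upper(), "X")))
                idx[key][s.atom_name] = i
        seq_x = "".join(c for _, c in res_x)
        seq_y = "".join(c for _, c in res_y)
        xi, yi = [], []
        for rx, ry in _align_sequences(seq_x, seq_y):
            ax = idx_x[res_x[rx][0]]
            ay = idx_y[res_y[ry][0]]
            for name, i in ax.items():
                if name in ay:
                    xi.append(i)
                    yi.append(ay[name])
    else:
        raise StructureError(f"unknown pairing method {method!r}")
    if len(xi) < 3:
        raise StructureError(f"pairing produced only {len(xi)} pairs (need >= 3)")
    return AtomPairing(np.array(xi, dtype=int), np.array(yi, dtype=int), method,
                       n_dropped_x=len(X) - len(xi), n_dropped_y=len(Y) - len(yi))


def identity_pairing(X: AtomSet) -> AtomPairing:
    idx = np.arange(len(X))
    return AtomPairing(idx, idx.copy(), "by_author_number")


# ---------------------------------------------------------------------------
# I/O via gemmi
# ---------------------------------------------------------------------------

def _looks_like_path(source: str) -> bool:
    return "\n" not in source and len(source) < 4096 and os.path.exists(source)


def read_structure(source, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF structure from a path or raw text.

    Only model 1 of multi-model files is taken.  Unit cell, space group and
    space-group operators are captured when the header carries them.
    """
    source = str(source) if not isinstance(source, str) else source
    is_path = _looks_like_path(source)
    text = None if is_path else source
    try:
        if fmt == "auto":
            if is_path:
                fmt = "mmcif" if source.lower().endswith((".cif", ".mmcif")) else "pdb"
            else:
                fmt = "mmcif" if ("loop_" in source or source.lstrip().startswith("data_")) else "pdb"
        if fmt == "pdb":
            st = gemmi.read_pdb(source) if is_path else gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            if is_path:
                doc = gemmi.cif.read(source)
            else:
                doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:                         # gemmi raises RuntimeError
        raise StructureError(f"cannot parse {fmt} input: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureError("input contains no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            res = Residue(gchain.name, gres.seqid.num, gres.seqid.icode.strip(),
                          gres.name)
            for ga in gres:
                el = ga.element.name if ga.element else ""
                res.atoms.append(Atom(ga.serial, ga.name, el,
                                      (ga.altloc or "").strip(),
                                      np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                      ga.occ, ga.b_iso))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    if not any(len(r.atoms) for c in chains for r in c.residues):
        raise StructureError("input contains no atoms")

    cell = None
    space_group = None
    operators = None
    if st.cell and st.cell.is_crystal():
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
        hm = st.spacegroup_hm or ""
        if hm and hm not in ("P 1", "P1"):
            space_group = hm
            sg = gemmi.find_spacegroup_by_name(hm)
            if sg is not None:
                operators = [SymOp.from_gemmi(op) for op in sg.operations()]

    sid = st.name or (os.path.splitext(os.path.basename(source))[0] if is_path else "structure")
    return Structure(sid, chains, cell, space_group, operators)


def to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    if s.cell is not None:
        st.cell = gemmi.UnitCell(s.cell.a, s.cell.b, s.cell.c,
                                 s.cell.alpha, s.cell.beta, s.cell.gamma)
    if s.space_group:
        st.spacegroup_hm = s.space_group
    model = gemmi.Model("1")
    serial = 1
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[:1])
                ga.altloc = a.altloc[:1] if a.altloc else "\x00"
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                ga.serial = serial
                serial += 1
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path, fmt: str | None = None) -> None:
    """Write a structure as PDB or mmCIF (format inferred from the suffix)."""
    if s.n_atoms == 0:
        raise StructureError("refusing to write an empty structure")
    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.lower().endswith((".cif", ".mmcif")) else "pdb"
    if fmt == "pdb":
        if len(s.chains) > 62 or any(len(c.chain_id) > 1 for c in s.chains):
            raise StructureError(
                f"{len(s.chains)} chains / long chain ids do not fit the PDB "
                "format; write mmCIF instead")
        to_gemmi(s).write_pdb(path)
    elif fmt == "mmcif":
        to_gemmi(s).make_mmcif_document().write_file(path)
    else:
        raise StructureError(f"unknown format {fmt!r}")
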