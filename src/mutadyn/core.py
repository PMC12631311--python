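"""Structure/trajectory data model, superposition, RMSD, ASA and sequence mass.

Coordinates are stored in Ångström and trajectory times in nanoseconds
throughout the package; unit conversions happen only at I/O boundaries.
Residue identifiers are author numbers (e.g. 1513–1657 for the alsin VPS9
construct) and are preserved end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio.SeqUtils import molecular_weight

__all__ = [
    "Structure",
    "TrajectorySeries",
    "CVSeries",
    "kabsch_superpose",
    "rmsd_series",
    "shrake_rupley_asa",
    "sequence_mass",
    "apply_substitutions",
    "extract_construct",
    "read_pdb",
    "write_pdb",
    "parse_selection",
]

# Van der Waals radii (Å), Bondi set; used by the accessible-surface routine.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}

# Theoretical maximum accessible surface area per residue (Å²),
# Tien et al. 2013 ("theoretical" column); used for relative ASA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class SelectionError(ValueError):
    """Raised when an atom selection is empty, degenerate or unresolvable."""


@dataclass
class Structure:
    """A single-frame molecular structure.

    Attributes
    ----------
    atom_names, elements, res_ids, res_names, chain_ids : arrays of length n_atoms
    coords : (n_atoms, 3) float array, Å
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_names), 3):
            raise ValueError("coords must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue ids in order of first appearance."""
        _, idx = np.unique(self.res_ids, return_index=True)
        return self.res_ids[np.sort(idx)]

    def mask(self, names=None, res_ids=None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            names = {names} if isinstance(names, str) else set(names)
            m &= np.array([a in names for a in self.atom_names])
        if res_ids is not None:
            res_ids = {int(res_ids)} if np.isscalar(res_ids) else set(int(r) for r in res_ids)
            m &= np.array([r in res_ids for r in self.res_ids])
        return m

    def select(self, names=None, res_ids=None) -> np.ndarray:
        """Indices of atoms matching the given atom names / residue ids."""
        return np.flatnonzero(self.mask(names=names, res_ids=res_ids))

    def subset(self, index) -> "Structure":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Structure(
            self.atom_names[index], self.elements[index], self.res_ids[index],
            self.res_names[index], self.chain_ids[index], self.coords[index],
        )

    def atom_index(self, res_id: int, atom_name: str) -> int:
        idx = np.flatnonzero((self.res_ids == res_id) & (self.atom_names == atom_name))
        if len(idx) != 1:
            raise SelectionError(f"atom {atom_name} of residue {res_id}: {len(idx)} matches")
        return int(idx[0])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return replace(self, coords=self.coords @ rotation.T + translation)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def sequence(self) -> str:
        """One-letter sequence over residues in order of appearance."""
        letters = []
        for rid in self.residue_ids:
            rname = self.res_names[self.res_ids == rid][0]
            letters.append(THREE_TO_ONE.get(rname, "X"))
        return "".join(letters)


@dataclass
class TrajectorySeries:
    """A trajectory: one topology plus per-frame coordinates and times (ns)."""

    topology: Structure
    coords: np.ndarray          # (n_frames, n_atoms, 3), Å
    times: np.ndarray           # (n_frames,), ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching topology")
        if len(self.times) != len(self.coords):
            raise ValueError("times and coords disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def dt(self) -> float:
        """Sampling interval in ns (uniform sampling assumed)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class CVSeries:
    """Per-frame values of a named collective variable."""

    name: str
    unit: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")


# ---------------------------------------------------------------------------
# Superposition and RMSD


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the mass-unweighted RMSD
    to ``reference``. Requires at least 3 non-collinear paired points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SelectionError("paired (n, 3) coordinate sets required")
    if len(mobile) < 3:
        raise SelectionError("at least 3 points required for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    # collinear selections leave the rotation about the line undetermined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise SelectionError("degenerate (collinear) selection")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - mc @ rot.T
    return rot, trans, _rmsd(mobile @ rot.T + trans, reference)


def batched_template_rmsd(coords: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Minimum RMSD of each (m, 3) coordinate set in ``coords`` (k, m, 3)
    against a single ``template`` (m, 3), via batched Kabsch."""
    coords = np.asarray(coords, dtype=float)
    template = np.asarray(template, dtype=float)
    a = coords - coords.mean(axis=1, keepdims=True)
    b = template - template.mean(axis=0)
    h = np.einsum("kmi,mj->kij", a, b)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("kij,kjl->kil", u, vt))
    # E0 = sum of squared norms; min residual = E0 - 2*sum(singular values with sign fix)
    e0 = np.sum(a ** 2, axis=(1, 2)) + np.sum(b ** 2)
    s_adj = s.copy()
    s_adj[:, -1] *= np.sign(det)
    msd = np.maximum(e0 - 2.0 * s_adj.sum(axis=1), 0.0) / coords.shape[1]
    return np.sqrt(msd)


def rmsd_series(traj: TrajectorySeries, reference: Structure,
                fit_selection=None, measure_selection=None) -> CVSeries:
    """Per-frame RMSD to ``reference`` after per-frame superposition.

    ``fit_selection`` / ``measure_selection`` are atom index arrays (or
    boolean masks) resolved against both the trajectory topology and the
    reference; ``None`` means all atoms.
    """
    def _resolve(sel, n):
        if sel is None:
            return np.arange(n)
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        if sel.size == 0 or sel.max() >= n:
            raise SelectionError("selection out of range or empty")
        return sel

    if traj.topology.n_atoms != reference.n_atoms:
        raise SelectionError("trajectory and reference atom counts differ")
    fit = _resolve(fit_selection, reference.n_atoms)
    meas = _resolve(measure_selection, reference.n_atoms)
    out = np.empty(traj.n_frames)
    ref_fit = reference.coords[fit]
    ref_meas = reference.coords[meas]
    for i in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coords[i][fit], ref_fit)
        moved = traj.coords[i][meas] @ rot.T + trans
        out[i] = _rmsd(moved, ref_meas)
    return CVSeries("rmsd", "A", traj.times.copy(), out)


# ---------------------------------------------------------------------------
# Accessible surface area (Shrake–Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_asa(structure: Structure, probe_radius: float = 1.4,
                      n_sphere_points: int = 960):
    """Solvent-accessible surface area by the rolling-probe point method.

    Returns ``(per_atom, per_residue, relative)`` where ``per_atom`` is an
    array of Å² values, ``per_residue`` maps residue id → Å² and ``relative``
    maps residue id → fraction of the residue's theoretical maximum ASA
    (NaN for residue types without a tabulated maximum).
    """
    from scipy.spatial import cKDTree

    radii = np.empty(structure.n_atoms)
    for i, el in enumerate(structure.elements):
        try:
            radii[i] = VDW_RADII[str(el).upper()]
        except KeyError:
            raise ValueError(f"unknown element {el!r}: no van der Waals radius")
    expanded = radii + probe_radius
    pts = _sphere_points(n_sphere_points)
    tree = cKDTree(structure.coords)
    max_reach = 2 * expanded.max()
    per_atom = np.zeros(structure.n_atoms)
    for i in range(structure.n_atoms):
        neigh = tree.query_ball_point(structure.coords[i], expanded[i] + max_reach / 2)
        neigh = [j for j in neigh if j != i]
        surface = structure.coords[i] + expanded[i] * pts
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(surface - structure.coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    per_residue = {}
    relative = {}
    for rid in structure.residue_ids:
        sel = structure.res_ids == rid
        asa = float(per_atom[sel].sum())
        per_residue[int(rid)] = asa
        rname = structure.res_names[sel][0]
        mx = MAX_ASA.get(rname)
        relative[int(rid)] = asa / mx if mx else float("nan")
    return per_atom, per_residue, relative


# ---------------------------------------------------------------------------
# Sequence mass and construct editing


def sequence_mass(sequence: str) -> float:
    """Average molecular mass of a peptide in kDa (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    bad = set(sequence) - set(ONE_TO_THREE)
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    return molecular_weight(sequence, seq_type="protein", monoisotopic=False) / 1000.0


def apply_substitutions(sequence: str, substitutions, first_res_id: int = 1) -> str:
    """Apply point substitutions given in author numbering, e.g. ``"C1551S"``.

    ``first_res_id`` is the author number of the sequence's first residue.
    """
    seq = list(sequence)
    for sub in substitutions:
        old, pos, new = sub[0], int(sub[1:-1]), sub[-1]
        i = pos - first_res_id
        if not 0 <= i < len(seq):
            raise ValueError(f"substitution {sub} outside sequence range")
        if seq[i] != old:
            raise ValueError(f"substitution {sub}: found {seq[i]} at position {pos}")
        seq[i] = new
    return "".join(seq)


def extract_construct(full_sequence: str, start: int, end: int,
                      substitutions=(), tag: str = "") -> str:
    """Slice residues ``start..end`` (author numbers, inclusive, full sequence
    numbered from 1), apply substitutions, optionally prepend a tag sequence."""
    if not 1 <= start <= end <= len(full_sequence):
        raise ValueError("construct range outside sequence")
    core = full_sequence[start - 1:end]
    core = apply_substitutions(core, substitutions, first_res_id=start)
    return tag + core


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed) and mdtraj conversion


def _from_biotite(arr) -> Structure:
    elements = [
        el if el else name.strip()[0]
        for el, name in zip(arr.element, arr.atom_name)
    ]
    return Structure(arr.atom_name, elements, arr.res_id, arr.res_name,
                     arr.chain_id, arr.coord)


def read_pdb(path) -> "Structure | TrajectorySeries":
    """Read a PDB file; multi-model files yield a TrajectorySeries with frame
    times 0, 1, 2, … ns (override via ``TrajectorySeries`` if known)."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure()  # AtomArrayStack
    top = _from_biotite(stack[0])
    if stack.stack_depth() == 1:
        return top
    return TrajectorySeries(top, np.asarray(stack.coord, dtype=float),
                            np.arange(stack.stack_depth(), dtype=float))


def write_pdb(path, obj) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(obj, TrajectorySeries):
        top, frames = obj.topology, obj.coords
    else:
        top, frames = obj, obj.coords[None]
    arr = struc.AtomArray(top.n_atoms)
    arr.atom_name = np.asarray(top.atom_names, dtype="U6")
    arr.element = np.asarray(top.elements, dtype="U2")
    arr.res_id = top.res_ids
    arr.res_name = np.asarray(top.res_names, dtype="U5")
    arr.chain_id = np.asarray(top.chain_ids, dtype="U4")
    stack = struc.AtomArrayStack(len(frames), top.n_atoms)
    for cat in ("atom_name", "element", "res_id", "res_name", "chain_id"):
        setattr(stack, cat, getattr(arr, cat))
    stack.coord = np.asarray(frames, dtype=np.float32)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def to_mdtraj(obj):
    """Convert a Structure or TrajectorySeries to an mdtraj.Trajectory (nm/ps)."""
    import mdtraj as md
    from mdtraj.core import element as md_element

    if isinstance(obj, TrajectorySeries):
        top_s, frames, times = obj.topology, obj.coords, obj.times
    else:
        top_s, frames, times = obj, obj.coords[None], np.zeros(1)
    top = md.Topology()
    chain_map = {}
    res_map = {}
    for i in range(top_s.n_atoms):
        cid = top_s.chain_ids[i]
        if cid not in chain_map:
            chain_map[cid] = top.add_chain()
        key = (cid, int(top_s.res_ids[i]))
        if key not in res_map:
            res_map[key] = top.add_residue(str(top_s.res_names[i]), chain_map[cid],
                                           resSeq=int(top_s.res_ids[i]))
        el = md_element.get_by_symbol(str(top_s.elements[i]).capitalize())
        top.add_atom(str(top_s.atom_names[i]), el, res_map[key])
    traj = md.Trajectory(frames / 10.0, top, time=times * 1000.0)
    return traj


# ---------------------------------------------------------------------------
# Tiny selection language for the CLI ("name CA and resid 1532-1542")


def parse_selection(structure: Structure, expr: str) -> np.ndarray:
    """Resolve ``"name CA[,CB] and resid 1532-1542[,1611]"`` to atom indices."""
    names = None
    res_ids = None
    for clause in expr.split(" and "):
        clause = clause.strip()
        if clause.startswith("name "):
            names = [t for t in clause[5:].replace(",", " ").split() if t]
        elif clause.startswith("resid "):
            res_ids = []
            for tok in clause[6:].replace(",", " ").split():
                if "-" in tok:
                    lo, hi = tok.split("-")
                    res_ids.extend(range(int(lo), int(hi) + 1))
                else:
                    res_ids.append(int(tok))
        elif clause in ("all", ""):
            continue
        else:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
    idx = structure.select(names=names, res_ids=res_ids)
    if idx.size == 0:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return idx
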