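"""Backbone geometry: internal-coordinate chain building, ideal secondary
structures, and the ideal β-sheet segment-pair templates.

The builders produce N/CA/CB/C/O backbones with standard bond lengths and
angles. They exist to support the collective-variable templates, the
secondary-structure oracles and the synthetic trajectory generator; they are
not a modelling tool.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import Structure

# Engh–Huber-style backbone geometry (Å, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_CA_CB = 1.530
B_N_H = 1.01
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8

# canonical (phi, psi) in degrees
TORSIONS = {
    "helix": (-57.0, -47.0),
    "antiparallel": (-139.0, 135.0),
    "parallel": (-119.0, 113.0),
    "extended": (180.0, 180.0),
}

# atom order per residue used by the β templates (30 atoms over 6 residues)
TEMPLATE_ATOMS = ("N", "CA", "CB", "C", "O")


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_cb(n, ca, c, length: float = B_CA_CB) -> np.ndarray:
    """Cβ at the ideal tetrahedral position given N, CA, C (also used to
    synthesize a glycine Cβ for the βRMSD templates)."""
    n, ca, c = (np.asarray(x, dtype=float) for x in (n, ca, c))
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    nrm = np.cross(u1, u2)
    nrm /= np.linalg.norm(nrm)
    half = np.arccos(np.clip(np.dot(u1, u2), -1, 1)) / 2.0
    alpha = (-1.0 / 3.0) / np.cos(half)  # d·u1 = d·u2 = cos(109.47°)
    beta = np.sqrt(max(1.0 - alpha ** 2, 0.0))
    return ca + length * (alpha * bis + beta * nrm)


def build_backbone(res_names, phi, psi, omega=None, *, chain_id="A",
                   first_res_id: int = 1, with_h: bool = False) -> Structure:
    """Build an N/CA/CB/C/O backbone from per-residue (φ, ψ) torsions.

    ``phi[0]`` is unused (no preceding C); glycine residues get no Cβ.
    With ``with_h`` an amide H is placed on every residue after the first,
    at 1.01 Å along the in-plane bisector of the two N bonds.
    """
    res_names = list(res_names)
    nres = len(res_names)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (nres,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (nres,))
    omega = np.full(nres, 180.0) if omega is None else np.broadcast_to(
        np.asarray(omega, dtype=float), (nres,))

    n_pos = np.zeros((nres, 3))
    ca_pos = np.zeros((nres, 3))
    c_pos = np.zeros((nres, 3))
    # seed residue
    n_pos[0] = (0.0, 0.0, 0.0)
    ca_pos[0] = (B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - A_N_CA_C)  # CA→C measured from +x, with CA→N along −x
    c_pos[0] = ca_pos[0] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, nres):
        n_pos[i] = place_atom(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                              B_C_N, A_CA_C_N, psi[i - 1])
        ca_pos[i] = place_atom(ca_pos[i - 1], c_pos[i - 1], n_pos[i],
                               B_N_CA, A_C_N_CA, omega[i - 1])
        c_pos[i] = place_atom(c_pos[i - 1], n_pos[i], ca_pos[i],
                              B_CA_C, A_N_CA_C, phi[i])

    names, elements, rids, rnames, chains, coords = [], [], [], [], [], []

    def add(name, el, i, xyz):
        names.append(name)
        elements.append(el)
        rids.append(first_res_id + i)
        rnames.append(res_names[i])
        chains.append(chain_id)
        coords.append(xyz)

    for i in range(nres):
        add("N", "N", i, n_pos[i])
        if with_h and i > 0:
            u1 = c_pos[i - 1] - n_pos[i]
            u1 /= np.linalg.norm(u1)
            u2 = ca_pos[i] - n_pos[i]
            u2 /= np.linalg.norm(u2)
            h_dir = -(u1 + u2)
            h_dir /= np.linalg.norm(h_dir)
            add("H", "H", i, n_pos[i] + B_N_H * h_dir)
        add("CA", "C", i, ca_pos[i])
        if res_names[i] != "GLY":
            add("CB", "C", i, ideal_cb(n_pos[i], ca_pos[i], c_pos[i]))
        add("C", "C", i, c_pos[i])
        # carbonyl O anti to the next amide N (torsion ψ − 180 about N-CA-C)
        add("O", "O", i, place_atom(n_pos[i], ca_pos[i], c_pos[i],
                                    B_C_O, A_CA_C_O, psi[i] - 180.0))
    return Structure(names, elements, rids, rnames, chains, np.array(coords))


def ideal_strand(nres: int = 3, kind: str = "antiparallel", **kw) -> Structure:
    phi, psi = TORSIONS[kind]
    return build_backbone(["ALA"] * nres, phi, psi, **kw)


def ideal_helix(nres: int = 12, **kw) -> Structure:
    phi, psi = TORSIONS["helix"]
    return build_backbone(["ALA"] * nres, phi, psi, **kw)


def _template_coords(strand: Structure) -> np.ndarray:
    """(15, 3) coordinates of a 3-residue strand in template atom order."""
    out = []
    for rid in strand.residue_ids:
        for name in TEMPLATE_ATOMS:
            out.append(strand.coords[strand.atom_index(rid, name)])
    return np.array(out)


def _hbond_cost(params, a_atoms, b_atoms, pairs, ca_pairs, all_a, all_b):
    """Rigid-transform cost: N···O hydrogen-bond targets (2.9 Å), paired
    Cα···Cα register targets (4.9 Å) and a soft steric floor at 3.4 Å."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    trans = params[3:]
    b_moved = {k: v @ rot.T + trans for k, v in b_atoms.items()}
    cost = 0.0
    for (ka, kb) in pairs:
        d = np.linalg.norm(a_atoms[ka] - b_moved[kb])
        cost += (d - 2.9) ** 2
    for (ka, kb) in ca_pairs:
        d = np.linalg.norm(a_atoms[ka] - b_moved[kb])
        cost += 0.5 * (d - 4.9) ** 2
    moved_all = all_b @ rot.T + trans
    d = np.linalg.norm(all_a[:, None, :] - moved_all[None, :, :], axis=-1)
    cost += np.sum(np.maximum(3.4 - d, 0.0) ** 2)
    return cost


@lru_cache(maxsize=None)
def beta_pair_template(kind: str = "antiparallel") -> np.ndarray:
    """Ideal 30-atom template for a pair of 3-residue β segments.

    Atom order: residues a1 a2 a3 b1 b2 b3, each contributing N, CA, CB, C, O.
    The second strand is positioned by numerically optimising the canonical
    inter-strand N···O hydrogen-bond registry (2.9 Å targets) subject to a
    soft steric floor; for the antiparallel template a1 pairs with b3, for
    the parallel template the registry is staggered by one residue.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    strand = ideal_strand(3, kind)
    rids = strand.residue_ids

    def atom(rid, name):
        return strand.coords[strand.atom_index(rid, name)]

    a_atoms = {(i, nm): atom(rids[i], nm) for i in range(3) for nm in ("N", "O", "CA")}
    b_atoms = dict(a_atoms)

    if kind == "antiparallel":
        # the second strand runs the opposite way: a1 pairs with b3
        start_rots = [Rotation.from_euler(ax, 180, degrees=True).as_matrix()
                      for ax in ("y", "z")]
        pairs = [((0, "N"), (2, "O")), ((0, "O"), (2, "N")),
                 ((2, "N"), (0, "O")), ((2, "O"), (0, "N"))]
        ca_pairs = [((0, "CA"), (2, "CA")), ((1, "CA"), (1, "CA")),
                    ((2, "CA"), (0, "CA"))]
    elif kind == "parallel":
        start_rots = [np.eye(3)]
        # parallel bridge: N(a2)···O(b1) and O(a2)···N(b3)
        pairs = [((1, "N"), (0, "O")), ((1, "O"), (2, "N"))]
        ca_pairs = [((0, "CA"), (0, "CA")), ((1, "CA"), (1, "CA")),
                    ((2, "CA"), (2, "CA"))]
    else:
        raise ValueError(f"unknown template kind {kind!r}")

    all_a = _template_coords(strand)
    best = None
    for start_rot in start_rots:
        all_b0 = all_a @ start_rot.T
        b_rot0 = {k: v @ start_rot.T for k, v in b_atoms.items()}
        for shift in ((0.0, 4.8, 0.0), (0.0, -4.8, 0.0),
                      (0.0, 0.0, 4.8), (0.0, 0.0, -4.8)):
            x0 = np.array([0.0, 0.0, 0.0, *shift])
            res = minimize(
                _hbond_cost, x0,
                args=(a_atoms, b_rot0, pairs, ca_pairs, all_a, all_b0),
                method="Nelder-Mead",
                options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-12},
            )
            if best is None or res.fun < best[0]:
                best = (res.fun, res.x, all_b0)
    _, x, all_b0 = best
    rot = Rotation.from_rotvec(x[:3]).as_matrix()
    b_final = all_b0 @ rot.T + x[3:]
    template = np.vstack([all_a, b_final])
    template -= template.mean(axis=0)
    template.setflags(write=False)
    return template
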