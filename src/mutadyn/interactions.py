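"""Noncovalent interaction fingerprints between a probe residue and the rest
of the protein.

Per frame, contacts are detected with geometric criteria (the classic
profiler defaults): hydrogen bond — donor–acceptor heavy-atom distance
≤ 4.1 Å with donor angle D–H···A ≥ 100° when an amide/side-chain H is
present; salt bridge — centroid distance of oppositely charged groups
≤ 5.5 Å; hydrophobic — apolar carbon pair distance ≤ 4.0 Å. Occupancy of a
(type, partner) contact is the fraction of frames in which it appears at
least once; records above a probability threshold (strictly greater, default
30%) make up the fingerprint.

Protonation is fixed at standard states: Asp/Glu anionic, Lys/Arg cationic,
His neutral. Metal complexes, π-stacking, π–cation and halogen bonds are
recognized record types but have no detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Structure, TrajectorySeries

__all__ = ["ContactCriteria", "InteractionRecord", "detect_contacts",
           "interaction_probability", "filter_interactions"]

IMPLEMENTED_TYPES = ("hydrogen_bond", "salt_bridge", "hydrophobic")
RECOGNIZED_TYPES = IMPLEMENTED_TYPES + ("metal_complex", "pi_stacking",
                                        "pi_cation", "halogen_bond")

# heavy-atom hydrogen-bond donors / acceptors per residue type
_SC_DONORS = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["ND2"], "GLN": ["NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "HIS": ["ND1", "NE2"], "TRP": ["NE1"],
}
_SC_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"],
}

# side-chain carbons bonded only to C/H (apolar)
_APOLAR_CARBONS = {
    "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"], "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "PRO": ["CB", "CG"], "LYS": ["CB", "CG", "CD"],
    "ARG": ["CB", "CG"], "GLU": ["CB", "CG"], "GLN": ["CB", "CG"],
    "ASP": ["CB"], "ASN": ["CB"], "THR": ["CG2"], "CYS": ["CB"],
    "HIS": ["CB"], "GLY": [], "SER": ["CB"],
}

# charged groups at standard protonation (His neutral)
_POSITIVE_GROUPS = {"LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"]}
_NEGATIVE_GROUPS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}

_STANDARD_RESIDUES = set(_APOLAR_CARBONS)


@dataclass
class ContactCriteria:
    """Geometric cutoffs; defaults follow the cited profiler."""

    hbond_dist: float = 4.1          # donor–acceptor heavy-atom distance, Å
    hbond_angle: float = 100.0       # minimum D–H···A angle, degrees
    saltbridge_dist: float = 5.5     # charged-group centroid distance, Å
    hydrophobic_dist: float = 4.0    # apolar carbon pair distance, Å


@dataclass
class InteractionRecord:
    """Occupancy of one (type, partner) contact over a trajectory."""

    type: str
    partner: int                     # author-numbered residue
    probability: float


def _residue_atoms(frame: Structure, rid: int):
    sel = frame.res_ids == rid
    return frame.atom_names[sel], frame.coords[sel], frame.res_names[sel][0]


def _angle(a, b, c) -> float:
    u = a - b
    v = c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _donors(names, coords, rname):
    """(heavy atom position, [attached H positions]) for each donor."""
    out = []
    cand = (["N"] if rname != "PRO" else []) + _SC_DONORS.get(rname, [])
    name_list = list(names)
    for dn in cand:
        if dn not in name_list:
            continue
        dpos = coords[name_list.index(dn)]
        hs = [coords[i] for i, nm in enumerate(name_list)
              if str(nm).startswith("H") and np.linalg.norm(coords[i] - dpos) < 1.25]
        out.append((dpos, hs))
    return out


def _acceptors(names, coords, rname):
    cand = ["O", "OXT"] + _SC_ACCEPTORS.get(rname, [])
    return [coords[list(names).index(an)] for an in cand if an in list(names)]


def _group_centroid(names, coords, atom_names):
    name_list = list(names)
    pts = [coords[name_list.index(a)] for a in atom_names if a in name_list]
    return np.mean(pts, axis=0) if pts else None


def detect_contacts(frame: Structure, probe: int,
                    criteria: ContactCriteria | None = None,
                    types=IMPLEMENTED_TYPES) -> list[tuple[str, int, dict]]:
    """Contacts between residue ``probe`` and every other residue in ``frame``.

    Returns one record per (type, partner); multiple geometric hits to the
    same partner collapse into a single record carrying the closest geometry.
    """
    criteria = criteria or ContactCriteria()
    unsupported = set(types) - set(IMPLEMENTED_TYPES)
    if unsupported & set(RECOGNIZED_TYPES):
        raise NotImplementedError(f"no detector for {sorted(unsupported)}")
    if unsupported:
        raise ValueError(f"unknown interaction types {sorted(unsupported)}")

    p_names, p_coords, p_rname = _residue_atoms(frame, probe)
    if p_rname not in _STANDARD_RESIDUES:
        raise ValueError(f"unknown probe residue type {p_rname!r}")
    if len(p_names) == 0:
        raise ValueError(f"probe residue {probe} not found")

    found: dict[tuple[str, int], dict] = {}

    def record(kind, partner, dist, **geometry):
        key = (kind, int(partner))
        if key not in found or dist < found[key]["distance"]:
            found[key] = {"distance": float(dist), **geometry}

    p_donors = _donors(p_names, p_coords, p_rname)
    p_acceptors = _acceptors(p_names, p_coords, p_rname)
    p_apolar = [p_coords[list(p_names).index(a)]
                for a in _APOLAR_CARBONS.get(p_rname, []) if a in list(p_names)]
    p_pos = _group_centroid(p_names, p_coords, _POSITIVE_GROUPS.get(p_rname, []))
    p_neg = _group_centroid(p_names, p_coords, _NEGATIVE_GROUPS.get(p_rname, []))

    def hbond_hits(donors, acceptors, charged_d=(), charged_a=()):
        # donor–acceptor pairs between oppositely charged groups are the
        # salt-bridge detector's business, not hydrogen bonds
        hits = []
        for dpos, hs in donors:
            if any(np.allclose(dpos, q) for q in charged_d):
                charged_donor = True
            else:
                charged_donor = False
            for apos in acceptors:
                if charged_donor and any(np.allclose(apos, q) for q in charged_a):
                    continue
                d = np.linalg.norm(dpos - apos)
                if d > criteria.hbond_dist:
                    continue
                if hs:
                    ang = max(_angle(dpos, h, apos) for h in hs)
                    if ang < criteria.hbond_angle:
                        continue
                else:
                    ang = float("nan")   # no explicit H: distance-only
                hits.append((d, ang))
        return hits

    for rid in frame.residue_ids:
        if rid == probe:
            continue
        names, coords, rname = _residue_atoms(frame, rid)
        if rname not in _STANDARD_RESIDUES:
            raise ValueError(f"unknown residue type {rname!r} at {rid}")

        if "hydrogen_bond" in types:
            def group_atoms(nm, co, table, rn):
                nl = list(nm)
                return [co[nl.index(a)] for a in table.get(rn, []) if a in nl]

            part_pos = group_atoms(names, coords, _POSITIVE_GROUPS, rname)
            part_neg = group_atoms(names, coords, _NEGATIVE_GROUPS, rname)
            probe_pos = group_atoms(p_names, p_coords, _POSITIVE_GROUPS, p_rname)
            probe_neg = group_atoms(p_names, p_coords, _NEGATIVE_GROUPS, p_rname)
            for d, ang in hbond_hits(p_donors, _acceptors(names, coords, rname),
                                     probe_pos, part_neg):
                record("hydrogen_bond", rid, d, angle=ang, donor="probe")
            for d, ang in hbond_hits(_donors(names, coords, rname), p_acceptors,
                                     part_pos, probe_neg):
                record("hydrogen_bond", rid, d, angle=ang, donor="partner")

        if "salt_bridge" in types:
            pos = _group_centroid(names, coords, _POSITIVE_GROUPS.get(rname, []))
            neg = _group_centroid(names, coords, _NEGATIVE_GROUPS.get(rname, []))
            for a, b in ((p_pos, neg), (p_neg, pos)):
                if a is not None and b is not None:
                    d = np.linalg.norm(a - b)
                    if d <= criteria.saltbridge_dist:
                        record("salt_bridge", rid, d)

        if "hydrophobic" in types:
            apolar = [coords[list(names).index(a)]
                      for a in _APOLAR_CARBONS.get(rname, []) if a in list(names)]
            for pa in p_apolar:
                for qa in apolar:
                    d = np.linalg.norm(pa - qa)
                    if d <= criteria.hydrophobic_dist:
                        record("hydrophobic", rid, d)

    return [(kind, partner, geom) for (kind, partner), geom in sorted(found.items())]


def interaction_probability(traj: TrajectorySeries, probe: int,
                            criteria: ContactCriteria | None = None) -> list[InteractionRecord]:
    """Occupancy of each (type, partner) contact over the trajectory frames."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    counts: dict[tuple[str, int], int] = {}
    for frame in traj:
        for kind, partner, _ in detect_contacts(frame, probe, criteria):
            counts[(kind, partner)] = counts.get((kind, partner), 0) + 1
    records = [InteractionRecord(kind, partner, c / traj.n_frames)
               for (kind, partner), c in counts.items()]
    records.sort(key=lambda r: (-r.probability, r.type, r.partner))
    return records


def filter_interactions(records, threshold: float = 0.30) -> list[InteractionRecord]:
    """Keep records with probability strictly greater than ``threshold``,
    ordered by descending probability."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    kept = [r for r in records if r.probability > threshold]
    kept.sort(key=lambda r: (-r.probability, r.type, r.partner))
    return kept
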