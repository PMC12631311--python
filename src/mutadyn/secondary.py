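"""Per-residue secondary-structure assignment and class probabilities.

Assignment uses the DSSP dictionary (Kabsch–Sander hydrogen-bond patterns)
through mdtraj's implementation, and the eight DSSP states are collapsed to
the four classes used throughout the package:

    {H, G, I} → helix,  {E, B} → strand,  {T, S} → turn,  rest → coil

Probabilities are occurrence frequencies over the frames of one or more
(concatenated) trajectories; overall class fractions are also reported per
replica with mean ± standard deviation across replicas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Structure, TrajectorySeries, to_mdtraj

__all__ = ["CLASSES", "DEFAULT_COLLAPSE", "SSAssignment", "SSProbabilityTable",
           "assign_secondary_structure", "ss_probability",
           "kabsch_sander_energy"]

CLASSES = ("helix", "strand", "turn", "coil")

DEFAULT_COLLAPSE = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "turn", "S": "turn",
    " ": "coil", "C": "coil", "": "coil",
}


@dataclass
class SSAssignment:
    """Per-frame, per-residue class labels (one label per residue per frame)."""

    residue_ids: np.ndarray          # (n_res,)
    labels: np.ndarray               # (n_frames, n_res) of CLASSES entries
    dssp_codes: np.ndarray | None = None   # raw 8-state codes, same shape


def _assign(traj_like, collapse) -> SSAssignment:
    import mdtraj as md

    mdt = to_mdtraj(traj_like)
    codes = md.compute_dssp(mdt, simplified=False)
    labels = np.vectorize(lambda c: collapse.get(c, "coil"))(codes)
    res_ids = np.array([r.resSeq for r in mdt.topology.residues])
    return SSAssignment(res_ids, labels, codes)


def assign_secondary_structure(frame: Structure | TrajectorySeries,
                               collapse: dict | None = None) -> SSAssignment:
    """DSSP-assign one structure (or every frame of a trajectory).

    Chains shorter than 3 residues come back all-coil (no H-bond pattern can
    form). Missing backbone atoms raise.
    """
    top = frame.topology if isinstance(frame, TrajectorySeries) else frame
    for rid in top.residue_ids:
        present = set(top.atom_names[top.res_ids == rid])
        missing = {"N", "CA", "C", "O"} - present
        if missing:
            raise ValueError(f"residue {rid} lacks backbone atoms {sorted(missing)}")
    return _assign(frame, collapse or DEFAULT_COLLAPSE)


@dataclass
class SSProbabilityTable:
    """Residue × class probabilities plus replica-level overall fractions."""

    per_residue: pd.DataFrame        # index: residue id; columns: CLASSES
    overall_mean: pd.Series          # class → mean fraction across replicas
    overall_sd: pd.Series            # class → sd across replicas (0 if 1 replica)
    n_frames: int


def ss_probability(trajs, collapse: dict | None = None) -> SSProbabilityTable:
    """Pooled per-residue class probabilities over one or more trajectories.

    Frames are concatenated across replicas for the per-residue table
    (occurrences / total frames); overall class fractions are additionally
    computed per replica and summarized as mean ± sd.
    """
    if isinstance(trajs, (Structure, TrajectorySeries)):
        trajs = [trajs]
    if len(trajs) == 0:
        raise ValueError("at least one trajectory required")

    assignments = [assign_secondary_structure(t, collapse) for t in trajs]
    ref_ids = assignments[0].residue_ids
    for a in assignments[1:]:
        if not np.array_equal(a.residue_ids, ref_ids):
            raise ValueError("replicas have inconsistent residue sets")

    all_labels = np.vstack([a.labels for a in assignments])
    n_frames = len(all_labels)
    table = pd.DataFrame(
        {cls: (all_labels == cls).mean(axis=0) for cls in CLASSES},
        index=pd.Index(ref_ids, name="residue"),
    )

    fractions = pd.DataFrame(
        [{cls: (a.labels == cls).mean() for cls in CLASSES} for a in assignments]
    )
    return SSProbabilityTable(table, fractions.mean(), fractions.std(ddof=1).fillna(0.0),
                              n_frames)


# ---------------------------------------------------------------------------
# Independent Kabsch–Sander energy (used as an oracle; assignment itself is
# delegated to the DSSP backend above)

KS_Q1Q2F = 0.42 * 0.20 * 332.0   # kcal·Å/mol


def kabsch_sander_energy(c, o, n, h) -> float:
    """Kabsch–Sander electrostatic H-bond energy (kcal/mol) for a C=O···H–N
    pair: E = q1 q2 f (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN). Bond if E < −0.5."""
    c, o, n, h = (np.asarray(x, dtype=float) for x in (c, o, n, h))
    d = np.linalg.norm
    return KS_Q1Q2F * (1 / d(o - n) + 1 / d(c - h) - 1 / d(o - h) - 1 / d(c - n))
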