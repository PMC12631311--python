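"""Collective variables: β-sheet content (βRMSD) and probe-to-loop distance.

βRMSD scores every pair of non-overlapping 3-residue backbone segments in a
region against an ideal parallel or antiparallel β-sheet segment-pair
template: the best-fit RMSD r of the 30 backbone atoms (N, CA, CB, C, O per
residue) is passed through the switching function

    S(r) = (1 − (r/r0)^n) / (1 − (r/r0)^m)

and summed over pairs. ``total`` mode is the parallel sum plus the
antiparallel sum. The probe-to-loop distance is the Euclidean distance from
one residue's Cα to the unweighted centroid of a loop's Cα atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CVSeries, SelectionError, Structure, TrajectorySeries, batched_template_rmsd
from .peptides import TEMPLATE_ATOMS, beta_pair_template, ideal_cb

__all__ = ["BetaRmsdConfig", "DistanceConfig", "switching_function",
           "beta_rmsd", "beta_rmsd_pairs", "probe_loop_distance"]


@dataclass
class BetaRmsdConfig:
    """Configuration of the βRMSD collective variable.

    region : inclusive author-numbered residue span, length ≥ 6
    mode : "parallel", "antiparallel" or "total"
    r0_nm, nn, mm : switching-function parameters (r0 in nm, nn < mm)
    strands_cutoff : Å cutoff on the distance between segment-centre Cα
        atoms beyond which a pair is skipped (contributes 0). The default of
        10 Å (1 nm) follows the reference implementation of this CV: segment
        pairs too far apart to form a sheet are not scored, which also makes
        a straight extended chain score ~0. Set to ``None`` to score all
        pairs.
    """

    region: tuple[int, int] = (1532, 1542)
    mode: str = "total"
    r0_nm: float = 0.1
    nn: int = 8
    mm: int = 12
    strands_cutoff: float | None = 10.0

    def __post_init__(self):
        if self.region[1] - self.region[0] + 1 < 6:
            raise ValueError("βRMSD region must span at least 6 residues")
        if self.r0_nm <= 0:
            raise ValueError("r0 must be positive")
        if self.nn >= self.mm:
            raise ValueError("switching exponents require n < m")
        if self.mode not in ("parallel", "antiparallel", "total"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DistanceConfig:
    """Probe residue Cα to loop-region Cα-centroid distance."""

    probe: int = 1611
    loop: tuple[int, int] = (1545, 1550)

    def __post_init__(self):
        if self.loop[0] <= self.probe <= self.loop[1]:
            raise ValueError("probe residue must lie outside the loop region")


def switching_function(r, r0: float, nn: int = 8, mm: int = 12):
    """Rational switching function S(r) with the l'Hôpital limit n/m at r = r0."""
    x = np.asarray(r, dtype=float) / r0
    num = 1.0 - x ** nn
    den = 1.0 - x ** mm
    with np.errstate(invalid="ignore", divide="ignore"):
        s = num / den
    # near x = 1 fall back to the ratio of derivatives, n x^(n-1) / (m x^(m-1))
    near = np.abs(x - 1.0) < 1e-7
    if np.any(near):
        xn = np.where(near, x, 1.0)
        s = np.where(near, (nn * xn ** (nn - 1)) / (mm * xn ** (mm - 1)), s)
    return s if s.shape else float(s)


def _template_atom_indices(top: Structure, residues) -> list:
    """Per residue: list of (atom_index or ('CB', n_idx, ca_idx, c_idx)) in
    template order; glycine Cβ is synthesized at the ideal position."""
    per_res = []
    for rid in residues:
        entry = []
        for name in TEMPLATE_ATOMS:
            idx = np.flatnonzero((top.res_ids == rid) & (top.atom_names == name))
            if len(idx) == 1:
                entry.append(int(idx[0]))
            elif name == "CB":
                entry.append(("CB", top.atom_index(rid, "N"),
                              top.atom_index(rid, "CA"), top.atom_index(rid, "C")))
            else:
                raise SelectionError(f"residue {rid} lacks backbone atom {name}")
        per_res.append(entry)
    return per_res


def _gather_segment_coords(coords: np.ndarray, per_res: list, residues) -> np.ndarray:
    """(n_frames, n_res, 5, 3) template-ordered coordinates with synthetic Gly Cβ."""
    n_frames = coords.shape[0]
    out = np.empty((n_frames, len(per_res), 5, 3))
    for r, entry in enumerate(per_res):
        for k, item in enumerate(entry):
            if isinstance(item, int):
                out[:, r, k] = coords[:, item]
            else:
                _, n_i, ca_i, c_i = item
                for f in range(n_frames):
                    out[f, r, k] = ideal_cb(coords[f, n_i], coords[f, ca_i], coords[f, c_i])
    return out


def _region_residues(top: Structure, region) -> np.ndarray:
    lo, hi = region
    residues = [r for r in top.residue_ids if lo <= r <= hi]
    if len(residues) < 6:
        raise SelectionError(f"region {region} resolves to {len(residues)} residues (< 6)")
    return np.asarray(residues)


def segment_pairs(n_residues: int) -> list[tuple[int, int]]:
    """Start indices (i, j) of non-overlapping 3-residue segment pairs, j ≥ i+3."""
    n_seg = n_residues - 2
    return [(i, j) for i in range(n_seg) for j in range(i + 3, n_seg)]


def beta_rmsd_pairs(traj: TrajectorySeries, cfg: BetaRmsdConfig):
    """Per-pair switching scores.

    Returns ``(pairs, scores)`` where ``pairs`` is the list of (i, j) segment
    start indices and ``scores`` has shape (n_frames, n_pairs) for parallel or
    antiparallel mode, or the per-pair sum of both for total mode.
    """
    top = traj.topology
    residues = _region_residues(top, cfg.region)
    per_res = _template_atom_indices(top, residues)
    seg_coords = _gather_segment_coords(traj.coords, per_res, residues)
    pairs = segment_pairs(len(residues))
    modes = ["parallel", "antiparallel"] if cfg.mode == "total" else [cfg.mode]

    n_frames = traj.n_frames
    scores = np.zeros((n_frames, len(pairs)))
    if not pairs:
        return pairs, scores

    # (n_frames, n_pairs, 30, 3) stacked segment-pair coordinates
    stacked = np.empty((n_frames, len(pairs), 30, 3))
    for p, (i, j) in enumerate(pairs):
        stacked[:, p, :15] = seg_coords[:, i:i + 3].reshape(n_frames, 15, 3)
        stacked[:, p, 15:] = seg_coords[:, j:j + 3].reshape(n_frames, 15, 3)

    keep = np.ones((n_frames, len(pairs)), dtype=bool)
    if cfg.strands_cutoff is not None:
        for p, (i, j) in enumerate(pairs):
            ca_i = seg_coords[:, i + 1, 1]   # centre-residue Cα of each segment
            ca_j = seg_coords[:, j + 1, 1]
            keep[:, p] = np.linalg.norm(ca_i - ca_j, axis=1) <= cfg.strands_cutoff

    flat = stacked.reshape(-1, 30, 3)
    for mode in modes:
        template = beta_pair_template(mode)
        r_A = batched_template_rmsd(flat, template).reshape(n_frames, len(pairs))
        s = switching_function(r_A / 10.0, cfg.r0_nm, cfg.nn, cfg.mm)  # Å → nm
        scores += np.where(keep, s, 0.0)
    return pairs, scores


def beta_rmsd(traj: TrajectorySeries, cfg: BetaRmsdConfig | None = None) -> CVSeries:
    """Total βRMSD content of the configured region, one value per frame."""
    cfg = cfg or BetaRmsdConfig()
    _, scores = beta_rmsd_pairs(traj, cfg)
    return CVSeries(f"beta_rmsd[{cfg.mode}]", "", traj.times.copy(), scores.sum(axis=1))


def probe_loop_distance(traj: TrajectorySeries, cfg: DistanceConfig | None = None) -> CVSeries:
    """Distance (Å) from the probe Cα to the centroid of the loop Cα atoms."""
    cfg = cfg or DistanceConfig()
    top = traj.topology
    probe_idx = top.atom_index(cfg.probe, "CA")
    loop_ids = [r for r in top.residue_ids if cfg.loop[0] <= r <= cfg.loop[1]]
    if not loop_ids:
        raise SelectionError(f"no residues in loop region {cfg.loop}")
    loop_idx = [top.atom_index(r, "CA") for r in loop_ids]
    centroid = traj.coords[:, loop_idx].mean(axis=1)
    d = np.linalg.norm(traj.coords[:, probe_idx] - centroid, axis=1)
    return CVSeries("distance", "A", traj.times.copy(), d)
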