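"""Synthetic ground-truth generators for every pipeline stage.

These generators are statistical stand-ins, not physics: a Markov two-state
(folded β-hairpin vs coil) trajectory whose probe–loop distance co-varies
with state, CD spectra that are noisy linear combinations of basis spectra,
and chromatograms that are Gaussian-peak mixtures placed by a log-linear
calibration. All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cd import BasisSet, CDSpectrum
from .core import CVSeries, Structure, TrajectorySeries
from .peptides import TEMPLATE_ATOMS, beta_pair_template, build_backbone
from .sec import CalibrationCurve, Chromatogram, fit_calibration

__all__ = [
    "TwoStateSpec", "gen_two_state_trajectory", "gen_two_state_cv",
    "gen_cd_spectrum", "gen_chromatogram", "gen_interaction_fixture",
    "synthetic_basis_set", "synthetic_calibration", "synthetic_standards",
    "SYNTHETIC_VPS9_LIKE_SEQUENCE",
]

# Synthetic stand-in for the 145-residue guanine-exchange-domain construct
# (author numbering 1513-1657). This sequence is NOT the natural protein: it
# is a randomly composed globular-like sequence, fixed here so that the
# construct-editing machinery (numbering, point substitutions such as
# C1551S/C1558S/C1647S, mass computation) can be exercised offline. Positions
# 1551/1558/1647 carry Cys and 1611 Arg / 1607 Tyr so the documented edits
# apply cleanly.
SYNTHETIC_VPS9_LIKE_SEQUENCE = (
    "LAGKSGAMEAPSKYNEDSVYDESQRAIRFSVLRKYFPKCSLVAEYCVLLDVLSGPLCVNDGDLHTPQEDATVYMPSEQMK"
    "DEYYIGMGIKKQPGYLVERDNIKLAADLPEGCGDTIRTALWSEDISADGFTHYQCAEVRREALLL"
)
SYNTHETIC_FIRST_RES_ID = 1513

PURIFICATION_TAG = "MGSSHHHHHHSSGLVPRGSHM"   # His-tag + thrombin site


@dataclass
class TwoStateSpec:
    """Specification of the two-state synthetic trajectory.

    The defaults mirror the study conditions the package analyses: a 200 ns
    span sampled every 0.4 ns (500 frames), folded occupancy 0.6, and basin
    distances of ~12 Å (folded, probe close to the loop) vs ~17.5 Å
    (unfolded). ``switch_rate`` sets the per-frame Markov relaxation
    (dwell times of a few ns, well below the 10 ns analysis windows).
    """

    region: tuple[int, int] = (1532, 1542)
    probe: int = 1611
    loop: tuple[int, int] = (1545, 1550)
    p_folded: float = 0.6
    switch_rate: float = 0.5
    noise_sigma: float = 0.25          # isotropic coordinate noise, Å
    distance_sd: float = 0.6           # in-basin spread of the probe distance, Å
    folded_distance: float = 12.0
    unfolded_distance: float = 17.5
    n_frames: int = 500
    dt_ns: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_folded < 1.0:
            raise ValueError("p_folded must lie strictly between 0 and 1")
        if not 0.0 < self.switch_rate <= 1.0:
            raise ValueError("switch_rate must lie in (0, 1]")
        if self.noise_sigma < 0 or self.distance_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.region[1] - self.region[0] + 1 < 6:
            raise ValueError("region must span at least 6 residues")
        if self.loop[0] <= self.probe <= self.loop[1]:
            raise ValueError("probe must lie outside the loop")
        if self.n_frames < 2 or self.dt_ns <= 0:
            raise ValueError("need at least 2 frames with positive spacing")


def _markov_states(spec: TwoStateSpec, rng) -> np.ndarray:
    """Boolean state series (True = folded) from the stationary two-state chain."""
    a = spec.switch_rate * (1.0 - spec.p_folded)   # P(folded → unfolded)
    b = spec.switch_rate * spec.p_folded           # P(unfolded → folded)
    states = np.empty(spec.n_frames, dtype=bool)
    states[0] = rng.random() < spec.p_folded
    u = rng.random(spec.n_frames - 1)
    for i in range(1, spec.n_frames):
        flip = u[i - 1] < (a if states[i - 1] else b)
        states[i] = states[i - 1] ^ flip
    return states


def _template_hairpin(region_ids) -> dict[int, np.ndarray]:
    """Folded-region coordinates: terminal 3-residue strands exactly at the
    ideal antiparallel template, turn residues on a connecting arc."""
    template = beta_pair_template("antiparallel")
    n = len(region_ids)
    coords: dict[int, np.ndarray] = {}
    for k in range(3):
        coords[region_ids[k]] = template[5 * k:5 * k + 5]
        coords[region_ids[n - 3 + k]] = template[15 + 5 * k:20 + 5 * k]
    # arc from C of strand-A end to N of strand-B start, bulging out of plane
    start = template[5 * 2 + 3]        # C of a3
    end = template[15]                 # N of b1
    normal = np.cross(template[6] - template[1], template[21] - template[1])
    normal /= np.linalg.norm(normal)
    n_turn = n - 6
    for k in range(n_turn):
        t = (k + 1) / (n_turn + 1)
        bulge = 4.5 * np.sin(np.pi * t)
        ca = start + t * (end - start) + bulge * normal
        along = (end - start) / np.linalg.norm(end - start)
        res = np.stack([
            ca - 1.2 * along,                      # N
            ca,                                    # CA
            ca + 1.0 * normal + 0.8 * np.cross(normal, along),  # CB
            ca + 1.2 * along,                      # C
            ca + 1.2 * along + 1.23 * normal,      # O
        ])
        coords[region_ids[3 + k]] = res
    return coords


def _coil_region(region_ids, rng) -> dict[int, np.ndarray]:
    """A fresh coil conformation of the region (broad torsion distribution)."""
    n = len(region_ids)
    phi = rng.uniform(-160.0, -50.0, size=n)
    psi = rng.uniform(-180.0, 180.0, size=n)
    chain = build_backbone(["ALA"] * n, phi, psi)
    out = {}
    for k, rid in enumerate(region_ids):
        out[rid] = np.stack([
            chain.coords[chain.atom_index(k + 1, nm)] for nm in TEMPLATE_ATOMS
        ])
    return out


def _assemble_topology(spec: TwoStateSpec) -> tuple[Structure, dict]:
    """Topology: region (chain A), loop (chain B), probe (chain C); every
    residue is ALA carrying N, CA, CB, C, O."""
    region_ids = list(range(spec.region[0], spec.region[1] + 1))
    loop_ids = list(range(spec.loop[0], spec.loop[1] + 1))
    names, elements, rids, rnames, chains, coords = [], [], [], [], [], []

    def add_residue(rid, cid, xyz):
        for nm, pos in zip(TEMPLATE_ATOMS, xyz):
            names.append(nm)
            elements.append(nm[0])
            rids.append(rid)
            rnames.append("ALA")
            chains.append(cid)
            coords.append(pos)

    placeholder = np.zeros((5, 3))
    for rid in region_ids:
        add_residue(rid, "A", placeholder)
    for rid in loop_ids:
        add_residue(rid, "B", placeholder)
    add_residue(spec.probe, "C", placeholder)
    top = Structure(names, elements, rids, rnames, chains, np.array(coords))
    layout = {"region_ids": region_ids, "loop_ids": loop_ids}
    return top, layout


def gen_two_state_trajectory(spec: TwoStateSpec | None = None):
    """Two-state coordinate trajectory with per-frame ground-truth labels.

    Folded frames place the region's terminal strands exactly on the ideal
    antiparallel pair template (βRMSD pair score 1 before noise) and the
    probe Cα ~``folded_distance`` from the loop Cα centroid; unfolded frames
    draw a fresh coil conformation and put the probe at
    ``unfolded_distance``. Returns ``(TrajectorySeries, labels)`` with
    labels True for folded frames.
    """
    spec = spec or TwoStateSpec()
    rng = np.random.default_rng(spec.seed)
    top, layout = _assemble_topology(spec)
    region_ids, loop_ids = layout["region_ids"], layout["loop_ids"]

    # fixed loop: an extended strand placed away from the region
    loop_chain = build_backbone(["ALA"] * len(loop_ids), -139.0, 135.0)
    loop_xyz = {}
    offset = np.array([40.0, 0.0, 0.0])
    for k, rid in enumerate(loop_ids):
        loop_xyz[rid] = np.stack([
            loop_chain.coords[loop_chain.atom_index(k + 1, nm)] for nm in TEMPLATE_ATOMS
        ]) + offset
    loop_ca = np.mean([loop_xyz[r][1] for r in loop_ids], axis=0)
    probe_dir = np.array([0.0, 0.0, 1.0])
    probe_local = build_backbone(["ALA"], -139.0, 135.0)
    probe_xyz0 = np.stack([
        probe_local.coords[probe_local.atom_index(1, nm)] for nm in TEMPLATE_ATOMS
    ])
    probe_xyz0 -= probe_xyz0[1]        # centre on CA

    folded_region = _template_hairpin(region_ids)
    states = _markov_states(spec, rng)
    frames = np.empty((spec.n_frames, top.n_atoms, 3))
    for f in range(spec.n_frames):
        region = folded_region if states[f] else _coil_region(region_ids, rng)
        d = (spec.folded_distance if states[f] else spec.unfolded_distance)
        d += spec.distance_sd * rng.standard_normal()
        probe_ca = loop_ca + probe_dir * d
        xyz = []
        for rid in region_ids:
            xyz.append(region[rid])
        for rid in loop_ids:
            xyz.append(loop_xyz[rid])
        xyz.append(probe_xyz0 + probe_ca)
        frames[f] = np.vstack(xyz)
    if spec.noise_sigma > 0:
        frames += spec.noise_sigma * rng.standard_normal(frames.shape)
    times = np.arange(spec.n_frames) * spec.dt_ns
    return TrajectorySeries(top, frames, times), states


def gen_two_state_cv(spec: TwoStateSpec | None = None,
                     beta_folded: float = 1.0, beta_unfolded: float = 0.08,
                     beta_sd: float = 0.12):
    """Two-state collective-variable series without building coordinates.

    Emits (βRMSD series, distance series, labels) from the same Markov chain
    as :func:`gen_two_state_trajectory`, with Gaussian in-basin spread; βRMSD
    values are clipped at 0. Used where many replicas/seeds are needed.
    """
    spec = spec or TwoStateSpec()
    rng = np.random.default_rng(spec.seed)
    states = _markov_states(spec, rng)
    beta_mu = np.where(states, beta_folded, beta_unfolded)
    dist_mu = np.where(states, spec.folded_distance, spec.unfolded_distance)
    beta = np.clip(beta_mu + beta_sd * rng.standard_normal(spec.n_frames), 0.0, None)
    dist = dist_mu + spec.distance_sd * rng.standard_normal(spec.n_frames)
    times = np.arange(spec.n_frames) * spec.dt_ns
    return (CVSeries("beta_rmsd[total]", "", times, beta),
            CVSeries("distance", "A", times, dist), states)


# ---------------------------------------------------------------------------
# CD


def synthetic_basis_set(name: str = "synthetic-3",
                        wavelengths=None) -> BasisSet:
    """Small synthetic CD basis sets (MRE units) for tests and examples.

    ``synthetic-3`` has one component per reporting class; ``synthetic-6``
    splits helix and strand into sub-classes with a grouping map. Shapes are
    Gaussian caricatures of far-UV class spectra (helix: 208/222 nm double
    minimum; strand: single ~217 nm minimum; coil: deep minimum near 200 nm).
    """
    wl = np.arange(200.0, 250.5, 0.5) if wavelengths is None else np.asarray(wavelengths)

    def g(center, width, amp):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    helix = g(193, 6, 60e3) + g(208, 6, -30e3) + g(222, 7, -33e3)
    strand = g(200, 7, 30e3) + g(218, 8, -15e3)
    coil = g(198, 7, -40e3) + g(225, 20, 4e3)
    if name == "synthetic-3":
        comps = {"helix": helix, "strand": strand, "coil": coil}
        grouping = {k: k for k in comps}
    elif name == "synthetic-6":
        comps = {
            "helix-regular": g(193, 6.2, 57e3) + g(208, 6.3, -29e3) + g(222, 7.4, -31e3),
            "helix-distorted": g(206, 7, -24e3) + g(221, 8, -22e3) + g(195, 5, 40e3),
            "strand-anti": g(201, 7.2, 28e3) + g(218, 8.4, -14e3),
            "strand-para": g(214, 8, -12e3) + g(201, 6, 24e3),
            "turn": g(205, 10, -8e3) + g(228, 8, 4e3),
            "coil": g(198, 7.4, -38e3) + g(226, 19, 3.6e3),
        }
        grouping = {
            "helix-regular": "helix", "helix-distorted": "helix",
            "strand-anti": "strand", "strand-para": "strand",
            "turn": "coil", "coil": "coil",
        }
    else:
        raise ValueError(f"unknown synthetic basis set {name!r}")
    return BasisSet(name, wl, comps, grouping)


def gen_cd_spectrum(fractions, basis: BasisSet, noise_sigma: float = 0.0,
                    seed: int = 0, label: str = "synthetic") -> CDSpectrum:
    """Noisy linear combination of basis spectra with known fractions."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    vals = basis.combine(fractions)
    if noise_sigma > 0:
        vals = vals + noise_sigma * rng.standard_normal(vals.shape)
    return CDSpectrum(basis.wavelengths.copy(), vals, unit="MRE", label=label)


# ---------------------------------------------------------------------------
# SEC


def synthetic_standards(slope: float = -0.25, intercept: float = 5.156,
                        volumes=(10.0, 11.5, 13.0, 14.5, 16.0, 17.5)):
    """Calibration standards lying exactly on a log-linear line."""
    return [(10.0 ** (slope * v + intercept), v) for v in volumes]


def synthetic_calibration(**kw) -> CalibrationCurve:
    return fit_calibration(synthetic_standards(**kw))


def gen_chromatogram(species, cal: CalibrationCurve, peak_sigma_ml: float = 0.25,
                     noise: float = 0.0, seed: int = 0,
                     volume_range=(8.0, 24.0), dv: float = 0.02) -> Chromatogram:
    """Gaussian-mixture chromatogram with peaks placed by the calibration.

    ``species`` is a list of (MW kDa, amount); peak centres are the
    calibration-inverted elution volumes, heights proportional to amounts.
    """
    species = [(float(m), float(a)) for m, a in species]
    if not species or any(m <= 0 or a < 0 for m, a in species):
        raise ValueError("species must have positive MW and nonnegative amount")
    lo, hi = cal.volume_range
    margin = 0.5 * (hi - lo)
    for m, _ in species:
        v = cal.volume_for_mw(m)
        if not (lo - margin) <= v <= (hi + margin):
            raise ValueError(f"species of {m} kDa elutes far outside calibration")
    rng = np.random.default_rng(seed)
    v = np.arange(*volume_range, dv)
    y = np.zeros_like(v)
    for mw, amount in species:
        centre = cal.volume_for_mw(mw)
        y += amount * np.exp(-0.5 * ((v - centre) / peak_sigma_ml) ** 2)
    if noise > 0:
        y = y + noise * rng.standard_normal(y.shape)
    return Chromatogram(v, y, flow_rate_ml_min=0.5, label="synthetic")


# ---------------------------------------------------------------------------
# Interaction fixtures


def _single_residue(res_name: str, atoms: dict[str, np.ndarray], rid: int,
                    chain: str) -> Structure:
    names = list(atoms)
    coords = np.array([atoms[n] for n in names])
    elements = [("H" if n.startswith("H") else n[0]) for n in names]
    return Structure(names, elements, [rid] * len(names), [res_name] * len(names),
                     [chain] * len(names), coords)


def _merge(a: Structure, b: Structure) -> Structure:
    return Structure(
        np.concatenate([a.atom_names, b.atom_names]),
        np.concatenate([a.elements, b.elements]),
        np.concatenate([a.res_ids, b.res_ids]),
        np.concatenate([a.res_names, b.res_names]),
        np.concatenate([a.chain_ids, b.chain_ids]),
        np.vstack([a.coords, b.coords]),
    )


def gen_interaction_fixture(kind: str, distance: float = 3.0,
                            angle: float = 160.0) -> Structure:
    """Minimal two-residue structure realizing exactly one requested contact.

    ``kind`` ∈ {hydrogen_bond, salt_bridge, hydrophobic, none}; ``distance``
    is the criterion distance (donor–acceptor, centroid–centroid, or
    carbon–carbon); ``angle`` the D–H···A angle for hydrogen bonds. The probe
    is residue 1; atoms not involved in the requested contact are kept beyond
    every cutoff.
    """
    far = np.array([0.0, 0.0, 12.0])
    if kind == "none":
        a = _single_residue("ALA", {
            "N": np.array([0.0, 0.0, 0.0]), "CA": np.array([1.46, 0.0, 0.0]),
            "CB": np.array([1.9, -1.4, 0.0]), "C": np.array([2.0, 1.4, 0.0]),
            "O": np.array([3.2, 1.5, 0.0])}, 1, "A")
        b = _single_residue("ALA", {
            "N": far, "CA": far + [1.46, 0, 0], "CB": far + [1.9, -1.4, 0],
            "C": far + [2.0, 1.4, 0], "O": far + [3.2, 1.5, 0]}, 2, "B")
        return _merge(a, b)

    if kind == "hydrogen_bond":
        if distance < 1.2:
            raise ValueError("unrealizable donor–acceptor distance")
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.01, 0.0, 0.0])
        # place the acceptor in the xy-plane at the requested N···A distance
        # and D-H-A angle (law of cosines for the H···A leg)
        th = np.radians(180.0 - angle)      # angle of HA leg vs +x at H
        ha = 1.01 * np.cos(np.radians(angle)) + np.sqrt(
            distance ** 2 - (1.01 * np.sin(np.radians(angle))) ** 2)
        acc = h + ha * np.array([np.cos(th), np.sin(th), 0.0])
        if abs(np.linalg.norm(acc - n) - distance) > 1e-6:
            raise ValueError("unrealizable hydrogen-bond geometry")
        a = _single_residue("ALA", {
            "N": n, "H": h, "CA": n + [-0.8, -1.2, 0.0],
            "CB": n + [-0.5, -2.6, 0.4], "C": n + [-2.3, -1.2, 0.0],
            "O": n + [-2.9, -2.3, 0.0]}, 1, "A")
        c_pos = acc + np.array([1.23, 0.6, 0.0])
        b = _single_residue("ALA", {
            "O": acc, "C": c_pos, "CA": c_pos + [1.5, 0.4, 0.0],
            "CB": c_pos + [1.9, 1.2, 1.1], "N": c_pos + [2.1, -0.8, 0.0]}, 2, "B")
        return _merge(a, b)

    if kind == "salt_bridge":
        if distance < 2.0:
            raise ValueError("unrealizable centroid distance")
        nz = np.array([0.0, 0.0, 0.0])
        a = _single_residue("LYS", {
            "N": nz + [-6.0, 0.5, 0.0], "CA": nz + [-5.0, -0.5, 0.0],
            "CB": nz + [-3.8, 0.3, 0.3], "CG": nz + [-2.6, -0.5, 0.3],
            "CD": nz + [-1.4, 0.3, 0.15], "CE": nz + [-0.9, 0.9, -0.4],
            "NZ": nz, "C": nz + [-5.2, -1.9, 0.4], "O": nz + [-5.9, -2.4, 1.3]},
            1, "A")
        centroid = nz + np.array([distance, 0.0, 0.0])
        od1 = centroid + np.array([0.0, 1.1, 0.0])
        od2 = centroid - np.array([0.0, 1.1, 0.0])
        cg = centroid + np.array([0.75, 0.0, 0.0])
        b = _single_residue("ASP", {
            "OD1": od1, "OD2": od2, "CG": cg, "CB": cg + [1.3, 0.0, 0.8],
            "CA": cg + [2.4, 0.0, 1.7], "N": cg + [3.5, 0.9, 1.4],
            "C": cg + [2.9, -1.4, 2.1], "O": cg + [2.4, -2.4, 1.7]}, 2, "B")
        return _merge(a, b)

    if kind == "hydrophobic":
        if distance < 1.5:
            raise ValueError("unrealizable carbon–carbon distance")
        cb1 = np.array([0.0, 0.0, 0.0])
        a = _single_residue("ALA", {
            "CB": cb1, "CA": cb1 + [0.0, 1.5, 0.0], "N": cb1 + [-1.2, 2.3, 0.0],
            "C": cb1 + [1.2, 2.4, 0.0], "O": cb1 + [1.1, 3.6, 0.2]}, 1, "A")
        cb2 = cb1 + np.array([distance, 0.0, 0.0])
        b = _single_residue("ALA", {
            "CB": cb2, "CA": cb2 + [0.0, -1.5, 0.0], "N": cb2 + [1.2, -2.3, 0.0],
            "C": cb2 + [-1.2, -2.4, 0.0], "O": cb2 + [-1.1, -3.6, -0.2]}, 2, "B")
        return _merge(a, b)

    raise ValueError(f"unknown fixture kind {kind!r}")
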