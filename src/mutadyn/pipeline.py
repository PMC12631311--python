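"""Configured end-to-end analysis: trajectory characterization (collective
variables, secondary structure, interaction fingerprints, free-energy
surfaces), CD deconvolution and SEC oligomer analysis, for one or two
labelled conditions (e.g. wild type vs mutant).

Every enabled stage writes tidy TSV tables under the output directory; a
JSON summary juxtaposes conditions, and a manifest records the configuration
and input checksums for provenance. Any stage failure aborts the run with
the stage name and cause; outputs written so far are kept next to a FAILED
marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cd as cdmod
from . import fileio
from .core import TrajectorySeries, read_pdb
from .cv import BetaRmsdConfig, DistanceConfig, beta_rmsd, probe_loop_distance
from .fes import basin_delta_g, block_histograms, project_1d, surface
from .interactions import filter_interactions, interaction_probability
from .sec import apparent_mw, detect_peaks, fit_calibration, oligomer_order
from .secondary import ss_probability

__all__ = ["AnalysisConfig", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("cv", "ss", "interactions", "fes", "cd", "sec")


@dataclass
class AnalysisConfig:
    """Inputs and parameters of a full analysis run.

    ``trajectories``, ``cd_spectra`` and ``chromatograms`` map condition
    labels (e.g. "wt", "mutant") to inputs; stages run for whichever inputs
    are present. Paths are accepted everywhere in-memory objects are.
    """

    output_dir: str = "mutadyn-report"
    seed: int = 0
    temperature: float = 298.15

    trajectories: dict = field(default_factory=dict)
    beta_region: tuple[int, int] = (1532, 1542)
    probe: int = 1611
    loop: tuple[int, int] = (1545, 1550)
    discard_ns: float = 50.0
    window_ns: float = 10.0
    bins: int = 50
    interaction_threshold: float = 0.30
    basin_split: float | None = None      # distance (Å) separating basins

    cd_spectra: dict = field(default_factory=dict)   # label → list of spectra
    cd_baseline: object = None
    basis_sets: list = field(default_factory=list)   # BasisSet or directory
    sg_order: int = 3
    sg_window: int = 9

    chromatograms: dict = field(default_factory=dict)
    standards: object = None                         # list or path
    monomer_mw_kda: float | None = None

    stages: tuple = ()                               # empty = infer from inputs

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for attr in ("beta_region", "loop"):
            setattr(cfg, attr, tuple(getattr(cfg, attr)))
        return cfg

    def enabled_stages(self) -> list[str]:
        if self.stages:
            unknown = set(self.stages) - set(STAGES)
            if unknown:
                raise ValueError(f"unknown stages {sorted(unknown)}")
            return list(self.stages)
        out = []
        if self.trajectories:
            out += ["cv", "ss", "interactions", "fes"]
        if self.cd_spectra:
            out.append("cd")
        if self.chromatograms:
            out.append("sec")
        return out

    def validate(self) -> None:
        if not self.enabled_stages():
            raise ValueError("no analysis stage enabled: provide trajectories, "
                             "CD spectra or chromatograms")
        if self.window_ns <= 0 or self.discard_ns < 0:
            raise ValueError("window/discard lengths must be sensible")
        if not 0 <= self.interaction_threshold <= 1:
            raise ValueError("interaction threshold must lie in [0, 1]")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_traj(obj) -> TrajectorySeries:
    if isinstance(obj, TrajectorySeries):
        return obj
    traj = read_pdb(obj)
    if not isinstance(traj, TrajectorySeries):
        raise ValueError(f"{obj} holds a single model, not a trajectory")
    return traj


def _load_spectra(objs):
    return [s if isinstance(s, cdmod.CDSpectrum) else fileio.read_spectrum(s)
            for s in objs]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every enabled stage and return the JSON-ready report dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _serializable(config), "stages": {}}
    manifest = {"inputs": {}, "outputs": []}
    for label, t in {**config.trajectories, **config.cd_spectra,
                     **config.chromatograms}.items():
        for item in (t if isinstance(t, (list, tuple)) else [t]):
            if isinstance(item, (str, Path)) and Path(item).exists():
                manifest["inputs"][str(item)] = _checksum(item)

    stage = None
    try:
        for stage in config.enabled_stages():
            log.info("stage %s", stage)
            runner = globals()[f"_stage_{stage}"]
            report["stages"][stage] = runner(config, out, manifest)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(report, indent=2, default=_jsonify))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _serializable(config: AnalysisConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, dict):
            d[k] = {kk: str(vv) for kk, vv in v.items()}
        elif not isinstance(v, (int, float, str, list, tuple, type(None))):
            d[k] = str(v)
    return d


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _write(manifest, path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["outputs"].append(str(path))


# --------------------------------------------------------------------- stages


def _stage_cv(config, out, manifest):
    res = {}
    for label, traj in config.trajectories.items():
        traj = _load_traj(traj)
        beta = beta_rmsd(traj, BetaRmsdConfig(region=config.beta_region))
        dist = probe_loop_distance(traj, DistanceConfig(config.probe, config.loop))
        _write(manifest, out / f"cv_{label}.tsv", pd.DataFrame({
            "frame": np.arange(traj.n_frames), "time_ns": traj.times,
            "beta_rmsd": beta.values, "distance_A": dist.values}))
        res[label] = {"beta_rmsd_mean": float(beta.values.mean()),
                      "distance_mean_A": float(dist.values.mean())}
    return res


def _stage_ss(config, out, manifest):
    res = {}
    for label, traj in config.trajectories.items():
        table = ss_probability(_load_traj(traj))
        df = table.per_residue.reset_index()
        _write(manifest, out / f"ss_{label}.tsv", df)
        res[label] = {
            "overall_mean": {k: float(v) for k, v in table.overall_mean.items()},
            "overall_sd": {k: float(v) for k, v in table.overall_sd.items()},
        }
    return res


def _stage_interactions(config, out, manifest):
    res = {}
    for label, traj in config.trajectories.items():
        records = interaction_probability(_load_traj(traj), config.probe)
        kept = filter_interactions(records, config.interaction_threshold)
        df = pd.DataFrame([{
            "Type": r.type.replace("_", " ").capitalize(),
            "Residue": r.partner,
            "Probability (%)": round(100.0 * r.probability),
        } for r in kept], columns=["Type", "Residue", "Probability (%)"])
        _write(manifest, out / f"interactions_{label}.tsv", df)
        res[label] = [{"type": r.type, "partner": r.partner,
                       "probability": r.probability} for r in kept]
    return res


def _stage_fes(config, out, manifest):
    res = {}
    for label, traj in config.trajectories.items():
        traj = _load_traj(traj)
        beta = beta_rmsd(traj, BetaRmsdConfig(region=config.beta_region))
        dist = probe_loop_distance(traj, DistanceConfig(config.probe, config.loop))
        stack = block_histograms(beta, dist, config.discard_ns, config.window_ns,
                                 config.bins)
        fes2d = surface(stack, config.temperature)
        c1, c2 = np.meshgrid(stack.centers1, stack.centers2, indexing="ij")
        _write(manifest, out / f"fes_{label}.tsv", pd.DataFrame({
            "beta_rmsd": c1.ravel(), "distance_A": c2.ravel(),
            "F_kJ_mol": fes2d.free_energy.ravel(),
            "error_kJ_mol": fes2d.error.ravel()}))
        entry = {}
        for axis, name in (("cv1", "beta_rmsd"), ("cv2", "distance")):
            prof = project_1d(stack, axis, config.temperature)
            _write(manifest, out / f"fes1d_{name}_{label}.tsv", pd.DataFrame({
                name: prof.centers, "F_kJ_mol": prof.free_energy,
                "error_kJ_mol": prof.error}))
        if config.basin_split is not None:
            dg, err, ci = basin_delta_g(stack, "cv2", config.basin_split,
                                        config.temperature)
            entry.update({"basin_delta_g_kJ_mol": dg, "error_kJ_mol": err,
                          "ci95_kJ_mol": ci})
        res[label] = entry
    return res


def _stage_cd(config, out, manifest):
    if config.basis_sets and isinstance(config.basis_sets, (str, Path)):
        candidates = fileio.read_basis_dir(config.basis_sets)
    elif config.basis_sets:
        candidates = list(config.basis_sets)
    else:
        from .synthetic import synthetic_basis_set
        candidates = [synthetic_basis_set()]
    baseline = (None if config.cd_baseline is None
                else _load_spectra([config.cd_baseline])[0])
    res = {}
    for label, spectra in config.cd_spectra.items():
        spectra = _load_spectra(spectra if isinstance(spectra, (list, tuple))
                                else [spectra])
        spectra = [cdmod.to_mre(s) if s.unit == "mdeg" else s for s in spectra]
        avg = cdmod.average_and_correct(spectra, baseline)
        smoothed = cdmod.smooth(avg, config.sg_order, config.sg_window)
        best, table = cdmod.select_basis(smoothed, candidates)
        fit = cdmod.deconvolve(smoothed, best)
        grouped = cdmod.group_classes(fit.fractions, best)
        fileio.write_spectrum(out / f"cd_{label}.tsv", smoothed)
        manifest["outputs"].append(str(out / f"cd_{label}.tsv"))
        res[label] = {"basis": best.name, "rmsd_kmre": fit.rmsd_kmre,
                      "fractions": grouped,
                      "candidate_rmsd": {n: r / 1000.0 for n, r in table}}
    _write(manifest, out / "cd_fractions.tsv", pd.DataFrame([
        {"condition": lbl, **{k: round(v, 4) for k, v in r["fractions"].items()}}
        for lbl, r in res.items()]))
    return res


def _stage_sec(config, out, manifest):
    if config.standards is None:
        raise ValueError("SEC stage requires calibration standards")
    standards = (fileio.read_standards(config.standards)
                 if isinstance(config.standards, (str, Path)) else config.standards)
    cal = fit_calibration(standards)
    res = {"calibration": {"slope": cal.slope, "intercept": cal.intercept}}
    rows = []
    for label, chrom in config.chromatograms.items():
        if not hasattr(chrom, "volume_ml"):
            chrom = fileio.read_chromatogram(chrom)
        for volume, height, kind in detect_peaks(chrom):
            mw, extrapolated = apparent_mw(volume, cal)
            entry = {"condition": label, "volume_mL": round(volume, 2),
                     "height_mAU": round(height, 2), "kind": kind,
                     "mw_app_kDa": round(mw, 1), "extrapolated": extrapolated}
            if config.monomer_mw_kda:
                ratio, order = oligomer_order(mw, config.monomer_mw_kda)
                entry.update({"ratio": round(ratio, 2), "order": order})
            rows.append(entry)
    _write(manifest, out / "sec_peaks.tsv", pd.DataFrame(rows))
    res["peaks"] = rows
    return res
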