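"""Plain-text readers/writers for spectra, chromatograms, standards and CV
tables. All tabular formats are 2+ column TSV/CSV with a header line; CD
spectra may carry a small YAML sidecar (same path + ``.yaml``) holding path
length, concentration, mean residue weight and units.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cd import BasisSet, CDSpectrum
from .core import CVSeries
from .sec import Chromatogram

__all__ = ["read_table", "read_spectrum", "write_spectrum",
           "read_chromatogram", "write_chromatogram", "read_standards",
           "read_cv_table", "write_cv_table", "read_basis_dir", "write_basis"]


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    return pd.read_csv(path, sep=sep, comment="#")


def read_spectrum(path, **overrides) -> CDSpectrum:
    """Read a 2-column (wavelength_nm, value) spectrum; metadata from a
    ``<path>.yaml`` sidecar when present, overridable by keyword."""
    df = read_table(path)
    meta = {}
    sidecar = Path(str(path) + ".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    meta.update(overrides)
    return CDSpectrum(
        df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
        unit=meta.get("unit", "mdeg"),
        path_length_cm=meta.get("path_length_cm"),
        concentration_mg_ml=meta.get("concentration_mg_ml"),
        mw_kda=meta.get("mw_kda"),
        label=meta.get("label", Path(path).stem),
    )


def write_spectrum(path, spectrum: CDSpectrum) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  spectrum.unit: spectrum.values}).to_csv(path, sep="\t", index=False)
    meta = {"unit": spectrum.unit, "label": spectrum.label}
    for k in ("path_length_cm", "concentration_mg_ml", "mw_kda"):
        v = getattr(spectrum, k)
        if v is not None:
            meta[k] = float(v)
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta))


def read_chromatogram(path, **kw) -> Chromatogram:
    df = read_table(path)
    return Chromatogram(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), **kw)


def write_chromatogram(path, chrom: Chromatogram) -> None:
    pd.DataFrame({"volume_mL": chrom.volume_ml,
                  "absorbance_mAU": chrom.absorbance_mau}).to_csv(path, sep="\t", index=False)


def read_standards(path):
    """Standards table with columns (name, MW_kDa, Ve_mL) or (MW_kDa, Ve_mL)."""
    df = read_table(path)
    cols = [c.lower() for c in df.columns]
    mw_col = next(i for i, c in enumerate(cols) if "mw" in c or "kda" in c)
    ve_col = next(i for i, c in enumerate(cols) if "ve" in c or "volume" in c or "ml" in c)
    return list(zip(df.iloc[:, mw_col].astype(float), df.iloc[:, ve_col].astype(float)))


def read_cv_table(path) -> dict[str, CVSeries]:
    """Tidy CV table (time_ns + one column per CV) → named series."""
    df = read_table(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    return {c: CVSeries(c, "", t, df[c].to_numpy(dtype=float)) for c in df.columns[1:]}


def write_cv_table(path, times, **series) -> None:
    pd.DataFrame({"time_ns": times, **series}).to_csv(path, sep="\t", index=False,
                                                      float_format="%.6g")


def read_basis_dir(directory) -> list[BasisSet]:
    """Load every basis set in a directory.

    Each ``*.tsv`` holds a wavelength column plus one column per class; an
    optional ``<stem>.grouping.yaml`` maps classes to helix/strand/coil
    (identity mapping assumed otherwise for those three names).
    """
    out = []
    for path in sorted(Path(directory).glob("*.tsv")):
        df = read_table(path)
        wl = df.iloc[:, 0].to_numpy(dtype=float)
        comps = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
        gpath = path.with_suffix("").with_suffix(".grouping.yaml")
        if gpath.exists():
            grouping = yaml.safe_load(gpath.read_text())
        else:
            grouping = {c: c for c in comps}
        out.append(BasisSet(path.stem, wl, comps, grouping))
    if not out:
        raise FileNotFoundError(f"no basis-set tables in {directory}")
    return out


def write_basis(directory, basis: BasisSet) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"wavelength_nm": basis.wavelengths,
                       **{c: basis.components[c] for c in basis.classes}})
    df.to_csv(directory / f"{basis.name}.tsv", sep="\t", index=False)
    (directory / f"{basis.name}.grouping.yaml").write_text(
        yaml.safe_dump(basis.grouping))
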