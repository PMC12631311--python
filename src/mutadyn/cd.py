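"""Far-UV circular-dichroism post-processing and basis-set deconvolution.

Raw ellipticity in millidegrees is converted to mean residue ellipticity

    [θ] = mdeg · Mw / (10 · L · C)

with Mw the mean residue (or molar) weight in kDa, L the cuvette path length
in cm and C the concentration in mg/mL. Replicate spectra are baseline
corrected and averaged, smoothed with a Savitzky–Golay filter (default order
3, window 9), and deconvolved against a basis set of per-class reference
spectra: nonnegative fractions summing to one are fitted jointly with a
single positive scale factor on the experimental spectrum, minimizing the
RMSD between scaled spectrum and predicted combination. Among several
candidate basis sets, the one with the lowest post-scaling RMSD wins, and
the fitted class fractions are grouped to three classes
(helix / strand / coil).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CDSpectrum", "BasisSet", "DeconvolutionResult", "to_mre",
           "average_and_correct", "smooth", "deconvolve", "select_basis",
           "group_classes"]

log = logging.getLogger(__name__)


@dataclass
class CDSpectrum:
    """A far-UV CD spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str = "mdeg"               # "mdeg" | "MRE"
    path_length_cm: float | None = None
    concentration_mg_ml: float | None = None
    mw_kda: float | None = None
    label: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelength and value arrays must align")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class BasisSet:
    """Named per-class basis spectra on a shared wavelength grid.

    ``grouping`` maps every basis class to one of the three reporting classes
    (helix / strand / coil).
    """

    name: str
    wavelengths: np.ndarray
    components: dict[str, np.ndarray]
    grouping: dict[str, str]

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for cls, spec in self.components.items():
            if np.asarray(spec).shape != self.wavelengths.shape:
                raise ValueError(f"basis component {cls!r} is off-grid")
        missing = set(self.components) - set(self.grouping)
        if missing:
            raise ValueError(f"grouping map misses classes {sorted(missing)}")

    @property
    def classes(self) -> list[str]:
        return list(self.components)

    def matrix(self, wavelengths=None) -> np.ndarray:
        """(n_points, n_classes) basis matrix, interpolated onto a grid."""
        if wavelengths is None:
            return np.column_stack([self.components[c] for c in self.classes])
        wavelengths = np.asarray(wavelengths, dtype=float)
        lo = max(self.wavelengths[0], wavelengths[0])
        hi = min(self.wavelengths[-1], wavelengths[-1])
        if lo > hi:
            raise ValueError("no wavelength overlap between spectrum and basis")
        return np.column_stack([
            np.interp(wavelengths, self.wavelengths, self.components[c])
            for c in self.classes
        ])

    def combine(self, fractions) -> np.ndarray:
        fractions = np.asarray(fractions, dtype=float)
        return self.matrix() @ fractions


def to_mre(spectrum: CDSpectrum, mw_kda: float | None = None,
           path_length_cm: float | None = None,
           concentration_mg_ml: float | None = None) -> CDSpectrum:
    """Convert a millidegree spectrum to mean residue ellipticity."""
    if spectrum.unit != "mdeg":
        raise ValueError("spectrum is not in millidegrees")
    mw = mw_kda if mw_kda is not None else spectrum.mw_kda
    pl = path_length_cm if path_length_cm is not None else spectrum.path_length_cm
    conc = concentration_mg_ml if concentration_mg_ml is not None else spectrum.concentration_mg_ml
    for name, v in (("Mw", mw), ("path length", pl), ("concentration", conc)):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be a positive number")
    values = spectrum.values * mw / (10.0 * pl * conc)
    return replace(spectrum, values=values, unit="MRE", mw_kda=mw,
                   path_length_cm=pl, concentration_mg_ml=conc)


def average_and_correct(spectra, baseline: CDSpectrum | None = None) -> CDSpectrum:
    """Subtract a baseline from each spectrum, then average pointwise."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].wavelengths
    unit = spectra[0].unit
    for s in spectra[1:] + ([baseline] if baseline is not None else []):
        if not np.array_equal(s.wavelengths, grid):
            raise ValueError("spectra are not on a shared wavelength grid")
        if s.unit != unit:
            raise ValueError("spectra mix units")
    vals = np.mean([s.values for s in spectra], axis=0)
    if baseline is not None:
        vals = vals - baseline.values
    return replace(spectra[0], values=vals, label="averaged")


def smooth(spectrum: CDSpectrum, order: int = 3, window: int = 9) -> CDSpectrum:
    """Savitzky–Golay smoothing; endpoints handled by polynomial fits on
    one-sided windows (scipy's interpolation mode)."""
    from scipy.signal import savgol_filter

    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and larger than the order")
    steps = np.diff(spectrum.wavelengths)
    if len(steps) and not np.allclose(steps, steps[0]):
        raise ValueError("Savitzky–Golay smoothing needs a uniform grid")
    vals = savgol_filter(spectrum.values, window, order, mode="interp")
    return replace(spectrum, values=vals)


@dataclass
class DeconvolutionResult:
    fractions: dict[str, float]
    scale: float
    rmsd: float                      # in spectrum units, post-scaling
    basis_name: str = ""

    @property
    def rmsd_kmre(self) -> float:
        """RMSD in thousands of MRE units (the customary reporting scale)."""
        return self.rmsd / 1000.0


def _support_solve(y, b_sup):
    """Exact minimizer of ‖s·y − B·f‖² subject to Σf = 1 over (f, s),
    via the KKT linear system (no sign constraints)."""
    a = np.column_stack([b_sup, -y])
    n = a.shape[1]
    c = np.ones(n)
    c[-1] = 0.0
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2.0 * a.T @ a
    kkt[:n, n] = c
    kkt[n, :n] = c
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    return sol[:-2], sol[-2]          # (f on support, scale)


def deconvolve(spectrum: CDSpectrum, basis: BasisSet) -> DeconvolutionResult:
    """Fit nonnegative, sum-to-one class fractions and a single positive
    scale on the spectrum minimizing ‖scale·y − B·f‖.

    The sum-to-one nonnegative fit uses active-set nonnegative least squares
    (with the constraint as a strongly weighted row) alternated with the
    closed-form optimal scale, then an exact equality-constrained solve on
    the detected support.
    """
    from scipy.optimize import nnls

    y = spectrum.values
    b = basis.matrix(spectrum.wavelengths)
    n = b.shape[1]
    yy = float(y @ y)
    if yy == 0:
        raise ValueError("spectrum is identically zero")

    lam = 1e4 * max(np.abs(b).max(), 1.0)
    m = np.vstack([b, lam * np.ones((1, n))])
    s = 1.0
    f = np.full(n, 1.0 / n)
    for _ in range(200):
        rhs = np.concatenate([s * y, [lam]])
        f_new, _ = nnls(m, rhs)
        total = f_new.sum()
        if total <= 0:
            raise ValueError("degenerate basis: all-zero fit")
        f_new = f_new / total
        s_new = max(float(y @ (b @ f_new)) / yy, 1e-12)
        if np.max(np.abs(f_new - f)) < 1e-15 and abs(s_new - s) < 1e-15:
            f, s = f_new, s_new
            break
        f, s = f_new, s_new

    # polish: exact KKT solve restricted to the active support
    support = f > 1e-12
    if support.any():
        f_sup, s_exact = _support_solve(y, b[:, support])
        if np.all(f_sup >= -1e-10) and s_exact > 0:
            f = np.zeros(n)
            f[support] = np.clip(f_sup, 0.0, None)
            f /= f.sum()
            s = s_exact

    pred = b @ f
    rmsd = float(np.sqrt(np.mean((s * y - pred) ** 2)))
    return DeconvolutionResult(dict(zip(basis.classes, f)), float(s), rmsd,
                               basis.name)


def select_basis(spectrum: CDSpectrum, candidates) -> tuple[BasisSet, "list[tuple[str, float]]"]:
    """Deconvolve against every candidate basis set and keep the one with the
    lowest post-scaling RMSD (ties broken by candidate order)."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("at least one candidate basis set required")
    table = []
    best = None
    for cand in candidates:
        res = deconvolve(spectrum, cand)
        table.append((cand.name, res.rmsd))
        if best is None or res.rmsd < best[1].rmsd:
            best = (cand, res)
        elif abs(res.rmsd - best[1].rmsd) < 1e-15:
            log.info("basis-set RMSD tie between %s and %s; keeping the first",
                     best[0].name, cand.name)
    return best[0], table


def group_classes(fractions: dict[str, float], basis: BasisSet) -> dict[str, float]:
    """Sum fitted fractions into the basis set's three reporting classes."""
    unmapped = set(fractions) - set(basis.grouping)
    if unmapped:
        raise ValueError(f"no grouping for classes {sorted(unmapped)}")
    out = {"helix": 0.0, "strand": 0.0, "coil": 0.0}
    for cls, f in fractions.items():
        out[basis.grouping[cls]] += f
    return out
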