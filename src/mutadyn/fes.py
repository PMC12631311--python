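"""Block-averaged histograms and Boltzmann-inverted free-energy surfaces.

A pair of aligned collective-variable series is split (after discarding an
equilibration span) into equal-length time windows. Each window yields a
normalized bivariate histogram H(i, j); the window-averaged histogram

    H̄_i = (1/N) Σ_j H_{i,j}

is Boltzmann-inverted to a free-energy surface

    F_i = −k_B T [ln(H̄_i) − ln(max(H̄_i))]

so the global minimum is 0 kJ/mol. The statistical error of F is obtained by
propagating the between-window standard error of the mean of H through the
logarithm (delta method): err_i = k_B T · sem(H_i·)/H̄_i. An alternative
estimator (invert each window, then take the spread of the window surfaces)
is available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CVSeries

__all__ = [
    "KB_KJ_PER_MOL_K",
    "BlockHistogramStack",
    "FreeEnergySurface",
    "FreeEnergyProfile",
    "block_histograms",
    "average_histogram",
    "boltzmann_invert",
    "fes_error",
    "surface",
    "project_1d",
    "basin_delta_g",
]

log = logging.getLogger(__name__)

KB_KJ_PER_MOL_K = 0.0083145  # Boltzmann constant, kJ/(mol·K)


@dataclass
class BlockHistogramStack:
    """Per-window normalized 2D histograms on shared bin edges."""

    histograms: np.ndarray      # (n_windows, n1, n2), each window sums to 1
    edges1: np.ndarray
    edges2: np.ndarray
    window_ns: float
    discard_ns: float
    cv_names: tuple[str, str] = ("cv1", "cv2")

    @property
    def n_windows(self) -> int:
        return len(self.histograms)

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])


@dataclass
class FreeEnergySurface:
    """F (kJ/mol) on 2D bins with a propagated error surface.

    Unvisited bins are masked (NaN in ``free_energy`` and ``error``), never 0.
    """

    free_energy: np.ndarray
    error: np.ndarray
    mask: np.ndarray            # True where visited
    centers1: np.ndarray
    centers2: np.ndarray
    temperature: float
    error_method: str = "delta"


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile with error band along one collective variable."""

    centers: np.ndarray
    free_energy: np.ndarray
    error: np.ndarray
    mask: np.ndarray
    temperature: float
    axis_name: str = "cv"


def _window_bounds(times: np.ndarray, discard_ns: float, window_ns: float):
    t0 = times[0] + discard_ns
    kept = times >= t0
    if window_ns <= 0:
        raise ValueError("window length must be positive")
    span = times[-1] - t0 + (times[1] - times[0] if len(times) > 1 else 0.0)
    n_windows = int(np.floor(span / window_ns + 1e-9))
    if n_windows < 2:
        raise ValueError("fewer than 2 complete windows after discard")
    remainder = span - n_windows * window_ns
    if remainder > 1e-9:
        log.warning("trailing %.3g ns do not fill a window and are dropped", remainder)
    return t0, n_windows, kept


def block_histograms(cv1: CVSeries, cv2: CVSeries, discard_ns: float = 50.0,
                     window_ns: float = 10.0, bins: int = 50,
                     ranges=None) -> BlockHistogramStack:
    """Split two aligned CV series into windows and histogram each window.

    ``bins`` may be an int or a pair; ``ranges`` a pair of (lo, hi) ranges.
    Default ranges span the observed post-discard values padded by 5%.
    """
    if cv1.times.shape != cv2.times.shape or not np.allclose(cv1.times, cv2.times):
        raise ValueError("collective-variable series are not frame-aligned")
    times = cv1.times
    t0, n_windows, kept = _window_bounds(times, discard_ns, window_ns)
    v1 = cv1.values[kept]
    v2 = cv2.values[kept]
    tk = times[kept]

    if isinstance(bins, int):
        bins = (bins, bins)
    if ranges is None:
        ranges = []
        for v in (v1, v2):
            lo, hi = float(v.min()), float(v.max())
            pad = 0.05 * (hi - lo) if hi > lo else max(0.05 * abs(hi), 0.5)
            ranges.append((lo - pad, hi + pad))
    edges1 = np.linspace(*ranges[0], bins[0] + 1)
    edges2 = np.linspace(*ranges[1], bins[1] + 1)

    hists = np.empty((n_windows, bins[0], bins[1]))
    for j in range(n_windows):
        in_win = (tk >= t0 + j * window_ns - 1e-9) & (tk < t0 + (j + 1) * window_ns - 1e-9)
        if not in_win.any():
            raise ValueError(f"window {j} contains no frames")
        h, _, _ = np.histogram2d(v1[in_win], v2[in_win], bins=[edges1, edges2])
        hists[j] = h / h.sum()
    return BlockHistogramStack(hists, edges1, edges2, window_ns, discard_ns,
                               (cv1.name, cv2.name))


def average_histogram(stack: BlockHistogramStack) -> np.ndarray:
    """Elementwise mean over windows; sums to 1."""
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows")
    return stack.histograms.mean(axis=0)


def boltzmann_invert(h_bar: np.ndarray, temperature: float = 298.15,
                     centers1=None, centers2=None,
                     error: np.ndarray | None = None) -> FreeEnergySurface:
    """Invert an averaged histogram to F (kJ/mol), minimum pinned at 0."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    h_bar = np.asarray(h_bar, dtype=float)
    if not np.any(h_bar > 0):
        raise ValueError("histogram is everywhere zero")
    mask = h_bar > 0
    kt = KB_KJ_PER_MOL_K * temperature
    f = np.full(h_bar.shape, np.nan)
    f[mask] = -kt * (np.log(h_bar[mask]) - np.log(h_bar.max()))
    err = np.full(h_bar.shape, np.nan) if error is None else np.where(mask, error, np.nan)
    return FreeEnergySurface(f, err, mask, centers1, centers2, temperature)


def _sem(histograms: np.ndarray) -> np.ndarray:
    n = len(histograms)
    return histograms.std(axis=0, ddof=1) / np.sqrt(n)


def fes_error(stack: BlockHistogramStack, temperature: float = 298.15,
              method: str = "delta") -> np.ndarray:
    """Per-bin error of F in kJ/mol.

    ``delta``: k_B T · sem(H)/H̄ (standard error propagated through the log).
    ``per-window``: standard error of the per-window inverted surfaces.
    NaN where H̄ = 0.
    """
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows")
    kt = KB_KJ_PER_MOL_K * temperature
    h_bar = stack.histograms.mean(axis=0)
    mask = h_bar > 0
    out = np.full(h_bar.shape, np.nan)
    if method == "delta":
        out[mask] = kt * _sem(stack.histograms)[mask] / h_bar[mask]
    elif method == "per-window":
        with np.errstate(divide="ignore"):
            f_w = -kt * np.log(np.where(stack.histograms > 0, stack.histograms, np.nan))
        f_w -= np.nanmin(f_w, axis=(1, 2), keepdims=True)
        n_vis = np.sum(~np.isnan(f_w), axis=0)
        sd = np.nanstd(f_w, axis=0, ddof=1)
        with np.errstate(invalid="ignore"):
            sem = sd / np.sqrt(n_vis)
        out[mask] = sem[mask]
    else:
        raise ValueError(f"unknown error method {method!r}")
    return out


def surface(stack: BlockHistogramStack, temperature: float = 298.15,
            error_method: str = "delta") -> FreeEnergySurface:
    """Convenience: averaged histogram → inverted surface with error."""
    h_bar = average_histogram(stack)
    err = fes_error(stack, temperature, method=error_method)
    fes = boltzmann_invert(h_bar, temperature, stack.centers1, stack.centers2, err)
    fes.error_method = error_method
    return fes


def _marginal_windows(stack: BlockHistogramStack, axis):
    """(per-window marginals, bin centres, axis name) for one CV axis."""
    if axis in ("cv1", 0, stack.cv_names[0]):
        return stack.histograms.sum(axis=2), stack.centers1, stack.cv_names[0]
    if axis in ("cv2", 1, stack.cv_names[1]):
        return stack.histograms.sum(axis=1), stack.centers2, stack.cv_names[1]
    raise ValueError(f"axis must identify one of {stack.cv_names}")


def project_1d(stack: BlockHistogramStack, axis="cv1",
               temperature: float = 298.15) -> FreeEnergyProfile:
    """Marginalize each window onto one CV, average, invert, propagate error."""
    marg, centers, name = _marginal_windows(stack, axis)
    p_bar = marg.mean(axis=0)
    mask = p_bar > 0
    kt = KB_KJ_PER_MOL_K * temperature
    f = np.full(p_bar.shape, np.nan)
    f[mask] = -kt * (np.log(p_bar[mask]) - np.log(p_bar.max()))
    err = np.full(p_bar.shape, np.nan)
    err[mask] = kt * _sem(marg)[mask] / p_bar[mask]
    return FreeEnergyProfile(centers, f, err, mask, temperature, name)


def basin_delta_g(stack: BlockHistogramStack, axis="cv1", split: float = 0.0,
                  temperature: float = 298.15):
    """Free-energy difference ΔG = G(right basin) − G(left basin) along one CV.

    Basins are the marginal probability mass below/above ``split``. Returns
    ``(delta_g, err_1sigma, ci95_halfwidth)`` in kJ/mol, with the error from
    delta-method propagation of the between-window SEM of the basin
    occupancies and the 95% half-width from the t distribution on N−1
    degrees of freedom.
    """
    from scipy.stats import t as t_dist

    marg, centers, _ = _marginal_windows(stack, axis)
    left = centers < split
    p1_w = marg[:, left].sum(axis=1)     # per-window left-basin occupancy
    p2_w = marg[:, ~left].sum(axis=1)
    p1, p2 = p1_w.mean(), p2_w.mean()
    if p1 <= 0 or p2 <= 0:
        raise ValueError("a basin has zero occupancy; move the split point")
    kt = KB_KJ_PER_MOL_K * temperature
    dg = -kt * np.log(p2 / p1)
    n = stack.n_windows
    # p2 = 1 − p1 within each window, so var(ln p2/p1) = var(p1)·(1/p1+1/p2)²
    sem_p1 = p1_w.std(ddof=1) / np.sqrt(n)
    err = kt * sem_p1 * (1.0 / p1 + 1.0 / p2)
    ci95 = float(t_dist.ppf(0.975, n - 1)) * err
    return float(dg), float(err), float(ci95)
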