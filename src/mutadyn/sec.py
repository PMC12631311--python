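"""Size-exclusion chromatography: column calibration, apparent molecular
weight and oligomeric-state assignment.

Calibration follows the classic log-linear model, log10(MW) = a·Ve + b, fit
by least squares to protein standards (larger species elute earlier, so
a < 0). Peaks are local maxima of the smoothed chromatogram; shoulders are
flank features located at local minima of the second derivative that do not
coincide with a detected peak. The oligomeric order of a species is the
apparent-to-monomer mass ratio rounded to the nearest integer, with the raw
ratio reported so borderline cases (rapid equilibria, compact assemblies)
stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationCurve", "Chromatogram", "fit_calibration",
           "apparent_mw", "detect_peaks", "oligomer_order"]


@dataclass
class CalibrationCurve:
    """log10(MW/kDa) = slope · Ve + intercept, valid within the standards' range."""

    slope: float
    intercept: float
    residuals: np.ndarray
    volume_range: tuple[float, float]

    def predict_log10_mw(self, volume_ml):
        return self.slope * np.asarray(volume_ml, dtype=float) + self.intercept

    def volume_for_mw(self, mw_kda: float) -> float:
        """Elution volume at which a species of the given mass elutes."""
        return (np.log10(mw_kda) - self.intercept) / self.slope


@dataclass
class Chromatogram:
    """Elution volume (mL) vs absorbance (mAU)."""

    volume_ml: np.ndarray
    absorbance_mau: np.ndarray
    flow_rate_ml_min: float | None = None
    label: str = ""

    def __post_init__(self):
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.absorbance_mau = np.asarray(self.absorbance_mau, dtype=float)
        if self.volume_ml.shape != self.absorbance_mau.shape:
            raise ValueError("volume and absorbance arrays must align")
        if len(self.volume_ml) > 1 and not np.all(np.diff(self.volume_ml) > 0):
            raise ValueError("elution volumes must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance_mau)):
            raise ValueError("absorbance must be finite")


def fit_calibration(standards) -> CalibrationCurve:
    """Least-squares log-linear calibration from (MW kDa, elution mL) pairs."""
    standards = [(float(m), float(v)) for m, v in standards]
    if len(standards) < 2:
        raise ValueError("at least 2 standards required")
    mw = np.array([m for m, _ in standards])
    ve = np.array([v for _, v in standards])
    if np.any(mw <= 0):
        raise ValueError("standard masses must be positive")
    if len(np.unique(ve)) != len(ve):
        raise ValueError("standards have duplicate elution volumes")
    slope, intercept = np.polyfit(ve, np.log10(mw), 1)
    if slope >= 0:
        raise ValueError("calibration slope is non-negative; larger species "
                         "must elute earlier")
    resid = np.log10(mw) - (slope * ve + intercept)
    return CalibrationCurve(float(slope), float(intercept), resid,
                            (float(ve.min()), float(ve.max())))


def apparent_mw(volume_ml: float, cal: CalibrationCurve) -> tuple[float, bool]:
    """Apparent MW (kDa) at an elution volume; flags extrapolation outside
    the standards' volume range."""
    mw = float(10.0 ** cal.predict_log10_mw(volume_ml))
    lo, hi = cal.volume_range
    return mw, not (lo <= volume_ml <= hi)


def detect_peaks(chrom: Chromatogram, smoothing_window: int = 11,
                 prominence_frac: float = 0.02,
                 shoulder_curvature_frac: float = 0.02):
    """Peaks and shoulders of a chromatogram.

    Peaks are local maxima of the Savitzky–Golay-smoothed signal with
    prominence above ``prominence_frac`` of the signal amplitude. Shoulders
    are local minima of the smoothed second derivative (curvature troughs)
    on a peak's flank: troughs that do not coincide with a detected apex,
    sit above the baseline, and whose depth exceeds
    ``shoulder_curvature_frac`` of the strongest apex curvature. Trough
    positions are refined by parabolic interpolation. Returns a list of
    (volume, height, kind) with kind "peak" or "shoulder", ordered by volume.
    """
    from scipy.signal import argrelmin, find_peaks, savgol_filter

    v = chrom.volume_ml
    y = chrom.absorbance_mau
    if len(v) < 5:
        raise ValueError("chromatogram too short for peak detection")
    window = min(smoothing_window if smoothing_window % 2 else smoothing_window + 1,
                 len(y) - (1 - len(y) % 2))
    ys = savgol_filter(y, window, 3, mode="interp") if window > 3 else y.copy()
    amp = ys.max() - ys.min()
    if amp <= 0:
        return []
    peak_idx, _ = find_peaks(ys, prominence=prominence_frac * amp)
    out = [(float(v[i]), float(ys[i]), "peak") for i in peak_idx]

    d2 = savgol_filter(y, window, 3, deriv=2, mode="interp")
    trough_idx = argrelmin(d2, order=2)[0]
    if len(trough_idx) and peak_idx.size:
        dv_min = max(2 * (v[1] - v[0]), 0.15)
        at_apex = [i for i in trough_idx
                   if any(abs(v[i] - pv) < dv_min for pv, _, _ in out)]
        apex_depth = max((-d2[i] for i in at_apex), default=(-d2).max())
        shoulder_vols: list[float] = []
        for i in sorted(trough_idx, key=lambda k: d2[k]):   # deepest first
            if i in at_apex or -d2[i] < shoulder_curvature_frac * apex_depth:
                continue
            if ys[i] < ys.min() + 0.02 * amp:    # baseline noise, not a flank
                continue
            if any(abs(v[i] - sv) < dv_min for sv in shoulder_vols):
                continue
            shoulder_vols.append(float(v[i]))
            # parabolic refinement of the trough position
            vol = float(v[i])
            if 0 < i < len(v) - 1:
                denom = d2[i - 1] - 2 * d2[i] + d2[i + 1]
                if abs(denom) > 0:
                    vol += float(0.5 * (d2[i - 1] - d2[i + 1]) / denom) * (v[1] - v[0])
            out.append((vol, float(ys[i]), "shoulder"))
    out.sort(key=lambda t: t[0])
    return out


def oligomer_order(mw_app_kda: float, monomer_mw_kda: float) -> tuple[float, int]:
    """Apparent-to-monomer mass ratio and its nearest integer order."""
    if mw_app_kda <= 0 or monomer_mw_kda <= 0:
        raise ValueError("masses must be positive")
    ratio = mw_app_kda / monomer_mw_kda
    return float(ratio), int(round(ratio))
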