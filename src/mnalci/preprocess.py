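"""Raw shot spectra -> calibrated, normalized, binned feature vectors.

The chain mirrors routine TOF practice: SNIP baseline subtraction,
Savitzky-Golay smoothing with a robust (MAD-based) noise estimate, centroid
peak picking with signal-to-noise and resolving power, the per-shot
acceptance rule (at least one peak in m/z 100-500 with resolving power > 300
and S/N > 30), accumulation of accepted shots, a six-calibrant affine mass
calibration, total-ion-current normalization, and uniform 0.5-Da binning
over 100-1000 Da. A PCA check over standard spots flags inconsistent runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter
from sklearn.decomposition import PCA

from .constants import DEFAULT_CALIBRANTS, MZ_MAX, MZ_MIN
from .spectra_io import Peak, PeakList, RawSpectrum


class QCFailure(RuntimeError):
    """A sample x matrix (or run) failed a quality gate."""


class CalibrationError(RuntimeError):
    """Too few calibrants matched to fit the affine correction."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CalibrantSet:
    """Named reference masses of the calibration standard, ascending in m/z."""

    calibrants: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_CALIBRANTS)
    )

    def __post_init__(self) -> None:
        if len(self.calibrants) < 2:
            raise ValueError("need at least 2 calibrants")
        mzs = [mz for _, mz in self.calibrants]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("calibrant reference m/z must be strictly increasing")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.calibrants]

    @property
    def reference_mzs(self) -> np.ndarray:
        return np.array([mz for _, mz in self.calibrants], dtype=float)


@dataclass
class CalibrationFit:
    """Affine map observed -> reference: ``mz_corr = slope * mz + offset``."""

    slope: float
    offset: float
    residuals: dict[str, float]
    matched: dict[str, float]

    def apply_mz(self, mz: np.ndarray | float) -> np.ndarray:
        return self.slope * np.asarray(mz, dtype=float) + self.offset

    def apply(self, spectrum: RawSpectrum) -> RawSpectrum:
        return spectrum.copy_with(mz=self.apply_mz(spectrum.mz))

    def apply_peaklist(self, peaklist: PeakList) -> PeakList:
        peaks = [
            Peak(float(self.apply_mz(p.mz)), p.intensity, p.snr, p.resolving_power)
            for p in peaklist.peaks
        ]
        return PeakList(peaklist.sample_id, peaklist.matrix_tag, peaks)

    def implied_drift(self) -> tuple[float, float]:
        """The forward affine drift this fit corrects: mz_obs = mz*(1+s) + o."""
        slope_fwd = 1.0 / self.slope - 1.0
        offset_fwd = -self.offset / self.slope
        return slope_fwd, offset_fwd


@dataclass
class FeatureGrid:
    """Uniform half-open [lo, hi) bins covering 100-1000 Da."""

    width: float = 0.5
    mz_min: float = MZ_MIN
    mz_max: float = MZ_MAX

    def __post_init__(self) -> None:
        span = self.mz_max - self.mz_min
        n = span / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"bin width {self.width} does not tile [{self.mz_min}, {self.mz_max}]")

    @property
    def n_bins(self) -> int:
        return int(round((self.mz_max - self.mz_min) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.mz_min + self.width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.mz_min + self.width * (np.arange(self.n_bins) + 0.5)

    def bin_index(self, mz: np.ndarray | float) -> np.ndarray:
        idx = np.floor((np.asarray(mz, dtype=float) - self.mz_min) / self.width).astype(int)
        # the terminal edge (exactly mz_max) folds into the last bin
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class AcceptanceRule:
    """Shot acceptance: one peak in the window with RP and S/N above both bars."""

    min_resolving_power: float = 300.0
    min_snr: float = 30.0
    window: tuple[float, float] = (100.0, 500.0)

    def __post_init__(self) -> None:
        if self.min_resolving_power <= 0 or self.min_snr <= 0:
            raise ValueError("acceptance thresholds must be strictly positive")


@dataclass
class QCReport:
    """Standard-spot PCA scores with outlier flags."""

    scores: pd.DataFrame  # columns PC1, PC2; index spot ids
    outlier: pd.Series
    k: float
    robust_sd: float


# ---------------------------------------------------------------------------
# baseline / denoise


def snip_baseline(intensity: np.ndarray, half_window: int = 50) -> np.ndarray:
    """SNIP baseline estimate: iterative clipping with a growing window.

    Each pass replaces a point by the smaller of itself and the mean of its
    two neighbours ``m`` points away, ``m`` growing to ``half_window``;
    peaks narrower than the window are clipped away while smooth baseline
    structure (constant, linear, slow curvature) is reproduced essentially
    exactly. Edges are continued by odd reflection so sloped baselines are
    not under-subtracted at the spectrum ends.
    """
    v = np.asarray(intensity, dtype=float).copy()
    n = v.size
    for m in range(1, min(half_window, (n - 1) // 2) + 1):
        padded = np.pad(v, m, mode="reflect", reflect_type="odd")
        avg = 0.5 * (padded[:n] + padded[2 * m:])
        v = np.minimum(v, avg)
    return v


def correct_baseline(spectrum: RawSpectrum, half_window: int = 50) -> RawSpectrum:
    """Subtract the SNIP baseline, clipping the result at zero."""
    baseline = snip_baseline(spectrum.intensity, half_window=half_window)
    return spectrum.copy_with(intensity=np.maximum(spectrum.intensity - baseline, 0.0))


_MAD_SCALE = 1.4826


def _savgol_residual_factor(window_length: int, polyorder: int) -> float:
    # sd of (y - smooth) at the window centre for iid noise:
    # residual = e - c.e  =>  var = 1 - 2*c0 + sum(c^2)
    c = savgol_coeffs(window_length, polyorder)
    c0 = c[window_length // 2]
    return float(np.sqrt(max(1.0 - 2.0 * c0 + np.sum(c**2), 1e-12)))


def denoise(
    spectrum: RawSpectrum, window_length: int = 7, polyorder: int = 3
) -> tuple[RawSpectrum, float]:
    """Savitzky-Golay smoothing plus a robust noise-sd estimate.

    The noise sd comes from the scaled median absolute deviation of the
    smoothing residual, corrected for the variance the filter removes.
    """
    y = spectrum.intensity
    if y.size < window_length:
        return spectrum.copy_with(), 0.0
    smooth = savgol_filter(y, window_length, polyorder, mode="interp")
    residual = y - smooth
    mad = np.median(np.abs(residual - np.median(residual)))
    noise_sd = float(_MAD_SCALE * mad / _savgol_residual_factor(window_length, polyorder))
    return spectrum.copy_with(intensity=np.maximum(smooth, 0.0)), noise_sd


# ---------------------------------------------------------------------------
# peak picking


def _interp_crossing(x0: float, x1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def _peak_fwhm(mz: np.ndarray, y: np.ndarray, apex: int, half: float) -> float | None:
    left = None
    for i in range(apex - 1, -1, -1):
        if y[i] <= half:
            left = _interp_crossing(mz[i], mz[i + 1], y[i], y[i + 1], half)
            break
    right = None
    for i in range(apex + 1, y.size):
        if y[i] <= half:
            right = _interp_crossing(mz[i - 1], mz[i], y[i - 1], y[i], half)
            break
    if left is None or right is None or right <= left:
        return None
    return right - left


def _gaussian_apex(mz: np.ndarray, y: np.ndarray, apex: int) -> tuple[float, float]:
    """Refine apex position/height by a log-parabola through 3 points.

    Exact for Gaussian peaks on a uniform grid; falls back to the grid apex
    when neighbours are missing or non-positive.
    """
    if apex == 0 or apex == y.size - 1:
        return float(mz[apex]), float(y[apex])
    y0, y1, y2 = y[apex - 1], y[apex], y[apex + 1]
    if min(y0, y1, y2) <= 0:
        return float(mz[apex]), float(y[apex])
    l0, l1, l2 = np.log([y0, y1, y2])
    denom = l0 - 2.0 * l1 + l2
    if denom >= 0:
        return float(mz[apex]), float(y[apex])
    delta = 0.5 * (l0 - l2) / denom
    step = 0.5 * (mz[apex + 1] - mz[apex - 1])
    height = float(np.exp(l1 - 0.25 * (l0 - l2) * delta))
    return float(mz[apex] + delta * step), height


def pick_peaks(
    spectrum: RawSpectrum,
    noise_sd: float,
    min_prominence: float | None = None,
) -> PeakList:
    """Centroid local maxima into a peak list with S/N and resolving power.

    S/N is apex height over ``noise_sd`` (infinite when the noise estimate is
    zero); resolving power is m/FWHM with the FWHM read off by linear
    interpolation at half height. A small prominence floor (default
    ``2 * noise_sd``) suppresses noise wiggles without applying the
    acceptance thresholds, which belong to :func:`accept_spectrum`.
    """
    y = spectrum.intensity
    mz = spectrum.mz
    if y.size < 3 or not np.any(y > 0):
        return PeakList(spectrum.sample_id, spectrum.matrix_tag, [])
    if min_prominence is None:
        min_prominence = 2.0 * noise_sd if noise_sd > 0 else 1e-12 * float(y.max())
    idx, _ = find_peaks(y, prominence=min_prominence)
    peaks: list[Peak] = []
    for apex in idx:
        apex_mz, apex_height = _gaussian_apex(mz, y, int(apex))
        fwhm = _peak_fwhm(mz, y, int(apex), apex_height / 2.0)
        if fwhm is None or fwhm <= 0:
            continue
        snr = float(apex_height / noise_sd) if noise_sd > 0 else float("inf")
        peaks.append(Peak(apex_mz, apex_height, snr, apex_mz / fwhm))
    return PeakList(spectrum.sample_id, spectrum.matrix_tag, peaks)


def accept_spectrum(peaklist: PeakList, rule: AcceptanceRule | None = None) -> bool:
    """True iff some peak inside the window beats both thresholds (strictly)."""
    rule = rule or AcceptanceRule()
    lo, hi = rule.window
    return any(
        lo <= p.mz <= hi and p.resolving_power > rule.min_resolving_power and p.snr > rule.min_snr
        for p in peaklist.peaks
    )


# ---------------------------------------------------------------------------
# accumulation / calibration / normalization / binning


def accumulate(shots: Sequence[RawSpectrum], accepted: Sequence[bool] | None = None) -> RawSpectrum:
    """Pointwise mean of accepted shots on their common grid."""
    shots = list(shots)
    if not shots:
        raise QCFailure("no shots to accumulate")
    if accepted is None:
        accepted = [True] * len(shots)
    kept = [s for s, ok in zip(shots, accepted) if ok]
    if not kept:
        raise QCFailure(
            f"{shots[0].sample_id}/{shots[0].matrix_tag}: zero accepted shots — failed QC"
        )
    grid = kept[0].mz
    for s in kept[1:]:
        if s.mz.shape != grid.shape or not np.allclose(s.mz, grid):
            raise ValueError("shots are not on a common m/z grid")
    mean = np.mean([s.intensity for s in kept], axis=0)
    out = kept[0].copy_with(intensity=mean)
    out.shot_index = len(kept)  # records the accepted count
    return out


def calibrate(
    peaklist: PeakList,
    calibrants: CalibrantSet | None = None,
    tolerance: float = 0.5,
) -> CalibrationFit:
    """Least-squares affine fit observed -> reference over matched calibrants.

    Each calibrant is matched to the nearest picked peak within ``tolerance``
    Da; at least two matches are required.
    """
    calibrants = calibrants or CalibrantSet()
    peak_mzs = peaklist.mzs()
    matched: dict[str, float] = {}
    for name, ref in calibrants.calibrants:
        if peak_mzs.size == 0:
            break
        j = int(np.argmin(np.abs(peak_mzs - ref)))
        if abs(peak_mzs[j] - ref) <= tolerance:
            matched[name] = float(peak_mzs[j])
    if len(matched) < 2:
        raise CalibrationError(
            f"only {len(matched)} calibrant(s) matched within {tolerance} Da; need >= 2"
        )
    ref = np.array([dict(calibrants.calibrants)[n] for n in matched])
    obs = np.array([matched[n] for n in matched])
    slope, offset = np.polyfit(obs, ref, 1)
    residuals = {n: float(slope * o + offset - r) for n, o, r in zip(matched, obs, ref)}
    return CalibrationFit(float(slope), float(offset), residuals, matched)


def normalize(spectrum: RawSpectrum) -> RawSpectrum:
    """Divide by total ion current over the analysed window."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise QCFailure(f"{spectrum.sample_id}/{spectrum.matrix_tag}: zero total ion current")
    return spectrum.copy_with(intensity=spectrum.intensity / total)


def bin_features(spectrum: RawSpectrum, grid: FeatureGrid | None = None) -> np.ndarray:
    """Per-bin summed intensity on the half-open uniform grid."""
    grid = grid or FeatureGrid()
    v = np.zeros(grid.n_bins)
    keep = (spectrum.mz >= grid.mz_min) & (spectrum.mz <= grid.mz_max)
    np.add.at(v, grid.bin_index(spectrum.mz[keep]), spectrum.intensity[keep])
    return v


# ---------------------------------------------------------------------------
# whole-sample convenience


def process_sample(
    shots: Sequence[RawSpectrum],
    rule: AcceptanceRule | None = None,
    grid: FeatureGrid | None = None,
    calibration: CalibrationFit | None = None,
    baseline_half_window: int = 50,
) -> tuple[np.ndarray, int]:
    """Shots -> accepted-mean -> (calibrated) -> normalized -> binned features.

    Returns the feature vector and the accepted shot count.
    """
    processed: list[RawSpectrum] = []
    flags: list[bool] = []
    for shot in shots:
        corrected = correct_baseline(shot, half_window=baseline_half_window)
        smooth, noise_sd = denoise(corrected)
        flags.append(accept_spectrum(pick_peaks(smooth, noise_sd), rule))
        processed.append(smooth)
    accumulated = accumulate(processed, flags)
    if calibration is not None:
        accumulated = calibration.apply(accumulated)
    return bin_features(normalize(accumulated), grid), accumulated.shot_index


# ---------------------------------------------------------------------------
# standards QC


def qc_standards_pca(
    standard_features: pd.DataFrame, k: float = 3.0
) -> QCReport | None:
    """PCA over standard-spot feature vectors; flag spots far from the pack.

    A spot is an outlier when its distance from the centroid in the first two
    component scores exceeds ``k`` times the robust (MAD-based) sd of those
    distances. Returns ``None`` (with a warning) for fewer than 3 spots.
    """
    X = pd.DataFrame(standard_features)
    if len(X) < 3:
        warnings.warn("QC skipped: need at least 3 standard spots", stacklevel=2)
        return None
    values = X.to_numpy(dtype=float)
    centred = values - values.mean(axis=0)
    n_comp = min(2, len(X) - 1, values.shape[1])
    if np.allclose(centred, 0.0):
        scores = np.zeros((len(X), 2))
    else:
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(values)
        if scores.shape[1] < 2:
            scores = np.column_stack([scores, np.zeros(len(X))])
    dist = np.linalg.norm(scores - np.median(scores, axis=0), axis=1)
    robust_sd = _MAD_SCALE * float(np.median(np.abs(dist - np.median(dist))))
    # absolute epsilon guards against flagging pure floating-point jitter
    eps = 1e-8 * (1.0 + float(np.abs(values).max()))
    outlier = dist > np.median(dist) + k * robust_sd + eps
    return QCReport(
        scores=pd.DataFrame(scores, index=X.index, columns=["PC1", "PC2"]),
        outlier=pd.Series(outlier, index=X.index),
        k=k,
        robust_sd=robust_sd,
    )
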