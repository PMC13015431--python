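"""Aperiodic/oscillatory spectral decomposition and Morlet band-power variability.

Each 10-s epoch's power spectrum is separated into a 1/f^chi aperiodic
component and Gaussian oscillatory peaks (the spectral-parameterization
model, fit iteratively in log10 power):

    log10 P(f) = offset - chi * log10 f + sum_p h_p * exp(-(f - c_p)^2 / (2 w_p^2))

Band power "over and above" the aperiodic fit is the in-band integral of the
fitted peaks.  Oscillatory variability is the coefficient of variation
(SD/mean) of the band-averaged Morlet power time course, computed with
3-cycle complex Morlet atoms at 1-Hz-spaced center frequencies and trimmed
of edge-contaminated samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit
from scipy.special import erf


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class SpectralConfig:
    psd_method: str = "welch"           # or "multitaper"
    fit_range: tuple[float, float] = (1.0, 45.0)
    theta_band: tuple[float, float] = (4.0, 7.0)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    morlet_cycles: float = 3.0
    max_peaks: int = 6
    peak_threshold: float = 2.0         # in residual SDs
    min_peak_height: float = 0.05       # absolute floor, log10 power units
    peak_width_bounds: tuple[float, float] = (1.0, 6.0)
    welch_seg_seconds: float = 2.0

    def __post_init__(self) -> None:
        for band in (self.theta_band, self.alpha_band):
            if not (self.fit_range[0] <= band[0] < band[1] <= self.fit_range[1]):
                raise ValueError("bands must lie inside fit_range")
        if self.morlet_cycles < 2:
            raise ValueError("morlet_cycles must be >= 2")


@dataclass(frozen=True)
class GaussianPeak:
    center: float   # Hz
    height: float   # log10 power over the aperiodic fit
    width: float    # Hz (Gaussian sigma)


@dataclass(frozen=True)
class SpectralFit:
    """Fitted aperiodic parameters and oscillatory peaks of one spectrum."""

    offset: float          # log10 power at 1 Hz
    exponent: float        # chi, PSD ~ f^-chi
    peaks: tuple[GaussianPeak, ...]
    converged: bool = True

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        out = self.aperiodic(freqs)
        for p in self.peaks:
            out = out + p.height * np.exp(-((freqs - p.center) ** 2)
                                          / (2.0 * p.width ** 2))
        return out


@dataclass(frozen=True)
class SpectralFeatures:
    aperiodic_offset: float
    aperiodic_exponent: float
    theta_power: float
    alpha_power: float
    theta_cv: float
    alpha_cv: float


def compute_psd(epoch: np.ndarray, fs: float,
                config: SpectralConfig = SpectralConfig()) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of one epoch (physical units, resolution <= 0.5 Hz).

    Welch: Hann-tapered segments of ``welch_seg_seconds`` with 50% overlap.
    Multitaper: DPSS tapers (NW=4) on the full epoch, averaged.
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains NaNs")
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of data")
    if config.psd_method == "welch":
        nperseg = int(round(config.welch_seg_seconds * fs))
        return sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                         window="hann", detrend="constant")
    if config.psd_method == "multitaper":
        from scipy.signal.windows import dpss

        nw = 4.0
        tapers = dpss(x.size, nw, Kmax=int(2 * nw - 1))
        specs = []
        for t in tapers:
            f, p = sps.periodogram(x * t, fs=fs, window="boxcar",
                                   detrend="constant")
            specs.append(p * x.size / (t ** 2).sum() / x.size)
        return f, np.mean(specs, axis=0)
    raise ValueError("psd_method must be 'welch' or 'multitaper'")


def _gauss(f, h, c, w):
    return h * np.exp(-((f - c) ** 2) / (2.0 * w ** 2))


def _robust_linfit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """First-pass aperiodic fit, downweighting positive (peak) residuals."""
    b, a = np.polyfit(logf, logp, 1)
    resid = logp - (a + b * logf)
    thresh = np.quantile(resid, 0.85)
    keep = resid <= thresh
    if keep.sum() >= 8:
        b, a = np.polyfit(logf[keep], logp[keep], 1)
    return a, b  # intercept, slope


def fit_aperiodic_peaks(freqs: np.ndarray, psd: np.ndarray,
                        config: SpectralConfig = SpectralConfig()) -> SpectralFit:
    """Iterative aperiodic + Gaussian-peak decomposition of a PSD.

    1. robust linear fit of log10 P on log10 f over ``fit_range``;
    2. fit Gaussians to residual peaks exceeding ``peak_threshold`` residual
       SDs, largest first, up to ``max_peaks``;
    3. refit the aperiodic line on the peak-removed spectrum.
    Non-convergent peak fits are dropped and flagged; the aperiodic part then
    comes from the robust first pass.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    mask = (freqs >= config.fit_range[0]) & (freqs <= config.fit_range[1])
    f, p = freqs[mask], psd[mask]
    if np.any(p <= 0):
        raise FitError("PSD must be positive on the fit range")
    logf, logp = np.log10(f), np.log10(p)

    a0, b0 = _robust_linfit(logf, logp)
    resid = logp - (a0 + b0 * logf)
    peaks: list[GaussianPeak] = []
    converged = True
    wlo, whi = config.peak_width_bounds
    work = resid.copy()
    for _ in range(config.max_peaks):
        i = int(np.argmax(work))
        height = work[i]
        if height < max(config.peak_threshold * work.std(),
                        config.min_peak_height):
            break
        guess = [height, f[i], max(min(2.0, whi), wlo)]
        try:
            popt, _ = curve_fit(
                _gauss, f, work, p0=guess,
                bounds=([0.0, config.fit_range[0], wlo],
                        [np.inf, config.fit_range[1], whi]),
                maxfev=2000)
        except RuntimeError:
            converged = False
            break
        pk = GaussianPeak(center=float(popt[1]), height=float(popt[0]),
                          width=float(popt[2]))
        peaks.append(pk)
        work = work - _gauss(f, pk.height, pk.center, pk.width)

    flat = logp - sum((_gauss(f, pk.height, pk.center, pk.width)
                       for pk in peaks), np.zeros_like(f))
    b1, a1 = np.polyfit(logf, flat, 1)
    return SpectralFit(offset=float(a1), exponent=float(-b1),
                       peaks=tuple(sorted(peaks, key=lambda q: q.center)),
                       converged=converged)


def band_power_above_aperiodic(fit: SpectralFit,
                               band: tuple[float, float]) -> float:
    """In-band integral of fitted peaks with centers inside ``band``.

    Units: (log10 power over the aperiodic baseline) x Hz; closed-form
    Gaussian integral, counting only the portion inside the band.  Zero when
    no peak center falls in the band.
    """
    lo, hi = band
    total = 0.0
    for p in fit.peaks:
        if lo <= p.center <= hi:
            s2 = p.width * math.sqrt(2.0)
            total += p.height * p.width * math.sqrt(2.0 * math.pi) * 0.5 * (
                erf((hi - p.center) / s2) - erf((lo - p.center) / s2))
    return float(total)


def _morlet_atom(freq: float, fs: float, cycles: float) -> np.ndarray:
    """Complex Morlet atom, unit energy, truncated at +-5 Gaussian SDs."""
    sigma_t = cycles / (2.0 * math.pi * freq)
    half = int(math.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    atom = np.exp(2j * math.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return atom / np.sqrt((np.abs(atom) ** 2).sum())


def morlet_power(epoch: np.ndarray, fs: float, band: tuple[float, float],
                 config: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Band-averaged Morlet power time course, edge-trimmed.

    Convolves the epoch with complex Morlet atoms at 1-Hz-spaced center
    frequencies inside ``band``, averages power across centers per time
    point, and trims one wavelet half-length (of the lowest, longest atom)
    from each side.
    """
    x = np.asarray(epoch, dtype=float)
    centers = np.arange(band[0], band[1] + 1e-9, 1.0)
    half_max = int(math.ceil(5.0 * config.morlet_cycles
                             / (2.0 * math.pi * centers[0]) * fs))
    if x.size <= 2 * half_max + 8:
        raise ValueError("epoch too short after edge trimming")
    power = np.zeros(x.size)
    for fc in centers:
        atom = _morlet_atom(fc, fs, config.morlet_cycles)
        conv = sps.fftconvolve(x, atom, mode="same")
        power += np.abs(conv) ** 2
    power /= centers.size
    return power[half_max:-half_max]


def morlet_cv(epoch: np.ndarray, fs: float, band: tuple[float, float],
              config: SpectralConfig = SpectralConfig()) -> float:
    """Coefficient of variation (SD/mean) of the band-power time course."""
    p = morlet_power(epoch, fs, band, config)
    return float(p.std() / p.mean())


def spectral_features(epoch: np.ndarray, fs: float,
                      config: SpectralConfig = SpectralConfig()) -> SpectralFeatures:
    """Full spectral summary of one epoch."""
    f, p = compute_psd(epoch, fs, config)
    fit = fit_aperiodic_peaks(f, p, config)
    return SpectralFeatures(
        aperiodic_offset=fit.offset,
        aperiodic_exponent=fit.exponent,
        theta_power=band_power_above_aperiodic(fit, config.theta_band),
        alpha_power=band_power_above_aperiodic(fit, config.alpha_band),
        theta_cv=morlet_cv(epoch, fs, config.theta_band, config),
        alpha_cv=morlet_cv(epoch, fs, config.alpha_band, config),
    )
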