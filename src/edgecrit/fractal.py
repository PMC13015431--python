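"""Long-range temporal correlations via wavelet-leader log-cumulants,
and the DWT-based spectral slope.

The scale-invariance analysis works on the dyadic discrete wavelet transform
of each epoch.  Wavelet *leaders* — the supremum of absolute (L1-normalized)
detail coefficients over a dyadic interval, its two neighbors, and all finer
scales — give access to the multifractal formalism: the cumulants of
log-leaders grow linearly across octaves,

    C_m(j) ~ c_m * j * ln 2 + const,

and the slopes (c1, c2) summarize the signal's scaling.  c1 is the dominant
regularity (Hurst-like) exponent indexing long-range temporal correlations;
c2 <= 0 quantifies multifractality (c2 ~ 0 for monofractal signals).

The spectral slope chi (PSD ~ f^-chi) is estimated from the same transform:
the log2 mean energy of the L2-normalized detail coefficients grows linearly
in the octave index with slope chi.

Octave indexing: analysis octave j corresponds to dyadic scale
2**(j + level_offset) samples (``level_offset`` defaults to 1), so the
default octaves 2-7 on 500 Hz data cover roughly 1-31 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt


class SignalTooShortError(ValueError):
    pass


@dataclass(frozen=True)
class FractalConfig:
    """Parameters of the wavelet scaling analysis.

    ``n_vanishing_moments`` selects the Daubechies analysis wavelet (db1 =
    Haar by default: one vanishing moment annihilates constants but not
    linear trends).  ``octave_range`` is inclusive in analysis-octave units;
    ``min_leaders_per_octave`` guards the coarse-scale statistics.
    """

    n_vanishing_moments: int = 1
    octave_range: tuple[int, int] = (2, 7)
    level_offset: int = 1
    min_leaders_per_octave: int = 8
    weighted: bool = True  # weight octave regression by coefficient counts

    @property
    def wavelet(self) -> str:
        return f"db{self.n_vanishing_moments}"

    @property
    def levels(self) -> range:
        """pywt decomposition levels covered by ``octave_range``."""
        j0, j1 = self.octave_range
        return range(j0 + self.level_offset, j1 + self.level_offset + 1)

    def min_samples(self) -> int:
        return 2 ** (max(self.levels) + 1)


@dataclass(frozen=True)
class FractalFeatures:
    """Scaling summary of one epoch: log-cumulants and spectral slope."""

    c1: float
    c2: float
    dwt_slope: float  # chi, PSD ~ f^-chi; larger = steeper
    n_octaves_used: int

    @property
    def multifractal_flag(self) -> bool:
        """Epochs with |c2| above 0.04 are flagged (retained, not dropped)."""
        return bool(np.isfinite(self.c2) and abs(self.c2) > 0.04)


def octave_frequencies(config: FractalConfig, fs: float) -> dict[int, tuple[float, float]]:
    """Analysis octave -> (low, high) frequency band in Hz."""
    out = {}
    for j in range(config.octave_range[0], config.octave_range[1] + 1):
        lev = j + config.level_offset
        out[j] = (fs / 2 ** (lev + 1), fs / 2 ** lev)
    return out


def dwt_coefficients(signal: np.ndarray,
                     config: FractalConfig = FractalConfig()) -> dict[int, np.ndarray]:
    """Dyadic detail coefficients (pywt L2 normalization) per level.

    Decomposes down to level 1 through max(config.levels) with periodized
    boundaries; counts halve per octave (rounded up).  Returns
    {level: coefficients}; boundary handling (dropping wrap-around-affected
    coefficients) is applied later, at the statistics stage.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    max_level = max(config.levels)
    if x.size < 2 ** (max_level + 1):
        raise SignalTooShortError(
            f"need at least {2 ** (max_level + 1)} samples for octave range "
            f"{config.octave_range} (got {x.size})")
    coeffs = pywt.wavedec(x, config.wavelet, mode="periodization",
                          level=max_level)
    # coeffs = [cA_L, cD_L, ..., cD_1]
    return {lev: coeffs[len(coeffs) - lev] for lev in range(1, max_level + 1)}


def _trim(arr: np.ndarray, n_b: int) -> np.ndarray:
    """Drop boundary-affected entries at each end (none for n_b=0)."""
    if n_b <= 0 or arr.size <= 2 * n_b:
        return arr
    return arr[n_b:-n_b]


def wavelet_leaders(coefficients: dict[int, np.ndarray],
                    config: FractalConfig = FractalConfig()) -> dict[int, np.ndarray]:
    """Wavelet leaders per level from the full detail-coefficient pyramid.

    The leader at (j, k) is the supremum of |d(j', k')| (L1 normalization)
    over the dyadic interval at (j, k) and its two neighbors, across all
    finer octaves j' <= j.  Computed bottom-up: the cone maximum at (j, k)
    is max(|d(j,k)|, cone(j-1, 2k), cone(j-1, 2k+1)); the leader then takes
    the running cone maximum over {k-1, k, k+1} (clipped at array edges).
    """
    levels = sorted(coefficients)
    cones: dict[int, np.ndarray] = {}
    for lev in levels:
        a = np.abs(np.asarray(coefficients[lev], dtype=float)) * 2.0 ** (-lev / 2.0)
        if lev - 1 in cones:
            child = cones[lev - 1]
            padded = np.full(2 * a.size, -np.inf)
            padded[: child.size] = child
            a = np.maximum(a, np.maximum(padded[0::2], padded[1::2]))
        cones[lev] = a
    leaders = {}
    for lev, cone in cones.items():
        ext = np.concatenate([cone[:1], cone, cone[-1:]])
        leaders[lev] = np.maximum(np.maximum(ext[:-2], ext[1:-1]), ext[2:])
    return leaders


def _weighted_slope(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> float:
    wx = w / w.sum()
    xb = (wx * x).sum()
    yb = (wx * y).sum()
    return float(((wx * (x - xb) * (y - yb)).sum()) / ((wx * (x - xb) ** 2).sum()))


def log_cumulants(leaders: dict[int, np.ndarray],
                  config: FractalConfig = FractalConfig()) -> tuple[float, float]:
    """(c1, c2) from the scale-wise cumulants of log-leaders.

    At each octave in range, C1(j) = mean(ln leaders), C2(j) = var(ln
    leaders); (c1, c2) are the slopes of C_m(j) against j*ln 2, by least
    squares weighted by leader counts.  Zero or non-finite leaders make the
    log-cumulants undefined and yield the NaN sentinel; zero within-scale
    variance (deterministic scaling) legitimately gives c2 = 0.
    """
    n_b = config.n_vanishing_moments
    js, c1s, c2s, ns = [], [], [], []
    for j in range(config.octave_range[0], config.octave_range[1] + 1):
        lev = j + config.level_offset
        if lev not in leaders:
            raise ValueError(f"octave {j} (level {lev}) missing from leaders")
        ell = _trim(np.asarray(leaders[lev], dtype=float), n_b)
        if ell.size < config.min_leaders_per_octave:
            raise SignalTooShortError(
                f"only {ell.size} leaders at octave {j}; need "
                f">= {config.min_leaders_per_octave}")
        if np.any(ell <= 0) or not np.all(np.isfinite(ell)):
            return float("nan"), float("nan")
        logs = np.log(ell)
        js.append(lev)
        c1s.append(logs.mean())
        c2s.append(logs.var(ddof=1) if logs.size > 1 else 0.0)
        ns.append(ell.size)
    x = np.asarray(js, dtype=float) * math.log(2.0)
    w = np.asarray(ns, dtype=float) if config.weighted else np.ones(len(ns))
    c1 = _weighted_slope(np.asarray(c1s), x, w)
    c2 = _weighted_slope(np.asarray(c2s), x, w)
    return c1, c2


def dwt_slope(coefficients: dict[int, np.ndarray],
              config: FractalConfig = FractalConfig()) -> float:
    """Spectral exponent chi (PSD ~ f^-chi) from detail-coefficient energies.

    Regresses log2(mean d(j,.)^2) (L2 normalization) on the octave index
    over ``octave_range``, weighted by coefficient counts.  For a signal
    with PSD ~ f^-beta the expected energy at scale 2^j is ~ 2^(j*beta), so
    the regression slope estimates chi = beta directly.
    """
    n_b = config.n_vanishing_moments
    js, es, ns = [], [], []
    for j in range(config.octave_range[0], config.octave_range[1] + 1):
        lev = j + config.level_offset
        if lev not in coefficients:
            raise ValueError(f"octave {j} (level {lev}) missing from coefficients")
        d = _trim(np.asarray(coefficients[lev], dtype=float), n_b)
        if d.size < config.min_leaders_per_octave:
            raise SignalTooShortError(
                f"only {d.size} coefficients at octave {j}")
        energy = float(np.mean(d ** 2))
        if energy <= 0:
            return float("nan")
        js.append(lev)
        es.append(math.log2(energy))
        ns.append(d.size)
    w = np.asarray(ns, dtype=float) if config.weighted else np.ones(len(ns))
    return _weighted_slope(np.asarray(es), np.asarray(js, dtype=float), w)


def fractal_features(signal: np.ndarray,
                     config: FractalConfig = FractalConfig()) -> FractalFeatures:
    """Full scaling summary of one epoch (c1, c2, chi)."""
    coeffs = dwt_coefficients(signal, config)
    leaders = wavelet_leaders(coeffs, config)
    c1, c2 = log_cumulants(leaders, config)
    chi = dwt_slope(coeffs, config)
    n_oct = config.octave_range[1] - config.octave_range[0] + 1
    return FractalFeatures(c1=c1, c2=c2, dwt_slope=chi, n_octaves_used=n_oct)
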