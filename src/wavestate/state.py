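"""Brain-state classification from field-potential RMS.

Segments of 2 s are summarized by their root-mean-square amplitude; under
urethane the resulting distribution is bimodal and is divided at the saddle
point of a density estimate.  Segments above the criterion are labelled
synchronized, segments at or below it desynchronized.  Normalized power
spectra are estimated from Hamming-windowed 2 s segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "UnimodalDistributionError", "StateSegmentation", "PowerSpectrum",
    "segment_rms", "saddle_criterion", "classify_states", "psd_hamming",
    "band_fraction",
]


class UnimodalDistributionError(ValueError):
    """The RMS distribution has no saddle between two modes."""


@dataclass
class StateSegmentation:
    seg_len: float                  # s
    rms: np.ndarray                 # per-segment RMS
    criterion: float                # RMS threshold at the saddle
    labels: np.ndarray              # 'sync' / 'desync' per segment
    episodes: list = field(default_factory=list)   # (state, start s, dur s)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray               # Hz
    density: np.ndarray             # normalized, integrates to 1
    seg_len: float
    window: str = "hamming"


def segment_rms(signal, rate: float, seg_len: float = 2.0) -> np.ndarray:
    """RMS of consecutive non-overlapping `seg_len` segments.

    A trailing partial segment is dropped; a signal shorter than one
    segment is an error.
    """
    x = np.asarray(signal, dtype=float)
    ns = int(round(seg_len * rate))
    if ns <= 0:
        raise ValueError("seg_len * rate must be positive")
    n_segs = x.size // ns
    if n_segs < 1:
        raise ValueError("signal shorter than one segment")
    segs = x[:n_segs * ns].reshape(n_segs, ns)
    return np.sqrt(np.mean(segs ** 2, axis=1))


def saddle_criterion(rms_values, grid_size: int = 512):
    """Locate the saddle (density minimum between the two modes) of a
    bimodal RMS sample.

    A Gaussian kernel density estimate with Silverman bandwidth is
    evaluated on a grid; the criterion is the density minimum between the
    two tallest modes (plateaus resolved at their midpoint).

    Returns the criterion (float).  Raises
    :class:`UnimodalDistributionError` when no two modes separated by a
    local minimum exist.
    """
    vals = np.asarray(rms_values, dtype=float)
    if vals.size < 100:
        raise ValueError("need at least 100 RMS values")
    kde = spstats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    dens = kde(grid)
    # modes must rise appreciably above their surroundings; incidental
    # density wiggles do not count as a second mode
    peaks, _ = sps.find_peaks(dens, prominence=0.05 * dens.max())
    if len(peaks) < 2:
        raise UnimodalDistributionError("unimodal distribution")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = sorted(top2)
    seg = dens[lo:hi + 1]
    dmin = seg.min()
    at_min = np.flatnonzero(np.isclose(seg, dmin, rtol=0.0, atol=1e-12 * max(dmin, 1.0)))
    mid = (at_min[0] + at_min[-1]) / 2.0
    return float(np.interp(lo + mid, np.arange(grid_size), grid))


def classify_states(rms, criterion: float, seg_len: float = 2.0,
                    t0: float = 0.0) -> StateSegmentation:
    """Label segments and merge consecutive equal labels into episodes.

    A segment is synchronized iff its RMS is strictly above the criterion;
    ties go to desynchronized.
    """
    rms = np.asarray(rms, dtype=float)
    if not np.isfinite(criterion):
        raise ValueError("criterion must be finite")
    labels = np.where(rms > criterion, "sync", "desync")
    episodes = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            episodes.append((str(labels[start]), t0 + start * seg_len,
                             (i - start) * seg_len))
            start = i
    return StateSegmentation(seg_len=seg_len, rms=rms, criterion=criterion,
                             labels=labels, episodes=episodes)


def psd_hamming(signal, rate: float, seg_len: float = 2.0) -> PowerSpectrum:
    """Averaged Hamming-tapered periodograms of non-overlapping `seg_len`
    segments, normalized so the density integrates to one over frequency."""
    x = np.asarray(signal, dtype=float)
    ns = int(round(seg_len * rate))
    if x.size < ns:
        raise ValueError("signal shorter than one segment")
    freqs, dens = sps.welch(x, fs=rate, window="hamming", nperseg=ns,
                            noverlap=0, detrend="constant",
                            scaling="density")
    area = np.trapezoid(dens, freqs)
    if area <= 0:
        raise ValueError("zero-power signal")
    return PowerSpectrum(freqs=freqs, density=dens / area, seg_len=seg_len)


def band_fraction(spectrum: PowerSpectrum, lo: float, hi: float) -> float:
    """Fraction of total power between `lo` and `hi` Hz (trapezoidal)."""
    f, d = spectrum.freqs, spectrum.density
    fine = np.linspace(f[0], f[-1], 8 * f.size)
    di = np.interp(fine, f, d)
    m = (fine >= lo) & (fine <= hi)
    return float(np.trapezoid(di[m], fine[m]) / np.trapezoid(di, fine))
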