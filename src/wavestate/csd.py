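"""Laminar current source density analysis.

The CSD is estimated as the negative second spatial difference of the depth
LFP profile (Vaknin-padded at the boundaries, optional 3-point Hamming
smoothing along depth).  Event triggers come from two state-specific
schemes -- a multi-unit persistence rule for the synchronized state and the
zero phase of the 3-6 Hz Hilbert phase for the desynchronized state --
followed by 1000 ms triggered averaging.  AVREC (average rectified CSD)
traces and the supragranular share of total rectified current are computed
from a 200 ms window around the trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CSDProfile", "TriggerSet", "AvrecResult",
    "csd_transform", "detect_up_transitions", "phase_triggers",
    "triggered_csd_average", "avrec_fraction", "DEFAULT_LAYER_BANDS",
]

DEFAULT_LAYER_BANDS = {"SG": (0, 10), "G": (10, 16), "IG": (16, 32)}


@dataclass
class CSDProfile:
    """Depth x time current source density."""

    csd: np.ndarray
    pitch: float                  # mm
    rate: float                   # Hz
    t: np.ndarray                 # time axis (s); centered for averages
    layer_bands: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_BANDS))
    trigger_count: int = 0

    def __post_init__(self):
        self.csd = np.asarray(self.csd, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.csd.shape[1] != self.t.size:
            raise ValueError("time axis does not match csd")
        if self.layer_bands:
            spans = sorted(self.layer_bands.values())
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                if a1 > b0:
                    raise ValueError("layer bands overlap")


@dataclass
class TriggerSet:
    times: np.ndarray             # s, strictly increasing
    kind: str                     # 'mua_up' or 'phase_zero'
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trigger times must be strictly increasing")

    def __len__(self):
        return self.times.size


@dataclass
class AvrecResult:
    avrec_total: np.ndarray       # mean |CSD| over all depths vs time
    avrec_sg: np.ndarray          # same over supragranular depths
    sg_fraction: float            # SG share of depth-integrated |CSD|
    t: np.ndarray
    window: float                 # s integration window around the trigger

    def __post_init__(self):
        if not 0.0 <= self.sg_fraction <= 1.0:
            raise ValueError("sg_fraction outside [0, 1]")


_SMOOTH3 = np.hamming(3) / np.hamming(3).sum()


def csd_transform(lfp, pitch: float, rate: float, *,
                  conductivity: float | None = None, smooth: bool = False,
                  depths=None, t0: float = 0.0,
                  layer_bands: dict | None = None) -> CSDProfile:
    """Second-spatial-difference CSD of a depth LFP profile.

    ``csd[z] = -(V[z-1] - 2 V[z] + V[z+1]) / pitch**2`` (times the tissue
    conductivity when given, otherwise in arbitrary units).  Boundary
    channels are estimated after duplicating the end channels (Vaknin), so
    the output has as many depths as the input.  ``smooth`` applies a
    3-point Hamming kernel along depth.
    """
    v = np.asarray(lfp, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise ValueError("need at least 3 depth channels")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if depths is not None:
        dz = np.diff(np.asarray(depths, dtype=float))
        if not np.allclose(dz, dz[0], rtol=1e-6):
            raise ValueError("non-uniform channel pitch")
    pad = np.vstack([v[:1], v, v[-1:]])
    csd = -(pad[:-2] - 2.0 * pad[1:-1] + pad[2:]) / pitch ** 2
    if conductivity is not None:
        csd = conductivity * csd
    if smooth:
        csd = np.apply_along_axis(
            lambda col: np.convolve(col, _SMOOTH3, mode="same"), 0, csd)
    t = t0 + np.arange(v.shape[1]) / rate
    return CSDProfile(csd=csd, pitch=pitch, rate=rate, t=t,
                      layer_bands=dict(layer_bands or DEFAULT_LAYER_BANDS))


def detect_up_transitions(mua_times, duration: float | None = None, *,
                          bin: float = 0.005, k_sd: float = 3.0,
                          persist: float = 0.5, baseline: float = 0.5,
                          integrate: float = 0.05) -> TriggerSet:
    """Down->up state transitions from pooled multi-unit activity.

    Spikes from all channels are pooled and binned at `bin` (5 ms); the
    binned counts are integrated over a trailing `integrate` window.  A
    trigger is placed at the first bin whose integrated count exceeds the
    trailing-`baseline` mean by `k_sd` standard deviations and stays above
    that (frozen) threshold for at least `persist`; the next trigger is
    allowed only after the count falls back below threshold.
    """
    pooled = np.concatenate([np.asarray(t, dtype=float) for t in mua_times]) \
        if isinstance(mua_times, (list, tuple)) else np.asarray(mua_times)
    if pooled.size == 0:
        raise ValueError("no spikes")
    if duration is None:
        duration = float(pooled.max()) + bin
    edges = np.arange(0.0, duration + bin, bin)
    counts, _ = np.histogram(pooled, bins=edges)
    ni = max(1, int(round(integrate / bin)))
    kernel = np.ones(ni)
    integ = np.convolve(counts, kernel)[:len(counts)]   # trailing sum
    nb = max(1, int(round(baseline / bin)))
    npers = max(1, int(round(persist / bin)))

    c1 = np.concatenate([[0.0], np.cumsum(integ)])
    c2 = np.concatenate([[0.0], np.cumsum(integ.astype(float) ** 2)])
    times = []
    k = nb
    n = len(integ)
    while k < n - npers:
        mu = (c1[k] - c1[k - nb]) / nb
        var = max((c2[k] - c2[k - nb]) / nb - mu * mu, 0.0)
        thr = mu + k_sd * np.sqrt(var)
        if integ[k] > thr and counts[k] > 0:
            if np.all(integ[k:k + npers] > thr):
                times.append(edges[k])
                j = k + npers
                while j < n and integ[j] > thr:
                    j += 1
                k = j
                continue
        k += 1
    return TriggerSet(times=np.asarray(times), kind="mua_up",
                      params=dict(bin=bin, k_sd=k_sd, persist=persist,
                                  baseline=baseline, integrate=integrate))


def phase_triggers(lfp_channel, rate: float,
                   band: tuple = (3.0, 6.0), *,
                   edge_margin: float = 1.5) -> TriggerSet:
    """Zero-phase triggers from the Hilbert phase of a band-passed trace.

    The channel is filtered forward-backward in `band`, the analytic-signal
    phase computed (cosine convention: phase 0 at local maxima of the
    filtered signal), and a trigger placed at every upward crossing of
    phase zero, i.e. at each oscillation peak.  Triggers within
    `edge_margin` of either end are dropped: the finite-length analytic
    signal is unreliable within a few cycles of the lower band edge.
    """
    x = np.asarray(lfp_channel, dtype=float)
    if x.size < 2 * rate:
        raise ValueError("recording must be at least 2 s")
    if band[1] >= rate / 2 or rate <= 12:
        raise ValueError("band must lie below the Nyquist frequency")
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    phase = np.angle(sps.hilbert(filt))
    ph0, ph1 = phase[:-1], phase[1:]
    cross = np.flatnonzero((ph0 < 0) & (ph1 >= 0) & (ph1 - ph0 < np.pi))
    frac = -ph0[cross] / (ph1[cross] - ph0[cross])
    times = (cross + frac) / rate
    end = x.size / rate
    times = times[(times >= edge_margin) & (times <= end - edge_margin)]
    return TriggerSet(times=times, kind="phase_zero",
                      params=dict(band=tuple(band), edge_margin=edge_margin))


def triggered_csd_average(profile: CSDProfile, triggers: TriggerSet,
                          window: float = 1.0) -> CSDProfile:
    """Mean CSD over `window`-long slices centered on each trigger.

    Triggers closer than half a window to a recording edge are dropped (and
    not counted); averaging zero usable triggers is an error.  The result
    has a centered time axis and records the number of triggers used.
    """
    half = int(round(window * profile.rate / 2))
    n = profile.csd.shape[1]
    t0 = profile.t[0]
    acc = np.zeros((profile.csd.shape[0], 2 * half + 1))
    used = 0
    for tt in triggers.times:
        c = int(round((tt - t0) * profile.rate))
        if c - half < 0 or c + half + 1 > n:
            continue
        acc += profile.csd[:, c - half:c + half + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable triggers inside the recording")
    t = (np.arange(2 * half + 1) - half) / profile.rate
    return CSDProfile(csd=acc / used, pitch=profile.pitch, rate=profile.rate,
                      t=t, layer_bands=dict(profile.layer_bands),
                      trigger_count=used)


def avrec_fraction(avg_csd: CSDProfile, window: float = 0.2) -> AvrecResult:
    """AVREC traces and the supragranular fraction of rectified current.

    ``avrec_total(t)`` is the mean absolute CSD over all depths and
    ``avrec_sg(t)`` the same over the supragranular band.  ``sg_fraction``
    is the depth-summed rectified CSD integrated over a `window`-long
    stretch centered on the trigger, SG channels over all channels, so it
    lies in [0, 1] and matches the printed AVREC_SG/AVREC_total ratios.
    """
    if not avg_csd.layer_bands or "SG" not in avg_csd.layer_bands:
        raise ValueError("layer_bands with an SG band are required")
    sg0, sg1 = avg_csd.layer_bands["SG"]
    r = np.abs(avg_csd.csd)
    avrec_total = r.mean(axis=0)
    avrec_sg = r[sg0:sg1].mean(axis=0)
    c = int(np.argmin(np.abs(avg_csd.t)))
    half = int(round(window * avg_csd.rate / 2))
    lo, hi = max(0, c - half), min(r.shape[1], c + half + 1)
    denom = r[:, lo:hi].sum()
    frac = float(r[sg0:sg1, lo:hi].sum() / denom) if denom > 0 else 0.0
    return AvrecResult(avrec_total=avrec_total, avrec_sg=avrec_sg,
                       sg_fraction=frac, t=avg_csd.t, window=window)
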