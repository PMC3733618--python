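"""Synthetic two-state cortical activity with known ground truth.

Emulates the three recording modalities of the study system so that every
analysis stage can be validated against known parameters:

* ``gen_vsd_recording`` -- optical (VSD-like) frames on a hexagonal detector
  array carrying plane waves of depolarization.  The synchronized preset
  produces sparse, large up-state fronts (spectral power below 3 Hz); the
  desynchronized preset produces a continuous train of low-amplitude ~4 Hz
  oscillatory wave packets, spatially fragmented by per-channel gain jitter.
* ``gen_laminar_session`` -- 32-channel depth LFP built by a declared forward
  model from a ground-truth laminar current source density (CSD) composed of
  layer-confined sink/source dipoles, plus multi-unit spike times.
* ``gen_ecog`` -- a surface field potential alternating between the two
  states, with bimodal segment RMS.

All randomness flows from the ``seed`` argument; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .geometry import ArrayGeometry, hex_array

__all__ = [
    "VSDRecording", "GroundTruth", "LaminarRecording", "ECoGTrace",
    "gen_vsd_recording", "gen_laminar_session", "gen_ecog",
    "SYNC_SPEED", "DESYNC_SPEED", "SYNC_DIRECTION", "DESYNC_DIRECTION",
    "SYNC_SG_FRACTION", "DESYNC_SG_FRACTION",
]

# --- study-condition presets -------------------------------------------------
SYNC_SPEED = 98.0        # mm/s, median lateral propagation speed, synchronized
DESYNC_SPEED = 118.0     # mm/s, desynchronized (~20% faster)
SYNC_DIRECTION = 0.0     # rad; desynchronized preference is 180 deg opposed
DESYNC_DIRECTION = np.pi
SYNC_SG_FRACTION = 0.684     # supragranular share of rectified current
DESYNC_SG_FRACTION = 0.699
DEFAULT_KAPPA = 2.0      # von Mises concentration of wave directions

DEFAULT_VSD_RATE = 1600.0    # Hz (200 ms correlation window = 320 frames)
DEFAULT_SPACING = 0.5        # mm inter-detector spacing (assumed; not printed)
WAVEFRONT_WIDTH = 2.0        # mm spatial width of the depolarization front

GAMMA_SHAPE = 4.0
# median of Gamma(shape=4, scale=1); presets are medians of the speed law
_GAMMA_MEDIAN1 = float(spstats.gamma.ppf(0.5, GAMMA_SHAPE))

_SYNC_DECAY = 0.45       # s, up-state repolarization tail
_SYNC_GAP = (0.9, 1.4)   # s, inter-wave gap, synchronized
_DESYNC_GAP = (0.7, 0.9)     # s, inter-packet onset gap (~1.25 Hz rate)
_DESYNC_F = 4.0          # Hz carrier of desynchronized wave packets
_DESYNC_PACKET = 0.5     # s packet duration (two carrier cycles)
_SYNC_AMP = 1.0          # a.u.
_DESYNC_AMP = 0.25
_FRAG_SD = 0.3           # per-channel multiplicative gain jitter (desync)

SEG_LEN = 2.0            # s, state-segment length used throughout


# --- containers --------------------------------------------------------------

@dataclass
class VSDRecording:
    """Optical frames: (n_frames, n_channels) fluorescence in a.u."""

    data: np.ndarray
    rate: float
    geometry: ArrayGeometry
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be (frames, channels)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.data.shape[1] != self.geometry.n_channels:
            raise ValueError("channel count does not match geometry")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate


@dataclass
class GroundTruth:
    """Simulation ground truth for recovery tests."""

    state_labels: list = field(default_factory=list)   # per 2 s segment
    wave_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    wave_speeds: np.ndarray = field(default_factory=lambda: np.empty(0))
    wave_directions: np.ndarray = field(default_factory=lambda: np.empty(0))
    laminar_sg_fraction: float | None = None

    def __post_init__(self):
        self.wave_times = np.asarray(self.wave_times, dtype=float)
        self.wave_speeds = np.asarray(self.wave_speeds, dtype=float)
        self.wave_directions = np.asarray(self.wave_directions, dtype=float)
        if np.any(self.wave_speeds <= 0):
            raise ValueError("wave speeds must be positive")
        if self.wave_directions.size and (
                self.wave_directions.min() < 0
                or self.wave_directions.max() >= 2 * np.pi):
            raise ValueError("directions must lie in [0, 2*pi)")
        if self.laminar_sg_fraction is not None and not (
                0.0 <= self.laminar_sg_fraction <= 1.0):
            raise ValueError("laminar_sg_fraction must lie in [0, 1]")


@dataclass
class LaminarRecording:
    """Depth LFP (mV), per-channel MUA spike times (s) and true CSD."""

    lfp: np.ndarray            # (n_depths, n_samples)
    mua_times: list            # list of per-channel timestamp arrays
    rate: float
    true_csd: np.ndarray       # (n_depths, n_samples), a.u.
    pitch: float = 0.05        # mm between contacts
    mode: str = "sync"
    up_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    sg_fraction: float | None = None

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.true_csd = np.asarray(self.true_csd, dtype=float)
        if self.lfp.shape != self.true_csd.shape:
            raise ValueError("lfp and true_csd shapes differ")

    @property
    def n_depths(self) -> int:
        return self.lfp.shape[0]

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.rate


@dataclass
class ECoGTrace:
    """Surface field potential (µV) with per-segment ground-truth labels."""

    signal: np.ndarray
    rate: float
    band: tuple = (0.5, 100.0)
    true_state_labels: list = field(default_factory=list)
    seg_len: float = SEG_LEN
    episodes: list = field(default_factory=list)   # (state, start s, dur s)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.rate <= 2 * self.band[1]:
            raise ValueError("sampling rate must exceed twice the band edge")


# --- plane-wave rendering -----------------------------------------------------

def _wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap to [0, 2*pi); guards against the modulo rounding up to 2*pi."""
    w = a % (2 * np.pi)
    return np.where(w >= 2 * np.pi, 0.0, w)

_SYNC_RIPPLE_F = 7.0     # Hz intra-up-state activity riding the decay
_SYNC_RIPPLE_A = 0.25


def _sync_waveform(tau: np.ndarray, front: float) -> np.ndarray:
    """Up-state front: half-sine rise over `front` s, then a decaying tail
    carrying a small oscillatory component (up states are not silent
    plateaus; the ripple keeps the propagating event informative for
    correlation throughout its duration)."""
    w = np.zeros_like(tau)
    rise = (tau >= 0) & (tau < front)
    w[rise] = np.sin(0.5 * np.pi * tau[rise] / front) ** 2
    dec = (tau >= front) & (tau < front + _SYNC_DECAY)
    td = tau[dec] - front
    env = np.cos(0.5 * np.pi * td / _SYNC_DECAY) ** 2
    w[dec] = env * (1.0 + _SYNC_RIPPLE_A * np.sin(2 * np.pi * _SYNC_RIPPLE_F
                                                  * td))
    return w


def _desync_waveform(tau: np.ndarray) -> np.ndarray:
    """Two-cycle 4 Hz packet under a sin^2 envelope."""
    w = np.zeros_like(tau)
    m = (tau >= 0) & (tau < _DESYNC_PACKET)
    env = np.sin(np.pi * tau[m] / _DESYNC_PACKET) ** 2
    w[m] = env * np.sin(2 * np.pi * _DESYNC_F * tau[m])
    return w


def _render_waves(times, speeds, directions, amplitudes, gains, geometry,
                  rate, n_frames, waveform, front_width):
    """Sum rigidly delayed copies of `waveform` over channels.

    Channel c receives the wave with delay (p_c - p_center) . u / speed, so
    the whole waveform (front and tail alike) propagates as a plane wave.
    """
    data = np.zeros((n_frames, geometry.n_channels))
    t = np.arange(n_frames) / rate
    rel = geometry.positions - geometry.center
    for k in range(len(times)):
        u = np.array([np.cos(directions[k]), np.sin(directions[k])])
        delays = rel @ u / speeds[k]
        for c in range(geometry.n_channels):
            tau = t - times[k] - delays[c]
            if waveform == "sync":
                w = _sync_waveform(tau, front_width / speeds[k])
            else:
                w = _desync_waveform(tau)
            data[:, c] += amplitudes[k] * gains[k, c] * w
    return data


def gen_vsd_recording(preset: str, duration: float = 60.0, *,
                      speed_mean: float | None = None,
                      direction_mean: float | None = None,
                      direction_kappa: float = DEFAULT_KAPPA,
                      noise_sd: float = 0.02,
                      seed: int | None = None,
                      geometry: ArrayGeometry | None = None,
                      rate: float = DEFAULT_VSD_RATE,
                      wavefront_width: float = WAVEFRONT_WIDTH,
                      waves: list | None = None):
    """Generate a two-state optical recording of propagating plane waves.

    Parameters
    ----------
    preset
        ``"sync"`` or ``"desync"``.
    duration
        Recording length in s (>= 2 s).
    speed_mean
        Central (median) wave speed in mm/s; defaults to the state preset
        (98 sync, 118 desync).  Per-wave speeds follow a right-skewed
        Gamma(shape 4) law with this median.
    direction_mean, direction_kappa
        von Mises parameters of wave directions; the desynchronized default
        mean is opposed 180 deg to the synchronized one.
    noise_sd
        Additive white detector noise (a.u.).
    waves
        Optional explicit list of ``(time_s, speed_mm_s, direction_rad)``
        tuples overriding the random event train (used for controlled
        injections; an empty list yields a pure-noise recording).

    Returns
    -------
    (VSDRecording, GroundTruth)
    """
    if preset not in ("sync", "desync"):
        raise ValueError(f"unknown preset {preset!r}")
    if duration < 2.0:
        raise ValueError("duration must be at least 2 s")
    if speed_mean is None:
        speed_mean = SYNC_SPEED if preset == "sync" else DESYNC_SPEED
    if speed_mean <= 0:
        raise ValueError("speed_mean must be positive")
    if direction_mean is None:
        direction_mean = SYNC_DIRECTION if preset == "sync" else DESYNC_DIRECTION
    if geometry is None:
        geometry = hex_array(spacing=DEFAULT_SPACING)
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * rate))

    amp = _SYNC_AMP if preset == "sync" else _DESYNC_AMP
    gap = _SYNC_GAP if preset == "sync" else _DESYNC_GAP
    margin = (wavefront_width / speed_mean + _SYNC_DECAY if preset == "sync"
              else _DESYNC_PACKET)

    if waves is not None:
        times = np.array([w[0] for w in waves], dtype=float)
        speeds = np.array([w[1] for w in waves], dtype=float)
        dirs = _wrap_angles(np.array([w[2] for w in waves], dtype=float))
    else:
        times = []
        t = rng.uniform(0.3, 0.3 + gap[1] - gap[0])
        while t < duration - margin:
            times.append(t)
            t += rng.uniform(*gap)
        times = np.asarray(times)
        scale = speed_mean / _GAMMA_MEDIAN1
        speeds = rng.gamma(GAMMA_SHAPE, scale=scale, size=len(times))
        dirs = _wrap_angles(rng.vonmises(direction_mean, direction_kappa,
                                         size=len(times)))

    n_waves = len(times)
    if preset == "desync" and n_waves:
        gains = np.clip(
            1.0 + _FRAG_SD * rng.standard_normal((n_waves, geometry.n_channels)),
            0.0, None)
    else:
        gains = np.ones((n_waves, geometry.n_channels))
    amplitudes = np.full(n_waves, amp)

    data = _render_waves(times, speeds, dirs, amplitudes, gains, geometry,
                         rate, n_frames, preset, wavefront_width)
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)

    n_segs = int(duration // SEG_LEN)
    truth = GroundTruth(state_labels=[preset] * n_segs,
                        wave_times=times, wave_speeds=speeds,
                        wave_directions=dirs)
    rec = VSDRecording(data=data.astype(np.float32), rate=rate,
                       geometry=geometry)
    return rec, truth


# --- laminar session ----------------------------------------------------------

N_DEPTHS = 32
LAYER_BANDS = {"SG": (0, 10), "G": (10, 16), "IG": (16, 32)}   # channel ranges
_LAMINAR_RATE = 1000.0
_CSD_AMP = 1200.0         # a.u.; forward-modelled LFP comes out ~0.5 mV RMS
_UP_MUA_RATE = 20.0       # Hz per channel during up states
_DOWN_MUA_RATE = 0.5      # Hz per channel between up states
_UP_MUA_DUR = 0.65        # s of elevated firing per up state
_DESYNC_OSC_F = 4.25      # Hz laminar oscillation, desynchronized mode
_ENV_SIGMA = 0.05         # s width of the up-state CSD transient


def _cos_bump(n: int, center: float, half_width: float) -> np.ndarray:
    """Compact cosine^2 bump over depth indices, zero outside the support."""
    z = np.arange(n, dtype=float)
    x = (z - center) / half_width
    out = np.where(np.abs(x) < 1.0, np.cos(0.5 * np.pi * x) ** 2, 0.0)
    return out


def _dipole(n: int, sink_c: float, src_c: float, hw: float) -> np.ndarray:
    """Sink/source pair with disjoint supports; sums to 0, |.| sums to 1."""
    sink = _cos_bump(n, sink_c, hw)
    src = _cos_bump(n, src_c, hw)
    sink *= 0.5 / sink.sum()
    src *= 0.5 / src.sum()
    return src - sink


def _lfp_forward(csd: np.ndarray, pitch: float) -> np.ndarray:
    """Forward model: the exact discrete inverse of the second-difference
    CSD estimator.  V[z+1] = 2 V[z] - V[z-1] - pitch^2 * C[z], V[0]=V[1]=0,
    then the depth mean is removed at every sample."""
    n, m = csd.shape
    v = np.zeros((n, m))
    h2 = pitch * pitch
    for z in range(1, n - 1):
        v[z + 1] = 2.0 * v[z] - v[z - 1] - h2 * csd[z]
    return v - v.mean(axis=0, keepdims=True)


def gen_laminar_session(duration: float = 60.0,
                        sg_fraction: float | None = None,
                        up_rate: float = 0.8,
                        seed: int | None = None, *,
                        mode: str = "sync",
                        rate: float = _LAMINAR_RATE,
                        noise_sd: float = 0.005) -> LaminarRecording:
    """Generate a laminar (32-contact, 50 µm pitch) session.

    The ground-truth CSD is a fixed depth profile -- a supragranular dipole
    carrying `sg_fraction` of the total rectified current, the remainder
    split equally between granular and infragranular dipoles -- driven by a
    temporal envelope: Gaussian transients at up-state onsets (sync mode) or
    a continuous 4.25 Hz oscillation (desync mode).  The LFP is the declared
    double-integration forward model of that CSD plus white noise; MUA rates
    are elevated ~40-fold for 650 ms at each up state (sync) or modulated
    sinusoidally (desync).
    """
    if mode not in ("sync", "desync"):
        raise ValueError(f"unknown mode {mode!r}")
    if sg_fraction is None:
        sg_fraction = SYNC_SG_FRACTION if mode == "sync" else DESYNC_SG_FRACTION
    if not 0.0 <= sg_fraction <= 1.0:
        raise ValueError("sg_fraction must lie in [0, 1]")
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    # depth profile: dipoles strictly inside their layer bands
    p_sg = _dipole(N_DEPTHS, sink_c=3.0, src_c=7.0, hw=2.0)
    p_g = _dipole(N_DEPTHS, sink_c=11.0, src_c=14.0, hw=1.5)
    p_ig = _dipole(N_DEPTHS, sink_c=19.0, src_c=25.0, hw=2.5)
    profile = (sg_fraction * p_sg
               + 0.5 * (1.0 - sg_fraction) * (p_g + p_ig)) * _CSD_AMP

    if mode == "sync":
        up_times = []
        tt = 1.0 + rng.uniform(0.0, 0.5)
        mean_iei = 1.0 / up_rate
        while tt < duration - 1.0:
            up_times.append(tt)
            tt += mean_iei * rng.uniform(0.8, 1.2)
        up_times = np.asarray(up_times)
        env = np.zeros(n)
        for tk in up_times:
            lo = max(0, int((tk - 4 * _ENV_SIGMA) * rate))
            hi = min(n, int((tk + 4 * _ENV_SIGMA) * rate))
            env[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tk) / _ENV_SIGMA) ** 2)
    else:
        up_times = np.empty(0)
        env = np.sin(2 * np.pi * _DESYNC_OSC_F * t)

    csd = profile[:, None] * env[None, :]
    lfp = _lfp_forward(csd, pitch=0.05)
    if noise_sd > 0:
        lfp = lfp + noise_sd * rng.standard_normal(lfp.shape)

    mua = []
    for _ch in range(N_DEPTHS):
        if mode == "sync":
            n_base = rng.poisson(_DOWN_MUA_RATE * duration)
            times = [rng.uniform(0.0, duration, size=n_base)]
            for tk in up_times:
                n_up = rng.poisson((_UP_MUA_RATE - _DOWN_MUA_RATE) * _UP_MUA_DUR)
                times.append(tk + rng.uniform(0.0, _UP_MUA_DUR, size=n_up))
            ch_times = np.sort(np.concatenate(times))
        else:
            # sinusoidally modulated rate via thinning
            r0, depth_mod = 5.0, 0.9
            rmax = r0 * (1 + depth_mod)
            cand = np.sort(rng.uniform(0.0, duration,
                                       size=rng.poisson(rmax * duration)))
            accept = rng.uniform(0.0, 1.0, size=cand.size) < (
                r0 * (1 + depth_mod * np.sin(2 * np.pi * _DESYNC_OSC_F * cand))
                / rmax)
            ch_times = cand[accept]
        mua.append(ch_times)

    return LaminarRecording(lfp=lfp, mua_times=mua, rate=rate, true_csd=csd,
                            pitch=0.05, mode=mode, up_times=up_times,
                            sg_fraction=sg_fraction)


# --- ECoG ---------------------------------------------------------------------

_ECOG_RATE = 500.0
_ECOG_SYNC_RMS = 200.0    # µV
_ECOG_RATIO = 4.0         # sync : desync amplitude ratio


def _episode_plan(duration, lo, hi, seg_len, rng):
    """Alternating episode durations, multiples of seg_len, inside [lo, hi]."""
    durs = []
    total = 0.0
    while total < duration:
        d = seg_len * round(rng.uniform(lo, hi) / seg_len)
        d = min(max(d, lo), hi)
        durs.append(d)
        total += d
    excess = total - duration
    if excess > 0:
        last = durs.pop()
        rem = last - excess
        if rem >= lo:
            durs.append(rem)
        elif rem > 0:
            if durs and durs[-1] + rem <= hi:
                durs[-1] += rem
            else:
                tot = durs.pop() + rem
                durs.extend([tot - lo, lo])
    return durs


def gen_ecog(duration: float = 600.0,
             episode_dur_range: tuple = (10.0, 60.0),
             seed: int | None = None, *,
             rate: float = _ECOG_RATE,
             amplitude_ratio: float = _ECOG_RATIO,
             seg_len: float = SEG_LEN) -> ECoGTrace:
    """Generate an ECoG alternating between synchronized and desynchronized
    episodes.

    Episode durations are uniform in `episode_dur_range` (a desk-scale
    stand-in for the minutes-long episodes seen in vivo), rounded to whole
    2 s segments so every segment has a well-defined state.  Synchronized
    episodes carry band-limited 0.5-3 Hz activity at ~200 µV RMS; the
    desynchronized episodes carry 3-6 Hz activity (spectral peak near 4 Hz)
    at 200/amplitude_ratio µV RMS.
    """
    lo, hi = episode_dur_range
    if not (0 < lo < hi):
        raise ValueError("invalid episode duration range")
    if duration <= 2 * hi:
        raise ValueError("duration must exceed twice the max episode length")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))

    slow = sps.sosfiltfilt(
        sps.butter(4, (0.5, 3.0), btype="bandpass", fs=rate, output="sos"),
        rng.standard_normal(n))
    fast = sps.sosfiltfilt(
        sps.butter(4, (3.0, 6.0), btype="bandpass", fs=rate, output="sos"),
        rng.standard_normal(n))
    slow *= _ECOG_SYNC_RMS / np.sqrt(np.mean(slow ** 2))
    fast *= (_ECOG_SYNC_RMS / amplitude_ratio) / np.sqrt(np.mean(fast ** 2))

    durs = _episode_plan(duration, lo, hi, seg_len, rng)
    first = rng.integers(2)
    signal = np.zeros(n)
    labels, episodes = [], []
    start = 0.0
    for k, d in enumerate(durs):
        state = ("sync", "desync")[(first + k) % 2]
        i0, i1 = int(round(start * rate)), int(round((start + d) * rate))
        i1 = min(i1, n)
        signal[i0:i1] = (slow if state == "sync" else fast)[i0:i1]
        episodes.append((state, start, d))
        labels.extend([state] * int(round(d / seg_len)))
        start += d
    signal += 5.0 * rng.standard_normal(n)   # broadband floor

    n_segs = int(duration // seg_len)
    return ECoGTrace(signal=signal, rate=rate, band=(0.5, 100.0),
                     true_state_labels=labels[:n_segs], seg_len=seg_len,
                     episodes=episodes)
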