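"""Temporospatial flow detection of propagating waves.

A 200 ms correlation window slides in 4-frame steps over the band-passed
(0.5-35 Hz) optical signal.  In each window, the lag that maximizes the
normalized cross-correlation (within +/-25 ms, refined to sub-frame
precision by a 3-point parabola) is extracted for every nearest-neighbor
detector pair of the analysis ring.  The spatial pattern of pair lags is
then matched to templates: a uniform lag gradient (translation wave, whose
gradient gives direction and speed), a radial pattern (source wave) and a
rotational pattern (spiral wave).  Flow reliability is the cosine
similarity between the observed pair-lag vector and the best template's
ideal lags; windows below 0.85 are discarded and runs of overlapping
above-threshold windows are merged into single events at the reliability
peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .geometry import ArrayGeometry
from .synth import VSDRecording
from .state import StateSegmentation

__all__ = [
    "FlowConfig", "LagField", "FlowEvent",
    "bandpass_vsd", "pairwise_lags", "flow_from_lags", "detect_flow_events",
]

_TEMPLATES = ("translation", "source", "spiral")


@dataclass(frozen=True)
class FlowConfig:
    """Parameters of the temporospatial correlation algorithm."""

    corr_window: float = 0.200      # s correlation window (320 frames)
    max_shift: float = 0.025        # s maximum lag searched (40 frames)
    step: int = 4                   # frames between successive windows
    band: tuple = (0.5, 35.0)       # Hz band-pass before flow detection
    reliability_min: float = 0.85   # template-match cut for retained events
    corr_min: float = 0.5           # minimum pair peak correlation
    sharp_min: float = 0.15         # minimum peak-to-trough correlation drop
    min_pairs: int = 10             # valid pairs required for a candidate
    amp_min: float = 0.1            # window RMS floor, fraction of the
                                    # recording's maximum window RMS
    merge_gap: float = 0.2          # s; above-threshold windows closer than
                                    # this belong to the same event
    echo_window: float = 0.6        # s; faint satellites of a much stronger
    echo_ratio: float = 2.5         # event within echo_window are dropped
    templates: tuple = _TEMPLATES

    def __post_init__(self):
        if not self.max_shift < self.corr_window / 2:
            raise ValueError("max_shift must be below corr_window / 2")
        if not 0.0 <= self.reliability_min <= 1.0:
            raise ValueError("reliability_min must lie in [0, 1]")
        if self.step < 1:
            raise ValueError("step must be a positive frame count")
        if self.min_pairs < 4:
            raise ValueError("min_pairs must be at least 4")
        unknown = set(self.templates) - set(_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates: {sorted(unknown)}")


@dataclass
class LagField:
    """Per-pair best-correlation lags inside one window."""

    pairs: list                      # [(i, j), ...]
    lags: np.ndarray                 # s; positive = j lags i
    corrs: np.ndarray                # peak correlation per pair
    valid: np.ndarray                # pair usable (finite variance)
    clipped: np.ndarray              # |lag| hit the max_shift boundary


@dataclass
class FlowEvent:
    t: float                         # window-center time (s)
    speed: float                     # mm/s (translation events; else nan)
    direction: float                 # rad in [0, 2*pi) (translation; else nan)
    pattern: str                     # 'translation' | 'source' | 'spiral'
    reliability: float
    state: str = "unknown"


def bandpass_vsd(rec: VSDRecording, band: tuple = (0.5, 35.0)) -> VSDRecording:
    """Zero-phase channelwise band-pass; removes DC by construction."""
    if band[1] >= rec.rate / 2:
        raise ValueError("band must lie below the Nyquist frequency")
    sos = sps.butter(4, band, btype="bandpass", fs=rec.rate, output="sos")
    data = sps.sosfiltfilt(sos, np.asarray(rec.data, dtype=float), axis=0)
    return VSDRecording(data=data, rate=rec.rate, geometry=rec.geometry,
                        t0=rec.t0)


# --- single-window lags -------------------------------------------------------

def _parabolic(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def pairwise_lags(window_data, geometry: ArrayGeometry, cfg: FlowConfig,
                  rate: float, pairs=None) -> LagField:
    """Best-correlation lags for nearest-neighbor pairs in one window.

    `window_data` is (frames, channels) of exactly ``corr_window * rate``
    frames; correlations at non-zero shift use the overlapping parts of the
    two traces.  Positive lag means channel j lags channel i.  Pairs whose
    correlation function is nearly flat over the shift range (peak-to-trough
    drop below ``cfg.sharp_min``) carry no timing information and are
    marked invalid, as are zero-variance traces.
    """
    x = np.asarray(window_data, dtype=float)
    w = int(round(cfg.corr_window * rate))
    if x.shape[0] != w:
        raise ValueError("window length must equal corr_window * rate")
    s_max = int(round(cfg.max_shift * rate))
    if pairs is None:
        pairs = geometry.neighbor_pairs(geometry.ring_channels)
    n_p = len(pairs)
    lags = np.full(n_p, np.nan)
    corrs = np.full(n_p, np.nan)
    valid = np.zeros(n_p, dtype=bool)
    clipped = np.zeros(n_p, dtype=bool)
    shifts = np.arange(-s_max, s_max + 1)
    for k, (i, j) in enumerate(pairs):
        xi, xj = x[:, i], x[:, j]
        if np.var(xi) <= 1e-30 or np.var(xj) <= 1e-30:
            continue
        r = np.empty(shifts.size)
        for si, s in enumerate(shifts):
            if s >= 0:
                a, b = xi[:w - s], xj[s:]
            else:
                a, b = xi[-s:], xj[:w + s]
            am, bm = a - a.mean(), b - b.mean()
            den = np.sqrt((am @ am) * (bm @ bm))
            r[si] = (am @ bm) / den if den > 0 else 0.0
        kmax = int(np.argmax(r))
        valid[k] = (r[kmax] - r.min()) >= cfg.sharp_min
        corrs[k] = r[kmax]
        if kmax in (0, shifts.size - 1):
            clipped[k] = True
            lags[k] = shifts[kmax] / rate
        else:
            delta = _parabolic(r[kmax - 1], r[kmax], r[kmax + 1])
            lags[k] = (shifts[kmax] + delta) / rate
    return LagField(pairs=list(pairs), lags=lags, corrs=corrs,
                    valid=valid, clipped=clipped)


# --- template matching --------------------------------------------------------

def _wrap_pi(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def _wrap_2pi(a):
    """Wrap to [0, 2*pi); guards against the modulo rounding to 2*pi."""
    w = np.asarray(a) % (2 * np.pi)
    return np.where(w >= 2 * np.pi, 0.0, w)


def _pair_features(pairs, geometry: ArrayGeometry):
    """Offset matrix D (pairs x 2, mm), radial and azimuthal feature
    vectors about the ring center, for template matching."""
    pos = geometry.positions
    c = geometry.center
    d = np.array([pos[j] - pos[i] for i, j in pairs])
    rad = np.array([np.linalg.norm(pos[j] - c) - np.linalg.norm(pos[i] - c)
                    for i, j in pairs])
    azi = np.zeros(len(pairs))
    for k, (i, j) in enumerate(pairs):
        ri = np.linalg.norm(pos[i] - c)
        rj = np.linalg.norm(pos[j] - c)
        if ri < 1e-9 or rj < 1e-9:
            azi[k] = 0.0          # pairs through the center carry no rotation
        else:
            pi_ = np.arctan2(*(pos[i] - c)[::-1])
            pj_ = np.arctan2(*(pos[j] - c)[::-1])
            azi[k] = _wrap_pi(pj_ - pi_)
    return d, rad, azi


def _scalar_cos(l, f):
    """Cosine between l and its projection on span{f}."""
    ff = f @ f
    if ff <= 0:
        return 0.0
    proj = (l @ f) / ff * f
    np_ = np.linalg.norm(proj)
    nl = np.linalg.norm(l)
    if np_ <= 0 or nl <= 0:
        return 0.0
    return float(np.clip((l @ proj) / (nl * np_), 0.0, 1.0))


def flow_from_lags(lagfield: LagField, geometry: ArrayGeometry,
                   cfg: FlowConfig) -> FlowEvent | None:
    """Aggregate pair lags into one propagation-pattern candidate.

    Fits the lag gradient g (s/mm) by least squares over pair offsets; the
    translation template is the uniform gradient (direction ``atan2(g_y,
    g_x)``, speed ``1 / ||g||``), the source template a radial lag pattern
    about the ring center, the spiral template a rotational one.
    Reliability is the best template's cosine match to the observed lags.
    Returns None when fewer than 4 valid pairs remain.
    """
    use = lagfield.valid & ~lagfield.clipped & (lagfield.corrs >= cfg.corr_min)
    if use.sum() < max(4, cfg.min_pairs):
        return None
    pairs = [p for p, u in zip(lagfield.pairs, use) if u]
    l = lagfield.lags[use]
    d, rad, azi = _pair_features(pairs, geometry)

    nl = np.linalg.norm(l)
    scores = {}
    g = np.linalg.lstsq(d, l, rcond=None)[0]
    gn = np.linalg.norm(g)
    if "translation" in cfg.templates:
        if gn > 1e-12 and nl > 0:
            ideal = d @ g
            ni = np.linalg.norm(ideal)
            scores["translation"] = float(
                np.clip((l @ ideal) / (nl * ni), 0.0, 1.0)) if ni > 0 else 0.0
        else:
            scores["translation"] = 0.0
    if "source" in cfg.templates:
        scores["source"] = _scalar_cos(l, rad)
    if "spiral" in cfg.templates:
        scores["spiral"] = _scalar_cos(l, azi)
    if not scores:
        return None
    pattern = max(_TEMPLATES, key=lambda k: (scores.get(k, -1.0),
                                             -_TEMPLATES.index(k)))
    reliability = scores[pattern]
    if pattern == "translation" and gn > 1e-12:
        speed = 1.0 / gn
        direction = float(_wrap_2pi(np.arctan2(g[1], g[0])))
    else:
        speed, direction = np.nan, np.nan
    return FlowEvent(t=np.nan, speed=speed, direction=direction,
                     pattern=pattern, reliability=reliability)


# --- sliding detection --------------------------------------------------------

def _sliding_pair_lags(x, y, starts, w, s_max, rate, sharp_min=0.15):
    """Vectorized normalized cross-correlation peak per window start.

    Windows of `w` frames on x against equally long windows of y shifted by
    -s_max..+s_max frames.  Returns (lags s, peak corrs, valid, clipped);
    pairs with a nearly flat correlation function (peak-to-trough drop
    below `sharp_min`) are invalid.
    """
    n = x.size
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    sx = cx[starts + w] - cx[starts]
    vx = (cx2[starts + w] - cx2[starts]) - sx * sx / w
    shifts = np.arange(-s_max, s_max + 1)
    r = np.empty((shifts.size, starts.size))
    for si, s in enumerate(shifts):
        st = starts + s
        sy = cy[st + w] - cy[st]
        vy = (cy2[st + w] - cy2[st]) - sy * sy / w
        prod = x[max(0, -s):n - max(0, s)] * y[max(0, s):n + min(0, s)]
        cz = np.concatenate([[0.0], np.cumsum(prod)])
        # prod[t] = x[t0] * y[t0 + s] with t0 = t + max(0, -s)
        pst = starts - max(0, -s)
        sxy = cz[pst + w] - cz[pst]
        cov = sxy - sx * sy / w
        den = np.sqrt(np.clip(vx, 0.0, None) * np.clip(vy, 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            r[si] = np.where(den > 1e-30, cov / den, 0.0)
    kmax = np.argmax(r, axis=0)
    cols = np.arange(starts.size)
    peak = r[kmax, cols]
    sharp = peak - r.min(axis=0)
    clipped = (kmax == 0) | (kmax == shifts.size - 1)
    km = np.clip(kmax, 1, shifts.size - 2)
    cm1, c0, cp1 = r[km - 1, cols], r[km, cols], r[km + 1, cols]
    denom = cm1 - 2.0 * c0 + cp1
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(denom < 0, 0.5 * (cm1 - cp1) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    lag = np.where(clipped, shifts[kmax], km - s_max + delta) / rate
    valid = (np.clip(vx, 0.0, None) > 1e-30) & (sharp >= sharp_min)
    st = starts + shifts[kmax]
    vy_at = (cy2[st + w] - cy2[st]) - (cy[st + w] - cy[st]) ** 2 / w
    valid &= vy_at > 1e-30
    return lag, peak, valid, clipped


def detect_flow_events(rec: VSDRecording, cfg: FlowConfig | None = None,
                       states: StateSegmentation | None = None) -> list:
    """Detect propagating-wave events in a band-passed optical recording.

    Slides the correlation window in `cfg.step`-frame steps, extracts pair
    lags for the analysis ring, matches templates, keeps windows with
    reliability >= `cfg.reliability_min`, and merges runs of overlapping
    above-threshold windows into single events at the reliability peak
    (earliest window on ties).  When a `states` segmentation is given each
    event is labelled with the state of its 2 s segment.
    """
    if cfg is None:
        cfg = FlowConfig()
    if rec.duration < cfg.corr_window:
        raise ValueError("recording shorter than the correlation window")
    filt = bandpass_vsd(rec, cfg.band)
    rate = rec.rate
    w = int(round(cfg.corr_window * rate))
    s_max = int(round(cfg.max_shift * rate))
    n = filt.n_frames
    if n < w + 2 * s_max + 1:
        return []
    starts = np.arange(s_max, n - w - s_max + 1, cfg.step)
    geometry = rec.geometry
    pairs = geometry.neighbor_pairs(geometry.ring_channels)
    n_p, n_w = len(pairs), starts.size

    lags = np.empty((n_w, n_p))
    corrs = np.empty((n_w, n_p))
    valid = np.empty((n_w, n_p), dtype=bool)
    clipped = np.empty((n_w, n_p), dtype=bool)
    data = np.ascontiguousarray(filt.data)
    for k, (i, j) in enumerate(pairs):
        lags[:, k], corrs[:, k], valid[:, k], clipped[:, k] = \
            _sliding_pair_lags(data[:, i], data[:, j], starts, w, s_max,
                               rate, cfg.sharp_min)

    # amplitude gate: normalized correlation is scale-free, so windows
    # holding only a faint image of a wave (filter tails, noise) would
    # otherwise match templates perfectly; require the pooled window RMS to
    # reach a fraction of the recording's typical active level
    ring = list(geometry.ring_channels)
    sq = np.concatenate([[0.0], np.cumsum((data[:, ring] ** 2).sum(axis=1))])
    win_rms = np.sqrt((sq[starts + w] - sq[starts]) / (w * len(ring)))
    amp_floor = cfg.amp_min * win_rms.max()

    use = valid & ~clipped & (corrs >= cfg.corr_min)
    use &= (win_rms >= amp_floor)[:, None]
    d, rad, azi = _pair_features(pairs, geometry)
    full = use.all(axis=1)

    rel = np.zeros(n_w)
    speed = np.full(n_w, np.nan)
    direction = np.full(n_w, np.nan)
    pattern = np.full(n_w, "", dtype=object)

    if full.any():
        lf = lags[full]                                    # (m, n_p)
        g = lf @ np.linalg.pinv(d).T                       # (m, 2)
        ideal = g @ d.T
        nl = np.linalg.norm(lf, axis=1)
        ni = np.linalg.norm(ideal, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_t = np.clip(np.einsum("ij,ij->i", lf, ideal)
                            / np.where(nl * ni > 0, nl * ni, np.inf), 0.0, 1.0)

        def scalar_cos_batch(f):
            ff = f @ f
            if ff <= 0:
                return np.zeros(lf.shape[0])
            coef = (lf @ f) / ff
            proj_n = np.abs(coef) * np.sqrt(ff)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.clip(coef * (lf @ f)
                               / np.where(nl * proj_n > 0, nl * proj_n,
                                          np.inf), 0.0, 1.0)

        cos_s = scalar_cos_batch(rad)
        cos_sp = scalar_cos_batch(azi)
        stack = []
        names = []
        for nm, arr in (("translation", cos_t), ("source", cos_s),
                        ("spiral", cos_sp)):
            if nm in cfg.templates:
                stack.append(arr)
                names.append(nm)
        smat = np.vstack(stack)
        best = np.argmax(smat, axis=0)
        rel[full] = smat[best, np.arange(lf.shape[0])]
        gn = np.linalg.norm(g, axis=1)
        is_t = (np.array(names)[best] == "translation") & (gn > 1e-12)
        sp = np.where(is_t, 1.0 / np.where(gn > 1e-12, gn, np.inf), np.nan)
        di = np.where(is_t, _wrap_2pi(np.arctan2(g[:, 1], g[:, 0])), np.nan)
        speed[full] = sp
        direction[full] = di
        pattern[full] = np.array(names, dtype=object)[best]

    partial = np.flatnonzero(~full & (use.sum(axis=1) >= max(4, cfg.min_pairs)))
    for wi in partial:
        lfld = LagField(pairs=pairs, lags=lags[wi], corrs=corrs[wi],
                        valid=valid[wi], clipped=clipped[wi])
        cand = flow_from_lags(lfld, geometry, cfg)
        if cand is not None:
            rel[wi] = cand.reliability
            speed[wi] = cand.speed
            direction[wi] = cand.direction
            pattern[wi] = cand.pattern

    # run segmentation uses the 0.85 retention cut (or lower, if the caller
    # asks for less); the reliability_min filter is applied to run peaks, so
    # tightening it can only remove events, never split runs into more
    run_thr = min(cfg.reliability_min, 0.85)
    above = np.flatnonzero(rel >= run_thr)
    events: list[FlowEvent] = []
    if above.size == 0:
        return events
    gaps = np.diff(starts[above])
    gap_frames = max(w, int(round(cfg.merge_gap * rate)))
    breaks = np.flatnonzero(gaps >= gap_frames) + 1
    bounds = np.concatenate([[0], breaks, [above.size]])
    amps = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        idx = above[b0:b1]
        best = idx[int(np.argmax(rel[idx]))]
        if rel[best] < cfg.reliability_min:
            continue
        t_evt = rec.t0 + (starts[best] + w / 2) / rate
        st = "unknown"
        if states is not None:
            seg = int((t_evt - rec.t0) // states.seg_len)
            if 0 <= seg < len(states.labels):
                st = str(states.labels[seg])
        events.append(FlowEvent(t=float(t_evt), speed=float(speed[best]),
                                direction=float(direction[best]),
                                pattern=str(pattern[best]),
                                reliability=float(rel[best]), state=st))
        amps.append(float(win_rms[idx].max()))

    # temporal non-maximum suppression: a much weaker event right next to a
    # strong one is a residual image of the same wave (filter tails), not a
    # new wave; genuine neighbors have comparable amplitude
    keep = []
    for k, ev in enumerate(events):
        echo = any(abs(events[m].t - ev.t) < cfg.echo_window
                   and amps[m] >= cfg.echo_ratio * amps[k]
                   for m in range(len(events)) if m != k)
        if not echo:
            keep.append(ev)
    return keep
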