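"""End-to-end pipeline: simulate -> classify -> flow per state -> statistics.

`run_pipeline` ties the stages together on synthetic sessions and returns a
JSON-serializable report: state-classification accuracy, per-session median
propagation speeds per state with the matched-pairs comparison, pooled
direction statistics (rose histograms and the two-sample Kuiper test) and,
optionally, the laminar AVREC supragranular fractions for both triggering
schemes.  All randomness flows from the named seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth, state, csd, flow, circstats

log = logging.getLogger("wavestate")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Defaults for every stage; unknown keys are rejected on load."""

    seed: int = 1
    # state classification
    seg_len: float = 2.0
    ecog_duration: float = 600.0
    episode_dur_range: tuple = (10.0, 60.0)
    # optical sessions
    n_sessions: int = 9
    session_duration: float = 60.0
    spacing: float = 0.5
    vsd_noise_sd: float = 0.02
    inject_waves: bool = True
    # flow detection
    corr_window: float = 0.2
    max_shift: float = 0.025
    step: int = 4
    vsd_band: tuple = (0.5, 35.0)
    reliability_min: float = 0.85
    # laminar stage
    include_laminar: bool = True
    n_laminar: int = 10
    laminar_duration: float = 60.0
    mua_bin: float = 0.005
    k_sd: float = 3.0
    persist: float = 0.5
    phase_band: tuple = (3.0, 6.0)
    csd_window: float = 1.0
    avrec_window: float = 0.2
    # metadata only: acquisition bands of the emulated hardware
    lfp_band: tuple = (1.0, 150.0)
    ecog_band: tuple = (0.5, 100.0)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def validate(self):
        if self.session_duration < 2.0 or self.ecog_duration <= 0:
            raise ValueError("invalid durations")
        if self.n_sessions < 1:
            raise ValueError("need at least one session")
        flow.FlowConfig(corr_window=self.corr_window,
                        max_shift=self.max_shift, step=self.step,
                        band=self.vsd_band,
                        reliability_min=self.reliability_min)

    def flow_config(self) -> flow.FlowConfig:
        return flow.FlowConfig(corr_window=self.corr_window,
                               max_shift=self.max_shift, step=self.step,
                               band=self.vsd_band,
                               reliability_min=self.reliability_min)


def _classify_stage(config: PipelineConfig):
    ecog = synth.gen_ecog(config.ecog_duration, config.episode_dur_range,
                          seed=config.seed, seg_len=config.seg_len)
    rms = state.segment_rms(ecog.signal, ecog.rate, config.seg_len)
    criterion = state.saddle_criterion(rms)
    seg = state.classify_states(rms, criterion, config.seg_len)
    truth = np.asarray(ecog.true_state_labels)
    acc = float(np.mean(seg.labels[:truth.size] == truth))
    log.info("classify: criterion=%.3g accuracy=%.4f over %d segments",
             criterion, acc, truth.size)
    return ecog, seg, acc


def _flow_stage(config: PipelineConfig):
    fcfg = config.flow_config()
    rows = []
    for i in range(config.n_sessions):
        for preset in ("sync", "desync"):
            waves = None if config.inject_waves else []
            rec, truth = synth.gen_vsd_recording(
                preset, config.session_duration, seed=config.seed + i,
                noise_sd=config.vsd_noise_sd,
                geometry=synth.hex_array(spacing=config.spacing),
                waves=waves)
            events = flow.detect_flow_events(rec, fcfg)
            log.info("flow: session=%d state=%s events=%d (injected=%d)",
                     i, preset, len(events), truth.wave_times.size)
            for ev in events:
                rows.append(dict(session=i, state=preset, t_s=ev.t,
                                 speed_mm_s=ev.speed,
                                 direction_rad=ev.direction,
                                 pattern=ev.pattern,
                                 reliability=ev.reliability))
    return pd.DataFrame(rows, columns=["session", "state", "t_s",
                                       "speed_mm_s", "direction_rad",
                                       "pattern", "reliability"])


def _stats_stage(events: pd.DataFrame):
    out = {"per_state": {}, "per_session_median_speed": {}}
    trans = events[events.pattern == "translation"]
    medians = {}
    for st in ("sync", "desync"):
        sub = trans[trans.state == st]
        med = sub.groupby("session").speed_mm_s.median()
        medians[st] = med
        out["per_session_median_speed"][st] = med.to_dict()
        entry = {"n_events": int(len(sub)),
                 "median_speed_mm_s": (float(sub.speed_mm_s.median())
                                       if len(sub) else None),
                 "mean_of_session_medians_mm_s": (float(med.mean())
                                                  if len(med) else None)}
        if len(sub):
            rh = circstats.rose_histogram(sub.direction_rad.to_numpy())
            entry["rose_counts"] = rh.counts.tolist()
            entry["rose_normalized"] = rh.normalized.tolist()
        out["per_state"][st] = entry
    both = medians["sync"].index.intersection(medians["desync"].index)
    if len(both) >= 5:
        stat, p = circstats.wilcoxon_matched_pairs(
            medians["desync"][both], medians["sync"][both])
        out["wilcoxon"] = {"statistic": stat, "p_value": p, "n_pairs": len(both)}
        ms, md = medians["sync"][both].mean(), medians["desync"][both].mean()
        out["speed_ratio_desync_over_sync"] = float(md / ms)
    s_dir = trans[trans.state == "sync"].direction_rad.to_numpy()
    d_dir = trans[trans.state == "desync"].direction_rad.to_numpy()
    if s_dir.size >= 8 and d_dir.size >= 8:
        kres = circstats.kuiper_two_sample(s_dir, d_dir)
        out["kuiper"] = {"statistic": kres.statistic, "p_value": kres.p_value,
                         "n1": kres.n1, "n2": kres.n2}
    return out


def _laminar_stage(config: PipelineConfig):
    out = {}
    for mode in ("sync", "desync"):
        fracs = []
        for i in range(config.n_laminar):
            rec = synth.gen_laminar_session(config.laminar_duration,
                                            seed=config.seed + i, mode=mode)
            prof = csd.csd_transform(rec.lfp, rec.pitch, rec.rate)
            if mode == "sync":
                trig = csd.detect_up_transitions(
                    rec.mua_times, duration=rec.duration, bin=config.mua_bin,
                    k_sd=config.k_sd, persist=config.persist)
            else:
                ch = int(np.argmax(rec.lfp.std(axis=1)))
                trig = csd.phase_triggers(rec.lfp[ch], rec.rate,
                                          config.phase_band)
            avg = csd.triggered_csd_average(prof, trig, config.csd_window)
            res = csd.avrec_fraction(avg, config.avrec_window)
            fracs.append(res.sg_fraction)
            log.info("laminar: mode=%s seed=%d triggers=%d sg_fraction=%.4f",
                     mode, config.seed + i, avg.trigger_count,
                     res.sg_fraction)
        out[mode] = {"sg_fractions": fracs,
                     "mean_sg_fraction": float(np.mean(fracs)),
                     "true_sg_fraction": (synth.SYNC_SG_FRACTION
                                          if mode == "sync"
                                          else synth.DESYNC_SG_FRACTION)}
    return out


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir=None) -> dict:
    """Run the full synthetic pipeline and return the report dict.

    When `out_dir` is given, writes ``states.csv``, ``events.csv`` and
    ``report.json`` there.  Deterministic for a fixed config.
    """
    if config is None:
        config = PipelineConfig()
    config.validate()
    report = {"config": dataclasses.asdict(config)}

    ecog, seg, acc = _classify_stage(config)
    report["classification"] = {
        "criterion": float(seg.criterion),
        "accuracy": acc,
        "n_segments": int(len(seg.labels)),
        "episodes": [(s, float(t), float(d)) for s, t, d in seg.episodes],
    }
    states_df = pd.DataFrame({
        "seg_index": np.arange(len(seg.labels)),
        "t_start_s": np.arange(len(seg.labels)) * config.seg_len,
        "rms": seg.rms,
        "label": seg.labels,
    })

    events = _flow_stage(config)
    report["stats"] = _stats_stage(events)

    if config.include_laminar:
        report["laminar"] = _laminar_stage(config)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        states_df.to_csv(out_dir / "states.csv", index=False)
        events.to_csv(out_dir / "events.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=float))
    report["n_events"] = int(len(events))
    return report
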