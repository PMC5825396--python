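"""Simulated experimental conditions and final-beat segmentation.

The standard condition set mirrors common wet-lab perturbations: pacing at
0.5/1/2 Hz, and raising/lowering extracellular Ca2+, Na+, or K+.  Cells are
run for a fixed duration (default 120 s) and the last complete beat is
segmented for biomarker extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

DEFAULT_DURATION_S = 120.0
DEFAULT_STIM_AMPLITUDE = 60.0  # uA/uF; ~1.5x the paced fixture's diastolic threshold
DEFAULT_STIM_DURATION_MS = 1.0

#: Extracellular concentration levels (mM): baseline / high / low.
ION_LEVELS = {
    "Cao": {"baseline": 1.8, "high": 3.0, "low": 0.9},
    "Nao": {"baseline": 151.0, "high": 300.0, "low": 70.0},
    "Ko": {"baseline": 5.4, "high": 10.0, "low": 3.0},
}


@dataclass(frozen=True)
class ProtocolSpec:
    """One simulated experimental condition."""

    protocol_id: str
    mode: str  # "paced" | "spontaneous"
    frequency_hz: float = 1.0
    duration_s: float = DEFAULT_DURATION_S
    overrides: Mapping[str, float] = field(default_factory=dict)
    stim_amplitude: float = DEFAULT_STIM_AMPLITUDE
    stim_duration_ms: float = DEFAULT_STIM_DURATION_MS

    def __post_init__(self):
        if self.mode not in ("paced", "spontaneous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.mode == "paced" and self.frequency_hz <= 0:
            raise ValueError("paced frequency must be > 0")
        for k, v in self.overrides.items():
            if v <= 0:
                raise ValueError(f"override {k}={v} must be > 0")
        object.__setattr__(self, "overrides", dict(self.overrides))

    @property
    def cycle_length_ms(self) -> Optional[float]:
        return 1000.0 / self.frequency_hz if self.mode == "paced" else None

    def replace(self, **kw) -> "ProtocolSpec":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def standard_protocol_set(cell_kind: str, duration_s: float = DEFAULT_DURATION_S):
    """The 10 standard conditions for a cell kind.

    ``adult-like``: baseline is 1 Hz pacing and ion-override conditions are
    paced at 1 Hz.  ``ipsc-like``: baseline is spontaneous beating,
    pacing at 0.5/1/2 Hz is added, and ion-override conditions run in
    spontaneous mode.
    """
    if cell_kind not in ("adult-like", "ipsc-like"):
        raise ValueError(f"unknown cell kind {cell_kind!r}")
    spont = cell_kind == "ipsc-like"

    def mk(pid, mode, freq=1.0, over=None):
        return ProtocolSpec(
            protocol_id=pid, mode=mode, frequency_hz=freq,
            duration_s=duration_s, overrides=over or {},
        )

    ion_mode = "spontaneous" if spont else "paced"
    protos = []
    if spont:
        protos.append(mk("spont", "spontaneous"))
        protos.append(mk("pace0.5", "paced", 0.5))
        protos.append(mk("pace1", "paced", 1.0))
        protos.append(mk("pace2", "paced", 2.0))
    else:
        protos.append(mk("pace1", "paced", 1.0))
        protos.append(mk("pace0.5", "paced", 0.5))
        protos.append(mk("pace2", "paced", 2.0))
    protos += [
        mk("CaHigh", ion_mode, over={"Cao": ION_LEVELS["Cao"]["high"]}),
        mk("CaLow", ion_mode, over={"Cao": ION_LEVELS["Cao"]["low"]}),
        mk("NaHigh", ion_mode, over={"Nao": ION_LEVELS["Nao"]["high"]}),
        mk("NaLow", ion_mode, over={"Nao": ION_LEVELS["Nao"]["low"]}),
        mk("KHigh", ion_mode, over={"Ko": ION_LEVELS["Ko"]["high"]}),
        mk("KLow", ion_mode, over={"Ko": ION_LEVELS["Ko"]["low"]}),
    ]
    if not spont:
        # adult-like set has no spontaneous baseline; still 10 conditions
        protos.insert(3, mk("pace1b", "paced", 1.0))
    ids = [p.protocol_id for p in protos]
    assert len(ids) == len(set(ids)) == 10
    return protos


@dataclass(frozen=True)
class BeatSegment:
    """The final beat of a trace: time-aligned V and Ca arrays.

    ``t`` starts at the segment's first sample (absolute trace time);
    ``upstroke_time`` is the time of maximum dV/dt within the beat.
    """

    t: np.ndarray
    v: np.ndarray
    cai: np.ndarray
    upstroke_time: float
    cycle_length_ms: float
    protocol_id: str = ""
    mode: str = "paced"
    stim_onset: Optional[float] = None


def _dvdt(t, v):
    return np.gradient(v, t)


def detect_upstrokes(t, v, frac: float = 0.1, refractory_ms: float = 100.0):
    """Times of spontaneous upstrokes: dV/dt crossings above frac*max(dV/dt)."""
    dv = _dvdt(t, v)
    peak = dv.max()
    if peak <= 0:
        return np.empty(0)
    thr = frac * peak
    above = dv >= thr
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    out = []
    last = -np.inf
    for i in idx:
        # local dV/dt maximum within the burst
        j = i
        while j + 1 < len(dv) and dv[j + 1] >= dv[j]:
            j += 1
        tt = t[j]
        if tt - last >= refractory_ms:
            out.append(tt)
            last = tt
    return np.asarray(out)


def segment_last_beat(trace, mode: str) -> Optional[BeatSegment]:
    """Extract the final complete beat of a trace.

    Paced: the segment starts at the last stimulus onset and runs to the end
    of the trace (one cycle length).  Spontaneous: the segment spans the last
    full inter-upstroke interval.  Returns None when no beat is present.
    """
    t, v, cai = trace.t, trace.v, trace.cai
    if trace.failed or v.max() - v.min() < 1.0:
        return None
    if mode == "paced":
        if len(trace.stim_times) == 0:
            return None
        onset = trace.stim_times[-1]
        if len(trace.stim_times) >= 2:
            cl = trace.stim_times[-1] - trace.stim_times[-2]
        else:
            cl = t[-1] - onset
        sel = t >= onset - 1e-9
        seg_t, seg_v, seg_c = t[sel], v[sel], cai[sel]
        dv = _dvdt(seg_t, seg_v)
        ups = seg_t[int(np.argmax(dv))]
        return BeatSegment(
            t=seg_t, v=seg_v, cai=seg_c, upstroke_time=float(ups),
            cycle_length_ms=float(cl), protocol_id=trace.meta.get("protocol_id", ""),
            mode="paced", stim_onset=float(onset),
        )
    ups = detect_upstrokes(t, v)
    if len(ups) < 2:
        return None
    a, b = ups[-2], ups[-1]
    # one full cycle, shifted 50 ms before the upstroke: the Ca2+ rise
    # begins during late diastolic depolarization, slightly ahead of the
    # voltage upstroke, and must fall inside the segment
    pre = min(50.0, a - t[0], 0.25 * (b - a))
    sel = (t >= a - pre - 1e-9) & (t <= b - pre + 1e-9)
    seg_t, seg_v, seg_c = t[sel], v[sel], cai[sel]
    return BeatSegment(
        t=seg_t, v=seg_v, cai=seg_c, upstroke_time=float(a),
        cycle_length_ms=float(b - a), protocol_id=trace.meta.get("protocol_id", ""),
        mode="spontaneous",
    )


def run_protocol(model, protocol: ProtocolSpec, **integrate_kw):
    """Integrate a model under a protocol and segment the final beat.

    Returns (Trace, BeatSegment or None).
    """
    from .model_core import integrate

    trace = integrate(model, protocol, **integrate_kw)
    beat = segment_last_beat(trace, protocol.mode)
    return trace, beat


def steady_state_metric(trace, mode: str):
    """Relative APD90 difference between the final two beats (steady-state check)."""
    from .biomarkers import extract_features

    if mode != "paced" or len(trace.stim_times) < 3:
        return np.nan
    vals = []
    for onset, nxt in [(trace.stim_times[-3], trace.stim_times[-2]),
                       (trace.stim_times[-2], trace.stim_times[-1])]:
        sel = (trace.t >= onset - 1e-9) & (trace.t <= nxt + 1e-9)
        seg_t, seg_v, seg_c = trace.t[sel], trace.v[sel], trace.cai[sel]
        dv = _dvdt(seg_t, seg_v)
        beat = BeatSegment(
            t=seg_t, v=seg_v, cai=seg_c,
            upstroke_time=float(seg_t[int(np.argmax(dv))]),
            cycle_length_ms=float(nxt - onset), mode="paced",
            stim_onset=float(onset),
        )
        feats, _ = extract_features(beat)
        vals.append(feats.get("APD90", np.nan))
    if not np.isfinite(vals).all() or vals[1] == 0:
        return np.nan
    return abs(vals[1] - vals[0]) / abs(vals[1])
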