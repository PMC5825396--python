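"""AP and Ca2+-transient biomarkers from a segmented beat.

Eleven waveform features are computed per beat (twelve for spontaneous
beats, where the beating rate is added):

==============  =====================================================
APDm60          total time the AP spends above -60 mV (ms)
APD90, APD50    AP duration at 90% / 50% repolarization (ms)
Vpeak, Vrest    peak and diastolic membrane potential (mV)
CaTA            Ca transient amplitude, Ca_peak - Ca_rest
Ca_rest/Ca_peak diastolic and systolic [Ca2+]i
CaD50, CaD90    CaT duration to 50% / 90% return toward baseline (ms)
CaDecayTime     time from Ca peak until the elevation above baseline
                has fallen by a factor of e (ms)
rate            spontaneous beating rate (Hz)
==============  =====================================================

Repolarization thresholds are Vpeak - q*(Vpeak - Vrest), located by linear
interpolation; AP durations are measured from the beat's upstroke time.
CaT durations are measured from the Ca upstroke (10% rise) to the return
crossing, relative to the within-beat diastolic baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PACED_FEATURES = (
    "APDm60", "APD90", "APD50", "Vpeak", "Vrest",
    "CaTA", "Ca_rest", "Ca_peak", "CaD50", "CaDecayTime", "CaD90",
)
SPONT_FEATURES = PACED_FEATURES + ("rate",)

#: Strictly positive features that are log-transformed before regression.
LOG_FEATURES = frozenset(
    ("APDm60", "APD90", "APD50", "CaTA", "Ca_rest", "Ca_peak",
     "CaD50", "CaDecayTime", "CaD90", "rate")
)

MIN_AP_AMPLITUDE_MV = 30.0  # below this the beat is treated as absent


def _cross_down(t, x, level, start_idx):
    """First downward crossing of `level` at or after start_idx (interpolated)."""
    for i in range(start_idx, len(x) - 1):
        if x[i] >= level > x[i + 1]:
            frac = (x[i] - level) / (x[i] - x[i + 1])
            return t[i] + frac * (t[i + 1] - t[i])
    return np.nan


def _cross_up(t, x, level, stop_idx):
    """First upward crossing of `level` before stop_idx (interpolated)."""
    for i in range(0, max(stop_idx, 1)):
        if x[i] < level <= x[i + 1]:
            frac = (level - x[i]) / (x[i + 1] - x[i])
            return t[i] + frac * (t[i + 1] - t[i])
    return np.nan


def _time_above(t, x, level):
    """Total time x > level, with interpolated boundary crossings."""
    total = 0.0
    for i in range(len(x) - 1):
        a, b = x[i], x[i + 1]
        dt = t[i + 1] - t[i]
        if a > level and b > level:
            total += dt
        elif a > level >= b:
            total += dt * (a - level) / (a - b)
        elif a <= level < b:
            total += dt * (b - level) / (b - a)
    return total


def extract_features(beat) -> tuple[pd.Series, set]:
    """Compute the feature vector of one beat.

    Returns (features, flags); undefined features are NaN and contribute a
    flag naming the problem.  Results are invariant to uniform time shifts.
    """
    flags: set[str] = set()
    t = np.asarray(beat.t, float)
    v = np.asarray(beat.v, float)
    ca = np.asarray(beat.cai, float)

    names = SPONT_FEATURES if beat.mode == "spontaneous" else PACED_FEATURES
    out = pd.Series(np.nan, index=list(names), dtype=float)

    vpeak = float(v.max())
    peak_idx = int(np.argmax(v))
    if beat.mode == "paced" and beat.stim_onset is not None and beat.stim_onset >= t[0] - 1e-9:
        vrest = float(np.interp(beat.stim_onset, t, v))
    else:
        vrest = float(v.min())
    out["Vpeak"] = vpeak
    out["Vrest"] = vrest

    if vpeak - vrest < MIN_AP_AMPLITUDE_MV:
        flags.add("no_beat")
        return out, flags

    ups = beat.upstroke_time
    for name, q in (("APD90", 0.90), ("APD50", 0.50)):
        level = vpeak - q * (vpeak - vrest)
        tc = _cross_down(t, v, level, peak_idx)
        if np.isnan(tc):
            flags.add(f"{name}_undefined")
        else:
            out[name] = tc - ups
    am60 = _time_above(t, v, -60.0)
    if am60 <= 0:
        flags.add("APDm60_undefined")
    else:
        out["APDm60"] = am60

    ca_rest = float(ca.min())
    ca_peak = float(ca.max())
    ca_peak_idx = int(np.argmax(ca))
    amp = ca_peak - ca_rest
    out["Ca_rest"] = ca_rest
    out["Ca_peak"] = ca_peak
    out["CaTA"] = amp
    if amp > 0:
        t10 = _cross_up(t, ca, ca_rest + 0.1 * amp, ca_peak_idx)
        if np.isnan(t10):
            t10 = t[ca_peak_idx]  # rise faster than sampling: start at peak
        for name, q in (("CaD50", 0.5), ("CaD90", 0.9)):
            level = ca_rest + (1.0 - q) * amp
            tc = _cross_down(t, ca, level, ca_peak_idx)
            if np.isnan(tc):
                flags.add(f"{name}_undefined")
            else:
                out[name] = tc - t10
        te = _cross_down(t, ca, ca_rest + amp / np.e, ca_peak_idx)
        if np.isnan(te):
            flags.add("CaDecayTime_undefined")
        else:
            out["CaDecayTime"] = te - t[ca_peak_idx]
    else:
        flags.add("no_ca_transient")

    if beat.mode == "spontaneous":
        out["rate"] = 1000.0 / beat.cycle_length_ms

    return out, flags


def feature_table(results: dict) -> pd.DataFrame:
    """Assemble per-protocol feature frames into one cells x (protocol, feature)
    matrix.

    ``results`` maps protocol id -> DataFrame (rows = cells, columns =
    feature names).  Column order follows the given protocol order; missing
    values stay NaN.
    """
    pieces = []
    seen = set()
    for pid, df in results.items():
        for feat in df.columns:
            if (pid, feat) in seen:
                raise ValueError(f"duplicated column {(pid, feat)!r}")
            seen.add((pid, feat))
        block = df.copy()
        block.columns = pd.MultiIndex.from_product([[pid], df.columns],
                                                   names=["protocol", "feature"])
        pieces.append(block)
    if not pieces:
        raise ValueError("no feature blocks given")
    table = pd.concat(pieces, axis=1)
    return table
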