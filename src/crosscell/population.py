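"""Heterogeneous cell populations via log-normal transport scaling.

Each cell of a population is defined by 13 multiplicative scale factors
applied to the transport maximal rates.  Factors are drawn i.i.d. from a
log-normal distribution whose log has mean 0 and SD 0.2624, so 95% of
values fall between roughly 60% and 167% of control.  The same factor table
is applied to both cell types of a pair, which index-aligns the two
populations for cross-cell-type regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CANONICAL_KEYS,
    CellModelSpec,
    TransportScaling,
    ValidationError,
    apply_scaling,
)

#: SD of log scale factors; places 95% of factors in [0.60, 1.67].
DEFAULT_SIGMA_LOG = 0.2624


@dataclass(frozen=True)
class PopulationConfig:
    n_cells: int
    sigma_log: float = DEFAULT_SIGMA_LOG
    mean_log: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.sigma_log <= 0:
            raise ValidationError("sigma_log must be > 0")


@dataclass(frozen=True)
class ScaleFactorTable:
    """n_cells x 13 positive multipliers; columns in canonical key order."""

    data: pd.DataFrame
    seed: Optional[int] = None

    def __post_init__(self):
        df = self.data
        if list(df.columns) != list(CANONICAL_KEYS):
            raise ValidationError(
                f"columns must be the canonical keys in order {CANONICAL_KEYS}"
            )
        if not (df.to_numpy() > 0).all():
            raise ValidationError("all scale factors must be > 0")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def row_scaling(self, i: int) -> TransportScaling:
        return TransportScaling(dict(zip(CANONICAL_KEYS, self.data.iloc[i])))

    def iter_scalings(self) -> Iterable[TransportScaling]:
        for row in self.data.itertuples(index=False):
            yield TransportScaling(dict(zip(CANONICAL_KEYS, row)))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
        side = Path(str(path)).with_suffix(".meta.json")
        side.write_text(json.dumps({"seed": self.seed, "columns": CANONICAL_KEYS}))

    @classmethod
    def from_csv(cls, path, seed: Optional[int] = None) -> "ScaleFactorTable":
        return cls(pd.read_csv(path), seed=seed)


def draw_scale_factors(config: PopulationConfig) -> ScaleFactorTable:
    """Draw an n_cells x 13 log-normal scale-factor table (seeded)."""
    rng = np.random.default_rng(config.seed)
    mat = rng.lognormal(
        mean=config.mean_log, sigma=config.sigma_log,
        size=(config.n_cells, len(CANONICAL_KEYS)),
    )
    df = pd.DataFrame(mat, columns=list(CANONICAL_KEYS))
    return ScaleFactorTable(df, seed=config.seed)


def build_paired_populations(
    model_a: CellModelSpec, model_b: CellModelSpec, table: ScaleFactorTable
) -> tuple[list[CellModelSpec], list[CellModelSpec]]:
    """Apply one factor table to two cell types, giving index-aligned lists."""
    for m in (model_a, model_b):
        missing = set(CANONICAL_KEYS) - set(m.transport_map)
        if missing:
            raise ValidationError(f"{m.model_id}: missing pathways {sorted(missing)}")
    pop_a, pop_b = [], []
    for sc in table.iter_scalings():
        pop_a.append(apply_scaling(model_a, sc))
        pop_b.append(apply_scaling(model_b, sc))
    return pop_a, pop_b


# ---------------------------------------------------------------------------
# abnormality detection

#: Configurable thresholds for the beat-abnormality detectors.
ABNORMALITY_DEFAULTS = {
    "repol_threshold_mv": -60.0,   # V must return below this after the upstroke
    "ead_min_deflection_mv": 2.0,  # depolarizing excursion that counts as an EAD
    "min_amplitude_mv": 30.0,      # below this peak-to-rest range: no beat
    "dd_onset_elevation_mv": 5.0,  # diastolic elevation at stimulus onset
}


def detect_abnormal(beat, thresholds: Optional[dict] = None,
                    spontaneous_cell: bool = False) -> set:
    """Abnormality flags for one segmented beat (pure function of the trace).

    Returns a subset of {"no_beat", "repolarization_failure",
    "afterdepolarization"}; the empty set means a normal beat.

    Definitions: no_beat = peak-to-rest amplitude below 30 mV;
    repolarization_failure = V never returns below -60 mV after the upstroke
    within the cycle; afterdepolarization = after 50% repolarization, a local
    voltage minimum followed by a depolarizing excursion of at least 2 mV.

    For cells without intrinsic automaticity (``spontaneous_cell=False``) the
    afterdepolarization window extends to the end of the cycle and an
    elevated potential at the stimulus onset (>= 5 mV above the repolarized
    minimum) also counts: both capture delayed afterdepolarizations and
    triggered activity.  For intrinsically spontaneous cells the window ends
    at 90% repolarization, because their diastolic depolarization is
    physiological.
    """
    th = dict(ABNORMALITY_DEFAULTS)
    if thresholds:
        th.update(thresholds)
    flags: set[str] = set()
    if beat is None:
        return {"no_beat"}
    v = np.asarray(beat.v, float)
    t = np.asarray(beat.t, float)

    vpeak = v.max()
    vrest = v.min()
    if vpeak - vrest < th["min_amplitude_mv"]:
        return {"no_beat"}

    peak_idx = int(np.argmax(v))
    after = v[peak_idx:]
    if after.min() > th["repol_threshold_mv"]:
        flags.add("repolarization_failure")

    # afterdepolarization window: from the APD50 crossing to the end of the
    # cycle (paced) or to the APD90 crossing (spontaneous)
    lvl50 = vpeak - 0.5 * (vpeak - vrest)
    lvl90 = vpeak - 0.9 * (vpeak - vrest)
    below50 = np.flatnonzero(after <= lvl50)
    if below50.size:
        start = peak_idx + below50[0]
        if spontaneous_cell:
            below90 = np.flatnonzero(v[start:] <= lvl90)
            stop = start + below90[0] if below90.size else len(v) - 1
        else:
            stop = len(v) - 1
        win = v[start:stop + 1]
        if win.size >= 3:
            run_min = np.minimum.accumulate(win)
            if np.max(win - run_min) >= th["ead_min_deflection_mv"]:
                flags.add("afterdepolarization")

    # triggered activity showing up as an elevated diastolic potential at
    # the stimulus of the recorded beat (period-2 dynamics leave the beat
    # itself clean)
    if not spontaneous_cell and getattr(beat, "stim_onset", None) is not None:
        v_onset = float(np.interp(beat.stim_onset, t, v))
        if v_onset - vrest >= th["dd_onset_elevation_mv"]:
            flags.add("afterdepolarization")
    return flags


def condition_abnormal_fraction(
    flags_per_cell: Sequence[set], max_fraction: float = 0.25
) -> tuple[float, bool]:
    """Fraction of abnormal cells under one condition and the keep decision.

    The condition is dropped only when the abnormal fraction strictly
    exceeds ``max_fraction`` (default 25%).
    Returns (fraction, keep).
    """
    if len(flags_per_cell) == 0:
        raise ValidationError("empty population")
    n_abn = sum(1 for fl in flags_per_cell if fl)
    frac = n_abn / len(flags_per_cell)
    return frac, frac <= max_fraction
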