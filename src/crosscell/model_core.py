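"""Cell-model contract, transport-pathway scaling, and reduced fixture models.

A cell model is a stiff ODE system describing membrane potential and
intracellular Ca2+ handling.  Thirteen canonical ion-transport pathways are
shared by all models in this package, each entering as a separable maximal
rate that can be multiplied by a dimensionless scale factor.  Populations of
cells, disease variants, and pore-block drugs are all expressed as such
multiplicative modifications.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _kernels

#: Canonical names of the 13 randomized ion-transport maximal rates:
#: fast Na+ current, inward rectifier, rapid/slow delayed rectifiers,
#: transient outward K+, L-type Ca2+, Na/Ca exchanger, Na/K pump,
#: sarcolemmal Ca pump, background Na+/Ca2+, SR release (RyR), SR uptake
#: (SERCA).
CANONICAL_KEYS: tuple[str, ...] = (
    "GNa", "GK1", "GKr", "GKs", "Gto", "GCaL", "KNCX", "KNaK",
    "GpCa", "GbNa", "GbCa", "KRyR", "KSERCA",
)

#: Packed parameter-vector order used by the numba kernels.
PARAM_ORDER: tuple[str, ...] = CANONICAL_KEYS + (
    "Nao", "Cao", "Ko", "Nai", "Ki", "Gf", "Ef",
)

EXTRACELLULAR_KEYS = ("Nao", "Cao", "Ko")


class ValidationError(ValueError):
    """Raised when a scaling, variant, or drug fails its invariants."""


@dataclass(frozen=True)
class TransportScaling:
    """One cell's dimensionless multipliers for the 13 transport pathways."""

    factors: Mapping[str, float]

    def __post_init__(self):
        f = dict(self.factors)
        for key in CANONICAL_KEYS:
            if key not in f:
                raise ValidationError(f"missing transport multiplier: {key!r}")
            v = f[key]
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"multiplier for {key!r} must be > 0, got {v!r}")
        extra = set(f) - set(CANONICAL_KEYS)
        if extra:
            raise ValidationError(f"unknown transport keys: {sorted(extra)}")
        object.__setattr__(self, "factors", {k: float(f[k]) for k in CANONICAL_KEYS})

    @classmethod
    def identity(cls) -> "TransportScaling":
        return cls({k: 1.0 for k in CANONICAL_KEYS})

    @classmethod
    def from_partial(cls, **overrides: float) -> "TransportScaling":
        f = {k: 1.0 for k in CANONICAL_KEYS}
        f.update(overrides)
        return cls(f)

    def __getitem__(self, key: str) -> float:
        return self.factors[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.factors[k] for k in CANONICAL_KEYS])

    def compose(self, other: "TransportScaling") -> "TransportScaling":
        """Element-wise product: applying self then other."""
        return TransportScaling(
            {k: self.factors[k] * other.factors[k] for k in CANONICAL_KEYS}
        )

    def hash(self) -> str:
        payload = json.dumps(self.factors, sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass(frozen=True)
class VariantTable:
    """Ordered multiplicative parameter modifications (disease/species variants)."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        entries = tuple((str(n), float(f)) for n, f in self.entries)
        for name, factor in entries:
            if not np.isfinite(factor) or factor <= 0:
                raise ValidationError(f"variant factor for {name!r} must be > 0")
        object.__setattr__(self, "entries", entries)

    def inverted(self) -> "VariantTable":
        return VariantTable(tuple((n, 1.0 / f) for n, f in self.entries))


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled voltage / [Ca2+]i time course.

    Time in ms, voltage in mV; Ca units declared in ``meta['ca_units']``
    (fixture models report uM).
    """

    t: np.ndarray
    v: np.ndarray
    cai: np.ndarray
    stim_times: np.ndarray
    failed: bool = False
    meta: Mapping[str, object] = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.t, "V_mV": self.v, "Cai": self.cai})


@dataclass(frozen=True)
class CellModelSpec:
    """A cell model: states, parameters, RHS contract, and capabilities.

    ``rhs(t, y, params_vector, istim)`` returns the state derivative; it is
    deterministic for fixed inputs.  ``transport_map`` names the model
    parameter realizing each canonical transport pathway, and the
    extracellular concentrations (Nao, Cao, Ko, mM) are plain parameters that
    protocols may override.
    """

    model_id: str
    state_names: tuple[str, ...]
    initial_state: np.ndarray
    params: Mapping[str, float]
    transport_map: Mapping[str, str]
    capabilities: frozenset
    rhs: Callable = None
    param_order: tuple[str, ...] = PARAM_ORDER

    def __post_init__(self):
        missing = [k for k in CANONICAL_KEYS if k not in self.transport_map]
        if missing:
            raise ValidationError(f"transport_map missing pathways: {missing}")
        for k in EXTRACELLULAR_KEYS:
            if k not in self.params:
                raise ValidationError(f"model lacks extracellular parameter {k!r}")
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "initial_state", np.asarray(self.initial_state, float))

    @property
    def paced(self) -> bool:
        return "paced" in self.capabilities

    @property
    def spontaneous(self) -> bool:
        return "spontaneous" in self.capabilities

    def packed_params(self) -> np.ndarray:
        return np.array([self.params[name] for name in self.param_order])

    def with_params(self, updates: Mapping[str, float]) -> "CellModelSpec":
        unknown = set(updates) - set(self.params)
        if unknown:
            raise ValidationError(
                f"unknown parameters {sorted(unknown)}; valid names: "
                f"{sorted(self.params)}"
            )
        new = dict(self.params)
        new.update({k: float(v) for k, v in updates.items()})
        return replace(self, params=new)

    def with_initial_state(self, y0: np.ndarray) -> "CellModelSpec":
        return replace(self, initial_state=np.asarray(y0, float))


def apply_scaling(model: CellModelSpec, scaling: TransportScaling) -> CellModelSpec:
    """Multiply the 13 transport parameters by the scaling's factors.

    Purely multiplicative: composing two scalings equals applying their
    element-wise product.  The input model is unmodified.
    """
    updates = {}
    for key in CANONICAL_KEYS:
        pname = model.transport_map[key]
        updates[pname] = model.params[pname] * scaling[key]
    return model.with_params(updates)


def apply_variant(model: CellModelSpec, table: VariantTable) -> CellModelSpec:
    """Apply a variant's multiplicative parameter modifications."""
    updates: dict[str, float] = {}
    for name, factor in table.entries:
        pname = model.transport_map.get(name, name)
        if pname not in model.params:
            raise ValidationError(
                f"unknown parameter {name!r}; valid names: {sorted(model.params)}"
            )
        updates[pname] = updates.get(pname, model.params[pname]) * factor
    return model.with_params(updates)


def _fixture_rhs(t, y, pvec, istim=0.0):
    dy = np.empty(_kernels.NSTATE)
    _kernels.fixture_rhs(t, np.asarray(y, float), np.asarray(pvec, float), istim, dy)
    return dy


_FIXTURE_STATES = ("V", "h", "xr", "f", "Cai", "CaSR", "yf")

# Baseline parameters for the paced, adult-ventricular-like fixture.
_ADULT_PARAMS = {
    "GNa": 5.5,
    "GK1": 0.9,
    "GKr": 0.045,
    "GKs": 0.008,
    "Gto": 0.01,
    "GCaL": 0.07,
    "KNCX": 1400.0,
    "KNaK": 1.6,
    "GpCa": 0.015,
    "GbNa": 0.003,
    "GbCa": 0.0005,
    "KRyR": 0.0006,
    "KSERCA": 0.006,
    "Nao": 151.0,
    "Cao": 1.8,
    "Ko": 5.4,
    "Nai": 9.0,
    "Ki": 140.0,
    "Gf": 0.0,
    "Ef": -20.0,
}

# Baseline parameters for the spontaneously beating, immature (iPSC-like)
# fixture: weak inward rectifier, a pacemaker current, smaller Na+ current
# and SR fluxes; the post-AP descent is carried by the slowly deactivating
# rapid delayed rectifier, giving a robust limit cycle.
_IPSC_PARAMS = {
    "GNa": 2.0,
    "GK1": 0.06,
    "GKr": 0.13,
    "GKs": 0.012,
    "Gto": 0.012,
    "GCaL": 0.065,
    "KNCX": 1200.0,
    "KNaK": 1.4,
    "GpCa": 0.008,
    "GbNa": 0.0025,
    "GbCa": 0.0006,
    "KRyR": 0.0005,
    "KSERCA": 0.006,
    "Nao": 151.0,
    "Cao": 1.8,
    "Ko": 5.4,
    "Nai": 10.0,
    "Ki": 140.0,
    "Gf": 0.03,
    "Ef": -20.0,
}

_ADULT_Y0 = np.array([-86.0, 0.9, 0.01, 0.95, 0.08, 120.0, 0.0])
_IPSC_Y0 = np.array([-62.0, 0.6, 0.3, 0.9, 0.15, 120.0, 0.3])

_IDENTITY_MAP = {k: k for k in CANONICAL_KEYS}


def make_fixture_models() -> tuple[CellModelSpec, CellModelSpec]:
    """Return (paced adult-like fixture, spontaneous iPSC-like fixture).

    Both share the 13 canonical transport pathways and the same reduced
    equation set; they differ only in baseline parameter values (the
    spontaneous fixture has weak inward-rectifier current and a nonzero
    pacemaker conductance).
    """
    adult = CellModelSpec(
        model_id="fixture-adult",
        state_names=_FIXTURE_STATES,
        initial_state=_ADULT_Y0,
        params=_ADULT_PARAMS,
        transport_map=_IDENTITY_MAP,
        capabilities=frozenset({"paced"}),
        rhs=_fixture_rhs,
    )
    ipsc = CellModelSpec(
        model_id="fixture-ipsc",
        state_names=_FIXTURE_STATES,
        initial_state=_IPSC_Y0,
        params=_IPSC_PARAMS,
        transport_map=_IDENTITY_MAP,
        capabilities=frozenset({"paced", "spontaneous"}),
        rhs=_fixture_rhs,
    )
    return adult, ipsc


def integrate(
    model: CellModelSpec,
    protocol,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    dt_out: float = 0.5,
    method: str = "adaptive",
) -> Trace:
    """Integrate a model under a protocol, returning a uniformly sampled Trace.

    ``method='adaptive'`` uses the package's compiled Dormand-Prince 5(4)
    integrator with error control; ``method='scipy'`` uses scipy's LSODA as a
    slow reference path.  Integration failure yields a Trace flagged
    ``failed`` rather than an exception, so population runs continue.
    """
    from .protocols import ProtocolSpec  # local import to avoid cycle

    if not isinstance(protocol, ProtocolSpec):
        raise TypeError("protocol must be a ProtocolSpec")
    if protocol.mode == "spontaneous" and not model.spontaneous:
        raise ValidationError(
            f"model {model.model_id!r} does not support spontaneous protocols"
        )
    if protocol.mode == "paced" and not model.paced:
        raise ValidationError(f"model {model.model_id!r} does not support pacing")

    work = model
    if protocol.overrides:
        work = model.with_params(protocol.overrides)
    p = work.packed_params()
    t_end = protocol.duration_s * 1000.0

    if protocol.mode == "paced":
        cl = 1000.0 / protocol.frequency_hz
        n_stim = int(np.floor((t_end - 1e-9) / cl)) + 1
        stim_starts = np.arange(n_stim) * cl
        stim_amp = protocol.stim_amplitude
        stim_dur = protocol.stim_duration_ms
    else:
        stim_starts = np.empty(0)
        stim_amp = 0.0
        stim_dur = 1.0

    meta = {
        "model_id": model.model_id,
        "protocol_id": protocol.protocol_id,
        "units": {"t": "ms", "V": "mV", "Cai": "uM"},
        "ca_units": "uM",
        "rtol": rtol,
        "atol": atol,
    }

    if method == "adaptive":
        t, v, cai, _, ok = _kernels.integrate_fixture(
            p, work.initial_state, t_end, stim_starts, stim_dur, stim_amp,
            dt_out, rtol, atol,
        )
        return Trace(t=t, v=v, cai=cai, stim_times=stim_starts, failed=not ok, meta=meta)
    elif method == "scipy":
        from scipy.integrate import solve_ivp

        t = np.arange(0.0, t_end + dt_out / 2, dt_out)
        v = np.empty_like(t)
        cai = np.empty_like(t)
        y = work.initial_state.copy()
        edges = [0.0]
        for s in stim_starts:
            edges += [s, s + stim_dur]
        edges.append(t_end)
        edges = sorted(set(e for e in edges if 0.0 <= e <= t_end))
        filled = 0
        ok = True
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < 1e-9:
                continue
            amp = stim_amp if any(
                s <= a + 1e-9 < s + stim_dur for s in stim_starts
            ) else 0.0
            tseg = t[(t >= a - 1e-9) & (t <= b + 1e-9)]
            sol = solve_ivp(
                lambda tt, yy: work.rhs(tt, yy, p, amp),
                (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                t_eval=tseg, max_step=5.0,
            )
            if not sol.success:
                ok = False
                break
            m = sol.y.shape[1]
            v[filled:filled + m] = sol.y[0]
            cai[filled:filled + m] = sol.y[4]
            filled += m
            # edge samples shared between segments get overwritten consistently
            if filled > 0 and abs(t[filled - 1] - b) < 1e-9 and b < t_end:
                filled -= 1
            y = sol.y[:, -1].copy()
        if filled < len(t):
            v[filled:] = y[0]
            cai[filled:] = y[4]
        return Trace(t=t, v=v, cai=cai, stim_times=stim_starts, failed=not ok, meta=meta)
    raise ValueError(f"unknown method {method!r}")
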