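"""Pore-block pharmacology: drugs as concentration-dependent conductance
scalings, the two-target hypothetical drug library, and population-level
evaluation of cross-cell predictions against direct simulation.

A drug is a set of (pathway, IC50) targets plus a concentration [C]; each
targeted maximal rate is multiplied by IC50/(IC50 + [C]).  No state-dependent
binding is modeled: a drug is a static multiplier set that composes with the
population's transport scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CANONICAL_KEYS,
    CellModelSpec,
    TransportScaling,
    ValidationError,
    apply_scaling,
)
from .pipeline import PopulationRunResult, simulate_population_features
from .population import ScaleFactorTable
from .protocols import ProtocolSpec
from .regression import CrossCellModel, feature_change_vector

#: The 10 pathways probed with selective blockers (backgrounds and the
#: sarcolemmal Ca pump are excluded).
DEFAULT_DRUG_PATHWAYS: tuple[str, ...] = (
    "GNa", "GK1", "GKr", "GKs", "Gto", "GCaL", "KNCX", "KNaK", "KRyR", "KSERCA",
)


@dataclass(frozen=True)
class DrugTarget:
    pathway: str
    ic50: float

    def __post_init__(self):
        if self.pathway not in CANONICAL_KEYS:
            raise ValidationError(f"unknown pathway {self.pathway!r}")
        if not self.ic50 > 0:
            raise ValidationError("IC50 must be > 0")


@dataclass(frozen=True)
class DrugSpec:
    """A named drug: 1-5 targets with distinct pathways, at concentration [C]."""

    name: str
    targets: tuple
    concentration: float

    def __post_init__(self):
        targets = tuple(self.targets)
        if not 1 <= len(targets) <= 5:
            raise ValidationError("a drug needs 1-5 targets")
        pathways = [t.pathway for t in targets]
        if len(set(pathways)) != len(pathways):
            raise ValidationError(f"duplicate pathway in drug {self.name!r}")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")
        object.__setattr__(self, "targets", targets)

    def at_concentration(self, c: float) -> "DrugSpec":
        return DrugSpec(self.name, self.targets, c)


def block_fraction(target: DrugTarget, concentration: float) -> float:
    """Remaining conductance fraction IC50/(IC50+[C]), in (0, 1]."""
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    return target.ic50 / (target.ic50 + concentration)


def drug_to_scaling(drug: DrugSpec) -> TransportScaling:
    """Reduce a drug to per-pathway multipliers (untargeted pathways: 1)."""
    factors = {k: 1.0 for k in CANONICAL_KEYS}
    for t in drug.targets:
        factors[t.pathway] = block_fraction(t, drug.concentration)
    return TransportScaling(factors)


def selective_block(pathway: str, fraction: float, name: Optional[str] = None
                    ) -> DrugSpec:
    """A single-target drug blocking ``pathway`` by ``fraction`` (0 <= f < 1).

    Uses IC50 = 1 and [C] = f/(1-f), the concentration at which the pore
    block equation leaves 1-f of the conductance.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("block fraction must be in [0, 1)")
    c = fraction / (1.0 - fraction)
    return DrugSpec(name or f"{pathway}_block{int(round(100 * fraction))}",
                    (DrugTarget(pathway, 1.0),), c)


def hypothetical_drug_library(
    pathways: Sequence[str] = DEFAULT_DRUG_PATHWAYS, ratio: float = math.e
) -> list[DrugSpec]:
    """Two-target drugs for every ordered (primary, secondary) pathway pair.

    The secondary IC50 is ``ratio`` (default e) times the primary's, and the
    concentration is set to the primary IC50, so the primary target is
    blocked by 50% and (at ratio e) the secondary by about 27%.
    """
    if len(pathways) < 2:
        raise ValidationError("need at least 2 pathways")
    drugs = []
    for prim in pathways:
        for sec in pathways:
            if prim == sec:
                continue
            drugs.append(DrugSpec(
                name=f"{prim}+{sec}",
                targets=(DrugTarget(prim, 1.0), DrugTarget(sec, ratio)),
                concentration=1.0,
            ))
    return drugs


def load_drug_catalog(table) -> list[DrugSpec]:
    """Read a drug catalog (CSV path or DataFrame) into DrugSpec objects.

    Expected columns: ``name``, then up to five (``pathway_i``, ``IC50_i``)
    pairs; empty cells mark absent targets.  The concentration defaults to
    the lowest IC50 among the drug's targets (50% block of the most potent
    target); a ``concentration`` column overrides this.
    """
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table
    drugs = []
    for i, row in df.iterrows():
        try:
            targets = []
            for k in range(1, 6):
                p = row.get(f"pathway_{k}")
                ic = row.get(f"IC50_{k}")
                if pd.isna(p) or p is None:
                    continue
                targets.append(DrugTarget(str(p), float(ic)))
            conc = row.get("concentration")
            if conc is None or pd.isna(conc):
                conc = min(t.ic50 for t in targets) if targets else 0.0
            drugs.append(DrugSpec(str(row["name"]), tuple(targets), float(conc)))
        except (ValidationError, ValueError, KeyError) as exc:
            raise ValidationError(f"malformed drug catalog row {i}: {exc}") from exc
    return drugs


# ---------------------------------------------------------------------------
# population-level panel evaluation


def _percent_change(pre: pd.Series, post: pd.Series) -> pd.Series:
    return (post / pre - 1.0) * 100.0


def _mean_sd(values: pd.Series) -> tuple[float, float]:
    v = values.dropna()
    if len(v) == 0:
        return np.nan, np.nan
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


def identity_r2(actual: np.ndarray, estimate: np.ndarray) -> float:
    """Coefficient of determination about the line of identity."""
    actual = np.asarray(actual, float)
    estimate = np.asarray(estimate, float)
    ok = np.isfinite(actual) & np.isfinite(estimate)
    a, e = actual[ok], estimate[ok]
    if a.size < 2:
        return float("nan")
    ss_res = np.sum((e - a) ** 2)
    ss_tot = np.sum((a - a.mean()) ** 2)
    if ss_tot == 0.0:
        return float("nan")
    return float(1.0 - ss_res / ss_tot)


@dataclass
class DrugPanelResult:
    """Per-drug evaluation table plus the across-drug accuracy contrast."""

    table: pd.DataFrame
    r2_cross: dict      # feature -> identity R^2 of cross-model predictions
    r2_direct: dict     # feature -> identity R^2 of direct source readouts


def _apply_drug(model: CellModelSpec, drug: DrugSpec) -> CellModelSpec:
    return apply_scaling(model, drug_to_scaling(drug))


def simulate_drug_panel(
    source_model: CellModelSpec,
    target_model: CellModelSpec,
    table: ScaleFactorTable,
    drugs: Sequence[DrugSpec],
    source_protocols: Sequence[ProtocolSpec],
    target_protocol: ProtocolSpec,
    cross_model: CrossCellModel,
    report_features: Sequence[str] = ("APD90", "CaTA"),
    source_baseline_id: Optional[str] = None,
    **integrate_kw,
) -> DrugPanelResult:
    """Evaluate cross-cell predictions of drug effects against simulation.

    For each drug: (i) the direct source readout -- per-cell percent change
    of the report features under the source baseline condition, mean and SD
    over non-flagged cells; (ii) the cross-model prediction -- the
    population-mean change vector over all source conditions pushed through
    B_cross; (iii) the directly simulated target change (mean, SD).  The
    across-drug identity R^2 of (ii) and of (i) against (iii) quantifies how
    much the translation improves on taking source responses at face value.
    """
    src_base_id = source_baseline_id or source_protocols[0].protocol_id
    tgt_id = target_protocol.protocol_id

    pre_src = simulate_population_features(
        source_model, table, source_protocols, **integrate_kw)
    pre_tgt = simulate_population_features(
        target_model, table, [target_protocol], **integrate_kw)

    x_cols = cross_model.x_stats.columns
    rows = []
    for drug in drugs:
        d_src = _apply_drug(source_model, drug)
        d_tgt = _apply_drug(target_model, drug)
        post_src = simulate_population_features(
            d_src, table, source_protocols, **integrate_kw)
        post_tgt = simulate_population_features(
            d_tgt, table, [target_protocol], **integrate_kw)

        ok_src = (pre_src.normal_mask([p.protocol_id for p in source_protocols])
                  & post_src.normal_mask([p.protocol_id for p in source_protocols]))
        ok_tgt = pre_tgt.normal_mask([tgt_id]) & post_tgt.normal_mask([tgt_id])

        row = {
            "drug": drug.name,
            "concentration": drug.concentration,
            "n_excluded_source": int((~ok_src).sum()),
            "n_excluded_target": int((~ok_tgt).sum()),
        }

        # (i) direct source readout under the baseline condition
        for feat in report_features:
            pc = _percent_change(
                pre_src.all_features[(src_base_id, feat)].loc[ok_src],
                post_src.all_features[(src_base_id, feat)].loc[ok_src],
            )
            row[f"src_d{feat}_pct"], row[f"src_d{feat}_sd"] = _mean_sd(pc)

        # (ii) cross-model prediction from the population-mean change vector
        pre_mean = pre_src.all_features.loc[ok_src, x_cols].mean()
        post_mean = post_src.all_features.loc[ok_src, x_cols].mean()
        change = feature_change_vector(pre_mean, post_mean)
        pred = cross_model.predict_change(change)
        pred_pct = cross_model.change_to_percent(pred)
        for feat in report_features:
            key = (tgt_id, feat) if (tgt_id, feat) in pred_pct.index else feat
            row[f"pred_d{feat}_pct"] = float(pred_pct[key])

        # (iii) directly simulated target change
        for feat in report_features:
            pc = _percent_change(
                pre_tgt.all_features[(tgt_id, feat)].loc[ok_tgt],
                post_tgt.all_features[(tgt_id, feat)].loc[ok_tgt],
            )
            row[f"tgt_d{feat}_pct"], row[f"tgt_d{feat}_sd"] = _mean_sd(pc)
        rows.append(row)

    out = pd.DataFrame(rows)
    r2_cross, r2_direct = {}, {}
    for feat in report_features:
        r2_cross[feat] = identity_r2(out[f"tgt_d{feat}_pct"], out[f"pred_d{feat}_pct"])
        r2_direct[feat] = identity_r2(out[f"tgt_d{feat}_pct"], out[f"src_d{feat}_pct"])
    return DrugPanelResult(table=out, r2_cross=r2_cross, r2_direct=r2_direct)
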