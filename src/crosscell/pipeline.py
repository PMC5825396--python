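"""Population-level simulation runs: features per condition, abnormality
screening, and cross-model construction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import extract_features, feature_table
from .model_core import CellModelSpec, apply_scaling
from .population import (
    ScaleFactorTable,
    condition_abnormal_fraction,
    detect_abnormal,
)
from .protocols import ProtocolSpec, run_protocol
from .regression import CVReport, CrossCellModel, fit_plsr, press_cv, select_components


@dataclass
class PopulationRunResult:
    """Feature matrices and abnormality screening for one population."""

    features: pd.DataFrame          # cells x (protocol, feature), retained only
    all_features: pd.DataFrame      # including dropped conditions
    flags: pd.DataFrame             # cells x protocols, ';'-joined flag strings
    abnormal_fraction: dict         # protocol id -> fraction
    retained: list                  # protocol ids kept (<= 25% abnormal)
    dropped: list                   # protocol ids dropped

    def normal_mask(self, protocol_ids: Optional[Sequence[str]] = None) -> pd.Series:
        """Cells with no abnormality flag under the given (default retained)
        conditions and complete feature rows there."""
        pids = list(protocol_ids) if protocol_ids is not None else self.retained
        ok = pd.Series(True, index=self.features.index)
        for pid in pids:
            ok &= self.flags[pid] == ""
            ok &= self.all_features[pid].notna().all(axis=1)
        return ok


def simulate_population_features(
    model: CellModelSpec,
    table: ScaleFactorTable,
    protocols: Sequence[ProtocolSpec],
    max_abnormal_fraction: float = 0.25,
    **integrate_kw,
) -> PopulationRunResult:
    """Simulate every cell under every condition and extract biomarkers.

    Conditions in which more than ``max_abnormal_fraction`` of cells show
    abnormal dynamics (afterdepolarizations, repolarization failure, absent
    beats, undefined features) are excluded from the retained set.
    """
    blocks: dict[str, pd.DataFrame] = {}
    flag_cols: dict[str, list[str]] = {}
    abn: dict[str, float] = {}
    retained, dropped = [], []
    for proto in protocols:
        rows = []
        flags_list = []
        for sc in table.iter_scalings():
            cell = apply_scaling(model, sc)
            _, beat = run_protocol(cell, proto, **integrate_kw)
            fl = detect_abnormal(beat, spontaneous_cell=model.spontaneous)
            if beat is None:
                feats = pd.Series(dtype=float)
            else:
                feats, feat_flags = extract_features(beat)
                fl = fl | feat_flags
            rows.append(feats)
            flags_list.append(";".join(sorted(fl)))
        block = pd.DataFrame(rows).reset_index(drop=True)
        blocks[proto.protocol_id] = block
        flag_cols[proto.protocol_id] = flags_list
        frac, keep = condition_abnormal_fraction(
            [set(f.split(";")) - {""} for f in flags_list], max_abnormal_fraction
        )
        abn[proto.protocol_id] = frac
        (retained if keep else dropped).append(proto.protocol_id)

    all_feats = feature_table(blocks)
    feats = all_feats.loc[:, all_feats.columns.get_level_values(0).isin(retained)]
    return PopulationRunResult(
        features=feats,
        all_features=all_feats,
        flags=pd.DataFrame(flag_cols),
        abnormal_fraction=abn,
        retained=retained,
        dropped=dropped,
    )


@dataclass
class CrossModelFit:
    """A fitted cross-cell model plus its cross-validation report."""

    model: CrossCellModel
    cv: CVReport
    rows_used: np.ndarray
    component_scan: list = field(default_factory=list)


def build_cross_model(
    source: PopulationRunResult,
    target: PopulationRunResult,
    target_protocol: str,
    source_protocols: Optional[Sequence[str]] = None,
    n_components: Optional[int] = None,
    k_folds: int = 5,
    seed: int = 0,
    tol: float = 0.05,
    max_components: Optional[int] = 25,
) -> CrossModelFit:
    """Assemble X (source, multiple conditions) and Y (target) and fit PLSR.

    Rows are cells normal in every used condition of both populations.  When
    ``n_components`` is None the count is chosen by the PRESS parsimony rule.
    """
    pids = list(source_protocols) if source_protocols is not None else source.retained
    x = source.features.loc[:, source.features.columns.get_level_values(0).isin(pids)]
    x = x.reindex(columns=pids, level=0)
    y = target.all_features[target_protocol]

    ok = source.normal_mask(pids) & target.normal_mask([target_protocol])
    ok &= x.notna().all(axis=1) & y.notna().all(axis=1)
    x, y = x.loc[ok], y.loc[ok]
    x.index = range(len(x))
    y.index = range(len(y))

    scan: list = []
    if n_components is None:
        n_components, scan = select_components(
            x, y, k_folds=k_folds, seed=seed, tol=tol, max_components=max_components
        )
    cv = press_cv(x, y, n_components, k_folds=k_folds, seed=seed)
    model = fit_plsr(
        x, y, n_components,
        meta={"target_protocol": target_protocol, "source_protocols": pids,
              "cv_seed": seed},
    )
    return CrossModelFit(model=model, cv=cv,
                         rows_used=np.flatnonzero(ok.to_numpy()),
                         component_scan=scan)
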