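"""Round-trip file formats: feature matrices, traces, configs, reports.

Feature matrices are CSV with a two-row header (protocol id, feature name);
scale-factor tables are CSV with the canonical key header plus a JSON
sidecar carrying the seed; reports and fitted models are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .population import DEFAULT_SIGMA_LOG


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="cell")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    df.columns.names = ["protocol", "feature"]
    df.index.name = None
    return df


def write_trace_csv(trace, path) -> None:
    trace.to_frame().to_csv(path, index=False)
    meta = dict(trace.meta)
    meta["failed"] = bool(trace.failed)
    Path(str(path)).with_suffix(".meta.json").write_text(json.dumps(meta, default=str))


@dataclass
class RunConfig:
    """A fully materialized pipeline configuration (all seeds explicit)."""

    source_model: str = "fixture-ipsc"
    target_model: str = "fixture-adult"
    n_cells: int = 600
    sigma_log: float = DEFAULT_SIGMA_LOG
    population_seed: int = 0
    cv_seed: int = 0
    duration_s: float = 120.0
    k_folds: int = 5
    n_components: Optional[int] = None
    component_tol: float = 0.05
    protocol_set: str = "ipsc-like"
    protocols: Optional[list] = None   # explicit ids; None = full standard set
    target_protocol: str = "pace1"
    out_dir: str = "crosscell-out"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]

    def stamp(self) -> dict:
        """Provenance block embedded in every output artifact."""
        from . import __version__

        return {"config_hash": self.hash(), "population_seed": self.population_seed,
                "cv_seed": self.cv_seed, "version": __version__}
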