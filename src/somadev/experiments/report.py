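"""Experiment reports: metrics, seeds, config hash and named verdicts."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field

import numpy as np

from ..embodiment.trajectory import config_hash

__all__ = ["ExperimentReport", "make_report"]


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


@dataclass
class ExperimentReport:
    experiment_id: str
    config: dict
    config_hash: str
    seeds: list
    metrics: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "experiment_id": self.experiment_id,
            "config": _jsonable(self.config),
            "config_hash": self.config_hash,
            "seeds": list(self.seeds),
            "metrics": _jsonable(self.metrics),
            "summary": _jsonable(self.summary),
            "verdicts": {k: bool(v) if isinstance(v, (bool, np.bool_)) else v
                         for k, v in self.verdicts.items()},
            "provenance": _jsonable(self.provenance),
        }

    def save_json(self, path):
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def export_csv(self, path):
        import pandas as pd
        rows = []
        for name, value in self.summary.items():
            rows.append({"metric": name, "value": value,
                         "config_hash": self.config_hash})
        pd.DataFrame(rows).to_csv(path, index=False)


def make_report(experiment_id: str, config: dict, seeds) -> ExperimentReport:
    from .. import __version__
    return ExperimentReport(
        experiment_id=experiment_id, config=config,
        config_hash=config_hash({"experiment": experiment_id, **config}),
        seeds=list(seeds),
        provenance={"package": f"somadev {__version__}",
                    "timestamp": datetime.datetime.now(datetime.timezone.utc)
                    .isoformat()},
    )
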