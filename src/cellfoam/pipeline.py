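"""Orchestration: run configurations, stage execution, phenotype tallies.

Every run serializes its full configuration (and a hash of it) next to its
outputs so any result directory can be reproduced from the embedded config
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cellfoam")


@dataclass
class RunConfig:
    """Parameters of one pipeline stage invocation."""

    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    output_dir: str = "results"
    pixel_size: float = 0.11
    frame_interval: float = 1.0
    seed: int = 0
    options: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @property
    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def prepare_output_dir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    logger.info("stage=%s config_hash=%s out=%s numpy=%s",
                config.stage, config.digest, out, np.__version__)
    return out


def run_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute one named stage; returns a dict of output paths/tables.

    Stages map one-to-one onto the CLI subcommands; this entry point exists
    for config-file driven, scripted runs.
    """
    from . import cli

    stage = config.stage.replace("-", "_")
    runner = getattr(cli, f"_stage_{stage}", None)
    if runner is None:
        raise ValueError(f"unknown stage {config.stage!r}")
    out = prepare_output_dir(config)
    result = runner(config, out)
    logger.info("stage=%s status=done", config.stage)
    return result


def tally_phenotypes(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-condition percentages from a category x condition count table.

    Returns a table with exact percentages and nearest-integer report
    percentages; each condition column sums to 100 within rounding.
    """
    counts = counts.astype(float)
    if (counts < 0).any().any() or not np.allclose(counts, counts.round()):
        raise ValueError("counts must be non-negative integers")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals[totals == 0].index)
        raise ValueError(f"zero total count in condition(s): {zero}")
    pct = counts / totals * 100.0
    out = pct.copy()
    rounded = pct.round(0).astype(int)
    result = pd.concat({"percent_exact": out, "percent": rounded}, axis=1)
    return result


def completion_percentage(completed: int, total: int) -> int:
    """Nearest-integer percentage of a completed/total tally."""
    if total <= 0:
        raise ValueError("total must be positive")
    if completed < 0 or completed > total:
        raise ValueError("completed must lie in [0, total]")
    return int(round(completed / total * 100))
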