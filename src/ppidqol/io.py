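"""Readers, writers and run configuration.

All interchange files are UTF-8 comma-separated text with a header row.
Cohort tables carry one row per horse (identifiers, covariates, global QoL,
one option-label column per item); ratings tables are wide (subject id plus
one column per rater or occasion).  Refinement and association reports are
serialized as JSON next to a human-readable log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .instrument import InstrumentDefinition
from .simulate import CohortTable

__all__ = [
    "RunConfig",
    "write_cohort",
    "read_cohort",
    "write_ratings",
    "read_ratings",
    "write_json",
    "setup_logging",
    "analysis_frame",
]

log = logging.getLogger("ppidqol")

_META_COLUMNS = [
    "horse_id",
    "group",
    "ppid",
    "age",
    "breed",
    "sex",
    "body_condition",
    "chronic",
    "treated",
    "years_diagnosed",
    "owner_global_qol",
]


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s", level=level)
    log.setLevel(level)


@dataclass
class RunConfig:
    """One pipeline run: inputs, thresholds, outputs, seed."""

    instrument: str = "ppid-final-24"
    responses: str | None = None
    weights: str | None = None  # path to an importance-ratings table, optional
    p_drop: float = 0.05
    r_merge: float = 0.60
    r_prune: float = 0.30
    alpha_adequate: float = 0.70
    model_preset: str = "all-horses"
    out_dir: str = "."
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        for name in ("p_drop", "r_merge", "r_prune", "alpha_adequate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "responses": self.responses,
            "weights": self.weights,
            "p_drop": self.p_drop,
            "r_merge": self.r_merge,
            "r_prune": self.r_prune,
            "alpha_adequate": self.alpha_adequate,
            "model_preset": self.model_preset,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table as headered CSV (instrument name in a comment)."""
    path = Path(path)
    frame = cohort.frame
    with path.open("w", newline="") as fh:
        fh.write(f"# instrument: {cohort.instrument_name}\n")
        frame.to_csv(fh, index=False)


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort table written by :func:`write_cohort`."""
    path = Path(path)
    instrument_name = ""
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# instrument:"):
            instrument_name = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        frame = pd.read_csv(fh)
    return CohortTable(frame=frame, instrument_name=instrument_name)


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, index=True, index_label="subject_id")


def read_ratings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(value):
    try:
        import numpy as np

        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)
        if isinstance(value, np.ndarray):
            return value.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(value)}")


def analysis_frame(cohort: CohortTable, instrument: InstrumentDefinition) -> pd.DataFrame:
    """Covariates + computed HRQoL score, ready for the association models."""
    from .instrument import score_table

    meta = [c for c in _META_COLUMNS if c in cohort.frame.columns]
    out = cohort.frame[meta].copy()
    out["hrqol"] = score_table(instrument, cohort.frame)
    return out
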