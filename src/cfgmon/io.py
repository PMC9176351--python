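"""Readers and writers: SMILES lists, generation-log CSVs, configs.

The generation log is a plain CSV, one row per generated molecule in
order, mirroring the result files de novo generators deposit. Mandatory
columns: ``index``, ``smiles``, ``valid``, ``reward``. Optional reward
and property columns (``f``, ``g``, ``lambda``, ``sa``, ``mw``,
``conjugate_length``, ``aromatic_rings``) are written by ``generate``
and preserved verbatim on round trip, as are any extra user columns
(e.g. externally computed wavelengths to be enveloped).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .catalog import MoleculeRecord, make_record
from .generator import GenerationLog
from .reward import RewardParams, SurrogateLambdaCoeffs

__all__ = [
    "RunConfig",
    "read_smiles",
    "write_smiles",
    "log_to_frame",
    "write_log",
    "read_log",
    "load_config",
    "dump_config",
]

logger = logging.getLogger("cfgmon")

MANDATORY_LOG_COLUMNS = ["index", "smiles", "valid", "reward"]
OPTIONAL_LOG_COLUMNS = ["f", "g", "lambda", "sa", "mw", "conjugate_length", "aromatic_rings"]


def read_smiles(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES list file: one molecule per non-empty line.

    An optional tab-separated identifier after the SMILES is ignored.
    Unparsable lines become records with ``valid=False`` (and a logged
    warning); they are never dropped, so stream indices stay aligned.
    """
    records: list[MoleculeRecord] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        smiles = line.split("\t")[0]
        rec = make_record(len(records), smiles)
        if not rec.valid:
            logger.warning("unparsable SMILES at line %d: %r", len(records), smiles)
        records.append(rec)
    return records


def write_smiles(records: Sequence[MoleculeRecord] | Sequence[str], path: str | Path) -> None:
    lines = [
        rec.smiles if isinstance(rec, MoleculeRecord) else rec for rec in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def log_to_frame(log: GenerationLog) -> pd.DataFrame:
    """Flatten a GenerationLog into the CSV column schema."""
    rows = []
    for rec in log:
        comp = rec.reward_components or {}
        props = rec.properties or {}
        row = {
            "index": rec.index,
            "smiles": rec.smiles,
            "valid": rec.valid,
            "reward": comp.get("r", 0.0),
            "f": comp.get("f"),
            "g": comp.get("g"),
            "lambda": comp.get("lambda"),
            "sa": comp.get("sa"),
            "mw": props.get("molecular_weight"),
            "conjugate_length": props.get("conjugate_length"),
            "aromatic_rings": props.get("aromatic_rings"),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=MANDATORY_LOG_COLUMNS + OPTIONAL_LOG_COLUMNS)


def write_log(log: GenerationLog | pd.DataFrame, path: str | Path) -> None:
    frame = log if isinstance(log, pd.DataFrame) else log_to_frame(log)
    frame.to_csv(path, index=False)


def read_log(path: str | Path) -> pd.DataFrame:
    """Read a generation-log CSV, validating the mandatory columns."""
    frame = pd.read_csv(path)
    missing = [c for c in MANDATORY_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"log {path} missing mandatory column(s): {', '.join(missing)}")
    return frame


def log_records(frame: pd.DataFrame) -> list[MoleculeRecord]:
    """Turn log rows back into molecule records (re-parsing SMILES)."""
    records = []
    for _, row in frame.iterrows():
        rec = make_record(int(row["index"]), str(row["smiles"]))
        records.append(rec)
    return records


@dataclass
class RunConfig:
    """Everything a full run needs, loadable from YAML or JSON."""

    catalog_path: str | None = None  # None -> built-in default catalog
    window_length: int = 100
    stride: int = 1
    pseudocount: float = 0.0
    seed: int = 0
    reward: RewardParams = field(default_factory=RewardParams)
    surrogate: SurrogateLambdaCoeffs = field(default_factory=SurrogateLambdaCoeffs)
    sa_provider: str = "auto"
    lm_order: int = 3
    lm_epsilon: float = 0.01
    c_explore: float = 2.0
    budget: int = 100
    n_virtual: int = 1
    max_tokens: int = 60

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.stride < 1:
            raise ValueError("window_length and stride must be >= 1")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    reward_raw = raw.pop("reward", {})
    surrogate_raw = raw.pop("surrogate", {})
    return RunConfig(
        reward=RewardParams(**reward_raw),
        surrogate=SurrogateLambdaCoeffs(**surrogate_raw),
        **raw,
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
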