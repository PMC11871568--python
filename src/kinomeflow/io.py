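"""Plain-text readers/writers for the pipeline's tabular artifacts.

All tables travel as TSV with fixed column schemas; sets travel as JSON
with sorted members so serialized artifacts are byte-stable for identical
inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .differential import DifferentialSet

KINETICS_COLUMNS = ["peptide_id", "sample_id", "cycle_time_min", "exposure_ms", "intensity"]
SIGNAL_COLUMNS = ["peptide_id", "sample_id", "slope", "intercept", "r_squared", "n_points", "signal", "qc_pass"]
CONTRAST_COLUMNS = ["gene_id", "log2fc", "padj"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_kinetics(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, KINETICS_COLUMNS)


def read_signals(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["peptide_id", "sample_id", "signal", "qc_pass"])
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["sample_id", "genotype", "treatment", "replicate"])


def read_contrast(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, CONTRAST_COLUMNS)


def write_differential_set(diff: DifferentialSet, path: str | Path) -> None:
    payload = {
        "name": diff.name,
        "up": sorted(diff.up),
        "down": sorted(diff.down),
        "background": sorted(diff.background),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_differential_set(path: str | Path) -> DifferentialSet:
    with open(path) as fh:
        payload = json.load(fh)
    return DifferentialSet(
        name=payload["name"],
        up=frozenset(payload["up"]),
        down=frozenset(payload["down"]),
        background=frozenset(payload["background"]),
    )


def write_json(obj: object, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
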