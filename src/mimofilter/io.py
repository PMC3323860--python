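"""Readers and writers for the delimited-text interchange formats.

Matrices are samples x features tables with a header row of feature
identifiers and a first column of sample identifiers; targets are
analogous tables of binary columns. Tab-separated is the default, with a
comma fallback detected by sniffing the header line. Every file written
by the command-line tools starts with '#' provenance comment lines
(version, seed, configuration echo) sufficient to reproduce the run;
readers skip them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import Dataset, FeatureMatrix, TargetSet
from .meta_protocols import StudyCollection

__all__ = [
    "read_matrix",
    "read_targets",
    "read_table",
    "write_table",
    "provenance_header",
    "load_manifest",
]


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: no header line found")


def read_table(path) -> pd.DataFrame:
    """Read a delimited table, skipping '#' comment lines, first column as
    the sample index. Rejects duplicate or missing entries with locations."""
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path, encoding="utf-8") as fh:
        header = next(line for line in fh if not line.startswith("#"))
    cols = header.rstrip("\n").split(sep)[1:]
    dupes = {c for c in cols if cols.count(c) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate column identifiers {sorted(dupes)}")
    df = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    if df.isna().any().any():
        bad = [
            (str(df.index[i]), df.columns[j])
            for i, j in zip(*np.where(df.isna().to_numpy()))
        ]
        raise ValueError(f"{path}: missing values at (sample, column) {bad[:5]}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    return df


def read_matrix(path) -> tuple[FeatureMatrix, list[str]]:
    """Read and standardize a feature matrix; returns (matrix, sample ids)."""
    df = read_table(path)
    fm = FeatureMatrix.from_raw(df.to_numpy(dtype=float), feature_ids=list(df.columns))
    return fm, [str(s) for s in df.index]


def read_targets(path, primary: str, secondaries: list[str] | None = None) -> TargetSet:
    """Read binary target columns by name from a targets table."""
    df = read_table(path)
    secondaries = secondaries or []
    for col in [primary, *secondaries]:
        if col not in df.columns:
            raise ValueError(f"{path}: target column {col!r} not found")
        vals = set(np.unique(df[col].to_numpy()))
        if not vals <= {0, 1}:
            raise ValueError(
                f"{path}: column {col!r} is not binary 0/1 (values {sorted(vals)})"
            )
    return TargetSet(
        primary=df[primary].to_numpy(dtype=int),
        secondaries=[df[c].to_numpy(dtype=int) for c in secondaries],
    )


def provenance_header(seed: int | None, **config) -> str:
    parts = [f"# mimofilter {__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config:
        parts.append(f"# config: {json.dumps(config, sort_keys=True, default=str)}")
    return "\n".join(parts) + "\n"


def write_table(
    path, df: pd.DataFrame, seed: int | None = None, force: bool = False, **config
) -> None:
    """Write a TSV table with a provenance comment header."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True / --force to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed, **config))
        df.to_csv(fh, sep="\t", index=True)


def load_manifest(path) -> StudyCollection:
    """Load a multi-study manifest: a JSON list of
    {"matrix_path", "targets_path", "primary_col", "secondary_cols", "name"}.
    Relative paths resolve against the manifest location."""
    path = Path(path)
    entries = json.loads(path.read_text(encoding="utf-8"))
    studies, names = [], []
    for i, entry in enumerate(entries):
        base = path.parent
        fm, _ = read_matrix(base / entry["matrix_path"])
        targets = read_targets(
            base / entry["targets_path"],
            entry["primary_col"],
            entry.get("secondary_cols", []),
        )
        name = entry.get("name", f"study{i}")
        studies.append(Dataset(features=fm, targets=targets, name=name))
        names.append(name)
    return StudyCollection(studies=studies, names=names)
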