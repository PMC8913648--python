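"""Readers and writers for the pipeline's tables, plus run configuration.

All kinetic data travels as long (tidy) CSV -- one row per (sample, time,
channel) -- which stays unambiguous with multiple channels and replicates;
abundance tables are TSV with samples as rows and metadata columns joined by
sample_id.  Readers validate and reject rather than coerce; writers emit a
deterministic column order so identical runs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RunConfig",
    "PLATE_COLUMNS",
    "read_plate_csv",
    "write_plate_csv",
    "read_taxa_tsv",
    "write_taxa_tsv",
    "read_config",
]

PLATE_COLUMNS = ["sample_id", "glycan_id", "compound_class", "replicate",
                 "time", "channel", "value"]
CHANNELS = {"OD600", "F_sens", "F_iso", "pressure_psi"}
META_COLUMNS = ["glycan_id", "compound_class", "donor_id", "replicate"]


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters shared across the pipeline."""

    seed: int = 0
    smoothing_window: int = 9
    smoothing_degree: int = 2
    elbow_kmax: int = 12
    kmeans_restarts: int = 25
    nmds_restarts: int = 20
    pseudocount: float = 1e-5
    alpha: float = 0.05
    control_label: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 3")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def read_config(path) -> RunConfig:
    """Parse a flat key = value config file; unrecognized keys are errors."""
    known = {f.name: f.type for f in fields(RunConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unrecognized config key {key!r}")
        typ = known[key]
        if typ == "int":
            kwargs[key] = int(val)
        elif typ == "float":
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def write_plate_csv(plate: pd.DataFrame, path) -> None:
    plate[PLATE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_plate_csv(path) -> pd.DataFrame:
    """Read and validate a long-format kinetic plate CSV."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV {path} is missing column(s): {missing}")
    for col in ("time", "value"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"column {col!r} contains non-numeric values")
    if df["value"].isna().any() or df["time"].isna().any():
        raise ValueError("plate CSV contains missing time/value entries")
    if (df["time"] < 0).any():
        raise ValueError("negative timepoints")
    bad_chan = set(df["channel"]) - CHANNELS
    if bad_chan:
        raise ValueError(f"unknown channel(s): {sorted(bad_chan)}")
    if df.duplicated(["sample_id", "time", "channel"]).any():
        raise ValueError("duplicate (sample_id, time, channel) rows")
    for (sample, _chan), grp in df.groupby(["sample_id", "channel"]):
        if (np.diff(grp["time"].to_numpy()) <= 0).any():
            raise ValueError(f"time not strictly increasing for sample {sample!r}")
    return df[PLATE_COLUMNS]


def write_taxa_tsv(taxa: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    out = pd.concat([meta[META_COLUMNS], taxa], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_taxa_tsv(path, normalize: bool = False):
    """Read a samples x taxa abundance TSV with leading metadata columns.

    Returns ``(taxa, meta)`` indexed by sample_id.  With ``normalize`` the
    abundance block is renormalized to unit row sums (counts -> relative).
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"taxa TSV {path} is missing metadata column(s): {missing}")
    meta = df[META_COLUMNS]
    taxa = df.drop(columns=META_COLUMNS).astype(float)
    if (taxa < 0).to_numpy().any():
        raise ValueError("negative abundance values")
    sums = taxa.sum(axis=1)
    empty = sums[sums == 0].index.tolist()
    if empty:
        raise ValueError(f"empty sample(s): {empty}")
    if normalize:
        taxa = taxa.div(sums, axis=0)
    elif (np.abs(sums - 1.0) > 1e-8).any():
        raise ValueError("rows do not sum to 1; pass normalize=True for count tables")
    return taxa, meta
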