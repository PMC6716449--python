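"""Reading and writing the TSV interchange formats.

Count tables are genera-as-rows, samples-as-columns TSVs with a header
row and an id column; metadata and environment tables are one row per
sample with ISO-8601 dates.  Every table written by the pipeline starts
with a provenance comment line (``# seed=... config_hash=...``) which the
readers skip.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .design import validate_design
from .exceptions import InputError
from .prep import validate_counts


def read_counts(path) -> pd.DataFrame:
    """Read a genus x sample count table; errors name the offending cell."""
    if not os.path.exists(path):
        raise InputError(f"counts file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = df.index.name or "genus_id"
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[~df[col].astype(str).str.fullmatch(r"-?\d+")][0]
            raise InputError(
                f"non-numeric count at genus {bad!r}, sample {col!r}"
            )
    return validate_counts(df)


def read_design(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise InputError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_design(df)


def read_env(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise InputError(f"environment file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df


def align_tables(counts: pd.DataFrame, design: pd.DataFrame,
                 env: pd.DataFrame | None = None):
    """Cross-validate ids and put all tables in the design's sample order."""
    design = validate_design(design)
    sample_ids = pd.Index(design["sample_id"])
    missing = pd.Index(counts.columns).difference(sample_ids)
    if len(missing):
        raise InputError(f"sample {missing[0]!r} in counts is missing from metadata")
    missing = sample_ids.difference(counts.columns)
    if len(missing):
        raise InputError(f"sample {missing[0]!r} in metadata is missing from counts")
    counts = counts[sample_ids]
    if env is not None:
        missing = sample_ids.difference(env.index)
        if len(missing):
            raise InputError(
                f"sample {missing[0]!r} in metadata is missing from environment table"
            )
        env = env.loc[sample_ids]
    return counts, design, env


def write_table(df: pd.DataFrame, path, provenance: str | None = None,
                index: bool = True):
    """Write a TSV, optionally prefixed with a provenance comment line."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        out = df.copy()
        for col in out.columns:
            if out[col].dtype == object and len(out) and isinstance(
                out[col].iloc[0], (pd.Timestamp,)
            ):
                out[col] = out[col].astype(str)
        out.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def labels_from_frame(df: pd.DataFrame) -> pd.Series:
    """Extract a genus -> cluster mapping from a labels table."""
    if "cluster" not in df.columns:
        raise InputError("labels table needs a 'cluster' column")
    return df["cluster"].astype(int)
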