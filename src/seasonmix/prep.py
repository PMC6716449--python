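"""Count-table preprocessing: rarefaction, richness, rank abundance."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import InputError
from .simulate import as_rng

logger = logging.getLogger(__name__)

#: Default rarefaction depths (reads per sample) for the two marker genes;
#: each is the lowest observed sequencing depth in the respective library.
DEFAULT_FUNGAL_DEPTH = 21_307
DEFAULT_BACTERIAL_DEPTH = 19_998


def validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check a genus x sample count table: integer-valued, non-negative,
    unique ids on both axes."""
    if table.index.duplicated().any():
        raise InputError(
            f"duplicate genus id {table.index[table.index.duplicated()][0]!r}"
        )
    if table.columns.duplicated().any():
        raise InputError(
            f"duplicate sample id {table.columns[table.columns.duplicated()][0]!r}"
        )
    vals = table.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise InputError("count table contains non-numeric entries")
    if (vals < 0).any():
        g, s = np.argwhere(vals < 0)[0]
        raise InputError(
            f"negative count at genus {table.index[g]!r}, sample {table.columns[s]!r}"
        )
    if not np.allclose(vals, np.round(vals)):
        g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise InputError(
            f"non-integer count at genus {table.index[g]!r}, sample {table.columns[s]!r}"
        )
    return table.astype(np.int64)


def rarefy(table: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Subsample each sample (column) to exactly ``depth`` reads without
    replacement.

    Samples whose total is below ``depth`` are dropped with a warning;
    samples already at ``depth`` pass through unchanged (the hypergeometric
    draw is then the identity).  Rarefied counts never exceed the originals
    and every retained column sums exactly to ``depth``.
    """
    if depth <= 0:
        raise InputError("rarefaction depth must be a positive integer")
    table = validate_counts(table)
    rng = as_rng(seed)
    totals = table.sum(axis=0)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning(
            "rarefy: dropping %d sample(s) with fewer than %d reads: %s",
            len(dropped), depth, ", ".join(map(str, dropped[:10])),
        )
    out = {}
    for sample in keep:
        col = table[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=table.index, columns=keep)


def genus_richness(table: pd.DataFrame) -> pd.Series:
    """Number of genera with at least one read, per sample."""
    table = validate_counts(table)
    return (table > 0).sum(axis=0).rename("richness")


def rank_abundance(table: pd.DataFrame, labels: pd.Series | None = None):
    """Rank genera by total reads (rank 1 = most abundant).

    Ties are broken by genus id in lexicographic order so ranks are a
    deterministic permutation of 1..G.  If cluster ``labels`` are given
    they must cover every genus; the per-cluster min/max rank range is
    returned as a second frame (the spread of abundance ranks a cluster
    spans).

    Returns ``ranks`` (DataFrame: genus_id, total, rank[, cluster]) and,
    when labels are given, ``ranges`` (DataFrame per cluster: min_rank,
    max_rank, n_genera).
    """
    table = validate_counts(table)
    totals = table.sum(axis=1)
    order = sorted(totals.index, key=lambda g: (-totals[g], str(g)))
    ranks = pd.DataFrame(
        {"total": totals.loc[order], "rank": np.arange(1, len(order) + 1)},
        index=pd.Index(order, name=table.index.name or "genus_id"),
    )
    if labels is None:
        return ranks
    labels = pd.Series(labels)
    missing = ranks.index.difference(labels.index)
    if len(missing):
        raise InputError(f"cluster labels missing for genus {missing[0]!r}")
    ranks["cluster"] = labels.loc[ranks.index].to_numpy()
    ranges = (
        ranks.groupby("cluster")["rank"]
        .agg(min_rank="min", max_rank="max", n_genera="count")
        .sort_index()
    )
    return ranks, ranges
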