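"""Compositional indicator-genus analysis.

Each genus in a cluster is scored by how faithfully its abundance profile
tracks the cluster: the indicator value is the mean proportional
similarity between the focal genus's sample-normalized profile and the
profiles of the other cluster members.  Proportional similarity of two
profiles p, q (each summing to 1 over samples) is sum_s min(p_s, q_s),
bounded in [0, 1]: 1 for identical seasonal/spatial shapes, 0 for
disjoint support.  The score only sees relative abundance, so it is
invariant to the overall abundance of a genus.

Significance is assessed by permutation: the same mean-similarity
statistic is recomputed for randomly drawn genus sets of the same size,
and p = (1 + #{null >= observed}) / (1 + n_permutations).  With the
default 99 permutations the smallest attainable p is 0.01.

Note: this is a genus-fidelity statistic for clusters *of genera*; it is
deliberately not the Dufrene-Legendre IndVal, which scores indicators of
sample groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InputError
from .prep import validate_counts
from .simulate import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "proportional_similarity",
    "indicator_value",
    "permutation_pvalue",
    "indicator_table",
]


def _normalize_profile(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    total = v.sum()
    if total <= 0:
        raise DegenerateInputError("profile has no reads; similarity undefined")
    return v / total


def proportional_similarity(p, q) -> float:
    """sum_s min(p_s, q_s) of two sample-normalized abundance profiles."""
    return float(np.minimum(_normalize_profile(p), _normalize_profile(q)).sum())


def indicator_value(focal, members) -> float:
    """Mean proportional similarity of a focal genus to its cluster mates.

    ``members`` are the profiles of the *other* genera in the cluster
    (the focal genus is excluded by the caller to avoid self-similarity
    inflation).
    """
    members = list(members)
    if not members:
        raise InputError("cluster must contain at least one other genus")
    return float(np.mean([proportional_similarity(focal, m) for m in members]))


def _similarity_matrix(table: pd.DataFrame) -> np.ndarray:
    """All-pairs proportional similarity between genus profiles."""
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = table.index[np.argmax(totals <= 0)]
        raise DegenerateInputError(f"genus {bad!r} has zero total reads")
    P = counts / totals[:, None]
    g = len(P)
    sim = np.empty((g, g))
    for i in range(g):
        sim[i] = np.minimum(P[i], P).sum(axis=1)
    return sim


def permutation_pvalue(observed: float, cluster_size: int, all_profiles,
                       n_permutations: int = 99, seed=None) -> float:
    """Permutation p-value for an observed mean-similarity statistic.

    Null draws pick ``cluster_size`` genera at random from the pool
    (one focal plus cluster_size - 1 comparison members) and recompute the
    focal-to-members mean similarity.  ``cluster_size`` counts the focal
    genus, matching the size of the observed cluster.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    table = pd.DataFrame(all_profiles)
    g = len(table)
    if cluster_size < 2:
        raise InputError("cluster_size must be >= 2 (focal plus one member)")
    if cluster_size > g:
        raise InputError(f"cluster_size {cluster_size} exceeds genus pool {g}")
    sim = _similarity_matrix(table)
    rng = as_rng(seed)
    null = _null_stats(sim, cluster_size, n_permutations, rng)
    return float((1 + np.sum(null >= observed)) / (1 + n_permutations))


def _null_stats(sim: np.ndarray, cluster_size: int, n_permutations: int,
                rng: np.random.Generator) -> np.ndarray:
    g = sim.shape[0]
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        idx = rng.choice(g, size=cluster_size, replace=False)
        out[i] = sim[idx[0], idx[1:]].mean()
    return out


def indicator_table(table: pd.DataFrame, clusters: pd.Series,
                    n_permutations: int = 99, seed=None) -> pd.DataFrame:
    """Score every genus's fidelity to its cluster, with permutation p.

    ``clusters`` maps every genus id to a cluster label.  For each genus
    the indicator value is its mean similarity to the other members of
    its cluster; singleton clusters get a missing value and a warning.
    The null distribution is drawn once per cluster (it depends only on
    the cluster size) and shared by that cluster's genera.

    Returns one row per genus: cluster, indicator_value, p_value,
    n_permutations, top (True for the cluster's most reliable indicator;
    value ties break toward the lexicographically first genus id).
    """
    table = validate_counts(table)
    clusters = pd.Series(clusters)
    missing = table.index.difference(clusters.index)
    if len(missing):
        raise InputError(f"cluster label missing for genus {missing[0]!r}")
    clusters = clusters.loc[table.index]
    sim = _similarity_matrix(table)
    rng = as_rng(seed)
    pos = {gid: i for i, gid in enumerate(table.index)}

    rows = []
    for cluster in sorted(clusters.unique()):
        members = clusters.index[clusters == cluster]
        midx = np.array([pos[m] for m in members])
        if len(members) < 2:
            logger.warning(
                "cluster %r is a singleton; indicator value undefined", cluster
            )
            rows.append(
                {"genus_id": members[0], "cluster": cluster,
                 "indicator_value": np.nan, "p_value": np.nan}
            )
            continue
        null = _null_stats(sim, len(members), n_permutations, rng)
        for gid in members:
            i = pos[gid]
            others = midx[midx != i]
            value = sim[i, others].mean()
            p = (1 + np.sum(null >= value)) / (1 + n_permutations)
            rows.append(
                {"genus_id": gid, "cluster": cluster,
                 "indicator_value": value, "p_value": p}
            )
    out = pd.DataFrame(rows).set_index("genus_id")
    out["n_permutations"] = n_permutations
    out["top"] = False
    for cluster, grp in out.groupby("cluster"):
        valid = grp.dropna(subset=["indicator_value"])
        if valid.empty:
            continue
        best = valid.sort_index().sort_values(
            "indicator_value", kind="stable", ascending=False
        ).index[0]
        out.loc[best, "top"] = True
    return out
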