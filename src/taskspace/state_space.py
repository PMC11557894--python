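"""Projection of activation maps into the gradient state space.

A map's coordinate on a gradient is the Spearman rank correlation between
the map and that gradient: ranks are assigned with the average-rank
convention for ties, then Pearson correlation is taken on the ranks (exact
under ties, unlike the classical sum-of-squared-rank-differences shortcut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .conditions import (
    TRAITS,
    MissingSubjectError,
    UndefinedCorrelationError,
    task_of,
)
from .synthetic import GradientBasis, MapSet

__all__ = [
    "project_map",
    "project_cohort",
    "condition_centroids",
    "map_similarity_matrix",
    "SimilarityMatrix",
]


def _zranks(x: np.ndarray) -> np.ndarray:
    """Average ranks, centered and scaled to unit norm (per column)."""
    r = np.apply_along_axis(rankdata, 0, x) if x.ndim == 2 else rankdata(x)
    r = r - r.mean(axis=0)
    nrm = np.linalg.norm(r, axis=0)
    if np.any(nrm == 0):
        raise UndefinedCorrelationError("constant vector: rank correlation undefined")
    return r / nrm


def project_map(map_values: np.ndarray, basis: GradientBasis) -> np.ndarray:
    """Spearman rank correlation of one map with each gradient.

    Invariant under any strictly increasing transform of the map; returns
    exactly +/-1 for maps that are monotone (anti-)transforms of a gradient.
    """
    m = np.asarray(map_values, dtype=float)
    if m.ndim != 1 or m.shape[0] != basis.n_vertices:
        raise ValueError(
            f"map has length {m.shape}, basis expects {basis.n_vertices} vertices"
        )
    if np.ptp(m) == 0:
        raise UndefinedCorrelationError("constant map: rank correlation undefined")
    rm = _zranks(m)
    rb = _zranks(basis.values)
    return rb.T @ rm


def project_cohort(
    maps: MapSet,
    basis: GradientBasis,
    cohort: pd.DataFrame,
) -> pd.DataFrame:
    """Project every map of a cohort; return the long state-space table.

    One row per (subject, condition, dimension) with location and joined
    covariates; mean framewise displacement is joined per the task owning
    each condition. Subjects missing a condition simply contribute no rows
    for it.
    """
    if maps.n_vertices != basis.n_vertices:
        raise ValueError(
            f"maps have {maps.n_vertices} vertices, basis has {basis.n_vertices}"
        )
    cohort_ids = set(cohort["subject_id"])
    missing = [s for s in maps.subjects if s not in cohort_ids]
    if missing:
        raise MissingSubjectError(
            f"subjects in map set but not in cohort: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    rb = _zranks(basis.values)  # nv x nd
    dims = basis.dim_names
    meta = cohort.set_index("subject_id")
    trait_cols = [t for t in TRAITS if t in cohort.columns]

    frames = []
    for c in maps.conditions:
        mat = maps.data[c]
        if np.any(np.ptp(mat, axis=0) == 0):
            j = int(np.flatnonzero(np.ptp(mat, axis=0) == 0)[0])
            raise UndefinedCorrelationError(
                f"constant map for subject {maps.subjects[j]!r}, condition {c!r}"
            )
        rm = _zranks(mat)  # nv x n
        locs = rm.T @ rb  # n x nd
        fd_col = f"mean_fd_{task_of(c)}"
        sub = list(maps.subjects)
        block = pd.DataFrame(
            {
                "subject_id": np.repeat(sub, len(dims)),
                "family_id": np.repeat(meta.loc[sub, "family_id"].to_numpy(), len(dims)),
                "condition": c,
                "dimension": np.tile(dims, len(sub)),
                "location": locs.ravel(),
                "age": np.repeat(meta.loc[sub, "age"].to_numpy(), len(dims)),
                "gender": np.repeat(meta.loc[sub, "gender"].to_numpy(), len(dims)),
                "mean_fd": np.repeat(
                    meta.loc[sub, fd_col].to_numpy() if fd_col in meta else np.nan,
                    len(dims),
                ),
            }
        )
        for t in trait_cols:
            block[t] = np.repeat(meta.loc[sub, t].to_numpy(), len(dims))
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def condition_centroids(table: pd.DataFrame) -> pd.DataFrame:
    """Mean location per (condition, dimension), with per-cell n."""
    if len(table) == 0:
        raise ValueError("state-space table is empty")
    g = table.groupby(["condition", "dimension"], observed=True)["location"]
    out = g.agg(mean="mean", n="size").reset_index()
    return out


@dataclass
class SimilarityMatrix:
    """Pairwise rank-correlation similarity of maps across the whole set."""

    labels: tuple[tuple[str, str], ...]  # (subject, condition) pairs
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.labels, names=["subject_id", "condition"])
        return pd.DataFrame(self.values, index=idx, columns=idx)


def map_similarity_matrix(maps: MapSet) -> SimilarityMatrix:
    """Spearman correlation between every pair of maps in the set."""
    labels = []
    cols = []
    for (s, c), vec in maps.items():
        if np.ptp(vec) == 0:
            raise UndefinedCorrelationError(
                f"constant map for subject {s!r}, condition {c!r}"
            )
        labels.append((s, c))
        cols.append(vec)
    if len(cols) < 2:
        raise ValueError("need at least two maps for a similarity matrix")
    R = _zranks(np.column_stack(cols))
    V = R.T @ R
    np.fill_diagonal(V, 1.0)
    V = np.clip((V + V.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(labels=tuple(labels), values=V)
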