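"""Cohort-level burden, enrichment testing and MDS patient grouping.

Per-sample LGT burden is the number of deduplicated events normalized to
the total number of sequenced read pairs, expressed as a percentage.
Cohort enrichment uses the classic pooled-variance unpaired two-tailed
t-test (a Welch variant is available behind a flag). Genus-level counts
of unique events form a samples x genera matrix; classical (Torgerson)
MDS of Euclidean distances between log2(count+1) profiles embeds samples
in two dimensions, and a deterministic 2-means split of the embedding
stratifies the cohort into a low- and a high-burden group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lgt_detection import LgtEvent

__all__ = [
    "MdsGrouping",
    "compute_burden",
    "compare_cohorts",
    "build_genus_matrix",
    "top_genera",
    "classical_mds",
    "mds_group",
]

BURDEN_COLUMNS = ["sample_id", "cohort", "n_events", "total_pairs", "pct_lgt"]


def compute_burden(event_counts: dict[str, int],
                   total_pairs: dict[str, int],
                   cohorts: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-sample burden: pct_lgt = 100 * n_events / total_pairs.

    ``event_counts`` maps sample_id to its deduplicated event count (a
    sample absent from the mapping has zero events); ``total_pairs`` maps
    every sample to its sequenced pair total.
    """
    rows = []
    for sid in sorted(total_pairs):
        total = total_pairs[sid]
        if total <= 0:
            raise ValueError(f"sample {sid}: total_pairs must be positive")
        n = int(event_counts.get(sid, 0))
        rows.append(
            {
                "sample_id": sid,
                "cohort": (cohorts or {}).get(sid, ""),
                "n_events": n,
                "total_pairs": total,
                "pct_lgt": 100.0 * n / total,
            }
        )
    return pd.DataFrame(rows, columns=BURDEN_COLUMNS)


def compare_cohorts(burdens: pd.DataFrame, case: str, control: str,
                    value_col: str = "pct_lgt",
                    welch: bool = False) -> dict[str, float]:
    """Unpaired two-tailed t-test of burden between two cohorts.

    Returns mean- and median-based fold changes (case over control), the
    t statistic and the two-sided p-value. Pooled-variance test by
    default; set ``welch`` for the unequal-variance variant.
    """
    a = burdens.loc[burdens["cohort"] == case, value_col].to_numpy(float)
    b = burdens.loc[burdens["cohort"] == control, value_col].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least two samples")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    mean_b, median_b = b.mean(), float(np.median(b))
    return {
        "fold_change_mean": a.mean() / mean_b if mean_b > 0 else np.inf,
        "fold_change_median": (float(np.median(a)) / median_b
                               if median_b > 0 else np.inf),
        "t": float(t),
        "p": float(p),
        "n_case": len(a),
        "n_control": len(b),
    }


def build_genus_matrix(events: list[LgtEvent] | pd.DataFrame,
                       sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Samples x genera matrix of unique (deduplicated) event counts.

    ``sample_ids`` fixes the row set (samples with no events get zero
    rows); genera are sorted alphabetically.
    """
    if isinstance(events, pd.DataFrame):
        df = events[["sample_id", "bact_genus"]]
    else:
        df = pd.DataFrame(
            {"sample_id": [e.sample_id for e in events],
             "bact_genus": [e.bact_genus for e in events]}
        )
    if df.empty:
        matrix = pd.DataFrame(index=pd.Index(sample_ids or [], name="sample_id"))
        return matrix
    matrix = (
        df.groupby(["sample_id", "bact_genus"]).size().unstack(fill_value=0)
    )
    if sample_ids is not None:
        matrix = matrix.reindex(sample_ids, fill_value=0)
    matrix = matrix[sorted(matrix.columns)].astype(int)
    matrix.index.name = "sample_id"
    matrix.columns.name = None
    return matrix


def top_genera(matrix: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Restrict to the ``n`` genera with the highest total counts,
    breaking ties alphabetically (the heat-map export)."""
    totals = matrix.sum(axis=0)
    order = sorted(matrix.columns, key=lambda g: (-totals[g], g))
    return matrix[order[:n]]


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Eigendecomposition of the doubly-centered squared-distance matrix;
    axes ordered by eigenvalue, negative eigenvalues contribute zero
    coordinates. Axis signs are fixed so the largest-magnitude coordinate
    on each axis is positive (first such sample on ties), making the
    embedding deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (dist**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:n_components]
    coords = np.zeros((n, n_components))
    for k, idx in enumerate(order):
        if eigval[idx] > 0:
            axis = eigvec[:, idx] * np.sqrt(eigval[idx])
            pivot = int(np.argmax(np.abs(axis)))
            if axis[pivot] < 0:
                axis = -axis
            coords[:, k] = axis
    return coords


def _two_means(coords: np.ndarray) -> np.ndarray:
    """Deterministic 2-means: centers initialized at the two most distant
    samples (smallest index pair on ties), Lloyd iterations to
    convergence, assignment ties to cluster 0."""
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    best = (-1.0, 0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best[0]:
                best = (d[i, j], i, j)
    centers = coords[[best[1], best[2]], :].copy()
    labels = None
    for _ in range(100):
        dist_to = np.linalg.norm(coords[:, None, :] - centers[None, :, :],
                                 axis=2)
        new_labels = (dist_to[:, 1] < dist_to[:, 0]).astype(int)
        if new_labels.sum() in (0, n):  # keep both clusters non-empty
            c = int(new_labels[0])
            far = int(np.argmax(dist_to[:, c]))
            new_labels[far] = 1 - c
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in (0, 1):
            centers[c] = coords[labels == c].mean(axis=0)
    return labels


@dataclass
class MdsGrouping:
    """Two-group stratification of samples from the MDS embedding.

    ``coordinates`` has columns dim1/dim2 indexed by sample; group 2 is
    the group with the higher mean burden, so ``fold_difference`` (mean
    group-2 burden over mean group-1 burden) is >= 1 by convention.
    """

    coordinates: pd.DataFrame
    group_labels: pd.Series
    fold_difference: float


def mds_group(matrix: pd.DataFrame, burdens: pd.DataFrame) -> MdsGrouping:
    """Stratify samples by classical MDS of genus profiles plus 2-means.

    Counts are damped as log2(count+1) before the Euclidean distance so a
    single hyper-abundant genus cannot dominate the geometry. Requires at
    least 4 samples.
    """
    if matrix.shape[0] < 4:
        raise ValueError("mds_group needs at least 4 samples")
    x = np.log2(matrix.to_numpy(float) + 1.0)
    dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    coords = classical_mds(dist, 2)
    raw_labels = _two_means(coords)
    pct = burdens.set_index("sample_id")["pct_lgt"]
    missing = set(matrix.index) - set(pct.index)
    if missing:
        raise ValueError(f"samples without burden: {sorted(missing)}")
    pct = pct.loc[matrix.index].to_numpy(float)
    mean0 = pct[raw_labels == 0].mean()
    mean1 = pct[raw_labels == 1].mean()
    # the higher-burden cluster is group 2
    if mean1 >= mean0:
        group = np.where(raw_labels == 1, 2, 1)
        hi, lo = mean1, mean0
    else:
        group = np.where(raw_labels == 0, 2, 1)
        hi, lo = mean0, mean1
    fold = hi / lo if lo > 0 else np.inf
    return MdsGrouping(
        coordinates=pd.DataFrame(coords, index=matrix.index,
                                 columns=["dim1", "dim2"]),
        group_labels=pd.Series(group, index=matrix.index, name="group"),
        fold_difference=float(fold),
    )
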