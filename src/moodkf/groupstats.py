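"""Group-level comparison of fitted dynamical features.

Eigenvectors are sign-indeterminate, so before any multivariate group
statistic each individual's vector is aligned against a valence
reference (e.g. ``[+1, +1, -1, -1]`` for cheerful/content/anxious/sad):
the vector is flipped when its inner product with the reference is
negative.  Aligned samples are compared with two-sample Hotelling T²
(multivariate) and Mann–Whitney U (univariate, non-normal); symptom
associations use Spearman rank correlation; families of element-wise
tests are Bonferroni-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlignedVectorSample",
    "align_vectors",
    "hotelling_t2",
    "mann_whitney_u",
    "spearman",
    "bonferroni_threshold",
    "apply_bonferroni",
    "elementwise_comparison_table",
]


@dataclass
class AlignedVectorSample:
    vectors: np.ndarray  # (n_subjects, N), after alignment
    reference: np.ndarray
    flipped: np.ndarray  # boolean per subject
    orthogonal: np.ndarray  # boolean: zero inner product, left unflipped


def align_vectors(vectors: np.ndarray, reference: np.ndarray) -> AlignedVectorSample:
    """Flip each vector whose inner product with the reference is negative.

    Zero inner products are left unflipped but flagged.  Idempotent.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    ref = np.asarray(reference, dtype=float).ravel()
    if np.linalg.norm(ref) == 0:
        raise ValueError("reference vector must be nonzero")
    if v.shape[1] != ref.size:
        raise ValueError("dimension mismatch")
    ips = v @ ref
    flip = ips < 0
    out = np.where(flip[:, None], -v, v)
    return AlignedVectorSample(
        vectors=out, reference=ref, flipped=flip, orthogonal=ips == 0
    )


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray):
    """Two-sample Hotelling T² with pooled covariance.

    Returns ``(T2, F, p)`` using the standard F conversion with
    ``(p, na + nb - p - 1)`` degrees of freedom.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, p = a.shape
    nb = b.shape[0]
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share dimension")
    if na <= p or nb <= p:
        raise ValueError("each group must be larger than the dimension")
    diff = a.mean(axis=0) - b.mean(axis=0)
    s_pool = ((na - 1) * np.cov(a.T) + (nb - 1) * np.cov(b.T)) / (na + nb - 2)
    s_pool = np.atleast_2d(s_pool)
    if np.linalg.cond(s_pool) > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; consider reducing the dimension"
        )
    t2 = float(na * nb / (na + nb) * diff @ np.linalg.solve(s_pool, diff))
    df2 = na + nb - p - 1
    f = t2 * df2 / ((na + nb - 2) * p)
    pval = float(stats.f.sf(f, p, df2))
    return t2, float(f), pval


def mann_whitney_u(sample_a, sample_b):
    """Two-sided Mann–Whitney U of group A (midranks for ties).

    Exact enumeration for tiny tie-free samples, normal approximation
    with tie correction otherwise (scipy's ``method='auto'``).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def spearman(x, y):
    """Spearman rank correlation with two-sided p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def apply_bonferroni(p_values: np.ndarray | pd.DataFrame, alpha: float = 0.05):
    """Boolean survived-mask for a table of p-values (family = table size)."""
    arr = p_values.to_numpy() if isinstance(p_values, pd.DataFrame) else np.asarray(p_values)
    thr = bonferroni_threshold(alpha, arr.size)
    mask = arr <= thr
    if isinstance(p_values, pd.DataFrame):
        return pd.DataFrame(mask, index=p_values.index, columns=p_values.columns)
    return mask


def elementwise_comparison_table(
    mats_a: np.ndarray,
    mats_b: np.ndarray,
    alpha: float = 0.05,
    item_names: list[str] | None = None,
) -> pd.DataFrame:
    """Mann–Whitney U per dynamics-matrix element between two groups.

    ``mats_a``/``mats_b`` are stacks of per-subject matrices (typically
    hourly dynamics matrices).  Returns a tidy table with one row per
    element (a_ij: influence of item j on item i), U, p, and a
    Bonferroni survived flag over the N*N family.
    """
    a = np.asarray(mats_a, dtype=float)
    b = np.asarray(mats_b, dtype=float)
    n = a.shape[1]
    names = item_names or [f"item{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(n):
            u, p = mann_whitney_u(a[:, i, j], b[:, i, j])
            rows.append(
                {
                    "target": names[i],
                    "source": names[j],
                    "element": f"a_{i + 1}{j + 1}",
                    "mean_a": float(a[:, i, j].mean()),
                    "mean_b": float(b[:, i, j].mean()),
                    "U": u,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["survives_bonferroni"] = df["p"] <= bonferroni_threshold(alpha, n * n)
    return df


def component_table(
    aligned_a: AlignedVectorSample,
    aligned_b: AlignedVectorSample,
    item_names: list[str] | None = None,
    alpha: float = 0.05,
    use_absolute: bool = True,
) -> pd.DataFrame:
    """Univariate per-component comparison of aligned vector samples.

    Uses absolute component values by default (the convention for
    univariate statistics on sign-aligned eigenvector components).
    """
    a, b = aligned_a.vectors, aligned_b.vectors
    if use_absolute:
        a, b = np.abs(a), np.abs(b)
    n = a.shape[1]
    names = item_names or [f"item{i}" for i in range(n)]
    rows = []
    for i in range(n):
        u, p = mann_whitney_u(a[:, i], b[:, i])
        rows.append(
            {
                "component": names[i],
                "mean_a": float(a[:, i].mean()),
                "sem_a": float(a[:, i].std(ddof=1) / np.sqrt(a.shape[0])),
                "mean_b": float(b[:, i].mean()),
                "sem_b": float(b[:, i].std(ddof=1) / np.sqrt(b.shape[0])),
                "U": u,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["survives_bonferroni"] = df["p"] <= bonferroni_threshold(alpha, n)
    return df


__all__.append("component_table")
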