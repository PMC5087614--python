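"""Spike-in-normalized, resampling-based non-parametric differential expression.

The scheme re-implemented here is the one used for 5'-tag (STRT) libraries:

1.  Per-sample size factors come from spike-in totals alone, so depth is
    estimated independently of endogenous expression (absolute rather than
    proportion-based normalization).
2.  Counts are equalized across samples by *binomial down-sampling* to the
    shallowest sample's depth — a resampled count can never exceed the
    observed one — repeated D times.
3.  Per TFE the two-class statistic is the standardized Wilcoxon rank-sum of
    the first class (mid-ranks for ties, tie-corrected null SD), averaged
    over the D resampled matrices.
4.  Significance is a SAM-style permutation q-value: for each threshold, the
    median over B label permutations of the number of null statistics at
    least as extreme, divided by the number of observed statistics at least
    as extreme; clipped to [0, 1] and monotonized so that thresholding at
    any q selects a contiguous top set.  A pooled permutation p-value is
    reported alongside.

Tag matrices are zero-inflated; the mid-rank treatment of ties means an
all-zero TFE gets statistic 0 and q 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import SpikeTagMatrix, NormalizationError, DesignError


def spike_size_factors(matrix: SpikeTagMatrix) -> pd.Series:
    """Per-sample size factors: spike total / median spike total.

    The median factor is 1 by construction.  A sample with zero spike counts
    cannot be normalized and raises :class:`NormalizationError` naming it.
    """
    totals = matrix.spike_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise NormalizationError(f"zero spike-in total in sample(s): {zero}")
    factors = totals / np.median(totals.to_numpy())
    factors.name = "size_factor"
    return factors.astype(float)


def resample_counts(
    matrix: SpikeTagMatrix,
    factors: pd.Series,
    D: int,
    seed: int,
) -> list[pd.DataFrame]:
    """D binomial down-samplings of the endogenous counts to the minimum depth.

    Each endogenous count c_ij is replaced by Binomial(c_ij, f_min / f_j)
    draws, independently per repetition; samples already at f_min are copied
    unchanged.  Spike rows are dropped from the output (they are the
    normalizer, not test material).
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    endo = matrix.endogenous()
    f = factors.loc[endo.columns].to_numpy(dtype=float)
    if (f <= 0).any():
        raise NormalizationError("non-positive size factor")
    p = f.min() / f  # per-sample retention probability, 1 for the shallowest
    rng = np.random.default_rng(seed)
    counts = endo.to_numpy()
    out = []
    at_min = np.isclose(p, 1.0)
    for _ in range(D):
        drawn = rng.binomial(counts, p[np.newaxis, :])
        drawn[:, at_min] = counts[:, at_min]
        out.append(pd.DataFrame(drawn, index=endo.index, columns=endo.columns))
    return out


@dataclass
class DEResult:
    """Per-TFE differential-expression calls for one two-class comparison."""

    table: pd.DataFrame  # columns: statistic, direction, p, q
    class_a: list[str]
    class_b: list[str]

    def calls(self, q_threshold: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]


def _ranks_and_sds(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise mid-ranks and the tie-corrected null SD of a rank-sum.

    For a subset of size n1 drawn without replacement from the row's ranks,
    Var(W) = n1 * n2 / (n * (n - 1)) * sum_j (R_j - (n+1)/2)^2, which reduces
    to the usual n1*n2*(n+1)/12 when there are no ties and to 0 when the whole
    row is tied.
    """
    n = mat.shape[1]
    ranks = rankdata(mat, axis=1)
    centered = ranks - (n + 1) / 2.0
    ss = (centered**2).sum(axis=1)
    return ranks, ss


def de_test(
    matrix: SpikeTagMatrix,
    class_a: list[str],
    class_b: list[str],
    D: int = 20,
    B: int = 100,
    seed: int = 0,
) -> DEResult:
    """Two-class resampling rank test with permutation q-values.

    ``class_a`` is the test class (e.g. GFP+ wells of a construct); a positive
    statistic / direction "up" means higher normalized expression in class_a.

    Label swaps flip every direction and leave q unchanged: the permutation
    null is built from column subsets of size min(n_a, n_b) of the identical
    sorted sample union, and |rank-sum statistic| of a subset equals that of
    its complement.
    """
    if len(class_a) < 2 or len(class_b) < 2:
        raise DesignError("each class needs >= 2 samples")
    if set(class_a) & set(class_b):
        raise DesignError("classes overlap")
    selected = sorted(set(class_a) | set(class_b))
    sub = matrix.subset_samples(selected)
    factors = spike_size_factors(sub)
    resampled = resample_counts(sub, factors, D=D, seed=seed)

    cols = list(resampled[0].columns)
    col_pos = {c: i for i, c in enumerate(cols)}
    idx_a = np.array([col_pos[c] for c in class_a])
    n = len(cols)
    n_a, n_b = len(class_a), len(class_b)
    mu_a = n_a * (n + 1) / 2.0
    var_scale = n_a * n_b / (n * (n - 1.0))

    # permutation subsets: size min(n_a, n_b) prefixes of seeded column shuffles
    rng = np.random.default_rng(np.random.SeedSequence([seed, n, B]))
    k = min(n_a, n_b)
    perm_idx = np.array([rng.permutation(n)[:k] for _ in range(B)])
    mu_k = k * (n + 1) / 2.0
    var_scale_k = k * (n - k) / (n * (n - 1.0))

    n_rows = resampled[0].shape[0]
    obs = np.zeros(n_rows)
    null = np.zeros((B, n_rows))
    for rep in resampled:
        ranks, ss = _ranks_and_sds(rep.to_numpy())
        sd = np.sqrt(var_scale * ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, (ranks[:, idx_a].sum(axis=1) - mu_a) / sd, 0.0)
        obs += t
        sd_k = np.sqrt(var_scale_k * ss)
        w_null = ranks[:, perm_idx.ravel()].reshape(n_rows, B, k).sum(axis=2).T
        with np.errstate(divide="ignore", invalid="ignore"):
            null += np.where(sd_k[np.newaxis, :] > 0, (w_null - mu_k) / sd_k, 0.0)
    obs /= D
    null /= D

    q, p = _sam_qvalues(obs, null)
    table = pd.DataFrame(
        {
            "statistic": obs,
            "direction": np.where(obs < 0, "down", "up"),
            "p": p,
            "q": q,
        },
        index=resampled[0].index,
    )
    table.index.name = "tfe_id"
    return DEResult(table=table, class_a=list(class_a), class_b=list(class_b))


def _sam_qvalues(obs: np.ndarray, null: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SAM-style q-values and pooled permutation p-values from |statistics|.

    q_raw(c) = median_b #{|null_b| >= c} / #{|obs| >= c}, evaluated at each
    observed |statistic|, clipped to [0, 1], then monotonized: each TFE gets
    the minimum raw q over all thresholds at or below its own |statistic|, so
    q is non-decreasing as |statistic| decreases.
    """
    a_obs = np.abs(obs)
    B, n = null.shape
    order = np.argsort(-a_obs)  # descending |t|
    thresholds = a_obs[order]
    # observed exceedances at each threshold (ties share the larger count)
    sorted_asc = np.sort(a_obs)
    obs_ge = n - np.searchsorted(sorted_asc, thresholds, side="left")
    null_sorted = np.sort(np.abs(null), axis=1)
    null_ge = np.empty((B, n))
    for b in range(B):
        null_ge[b] = n - np.searchsorted(null_sorted[b], thresholds, side="left")
    med_null = np.median(null_ge, axis=0)
    q_raw = np.clip(med_null / np.maximum(obs_ge, 1), 0.0, 1.0)
    # monotonize: cumulative min from the least extreme threshold upward
    q_desc = np.minimum.accumulate(q_raw[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_desc

    pooled = null_sorted.ravel()
    pooled.sort()
    ge = pooled.size - np.searchsorted(pooled, a_obs, side="left")
    p = (1.0 + ge) / (1.0 + pooled.size)
    return q, np.minimum(p, 1.0)
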