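"""Gene-set overlap statistics: expected counts, chi-squared association,
exact binomial/Poisson tails, BH-adjusted multi-dataset families and Venn
decomposition.

The universe is the set of genes testable in the experiment (genes with at
least one detected coding-5'UTR TFE), supplied explicitly — "expected by
chance" is only meaningful against a finite tested universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def expected_overlap(a: int, b: int, n: int) -> float:
    """Expected overlap a*b/n of two random subsets of sizes a, b in a universe of n."""
    if n <= 0:
        raise ValueError("universe size must be positive")
    if a > n or b > n or a < 0 or b < 0:
        raise ValueError("set sizes must lie in [0, universe size]")
    return a * b / n


@dataclass
class OverlapTestResult:
    set_a_size: int
    set_b_size: int
    universe_size: int
    observed: int
    expected: float
    chi2_stat: float
    chi2_p: float
    tail_p: float
    fdr_adjusted_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= min(self.set_a_size, self.set_b_size):
            raise ValueError("observed overlap outside [0, min set size]")


def overlap_chisq(set_a: set, set_b: set, universe: set) -> OverlapTestResult:
    """Chi-squared test of association (1 df, no continuity correction) on the
    2x2 membership table of two gene sets over a universe."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    a, b = len(set_a), len(set_b)
    obs = len(set_a & set_b)
    table = np.array(
        [
            [obs, a - obs],
            [b - obs, n - a - b + obs],
        ],
        dtype=float,
    )
    exp = expected_overlap(a, b, n)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected_table = row * col / n
    if (expected_table == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2 = float(((table - expected_table) ** 2 / expected_table).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    tail = overlap_tail_p(obs, exp, trials=a) if exp > 0 else 1.0
    return OverlapTestResult(
        set_a_size=a,
        set_b_size=b,
        universe_size=n,
        observed=obs,
        expected=exp,
        chi2_stat=chi2,
        chi2_p=p,
        tail_p=tail,
    )


def overlap_tail_p(observed: int, expected: float, trials: Optional[int] = None) -> float:
    """Exact upper-tail probability of seeing >= ``observed`` overlapping genes.

    With ``trials`` given: P(X >= observed) for X ~ Binomial(trials,
    expected/trials) — the chance a target set of that size overlaps an
    activated set at least as much as observed.  Without ``trials``: the
    Poisson(expected) upper tail.  Both are exact tail summations (regularized
    incomplete beta/gamma), not normal approximations.
    """
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if trials is not None:
        if expected > trials:
            raise ValueError("expected cannot exceed trials")
        p = expected / trials
        return float(stats.binom.sf(observed - 1, trials, p))
    return float(stats.poisson.sf(observed - 1, expected))


def multi_dataset_overlap(
    target_sets: dict[str, set],
    activated_sets: dict[str, set],
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chi-squared overlap tests for every (target set x dataset) pair, with
    Benjamini-Hochberg adjustment across the whole family.

    Returns a tidy frame with one row per pair and a ``significant`` flag at
    the adjusted-p < alpha level.
    """
    if not target_sets or not activated_sets:
        raise ValueError("need at least one target set and one dataset")
    rows = []
    for t_name, t_set in target_sets.items():
        for d_name, d_set in activated_sets.items():
            r = overlap_chisq(t_set, d_set, universe)
            rows.append(
                {
                    "target_set": t_name,
                    "dataset": d_name,
                    "set_a_size": r.set_a_size,
                    "set_b_size": r.set_b_size,
                    "universe_size": r.universe_size,
                    "observed": r.observed,
                    "expected": r.expected,
                    "chi2_stat": r.chi2_stat,
                    "chi2_p": r.chi2_p,
                    "tail_p": r.tail_p,
                }
            )
    out = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(out["chi2_p"], method="fdr_bh")
    out["fdr_adjusted_p"] = adj
    out["significant"] = out["fdr_adjusted_p"] < alpha
    return out


VENN_REGIONS = ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc")


def venn_counts(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a three-set Venn decomposition."""
    abc = set_a & set_b & set_c
    ab = (set_a & set_b) - abc
    ac = (set_a & set_c) - abc
    bc = (set_b & set_c) - abc
    return {
        "a_only": len(set_a - set_b - set_c),
        "b_only": len(set_b - set_a - set_c),
        "c_only": len(set_c - set_a - set_b),
        "ab_only": len(ab),
        "ac_only": len(ac),
        "bc_only": len(bc),
        "abc": len(abc),
    }
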