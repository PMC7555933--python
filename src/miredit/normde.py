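"""Median-of-ratios count normalization and two-group differential expression.

Normalization: each sample's scaling factor is the median, over miRNAs
with a nonzero count in every sample, of the ratio between the sample's
count and the miRNA's across-sample geometric mean; normalized counts
are raw counts divided by the factor. Rows containing a zero are
excluded from factor estimation (their geometric mean is degenerate)
but are still normalized.

Differential expression: per-miRNA Welch two-sample t-test, by default
on log2(normalized + 1), two-tailed, without multiple-testing
correction; results carry the three significance tiers used for the
expression heat maps (red p <= 0.01, orange p <= 0.05, blue p <= 0.1).
A Benjamini-Hochberg column is emitted as supplementary output but does
not drive the tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_TIERS = (0.01, 0.05, 0.1)  # red / orange / blue
TIER_NAMES = ("red", "orange", "blue")


def norm_factors(matrix: pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios normalization factors.

    For sample j the factor is
    ``median_m count(m, j) / geomean_over_samples(count(m, .))``
    over miRNAs m with nonzero counts in every sample.
    """
    if matrix.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    nonzero = (matrix > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no miRNA has nonzero counts in every sample; "
            "median-of-ratios factors are undefined"
        )
    sub = matrix.loc[nonzero].astype(float)
    log_geomean = np.log(sub).mean(axis=1)
    ratios = sub.div(np.exp(log_geomean), axis=0)
    factors = ratios.median(axis=0)
    factors.name = "factor"
    return factors


def normalize(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its normalization factor."""
    missing = [s for s in matrix.columns if s not in factors.index]
    if missing:
        raise ValueError(f"missing normalization factors for: {missing}")
    return matrix.astype(float).div(factors[matrix.columns], axis=1)


@dataclass(frozen=True)
class DEOptions:
    pseudocount: float = 1.0
    log_scale: bool = True  # test on log2(normalized + pseudocount)
    equal_var: bool = False  # Welch by default
    tiers: tuple[float, float, float] = P_TIERS

    def __post_init__(self) -> None:
        if list(self.tiers) != sorted(self.tiers):
            raise ValueError("tiers must be increasing p cut-offs")


def _tier(p: float, tiers: Sequence[float] = P_TIERS) -> str:
    for cut, name in zip(tiers, TIER_NAMES):
        if p <= cut:
            return name
    return "ns"


def de_test(
    norm_matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    options: DEOptions = DEOptions(),
) -> pd.DataFrame:
    """Per-miRNA two-group t-test on the normalized matrix.

    Group A is the reference (e.g. the 3-month controls); log2FC is
    ``log2((mean_B + c) / (mean_A + c))`` on the normalized-count scale.
    Degenerate rows with zero variance in both groups get t = 0, p = 1
    when the means are equal, else an infinite t with p = 0.
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 samples")
        missing = [s for s in grp if s not in norm_matrix.columns]
        if missing:
            raise ValueError(f"group {name} samples not in matrix: {missing}")
    a = norm_matrix[list(group_a)].to_numpy(dtype=float)
    b = norm_matrix[list(group_b)].to_numpy(dtype=float)
    c = options.pseudocount
    xa, xb = (np.log2(a + c), np.log2(b + c)) if options.log_scale else (a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(
            xb, xa, axis=1, equal_var=options.equal_var
        )
    # zero variance in both groups -> scipy yields nan; apply conventions
    degenerate = np.isnan(t)
    equal_means = np.isclose(xa.mean(axis=1), xb.mean(axis=1))
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    diff = degenerate & ~equal_means
    with np.errstate(invalid="ignore"):
        t_inf = np.sign(xb.mean(axis=1) - xa.mean(axis=1)) * np.inf
    t = np.where(diff, t_inf, t)
    p = np.where(diff, 0.0, p)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + c) / (mean_a + c))
    result = pd.DataFrame(
        {
            "mirna_id": norm_matrix.index,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": log2fc,
            "t": t,
            "p": p,
            "p_adj_bh": multipletests(p, method="fdr_bh")[1],
            "tier": [_tier(v, options.tiers) for v in p],
            "direction": np.where(log2fc < 0, "down", "up"),
        }
    )
    return result.reset_index(drop=True)


def comparison_matrix(de_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Heatmap-ready miRNA x comparison matrix of signed -log10 p.

    The sign carries the direction of change (positive = up in group B).
    """
    cols = {}
    for name, table in de_tables.items():
        signed = -np.log10(np.clip(table["p"].to_numpy(), 1e-300, None))
        signed = signed * np.where(table["log2FC"].to_numpy() < 0, -1.0, 1.0)
        cols[name] = pd.Series(signed, index=table["mirna_id"])
    return pd.DataFrame(cols)
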