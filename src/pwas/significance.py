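"""Ratio-outlier p-values and label-swap combination.

The vast majority of proteins in a DNA pull-down bind non-specifically,
so a specific interactor shows up as an *outlier* of the experiment-wide
log-ratio distribution.  Each protein receives a robust z-score built
from the median and an asymmetric percentile spread (the 15.87th and
84.13th percentiles, which bracket one standard deviation of a normal),
and a one-sided normal tail p-value.  The forward and reverse
orientations are then combined by Fisher's method, but only when both
orientations prefer the same allele; a direction conflict cannot be a
consistent allele-specific binder and is assigned a combined p of 1.

The reported per-experiment p-value is the upper tail of the *signed*
z-score, i.e. the p-value for preference of allele 1: small values mean
allele-1 preference, values near 1 mean allele-2 preference, and the
distribution is uniform under the null.  The protein's own direction is
carried alongside and selects the tail at combination time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300
DEFAULT_THRESHOLD = 1e-7
LOWER_Q = 15.87
UPPER_Q = 84.13

#: columns of a per-pair outlier-statistics table
RESULT_COLUMNS = [
    "protein_id",
    "p_forward",
    "p_reverse",
    "direction_forward",
    "direction_reverse",
    "p_combined",
]


def robust_z(values: np.ndarray) -> np.ndarray:
    """Signed robust z-scores from median and asymmetric percentile spread.

    Values above the median are scaled by the (84.13th percentile -
    median) distance, values below by (median - 15.87th percentile), so
    skewed ratio clouds get separate left and right scales.
    """
    x = np.asarray(values, dtype=float)
    m = np.median(x)
    q_low, q_high = np.percentile(x, [LOWER_Q, UPPER_Q])
    right = q_high - m
    left = m - q_low
    if right <= 0 or left <= 0:
        raise ValueError(
            "degenerate log-ratio distribution (zero percentile spread); "
            "check that the input contains varying protein ratios"
        )
    return np.where(x >= m, (x - m) / right, (x - m) / left)


def outlier_pvalues(quants: pd.DataFrame, min_proteins: int = 20) -> pd.DataFrame:
    """Per-protein outlier p-values for one experiment.

    Returns a table with ``protein_id``, ``z``, ``p`` (upper-tail normal
    p of the signed robust z; uniform under the null) and ``direction``
    (sign of the oriented log-ratio).  Requires at least ``min_proteins``
    quantified proteins for the distribution to be estimable.
    """
    if len(quants) < min_proteins:
        raise ValueError(
            f"{len(quants)} quantified proteins < {min_proteins} required "
            "for outlier statistics"
        )
    x = quants["log2_ratio_oriented"].to_numpy(dtype=float)
    z = robust_z(x)
    p = np.clip(stats.norm.sf(z), P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "protein_id": quants["protein_id"].to_numpy(),
            "z": z,
            "p": p,
            "direction": np.sign(x).astype(int),
        }
    )


def combine(
    p_forward: float,
    direction_forward: int,
    p_reverse: float,
    direction_reverse: int,
) -> float:
    """Fisher-combine the two orientations' one-sided p-values.

    When both orientations prefer allele 1 (direction +) the upper-tail
    p-values are combined; when both prefer allele 2 the lower tails
    (1 - p) are combined; a direction conflict yields 1.0.  The Fisher
    statistic -2(ln p1 + ln p2) is referred to a chi-squared law with 4
    degrees of freedom.
    """
    if not (np.isfinite(p_forward) and np.isfinite(p_reverse)):
        raise ValueError("both per-experiment p-values are required")
    if direction_forward * direction_reverse <= 0:
        return 1.0
    if direction_forward < 0:
        p_forward, p_reverse = 1.0 - p_forward, 1.0 - p_reverse
    p_forward = max(p_forward, P_FLOOR)
    p_reverse = max(p_reverse, P_FLOOR)
    stat = -2.0 * (np.log(p_forward) + np.log(p_reverse))
    return float(max(stats.chi2.sf(stat, df=4), P_FLOOR))


def pair_statistics(
    fwd_quants: pd.DataFrame,
    rev_quants: pd.DataFrame,
    min_proteins: int = 20,
) -> pd.DataFrame:
    """Outlier statistics for a forward/reverse experiment pair.

    Proteins quantified in both orientations receive a combined p-value;
    proteins seen in only one carry NaN in the missing columns and no
    combined value (they are not callable downstream).
    """
    fwd = outlier_pvalues(fwd_quants, min_proteins).rename(
        columns={"p": "p_forward", "direction": "direction_forward", "z": "z_forward"}
    )
    rev = outlier_pvalues(rev_quants, min_proteins).rename(
        columns={"p": "p_reverse", "direction": "direction_reverse", "z": "z_reverse"}
    )
    merged = fwd.merge(rev, on="protein_id", how="outer")
    both = merged["p_forward"].notna() & merged["p_reverse"].notna()
    p_comb = np.full(len(merged), np.nan)
    sub = merged[both]
    p_comb[both.to_numpy()] = [
        combine(pf, int(df_), pr, int(dr))
        for pf, df_, pr, dr in zip(
            sub["p_forward"], sub["direction_forward"], sub["p_reverse"], sub["direction_reverse"]
        )
    ]
    merged["p_combined"] = p_comb
    return merged
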