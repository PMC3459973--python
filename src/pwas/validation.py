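"""Downstream validation statistics: qPCR knock-down and reporter assays.

Two small, self-contained computations used to confirm screen hits:

* relative expression after knock-down by the comparative-Ct method:
  dCt = Ct(target) - Ct(reference) per sample, ddCt = dCt(treated) -
  dCt(control), relative expression = 2 ** -ddCt;
* allele-specific reporter activation: firefly/renilla-normalized
  activity per replicate, percent change of each allele under
  knock-down versus mock, and a Welch two-sample t-test comparing the
  two alleles' replicate percent changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]
REPORTER_COLUMNS = ["condition", "allele", "replicate", "firefly", "renilla"]


@dataclass(frozen=True)
class DdctResult:
    """Comparative-Ct quantification of one target gene."""

    target_gene: str
    treated_sample: str
    control_sample: str
    reference_gene: str
    ddct: float
    ddct_sd: float | None
    relative_expression: float
    expression_sd: float | None
    n_replicates: int


def _mean_ct(table: pd.DataFrame, sample: str, gene: str) -> pd.Series:
    sub = table[(table["sample"] == sample) & (table["gene"] == gene)]
    if sub.empty:
        raise ValueError(f"no Ct values for gene {gene!r} in sample {sample!r}")
    if (sub["ct"] <= 0).any():
        raise ValueError(f"non-positive Ct for gene {gene!r} in sample {sample!r}")
    return sub.set_index("replicate")["ct"]


def ddct(
    table: pd.DataFrame,
    target_gene: str,
    treated_sample: str,
    reference_gene: str = "GAPDH",
    control_sample: str = "mock",
) -> DdctResult:
    """Relative expression of ``target_gene`` in ``treated_sample``.

    Replicate Ct values are averaged before differencing; the spread is
    the standard deviation of replicate-wise ddCt values (replicates
    paired by their identifier).  With a single replicate the result
    carries no spread and a warning is logged.
    """
    cts = {
        (s, g): _mean_ct(table, s, g)
        for s in (treated_sample, control_sample)
        for g in (target_gene, reference_gene)
    }
    d_treated = cts[(treated_sample, target_gene)].mean() - cts[(treated_sample, reference_gene)].mean()
    d_control = cts[(control_sample, target_gene)].mean() - cts[(control_sample, reference_gene)].mean()
    dd = float(d_treated - d_control)

    per_rep = (
        (cts[(treated_sample, target_gene)] - cts[(treated_sample, reference_gene)])
        - (cts[(control_sample, target_gene)] - cts[(control_sample, reference_gene)])
    ).dropna()
    n = len(per_rep)
    if n < 2:
        logger.warning("single replicate: relative expression reported without spread")
        ddct_sd = expr_sd = None
    else:
        ddct_sd = float(per_rep.std(ddof=1))
        # spread on the expression scale, propagated from replicate ddCt values
        expr_sd = float((2.0 ** (-per_rep)).std(ddof=1))
    return DdctResult(
        target_gene=target_gene,
        treated_sample=treated_sample,
        control_sample=control_sample,
        reference_gene=reference_gene,
        ddct=dd,
        ddct_sd=ddct_sd,
        relative_expression=float(2.0 ** (-dd)),
        expression_sd=expr_sd,
        n_replicates=n,
    )


@dataclass(frozen=True)
class ActivationResult:
    """Allele-specific reporter activation under knock-down."""

    knockdown_condition: str
    alleles: tuple[str, str]
    percent_change: dict[str, float]
    sd: dict[str, float]
    n_replicates: dict[str, int]
    p_between_alleles: float


def allele_activation(
    table: pd.DataFrame,
    knockdown_condition: str,
    mock_condition: str = "mock",
) -> ActivationResult:
    """Per-allele percent activation and the between-allele comparison.

    Activity is firefly/renilla per replicate.  For each allele the
    percent change of each knock-down replicate relative to the mock
    mean is computed; the reported value is its mean with replicate
    standard deviation, and the two alleles are compared by a two-sided
    Welch t-test on the replicate percent changes.
    """
    for col in REPORTER_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"reporter table lacks column {col!r}")
    if (table[["firefly", "renilla"]] <= 0).any().any():
        raise ValueError("luminometer signals must be positive")
    alleles = sorted(table["allele"].unique())
    if len(alleles) != 2:
        raise ValueError(f"expected exactly two alleles, got {alleles}")
    work = table.assign(activity=table["firefly"] / table["renilla"])

    changes: dict[str, np.ndarray] = {}
    for allele in alleles:
        sub = work[work["allele"] == allele]
        mock = sub[sub["condition"] == mock_condition]["activity"].to_numpy()
        kd = sub[sub["condition"] == knockdown_condition]["activity"].to_numpy()
        if len(mock) == 0 or len(kd) == 0:
            raise ValueError(
                f"allele {allele!r}: both {mock_condition!r} and "
                f"{knockdown_condition!r} conditions are required"
            )
        changes[allele] = 100.0 * (kd - mock.mean()) / mock.mean()

    enough = all(len(changes[a]) >= 2 for a in alleles)
    if enough:
        p = float(stats.ttest_ind(changes[alleles[0]], changes[alleles[1]], equal_var=False).pvalue)
    else:
        logger.warning("fewer than 2 replicates per allele: between-allele test skipped")
        p = float("nan")
    return ActivationResult(
        knockdown_condition=knockdown_condition,
        alleles=(alleles[0], alleles[1]),
        percent_change={a: float(changes[a].mean()) for a in alleles},
        sd={a: float(changes[a].std(ddof=1)) if len(changes[a]) >= 2 else float("nan") for a in alleles},
        n_replicates={a: int(len(changes[a])) for a in alleles},
        p_between_alleles=p,
    )
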