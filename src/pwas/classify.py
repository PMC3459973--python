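"""Two-dimensional label-swap classification of pull-down proteins.

Each protein quantified in both orientations of a SNP's label-swap pair
is placed on a 2D interaction plot and assigned exactly one class:

* ``contaminant`` -- raw heavy/light ratio below the contaminant cutoff
  in *both* orientations: an unlabelled protein (e.g. keratin) is
  light-only, so its ratio stays low no matter which extract is heavy
  (lower-left quadrant).  The cutoff defaults to H/L 0.5 rather than
  1.0 so that origin-cluster proteins drifting slightly negative in
  both orientations are not swept into the contaminant class;
* ``specific_allele1`` / ``specific_allele2`` -- combined p-value below
  the threshold with the same allele preferred in both orientations
  (off-diagonal quadrants);
* ``background`` -- everything else, the nonspecific cloud around the
  origin;
* ``not_callable`` -- quantified in only one orientation.

Axis convention: x is the forward oriented log2(allele1/allele2) ratio
and y the reverse raw log2(heavy/light) ratio, which puts allele-1
binders lower-right, allele-2 binders upper-left and contaminants
lower-left.  The contaminant rule reads pre-normalization heavy/light
ratios; classification precedence is contaminant, then specific, then
background.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .significance import DEFAULT_THRESHOLD

SPECIFIC_ALLELE1 = "specific_allele1"
SPECIFIC_ALLELE2 = "specific_allele2"
CONTAMINANT = "contaminant"
BACKGROUND = "background"
NOT_CALLABLE = "not_callable"

#: default upper bound on raw heavy/light ratio (both orientations) for
#: the contaminant call; must be <= 1
DEFAULT_CONTAMINANT_MAX_HL = 0.5

CALL_COLUMNS = [
    "rsid",
    "protein_id",
    "x",
    "y",
    "interaction_class",
    "p_combined",
    "fold_estimate",
]


def _pair_rsid(fwd_quants: pd.DataFrame, rev_quants: pd.DataFrame) -> str:
    fids = set(fwd_quants["experiment_id"].unique())
    rids = set(rev_quants["experiment_id"].unique())
    if len(fids) != 1 or len(rids) != 1:
        raise ValueError("each quant table must come from a single experiment")
    fid, rid = fids.pop(), rids.pop()
    f_rsid, f_orient = fid.rsplit("_", 1)
    r_rsid, r_orient = rid.rsplit("_", 1)
    if f_rsid != r_rsid or f_orient == r_orient:
        raise ValueError(f"mismatched experiment pair: {fid} vs {rid}")
    return f_rsid


def call_interactions(
    fwd_quants: pd.DataFrame,
    rev_quants: pd.DataFrame,
    pair_stats: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    contaminant_max_hl: float = DEFAULT_CONTAMINANT_MAX_HL,
) -> pd.DataFrame:
    """Classify every protein of one forward/reverse pair.

    ``pair_stats`` must be the outlier-statistics table computed from
    the same pair.  Returns one row per protein (``CALL_COLUMNS``).
    The fold estimate is the geometric mean of the two orientations'
    implied folds, ``2 ** ((|x| + |y_oriented|) / 2)``.
    """
    if not 0 < contaminant_max_hl <= 1:
        raise ValueError("contaminant_max_hl must lie in (0, 1]")
    log2_cont = np.log2(contaminant_max_hl)
    rsid = _pair_rsid(fwd_quants, rev_quants)
    fwd = fwd_quants.set_index("protein_id")
    rev = rev_quants.set_index("protein_id")
    merged = pair_stats.set_index("protein_id")
    missing = set(fwd.index).union(rev.index) - set(merged.index)
    if missing:
        raise ValueError(f"pair statistics lack {len(missing)} quantified proteins")

    rows = []
    for pid, st in merged.iterrows():
        in_fwd, in_rev = pid in fwd.index, pid in rev.index
        x = float(fwd.loc[pid, "log2_ratio_oriented"]) if in_fwd else np.nan
        y = float(rev.loc[pid, "log2_ratio_hl"]) if in_rev else np.nan
        if not (in_fwd and in_rev):
            rows.append((rsid, pid, x, y, NOT_CALLABLE, np.nan, np.nan))
            continue
        raw_f = float(fwd.loc[pid, "log2_ratio_hl"])
        raw_r = float(rev.loc[pid, "log2_ratio_hl"])
        y_oriented = float(rev.loc[pid, "log2_ratio_oriented"])
        p_comb = float(st["p_combined"])
        fold = float(2.0 ** ((abs(x) + abs(y_oriented)) / 2.0))
        d_f, d_r = int(st["direction_forward"]), int(st["direction_reverse"])
        if raw_f < log2_cont and raw_r < log2_cont:
            cls = CONTAMINANT
        elif p_comb < threshold and d_f == d_r and d_f != 0:
            cls = SPECIFIC_ALLELE1 if d_f > 0 else SPECIFIC_ALLELE2
        else:
            cls = BACKGROUND
        rows.append((rsid, pid, x, y, cls, p_comb, fold))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def summarize_screen(
    calls_by_snp: Mapping[str, pd.DataFrame],
    alleles_by_snp: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Screen-level summary across SNPs.

    Returns per-SNP counts of specific binders by allele, the SNPs with
    no specific call, and a hit table (rsid, protein, preferred allele,
    fold estimate, combined p).
    """
    counts = []
    hits = []
    silent = []
    for rsid, calls in calls_by_snp.items():
        spec1 = calls[calls["interaction_class"] == SPECIFIC_ALLELE1]
        spec2 = calls[calls["interaction_class"] == SPECIFIC_ALLELE2]
        alleles = list(alleles_by_snp[rsid]) if alleles_by_snp else ["allele1", "allele2"]
        counts.append({"rsid": rsid, "n_specific_allele1": len(spec1), "n_specific_allele2": len(spec2)})
        if spec1.empty and spec2.empty:
            silent.append(rsid)
        for sub, allele in ((spec1, alleles[0]), (spec2, alleles[1])):
            for _, row in sub.iterrows():
                hits.append(
                    {
                        "rsid": rsid,
                        "protein_id": row["protein_id"],
                        "preferred_allele": allele,
                        "fold_estimate": row["fold_estimate"],
                        "p_combined": row["p_combined"],
                    }
                )
    hit_cols = ["rsid", "protein_id", "preferred_allele", "fold_estimate", "p_combined"]
    return {
        "per_snp_counts": pd.DataFrame(counts, columns=["rsid", "n_specific_allele1", "n_specific_allele2"]),
        "snps_without_specific_calls": silent,
        "hits": pd.DataFrame(hits, columns=hit_cols),
    }
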