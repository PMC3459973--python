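"""Peptide evidence -> filtered, oriented protein log-ratios.

A protein is retained only if it has at least one unique peptide and at
least two quantitation events in the experiment; its heavy/light ratio
is the median of its peptide log2 ratios (robust to a stray peptide).
Orientation correction re-expresses the heavy/light ratio on a common
allele-1/allele-2 scale: it equals the raw log-ratio in the forward
orientation and its negative in the reverse one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FORWARD, REVERSE, EVIDENCE_COLUMNS, PulldownExperiment

logger = logging.getLogger(__name__)

MIN_EVENTS = 2
MIN_UNIQUE_PEPTIDES = 1

#: columns of a protein quantitation table
QUANT_COLUMNS = [
    "experiment_id",
    "protein_id",
    "n_events",
    "n_unique_peptides",
    "log2_ratio_hl",
    "log2_ratio_oriented",
    "median_intensity",
]


@dataclass
class QuantLog:
    """Run-log entry for one aggregation/normalization pass."""

    experiment_id: str
    n_proteins_in: int = 0
    n_filtered_events: int = 0
    n_filtered_unique: int = 0
    n_retained: int = 0
    normalization_offset: float | None = None


def aggregate(
    evidence: pd.DataFrame,
    experiment: PulldownExperiment,
    log: QuantLog | None = None,
) -> pd.DataFrame:
    """Aggregate peptide evidence to protein-level oriented log2 ratios.

    Returns one row per retained protein with the ``QUANT_COLUMNS``
    schema.  Proteins with fewer than two quantitation events or no
    unique peptide are dropped and counted in the run log.
    """
    if log is None:
        log = QuantLog(experiment.experiment_id)
    if evidence.empty:
        logger.warning("%s: no evidence rows", experiment.experiment_id)
        return pd.DataFrame(columns=QUANT_COLUMNS)
    ids = evidence["experiment_id"].unique()
    if set(ids) - {experiment.experiment_id}:
        raise ValueError(
            f"evidence contains rows for {sorted(set(ids))}, expected only "
            f"{experiment.experiment_id}"
        )
    ev = evidence.assign(log2_ratio=np.log2(evidence["ratio_hl"].to_numpy(dtype=float)))
    grouped = ev.groupby("protein_id", sort=True)
    stats = grouped.agg(
        n_events=("ratio_hl", "size"),
        log2_ratio_hl=("log2_ratio", "median"),
        median_intensity=("intensity", "median"),
    )
    uniq = ev[ev["is_unique"]].groupby("protein_id")["peptide_sequence"].nunique()
    stats["n_unique_peptides"] = uniq.reindex(stats.index, fill_value=0).astype(int)

    log.n_proteins_in = len(stats)
    enough_events = stats["n_events"] >= MIN_EVENTS
    enough_unique = stats["n_unique_peptides"] >= MIN_UNIQUE_PEPTIDES
    log.n_filtered_events = int((~enough_events).sum())
    log.n_filtered_unique = int((enough_events & ~enough_unique).sum())
    kept = stats[enough_events & enough_unique].reset_index()
    log.n_retained = len(kept)

    sign = 1.0 if experiment.orientation == FORWARD else -1.0
    kept["log2_ratio_oriented"] = sign * kept["log2_ratio_hl"]
    kept["experiment_id"] = experiment.experiment_id
    return kept[QUANT_COLUMNS]


def orient(log2_ratio_hl: float, orientation: str) -> float:
    """Re-express a raw heavy/light log-ratio as allele1/allele2."""
    if orientation == FORWARD:
        return log2_ratio_hl
    if orientation == REVERSE:
        return -log2_ratio_hl
    raise ValueError(f"unknown orientation {orientation!r}")


def normalize(
    quants: pd.DataFrame,
    min_proteins: int = 20,
    log: QuantLog | None = None,
) -> pd.DataFrame:
    """Median-centre the oriented log-ratios of one experiment.

    Mixing of the extracts is nominally 1:1, but systematic offsets
    (labelling efficiency, mixing error) shift the whole ratio cloud;
    since the bulk of proteins bind non-specifically, centring the
    median at zero removes the offset.  The raw ``log2_ratio_hl`` column
    is left untouched so the contaminant rule downstream can read
    pre-normalization heavy/light ratios.  Skipped (with a warning) when
    fewer than ``min_proteins`` proteins are present.
    """
    if len(quants) < min_proteins:
        logger.warning(
            "normalization skipped: %d proteins < %d required", len(quants), min_proteins
        )
        if log is not None:
            log.normalization_offset = None
        return quants.copy()
    offset = float(quants["log2_ratio_oriented"].median())
    out = quants.copy()
    out["log2_ratio_oriented"] = out["log2_ratio_oriented"] - offset
    if log is not None:
        log.normalization_offset = offset
    logger.info("normalization offset %.4f removed", offset)
    return out


def quantify_experiment(
    experiment: PulldownExperiment,
    min_proteins_for_norm: int = 20,
    do_normalize: bool = True,
) -> tuple[pd.DataFrame, QuantLog]:
    """Aggregate and (by default) normalize one experiment's evidence."""
    log = QuantLog(experiment.experiment_id)
    quants = aggregate(experiment.evidence, experiment, log)
    if do_normalize and not quants.empty:
        quants = normalize(quants, min_proteins=min_proteins_for_norm, log=log)
    return quants, log


def fold_change(log2_ratio_oriented: float) -> float:
    """Fold enrichment implied by an oriented log2 ratio (>= 1)."""
    return float(2.0 ** abs(log2_ratio_oriented))
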