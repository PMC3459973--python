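"""End-to-end orchestration: evidence -> quants -> statistics -> calls.

Library-level counterpart of the command-line pipeline; every stage can
also be run on its own from the per-stage modules.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Mapping, Sequence

import pandas as pd

from . import classify, quantify, significance
from .panel import SnpRecord
from .simulate import FORWARD, REVERSE, PulldownExperiment


def experiments_from_evidence(
    evidence: pd.DataFrame, panel: Sequence[SnpRecord]
) -> list[PulldownExperiment]:
    """Rebuild experiments from a pooled evidence table.

    ``experiment_id`` values must follow the ``{rsid}_{orientation}``
    convention; heavy/light alleles are looked up in the panel (forward:
    first allele heavy).
    """
    by_rsid = {snp.rsid: snp for snp in panel}
    experiments = []
    for exp_id, rows in evidence.groupby("experiment_id", sort=False):
        rsid, _, orientation = str(exp_id).rpartition("_")
        if orientation not in (FORWARD, REVERSE):
            raise ValueError(f"experiment id {exp_id!r} lacks a forward/reverse suffix")
        if rsid not in by_rsid:
            raise KeyError(f"experiment {exp_id!r}: rsid {rsid!r} not in panel")
        a1, a2 = by_rsid[rsid].alleles
        heavy, light = (a1, a2) if orientation == FORWARD else (a2, a1)
        experiments.append(
            PulldownExperiment(
                rsid=rsid,
                orientation=orientation,
                heavy_allele=heavy,
                light_allele=light,
                evidence=rows.reset_index(drop=True),
            )
        )
    return experiments


def analyze_pair(
    fwd: PulldownExperiment,
    rev: PulldownExperiment,
    threshold: float = significance.DEFAULT_THRESHOLD,
    min_proteins: int = 20,
    do_normalize: bool = True,
    contaminant_max_hl: float = classify.DEFAULT_CONTAMINANT_MAX_HL,
) -> dict:
    """Quantify, test and classify one forward/reverse pair.

    Returns a dict with the two quant tables, the pair statistics, the
    interaction calls and the two quantification run logs.
    """
    if fwd.rsid != rev.rsid or fwd.orientation != FORWARD or rev.orientation != REVERSE:
        raise ValueError(f"not a forward/reverse pair: {fwd.experiment_id}, {rev.experiment_id}")
    fwd_quants, fwd_log = quantify.quantify_experiment(
        fwd, min_proteins_for_norm=min_proteins, do_normalize=do_normalize
    )
    rev_quants, rev_log = quantify.quantify_experiment(
        rev, min_proteins_for_norm=min_proteins, do_normalize=do_normalize
    )
    stats = significance.pair_statistics(fwd_quants, rev_quants, min_proteins=min_proteins)
    calls = classify.call_interactions(
        fwd_quants, rev_quants, stats, threshold=threshold,
        contaminant_max_hl=contaminant_max_hl,
    )
    return {
        "rsid": fwd.rsid,
        "fwd_quants": fwd_quants,
        "rev_quants": rev_quants,
        "stats": stats,
        "calls": calls,
        "logs": [asdict(fwd_log), asdict(rev_log)],
    }


def analyze_study(
    experiments: Sequence[PulldownExperiment],
    threshold: float = significance.DEFAULT_THRESHOLD,
    min_proteins: int = 20,
    alleles_by_snp: Mapping[str, Sequence[str]] | None = None,
    contaminant_max_hl: float = classify.DEFAULT_CONTAMINANT_MAX_HL,
) -> dict:
    """Analyze every forward/reverse pair of a study and summarize.

    Experiments are paired by rsid; a SNP missing either orientation is
    an error.
    """
    by_key = {(e.rsid, e.orientation): e for e in experiments}
    rsids = list(dict.fromkeys(e.rsid for e in experiments))
    results: dict[str, dict] = {}
    for rsid in rsids:
        try:
            fwd, rev = by_key[(rsid, FORWARD)], by_key[(rsid, REVERSE)]
        except KeyError as exc:
            raise ValueError(f"{rsid}: missing label orientation {exc}") from exc
        results[rsid] = analyze_pair(
            fwd, rev, threshold=threshold, min_proteins=min_proteins,
            contaminant_max_hl=contaminant_max_hl,
        )
    calls_by_snp = {rsid: res["calls"] for rsid, res in results.items()}
    summary = classify.summarize_screen(calls_by_snp, alleles_by_snp=alleles_by_snp)
    return {"pairs": results, "summary": summary}
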