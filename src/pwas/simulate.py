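"""Synthetic SILAC pull-down evidence with known ground truth.

Emulates the peptide-level quantitation tables of a label-swap DNA
pull-down pair: a dominant nonspecific background whose heavy/light
ratios scatter around 1, unlabelled contaminants whose heavy/light ratio
stays below 1 in *both* label orientations, and spiked allele-specific
binders whose ratio follows the label orientation (fold ``f`` where the
preferred allele meets the heavy extract, ``1/f`` where it meets the
light one).

Peptide ratios are lognormal around the protein's true ratio
(multiplicative noise, symmetric in log space); peptide counts per
protein follow a geometric law with a floor of one; intensities are
log-uniform.  Everything is reproducible from the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import SnpRecord

#: columns of a peptide-level evidence table
EVIDENCE_COLUMNS = [
    "experiment_id",
    "protein_id",
    "peptide_sequence",
    "is_unique",
    "ratio_hl",
    "intensity",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class BinderSpec:
    """Ground truth for one spiked protein.

    ``fold_change`` is the true allele-1/allele-2 abundance ratio when
    ``target_allele`` is the record's first allele (values > 1 mean
    preference for the target allele).  Contaminants have no target
    allele; their ratio behaviour comes from the simulation config.
    """

    protein_id: str
    target_allele: str | None = None
    fold_change: float = 1.0
    n_peptides: int = 5
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.protein_id}: fold_change must be > 0")
        if self.n_peptides < 1:
            raise ValueError(f"{self.protein_id}: n_peptides must be >= 1")
        if self.is_contaminant and self.target_allele is not None:
            raise ValueError(f"{self.protein_id}: contaminants have no target allele")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the evidence generator.

    The defaults produce the familiar label-swap scatter at desk scale:
    a thousand background proteins clustered at log-ratio 0, fifty
    unlabelled contaminants at heavy/light ~ 0.2 in both orientations,
    peptide-level log2 noise of 0.3, geometric peptide counts with mean
    3 and 90% of peptides flagged unique.  The seed has no default; the
    caller must choose one.
    """

    seed: int
    n_background: int = 1000
    n_contaminants: int = 50
    contaminant_hl_ratio: float = 0.2
    peptide_noise_sd: float = 0.3
    mean_peptides: float = 3.0
    unique_fraction: float = 0.9
    log10_intensity_min: float = 5.0
    log10_intensity_max: float = 9.0

    def __post_init__(self) -> None:
        if not 0 < self.contaminant_hl_ratio < 1:
            raise ValueError("contaminant_hl_ratio must lie in (0, 1)")
        if self.peptide_noise_sd < 0:
            raise ValueError("peptide_noise_sd must be >= 0")
        if self.n_background < 0 or self.n_contaminants < 0:
            raise ValueError("protein counts must be >= 0")
        if self.mean_peptides < 1:
            raise ValueError("mean_peptides must be >= 1")
        if not 0 <= self.unique_fraction <= 1:
            raise ValueError("unique_fraction must lie in [0, 1]")


@dataclass
class PulldownExperiment:
    """One label orientation of a SNP's allele comparison.

    An orientation comprises two physical pull-downs (one allele bait
    incubated with the heavy extract, the other with the light one) that
    are pooled before measurement, yielding a single evidence table.
    """

    rsid: str
    orientation: str
    heavy_allele: str
    light_allele: str
    evidence: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVIDENCE_COLUMNS))

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation}")
        if self.heavy_allele == self.light_allele:
            raise ValueError("heavy and light alleles must differ")

    @property
    def experiment_id(self) -> str:
        return f"{self.rsid}_{self.orientation}"


def _protein_table(
    snp: SnpRecord, binders: Sequence[BinderSpec], config: SimulationConfig
) -> pd.DataFrame:
    """Per-protein ground truth: class, fold change, preferred allele."""
    ids, classes, folds, targets, npep = [], [], [], [], []
    for spec in binders:
        ids.append(spec.protein_id)
        if spec.is_contaminant:
            classes.append("contaminant")
            folds.append(np.nan)
            targets.append(None)
        elif spec.target_allele is None or spec.fold_change == 1.0:
            classes.append("background")
            folds.append(1.0)
            targets.append(None)
        else:
            if spec.target_allele not in snp.alleles:
                raise ValueError(
                    f"{spec.protein_id}: target allele {spec.target_allele!r} "
                    f"not among {snp.rsid} alleles {snp.alleles}"
                )
            classes.append("specific")
            folds.append(spec.fold_change)
            targets.append(spec.target_allele)
        npep.append(spec.n_peptides)
    for i in range(config.n_background):
        ids.append(f"BG{i + 1:05d}")
        classes.append("background")
        folds.append(1.0)
        targets.append(None)
        npep.append(0)  # drawn at simulation time
    for i in range(config.n_contaminants):
        ids.append(f"CONT{i + 1:04d}")
        classes.append("contaminant")
        folds.append(np.nan)
        targets.append(None)
        npep.append(0)
    if len(set(ids)) != len(ids):
        raise ValueError("binder protein_ids must be unique and not collide with BG/CONT ids")
    return pd.DataFrame(
        {"protein_id": ids, "true_class": classes, "true_fold_change": folds,
         "target_allele": targets, "n_peptides": npep}
    )


def ground_truth(
    snp: SnpRecord, binders: Sequence[BinderSpec], config: SimulationConfig
) -> pd.DataFrame:
    """Ground-truth sidecar (protein_id, true_class, true_fold_change, target_allele)."""
    return _protein_table(snp, binders, config).drop(columns="n_peptides")


def _orientation_evidence(
    experiment: PulldownExperiment,
    proteins: pd.DataFrame,
    snp: SnpRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    heavy = experiment.heavy_allele
    # true heavy/light ratio per protein in this orientation
    base = np.ones(len(proteins))
    is_cont = (proteins["true_class"] == "contaminant").to_numpy()
    base[is_cont] = config.contaminant_hl_ratio
    is_spec = (proteins["true_class"] == "specific").to_numpy()
    fold = proteins["true_fold_change"].to_numpy(dtype=float)
    target_is_heavy = (proteins["target_allele"] == heavy).to_numpy()
    base[is_spec & target_is_heavy] = fold[is_spec & target_is_heavy]
    base[is_spec & ~target_is_heavy] = 1.0 / fold[is_spec & ~target_is_heavy]

    npep = proteins["n_peptides"].to_numpy().copy()
    free = npep == 0
    npep[free] = rng.geometric(1.0 / config.mean_peptides, size=int(free.sum()))

    pid = np.repeat(proteins["protein_id"].to_numpy(), npep)
    true_ratio = np.repeat(base, npep)
    n_rows = len(pid)
    noise = rng.normal(0.0, config.peptide_noise_sd, size=n_rows) if config.peptide_noise_sd > 0 else np.zeros(n_rows)
    ratio = true_ratio * np.exp2(noise)
    within = np.concatenate([np.arange(1, n + 1) for n in npep]) if n_rows else np.array([], dtype=int)
    peptides = np.char.add(np.char.add(pid.astype(str), "_pep"), within.astype(str))
    return pd.DataFrame(
        {
            "experiment_id": experiment.experiment_id,
            "protein_id": pid,
            "peptide_sequence": peptides,
            "is_unique": rng.random(n_rows) < config.unique_fraction,
            "ratio_hl": ratio,
            "intensity": np.power(10.0, rng.uniform(config.log10_intensity_min, config.log10_intensity_max, n_rows)),
        }
    )


def simulate_pair(
    snp: SnpRecord,
    binders: Sequence[BinderSpec],
    config: SimulationConfig,
) -> tuple[PulldownExperiment, PulldownExperiment]:
    """Simulate the forward/reverse label-swap pair for one SNP.

    Forward: the first allele's bait meets the heavy extract; reverse:
    the labels are switched.  Identical ``config`` (including seed)
    yields identical evidence tables.
    """
    proteins = _protein_table(snp, binders, config)
    rng = np.random.default_rng(config.seed)
    a1, a2 = snp.alleles
    fwd = PulldownExperiment(snp.rsid, FORWARD, heavy_allele=a1, light_allele=a2)
    rev = PulldownExperiment(snp.rsid, REVERSE, heavy_allele=a2, light_allele=a1)
    fwd.evidence = _orientation_evidence(fwd, proteins, snp, config, rng)
    rev.evidence = _orientation_evidence(rev, proteins, snp, config, rng)
    return fwd, rev


def simulate_study(
    panel: Sequence[SnpRecord],
    design: Mapping[str, Sequence[BinderSpec]],
    config: SimulationConfig,
) -> list[PulldownExperiment]:
    """Simulate forward/reverse pairs for every SNP of a panel.

    ``design`` maps rsid to spiked binders; SNPs absent from the design
    receive background and contaminants only.  Per-SNP seeds are derived
    deterministically from the study seed.
    """
    known = {snp.rsid for snp in panel}
    unknown = set(design) - known
    if unknown:
        raise KeyError(f"design refers to rsids not in the panel: {sorted(unknown)}")
    if not panel:
        return []
    child_seeds = np.random.SeedSequence(config.seed).generate_state(len(panel))
    experiments: list[PulldownExperiment] = []
    for snp, child in zip(panel, child_seeds):
        cfg = replace(config, seed=int(child))
        fwd, rev = simulate_pair(snp, design.get(snp.rsid, ()), cfg)
        experiments.extend([fwd, rev])
    return experiments


def enumerate_pulldowns(experiments: Sequence[PulldownExperiment]) -> pd.DataFrame:
    """Physical pull-downs behind a set of experiments.

    Each label orientation comprises two pull-downs: one allele bait per
    extract.  A 12-SNP panel therefore yields 48 pull-downs (24
    experiment pairs).
    """
    rows = []
    for exp in experiments:
        for allele, label in ((exp.heavy_allele, "heavy"), (exp.light_allele, "light")):
            rows.append(
                {
                    "pulldown_id": f"{exp.rsid}_{exp.orientation}_{allele}_{label}",
                    "rsid": exp.rsid,
                    "orientation": exp.orientation,
                    "allele": allele,
                    "extract_label": label,
                }
            )
    return pd.DataFrame(rows, columns=["pulldown_id", "rsid", "orientation", "allele", "extract_label"])


def write_evidence(experiments: Sequence[PulldownExperiment], path: str | Path) -> None:
    """Write the pooled evidence of all experiments as one tab-delimited table."""
    tables = [e.evidence for e in experiments]
    pooled = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=EVIDENCE_COLUMNS)
    pooled.to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read an evidence table written by :func:`write_evidence`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table {path} lacks columns {sorted(missing)}")
    return df
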