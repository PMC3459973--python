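"""IUPAC consensus motif scanning over allele baits.

A consensus motif (degenerate IUPAC string, e.g. ``TGTGGBH``) matches a
window when every consensus code's degeneracy set contains the window
base, with at most ``max_mismatches`` violations.  Both strands are
scanned; minus-strand hits are found by matching the reverse complement
of the consensus along the plus strand, and all offsets are reported
0-based on the plus strand so the two alleles of a SNP can be compared
in a single coordinate frame.

A motif is *allele-differential* for a SNP when the presence of a
perfect SNP-overlapping hit differs between the two alleles -- the
variant either creates or destroys the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .panel import IUPAC_CODES, IUPAC_SETS, AlleleBait, SnpRecord, allele_baits, reverse_complement

logger = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"


@dataclass(frozen=True)
class ConsensusMotif:
    """A named IUPAC consensus with an allowed mismatch budget."""

    motif_id: str
    consensus: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if not cons or set(cons) - IUPAC_CODES:
            raise ValueError(f"{self.motif_id}: consensus must be a nonempty IUPAC string")
        object.__setattr__(self, "consensus", cons)
        if self.max_mismatches < 0:
            raise ValueError(f"{self.motif_id}: max_mismatches must be >= 0")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    """One consensus match on a bait, in plus-strand coordinates."""

    motif_id: str
    rsid: str
    allele: str
    strand: str
    offset: int
    mismatches: int
    overlaps_snp: bool


def _mismatches(consensus: str, window: str) -> int:
    return sum(base not in IUPAC_SETS[code] for code, base in zip(consensus, window))


def scan(bait: AlleleBait, motif: ConsensusMotif) -> list[MotifHit]:
    """All hits of ``motif`` on both strands of ``bait``.

    Returns hits ordered by offset then strand.  A motif longer than
    the bait yields an empty list with a warning.
    """
    L = len(motif)
    seq = bait.sequence.upper()
    if L > len(seq):
        logger.warning(
            "%s: motif %s (%d nt) longer than bait (%d nt)",
            bait.name, motif.motif_id, L, len(seq),
        )
        return []
    patterns = ((PLUS, motif.consensus), (MINUS, reverse_complement(motif.consensus)))
    hits = []
    for offset in range(len(seq) - L + 1):
        window = seq[offset : offset + L]
        for strand, pattern in patterns:
            mm = _mismatches(pattern, window)
            if mm <= motif.max_mismatches:
                hits.append(
                    MotifHit(
                        motif_id=motif.motif_id,
                        rsid=bait.rsid,
                        allele=bait.allele,
                        strand=strand,
                        offset=offset,
                        mismatches=mm,
                        overlaps_snp=offset <= bait.snp_offset < offset + L,
                    )
                )
    return hits


def differential_report(record: SnpRecord, motifs: list[ConsensusMotif]) -> pd.DataFrame:
    """Allele-differential motif table for one SNP.

    For each motif, counts SNP-overlapping hits on each allele at 0 and
    1 mismatches and flags the motif ``differential`` when the presence
    of a perfect SNP-overlapping hit differs between the alleles.
    """
    bait1, bait2 = allele_baits(record)
    rows = []
    for motif in motifs:
        per_allele = {}
        for bait in (bait1, bait2):
            relaxed = ConsensusMotif(motif.motif_id, motif.consensus, max_mismatches=max(motif.max_mismatches, 1))
            snp_hits = [h for h in scan(bait, relaxed) if h.overlaps_snp]
            per_allele[bait.allele] = {
                "perfect": sum(h.mismatches == 0 for h in snp_hits),
                "one_mm": sum(h.mismatches <= 1 for h in snp_hits),
            }
        a1, a2 = record.alleles
        rows.append(
            {
                "rsid": record.rsid,
                "motif_id": motif.motif_id,
                "consensus": motif.consensus,
                "allele1": a1,
                "allele2": a2,
                "perfect_hits_allele1": per_allele[a1]["perfect"],
                "perfect_hits_allele2": per_allele[a2]["perfect"],
                "one_mismatch_hits_allele1": per_allele[a1]["one_mm"],
                "one_mismatch_hits_allele2": per_allele[a2]["one_mm"],
                "differential": (per_allele[a1]["perfect"] > 0) != (per_allele[a2]["perfect"] > 0),
            }
        )
    return pd.DataFrame(rows)


def hits_table(hits: list[MotifHit]) -> pd.DataFrame:
    """Hits as a tab-friendly table."""
    return pd.DataFrame(
        [
            {
                "motif_id": h.motif_id,
                "rsid": h.rsid,
                "allele": h.allele,
                "strand": h.strand,
                "offset": h.offset,
                "mismatches": h.mismatches,
                "overlaps_snp": h.overlaps_snp,
            }
            for h in hits
        ],
        columns=["motif_id", "rsid", "allele", "strand", "offset", "mismatches", "overlaps_snp"],
    )


def read_motifs(path: str | Path, max_mismatches: int = 0) -> list[ConsensusMotif]:
    """Read a tab-delimited motif file (columns motif_id, consensus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"motif_id", "consensus"} - set(df.columns)
    if missing:
        raise ValueError(f"motif file {path} lacks columns {sorted(missing)}")
    return [
        ConsensusMotif(row["motif_id"], row["consensus"], max_mismatches)
        for _, row in df.iterrows()
    ]


def default_motifs_path() -> Path:
    """Path of the bundled consensus motifs (CREB1, RUNX1)."""
    return Path(__file__).parent / "data" / "motifs.tsv"


def load_default_motifs(max_mismatches: int = 0) -> list[ConsensusMotif]:
    """The bundled consensus motifs: CREB1 ``TGACG`` and RUNX1 ``TGTGGBH``."""
    return read_motifs(default_motifs_path(), max_mismatches)
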