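"""SNP panel parsing and allele bait construction.

A panel row describes one SNP as its two flanking sequences, an ordered
allele pair and a haplotype-group label.  From each row two *allele baits*
are derived -- the flank/allele/flank concatenations that are synthesised,
concatemerised head-to-tail and immobilised for the pull-downs.

Coordinates are 0-based, half-open throughout; the SNP position within a
bait is ``len(left_flank)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import parse as fasta_parse
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: degeneracy sets of the IUPAC nucleotide alphabet
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_ALLELE_TOKEN = re.compile(r"\[([ACGT])/([ACGT])\]")


class PanelError(ValueError):
    """Raised for malformed panel files or records."""


@dataclass(frozen=True)
class SnpRecord:
    """One panel row: the SNP flanks, allele pair and group label."""

    rsid: str
    left_flank: str
    alleles: tuple[str, str]
    right_flank: str
    group: str
    tag: bool = False

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a == b or {a, b} - set("ACGT"):
            raise PanelError(f"{self.rsid}: alleles must be two distinct bases, got {self.alleles}")
        for name, flank in (("left", self.left_flank), ("right", self.right_flank)):
            if not flank or set(flank) - set("ACGT"):
                raise PanelError(f"{self.rsid}: {name} flank must be nonempty A/C/G/T")

    @property
    def snp_offset(self) -> int:
        """0-based position of the variant base within either allele bait."""
        return len(self.left_flank)

    @property
    def bracketed(self) -> str:
        """Round-trippable ``flank[X/Y]flank`` representation."""
        return f"{self.left_flank}[{self.alleles[0]}/{self.alleles[1]}]{self.right_flank}"


@dataclass(frozen=True)
class AlleleBait:
    """One allele's bait: ``left_flank + allele + right_flank``."""

    rsid: str
    allele: str
    sequence: str
    snp_offset: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def name(self) -> str:
        return f"{self.rsid}_{self.allele}"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Ambiguity codes are complemented by their degeneracy sets
    (B<->V, H<->D, R<->Y, ...).  Raises ``ValueError`` on non-IUPAC
    characters.
    """
    bad = set(seq.upper()) - IUPAC_CODES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return str(Seq(seq.upper()).reverse_complement())


def parse_panel(path: str | Path) -> list[SnpRecord]:
    """Read a tab-delimited panel file into :class:`SnpRecord` objects.

    Expected columns: ``rsid``, ``group``, ``sequence`` (with a single
    bracketed ``[X/Y]`` allele token) and optionally ``tag`` (truthy for
    haplotype-tagging SNPs).  Rows are returned in file order; sequences
    are uppercased on parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        logger.warning("panel file %s has no records", path)
        return []
    missing = {"rsid", "group", "sequence"} - set(df.columns)
    if missing:
        raise PanelError(f"panel file {path} lacks columns {sorted(missing)}")
    records: list[SnpRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rsid = str(row["rsid"]).strip()
        if rsid in seen:
            raise PanelError(f"row {i + 1}: duplicate rsid {rsid}")
        seen.add(rsid)
        seq = str(row["sequence"]).strip().upper()
        tokens = _ALLELE_TOKEN.findall(seq)
        if len(tokens) != 1:
            raise PanelError(f"row {i + 1} ({rsid}): expected exactly one [X/Y] allele token")
        left, right = _ALLELE_TOKEN.split(seq)[0], _ALLELE_TOKEN.split(seq)[3]
        tag = str(row.get("tag", "0")).strip() in {"1", "true", "True", "yes"}
        try:
            records.append(
                SnpRecord(
                    rsid=rsid,
                    left_flank=left,
                    alleles=tokens[0],
                    right_flank=right,
                    group=str(row["group"]).strip(),
                    tag=tag,
                )
            )
        except PanelError as exc:
            raise PanelError(f"row {i + 1}: {exc}") from exc
    return records


def write_panel(records: Sequence[SnpRecord], path: str | Path) -> None:
    """Inverse of :func:`parse_panel` (tab-delimited, bracketed alleles)."""
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "group": [r.group for r in records],
            "sequence": [r.bracketed for r in records],
            "tag": [int(r.tag) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def allele_sequence(record: SnpRecord, which: int) -> AlleleBait:
    """Build the bait for allele ``which`` (0 or 1) of ``record``."""
    if which not in (0, 1):
        raise IndexError(f"allele index must be 0 or 1, got {which}")
    allele = record.alleles[which]
    return AlleleBait(
        rsid=record.rsid,
        allele=allele,
        sequence=record.left_flank + allele + record.right_flank,
        snp_offset=record.snp_offset,
    )


def allele_baits(record: SnpRecord) -> tuple[AlleleBait, AlleleBait]:
    """Both allele baits of a record, in allele order."""
    return allele_sequence(record, 0), allele_sequence(record, 1)


def is_ligation_compatible(overhang: str) -> bool:
    """Whether a sticky-end overhang supports head-to-tail self-ligation.

    Two cases are modelled: a palindromic overhang (equal to its own
    reverse complement) anneals directly between identical units; and a
    homopolymer of A or T, the asymmetric TT/AA two-oligo scheme in which
    the top oligo carries the T overhang and the bottom oligo the
    complementary A overhang.  The latter is the conventional choice
    because the resulting junctions template adenine-directed fill-in
    labelling.  Anything else (e.g. ``GG``) has no annealing partner
    within a single unit design and is rejected.
    """
    ov = overhang.upper()
    if not ov or set(ov) - set("ACGT"):
        return False
    if ov == reverse_complement(ov):
        return True
    return set(ov) <= {"A"} or set(ov) <= {"T"}


def build_concatemer(bait: AlleleBait, copies: int, overhang: str = "TT") -> str:
    """Top-strand sequence of a head-to-tail ``copies``-mer of ``bait``.

    Each repeat unit contributes the bait followed by one copy of the
    overhang, so the junction between consecutive units carries the
    overhang exactly once and the final overhang is the terminal sticky
    end: ``len == copies * (len(bait) + len(overhang))``.
    """
    if copies < 1:
        raise ValueError(f"copies must be >= 1, got {copies}")
    if not is_ligation_compatible(overhang):
        raise ValueError(
            f"overhang {overhang!r} cannot anneal head-to-tail: it is neither "
            "palindromic nor an A/T homopolymer"
        )
    unit = bait.sequence + overhang.upper()
    return unit * copies


def write_fasta(baits: Iterable[AlleleBait], path: str | Path) -> int:
    """Write baits as FASTA (headers ``rsid_allele``, 60-column wrap).

    Returns the number of records written.
    """
    records = [SeqRecord(Seq(b.sequence), id=b.name, description="") for b in baits]
    if not records:
        raise ValueError("no baits to write")
    return SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in fasta_parse(str(path), "fasta")}


def default_panel_path() -> Path:
    """Path of the bundled 12-SNP type 1 diabetes panel."""
    return Path(__file__).parent / "data" / "il2ra_t1d_panel.tsv"


def load_default_panel() -> list[SnpRecord]:
    """The bundled 12-SNP panel at the IL2RA locus."""
    return parse_panel(default_panel_path())
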