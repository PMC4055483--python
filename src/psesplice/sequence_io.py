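"""FASTA input/output and validation for fixed-length splice-site windows.

A benchmark window is a 140-nt DNA sequence with the candidate splice
signal — GT for a donor (5' splice site), AG for an acceptor (3' splice
site) — at its centre, here taken as 1-based positions 70-71. Positive
(true-site) and negative (false-site) sequences are carried in separate
FASTA files; the truth label is a property of the file, not of the
record header.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")


class SiteType(str, enum.Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"

    @property
    def signal(self) -> str:
        """Canonical dinucleotide at the site: GT for donor, AG for acceptor."""
        return "GT" if self is SiteType.DONOR else "AG"


class Label(str, enum.Enum):
    TRUE_SITE = "true_site"
    FALSE_SITE = "false_site"
    UNLABELED = "unlabeled"


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class SpliceSequence:
    """One fixed-length DNA window around a candidate splice signal."""

    id: str
    residues: str
    site_type: SiteType = SiteType.DONOR
    label: Label = Label.UNLABELED

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        object.__setattr__(self, "site_type", SiteType(self.site_type))
        object.__setattr__(self, "label", Label(self.label))
        for pos, base in enumerate(self.residues, start=1):
            if base not in VALID_BASES:
                raise AlphabetError(
                    f"record {self.id!r}: invalid base {base!r} at position {pos}"
                )
        if not self.residues:
            raise AlphabetError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def dinucleotide_at(self, position: int) -> str:
        """Dinucleotide at 1-based (position, position+1)."""
        return self.residues[position - 1 : position + 1]


class LabeledDataset:
    """Ordered collection of equal-length windows sharing one site type."""

    def __init__(self, sequences: Iterable[SpliceSequence], site_type: SiteType):
        self.sequences: list[SpliceSequence] = list(sequences)
        self.site_type = SiteType(site_type)
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
        for s in self.sequences:
            if s.site_type is not self.site_type:
                raise ValueError(
                    f"record {s.id!r} has site_type {s.site_type.value}, "
                    f"dataset is {self.site_type.value}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[SpliceSequence]:
        return iter(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]

    @property
    def length(self) -> int:
        """Common window length L."""
        if not self.sequences:
            raise ValueError("empty dataset has no length")
        return len(self.sequences[0])

    @property
    def n_pos(self) -> int:
        return sum(1 for s in self if s.label is Label.TRUE_SITE)

    @property
    def n_neg(self) -> int:
        return sum(1 for s in self if s.label is Label.FALSE_SITE)

    def relabel(self, label: Label) -> "LabeledDataset":
        return LabeledDataset(
            (SpliceSequence(s.id, s.residues, s.site_type, label) for s in self),
            self.site_type,
        )


def read_fasta(
    path: str | Path,
    site_type: SiteType | str = SiteType.DONOR,
    label: Label | str = Label.UNLABELED,
) -> LabeledDataset:
    """Read a FASTA file into a dataset, one label for every record.

    Residues are uppercased; record order is preserved. The full header
    line (id plus description) is kept as the sequence id so that ids
    containing whitespace survive a round trip.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    sequences = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
        rec_id = rec.description if rec.description else rec.id
        sequences.append(SpliceSequence(rec_id, str(rec.seq), site_type, label))
    return LabeledDataset(sequences, site_type)


def load_benchmark(
    positive_path: str | Path,
    negative_path: str | Path,
    site_type: SiteType | str = SiteType.DONOR,
) -> LabeledDataset:
    """Merge a positive (true-site) and a negative (false-site) FASTA file."""
    pos = read_fasta(positive_path, site_type, Label.TRUE_SITE)
    neg = read_fasta(negative_path, site_type, Label.FALSE_SITE)
    return LabeledDataset(list(pos) + list(neg), site_type)


def write_fasta(ds: LabeledDataset, path: str | Path) -> None:
    """Write a dataset to FASTA; round-trips ids and residues exactly."""
    if len(ds) == 0:
        raise ValueError("refusing to write an empty dataset")
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in ds
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


@dataclass
class ValidationReport:
    """Per-record rule violations from benchmark validation."""

    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_text(self) -> str:
        if self.ok:
            return "OK: all records conform to the benchmark conventions\n"
        return "".join(
            f"{seq_id}\t{rule}\t{observed}\n" for seq_id, rule, observed in self.violations
        )


def validate_benchmark(
    ds: LabeledDataset,
    expected_length: int = 140,
    center_offset: int = 70,
) -> ValidationReport:
    """Check window length and the central splice signal; report-only.

    A donor window must carry GT at 1-based positions
    (center_offset, center_offset + 1); an acceptor window AG. The data
    are never mutated.
    """
    if len(ds) == 0:
        raise ValueError("cannot validate an empty dataset")
    signal = ds.site_type.signal
    report = ValidationReport()
    for s in ds:
        if len(s) != expected_length:
            report.violations.append((s.id, "length", str(len(s))))
            continue
        observed = s.dinucleotide_at(center_offset)
        if observed != signal:
            report.violations.append(
                (s.id, f"center_signal[{center_offset}-{center_offset + 1}]", observed)
            )
    return report
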