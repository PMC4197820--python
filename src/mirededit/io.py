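"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open throughout; positions inside a
mature miRNA are reported 1-based from the annotated 5' end.  FASTQ qualities
are Phred+33.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A malformed record in an external file."""


class ValidationError(ValueError):
    """A record that parses but violates an invariant."""


@dataclass(frozen=True)
class SmallRead:
    """One small-RNA sequencing read.

    ``qualities`` are integer Phred scores, one per base.  ``has_n`` flags
    reads containing ambiguous bases; they are permitted here and rejected
    later by the quality filter (N counts as quality 0).
    """

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValidationError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValidationError(f"read {self.read_id!r}: quality outside [0, 60]")

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MiRNARecord:
    """One annotated mature or star miRNA on a genome.

    ``start``/``end`` are 0-based half-open genomic coordinates; the
    annotated sequence is given in miRNA sense (reverse-complemented
    relative to the genome for minus-strand records).
    """

    species: str
    mirna_id: str
    arm: str  # "mature" | "star"
    family_id: str
    contig: str
    start: int
    end: int
    strand: str  # "+" | "-"
    sequence: str

    def __post_init__(self) -> None:
        if self.arm not in ("mature", "star"):
            raise ValidationError(f"{self.mirna_id}: arm must be mature/star, got {self.arm!r}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.mirna_id}: malformed strand {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValidationError(
                f"{self.mirna_id}: interval length {self.end - self.start} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def genomic_slice(self, contigs: dict[str, str]) -> str:
        """Extract the annotated sequence from the genome (miRNA sense)."""
        raw = contigs[self.contig][self.start : self.end]
        return revcomp(raw) if self.strand == "-" else raw

    def validate_against(self, contigs: dict[str, str]) -> None:
        if self.contig not in contigs:
            raise ValidationError(f"{self.mirna_id}: unknown contig {self.contig!r}")
        if not (0 <= self.start < self.end <= len(contigs[self.contig])):
            raise ValidationError(
                f"{self.mirna_id}: interval [{self.start}, {self.end}) outside "
                f"contig {self.contig} of length {len(contigs[self.contig])}"
            )
        if self.genomic_slice(contigs) != self.sequence:
            raise ValidationError(
                f"{self.mirna_id}: annotated sequence does not match genome slice"
            )


@dataclass(frozen=True)
class SnpRecord:
    """One known polymorphic site (used only to exclude candidate edits)."""

    species: str
    contig: str
    position: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"SNP at {self.contig}:{self.position}: ref == alt")
        for b in (self.ref, self.alt):
            if b not in "ACGT":
                raise ValidationError(f"SNP at {self.contig}:{self.position}: base {b!r}")


# ---------------------------------------------------------------------------
# FASTQ


def phred_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def read_fastq(path: str | Path | _io.TextIOBase) -> Iterator[SmallRead]:
    """Lazily yield validated reads from a Phred+33 FASTQ file.

    Raises :class:`FormatError` naming the (1-based) index of the first
    malformed record, e.g. a trailing record with fewer than four lines or a
    sequence/quality length mismatch.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                if len(seq) != len(qual):
                    raise FormatError(
                        f"record {n}: sequence and quality lengths differ"
                    )
                yield SmallRead(
                    read_id=title.split()[0] if title else "",
                    sequence=seq.upper(),
                    qualities=tuple(ord(c) - 33 for c in qual),
                )
        except ValueError as exc:  # malformed FASTQ structure
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"record {n + 1}: {exc}") from exc
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def write_fastq(reads: Iterable[SmallRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{phred_to_string(r.qualities)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation / SNP / family tables

ANNOTATION_COLUMNS = [
    "species", "mirna_id", "arm", "family_id",
    "contig", "start", "end", "strand", "sequence",
]
SNP_COLUMNS = ["species", "contig", "position", "ref", "alt", "allele_freq"]


def read_annotations(
    path: str | Path, contigs: dict[str, str] | None = None
) -> list[MiRNARecord]:
    """Read the BED-like miRNA annotation table (0-based half-open).

    If ``contigs`` is given, every record is validated against the genome.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"start": int, "end": int})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    records = [
        MiRNARecord(
            species=row.species, mirna_id=row.mirna_id, arm=row.arm,
            family_id=row.family_id, contig=row.contig,
            start=int(row.start), end=int(row.end),
            strand=row.strand, sequence=row.sequence,
        )
        for row in df.itertuples(index=False)
    ]
    if contigs is not None:
        for rec in records:
            rec.validate_against(contigs)
    return records


def write_annotations(records: Iterable[MiRNARecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.species, r.mirna_id, r.arm, r.family_id, r.contig,
             r.start, r.end, r.strand, r.sequence)
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"position": int})
    missing = {"species", "contig", "position", "ref", "alt"} - set(df.columns)
    if missing:
        raise FormatError(f"SNP table missing columns: {sorted(missing)}")
    return [
        SnpRecord(row.species, row.contig, int(row.position), row.ref, row.alt)
        for row in df.itertuples(index=False)
    ]


def write_snp_table(snps: Iterable, path: str | Path) -> None:
    rows = []
    for s in snps:
        if isinstance(s, SnpRecord):
            rows.append((s.species, s.contig, s.position, s.ref, s.alt, ""))
        else:  # (species, contig, pos, ref, alt, freq) tuples from the simulator
            rows.append(tuple(s))
    pd.DataFrame(rows, columns=SNP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_families(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.family_id, []).append((row.species, row.mirna_id))
    return out


def write_families(families: dict[str, list[tuple[str, str]]], path: str | Path) -> None:
    rows = [
        (fam, sp, mid) for fam, members in families.items() for sp, mid in members
    ]
    pd.DataFrame(rows, columns=["family_id", "species", "mirna_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(df: pd.DataFrame, path: str | Path, header_note: str = "") -> None:
    """Write a result table as TSV with a commented provenance header.

    All positions in result tables are 1-based inclusive within the mature
    miRNA, and the header says so.
    """
    with open(path, "w") as fh:
        fh.write("# mirededit result table; positions are 1-based inclusive\n")
        if header_note:
            for line in header_note.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
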