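"""Remapping-based editing-frequency estimation.

Instead of trusting the detection pipeline's read counts (which treat edited
and unedited reads asymmetrically: an edited read with one extra mismatch is
dropped while its unedited counterpart is kept), frequencies are estimated
by remapping the quality-filtered reads against three variant references per
site — the unedited genomic sequence, the edited sequence (site A -> G), and
a "fake-edited" decoy where the adenosine closest to the genuine site is
replaced by G.  Each reference is the annotated mature/star sequence plus
10 nt of genomic context on either side.  A read is counted for a variant
only if it matches it with zero mismatches and spans that variant's site;
reads consistent with more than one variant are discarded.  The fake-edit
count estimates the error-driven background of the estimator, and a
cross-mapping check counts reads with additional perfect genomic matches
outside the quantified loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import MiRNARecord, SmallRead, revcomp
from .synthetic import extended_sequence

DEFAULT_FLANK = 10
KINDS = ("unedited", "edited", "fake-edited")


@dataclass(frozen=True)
class VariantReference:
    mirna_id: str
    kind: str  # "unedited" | "edited" | "fake-edited"
    sequence: str
    site_offset: int  # 0-based offset of this kind's diagnostic site
    annotated_start: int  # offset of the annotated 5' end within sequence

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")


def build_variant_refs(
    record: MiRNARecord,
    position: int,
    contigs: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> dict[str, VariantReference]:
    """Build unedited/edited/fake-edited references for one site.

    ``position`` is 1-based within the annotated sequence and must be an
    adenosine.  The fake site is the A nearest to the genuine site anywhere
    in the flanked sequence (ties resolved to the 5' side); when no other A
    exists the fake reference is omitted with a warning.
    """
    import warnings

    base_seq = extended_sequence(record, dict(contigs), up=flank, down=flank)
    site = flank + position - 1
    if record.sequence[position - 1] != "A" or base_seq[site] != "A":
        raise ValueError(
            f"{record.mirna_id}: position {position} is "
            f"{record.sequence[position - 1]}, not A"
        )
    edited_seq = base_seq[:site] + "G" + base_seq[site + 1 :]
    refs = {
        "unedited": VariantReference(record.mirna_id, "unedited", base_seq, site, flank),
        "edited": VariantReference(record.mirna_id, "edited", edited_seq, site, flank),
    }
    other_as = [i for i, b in enumerate(base_seq) if b == "A" and i != site]
    if not other_as:
        warnings.warn(f"{record.mirna_id}: no other A in window; fake reference omitted")
        return refs
    # nearest A; ties go to the 5' side (the smaller index)
    fake_site = min(other_as, key=lambda i: (abs(i - site), i))
    fake_seq = base_seq[:fake_site] + "G" + base_seq[fake_site + 1 :]
    refs["fake-edited"] = VariantReference(
        record.mirna_id, "fake-edited", fake_seq, fake_site, flank
    )
    return refs


@dataclass
class EditingQuant:
    """Remapping counts and frequency for one miRNA in one sample."""

    sample_id: str
    mirna_id: str
    edited: int = 0
    unedited: int = 0
    fake: int = 0
    crossmap: int = 0

    @property
    def total(self) -> int:
        return self.edited + self.unedited

    @property
    def frequency(self) -> float:
        """edited / (edited + unedited); NaN when no spanning reads."""
        return self.edited / self.total if self.total else float("nan")

    @property
    def fake_fraction(self) -> float:
        denom = self.fake + self.unedited
        return self.fake / denom if denom else float("nan")

    def passes_timecourse_coverage(self, min_edited: int = 10) -> bool:
        return self.edited >= min_edited

    def passes_cancer_coverage(self, min_reads: int = 100) -> bool:
        return self.total >= min_reads


def _spanning_occurrence(read_seq: str, ref: VariantReference) -> int | None:
    """Leftmost occurrence of the read in the reference that spans the site."""
    idx = ref.sequence.find(read_seq)
    while idx != -1:
        if idx <= ref.site_offset < idx + len(read_seq):
            return idx
        idx = ref.sequence.find(read_seq, idx + 1)
    return None


@dataclass
class RemapResult:
    quant: EditingQuant
    read_assignments: list[tuple[str, str, int]] = field(default_factory=list)
    # (read_id, kind, 5' start offset relative to the annotated start)
    counted_sequences: list[str] = field(default_factory=list)


def remap_and_count(
    reads: Iterable[SmallRead | str],
    refs: Mapping[str, VariantReference],
    sample_id: str = "",
) -> RemapResult:
    """Count reads matching exactly one variant reference without mismatches.

    Deterministic; tracks each counted read's 5' start offset relative to
    the annotated miRNA start for the isomiR breakdown.
    """
    mirna_id = next(iter(refs.values())).mirna_id
    quant = EditingQuant(sample_id=sample_id, mirna_id=mirna_id)
    result = RemapResult(quant=quant)
    for read in reads:
        read_id = read.read_id if isinstance(read, SmallRead) else ""
        seq = read.sequence if isinstance(read, SmallRead) else read
        matches: list[tuple[str, int]] = []
        for kind, ref in refs.items():
            occ = _spanning_occurrence(seq, ref)
            if occ is not None:
                matches.append((kind, occ))
        if len(matches) != 1:
            continue
        kind, occ = matches[0]
        if kind == "edited":
            quant.edited += 1
        elif kind == "unedited":
            quant.unedited += 1
        else:
            quant.fake += 1
        offset = occ - refs[kind].annotated_start
        result.read_assignments.append((read_id, kind, offset))
        result.counted_sequences.append(seq)
    return result


def frequency_from_counts(edited: int, unedited: int) -> float:
    """Editing frequency as edited / (edited + unedited)."""
    if edited + unedited == 0:
        return float("nan")
    return edited / (edited + unedited)


def crossmap_check(
    counted_sequences: Sequence[str],
    contigs: Mapping[str, str],
    variant_loci: Sequence[tuple[str, int, int]],
) -> tuple[int, float]:
    """Count counted reads with a perfect genomic match outside all loci.

    ``variant_loci`` are (contig, start, end) intervals covering the
    quantified miRNAs plus flanks; a perfect occurrence (either strand)
    outside every interval flags the read as cross-mappable.
    """
    loci_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in variant_loci:
        loci_by_contig.setdefault(contig, []).append((start, end))

    def outside(contig: str, start: int, end: int) -> bool:
        return all(
            end <= lo or start >= hi
            for lo, hi in loci_by_contig.get(contig, ())
        )

    n_flagged = 0
    for seq in counted_sequences:
        flagged = False
        for query in (seq, revcomp(seq)):
            for contig, genome in contigs.items():
                idx = genome.find(query)
                while idx != -1:
                    if outside(contig, idx, idx + len(query)):
                        flagged = True
                        break
                    idx = genome.find(query, idx + 1)
                if flagged:
                    break
            if flagged:
                break
        n_flagged += flagged
    fraction = n_flagged / len(counted_sequences) if counted_sequences else 0.0
    return n_flagged, fraction


@dataclass
class IsomirBreakdown:
    """2x2 start-offset x editing-status table with an independence test."""

    table: pd.DataFrame  # rows: offsets; columns: edited, unedited
    chi2: float
    p_value: float
    n_excluded: int
    low_expectation: bool  # some expected cell count < 5


def isomir_editing_breakdown(
    assignments: Sequence[tuple[str, str, int]],
    offsets: tuple[int, int] = (0, -1),
) -> IsomirBreakdown:
    """Test independence of 5' cleavage offset and editing status.

    ``assignments`` come from :func:`remap_and_count`; reads with start
    offsets outside ``offsets`` and fake-edit reads are excluded from the
    test.  Chi-square with 1 df, no continuity correction; a warning flag is
    set when any expected cell count is below 5.
    """
    counts = {(o, k): 0 for o in offsets for k in ("edited", "unedited")}
    n_excluded = 0
    for _read_id, kind, offset in assignments:
        if kind not in ("edited", "unedited") or offset not in offsets:
            n_excluded += 1
            continue
        counts[(offset, kind)] += 1
    table = pd.DataFrame(
        {
            "edited": [counts[(o, "edited")] for o in offsets],
            "unedited": [counts[(o, "unedited")] for o in offsets],
        },
        index=[f"start{o:+d}" if o else "start0" for o in offsets],
    )
    arr = table.to_numpy()
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return IsomirBreakdown(table, 0.0, 1.0, n_excluded, True)
    chi2, p, _dof, expected = chi2_contingency(arr, correction=False)
    return IsomirBreakdown(table, float(chi2), float(p), n_excluded,
                           bool((expected < 5).any()))


def quants_to_frame(quants: Sequence[EditingQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "mirna_id": q.mirna_id,
                "edited": q.edited,
                "unedited": q.unedited,
                "fake": q.fake,
                "frequency": q.frequency,
                "crossmap": q.crossmap,
            }
            for q in quants
        ]
    )
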