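"""Per-site mismatch tallies inside annotated miRNAs and candidate filters.

The filter battery, applied to every candidate RNA-DNA mismatch site:

* edge exclusion — mismatches in the first one or last two bases of the
  (post-trim) read, or at the first one or last two positions of the
  annotated sequence, are never tallied (they are dominated by 5'/3'
  modification artifacts rather than editing);
* perfect-read coverage — a site must be covered by at least one read that
  maps without any mismatch;
* single mismatch type — more than one mismatch type above the sequencing
  error rate (0.1%) rejects the site;
* evidence tiers, per tissue — "high" needs both variants at >= 5 reads and
  a mismatch count of at least 5% of the miRNA's total read count in that
  tissue; "relaxed" needs >= 1 read of each variant and >= 1% frequency at
  the site; anything below is "trace";
* SNP overlap — a known polymorphism at the same genomic position in the
  same species rejects the site.

All positions are reported 1-based within the annotated mature/star
sequence; a genomic T->C on a minus-strand miRNA is recorded as A->G in
miRNA sense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentResult
from .io import MiRNARecord, SnpRecord, ValidationError

READ_EDGE_5P = 1   # mismatches in the first base of the read are ignored
READ_EDGE_3P = 2   # ... and in the last two bases
ANN_EDGE_5P = 1    # site positions excluded at the annotation edges
ANN_EDGE_3P = 2


@dataclass
class CallerConfig:
    high_min_reads: int = 5        # reads per variant for the high tier
    high_min_fraction: float = 0.05  # of the miRNA's tissue read total
    relaxed_min_frequency: float = 0.01
    error_rate: float = 0.001      # multi-type rejection threshold
    min_overlap_fraction: float = 0.5  # read-to-annotation assignment


@dataclass
class SiteTally:
    """Raw per-site counts for one candidate position, split by tissue."""

    species: str
    mirna_id: str
    position: int  # 1-based within the annotated sequence
    contig: str
    genomic_pos: int
    strand: str
    ref_base: str
    mismatch_counts: dict[str, dict[str, int]]  # tissue -> change -> reads
    match_counts: dict[str, int]                # tissue -> ref-base spanning reads
    perfect_counts: dict[str, int]              # tissue -> mismatch-free spanning reads
    mirna_totals: dict[str, int]                # tissue -> reads assigned to miRNA

    def spanning(self, tissue: str) -> int:
        return self.match_counts.get(tissue, 0) + sum(
            self.mismatch_counts.get(tissue, {}).values()
        )

    def change_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for per_tissue in self.mismatch_counts.values():
            for change, n in per_tissue.items():
                out[change] = out.get(change, 0) + n
        return out


@dataclass
class SiteCall:
    """One tiered candidate editing site."""

    tally: SiteTally
    change: str                    # dominant change type, e.g. "A>G"
    tier: str                      # "high" | "relaxed" | "trace" | "rejected"
    tier_by_tissue: dict[str, str]
    frequency_by_tissue: dict[str, float]  # mismatch / spanning reads
    flags: frozenset[str]          # subset of {low-coverage, multi-type,
                                   #   below-threshold, snp-overlap, edge-excluded}
    is_canonical_editing: bool = False


class _AnnTally:
    """Accumulator for one annotation: per-position base-level counts."""

    __slots__ = ("rec", "mismatch", "ref", "perfect", "total")

    def __init__(self, rec: MiRNARecord):
        n = len(rec.sequence)
        self.rec = rec
        self.mismatch: dict[str, dict[str, np.ndarray]] = {}
        self.ref: dict[str, np.ndarray] = {}
        self.perfect: dict[str, np.ndarray] = {}
        self.total: dict[str, int] = {}

    def _arrays(self, tissue: str) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.rec.sequence)
        if tissue not in self.ref:
            self.ref[tissue] = np.zeros(n, dtype=np.int64)
            self.perfect[tissue] = np.zeros(n, dtype=np.int64)
            self.total[tissue] = 0
        return self.ref[tissue], self.perfect[tissue]


def collect_site_tallies(
    results_by_tissue: Mapping[str, Iterable[AlignmentResult]],
    annotations: Sequence[MiRNARecord],
    contigs: Mapping[str, str] | None = None,
    config: CallerConfig | None = None,
) -> list[SiteTally]:
    """Tally mismatches of uniquely mapped reads inside annotated miRNAs.

    A read is assigned to an annotation when it aligns on the same strand
    and overlaps it by at least half the aligned read length.  Mismatches at
    read edges or annotation-edge positions are excluded at this stage, so
    a planted edit at annotation position 1 never appears in the tallies.
    """
    config = config or CallerConfig()
    by_contig: dict[str, list[MiRNARecord]] = {}
    for rec in annotations:
        if contigs is not None:
            rec.validate_against(dict(contigs))
        by_contig.setdefault(rec.contig, []).append(rec)

    acc: dict[tuple[str, str], _AnnTally] = {}
    for tissue, results in results_by_tissue.items():
        for res in results:
            if res.status != "mapped" or len(res.hits) != 1:
                continue
            hit = res.hits[0]
            for rec in by_contig.get(hit.contig, ()):
                if rec.strand != hit.strand:
                    continue
                lo, hi = max(hit.start, rec.start), min(hit.end, rec.end)
                if hi - lo < config.min_overlap_fraction * hit.aligned_length:
                    continue
                key = (rec.species, rec.mirna_id)
                tally = acc.get(key)
                if tally is None:
                    tally = acc[key] = _AnnTally(rec)
                ref_arr, perf_arr = tally._arrays(tissue)
                tally.total[tissue] += 1

                L = hit.aligned_length
                # genomic positions of the read's mismatches
                mm_genomic: dict[int, tuple[str, str]] = {}
                edge_ok_genomic: set[int] = set()
                for off, ref_b, read_b in hit.mismatches:
                    g = (hit.start + off if hit.strand == "+"
                         else hit.start + L - 1 - off)
                    mm_genomic[g] = (ref_b, read_b)
                    if READ_EDGE_5P <= off < L - READ_EDGE_3P:
                        edge_ok_genomic.add(g)

                # annotation-sense position range covered by this read
                if rec.strand == "+":
                    a_lo, a_hi = lo - rec.start, hi - rec.start
                    g_of = lambda a: rec.start + a  # noqa: E731
                else:
                    a_lo, a_hi = rec.end - hi, rec.end - lo
                    g_of = lambda a: rec.end - 1 - a  # noqa: E731

                n_ann = len(rec.sequence)
                valid_lo, valid_hi = ANN_EDGE_5P, n_ann - ANN_EDGE_3P
                is_perfect = not hit.mismatches
                for a in range(a_lo, a_hi):
                    g = g_of(a)
                    if g in mm_genomic:
                        if (valid_lo <= a < valid_hi) and g in edge_ok_genomic:
                            per_t = tally.mismatch.setdefault(tissue, {})
                            change = f"{rec.sequence[a]}>{mm_genomic[g][1]}"
                            arr = per_t.get(change)
                            if arr is None:
                                arr = per_t[change] = np.zeros(n_ann, dtype=np.int64)
                            arr[a] += 1
                    else:
                        ref_arr[a] += 1
                        if is_perfect:
                            perf_arr[a] += 1

    tallies: list[SiteTally] = []
    for (species, mirna_id), t in sorted(acc.items()):
        rec = t.rec
        n_ann = len(rec.sequence)
        positions = set()
        for per_t in t.mismatch.values():
            for arr in per_t.values():
                positions.update(np.nonzero(arr)[0].tolist())
        for a in sorted(positions):
            g = rec.start + a if rec.strand == "+" else rec.end - 1 - a
            tallies.append(
                SiteTally(
                    species=species,
                    mirna_id=mirna_id,
                    position=a + 1,
                    contig=rec.contig,
                    genomic_pos=g,
                    strand=rec.strand,
                    ref_base=rec.sequence[a],
                    mismatch_counts={
                        tissue: {c: int(arr[a]) for c, arr in per_t.items() if arr[a] > 0}
                        for tissue, per_t in t.mismatch.items()
                        if any(arr[a] > 0 for arr in per_t.values())
                    },
                    match_counts={ti: int(t.ref[ti][a]) for ti in t.ref},
                    perfect_counts={ti: int(t.perfect[ti][a]) for ti in t.perfect},
                    mirna_totals=dict(t.total),
                )
            )
    return tallies


TIER_ORDER = {"none": 0, "trace": 1, "relaxed": 2, "high": 3}


def _tissue_tier(
    mm: int, match: int, spanning: int, mirna_total: int, config: CallerConfig
) -> str:
    if mm <= 0:
        return "none"
    freq = mm / spanning if spanning else 0.0
    if (mm >= config.high_min_reads and match >= config.high_min_reads
            and mirna_total > 0 and mm >= config.high_min_fraction * mirna_total):
        return "high"
    if freq >= config.relaxed_min_frequency and match >= 1:
        return "relaxed"
    return "trace"


def apply_site_filters(
    tallies: Iterable[SiteTally],
    snps: Iterable[SnpRecord] = (),
    config: CallerConfig | None = None,
) -> list[SiteCall]:
    """Flag and tier every candidate site; flags imply rejection."""
    config = config or CallerConfig()
    snp_positions = {(s.species, s.contig, s.position) for s in snps}
    calls: list[SiteCall] = []
    for t in tallies:
        totals = t.change_totals()
        if not totals:
            continue
        best = max(totals.values())
        leaders = sorted(c for c, n in totals.items() if n == best)
        change = leaders[0]

        flags: set[str] = set()
        spanning_all = sum(t.spanning(ti) for ti in set(t.match_counts) | set(t.mismatch_counts))
        if sum(t.perfect_counts.values()) < 1:
            flags.add("low-coverage")
        # a mismatch type competes only when it is distinguishable from
        # sequencing error: above the error rate AND seen in >= 2 reads (a
        # singleton is within expectation at 0.1% error for any coverage)
        above_error = [
            c for c, n in totals.items()
            if n >= 2 and spanning_all and n / spanning_all > config.error_rate
        ]
        if len(above_error) > 1:
            flags.add("multi-type")
        if (t.species, t.contig, t.genomic_pos) in snp_positions:
            flags.add("snp-overlap")

        tier_by_tissue: dict[str, str] = {}
        freq_by_tissue: dict[str, float] = {}
        for tissue in sorted(set(t.match_counts) | set(t.mismatch_counts)):
            mm = t.mismatch_counts.get(tissue, {}).get(change, 0)
            match = t.match_counts.get(tissue, 0)
            spanning = t.spanning(tissue)
            tier_by_tissue[tissue] = _tissue_tier(
                mm, match, spanning, t.mirna_totals.get(tissue, 0), config
            )
            freq_by_tissue[tissue] = mm / spanning if spanning else float("nan")

        site_tier = max(tier_by_tissue.values(), key=TIER_ORDER.__getitem__, default="none")
        if TIER_ORDER[site_tier] < TIER_ORDER["relaxed"]:
            flags.add("below-threshold")
        tier = "rejected" if flags - {"below-threshold"} else site_tier
        if "below-threshold" in flags and tier not in ("trace", "none"):
            tier = "rejected"

        call = SiteCall(
            tally=t,
            change=change,
            tier=tier,
            tier_by_tissue=tier_by_tissue,
            frequency_by_tissue=freq_by_tissue,
            flags=frozenset(flags),
        )
        call.is_canonical_editing = classify_change(call, _leaders=leaders)
        calls.append(call)
    return calls


def classify_change(call: SiteCall, _leaders: list[str] | None = None) -> bool:
    """True iff the dominant mismatch type is A->G in miRNA sense.

    A tie between two change types is not classified (returns False with a
    warning): the data cannot say which change dominates.
    """
    if _leaders is None:
        totals = call.tally.change_totals()
        best = max(totals.values())
        _leaders = sorted(c for c, n in totals.items() if n == best)
    if len(_leaders) > 1:
        warnings.warn(
            f"{call.tally.mirna_id} position {call.tally.position}: tie between "
            f"change types {_leaders}; not classified as canonical editing",
            stacklevel=2,
        )
        return False
    return _leaders[0] == "A>G"


def calls_to_frame(calls: Sequence[SiteCall]) -> pd.DataFrame:
    """Flatten calls into the site-call result table."""
    rows = []
    for c in calls:
        t = c.tally
        tissues = sorted(set(t.match_counts) | set(t.mismatch_counts))
        rows.append({
            "species": t.species,
            "mirna_id": t.mirna_id,
            "position": t.position,
            "change": c.change,
            "tier": c.tier,
            "canonical_A_to_G": c.is_canonical_editing,
            "flags": ",".join(sorted(c.flags)) or "-",
            "mismatch_reads": sum(
                t.mismatch_counts.get(ti, {}).get(c.change, 0) for ti in tissues
            ),
            "match_reads": sum(t.match_counts.get(ti, 0) for ti in tissues),
            "tissue_tiers": ";".join(f"{ti}:{c.tier_by_tissue[ti]}" for ti in tissues),
            "tissue_frequencies": ";".join(
                f"{ti}:{c.frequency_by_tissue[ti]:.4f}" for ti in tissues
            ),
        })
    return pd.DataFrame(rows)
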