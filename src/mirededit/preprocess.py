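"""Adapter trimming and read-level length/quality filters.

Reads are kept only if, after adapter removal, they are 15-28 nt long and
every base call has Phred quality >= 30 (error rate <= 0.1%).  A relaxed
mode (minimum quality 20 read-wide) exists for datasets of lower quality,
where per-site evaluation then re-imposes Q30 at the interrogated base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .io import SmallRead

MIN_ADAPTER_OVERLAP = 8


@dataclass(frozen=True)
class FilterConfig:
    min_length: int = 15
    max_length: int = 28
    min_quality: int = 30
    alt_min_quality: int = 20  # relaxed mode, additional-species datasets
    adapter: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("require 0 < min_length <= max_length")
        for q in (self.min_quality, self.alt_min_quality):
            if not 0 <= q <= 60:
                raise ValueError("quality thresholds must lie in [0, 60]")


@dataclass
class FilterTally:
    """Rejection bookkeeping; input == kept + length + quality always holds."""

    kept: int = 0
    rejected_length: int = 0
    rejected_quality: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.rejected_length + self.rejected_quality

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.total,
            "kept": self.kept,
            "rejected_length": self.rejected_length,
            "rejected_quality": self.rejected_quality,
        }


def trim_adapter(read: SmallRead, adapter: str) -> SmallRead:
    """Remove a 3' adapter and everything downstream of it.

    The full adapter is searched anywhere in the read; failing that, a
    prefix of the adapter (>= 8 nt, exact) is matched against the read's
    3' end.  Qualities are trimmed in lockstep.  No match leaves the read
    unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    cut = seq.find(adapter)
    if cut == -1:
        cut = len(seq)
        for overlap in range(min(len(adapter), len(seq)) - 1, MIN_ADAPTER_OVERLAP - 1, -1):
            if seq.endswith(adapter[:overlap]):
                cut = len(seq) - overlap
                break
    if cut == len(seq):
        return read
    return SmallRead(read.read_id, seq[:cut], read.qualities[:cut])


def filter_reads(
    reads: Iterable[SmallRead],
    config: FilterConfig,
    tally: FilterTally | None = None,
    relaxed: bool = False,
) -> Iterator[SmallRead]:
    """Yield reads passing the length then quality filters.

    A read failing both criteria is tallied once, under length (checked
    first).  N bases count as quality 0 and therefore always fail.
    """
    min_q = config.alt_min_quality if relaxed else config.min_quality
    tally = tally if tally is not None else FilterTally()
    for read in reads:
        if config.adapter:
            read = trim_adapter(read, config.adapter)
        if not (config.min_length <= len(read) <= config.max_length):
            tally.rejected_length += 1
            continue
        quals = [0 if b == "N" else q for b, q in zip(read.sequence, read.qualities)]
        if any(q < min_q for q in quals):
            tally.rejected_quality += 1
            continue
        tally.kept += 1
        yield read


def preprocess_reads(
    reads: Iterable[SmallRead], config: FilterConfig, relaxed: bool = False
) -> tuple[list[SmallRead], FilterTally]:
    """Eager convenience wrapper: trim + filter, returning reads and tally."""
    tally = FilterTally()
    kept = list(filter_reads(reads, config, tally, relaxed=relaxed))
    return kept, tally
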