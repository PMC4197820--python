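"""Short-read alignment with bounded mismatches and best-stratum semantics.

The mapping contract: enumerate every alignment of a read with at most
``max_mismatches`` substitutions (no gaps) on either strand; alignments with
fewer mismatches form a better stratum; a read is kept only if its best
stratum holds no more than ``multimap_limit`` hits (one, by default).  Reads
that fail to map are retried with one and then two bases removed from the 3'
end, to absorb non-templated 3' additions.

``align_read`` is seed-and-extend: a read with at most m mismatches contains
m+1 contiguous chunks of which at least one is mismatch-free (pigeonhole), so
exact occurrences of each chunk enumerate every candidate locus.  Chunks of
at least the index k-mer size are located through the k-mer index; shorter
chunks (short reads at m=2) fall back to exact substring scanning, which
keeps sensitivity complete.  ``brute_force_align`` is an independent
sliding-window implementation with the identical return contract, used as a
test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import SmallRead, revcomp

COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

Mismatch = tuple[int, str, str]  # (read offset, ref base, read base), miRNA sense


@dataclass(frozen=True)
class AlignPolicy:
    max_mismatches: int = 1
    unique_best: bool = True
    multimap_limit: int = 1  # 5 in relaxed (additional-species) mode
    trim_retry: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1, 2):
            raise ValueError("max_mismatches must be 0, 1 or 2")
        if self.multimap_limit < 1:
            raise ValueError("multimap_limit must be >= 1")


RELAXED_POLICY = AlignPolicy(max_mismatches=1, unique_best=False, multimap_limit=5)


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    contig: str
    start: int  # 0-based, forward-genome coordinate of the leftmost base
    strand: str
    mismatches: tuple[Mismatch, ...]
    trim: int  # bases removed from the 3' end before mapping (0, 1 or 2)
    aligned_length: int

    @property
    def end(self) -> int:
        return self.start + self.aligned_length


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome for one read: mapped / unmapped / suppressed multimapper."""

    status: str  # "mapped" | "unmapped" | "suppressed"
    hits: tuple[AlignmentHit, ...] = ()
    trim: int = 0

    @property
    def hit(self) -> AlignmentHit:
        if self.status != "mapped" or len(self.hits) != 1:
            raise ValueError("no unique hit on this result")
        return self.hits[0]


UNMAPPED = AlignmentResult("unmapped")


class GenomeIndex:
    """Exact k-mer position index over a set of contigs (forward strand).

    Reverse-strand queries are answered by looking up the reverse complement
    and mirroring the coordinate.  Contigs shorter than k are kept in a
    full-length exact table instead.
    """

    def __init__(self, contigs: dict[str, str], k: int = 12):
        if not contigs:
            raise ValueError("contigs must be non-empty")
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self.k = k
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        self._short: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            if len(seq) < k:
                self._short.setdefault(seq, []).append((name, 0))
                continue
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i : i + k], []).append((name, i))

    def lookup(self, query: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of a k-mer, as (contig, start, strand)."""
        if len(query) != self.k:
            raise ValueError(f"query length {len(query)} != k={self.k}")
        hits = [(c, p, "+") for c, p in self._kmers.get(query, [])]
        hits += [(c, p, "-") for c, p in self._kmers.get(revcomp(query), [])]
        return hits

    def forward_positions(self, kmer: str) -> list[tuple[str, int]]:
        return self._kmers.get(kmer, [])


def build_index(contigs: dict[str, str], k: int = 12) -> GenomeIndex:
    return GenomeIndex(contigs, k=k)


# ---------------------------------------------------------------------------
# Seed-and-extend alignment


def _chunk_offsets(length: int, parts: int) -> list[tuple[int, int]]:
    """Split [0, length) into ``parts`` near-equal contiguous chunks."""
    bounds = [round(j * length / parts) for j in range(parts + 1)]
    return [(bounds[j], bounds[j + 1]) for j in range(parts)]

def _verify(contig_seq: str, start: int, query: str, max_mm: int) -> int:
    """Mismatch count of query vs contig at start, or -1 if > max_mm."""
    mm = 0
    for off in range(len(query)):
        if contig_seq[start + off] != query[off]:
            mm += 1
            if mm > max_mm:
                return -1
    return mm


def _candidate_starts(index: GenomeIndex, query: str, max_mm: int) -> set[tuple[str, int]]:
    """Genome starts at which ``query`` may align with <= max_mm mismatches."""
    k = index.k
    candidates: set[tuple[str, int]] = set()
    for lo, hi in _chunk_offsets(len(query), max_mm + 1):
        chunk = query[lo:hi]
        if not chunk:
            continue
        if len(chunk) >= k:
            for contig, pos in index.forward_positions(chunk[:k]):
                candidates.add((contig, pos - lo))
        else:  # short chunk: exact scan (keeps pigeonhole sensitivity)
            for contig, seq in index.contigs.items():
                p = seq.find(chunk)
                while p != -1:
                    candidates.add((contig, p - lo))
                    p = seq.find(chunk, p + 1)
    # contigs shorter than k are only reachable by full-length identity
    for contig, pos in index._short.get(query, []):
        candidates.add((contig, pos))
    return candidates


def _mismatch_tuple(
    contig_seq: str, start: int, sequence: str, strand: str
) -> tuple[Mismatch, ...]:
    """Mismatch descriptors in read orientation (miRNA sense)."""
    L = len(sequence)
    out = []
    if strand == "+":
        for off in range(L):
            ref = contig_seq[start + off]
            if ref != sequence[off]:
                out.append((off, ref, sequence[off]))
    else:
        for off in range(L):
            g = start + L - 1 - off
            ref = COMPLEMENT_BASE[contig_seq[g]]
            if ref != sequence[off]:
                out.append((off, ref, sequence[off]))
    return tuple(out)


def _enumerate_hits(
    read_id: str, sequence: str, index: GenomeIndex, max_mm: int, trim: int
) -> list[AlignmentHit]:
    L = len(sequence)
    hits: list[AlignmentHit] = []
    seen: set[tuple[str, int, str]] = set()
    for strand in "+-":
        query = sequence if strand == "+" else revcomp(sequence)
        for contig, start in _candidate_starts(index, query, max_mm):
            if start < 0 or start + L > len(index.contigs[contig]):
                continue
            key = (contig, start, strand)
            if key in seen:
                continue
            seen.add(key)
            mm = _verify(index.contigs[contig], start, query, max_mm)
            if mm < 0:
                continue
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    contig=contig,
                    start=start,
                    strand=strand,
                    mismatches=_mismatch_tuple(index.contigs[contig], start, sequence, strand),
                    trim=trim,
                    aligned_length=L,
                )
            )
    return hits


def _resolve(hits: list[AlignmentHit], policy: AlignPolicy, trim: int) -> AlignmentResult:
    if not hits:
        return UNMAPPED
    best = min(len(h.mismatches) for h in hits)
    best_hits = sorted(
        (h for h in hits if len(h.mismatches) == best),
        key=lambda h: (h.contig, h.start, h.strand),
    )
    if len(best_hits) > policy.multimap_limit:
        return AlignmentResult("suppressed", trim=trim)
    return AlignmentResult("mapped", hits=tuple(best_hits), trim=trim)


def align_read(
    read: SmallRead | str,
    index: GenomeIndex,
    policy: AlignPolicy = AlignPolicy(),
) -> AlignmentResult:
    """Align one read; on failure retry with 1 then 2 bases trimmed 3'."""
    read_id = read.read_id if isinstance(read, SmallRead) else ""
    sequence = (read.sequence if isinstance(read, SmallRead) else read).upper()
    trims = (0, 1, 2) if policy.trim_retry else (0,)
    for trim in trims:
        if trim >= len(sequence):
            break
        seq = sequence[: len(sequence) - trim] if trim else sequence
        hits = _enumerate_hits(read_id, seq, index, policy.max_mismatches, trim)
        result = _resolve(hits, policy, trim)
        if result.status != "unmapped":
            return result
    return UNMAPPED


class CachedAligner:
    """Memoizes alignment outcomes by read sequence.

    Small-RNA libraries are dominated by duplicate sequences (one mature
    miRNA yields thousands of identical reads), so caching turns alignment
    cost from per-read into per-distinct-sequence.
    """

    def __init__(self, index: GenomeIndex, policy: AlignPolicy = AlignPolicy()):
        self.index = index
        self.policy = policy
        self._cache: dict[str, AlignmentResult] = {}

    def align(self, read: SmallRead) -> AlignmentResult:
        template = self._cache.get(read.sequence)
        if template is None:
            template = align_read(read.sequence, self.index, self.policy)
            self._cache[read.sequence] = template
        if template.status != "mapped":
            return template
        hits = tuple(
            AlignmentHit(read.read_id, h.contig, h.start, h.strand,
                         h.mismatches, h.trim, h.aligned_length)
            for h in template.hits
        )
        return AlignmentResult("mapped", hits=hits, trim=template.trim)

    def align_all(self, reads: Iterable[SmallRead]) -> list[AlignmentResult]:
        return [self.align(r) for r in reads]


# ---------------------------------------------------------------------------
# Brute-force oracle (independent implementation, numpy sliding windows)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def brute_force_align(
    read: SmallRead | str,
    contigs: dict[str, str],
    policy: AlignPolicy = AlignPolicy(),
) -> AlignmentResult:
    """Sliding-window alignment at every position and strand.

    Same return contract as :func:`align_read`; kept deliberately free of
    seeding or indexing so it can serve as an equivalence oracle.
    """
    read_id = read.read_id if isinstance(read, SmallRead) else ""
    sequence = (read.sequence if isinstance(read, SmallRead) else read).upper()
    trims = (0, 1, 2) if policy.trim_retry else (0,)
    arrays = {name: _seq_array(seq.upper()) for name, seq in contigs.items()}
    for trim in trims:
        if trim >= len(sequence):
            break
        seq = sequence[: len(sequence) - trim] if trim else sequence
        L = len(seq)
        hits: list[AlignmentHit] = []
        for strand in "+-":
            query = _seq_array(seq if strand == "+" else revcomp(seq))
            for name, garr in arrays.items():
                if len(garr) < L:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(garr, L)
                counts = (windows != query).sum(axis=1)
                for start in np.nonzero(counts <= policy.max_mismatches)[0]:
                    hits.append(
                        AlignmentHit(
                            read_id=read_id,
                            contig=name,
                            start=int(start),
                            strand=strand,
                            mismatches=_mismatch_tuple(
                                contigs[name].upper(), int(start), seq, strand
                            ),
                            trim=trim,
                            aligned_length=L,
                        )
                    )
        result = _resolve(hits, policy, trim)
        if result.status != "unmapped":
            return result
    return UNMAPPED
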