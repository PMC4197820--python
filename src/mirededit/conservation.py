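"""Cross-species conservation of candidate editing sites.

miRNAs are grouped into families of orthologs; the mature (or star)
sequences of each family are multiple-aligned so that per-species candidate
sites can be projected onto common alignment columns.  A conserved editing
event requires (a) the column to be a non-gap adenosine in every species
claiming editing there (non-conserved sites are more likely to harbor
polymorphisms), and (b) evidence in at least two species — at the high tier
for the stringent set, or at the relaxed >=1% tier for the extended set.

The multiple alignment is a progressive star alignment over pairwise global
alignments with unit match/mismatch/gap costs: mature miRNAs are ~22 nt and
near-identical across species, so any optimal-cost aligner reproduces the
same columns; a dynamic-programming oracle in the test suite guards this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .align import AlignPolicy, CachedAligner, GenomeIndex, align_read
from .caller import SiteCall, TIER_ORDER
from .io import SmallRead
from .preprocess import FilterConfig, preprocess_reads

Member = tuple[str, str]  # (species, mirna_id)


def _unit_cost_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_global(a: str, b: str) -> tuple[str, str, int]:
    """Optimal global alignment of two sequences under unit costs.

    Returns the two gapped rows and the total cost (substitutions + gaps).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _unit_cost_aligner()
    alignment = aligner.align(a, b)[0]
    rows = str(alignment).splitlines()
    # Bio.Align text blocks: target / match / query lines; extract gapped rows
    ga, gb = alignment[0], alignment[1]
    return ga, gb, int(-alignment.score)


@dataclass
class FamilyAlignment:
    """Gapped alignment of one miRNA family, with position<->column maps."""

    family_id: str
    members: list[Member]
    rows: dict[Member, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"family {self.family_id}: unequal row lengths")
        self._col_of: dict[Member, list[int]] = {}
        self._pos_of: dict[Member, dict[int, int]] = {}
        for member, row in self.rows.items():
            cols, pos_of = [], {}
            for col, ch in enumerate(row):
                if ch != "-":
                    pos_of[col] = len(cols)
                    cols.append(col)
            self._col_of[member] = cols
            self._pos_of[member] = pos_of

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def column_of(self, member: Member, position: int) -> int:
        """Alignment column of a 1-based sequence position."""
        return self._col_of[member][position - 1]

    def position_of(self, member: Member, column: int) -> int | None:
        """1-based sequence position at a column, or None for a gap."""
        p = self._pos_of[member].get(column)
        return None if p is None else p + 1

    def base_at(self, member: Member, column: int) -> str:
        return self.rows[member][column]


def align_family(sequences: Mapping[Member, str], family_id: str = "") -> FamilyAlignment:
    """Progressive star alignment of a family's sequences.

    The first member is the center; every other member is aligned pairwise
    to it and the pairwise alignments are merged on the center's coordinate
    system (a gap introduced into the center by any member is propagated to
    all rows).  Identical sequences align gap-free.
    """
    members = list(sequences)
    if len(members) < 2:
        raise ValueError("need at least two sequences to align")
    for m, s in sequences.items():
        if not s:
            raise ValueError(f"empty sequence for {m}")

    center = members[0]
    center_seq = sequences[center]
    # msa rows as lists of chars; center row defines the master gap structure
    msa: dict[Member, list[str]] = {center: list(center_seq)}
    for member in members[1:]:
        gc, gm, _ = pairwise_global(center_seq, sequences[member])
        new_row: list[str] = []
        # walk the existing master center row and the new pairwise center row,
        # reconciling their gap patterns
        old_center = msa[center]
        i = j = 0
        merged_old_idx: list[int | None] = []  # per merged column: old msa col
        merged_new: list[str] = []
        while i < len(old_center) or j < len(gc):
            old_ch = old_center[i] if i < len(old_center) else None
            new_ch = gc[j] if j < len(gc) else None
            if old_ch is not None and new_ch is not None and old_ch == new_ch:
                merged_old_idx.append(i)
                merged_new.append(gm[j])
                i += 1
                j += 1
            elif old_ch == "-":  # gap already in master, absent from new pair
                merged_old_idx.append(i)
                merged_new.append("-")
                i += 1
            elif new_ch == "-":  # new gap in center: insert into master
                merged_old_idx.append(None)
                merged_new.append(gm[j])
                j += 1
            else:  # same residue, consume both
                merged_old_idx.append(i)
                merged_new.append(gm[j])
                i += 1
                j += 1
        for m_key in list(msa):
            msa[m_key] = [
                (msa[m_key][idx] if idx is not None else "-") for idx in merged_old_idx
            ]
        msa[member] = merged_new

    return FamilyAlignment(family_id, members, {m: "".join(r) for m, r in msa.items()})


def select_ortholog(
    species: str,
    candidates: Mapping[str, str],
    reference_sequence: str,
) -> str:
    """Pick the candidate ortholog most similar to the reference mature.

    Similarity is the unit-cost alignment distance (fewest mismatches);
    ties are broken lexicographically by miRNA id, with a warning.
    """
    if not candidates:
        raise ValueError(f"no candidate orthologs for {species}")
    distances = {
        mid: pairwise_global(reference_sequence, seq)[2]
        for mid, seq in candidates.items()
    }
    best = min(distances.values())
    leaders = sorted(mid for mid, d in distances.items() if d == best)
    if len(leaders) > 1:
        warnings.warn(
            f"{species}: ortholog tie at distance {best} between {leaders}; "
            f"keeping {leaders[0]}",
            stacklevel=2,
        )
    return leaders[0]


@dataclass
class ConservedEvent:
    """One alignment column with editing evidence in >= min_species species."""

    family_id: str
    column: int
    positions: dict[str, int]        # species -> 1-based position in its sequence
    species_tiers: dict[str, str]    # high | relaxed | trace | none | no-data
    n_species: int                   # species at >= relaxed tier
    clade_label: str = ""

    @property
    def claiming_species(self) -> list[str]:
        return sorted(
            sp for sp, t in self.species_tiers.items()
            if TIER_ORDER.get(t, 0) >= TIER_ORDER["relaxed"]
        )


def call_conserved_events(
    calls_by_species: Mapping[str, Sequence[SiteCall]],
    family_alignments: Mapping[str, FamilyAlignment],
    min_species: int = 2,
    mode: str = "high",
    species_with_data: Iterable[str] | None = None,
) -> tuple[list[ConservedEvent], list[SiteCall]]:
    """Project site calls onto family alignments and keep conserved events.

    ``mode="high"`` demands the high tier in at least two species (the
    stringent set); ``mode="relaxed"`` accepts the >=1% tier.  Returns the
    events plus orphan calls whose miRNA belongs to no aligned family.
    Rejected calls never contribute evidence.
    """
    if mode not in ("high", "relaxed"):
        raise ValueError("mode must be 'high' or 'relaxed'")
    member_to_family: dict[Member, str] = {}
    for fam_id, aln in family_alignments.items():
        for member in aln.members:
            member_to_family[member] = fam_id

    all_species = set(calls_by_species)
    data_species = set(species_with_data) if species_with_data is not None else all_species

    per_column: dict[tuple[str, int], dict[str, tuple[str, SiteCall]]] = {}
    orphans: list[SiteCall] = []
    for species, calls in calls_by_species.items():
        for call in calls:
            member = (call.tally.species, call.tally.mirna_id)
            fam_id = member_to_family.get(member)
            if fam_id is None:
                orphans.append(call)
                continue
            aln = family_alignments[fam_id]
            col = aln.column_of(member, call.tally.position)
            slot = per_column.setdefault((fam_id, col), {})
            tier = call.tier if call.tier in TIER_ORDER else "none"
            prev = slot.get(species)
            if prev is None or TIER_ORDER[tier] > TIER_ORDER[prev[0]]:
                slot[species] = (tier, call)

    events: list[ConservedEvent] = []
    for (fam_id, col), by_species in sorted(per_column.items()):
        aln = family_alignments[fam_id]
        tiers = {sp: t for sp, (t, _) in by_species.items()}
        claiming = [sp for sp, t in tiers.items() if TIER_ORDER[t] >= TIER_ORDER["relaxed"]]
        # conserved-site rule: non-gap A in every claiming species
        conserved = True
        positions: dict[str, int] = {}
        for member in aln.members:
            sp = member[0]
            pos = aln.position_of(member, col)
            if pos is not None:
                positions[sp] = pos
            if sp in claiming and (pos is None or aln.base_at(member, col) != "A"):
                conserved = False
        if not conserved:
            continue
        if len(claiming) < min_species:
            continue
        required = "high" if mode == "high" else "relaxed"
        n_required = sum(
            1 for t in tiers.values() if TIER_ORDER[t] >= TIER_ORDER[required]
        )
        if n_required < min_species:
            continue
        full_tiers: dict[str, str] = {}
        for member in aln.members:
            sp = member[0]
            if sp in tiers:
                full_tiers[sp] = tiers[sp]
            elif sp in data_species:
                full_tiers[sp] = "none"
            else:
                full_tiers[sp] = "no-data"
        events.append(
            ConservedEvent(
                family_id=fam_id,
                column=col,
                positions=positions,
                species_tiers=full_tiers,
                n_species=len(claiming),
            )
        )
    return events, orphans


def label_clades(events: Sequence[ConservedEvent], tree_newick: str) -> None:
    """Annotate events with the name of the smallest clade containing all
    claiming species (report metadata only; ages are configuration, never
    computed)."""
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(tree_newick), "newick")
    terminal_names = {t.name for t in tree.get_terminals()}
    for ev in events:
        names = [sp for sp in ev.claiming_species if sp in terminal_names]
        if len(names) < 1:
            continue
        if len(names) == 1:
            ev.clade_label = names[0]
            continue
        mrca = tree.common_ancestor(names)
        ev.clade_label = mrca.name or "+".join(sorted(names))


# ---------------------------------------------------------------------------
# Relaxed additional-species scan


def relaxed_species_scan(
    reads: Sequence[SmallRead],
    reference_sequences: Mapping[str, tuple[str, int]],
    target_contigs: Mapping[str, str],
    filter_config: FilterConfig | None = None,
    site_min_quality: int = 30,
) -> dict[str, str]:
    """Tier known editing events in a species with sparse data.

    ``reference_sequences`` maps miRNA id to (annotated human mature/star
    sequence, 1-based edited position).  The ortholog locus is found by
    mapping the reference sequence to the target genome with at most two
    mismatches (up to five locations, best stratum only); reads filtered at
    the relaxed read-wide Q20 threshold are then piled up over the site,
    requiring Q30 at the interrogated base.  Tiers: "relaxed" (both
    variants covered, mismatch >= 1% of reads over the site), "trace"
    (mismatching reads below 1%), "none" (coverage but no mismatch),
    "no-data" (no coverage or unmappable reference).
    """
    filter_config = filter_config or FilterConfig()
    index = GenomeIndex(dict(target_contigs), k=12)
    locate_policy = AlignPolicy(max_mismatches=2, unique_best=False,
                                multimap_limit=5, trim_retry=False)
    read_policy = AlignPolicy(max_mismatches=1, unique_best=False,
                              multimap_limit=5, trim_retry=True)
    kept, _ = preprocess_reads(reads, filter_config, relaxed=True)
    aligner = CachedAligner(index, read_policy)
    results = [(r, aligner.align(r)) for r in kept]

    tiers: dict[str, str] = {}
    for mirna_id, (ref_seq, position) in reference_sequences.items():
        located = align_read(ref_seq, index, locate_policy)
        if located.status != "mapped":
            tiers[mirna_id] = "no-data"
            continue
        hit = located.hits[0]
        if hit.strand == "+":
            site_g = hit.start + (position - 1)
        else:
            site_g = hit.start + hit.aligned_length - 1 - (position - 1)
        n_match = n_mismatch = n_total = 0
        for read, res in results:
            if res.status != "mapped":
                continue
            for h in res.hits:
                if h.contig != hit.contig or h.strand != hit.strand:
                    continue
                if not (h.start <= site_g < h.end):
                    continue
                off = (site_g - h.start if h.strand == "+"
                       else h.start + h.aligned_length - 1 - site_g)
                if read.qualities[off] < site_min_quality:
                    continue
                base = read.sequence[off]
                n_total += 1
                if base == "A":
                    n_match += 1
                elif base == "G":
                    n_mismatch += 1
                break
        if n_total == 0:
            tiers[mirna_id] = "no-data"
        elif n_mismatch >= 1 and n_match >= 1 and n_mismatch / n_total >= 0.01:
            tiers[mirna_id] = "relaxed"
        elif n_mismatch >= 1:
            tiers[mirna_id] = "trace"
        else:
            tiers[mirna_id] = "none"
    return tiers
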