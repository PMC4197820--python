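"""Family alignment, ortholog selection and conserved-event calling."""

import numpy as np
import pytest

from mirededit import synthetic
from mirededit.caller import SiteCall, SiteTally, apply_site_filters
from mirededit.conservation import (
    ConservedEvent,
    align_family,
    call_conserved_events,
    label_clades,
    pairwise_global,
    relaxed_species_scan,
    select_ortholog,
)
from mirededit.io import SmallRead


def edit_distance_dp(a: str, b: str) -> int:
    """Independent oracle: textbook Levenshtein dynamic programming."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestPairwiseAlignment:
    def test_identical_sequences_gap_free(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        ga, gb, cost = pairwise_global(seq, seq)
        assert ga == gb == seq and cost == 0

    def test_single_deletion_forced_by_unit_costs(self):
        ga, gb, cost = pairwise_global("ACGT", "AGT")
        assert cost == 1
        assert len(ga) == 4 and gb.count("-") == 1

    def test_cost_equals_dp_oracle_on_mutated_mirnas(self):
        rng = np.random.default_rng(8)
        bases = "ACGT"
        for _ in range(40):
            a = "".join(bases[i] for i in rng.integers(0, 4, 22))
            chars = list(a)
            for pos in rng.choice(22, size=int(rng.integers(0, 4)), replace=False):
                chars[pos] = bases[int(rng.integers(0, 4))]
            if rng.random() < 0.5 and len(chars) > 1:  # <=1 indel
                del chars[int(rng.integers(0, len(chars)))]
            b = "".join(chars)
            _ga, _gb, cost = pairwise_global(a, b)
            assert cost == edit_distance_dp(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_global("", "ACGT")


class TestFamilyAlignment:
    def test_identical_members_align_gap_free(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        fa = align_family({("sp1", "a"): seq, ("sp2", "b"): seq, ("sp3", "c"): seq})
        assert fa.n_columns == 22
        assert all(row == seq for row in fa.rows.values())

    def test_deletion_creates_single_gap_column(self):
        fa = align_family({("sp1", "a"): "ACGT", ("sp2", "b"): "AGT"})
        assert fa.n_columns == 4
        assert fa.rows[("sp2", "b")].count("-") == 1

    def test_projection_round_trip(self, bundle3):
        for fam, members in bundle3.families.items():
            if len(members) < 2:
                continue
            seqs = {m: bundle3.record(*m).sequence for m in members}
            fa = align_family(seqs, fam)
            for member, seq in seqs.items():
                for pos in range(1, len(seq) + 1):
                    col = fa.column_of(member, pos)
                    assert fa.position_of(member, col) == pos
                    assert fa.base_at(member, col) == seq[pos - 1]

    def test_determinism(self):
        seqs = {("sp1", "a"): "ACGTACGTAC", ("sp2", "b"): "ACGAACGTAC",
                ("sp3", "c"): "ACGTACGGAC"}
        fa1, fa2 = align_family(seqs), align_family(seqs)
        assert fa1.rows == fa2.rows


class TestSelectOrtholog:
    REF = "ACGTACGTACGTACGTACGTAC"

    def test_single_candidate_returned(self):
        assert select_ortholog("sp", {"m1": "ACGAACGTACGTACGTACGTAC"}, self.REF) == "m1"

    def test_fewest_mismatches_wins(self):
        cands = {"m1": "ACGAACGTACGTACGTACGTAC",      # 1 mismatch
                 "m2": "ACGAACGAACGAACGTACGTAC"}      # 3 mismatches
        assert select_ortholog("sp", cands, self.REF) == "m1"

    def test_tie_breaks_lexicographically_with_warning(self):
        cands = {"mB": "ACGAACGTACGTACGTACGTAC",
                 "mA": "ACGTACGAACGTACGTACGTAC"}
        with pytest.warns(UserWarning, match="tie"):
            assert select_ortholog("sp", cands, self.REF) == "mA"


def _call(species, mirna_id, tier, position, ref="A"):
    tally = SiteTally(
        species=species, mirna_id=mirna_id, position=position, contig="c",
        genomic_pos=0, strand="+", ref_base=ref,
        mismatch_counts={"b": {"A>G": 50 if tier == "high" else 2}},
        match_counts={"b": 50 if tier == "high" else 100},
        perfect_counts={"b": 50}, mirna_totals={"b": 100},
    )
    call = apply_site_filters([tally])[0]
    assert call.tier == tier, f"fixture built wrong tier: {call.tier}"
    return call


class TestConservedEvents:
    def _family(self, seqs):
        return {"fam": align_family(seqs, "fam")}

    def test_two_species_high_tier_emitted(self):
        seq = "ACGTAACGTACGTACGTACGTC"
        fams = self._family({("sp1", "m1"): seq, ("sp2", "m2"): seq})
        calls = {"sp1": [_call("sp1", "m1", "high", 5)],
                 "sp2": [_call("sp2", "m2", "high", 5)]}
        events, orphans = call_conserved_events(calls, fams)
        assert len(events) == 1 and not orphans
        assert events[0].species_tiers == {"sp1": "high", "sp2": "high"}
        assert events[0].positions == {"sp1": 5, "sp2": 5}

    def test_single_species_excluded(self):
        seq = "ACGTAACGTACGTACGTACGTC"
        fams = self._family({("sp1", "m1"): seq, ("sp2", "m2"): seq})
        calls = {"sp1": [_call("sp1", "m1", "high", 5)], "sp2": []}
        events, _ = call_conserved_events(calls, fams)
        assert events == []

    def test_non_A_column_in_claiming_species_excluded(self):
        # species 2 carries a fixed G at the claimed column
        s1 = "ACGTAACGTACGTACGTACGTC"
        s2 = "ACGTGACGTACGTACGTACGTC"
        fams = self._family({("sp1", "m1"): s1, ("sp2", "m2"): s2})
        calls = {"sp1": [_call("sp1", "m1", "high", 5)],
                 "sp2": [_call("sp2", "m2", "high", 5, ref="G")]}
        events, _ = call_conserved_events(calls, fams)
        assert events == []

    def test_relaxed_mode_accepts_one_percent_pairs(self):
        seq = "ACGTAACGTACGTACGTACGTC"
        fams = self._family({("sp1", "m1"): seq, ("sp2", "m2"): seq})
        calls = {"sp1": [_call("sp1", "m1", "relaxed", 5)],
                 "sp2": [_call("sp2", "m2", "relaxed", 5)]}
        assert call_conserved_events(calls, fams, mode="high")[0] == []
        events, _ = call_conserved_events(calls, fams, mode="relaxed")
        assert len(events) == 1

    def test_orphan_mirna_reported(self):
        fams = self._family({("sp1", "m1"): "ACGTAACGTACGTACGTACGTC",
                             ("sp2", "m2"): "ACGTAACGTACGTACGTACGTC"})
        stray = _call("sp3", "unknown", "high", 5)
        events, orphans = call_conserved_events({"sp3": [stray]}, fams)
        assert orphans == [stray] and events == []

    def test_no_data_species_does_not_change_events(self):
        seq = "ACGTAACGTACGTACGTACGTC"
        fams2 = self._family({("sp1", "m1"): seq, ("sp2", "m2"): seq})
        calls = {"sp1": [_call("sp1", "m1", "high", 5)],
                 "sp2": [_call("sp2", "m2", "high", 5)]}
        base, _ = call_conserved_events(calls, fams2)
        fams3 = self._family({("sp1", "m1"): seq, ("sp2", "m2"): seq,
                              ("sp3", "m3"): seq})
        grown, _ = call_conserved_events(calls, fams3,
                                         species_with_data=["sp1", "sp2"])
        assert len(grown) == len(base) == 1
        assert grown[0].species_tiers["sp3"] == "no-data"
        assert grown[0].n_species == base[0].n_species

    def test_planted_conserved_events_recovered_exactly(self):
        """6-species bundle: 3 conserved + 5 single-species planted events."""
        bundle = synthetic.generate_reference(6, 8, seed=19)
        mature_fams = sorted(f for f in bundle.families if not f.endswith("*")
                             and len(bundle.families[f]) == 6)
        conserved_fams = mature_fams[:3]
        single_fams = [f for f in sorted(bundle.families)
                       if not f.endswith("*") and f not in conserved_fams][:5]
        calls_by_species: dict[str, list] = {sp: [] for sp in bundle.species}
        for fam in conserved_fams:
            pos = bundle.family_edit_sites[fam]
            for sp, mid in bundle.families[fam]:
                calls_by_species[sp].append(_call(sp, mid, "high", pos))
        for i, fam in enumerate(single_fams):
            pos = bundle.family_edit_sites[fam]
            sp, mid = bundle.families[fam][i % len(bundle.families[fam])]
            calls_by_species[sp].append(_call(sp, mid, "high", pos))
        fams = {
            fam: align_family({m: bundle.record(*m).sequence for m in members}, fam)
            for fam, members in bundle.families.items() if len(members) >= 2
        }
        events, _ = call_conserved_events(calls_by_species, fams, min_species=2)
        assert sorted(e.family_id for e in events) == sorted(conserved_fams)


class TestCladeLabels:
    def test_mrca_name_used(self):
        tree = "((sp1,sp2)placental,(sp3)marsupial)mammal;"
        ev = ConservedEvent("fam", 4, {}, {"sp1": "high", "sp2": "high"}, 2)
        label_clades([ev], tree)
        assert ev.clade_label == "placental"
        ev2 = ConservedEvent("fam", 4, {}, {"sp1": "high", "sp3": "relaxed"}, 2)
        label_clades([ev2], tree)
        assert ev2.clade_label == "mammal"


class TestRelaxedSpeciesScan:
    CONTEXT = "TTACC" + "GCTAGCTAAGCTTACGGATCCA" + "GGTTA"
    MIRNA = "GCTAGCTAAGCTTACGGATCCA"  # position 9 is A
    POS = 9

    def _reads(self, n_match, n_mismatch, q=30):
        reads = []
        edited = self.MIRNA[: self.POS - 1] + "G" + self.MIRNA[self.POS :]
        for i in range(n_match):
            reads.append(SmallRead(f"m{i}", self.MIRNA, (q,) * 22))
        for i in range(n_mismatch):
            reads.append(SmallRead(f"e{i}", edited, (q,) * 22))
        return reads

    def _scan(self, reads):
        return relaxed_species_scan(
            reads, {"mirX": (self.MIRNA, self.POS)}, {"chr": self.CONTEXT}
        )

    def test_two_percent_is_relaxed_tier(self):
        assert self._scan(self._reads(98, 2)) == {"mirX": "relaxed"}

    def test_sub_one_percent_is_trace(self):
        assert self._scan(self._reads(150, 1)) == {"mirX": "trace"}

    def test_no_reads_is_no_data(self):
        assert self._scan([]) == {"mirX": "no-data"}

    def test_unmappable_reference_is_no_data(self):
        tiers = relaxed_species_scan(
            self._reads(10, 0), {"mirX": ("GGGGGGGGCCCCCCCCGGGGGG", 5)},
            {"chr": self.CONTEXT},
        )
        assert tiers == {"mirX": "no-data"}

    def test_low_site_quality_reads_not_counted(self):
        # reads pass the relaxed Q20 filter but fail Q30 at the site
        reads = self._reads(50, 5, q=25)
        assert self._scan(reads) == {"mirX": "no-data"}
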