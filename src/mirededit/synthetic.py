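"""Synthetic reference bundles and small-RNA reads with known truth.

The generator emulates the statistical structure the detection pipeline
assumes: hairpin-derived mature/star reads carrying site-specific A->G edits
at programmed per-sample frequencies, per-base sequencing errors at a
quality-consistent rate (0.1% at Q30 by default), 1-2 nt non-templated 3'
additions, 5' cleavage-site variation (optionally coupled to editing
status), genomic SNP confounders, and age- or condition-dependent editing
and expression trends.  Every read carries a provenance id and a truth-table
row, so false positives and negatives can be accounted exactly.

Deliberate simplifications: qualities are constant per run (the pipeline's
filters are threshold- not shape-based), errors are substitutions only (the
mapping contract allows no gaps), and hairpin thermodynamics are not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import (
    MiRNARecord,
    SmallRead,
    read_annotations,
    read_fasta,
    revcomp,
    write_annotations,
    write_families,
    write_fasta,
    write_snp_table,
)

BASES = "ACGT"
MATURE_LEN = 22


class DesignError(ValueError):
    """An inconsistent truth specification (e.g. editing at a non-A base)."""


@dataclass(frozen=True)
class SampleMeta:
    """Labels that key every downstream statistical stage."""

    sample_id: str
    species: str
    tissue: str = "brain"
    age: float | None = None
    age_unit: str = "years"
    condition: str | None = None  # "normal" | "tumor"
    patient_id: str | None = None
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in (None, "normal", "tumor"):
            raise ValueError(f"condition must be normal/tumor, got {self.condition!r}")


def validate_matched_pairs(samples: Iterable[SampleMeta]) -> dict[str, tuple[SampleMeta, SampleMeta]]:
    """Group samples by patient and check each pair is normal+tumor."""
    by_patient: dict[str, list[SampleMeta]] = {}
    for s in samples:
        if s.patient_id is not None:
            by_patient.setdefault(s.patient_id, []).append(s)
    pairs = {}
    for pid, group in by_patient.items():
        conditions = sorted(s.condition or "" for s in group)
        if len(group) != 2 or conditions != ["normal", "tumor"]:
            raise ValueError(f"patient {pid}: expected one normal and one tumor sample")
        normal = next(s for s in group if s.condition == "normal")
        tumor = next(s for s in group if s.condition == "tumor")
        pairs[pid] = (normal, tumor)
    return pairs


@dataclass
class ReferenceBundle:
    """Genome contigs + miRNA annotations + families + SNPs for >=1 species.

    ``family_edit_sites`` records, per mature family, one adenosine position
    (1-based within the mature sequence) that is guaranteed identical across
    orthologs — the canonical place for tests to plant conserved edits.
    """

    contigs: dict[str, str]
    annotations: list[MiRNARecord]
    families: dict[str, list[tuple[str, str]]]
    snps: list[tuple[str, str, int, str, str, float]]
    family_edit_sites: dict[str, int] = field(default_factory=dict)

    def validate(self, max_ortholog_subs: int = 3) -> None:
        by_id = {}
        for rec in self.annotations:
            rec.validate_against(self.contigs)
            by_id[(rec.species, rec.mirna_id)] = rec
        for fam, members in self.families.items():
            seqs = [by_id[m].sequence for m in members if m in by_id]
            for s in seqs[1:]:
                if len(s) == len(seqs[0]):
                    diff = sum(a != b for a, b in zip(seqs[0], s))
                    if diff > max_ortholog_subs:
                        raise ValueError(
                            f"family {fam}: orthologs differ at {diff} > "
                            f"{max_ortholog_subs} positions"
                        )
        for sp, contig, pos, ref, alt, _ in self.snps:
            if self.contigs[contig][pos] != ref:
                raise ValueError(f"SNP ref mismatch at {contig}:{pos}")

    def record(self, species: str, mirna_id: str) -> MiRNARecord:
        for rec in self.annotations:
            if rec.species == species and rec.mirna_id == mirna_id:
                return rec
        raise KeyError((species, mirna_id))

    def species_contigs(self, species: str) -> dict[str, str]:
        prefix = f"{species}:"
        return {n: s for n, s in self.contigs.items() if n.startswith(prefix)}

    @property
    def species(self) -> list[str]:
        return sorted({rec.species for rec in self.annotations})

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "genome.fa")
        write_annotations(self.annotations, outdir / "annotations.tsv")
        write_families(self.families, outdir / "families.tsv")
        write_snp_table(self.snps, outdir / "snps.tsv")
        pd.DataFrame(
            sorted(self.family_edit_sites.items()), columns=["family_id", "position"]
        ).to_csv(outdir / "edit_sites.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "ReferenceBundle":
        indir = Path(indir)
        contigs = read_fasta(indir / "genome.fa")
        annotations = read_annotations(indir / "annotations.tsv", contigs)
        fam_df = pd.read_csv(indir / "families.tsv", sep="\t")
        families: dict[str, list[tuple[str, str]]] = {}
        for row in fam_df.itertuples(index=False):
            families.setdefault(row.family_id, []).append((row.species, row.mirna_id))
        snp_df = pd.read_csv(indir / "snps.tsv", sep="\t")
        snps = [
            (r.species, r.contig, int(r.position), r.ref, r.alt,
             float(r.allele_freq) if r.allele_freq == r.allele_freq else 0.0)
            for r in snp_df.itertuples(index=False)
        ]
        edit_sites: dict[str, int] = {}
        sites_path = indir / "edit_sites.tsv"
        if sites_path.exists():
            sites_df = pd.read_csv(sites_path, sep="\t")
            edit_sites = dict(zip(sites_df.family_id, sites_df.position.astype(int)))
        return cls(contigs, annotations, families, snps, edit_sites)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def _variable_positions(
    rng: np.random.Generator, length: int, n: int, protected: set[int]
) -> list[int]:
    """Pick up to n positions at which orthologs may differ."""
    candidates = [i for i in range(length) if i not in protected]
    if not candidates or n == 0:
        return []
    picked = rng.choice(len(candidates), size=min(n, len(candidates)), replace=False)
    return sorted(candidates[int(i)] for i in picked)


def _derive_ortholog(
    rng: np.random.Generator, ancestral: str, variable: list[int]
) -> str:
    """Substitute at a subset of the family's variable positions only.

    Confining substitutions to a fixed per-family position set bounds the
    pairwise divergence between any two orthologs by len(variable).
    """
    chars = list(ancestral)
    for pos in variable:
        if rng.random() < 0.5:
            alternatives = [b for b in BASES if b != ancestral[pos]]
            chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def generate_reference(
    n_species: int,
    mirnas_per_species: int,
    seed: int,
    max_ortholog_subs: int = 3,
    restricted_fraction: float = 0.2,
    snps_per_species: int = 2,
    minus_strand_fraction: float = 0.3,
) -> ReferenceBundle:
    """Build a deterministic multi-species reference bundle.

    Each miRNA family has an ancestral 22-nt mature sequence; per-species
    orthologs carry at most ``max_ortholog_subs`` substitutions, never at the
    family's designated editable adenosine.  A ``restricted_fraction`` of
    families is annotated only in a subset of species, to exercise the
    missing-ortholog path.  Precursors are mature + loop + near-reverse-
    complement star arms, embedded in per-species contigs with random
    spacers; a subset lands on the minus strand.
    """
    if n_species < 1 or mirnas_per_species < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1:02d}" for i in range(n_species)]

    families: dict[str, list[tuple[str, str]]] = {}
    family_edit_sites: dict[str, int] = {}
    annotations: list[MiRNARecord] = []
    # per-species growing contig sequence
    parts: dict[str, list[str]] = {sp: [_random_seq(rng, 50)] for sp in species}
    lengths: dict[str, int] = {sp: 50 for sp in species}

    for j in range(mirnas_per_species):
        fam = f"fam{j + 1:03d}"
        # ancestral mature with a protected adenosine away from both edges
        while True:
            ancestral = _random_seq(rng, MATURE_LEN)
            a_positions = [i for i in range(3, MATURE_LEN - 3) if ancestral[i] == "A"]
            if a_positions:
                break
        edit_idx = int(rng.choice(a_positions))
        family_edit_sites[fam] = edit_idx + 1  # 1-based

        restricted = rng.random() < restricted_fraction and n_species > 1
        if restricted:
            n_keep = int(rng.integers(1, n_species))
            members = sorted(rng.choice(n_species, size=n_keep, replace=False))
            fam_species = [species[int(i)] for i in members]
        else:
            fam_species = species

        mature_variable = _variable_positions(
            rng, MATURE_LEN, max_ortholog_subs, protected={edit_idx}
        )
        # real miRNA duplexes are imperfect: give the ancestral star arm two
        # substitutions relative to the mature's exact reverse complement, at
        # positions shielded from species-level variation, so arm-specific
        # reads always map uniquely
        mirrored = {MATURE_LEN - 1 - j for j in mature_variable}
        duplex_break = _variable_positions(rng, MATURE_LEN, 2, protected=mirrored)
        star_chars = list(revcomp(ancestral))
        for i in duplex_break:
            alternatives = [b for b in BASES if b != star_chars[i]]
            star_chars[i] = alternatives[int(rng.integers(0, 3))]
        star_ancestral = "".join(star_chars)
        star_variable = _variable_positions(
            rng, MATURE_LEN, max_ortholog_subs, protected=set(duplex_break)
        )

        families[fam] = []
        families[fam + "*"] = []
        for sp in fam_species:
            mature = _derive_ortholog(rng, ancestral, mature_variable)
            star = _derive_ortholog(rng, star_ancestral, star_variable)
            loop = _random_seq(rng, int(rng.integers(8, 13)))
            precursor = mature + loop + star
            strand = "-" if rng.random() < minus_strand_fraction else "+"
            contig = f"{sp}:chr1"
            inserted = revcomp(precursor) if strand == "-" else precursor
            start = lengths[sp]
            parts[sp].append(inserted)
            parts[sp].append(_random_seq(rng, int(rng.integers(30, 61))))
            lengths[sp] += len(inserted) + len(parts[sp][-1])

            mid = f"{sp}-mir-{j + 1}"
            if strand == "+":
                m_start, m_end = start, start + len(mature)
                s_start = start + len(mature) + len(loop)
                s_end = s_start + len(star)
            else:
                # inserted is revcomp(precursor): star arm comes first on the genome
                m_end = start + len(inserted)
                m_start = m_end - len(mature)
                s_start, s_end = start, start + len(star)
            annotations.append(MiRNARecord(sp, mid, "mature", fam, contig,
                                           m_start, m_end, strand, mature))
            annotations.append(MiRNARecord(sp, mid + "*", "star", fam + "*", contig,
                                           s_start, s_end, strand, star))
            families[fam].append((sp, mid))
            families[fam + "*"].append((sp, mid + "*"))

    contigs = {f"{sp}:chr1": "".join(parts[sp]) for sp in species}

    snps: list[tuple[str, str, int, str, str, float]] = []
    for sp in species:
        contig = f"{sp}:chr1"
        seq = contigs[contig]
        for pos in rng.integers(0, len(seq), snps_per_species):
            ref = seq[int(pos)]
            alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
            snps.append((sp, contig, int(pos), ref, alt, float(rng.uniform(0.01, 0.5))))

    bundle = ReferenceBundle(contigs, annotations, families, snps, family_edit_sites)
    bundle.validate(max_ortholog_subs=max_ortholog_subs)
    return bundle


# ---------------------------------------------------------------------------
# Read simulation

# 5' cleavage-offset distributions; the defaults mirror the observed
# proportions for an edited/unedited miRNA pair with coupled processing
# (54/45 vs 32/68 at offsets 0/-1).
DEFAULT_OFFSETS: dict[int, float] = {0: 0.54, -1: 0.45, 1: 0.01}
COUPLED_OFFSETS: dict[int, float] = {0: 0.32, -1: 0.68, 1: 0.0}


@dataclass
class SimDesign:
    """Truth specification for one simulated sequencing run.

    ``edit_truth`` maps (species, mirna_id, 1-based position in the annotated
    sequence) to an editing frequency — a scalar applied to all samples, or a
    per-sample-id mapping.  ``expression`` maps (species, mirna_id) to the
    expected read count per sample (Poisson mean), scalar or per-sample.
    """

    samples: list[SampleMeta]
    edit_truth: dict[tuple[str, str, int], float | Mapping[str, float]] = field(default_factory=dict)
    expression: dict[tuple[str, str], float | Mapping[str, float]] = field(default_factory=dict)
    error_rate: float = 0.001
    tail_add_prob: float = 0.1
    five_prime_offsets: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    edit_cleavage_coupling: Mapping[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.five_prime_offsets.values()), 1.0, abs_tol=1e-9):
            raise DesignError("five_prime_offsets must sum to 1")
        if self.edit_cleavage_coupling is not None and not math.isclose(
            sum(self.edit_cleavage_coupling.values()), 1.0, abs_tol=1e-9
        ):
            raise DesignError("edit_cleavage_coupling must sum to 1")
        for key, f in self.edit_truth.items():
            values = f.values() if isinstance(f, Mapping) else [f]
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise DesignError(f"editing frequency outside [0,1] for {key}")
        for key, e in self.expression.items():
            values = e.values() if isinstance(e, Mapping) else [e]
            if any(v < 0 for v in values):
                raise DesignError(f"negative expected count for {key}")

    def frequency(self, key: tuple[str, str, int], sample_id: str) -> float:
        f = self.edit_truth[key]
        return float(f[sample_id]) if isinstance(f, Mapping) else float(f)

    def expected_count(self, key: tuple[str, str], sample_id: str) -> float:
        e = self.expression[key]
        return float(e[sample_id]) if isinstance(e, Mapping) else float(e)


def quality_for_error_rate(error_rate: float) -> int:
    """Constant Phred score consistent with the per-base error rate."""
    if error_rate <= 0:
        return 40
    return min(60, round(-10 * math.log10(error_rate)))


def extended_sequence(rec: MiRNARecord, contigs: dict[str, str], up: int, down: int) -> str:
    """Annotated sequence with genomic flanks, in miRNA sense."""
    seq = contigs[rec.contig]
    if rec.strand == "+":
        lo, hi = rec.start - up, rec.end + down
        if lo < 0 or hi > len(seq):
            raise ValueError(f"{rec.mirna_id}: flank outside contig")
        return seq[lo:hi]
    lo, hi = rec.start - down, rec.end + up
    if lo < 0 or hi > len(seq):
        raise ValueError(f"{rec.mirna_id}: flank outside contig")
    return revcomp(seq[lo:hi])


TRUTH_COLUMNS = ["read_id", "sample_id", "species", "mirna_id",
                 "edited", "offset", "n_tail", "n_errors"]


def simulate_reads(
    bundle: ReferenceBundle, design: SimDesign
) -> tuple[list[SmallRead], pd.DataFrame]:
    """Draw reads per the design; returns (reads, per-read truth table).

    Read counts per (sample, miRNA) are Poisson around the design
    expectation.  Each read starts at the annotated 5' end shifted by a
    cleavage offset drawn from the (possibly editing-coupled) distribution,
    carries programmed A->G edits, optional 1-2 nt random 3' additions, and
    uniform per-base substitution errors at ``error_rate``.
    """
    rng = np.random.default_rng(design.seed)
    qual = quality_for_error_rate(design.error_rate)

    # validate edit sites against annotation sequences up front
    sites_by_mirna: dict[tuple[str, str], list[int]] = {}
    for (sp, mid, pos) in design.edit_truth:
        rec = bundle.record(sp, mid)
        if not 1 <= pos <= len(rec.sequence):
            raise DesignError(f"site {pos} outside {mid} (length {len(rec.sequence)})")
        if rec.sequence[pos - 1] != "A":
            raise DesignError(
                f"editing frequency specified at non-A position {pos} of {mid} "
                f"(ref {rec.sequence[pos - 1]})"
            )
        sites_by_mirna.setdefault((sp, mid), []).append(pos)

    offset_vals = np.array(sorted(design.five_prime_offsets), dtype=int)
    offset_p = np.array([design.five_prime_offsets[o] for o in offset_vals])
    if design.edit_cleavage_coupling is not None:
        coup_vals = np.array(sorted(design.edit_cleavage_coupling), dtype=int)
        coup_p = np.array([design.edit_cleavage_coupling[o] for o in coup_vals])

    reads: list[SmallRead] = []
    truth_rows: list[tuple] = []
    serial = 0
    for sample in design.samples:
        for (sp, mid), _expr in sorted(design.expression.items()):
            if sp != sample.species:
                continue
            rec = bundle.record(sp, mid)
            mean = design.expected_count((sp, mid), sample.sample_id)
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            ext = extended_sequence(rec, bundle.contigs, up=2, down=0)
            sites = sites_by_mirna.get((sp, mid), [])
            freqs = [design.frequency((sp, mid, p), sample.sample_id) for p in sites]

            edited_mat = (
                rng.random((n, len(sites))) < np.asarray(freqs)
                if sites else np.zeros((n, 0), dtype=bool)
            )
            any_edit = edited_mat.any(axis=1)
            offsets = offset_vals[rng.choice(len(offset_vals), size=n, p=offset_p)]
            if design.edit_cleavage_coupling is not None and any_edit.any():
                coupled = coup_vals[rng.choice(len(coup_vals), size=n, p=coup_p)]
                offsets = np.where(any_edit, coupled, offsets)
            tails = np.where(
                rng.random(n) < design.tail_add_prob, rng.integers(1, 3, n), 0
            )
            tail_bases = rng.integers(0, 4, (n, 2))
            max_len = len(ext) + 2
            err_mask = rng.random((n, max_len)) < design.error_rate
            err_shift = rng.integers(1, 4, (n, max_len))

            for i in range(n):
                o = int(offsets[i])
                chars = list(ext[2 + o :])
                for s_idx, pos in enumerate(sites):
                    if edited_mat[i, s_idx]:
                        chars[(pos - 1) - o] = "G"
                for t in range(int(tails[i])):
                    chars.append(BASES[int(tail_bases[i, t])])
                n_err = 0
                for b in range(len(chars)):
                    if err_mask[i, b]:
                        chars[b] = BASES[(BASES.index(chars[b]) + int(err_shift[i, b])) % 4]
                        n_err += 1
                seq = "".join(chars)
                rid = f"{sample.sample_id}|{sp}|{mid}|{serial}"
                serial += 1
                reads.append(SmallRead(rid, seq, (qual,) * len(seq)))
                truth_rows.append(
                    (rid, sample.sample_id, sp, mid,
                     bool(any_edit[i]), o, int(tails[i]), n_err)
                )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


# ---------------------------------------------------------------------------
# Developmental time course

DEFAULT_AGES = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 25.0, 35.0, 47.0, 60.0]


@dataclass
class TimecourseTruth:
    """Truth tables for one simulated postnatal time course."""

    samples: list[SampleMeta]
    ages: list[float]
    frequencies: pd.DataFrame       # miRNA x sample expected editing frequency
    expression: pd.DataFrame        # gene x sample normalized expression
    edited_targets: dict[str, list[str]]
    unedited_targets: dict[str, list[str]]
    design: SimDesign

    def sample_edit_counts(
        self, coverage: int, rng: np.random.Generator
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Binomial (edited, unedited) read counts at the given coverage."""
        f = self.frequencies.to_numpy()
        edited = rng.binomial(coverage, f)
        ed = pd.DataFrame(edited, index=self.frequencies.index,
                          columns=self.frequencies.columns)
        un = coverage - ed
        return ed, un


def simulate_timecourse(
    bundle: ReferenceBundle,
    ages: list[float] | None = None,
    edit_slope: Mapping[str, float] | float = 0.35,
    target_coupling: float = 1.0,
    seed: int = 0,
    species: str | None = None,
    base_frequency: float = 0.15,
    expression_noise: float = 0.3,
    targets_per_mirna: int = 30,
    coverage: float = 300.0,
) -> TimecourseTruth:
    """Simulate brain samples across postnatal ages for one species.

    Expected editing frequency for miRNA m at normalized age tau is
    clip(base + slope_m * tau, 0, 1); reads sampled around that expectation
    are binomial, so realized frequencies are noisy.  Each miRNA gets
    disjoint edited-form and unedited-form target gene sets; edited-form
    targets decline in expression by ``target_coupling`` units over the full
    age range (plus Gaussian noise), unedited-form targets stay flat.
    """
    if ages is None:
        ages = list(DEFAULT_AGES)
    if len(ages) < 3:
        raise ValueError("need at least 3 ages")
    rng = np.random.default_rng(seed)
    species = species or bundle.species[0]
    mature = sorted(
        {m for fam, members in bundle.families.items() if not fam.endswith("*")
         for s, m in members if s == species}
    )
    slopes = (
        {m: float(edit_slope) for m in mature}
        if not isinstance(edit_slope, Mapping) else dict(edit_slope)
    )

    samples = [
        SampleMeta(f"{species}-age{i:02d}", species, tissue="brain", age=a)
        for i, a in enumerate(ages)
    ]
    taus = np.array(ages, dtype=float)
    taus = (taus - taus.min()) / (taus.max() - taus.min())

    edit_truth: dict[tuple[str, str, int], dict[str, float]] = {}
    freq_rows = {}
    expression_spec: dict[tuple[str, str], float] = {}
    for m in mature:
        rec = bundle.record(species, m)
        pos = bundle.family_edit_sites.get(rec.family_id)
        if pos is None or rec.sequence[pos - 1] != "A":
            continue
        f = np.clip(base_frequency + slopes.get(m, 0.0) * taus, 0.0, 1.0)
        edit_truth[(species, m, pos)] = {
            s.sample_id: float(f[i]) for i, s in enumerate(samples)
        }
        freq_rows[m] = f
        expression_spec[(species, m)] = coverage
    frequencies = pd.DataFrame(
        freq_rows, index=[s.sample_id for s in samples]
    ).T

    # target gene expression: edited-form targets decline with age
    genes, expr_rows, edited_targets, unedited_targets = [], [], {}, {}
    for m in freq_rows:
        ed = [f"{m}:edT{g:02d}" for g in range(targets_per_mirna)]
        un = [f"{m}:unT{g:02d}" for g in range(targets_per_mirna)]
        edited_targets[m], unedited_targets[m] = ed, un
        for g in ed:
            genes.append(g)
            expr_rows.append(8.0 - target_coupling * taus
                             + rng.normal(0, expression_noise, len(taus)))
        for g in un:
            genes.append(g)
            expr_rows.append(8.0 + rng.normal(0, expression_noise, len(taus)))
    expression = pd.DataFrame(
        expr_rows, index=genes, columns=[s.sample_id for s in samples]
    )

    design = SimDesign(
        samples=samples,
        edit_truth=edit_truth,
        expression=expression_spec,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return TimecourseTruth(samples, list(ages), frequencies, expression,
                           edited_targets, unedited_targets, design)


# ---------------------------------------------------------------------------
# Matched tumor/normal pairs


@dataclass
class MatchedPairTruth:
    samples: list[SampleMeta]
    frequencies: pd.DataFrame  # miRNA x sample expected editing frequency
    design: SimDesign

    def sample_edit_counts(
        self, coverage: int, rng: np.random.Generator
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        f = self.frequencies.to_numpy()
        edited = rng.binomial(coverage, f)
        ed = pd.DataFrame(edited, index=self.frequencies.index,
                          columns=self.frequencies.columns)
        return ed, coverage - ed


def simulate_matched_pairs(
    bundle: ReferenceBundle,
    n_patients: int,
    down_effect: float,
    seed: int = 0,
    species: str | None = None,
    coverage: float = 1000.0,
    n_mirnas: int | None = None,
) -> MatchedPairTruth:
    """Tumor/control pairs where tumor editing is shifted by ``down_effect``.

    The tumor frequency is the patient's control frequency plus the effect,
    clamped to [0, 1]; control frequencies vary across patients around each
    miRNA's baseline.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not -1.0 <= down_effect <= 1.0:
        raise ValueError("down_effect must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    species = species or bundle.species[0]
    mature = sorted(
        {m for fam, members in bundle.families.items() if not fam.endswith("*")
         for s, m in members if s == species}
    )
    usable = [
        m for m in mature
        if bundle.family_edit_sites.get(bundle.record(species, m).family_id)
    ]
    if n_mirnas is not None:
        usable = usable[:n_mirnas]

    samples: list[SampleMeta] = []
    edit_truth: dict[tuple[str, str, int], dict[str, float]] = {}
    expression_spec: dict[tuple[str, str], float] = {}
    freq = {}
    baselines = {m: float(rng.uniform(0.2, 0.7)) for m in usable}
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        normal = SampleMeta(f"{pid}-N", species, tissue="tissue", condition="normal", patient_id=pid)
        tumor = SampleMeta(f"{pid}-T", species, tissue="tissue", condition="tumor", patient_id=pid)
        samples += [normal, tumor]
        for m in usable:
            rec = bundle.record(species, m)
            pos = bundle.family_edit_sites[rec.family_id]
            ctrl = float(np.clip(baselines[m] + rng.normal(0, 0.05), 0.0, 1.0))
            tum = float(np.clip(ctrl + down_effect, 0.0, 1.0))
            edit_truth.setdefault((species, m, pos), {})[normal.sample_id] = ctrl
            edit_truth[(species, m, pos)][tumor.sample_id] = tum
            freq.setdefault(m, {})[normal.sample_id] = ctrl
            freq[m][tumor.sample_id] = tum
            expression_spec[(species, m)] = coverage
    validate_matched_pairs(samples)
    frequencies = pd.DataFrame(freq).T[[s.sample_id for s in samples]]
    design = SimDesign(
        samples=samples,
        edit_truth=edit_truth,
        expression=expression_spec,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return MatchedPairTruth(samples, frequencies, design)
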