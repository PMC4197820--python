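"""Manifest-driven orchestration of the analysis stages.

Each stage is a pure function of (manifest, seed): it reads the upstream
artifacts from the run directory, writes its result TSVs plus a JSON run
report with per-filter attrition counts, and re-running it reproduces the
outputs byte-identically.  The filters are the science here, so every stage
accounts for its reads: input = kept + each rejection class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, caller, conservation, quantify, stats, synthetic
from .align import AlignPolicy, CachedAligner, GenomeIndex
from .caller import CallerConfig
from .io import read_fastq, write_fastq, write_results
from .preprocess import FilterConfig, preprocess_reads
from .synthetic import ReferenceBundle, SampleMeta, SimDesign

TISSUES = ("brain", "cerebellum", "heart", "kidney", "testis")
# default per-tissue editing frequencies for conserved sites: neural-enriched
TISSUE_FREQS = {"brain": 0.40, "cerebellum": 0.35, "heart": 0.10,
                "kidney": 0.15, "testis": 0.05}


class StageError(RuntimeError):
    """A missing upstream artifact; the message names the stage to run."""


@dataclass
class RunManifest:
    """All paths, thresholds and the seed for one pipeline run."""

    output_dir: str
    seed: int = 0
    dataset: str = "tissues"  # "tissues" | "cancer"
    # simulation scale
    n_species: int = 3
    mirnas_per_species: int = 8
    coverage: float = 300.0
    edited_family_fraction: float = 0.5
    n_patients: int = 10
    down_effect: float = -0.15
    # thresholds (defaults are the pipeline's standard operating values)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    align_policy: AlignPolicy = field(default_factory=AlignPolicy)
    caller_config: CallerConfig = field(default_factory=CallerConfig)
    conservation_mode: str = "high"
    min_species: int = 2
    flank: int = 10

    @property
    def outdir(self) -> Path:
        return Path(self.output_dir)

    def require(self, name: str, stage: str) -> Path:
        path = self.outdir / name
        if not path.exists():
            raise StageError(f"missing {name}; run the `{stage}` stage first")
        return path


def _write_report(manifest: RunManifest, stage: str, payload: dict) -> None:
    report = {
        "stage": stage,
        "seed": manifest.seed,
        "version": __version__,
        **payload,
    }
    path = manifest.outdir / f"report_{stage}.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def _samples_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id, "species": s.species, "tissue": s.tissue,
                "age": s.age if s.age is not None else "",
                "condition": s.condition or "", "patient_id": s.patient_id or "",
            }
            for s in samples
        ]
    )


def run_simulate(manifest: RunManifest) -> ReferenceBundle:
    """Generate the reference bundle, samples, FASTQ reads and truth tables."""
    out = manifest.outdir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(manifest.seed)
    bundle = synthetic.generate_reference(
        manifest.n_species, manifest.mirnas_per_species, seed=manifest.seed
    )
    bundle.write(out / "bundle")

    mature_fams = sorted(f for f in bundle.families if not f.endswith("*"))
    n_edited = max(1, round(manifest.edited_family_fraction * len(mature_fams)))
    edited_fams = mature_fams[:n_edited]

    if manifest.dataset == "cancer":
        truth = synthetic.simulate_matched_pairs(
            bundle, manifest.n_patients, manifest.down_effect,
            seed=manifest.seed, coverage=manifest.coverage,
        )
        design, samples = truth.design, truth.samples
        truth.frequencies.to_csv(out / "truth_frequencies.tsv", sep="\t")
    else:
        samples = []
        edit_truth: dict[tuple[str, str, int], dict[str, float]] = {}
        expression: dict[tuple[str, str], float] = {}
        for sp in bundle.species:
            for tissue in TISSUES:
                samples.append(SampleMeta(f"{sp}-{tissue}", sp, tissue=tissue))
        for fam in edited_fams:
            pos = bundle.family_edit_sites[fam]
            for sp, mid in bundle.families[fam]:
                for s in samples:
                    if s.species != sp:
                        continue
                    edit_truth.setdefault((sp, mid, pos), {})[s.sample_id] = (
                        TISSUE_FREQS[s.tissue]
                    )
        for sp in bundle.species:
            for fam in mature_fams:
                for sp2, mid in bundle.families[fam]:
                    if sp2 == sp:
                        expression[(sp, mid)] = manifest.coverage
        design = SimDesign(
            samples=samples, edit_truth=edit_truth, expression=expression,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pd.DataFrame(
            [
                {"species": sp, "mirna_id": mid, "position": pos,
                 "sample_id": sid, "frequency": f}
                for (sp, mid, pos), per in edit_truth.items()
                for sid, f in per.items()
            ]
        ).to_csv(out / "truth_frequencies.tsv", sep="\t", index=False)

    reads, truth_table = synthetic.simulate_reads(bundle, design)
    (out / "fastq").mkdir(exist_ok=True)
    by_sample: dict[str, list] = {s.sample_id: [] for s in samples}
    for read in reads:
        by_sample[read.read_id.split("|", 1)[0]].append(read)
    for sid, sample_reads in by_sample.items():
        write_fastq(sample_reads, out / "fastq" / f"{sid}.fastq")
    truth_table.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    _samples_frame(samples).to_csv(out / "samples.tsv", sep="\t", index=False)
    with open(out / "design.json", "w") as fh:
        json.dump({"edited_families": edited_fams, "dataset": manifest.dataset},
                  fh, indent=2, sort_keys=True)
    _write_report(manifest, "simulate", {
        "n_reads": len(reads), "n_samples": len(samples),
        "n_species": manifest.n_species,
    })
    return bundle


def _load_sample_reads(manifest: RunManifest) -> tuple[pd.DataFrame, dict[str, list]]:
    samples = pd.read_csv(manifest.require("samples.tsv", "simulate"), sep="\t",
                          keep_default_na=False)
    reads = {
        row.sample_id: list(read_fastq(manifest.outdir / "fastq" / f"{row.sample_id}.fastq"))
        for row in samples.itertuples(index=False)
    }
    return samples, reads


def run_detect(manifest: RunManifest) -> pd.DataFrame:
    """Preprocess, align, tally, filter and call conserved events."""
    bundle = ReferenceBundle.load(manifest.require("bundle", "simulate"))
    samples, reads_by_sample = _load_sample_reads(manifest)

    attrition: dict[str, dict] = {}
    calls_by_species: dict[str, list] = {}
    for sp in bundle.species:
        index = GenomeIndex(bundle.species_contigs(sp))
        aligner = CachedAligner(index, manifest.align_policy)
        results_by_tissue: dict[str, list] = {}
        for row in samples[samples.species == sp].itertuples(index=False):
            kept, tally = preprocess_reads(
                reads_by_sample[row.sample_id], manifest.filter_config
            )
            results = aligner.align_all(kept)
            results_by_tissue.setdefault(row.tissue, []).extend(results)
            attrition[row.sample_id] = {
                **tally.as_dict(),
                "mapped": sum(r.status == "mapped" for r in results),
                "unmapped": sum(r.status == "unmapped" for r in results),
                "suppressed": sum(r.status == "suppressed" for r in results),
            }
        annotations = [a for a in bundle.annotations if a.species == sp]
        tallies = caller.collect_site_tallies(
            results_by_tissue, annotations, config=manifest.caller_config
        )
        snps = [
            s for s in _bundle_snps(bundle) if s.species == sp
        ]
        calls_by_species[sp] = caller.apply_site_filters(
            tallies, snps, manifest.caller_config
        )

    fam_alignments = {}
    seq_of = {(a.species, a.mirna_id): a.sequence for a in bundle.annotations}
    for fam, members in bundle.families.items():
        present = [(m, seq_of[m]) for m in members if m in seq_of]
        if len(present) >= 2:
            fam_alignments[fam] = conservation.align_family(dict(present), fam)
    events, orphans = conservation.call_conserved_events(
        calls_by_species, fam_alignments,
        min_species=manifest.min_species, mode=manifest.conservation_mode,
    )

    rows = []
    for ev in events:
        rows.append({
            "family_id": ev.family_id,
            "column": ev.column,
            "n_species": ev.n_species,
            "positions": ";".join(f"{sp}:{p}" for sp, p in sorted(ev.positions.items())),
            "species_tiers": ";".join(
                f"{sp}:{t}" for sp, t in sorted(ev.species_tiers.items())
            ),
        })
    events_df = pd.DataFrame(
        rows, columns=["family_id", "column", "n_species", "positions", "species_tiers"]
    )
    write_results(events_df, manifest.outdir / "events.tsv",
                  header_note=f"conserved editing events; mode={manifest.conservation_mode}")
    all_calls = [c for calls in calls_by_species.values() for c in calls]
    write_results(caller.calls_to_frame(all_calls), manifest.outdir / "site_calls.tsv")
    _write_report(manifest, "detect", {
        "attrition": attrition,
        "n_site_calls": len(all_calls),
        "n_events": len(events),
        "n_orphans": len(orphans),
    })
    return events_df


def _bundle_snps(bundle: ReferenceBundle):
    from .io import SnpRecord

    return [SnpRecord(sp, contig, pos, ref, alt)
            for sp, contig, pos, ref, alt, _freq in bundle.snps]


def run_quantify(manifest: RunManifest) -> pd.DataFrame:
    """Remap reads per sample against variant references of the truth sites."""
    bundle = ReferenceBundle.load(manifest.require("bundle", "simulate"))
    samples, reads_by_sample = _load_sample_reads(manifest)
    design = json.loads((manifest.require("design.json", "simulate")).read_text())

    quants = []
    for row in samples.itertuples(index=False):
        sp = row.species
        for fam in design["edited_families"]:
            members = [
                (s, mid) for s, mid in bundle.families.get(fam, []) if s == sp
            ]
            if not members:
                continue
            _, mid = members[0]
            rec = bundle.record(sp, mid)
            pos = bundle.family_edit_sites.get(fam)
            if pos is None or rec.sequence[pos - 1] != "A":
                continue
            refs = quantify.build_variant_refs(rec, pos, bundle.contigs,
                                               flank=manifest.flank)
            kept, _ = preprocess_reads(reads_by_sample[row.sample_id],
                                       manifest.filter_config)
            result = quantify.remap_and_count(kept, refs, sample_id=row.sample_id)
            quants.append(result.quant)
    df = quantify.quants_to_frame(quants)
    write_results(df, manifest.outdir / "quant.tsv")
    _write_report(manifest, "quantify", {
        "n_quants": len(quants),
        "n_spanning_reads": int(df["edited"].sum() + df["unedited"].sum()) if len(df) else 0,
    })
    return df


def run_cancer(manifest: RunManifest) -> stats.CancerAnalysis:
    """Matched tumor/normal comparison from the quantification table."""
    quant_path = manifest.require("quant.tsv", "quantify")
    samples = pd.read_csv(manifest.require("samples.tsv", "simulate"), sep="\t",
                          keep_default_na=False)
    qdf = pd.read_csv(quant_path, sep="\t", comment="#")
    meta = samples.set_index("sample_id")
    pairs, pids = [], []
    for pid, group in samples[samples.patient_id != ""].groupby("patient_id"):
        normal = group[group.condition == "normal"].sample_id.iloc[0]
        tumor = group[group.condition == "tumor"].sample_id.iloc[0]
        for mirna in sorted(qdf[qdf.sample_id == normal].mirna_id.unique()):
            qn = qdf[(qdf.sample_id == normal) & (qdf.mirna_id == mirna)]
            qt = qdf[(qdf.sample_id == tumor) & (qdf.mirna_id == mirna)]
            if qn.empty or qt.empty:
                continue
            pairs.append((
                quantify.EditingQuant(normal, mirna, int(qn.edited.iloc[0]),
                                      int(qn.unedited.iloc[0]), int(qn.fake.iloc[0])),
                quantify.EditingQuant(tumor, mirna, int(qt.edited.iloc[0]),
                                      int(qt.unedited.iloc[0]), int(qt.fake.iloc[0])),
            ))
            pids.append(str(pid))
    if not pairs:
        raise StageError("no matched pairs in quant.tsv; run `simulate` with dataset=cancer")
    analysis = stats.analyze_cancer_pairs(pairs, patient_ids=pids)
    rows = pd.DataFrame(
        [
            {
                "patient_id": c.patient_id, "mirna_id": c.mirna_id,
                "control_frequency": c.control_frequency,
                "tumor_frequency": c.tumor_frequency,
                "direction": c.direction, "chi2": c.chi2,
                "p_value": c.p_value, "q_value": c.q_value,
                "significant": c.significant,
            }
            for c in analysis.comparisons
        ]
    )
    write_results(rows, manifest.outdir / "cancer_pairs.tsv")
    _write_report(manifest, "cancer", {
        "n_tested": analysis.n_tested,
        "n_down": analysis.n_down,
        "binomial_p_all": analysis.binomial_p_all,
        "n_significant_down": analysis.n_significant_down,
        "n_significant_up": analysis.n_significant_up,
        "binomial_p_significant": analysis.binomial_p_significant,
        "n_excluded_coverage": analysis.n_excluded_coverage,
    })
    return analysis


def run_timecourse(manifest: RunManifest) -> pd.DataFrame:
    """Age-correlation analysis over a simulated postnatal time course."""
    bundle = ReferenceBundle.load(manifest.require("bundle", "simulate"))
    truth = synthetic.simulate_timecourse(bundle, seed=manifest.seed)
    rng = np.random.default_rng(manifest.seed + 1)
    edited, unedited = truth.sample_edit_counts(int(manifest.coverage), rng)
    frequencies = edited / (edited + unedited)
    corr = stats.age_correlation(frequencies, truth.ages, edited_counts=edited)
    write_results(corr, manifest.outdir / "age_correlations.tsv")

    all_ed = [g for gs in truth.edited_targets.values() for g in gs]
    all_un = [g for gs in truth.unedited_targets.values() for g in gs]
    r_ed, r_un, p = stats.target_expression_comparison(
        all_ed, all_un, truth.expression, truth.ages
    )
    _write_report(manifest, "timecourse", {
        "n_mirnas": int(len(corr)),
        "n_significant_positive": int(
            ((corr.q_value < 0.05) & (corr.rho > 0)).sum()
        ),
        "target_comparison_p": p,
        "median_rho_edited_targets": float(np.median(r_ed)),
        "median_rho_unedited_targets": float(np.median(r_un)),
    })
    return corr
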