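"""Statistical procedures over editing quantifications.

Covers seed-region classification, Benjamini-Hochberg correction, the exact
two-sided binomial direction test, the matched-pair chi-square comparison,
Spearman age correlations, the edited- vs unedited-target expression
comparison, neural/non-neural and cross-species group tests, and Ward
hierarchical clustering of per-tissue editing profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

from .quantify import EditingQuant

SEED_SPAN = (2, 8)  # nucleotides 2-8 of the mature miRNA, 1-based inclusive

#: Catalog of conserved miRNA editing sites (mature/star id, 1-based edited
#: position).  These are the reference positions used for the seed-region
#: summary.
CONSERVED_SITE_CATALOG: tuple[tuple[str, int], ...] = (
    ("miR-27a", 6),
    ("miR-99b*", 2),
    ("miR-140*", 16),
    ("miR-187*", 5),
    ("miR-301a", 20),
    ("miR-376a-1", 3),
    ("miR-376b", 6),
    ("miR-376c", 6),
    ("miR-379", 5),
    ("miR-381", 4),
    ("miR-411", 5),
    ("miR-455", 17),
    ("miR-497", 2),
    ("miR-497*", 20),
    ("miR-1251", 6),
)


def seed_classify(position: int, seed_span: tuple[int, int] = SEED_SPAN) -> bool:
    """True iff a 1-based mature-miRNA position lies inside the seed region."""
    if position < 1:
        raise ValueError("positions are 1-based")
    return seed_span[0] <= position <= seed_span[1]


def seed_fraction(
    positions: Iterable[int], seed_span: tuple[int, int] = SEED_SPAN
) -> float:
    """Fraction of positions inside the seed region."""
    positions = list(positions)
    if not positions:
        raise ValueError("no positions given")
    return sum(seed_classify(p, seed_span) for p in positions) / len(positions)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_direction_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood summation).

    At p0 = 0.5 this equals twice the one-sided tail, capped at 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    return float(sps.binomtest(k, n, p0).pvalue)


@dataclass
class PairComparison:
    """Matched tumor/control comparison for one miRNA in one patient."""

    patient_id: str
    mirna_id: str
    cancer_type: str
    control_frequency: float
    tumor_frequency: float
    direction: str  # "down" | "up" | "tied"
    chi2: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    low_expectation: bool = False


def chisq_pair_test(
    control: EditingQuant, tumor: EditingQuant,
    patient_id: str = "", cancer_type: str = "",
) -> PairComparison:
    """Chi-square (1 df, no continuity correction) on the 2x2
    (edited, unedited) x (control, tumor) table."""
    table = np.array(
        [[control.edited, control.unedited], [tumor.edited, tumor.unedited]]
    )
    fc, ft = control.frequency, tumor.frequency
    direction = "tied" if fc == ft else ("down" if ft < fc else "up")
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p, low = 0.0, 1.0, True
    else:
        chi2, p, _dof, expected = sps.chi2_contingency(table, correction=False)
        low = bool((expected < 5).any())
    return PairComparison(
        patient_id=patient_id or (control.sample_id.split("-")[0] if control.sample_id else ""),
        mirna_id=control.mirna_id,
        cancer_type=cancer_type,
        control_frequency=fc,
        tumor_frequency=ft,
        direction=direction,
        chi2=float(chi2),
        p_value=float(p),
        low_expectation=low,
    )


@dataclass
class CancerAnalysis:
    comparisons: list[PairComparison]
    n_tested: int
    n_down: int
    binomial_p_all: float
    n_significant_down: int
    n_significant_up: int
    binomial_p_significant: float
    n_excluded_coverage: int


def analyze_cancer_pairs(
    pairs: Sequence[tuple[EditingQuant, EditingQuant]],
    patient_ids: Sequence[str] | None = None,
    cancer_types: Sequence[str] | None = None,
    min_reads: int = 100,
    alpha: float = 0.05,
) -> CancerAnalysis:
    """Matched tumor/normal analysis across all patient x miRNA pairs.

    Pairs failing the >= ``min_reads``-per-individual rule are excluded and
    tallied; chi-square p-values are BH-corrected across the remaining
    pairs; direction binomial tests are reported both for all tested pairs
    and for the significantly different ones.
    """
    comparisons: list[PairComparison] = []
    n_excluded = 0
    for i, (control, tumor) in enumerate(pairs):
        if not (control.passes_cancer_coverage(min_reads)
                and tumor.passes_cancer_coverage(min_reads)):
            n_excluded += 1
            continue
        comparisons.append(
            chisq_pair_test(
                control, tumor,
                patient_id=patient_ids[i] if patient_ids else "",
                cancer_type=cancer_types[i] if cancer_types else "",
            )
        )
    if comparisons:
        q = bh_adjust([c.p_value for c in comparisons])
        for c, qv in zip(comparisons, q):
            c.q_value = float(qv)
            c.significant = qv < alpha
    directed = [c for c in comparisons if c.direction != "tied"]
    n_down = sum(c.direction == "down" for c in directed)
    sig = [c for c in comparisons if c.significant and c.direction != "tied"]
    n_sig_down = sum(c.direction == "down" for c in sig)
    n_sig_up = len(sig) - n_sig_down
    return CancerAnalysis(
        comparisons=comparisons,
        n_tested=len(directed),
        n_down=n_down,
        binomial_p_all=(
            binomial_direction_test(n_down, len(directed)) if directed else float("nan")
        ),
        n_significant_down=n_sig_down,
        n_significant_up=n_sig_up,
        binomial_p_significant=(
            binomial_direction_test(n_sig_down, len(sig)) if sig else float("nan")
        ),
        n_excluded_coverage=n_excluded,
    )


def age_correlation(
    frequencies: pd.DataFrame,
    ages: Sequence[float],
    edited_counts: pd.DataFrame | None = None,
    min_edited: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of editing frequency with age, per miRNA.

    ``frequencies`` is miRNA x sample (columns ordered like ``ages``);
    replicates must already be merged.  A miRNA is only considered when it
    is detected in every sample and, if ``edited_counts`` is given, has at
    least ``min_edited`` edited reads in total.  P-values are BH-corrected
    across the retained miRNAs.  Constant series yield NaN rho and are
    flagged, not tested.
    """
    if len(ages) < 3:
        raise ValueError("need at least 3 age points")
    if len(ages) != frequencies.shape[1]:
        raise ValueError("ages must align with frequency columns")
    rows = []
    for mirna, series in frequencies.iterrows():
        values = series.to_numpy(dtype=float)
        if np.isnan(values).any():
            rows.append((mirna, float("nan"), float("nan"), "missing-sample"))
            continue
        if edited_counts is not None and edited_counts.loc[mirna].sum() < min_edited:
            rows.append((mirna, float("nan"), float("nan"), "low-coverage"))
            continue
        if np.all(values == values[0]):
            rows.append((mirna, float("nan"), float("nan"), "constant"))
            continue
        rho, p = sps.spearmanr(values, ages)
        rows.append((mirna, float(rho), float(p), ""))
    df = pd.DataFrame(rows, columns=["entity_id", "rho", "p_value", "flag"])
    tested = df["flag"] == ""
    df["q_value"] = float("nan")
    if tested.any():
        df.loc[tested, "q_value"] = bh_adjust(df.loc[tested, "p_value"].tolist())
    return df


def target_expression_comparison(
    edited_targets: Iterable[str],
    unedited_targets: Iterable[str],
    expression: pd.DataFrame,
    ages: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Compare age-trends of edited-form vs unedited-form target genes.

    Genes predicted as targets of both forms are excluded first; per-gene
    Spearman rho of expression vs age is computed, and the two rho
    distributions are compared with a two-sided Mann-Whitney test.
    Returns (edited rhos, unedited rhos, p).
    """
    edited_set, unedited_set = set(edited_targets), set(unedited_targets)
    shared = edited_set & unedited_set
    edited_only = sorted((edited_set - shared) & set(expression.index))
    unedited_only = sorted((unedited_set - shared) & set(expression.index))
    if not edited_only:
        raise ValueError("edited-target set empty after exclusion")
    if not unedited_only:
        raise ValueError("unedited-target set empty after exclusion")

    def rhos(genes: list[str]) -> np.ndarray:
        return np.array(
            [sps.spearmanr(expression.loc[g].to_numpy(), ages)[0] for g in genes]
        )

    r_ed, r_un = rhos(edited_only), rhos(unedited_only)
    method = "exact" if (len(r_ed) < 20 and len(r_un) < 20) else "auto"
    _u, p = sps.mannwhitneyu(r_ed, r_un, alternative="two-sided", method=method)
    return r_ed, r_un, float(p)


NEURAL_TISSUES = frozenset({"brain", "cerebellum"})
NON_NEURAL_TISSUES = frozenset({"heart", "kidney", "testis"})


def tissue_comparison(
    frequencies: Mapping[str, Sequence[float]] | pd.DataFrame,
    neural: frozenset[str] = NEURAL_TISSUES,
    non_neural: frozenset[str] = NON_NEURAL_TISSUES,
) -> float:
    """Two-sided Mann-Whitney p for neural vs non-neural editing frequencies.

    ``frequencies`` maps tissue -> editing frequencies (or a DataFrame with
    tissue columns); callers are expected to restrict to miRNAs with
    adequate coverage in all relevant samples.
    """
    if isinstance(frequencies, pd.DataFrame):
        frequencies = {t: frequencies[t].dropna().tolist() for t in frequencies.columns}
    a = [v for t in sorted(neural) for v in frequencies.get(t, [])]
    b = [v for t in sorted(non_neural) for v in frequencies.get(t, [])]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a + b) == 0:
        return 1.0
    _u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(p)


def species_comparison(paired_frequencies: Sequence[tuple[float, float]]) -> float:
    """Two-sided Wilcoxon signed-rank p on paired per-miRNA frequencies."""
    if len(paired_frequencies) < 2:
        raise ValueError("need at least 2 pairs")
    a = np.array([x for x, _ in paired_frequencies])
    b = np.array([y for _, y in paired_frequencies])
    if np.all(a == b):
        return 1.0
    _w, p = sps.wilcoxon(a, b, alternative="two-sided")
    return float(p)


def cluster_profiles(profiles: pd.DataFrame) -> np.ndarray:
    """Ward hierarchical clustering of per-tissue editing-frequency vectors.

    Rows are entities (one miRNA in one species), columns tissues.  Returns
    the scipy linkage matrix (Ward criterion on Euclidean distances;
    scipy's deterministic merge order breaks ties by index).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles to cluster")
    return linkage(profiles.to_numpy(dtype=float), method="ward")


def cut_clusters(link: np.ndarray, n_clusters: int) -> np.ndarray:
    from scipy.cluster.hierarchy import fcluster

    return fcluster(link, t=n_clusters, criterion="maxclust")
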