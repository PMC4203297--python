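"""Per-locus population-genetic summary statistics and diversity
comparisons: nucleotide diversity, segregating sites, haplotype counts,
fixed differences, Tajima's D, heterozygous-SNP frequencies, and Welch
t-tests of mean diversity between groups.

Gap and missing-data handling follows the complete-deletion convention:
alignment columns containing any non-ACGT character are removed before a
statistic is computed, so all sequences are compared over the same sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqsim import LocusAlignment

__all__ = [
    "LocusSummary",
    "DiversityComparison",
    "nucleotide_diversity",
    "segregating_sites",
    "count_haplotypes",
    "fixed_differences",
    "tajimas_d",
    "compare_mean_diversity",
    "het_snp_frequency",
    "locus_summary",
    "summarize_loci",
]


def _complete_deletion(matrix: np.ndarray) -> np.ndarray:
    keep = (matrix < 4).all(axis=0)
    return matrix[:, keep]


def _pairwise_diff_total(x: np.ndarray) -> float:
    """Sum over pairs of per-pair differing-site counts."""
    total = 0
    for i in range(x.shape[0] - 1):
        total += (x[i] != x[i + 1 :]).sum()
    return float(total)


def nucleotide_diversity(alignment: LocusAlignment, pairwise_deletion: bool = False) -> float:
    """Per-site nucleotide diversity pi: the average proportion of
    differing sites between two sequences of the sample (a proportion;
    multiply by 100 for the conventional percentage).

    Complete deletion of columns with gaps/missing data by default;
    ``pairwise_deletion`` compares each pair over its own valid sites.
    """
    n = alignment.n_sequences
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    if pairwise_deletion:
        from .seqsim import mean_pairwise_divergence

        return mean_pairwise_divergence(alignment)
    x = _complete_deletion(alignment.matrix)
    if x.shape[1] == 0:
        raise ValueError("no complete columns left after deletion")
    n_pairs = n * (n - 1) / 2
    return _pairwise_diff_total(x) / (n_pairs * x.shape[1])


def segregating_sites(alignment: LocusAlignment) -> int:
    """Number of columns with at least two states (complete deletion)."""
    x = _complete_deletion(alignment.matrix)
    return int(((x != x[0]).any(axis=0)).sum())


def count_haplotypes(alignment: LocusAlignment) -> int:
    """Distinct sequences; rows differing only at deleted (gap/missing)
    columns count as identical."""
    x = _complete_deletion(alignment.matrix)
    return len({row.tobytes() for row in x})


def fixed_differences(group1: LocusAlignment, group2: LocusAlignment) -> int:
    """Columns where each group is monomorphic for a different state."""
    if group1.length != group2.length:
        raise ValueError("alignments differ in length")
    both = np.vstack([group1.matrix, group2.matrix])
    keep = (both < 4).all(axis=0)
    x1 = group1.matrix[:, keep]
    x2 = group2.matrix[:, keep]
    mono1 = (x1 == x1[0]).all(axis=0)
    mono2 = (x2 == x2[0]).all(axis=0)
    return int((mono1 & mono2 & (x1[0] != x2[0])).sum())


def tajimas_d(alignment: LocusAlignment) -> float:
    """Tajima's D: standardised difference between mean pairwise
    differences and the segregating-sites estimate of theta.

    Undefined (raises ``ValueError``) for fewer than 4 sequences or no
    segregating sites -- a zero would be misleading there.
    """
    x = _complete_deletion(alignment.matrix)
    n = x.shape[0]
    if n < 4:
        raise ValueError("Tajima's D undefined for n < 4")
    s = int(((x != x[0]).any(axis=0)).sum())
    if s == 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    n_pairs = n * (n - 1) / 2
    pi_abs = _pairwise_diff_total(x) / n_pairs  # mean pairwise differences
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((pi_abs - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1)))


@dataclass
class DiversityComparison:
    values1: list[float]
    values2: list[float]
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t_statistic: float
    df: float
    p_value: float


def compare_mean_diversity(
    values1: Sequence[float], values2: Sequence[float]
) -> DiversityComparison:
    """Unpaired two-tailed Welch t-test on per-locus diversity values."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    v1 = v1[~np.isnan(v1)]
    v2 = v2[~np.isnan(v2)]
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("need at least two values per group")
    res = stats.ttest_ind(v1, v2, equal_var=False)
    s1, s2 = v1.var(ddof=1), v2.var(ddof=1)
    n1, n2 = len(v1), len(v2)
    # Welch-Satterthwaite degrees of freedom
    df = (s1 / n1 + s2 / n2) ** 2 / (
        (s1 / n1) ** 2 / (n1 - 1) + (s2 / n2) ** 2 / (n2 - 1)
    )
    return DiversityComparison(
        values1=list(v1), values2=list(v2),
        mean1=float(v1.mean()), mean2=float(v2.mean()),
        sd1=float(v1.std(ddof=1)), sd2=float(v2.std(ddof=1)),
        t_statistic=float(res.statistic), df=float(df),
        p_value=float(res.pvalue),
    )


def het_snp_frequency(count: int, bp: int, decimals: int = 2) -> float:
    """Heterozygous SNP (or indel) calls per 100 bp surveyed, as a
    percentage reported to ``decimals`` places."""
    if bp <= 0:
        raise ValueError("surveyed base-pair count must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return round(100.0 * count / bp, decimals)


@dataclass
class LocusSummary:
    """One locus worth of summary statistics for two focal groups."""

    locus: str
    length: int
    segregating: int
    pi_group1: float  # percent
    pi_group2: float  # percent
    tajimas_d_group1: Optional[float]
    tajimas_d_group2: Optional[float]
    haplotypes_group1: int
    haplotypes_group2: int
    n_group1: int
    n_group2: int
    fixed_differences: int


def locus_summary(
    alignment: LocusAlignment, group1: str, group2: str
) -> LocusSummary:
    """Compute the standard per-locus summary row from one alignment with
    a two-group population map."""
    a1 = alignment.restrict(group1)
    a2 = alignment.restrict(group2)

    def _d(a: LocusAlignment) -> Optional[float]:
        try:
            return tajimas_d(a)
        except ValueError:
            return None

    return LocusSummary(
        locus=alignment.name,
        length=alignment.length,
        segregating=segregating_sites(alignment),
        pi_group1=100.0 * nucleotide_diversity(a1),
        pi_group2=100.0 * nucleotide_diversity(a2),
        tajimas_d_group1=_d(a1),
        tajimas_d_group2=_d(a2),
        haplotypes_group1=count_haplotypes(a1),
        haplotypes_group2=count_haplotypes(a2),
        n_group1=a1.n_sequences,
        n_group2=a2.n_sequences,
        fixed_differences=fixed_differences(a1, a2),
    )


def summarize_loci(
    alignments: Sequence[LocusAlignment], group1: str, group2: str
) -> pd.DataFrame:
    """Per-locus summary table (one row per alignment) plus a mean row,
    mirroring the layout of multilocus diversity tables."""
    rows = [locus_summary(a, group1, group2) for a in alignments]
    df = pd.DataFrame([r.__dict__ for r in rows])
    mean = df.select_dtypes("number").mean(numeric_only=True)
    mean_row = {c: mean.get(c, np.nan) for c in df.columns}
    mean_row["locus"] = "Mean"
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
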