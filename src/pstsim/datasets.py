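"""Published summary tables from the fringe-toed lizard study that this
package's worked examples and default calibrations are built around.

The study sequenced 14 nuclear loci (four exons, ten anonymous loci) in
the Mojave fringe-toed lizard *Uma scoparia* and its sister lineage, the
*U. notata* species complex.  The raw sequences are not redistributed
here; what ships is the per-locus summary table (locus lengths,
segregating sites, per-group nucleotide diversity, haplotype and sample
counts, fixed differences), the heterozygous SNP/indel tallies of the
unphased data, the isolation-with-migration point estimates, and the
nested-model fit table (parameter counts and log-probabilities) -- enough
to reproduce every derived statistic and to parameterise the simulation
models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "uma_locus_table",
    "uma_snp_table",
    "uma_model_fit_table",
    "uma_mutation_rates",
    "uma_im_high_point",
    "observed_mean_diversity",
    "observed_between_divergence",
]

_LOCUS_COLUMNS = [
    "locus", "L", "S", "D_notata", "D_scoparia", "pi_total", "pi_notata",
    "pi_algodones", "pi_scoparia", "pi_colorado", "pi_mojave",
    "pi_amargosa", "k_notata", "k_scoparia", "n_notata", "n_scoparia",
    "F_NS",
]

# per-locus summaries of the phased data; diversities (pi) in percent,
# Tajima's D unitless, missing entries (insufficient sampling) as NaN
_LOCUS_ROWS = [
    ("BDNF",  628,  4, -0.098,  np.nan, 0.159, 0.173, 0.152, 0.000, 0.000, 0.000, 0.000,  4, 1, 20,  56, 0),
    ("RAG-1", 705, 10, -1.868,  1.430, 0.208, 0.057, 0.081, 0.088, 0.103, 0.072, 0.024,  4, 5, 20,  54, 2),
    ("PNN",   600, 13, -0.887, -0.804, 0.181, 0.343, 0.393, 0.121, 0.146, 0.039, 0.108,  6, 6, 12,  54, 0),
    ("R35",   577, 13,  0.873,  0.092, 0.387, 0.565, 0.504, 0.155, 0.206, 0.099, 0.000, 13, 4, 18,  60, 0),
    ("Sun07", 546, 11, -1.640, -1.452, 0.211, 0.212, 0.134, 0.013, 0.033, 0.000, 0.000,  8, 3, 20,  56, 2),
    ("Sun08", 619,  7,  np.nan, -0.532, 0.193, 0.000, 0.000, 0.069, 0.059, 0.163, 0.054,  1, 3,  2,  22, 5),
    ("Sun10", 651, 22, -0.589,  0.922, 0.455, 0.665, 0.716, 0.157, 0.127, 0.072, 0.183, 14, 6, 20,  54, 1),
    ("Sun12", 419,  9,  0.050, -0.137, 0.192, 0.564, 0.524, 0.047, 0.000, 0.056, 0.088, 12, 2, 18,  56, 0),
    ("Sun18", 379,  7,  0.022, -0.448, 0.630, 0.375, 0.352, 0.062, np.nan, 0.080, 0.000,  3, 2, 10,  16, 2),
    ("Sun28", 571, 14,  0.252, -1.356, 0.484, 0.586, 0.530, 0.154, 0.267, 0.065, 0.077, 13, 9, 20,  54, 0),
    ("Uma03", 523,  6, -0.329, -0.911, 0.131, 0.241, 0.148, 0.007, 0.016, 0.000, 0.000,  5, 2, 20, 108, 0),
    ("Uma05", 298, 11,  1.062, -1.220, 0.768, 0.774, 0.745, 0.252, 0.225, 0.302, 0.137,  9, 5, 18,  42, 0),
    ("Uma06", 146, 11,  1.739, -0.132, 1.237, 1.514, 1.428, 0.579, 0.695, 0.289, 0.756,  8, 6, 20, 142, 2),
    ("Uma08", 384, 19, -1.326, -1.789, 0.219, 0.482, 0.456, 0.065, 0.030, 0.074, 0.100, 11, 7, 28, 142, 0),
]


def uma_locus_table() -> pd.DataFrame:
    """Per-locus summary statistics of the phased 14-locus dataset."""
    return pd.DataFrame(_LOCUS_ROWS, columns=_LOCUS_COLUMNS)


def uma_snp_table() -> pd.DataFrame:
    """Heterozygous SNP and indel counts in the unphased data, with the
    total base pairs surveyed, by population."""
    rows = [
        ("U. notata complex",      200, 5,  60_836),
        ("U. scoparia",            144, 3, 212_114),
        ("U. scoparia (Colorado)",  74, 3,  81_578),
        ("U. scoparia (Mojave)",    32, 0,  73_369),
        ("U. scoparia (Amargosa)",  38, 0,  57_167),
    ]
    return pd.DataFrame(rows, columns=["population", "snps", "indels", "bp"])


def uma_model_fit_table() -> pd.DataFrame:
    """Nested isolation-with-migration models: parameter count ``k``,
    reported log-probability, degrees of freedom of the likelihood-ratio
    test against the full model, and whether the null distribution of the
    likelihood-ratio statistic is a chi-square mixture (a boundary
    parameter is involved).  ``lrt_rejected`` records the published test
    outcome (used for cross-checking, not as an input).
    """
    rows = [
        # label, k, logP, df, mixture, lrt_rejected
        ("t1 t2=tA m1=0 m2=0", 2,    4.89, 3, True,  False),
        ("t1 t2=tA m1=m2",     3,    5.47, 2, False, False),
        ("t1 t2 tA m1 m2=0",   4,    6.40, 1, True,  False),
        ("t1 t2=tA m1 m2",     4,    6.40, 1, False, False),
        ("t1 t2 tA m1=0 m2=0", 3,    4.98, 2, True,  False),
        ("t1 t2 tA m1=m2",     4,    5.52, 1, False, False),
        ("FULL",               5,    6.40, np.nan, False, False),
        ("t1 t2 tA m1=0 m2",   4,    4.98, 1, True,  False),
        ("t1=tA t2 m1 m2",     4,   -4.79, 1, False, True),
        ("t1=tA t2 m1=m2",     3,   -5.94, 2, False, True),
        ("t1=tA t2 m1=0 m2=0", 2,   -9.21, 3, True,  True),
        ("t1=t2 tA m1 m2",     4, -118.52, 1, False, True),
        ("t1=t2 tA m1=m2",     3, -121.38, 2, False, True),
        ("t1=t2=tA m1 m2",     3, -142.72, 2, False, True),
        ("t1=t2 tA m1=0 m2=0", 2, -144.20, 3, True,  True),
        ("t1=t2=tA m1=m2",     2, -148.98, 3, False, True),
        ("t1=t2=tA m1=0 m2=0", 1, -161.59, 4, True,  True),
    ]
    return pd.DataFrame(
        rows, columns=["label", "k", "logP", "df", "mixture", "lrt_rejected"]
    )


def uma_mutation_rates() -> dict[str, float]:
    """Per-locus mutation rates in substitutions/site/year: fossil-
    calibrated estimates for the four exons, a published anonymous-locus
    rate for the rest."""
    anon = 2.56e-9
    rates = {"BDNF": 2.2e-9, "RAG-1": 2.19e-9, "PNN": 2.23e-9, "R35": 4.25e-9}
    for row in _LOCUS_ROWS:
        rates.setdefault(row[0], anon)
    return rates


def uma_im_high_point() -> dict[str, float]:
    """Converted IM point estimates (treatment with all species pooled):
    effective sizes in individuals, divergence in years, founder count."""
    return {
        "N_notata": 1_090_596.0,
        "N_scoparia": 121_955.0,
        "N_ancestor": 43_764.0,
        "T_years": 990_000.0,
        "F": 241.0,
        "two_Nm_1": 0.356,
        "two_Nm_2": 0.001,
        "generation_years": 2.0,
    }


def observed_mean_diversity() -> float:
    """Mean total per-locus nucleotide diversity (proportion, ~0.0039)."""
    return float(uma_locus_table()["pi_total"].mean()) / 100.0


def observed_between_divergence() -> float:
    """Mean between-species pairwise divergence (proportion, ~0.0088).

    Not printed directly; recovered per locus from the identity

        pi_total * C(n,2) = pi_notata * C(n1,2) + pi_scoparia * C(n2,2)
                            + d_between * n1 * n2

    (total diversity decomposes into within- and between-group pair
    sums), then averaged over loci.  This is the divergence that controls
    how much sequence signal separates the two species, hence the default
    calibration target for the simulation pipeline.
    """
    t = uma_locus_table()
    n1, n2 = t["n_notata"], t["n_scoparia"]
    n = n1 + n2
    c = lambda k: k * (k - 1) / 2.0
    d = (t["pi_total"] * c(n) - t["pi_notata"] * c(n1)
         - t["pi_scoparia"] * c(n2)) / (n1 * n2)
    return float(d.mean()) / 100.0
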