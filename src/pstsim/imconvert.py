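"""Isolation-with-migration parameter conversion and nested-model ranking.

IM-style samplers report mutation-scaled parameters: population sizes
``theta = 4*N*mu`` (per locus-averaged site), a divergence time ``t``
scaled by the mutation rate, migration rates ``m``, and a splitting
parameter ``s`` (the fraction of the ancestral population founding
descendant 1).  Given a per-year mutation rate (the geometric mean across
loci) and a generation time ``G``, these convert to demographic units:

    T (years)   = t / mu
    N           = theta / (4 * G * mu)
    2Nm         = theta * m / 2
    F (founders)= (1 - s) * theta_ancestor / (4 * G * mu)

Nested demographic models are ranked with AIC computed from each model's
reported log-probability, and tested against the full model with
likelihood-ratio tests whose null distribution is chi-square -- or, when
a parameter sits on the boundary of its space (e.g. a migration rate
fixed at zero), the conventional 50:50 mixture of chi-squares with ``df``
and ``df - 1`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IMRawEstimates",
    "DemographicEstimates",
    "geometric_mean_rate",
    "convert_im",
    "invert_demographic",
    "rank_models",
]


def geometric_mean_rate(per_locus_rates: Sequence[float]) -> float:
    """Geometric mean of per-locus mutation rates (substitutions/site/yr)."""
    rates = np.asarray(list(per_locus_rates), dtype=float)
    if rates.size == 0:
        raise ValueError("no rates given")
    if (rates <= 0).any():
        raise ValueError("all mutation rates must be positive")
    return float(np.exp(np.log(rates).mean()))


@dataclass(frozen=True)
class IMRawEstimates:
    """Mutation-scaled point estimates as reported by an IM-style run."""

    theta1: float
    theta2: float
    theta_ancestor: float
    t_raw: float
    m1: float = 0.0
    m2: float = 0.0
    s_split: float = 0.5
    generation_years: float = 2.0

    def __post_init__(self) -> None:
        if min(self.theta1, self.theta2, self.theta_ancestor) < 0:
            raise ValueError("theta values must be non-negative")
        if not (0.0 < self.s_split < 1.0):
            raise ValueError("splitting parameter must lie in (0, 1)")
        if self.generation_years <= 0:
            raise ValueError("generation time must be positive")


@dataclass(frozen=True)
class DemographicEstimates:
    """Demographic quantities: sizes in individuals, time in years."""

    n1: float
    n2: float
    n_ancestor: float
    t_years: float
    founders: float
    two_nm_1: float
    two_nm_2: float


def convert_im(raw: IMRawEstimates, mu: float) -> DemographicEstimates:
    """Convert mutation-scaled IM estimates into demographic units using
    the per-year rate ``mu`` and the generation time in ``raw``."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    denom = 4.0 * raw.generation_years * mu
    return DemographicEstimates(
        n1=raw.theta1 / denom,
        n2=raw.theta2 / denom,
        n_ancestor=raw.theta_ancestor / denom,
        t_years=raw.t_raw / mu,
        founders=(1.0 - raw.s_split) * raw.theta_ancestor / denom,
        two_nm_1=raw.theta1 * raw.m1 / 2.0,
        two_nm_2=raw.theta2 * raw.m2 / 2.0,
    )


def invert_demographic(
    est: DemographicEstimates,
    mu: float,
    s_split: float,
    generation_years: float = 2.0,
) -> IMRawEstimates:
    """Algebraic inverse of :func:`convert_im` (round-trip checking)."""
    denom = 4.0 * generation_years * mu
    theta1 = est.n1 * denom
    theta2 = est.n2 * denom
    theta_a = est.n_ancestor * denom
    return IMRawEstimates(
        theta1=theta1,
        theta2=theta2,
        theta_ancestor=theta_a,
        t_raw=est.t_years * mu,
        m1=2.0 * est.two_nm_1 / theta1 if theta1 else 0.0,
        m2=2.0 * est.two_nm_2 / theta2 if theta2 else 0.0,
        s_split=s_split,
        generation_years=generation_years,
    )


def _lrt_p_value(two_llr: float, df: float, mixture: bool) -> float:
    """Upper-tail probability of the likelihood-ratio statistic.

    Boundary cases use the 50:50 mixture of chi-square(df) and
    chi-square(df-1); chi-square(0) is a point mass at zero.
    """
    if two_llr < 0:
        two_llr = 0.0  # numerical guard: nested fit cannot beat the full model
    if not mixture:
        return float(stats.chi2.sf(two_llr, df))
    upper = stats.chi2.sf(two_llr, df)
    if df - 1 <= 0:
        lower = 1.0 if two_llr == 0 else 0.0
    else:
        lower = stats.chi2.sf(two_llr, df - 1)
    return float(0.5 * (upper + lower))


def rank_models(
    table: pd.DataFrame,
    full_label: str = "FULL",
    alpha: float = 0.05,
    mixture: bool = True,
) -> pd.DataFrame:
    """Rank candidate models by AIC and test nested models by LRT.

    ``table`` needs columns ``label``, ``k`` (parameter count) and
    ``logP`` (reported log-probability); nested rows additionally carry
    ``df`` (LRT degrees of freedom vs the full model) and optionally
    ``mixture`` (boundary-parameter chi-square mixture flag).  Returns a
    new frame sorted by AIC with columns ``AIC``, ``delta``, ``ML``
    (relative model likelihood exp(-delta/2)), Akaike weights ``w``,
    evidence ratios ``ER`` (best model / this model), ``two_LLR`` and the
    LRT ``p_value``/``rejected`` outcome.  Setting ``mixture=False``
    forces plain chi-square tests everywhere.
    """
    df = table.copy().reset_index(drop=True)
    required = {"label", "k", "logP"}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if full_label not in set(df["label"]):
        raise ValueError(f"full model {full_label!r} missing from table")
    if "mixture" not in df.columns:
        df["mixture"] = False
    if "df" not in df.columns:
        df["df"] = np.nan

    full_logp = float(df.loc[df["label"] == full_label, "logP"].iloc[0])
    df["AIC"] = 2.0 * df["k"] - 2.0 * df["logP"]
    df["delta"] = df["AIC"] - df["AIC"].min()
    df["ML"] = np.exp(-df["delta"] / 2.0)
    df["w"] = df["ML"] / df["ML"].sum()
    df["ER"] = 1.0 / df["ML"]

    two_llr, p_vals, rejected = [], [], []
    for _, row in df.iterrows():
        if row["label"] == full_label or not np.isfinite(row["df"]):
            two_llr.append(np.nan)
            p_vals.append(np.nan)
            rejected.append(False)
            continue
        stat = 2.0 * (full_logp - float(row["logP"]))
        use_mix = bool(row["mixture"]) and mixture
        p = _lrt_p_value(stat, float(row["df"]), use_mix)
        two_llr.append(stat)
        p_vals.append(p)
        rejected.append(p < alpha)
    df["two_LLR"] = two_llr
    df["p_value"] = p_vals
    df["rejected"] = rejected
    return df.sort_values("AIC", kind="stable").reset_index(drop=True)
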