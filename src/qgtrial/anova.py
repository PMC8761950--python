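"""Per-trait RCBD analysis of variance and variance-component extraction.

For a balanced trial with G genotypes and r complete blocks the two-way
fixed-layout decomposition is

    SS_total = SS_genotype + SS_block + SS_error

with expected mean squares E[MS_G] = sigma2_e + r*sigma2_g under the usual
random-genotype algebra, giving the method-of-moments components

    sigma2_e = MS_E,   sigma2_g = (MS_G - MS_E)/r,   sigma2_p = sigma2_g + sigma2_e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import NegativeVarianceWarning, warn

__all__ = [
    "AnovaResult",
    "VarianceComponents",
    "rcbd_anova",
    "extract_components",
    "components_from_mean_squares",
    "significance_stars",
    "variance_table",
]


@dataclass(frozen=True)
class AnovaResult:
    """Two-way RCBD ANOVA for a single trait."""

    trait: str
    n_genotypes: int
    n_blocks: int
    df_genotype: int
    df_block: int
    df_error: int
    ss_genotype: float
    ss_block: float
    ss_error: float
    ms_genotype: float
    ms_block: float
    ms_error: float
    f_statistic: float
    p_value: float
    se_mean: float
    grand_mean: float


@dataclass(frozen=True)
class VarianceComponents:
    """Error, genotypic and phenotypic variance components for one trait.

    ``sigma2_g`` is truncated at zero (negative method-of-moments estimates
    are a sampling artifact); the untruncated value is kept in
    ``sigma2_g_raw`` for diagnostics. ``sigma2_p = sigma2_g + sigma2_e``
    holds exactly by construction.
    """

    trait: str
    sigma2_e: float
    sigma2_g: float
    sigma2_g_raw: float
    sigma2_p: float
    n_blocks: int


def _balanced_pivot(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    if not np.isfinite(sub["value"]).all():
        raise ValueError(f"trait {trait!r} has non-finite values")
    pivot = sub.pivot_table(
        index="genotype", columns="block", values="value", aggfunc="count"
    )
    bad = pivot.isna() | (pivot != 1)
    if bad.to_numpy().any():
        cells = [
            f"({g}, {b})"
            for g, b in zip(*np.nonzero(bad.to_numpy()))
        ]
        names = [
            f"({pivot.index[g]}, {pivot.columns[b]})"
            for g, b in zip(*np.nonzero(bad.to_numpy()))
        ]
        raise ValueError(
            f"trait {trait!r} is not a balanced one-observation-per-cell design; "
            f"offending cells: {', '.join(names[:10])}"
        )
    return sub.pivot(index="genotype", columns="block", values="value")


def rcbd_anova(table: pd.DataFrame, trait: str) -> AnovaResult:
    """Two-way ANOVA with genotype and block strata for one trait.

    Requires a balanced table (every genotype in every block exactly once).
    The F test for genotypes uses (G-1, (G-1)(r-1)) degrees of freedom; for
    constant data all mean squares are zero and F is 0 by convention.
    """
    pivot = _balanced_pivot(table, trait)
    y = pivot.to_numpy(dtype=float)
    g_n, r = y.shape
    if g_n < 2 or r < 2:
        raise ValueError("need at least 2 genotypes and 2 blocks")

    grand = y.mean()
    geno_means = y.mean(axis=1)
    block_means = y.mean(axis=0)

    ss_g = r * float(((geno_means - grand) ** 2).sum())
    ss_b = g_n * float(((block_means - grand) ** 2).sum())
    resid = y - geno_means[:, None] - block_means[None, :] + grand
    ss_e = float((resid**2).sum())

    df_g, df_b = g_n - 1, r - 1
    df_e = df_g * df_b
    ms_g, ms_b, ms_e = ss_g / df_g, ss_b / df_b, ss_e / df_e

    if ms_e > 0:
        f_stat = ms_g / ms_e
        p = float(stats.f.sf(f_stat, df_g, df_e))
    elif ms_g > 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat, p = 0.0, 1.0

    return AnovaResult(
        trait=trait,
        n_genotypes=g_n,
        n_blocks=r,
        df_genotype=df_g,
        df_block=df_b,
        df_error=df_e,
        ss_genotype=ss_g,
        ss_block=ss_b,
        ss_error=ss_e,
        ms_genotype=ms_g,
        ms_block=ms_b,
        ms_error=ms_e,
        f_statistic=float(f_stat),
        p_value=p,
        se_mean=float(np.sqrt(ms_e / r)),
        grand_mean=float(grand),
    )


def extract_components(anova: AnovaResult, n_blocks: int | None = None) -> VarianceComponents:
    """Method-of-moments variance components from the genotype/error mean squares."""
    r = anova.n_blocks if n_blocks is None else n_blocks
    return components_from_mean_squares(
        anova.ms_genotype, anova.ms_error, r, trait=anova.trait
    )


def components_from_mean_squares(
    ms_genotype: float, ms_error: float, n_blocks: int, trait: str = ""
) -> VarianceComponents:
    """Components directly from printed/stored mean squares (no raw data needed)."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if ms_genotype < 0 or ms_error < 0:
        raise ValueError("mean squares must be non-negative")
    sigma2_g_raw = (ms_genotype - ms_error) / n_blocks
    if sigma2_g_raw < 0:
        warn(
            NegativeVarianceWarning,
            f"negative genotypic variance estimate {sigma2_g_raw:.6g} for trait "
            f"{trait or '<unnamed>'} truncated to 0",
        )
    sigma2_g = max(0.0, sigma2_g_raw)
    return VarianceComponents(
        trait=trait,
        sigma2_e=ms_error,
        sigma2_g=sigma2_g,
        sigma2_g_raw=sigma2_g_raw,
        sigma2_p=sigma2_g + ms_error,
        n_blocks=n_blocks,
    )


def significance_stars(p_value: float) -> str:
    """F-test significance stars at the 0.05 / 0.01 / 0.001 levels."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def variance_table(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """ANOVA-report frame: one column per trait, classical rows.

    Rows: DF, mean square, sum square, SE of mean, sigma2_e, sigma2_g,
    sigma2_p — the upper half of the standard genetic-parameters table.
    """
    if traits is None:
        traits = list(pd.unique(table["trait"]))
    cols = {}
    for trait in traits:
        a = rcbd_anova(table, trait)
        vc = extract_components(a)
        cols[trait] = {
            "DF": a.df_genotype,
            "mean square": a.ms_genotype,
            "sum square": a.ss_genotype,
            "S.E of mean": a.se_mean,
            "sigma2_e": vc.sigma2_e,
            "sigma2_g": vc.sigma2_g,
            "sigma2_p": vc.sigma2_p,
        }
    return pd.DataFrame(cols).loc[
        ["DF", "mean square", "sum square", "S.E of mean", "sigma2_e", "sigma2_g", "sigma2_p"]
    ]
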