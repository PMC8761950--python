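"""Genetic variability parameters: GCV/PCV, broad-sense heritability, genetic advance.

Definitions (all per trait):

    GCV% = 100 * sigma_g / mean        PCV% = 100 * sigma_p / mean
    h2b  = sigma2_g / sigma2_p         (low < 0.50 <= medium <= 0.80 < high)
    GA   = K * h2b * sigma_p           (K = 2.06 at 5% selection intensity)

GA is the expected one-generation gain from truncation selection on the best
5% of genotypes; heritability enters unrounded, which matters because the
printed parameter tables in this literature round aggressively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import VarianceComponents, extract_components, rcbd_anova, variance_table

__all__ = [
    "K_5PERCENT",
    "GeneticParameters",
    "coefficients_of_variation",
    "heritability",
    "genetic_advance",
    "genetic_parameters",
    "summary_table",
]

#: Standardized selection differential for 5% selection intensity.
K_5PERCENT = 2.06


@dataclass(frozen=True)
class GeneticParameters:
    trait: str
    mean: float
    gcv_percent: float
    pcv_percent: float
    h2b: float
    h2b_class: str
    genetic_advance: float
    ga_percent_of_mean: float
    selection_constant: float


def coefficients_of_variation(vc: VarianceComponents, mean: float) -> tuple[float, float]:
    """(GCV%, PCV%) — component standard deviations as a percent of the trait mean."""
    if mean <= 0:
        raise ValueError("coefficient of variation undefined for mean <= 0")
    gcv = 100.0 * np.sqrt(vc.sigma2_g) / mean
    pcv = 100.0 * np.sqrt(vc.sigma2_p) / mean
    return float(gcv), float(pcv)


def heritability(vc: VarianceComponents) -> tuple[float, str]:
    """Broad-sense heritability sigma2_g/sigma2_p and its conventional class.

    Class boundaries 0.50 and 0.80 belong to "medium" (closed interval).
    """
    if vc.sigma2_p <= 0:
        raise ValueError(
            f"heritability undefined for trait {vc.trait!r}: phenotypic variance is 0"
        )
    h2b = vc.sigma2_g / vc.sigma2_p
    if h2b < 0.50:
        cls = "low"
    elif h2b <= 0.80:
        cls = "medium"
    else:
        cls = "high"
    return float(h2b), cls


def genetic_advance(
    vc: VarianceComponents, h2b: float, k: float = K_5PERCENT
) -> float:
    """Expected selection gain GA = K * h2b * sigma_p in trait units."""
    if k <= 0:
        raise ValueError("selection constant k must be positive")
    if not 0.0 <= h2b <= 1.0:
        raise ValueError("h2b must lie in [0, 1]")
    return float(k * h2b * np.sqrt(vc.sigma2_p))


def genetic_parameters(
    vc: VarianceComponents, mean: float, k: float = K_5PERCENT
) -> GeneticParameters:
    """All variability parameters for one trait from its variance components."""
    gcv, pcv = coefficients_of_variation(vc, mean)
    h2b, cls = heritability(vc)
    ga = genetic_advance(vc, h2b, k)
    return GeneticParameters(
        trait=vc.trait,
        mean=float(mean),
        gcv_percent=gcv,
        pcv_percent=pcv,
        h2b=h2b,
        h2b_class=cls,
        genetic_advance=ga,
        ga_percent_of_mean=100.0 * ga / mean,
        selection_constant=k,
    )


def summary_table(
    table: pd.DataFrame, traits: list[str] | None = None, k: float = K_5PERCENT
) -> pd.DataFrame:
    """Full genetic-parameters report (one column per trait).

    Extends the ANOVA report with GCV, PCV, h2b (+class), GA and GA% of mean;
    trait means are taken from the data.
    """
    if traits is None:
        traits = list(pd.unique(table["trait"]))
    report = variance_table(table, traits)
    extra = {}
    for trait in traits:
        a = rcbd_anova(table, trait)
        gp = genetic_parameters(extract_components(a), a.grand_mean, k)
        extra[trait] = {
            "mean": gp.mean,
            "GCV": gp.gcv_percent,
            "PCV": gp.pcv_percent,
            "h2b": gp.h2b,
            "h2b class": gp.h2b_class,
            "GA": gp.genetic_advance,
            "GA % of mean": gp.ga_percent_of_mean,
        }
    rows = ["mean", "GCV", "PCV", "h2b", "h2b class", "GA", "GA % of mean"]
    return pd.concat([report, pd.DataFrame(extra).loc[rows]])
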