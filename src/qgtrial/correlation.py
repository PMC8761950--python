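"""Genotypic and phenotypic correlations from RCBD (co)variance components.

The estimator is the classical analysis-of-covariance companion to the
variance-component decomposition: per stratum the mean cross-product of two
traits is obtained from the mean squares of the traits and of their sum,

    MCP(x, y) = [MS(x + y) - MS(x) - MS(y)] / 2,

then cov_g = (MCP_G - MCP_E)/r, cov_e = MCP_E, cov_p = cov_g + cov_e, and

    rg(x, y) = cov_g / sqrt(sigma2_g(x) sigma2_g(y))
    rp(x, y) = cov_p / sqrt(sigma2_p(x) sigma2_p(y)).

Because these are method-of-moments ratios, |rg| can exceed 1 in finite
samples; such entries are clamped to +/-1 and flagged (pre-clamp values are
retained). This reduces exactly to the variance components on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import rcbd_anova
from .diagnostics import ClampWarning, warn

__all__ = [
    "CorrelationSet",
    "cross_product_components",
    "correlation_matrices",
    "rp_significance",
]


@dataclass(frozen=True)
class CorrelationSet:
    """Genotypic/phenotypic correlation matrices over an ordered trait list."""

    traits: list[str]
    rg: np.ndarray
    rp: np.ndarray
    cov_g: np.ndarray
    cov_p: np.ndarray
    clamped_flags: np.ndarray
    rg_raw: np.ndarray
    rp_raw: np.ndarray
    n_genotypes: int
    n_blocks: int

    def to_frame(self, which: str = "rg") -> pd.DataFrame:
        m = {"rg": self.rg, "rp": self.rp, "cov_g": self.cov_g, "cov_p": self.cov_p}[which]
        return pd.DataFrame(m, index=self.traits, columns=self.traits)


def cross_product_components(
    table: pd.DataFrame, x: str, y: str
) -> tuple[float, float, float]:
    """(cov_g, cov_p, cov_e) for one trait pair via the sum-trait identity."""
    ax = rcbd_anova(table, x)
    ay = rcbd_anova(table, y)
    if (ax.n_genotypes, ax.n_blocks) != (ay.n_genotypes, ay.n_blocks):
        raise ValueError(f"traits {x!r} and {y!r} come from different designs")

    wide = (
        table[table["trait"].isin([x, y])]
        .pivot_table(index=["genotype", "block"], columns="trait", values="value")
    )
    if wide[[x, y]].isna().any().any():
        raise ValueError(f"traits {x!r} and {y!r} are not aligned on the same plots")
    summed = wide.reset_index().assign(
        trait="__sum__", value=lambda d: d[x] + d[y]
    )[["genotype", "block", "trait", "value"]]
    asum = rcbd_anova(summed, "__sum__")

    mcp_g = (asum.ms_genotype - ax.ms_genotype - ay.ms_genotype) / 2.0
    mcp_e = (asum.ms_error - ax.ms_error - ay.ms_error) / 2.0
    cov_g = (mcp_g - mcp_e) / ax.n_blocks
    cov_e = mcp_e
    return cov_g, cov_g + cov_e, cov_e


def _stratum_cross_products(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genotype- and error-stratum mean cross-product matrices for Y[g, b, t]."""
    g_n, r, _ = y.shape
    grand = y.mean(axis=(0, 1))
    geno = y.mean(axis=1) - grand
    block = y.mean(axis=0) - grand
    mcp_g = r * (geno.T @ geno) / (g_n - 1)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
    flat = resid.reshape(-1, y.shape[2])
    mcp_e = (flat.T @ flat) / ((g_n - 1) * (r - 1))
    return mcp_g, mcp_e


def correlation_matrices(table: pd.DataFrame, traits: list[str]) -> CorrelationSet:
    """Full rg/rp matrices for an ordered trait list on one balanced trial.

    Traits with zero genotypic variance get a missing (NaN) rg row/column
    with a diagnostic; entries beyond |1| are clamped and flagged.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    wide = (
        table[table["trait"].isin(traits)]
        .pivot_table(index=["genotype", "block"], columns="trait", values="value")
    )
    if wide[traits].isna().any().any():
        raise ValueError("traits are not balanced on a shared (genotype, block) grid")
    g_n = wide.index.get_level_values("genotype").nunique()
    r = wide.index.get_level_values("block").nunique()
    if len(wide) != g_n * r:
        raise ValueError("table is unbalanced: expected one row per (genotype, block)")
    y = (
        wide[traits]
        .to_numpy(dtype=float)
        .reshape(g_n, r, len(traits))
    )

    mcp_g, mcp_e = _stratum_cross_products(y)
    cov_g = (mcp_g - mcp_e) / r
    cov_p = cov_g + mcp_e

    var_g = np.diag(cov_g).copy()
    var_p = np.diag(cov_p).copy()
    degenerate = var_g <= 0
    if degenerate.any():
        bad = [t for t, d in zip(traits, degenerate) if d]
        warn(
            ClampWarning,
            f"zero genotypic variance for {bad}; their rg rows are reported missing",
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        rg_raw = cov_g / np.sqrt(np.outer(np.where(degenerate, np.nan, var_g), np.where(degenerate, np.nan, var_g)))
        rp_raw = cov_p / np.sqrt(np.outer(var_p, var_p))
    np.fill_diagonal(rg_raw, np.where(degenerate, np.nan, 1.0))
    np.fill_diagonal(rp_raw, 1.0)

    clamped = np.abs(rg_raw) > 1.0
    clamped |= np.abs(rp_raw) > 1.0
    clamped &= np.isfinite(rg_raw)
    rg = np.clip(rg_raw, -1.0, 1.0)
    rp = np.clip(rp_raw, -1.0, 1.0)
    if clamped.any():
        n = int(clamped.sum()) // 2
        warn(ClampWarning, f"{n} correlation pair(s) exceeded |1| and were clamped")

    return CorrelationSet(
        traits=list(traits),
        rg=rg,
        rp=rp,
        cov_g=cov_g,
        cov_p=cov_p,
        clamped_flags=clamped,
        rg_raw=rg_raw,
        rp_raw=rp_raw,
        n_genotypes=g_n,
        n_blocks=r,
    )


def rp_significance(rp: np.ndarray, n_genotypes: int) -> np.ndarray:
    """Two-sided p-values for phenotypic correlations, t approximation, G-2 df.

    Applied to rp only: genotypic correlations have no agreed small-sample
    distribution and are reported without significance.
    """
    df = n_genotypes - 2
    if df < 1:
        raise ValueError("need more than 2 genotypes")
    r = np.clip(np.asarray(rp, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    return p
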