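"""Path-coefficient decomposition of trait correlations with a response.

Given the genotypic correlation matrix R among predictor traits and their
correlations r with a response trait, the direct effects (standardized path
coefficients) P solve

    R P = r,

the indirect effect of predictor i routed through j is R[i, j] * P[j], and
the residual effect is sqrt(1 - sum_i P_i r_i). The solve is exact — no
ridge or pseudo-inverse — because with near-collinear predictor sets the
very large direct effects ARE the result; a condition-number warning is
emitted instead of silently regularizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import correlation_matrices
from .diagnostics import CollinearityWarning, QualityFlagWarning, warn

__all__ = ["PathResult", "path_coefficients", "path_from_trial", "path_table"]

#: Condition number above which direct effects are flagged as unstable.
COND_WARN_THRESHOLD = 1e3

_SINGULAR_RTOL = 1e-12


@dataclass(frozen=True)
class PathResult:
    predictors: list[str]
    response: str
    direct: np.ndarray
    indirect: np.ndarray  # [i, j] = r_ij * P_j for i != j; diagonal holds direct
    r_with_response: np.ndarray
    residual_effect: float
    residual_raw: float  # 1 - sum P_i r_i, possibly negative under ill-conditioning
    condition_number: float
    reconstruction_error: float


def path_coefficients(
    rg_predictors: np.ndarray,
    r_response: np.ndarray,
    predictors: list[str] | None = None,
    response: str = "response",
    cond_warn: float = COND_WARN_THRESHOLD,
) -> PathResult:
    """Direct/indirect effects by exact linear solve of the correlation system.

    Rejects exactly singular systems (direct effects non-identifiable) naming
    the null-space direction; merely ill-conditioned systems are solved and
    flagged with a collinearity warning.
    """
    R = np.asarray(rg_predictors, dtype=float)
    r = np.asarray(r_response, dtype=float)
    n = r.shape[0]
    if R.shape != (n, n):
        raise ValueError(f"correlation matrix shape {R.shape} does not match {n} responses")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("predictor correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("predictor correlation matrix must have unit diagonal")
    if predictors is None:
        predictors = [f"x{i + 1}" for i in range(n)]

    lam, vec = np.linalg.eigh(R)
    if np.min(np.abs(lam)) <= _SINGULAR_RTOL * np.max(np.abs(lam)):
        null = vec[:, int(np.argmin(np.abs(lam)))]
        direction = ", ".join(f"{c:+.3f}*{p}" for c, p in zip(null, predictors))
        raise np.linalg.LinAlgError(
            f"predictor correlation matrix is singular; null-space direction {direction}"
        )
    cond = float(np.max(np.abs(lam)) / np.min(np.abs(lam)))
    if cond > cond_warn:
        warn(
            CollinearityWarning,
            f"predictor correlation matrix condition number {cond:.3g} exceeds "
            f"{cond_warn:.0e}; direct effects are numerically unstable",
        )

    direct = np.linalg.solve(R, r)
    indirect = R * direct[None, :]
    np.fill_diagonal(indirect, direct)

    recon = indirect.sum(axis=1)
    reconstruction_error = float(np.max(np.abs(recon - r))) if n else 0.0

    residual_raw = float(1.0 - direct @ r)
    if residual_raw < 0:
        warn(
            QualityFlagWarning,
            f"explained correlation exceeds 1 (1 - sum P*r = {residual_raw:.4g}); "
            "residual effect reported as 0",
        )
    residual = float(np.sqrt(max(0.0, residual_raw)))

    return PathResult(
        predictors=list(predictors),
        response=response,
        direct=direct,
        indirect=indirect,
        r_with_response=r,
        residual_effect=residual,
        residual_raw=residual_raw,
        condition_number=cond,
        reconstruction_error=reconstruction_error,
    )


def path_from_trial(
    table: pd.DataFrame,
    predictors: list[str],
    response: str,
    cond_warn: float = COND_WARN_THRESHOLD,
) -> PathResult:
    """Genotypic path analysis straight from a balanced trial table."""
    traits = list(predictors) + [response]
    cs = correlation_matrices(table, traits)
    k = len(predictors)
    if len(predictors) == 1:
        # Single-predictor degeneracy: direct effect is the correlation itself.
        r = cs.rg[:k, k]
        return path_coefficients(
            np.ones((1, 1)), r, predictors=list(predictors), response=response,
            cond_warn=cond_warn,
        )
    if np.isnan(cs.rg[: k + 1, : k + 1]).any():
        raise ValueError("genotypic correlations are missing for some requested traits")
    return path_coefficients(
        cs.rg[:k, :k], cs.rg[:k, k], predictors=list(predictors), response=response,
        cond_warn=cond_warn,
    )


def path_table(result: PathResult) -> pd.DataFrame:
    """Report frame: predictors x predictors with direct effects on the
    diagonal, indirect effects off-diagonal, and the correlation with the
    response as the last column."""
    frame = pd.DataFrame(
        result.indirect, index=result.predictors, columns=result.predictors
    )
    frame[result.response] = result.r_with_response
    return frame
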