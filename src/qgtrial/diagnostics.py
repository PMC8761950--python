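"""Warning categories with stable codes so pipelines can grep diagnostics.

Every warning the pipeline emits carries one of the codes below in its
message; the CLI manifest collects them per run.
"""

from __future__ import annotations

import warnings

W_COLLIN = "W-COLLIN"
W_CLAMP = "W-CLAMP"
W_NEGVAR = "W-NEGVAR"
W_QC = "W-QC"


class QgtrialWarning(UserWarning):
    """Base class for all diagnostics emitted by this package."""

    code = "W-GENERIC"


class CollinearityWarning(QgtrialWarning):
    """Predictor correlation matrix is ill-conditioned; direct effects unstable."""

    code = W_COLLIN


class ClampWarning(QgtrialWarning):
    """A method-of-moments correlation exceeded |1| and was clamped."""

    code = W_CLAMP


class NegativeVarianceWarning(QgtrialWarning):
    """A genotypic variance component estimate was negative and truncated to 0."""

    code = W_NEGVAR


class QualityFlagWarning(QgtrialWarning):
    """A derived-trait value is physically implausible (QC flag, not an error)."""

    code = W_QC


def warn(category: type[QgtrialWarning], message: str) -> None:
    warnings.warn(f"{category.code}: {message}", category, stacklevel=3)
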