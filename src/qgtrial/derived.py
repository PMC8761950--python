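"""Compositional, color and antioxidant arithmetic for trait panels.

Pure functions implementing the standard downstream calculations of a
proximate-composition workup: carbohydrate by difference, Atwater calories,
Kjeldahl nitrogen-to-protein conversion, CIE 1976 L*a*b* color difference,
and DPPH radical-scavenging percent inhibition. Implausible values raise QC
flags (warnings), not errors, so batch processing of noisy panels proceeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .diagnostics import QualityFlagWarning, warn

__all__ = [
    "ProximatePanel",
    "ColorReading",
    "DpphReading",
    "percent_carbohydrates",
    "calories",
    "protein_from_nitrogen",
    "delta_e",
    "dpph_inhibition",
    "derive_batch",
]

#: Atwater energy factors, kcal per gram (per-100 g convention).
ATWATER_PROTEIN = 4.0
ATWATER_FAT = 9.0
ATWATER_CARB = 4.0

#: Kjeldahl nitrogen-to-protein conversion factor.
NITROGEN_FACTOR = 6.25


@dataclass(frozen=True)
class ColorReading:
    """CIE 1976 L*a*b* color coordinates."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class DpphReading:
    """DPPH absorbances at 517 nm before and after 30 min incubation."""

    abs_t0: float
    abs_t30: float

    def __post_init__(self) -> None:
        if self.abs_t0 <= 0:
            raise ValueError("initial absorbance must be positive")
        if self.abs_t30 < 0:
            raise ValueError("absorbance cannot be negative")


def percent_carbohydrates(
    ash: float, moisture: float, fat: float, fiber: float, protein: float
) -> float:
    """Carbohydrate percentage by difference: 100 minus the other components.

    A negative result (inconsistent inputs summing past 100) is flagged, not
    rejected.
    """
    for name, v in (("ash", ash), ("moisture", moisture), ("fat", fat),
                    ("fiber", fiber), ("protein", protein)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} = {v} outside [0, 100]")
    carb = 100.0 - (ash + moisture + fat + fiber + protein)
    if carb < 0:
        warn(
            QualityFlagWarning,
            f"derived carbohydrates {carb:.3f}% is negative: components sum past 100",
        )
    return carb


def calories(protein: float, fat: float, carbohydrates: float) -> float:
    """Atwater energy: 4*protein + 9*fat + 4*carbohydrates (kcal/100 g)."""
    if min(protein, fat, carbohydrates) < 0:
        raise ValueError("calorie inputs must be non-negative")
    return ATWATER_PROTEIN * protein + ATWATER_FAT * fat + ATWATER_CARB * carbohydrates


def protein_from_nitrogen(nitrogen_percent: float) -> float:
    """Crude protein from Kjeldahl nitrogen: N x 6.25; >100% is flagged."""
    if nitrogen_percent < 0:
        raise ValueError("nitrogen percentage must be non-negative")
    protein = NITROGEN_FACTOR * nitrogen_percent
    if protein > 100.0:
        warn(
            QualityFlagWarning,
            f"protein {protein:.2f}% from N = {nitrogen_percent}% is implausible (>100%)",
        )
    return protein


def delta_e(sample: ColorReading, reference: ColorReading) -> float:
    """CIE 1976 color difference: Euclidean distance in L*a*b* space."""
    return math.sqrt(
        (sample.L_star - reference.L_star) ** 2
        + (sample.a_star - reference.a_star) ** 2
        + (sample.b_star - reference.b_star) ** 2
    )


def dpph_inhibition(reading: DpphReading) -> float:
    """DPPH radical-scavenging activity: 100*(A_t0 - A_t30)/A_t0.

    Negative inhibition (absorbance increased: pro-oxidant artifact) is
    returned with a QC flag rather than raising.
    """
    inhibition = 100.0 * (reading.abs_t0 - reading.abs_t30) / reading.abs_t0
    if inhibition < 0:
        warn(
            QualityFlagWarning,
            f"negative DPPH inhibition {inhibition:.2f}% (absorbance increased)",
        )
    return inhibition


@dataclass(frozen=True)
class ProximatePanel:
    """Proximate composition of one sample with its derived quantities."""

    ash: float
    moisture: float
    fat: float
    fiber: float
    protein: float
    carbohydrates: float
    calories: float

    @classmethod
    def from_components(
        cls, ash: float, moisture: float, fat: float, fiber: float, protein: float
    ) -> "ProximatePanel":
        carb = percent_carbohydrates(ash, moisture, fat, fiber, protein)
        kcal = calories(protein, fat, max(carb, 0.0))
        return cls(ash, moisture, fat, fiber, protein, carb, kcal)


_COMPONENTS = ["ash", "moisture", "fat", "fiber", "protein"]


def derive_batch(samples: pd.DataFrame) -> pd.DataFrame:
    """Batch derivation: component columns in, derived columns + QC flags out.

    Expects columns ash, moisture, fat, fiber, protein (percent); adds
    carbohydrates, calories and a qc_flag column ('' when clean).
    """
    missing = [c for c in _COMPONENTS if c not in samples.columns]
    if missing:
        raise ValueError(f"missing component columns: {missing}")
    out = samples.copy()
    carbs, kcal, flags = [], [], []
    for _, row in samples.iterrows():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            c = percent_carbohydrates(*(float(row[k]) for k in _COMPONENTS))
            e = calories(float(row["protein"]), float(row["fat"]), max(c, 0.0))
        carbs.append(c)
        kcal.append(e)
        flags.append(";".join(str(w.message) for w in caught))
    out["carbohydrates"] = carbs
    out["calories"] = kcal
    out["qc_flag"] = flags
    return out
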