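"""Clinical image-quality and dose metrics.

Quantities computed from per-patient ROI measurements and dose reports:

* objective noise — the across-patient mean (± SD) of the ROI SD in an
  anatomy, with the liver value taken as the arithmetic mean of its three
  ROI SDs;
* two contrast-to-noise ratios —

  ``CNR_liver  = (HU_liver − HU_psoas)   / SD_upper_fat``
  ``CNR_pelvis = (HU_organ − HU_bladder) / SD_lower_fat``

  where the "noise" in the denominator is the SD in the subcutaneous fat at
  the same level;
* effective dose — DLP × k, with k = 0.015 mSv·mGy⁻¹·cm⁻¹ for the
  abdomen/pelvis;
* contrast-material arithmetic — injected volume and flow rate from body
  weight, the iodine dose per kg, the agent concentration and the injection
  duration, plus the percent reduction of one iodine load versus another.

All functions keep full precision; :func:`present` applies the 1-decimal
rounding used for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import ANATOMIES, PatientRecord

__all__ = [
    "CNRResult",
    "cnr_liver",
    "cnr_pelvis",
    "objective_noise",
    "effective_dose",
    "cm_dose",
    "percent_reduction",
    "present",
]


@dataclass(frozen=True)
class CNRResult:
    """A contrast-to-noise ratio at one site (dimensionless)."""

    site: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("CNR must be finite")


def cnr_liver(liver_mean: float, psoas_mean: float, upper_fat_sd: float) -> CNRResult:
    """Liver CNR: (liver − psoas) attenuation over upper-abdominal fat noise.

    >>> cnr_liver(110, 60, 10).value
    5.0
    """

    if not upper_fat_sd > 0:
        raise ZeroDivisionError("upper_fat_sd must be > 0")
    return CNRResult("liver", (liver_mean - psoas_mean) / upper_fat_sd)


def cnr_pelvis(organ_mean: float, bladder_mean: float, lower_fat_sd: float) -> CNRResult:
    """Pelvis CNR: (prostate/uterus − bladder) over lower-abdominal fat noise."""

    if not lower_fat_sd > 0:
        raise ZeroDivisionError("lower_fat_sd must be > 0")
    return CNRResult("pelvis", (organ_mean - bladder_mean) / lower_fat_sd)


def patient_noise(record: PatientRecord, anatomy: str, arm: str) -> float:
    """Per-patient objective noise for one anatomy and arm.

    The liver aggregates its three ROI SDs by arithmetic mean; other
    anatomies report the single ROI SD.
    """

    m = record.measurements[arm][anatomy]
    if m.roi_sds is not None:
        return float(np.mean(m.roi_sds))
    return m.sd_hu


def objective_noise(
    records: Sequence[PatientRecord], anatomy: str, arm: str
) -> tuple[float, float]:
    """Across-patient mean and SD of the objective noise in ``anatomy``.

    Requires at least 2 patients; raises ``ValueError`` naming the patients
    missing the requested anatomy/arm.
    """

    if anatomy not in ANATOMIES:
        raise ValueError(f"unknown anatomy {anatomy!r}")
    if len(records) < 2:
        raise ValueError("objective noise needs at least 2 patients")
    missing = [
        r.patient_id
        for r in records
        if arm not in r.measurements or anatomy not in r.measurements[arm]
    ]
    if missing:
        raise ValueError(
            f"anatomy {anatomy!r} (arm {arm!r}) missing for patients: {missing}"
        )
    values = np.array([patient_noise(r, anatomy, arm) for r in records])
    return float(values.mean()), float(values.std(ddof=1))


def effective_dose(dlp: float, k: float = 0.015) -> float:
    """Estimated effective dose in mSv: DLP (mGy·cm) × k (mSv·mGy⁻¹·cm⁻¹).

    The default k of 0.015 is the abdomen-and-pelvis conversion factor.
    Full precision is kept; round only at presentation:

    >>> present(effective_dose(243.2))
    3.6
    """

    if dlp < 0:
        raise ValueError("dlp must be >= 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    return dlp * k


def cm_dose(
    body_weight: float,
    dose_per_kg: float = 312.0,
    concentration: float = 300.0,
    duration: float = 45.0,
) -> tuple[float, float]:
    """Contrast-material volume (mL) and flow rate (mL/s).

    ``volume = weight × dose_per_kg / concentration``;
    ``rate = volume / duration``.  The defaults describe a reduced iodine
    load of 312 mgI/kg of a 300 mgI/mL agent injected over 45 s.

    >>> cm_dose(60.0)
    (62.4, 1.3866666666666667)
    """

    if min(body_weight, dose_per_kg, concentration, duration) <= 0:
        raise ValueError("all contrast-material inputs must be > 0")
    volume = body_weight * dose_per_kg / concentration
    return volume, volume / duration


def percent_reduction(new_value: float, reference_value: float) -> float:
    """Percent reduction of ``new_value`` relative to ``reference_value``.

    >>> percent_reduction(312, 520)
    40.0
    """

    if reference_value <= 0:
        raise ValueError("reference_value must be > 0")
    return (1.0 - new_value / reference_value) * 100.0


def present(value: float, decimals: int = 1) -> float:
    """Presentation rounding (default 1 decimal, the reporting convention)."""

    return round(float(value), decimals)
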