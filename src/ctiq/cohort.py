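"""Synthetic clinical cohorts with paired reconstruction arms.

A cohort emulates the measurement structure of a paired image-quality
reading study: every patient is scanned once and reconstructed with two
algorithms ("arms"), technologists place ROIs in six anatomies (liver ×3,
upper abdominal fat, psoas, bladder, prostate/uterus, lower abdominal fat)
per arm, two radiologists grade seven subjective items on a 1–5 scale per
arm, and a dose record (CTDIvol, DLP) is kept per patient.

The generator is parameterized directly by the quantities the analysis
estimates: per-anatomy objective-noise mean/SD across patients per arm,
per-site CNR mean/SD per arm, and per-item rating distributions per arm.
Objective noise values are drawn as (optionally paired-correlated)
Gaussians; ROI mean attenuations are drawn around fixed tissue values, with
the liver and pelvic-organ means *derived* from the drawn CNR and the
drawn fat noise so that the generated cohort reproduces the requested CNR
structure exactly in expectation.  Everything is reproducible from the
spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ANATOMIES",
    "RATING_ITEMS",
    "ArmPair",
    "ROIMeasurement",
    "DoseRecord",
    "PatientRecord",
    "CohortSpec",
    "default_cohort_spec",
    "two_point_distribution",
    "generate_cohort",
    "cohort_to_frames",
    "records_from_frames",
]

ANATOMIES = ("liver", "upper_fat", "psoas", "bladder", "pelvic_organ", "lower_fat")

#: Subjective 1–5 items graded per arm: noise, overall diagnostic confidence,
#: and appearance/texture in the liver and pelvis.
RATING_ITEMS = (
    "noise_liver",
    "noise_pelvis",
    "diagnostic_confidence",
    "appearance_liver",
    "appearance_pelvis",
    "texture_liver",
    "texture_pelvis",
)


@dataclass(frozen=True)
class ArmPair:
    """Generating mean/SD for one quantity in each arm (A, B)."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    def __post_init__(self) -> None:
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError("SDs must be >= 0")


@dataclass
class ROIMeasurement:
    """One ROI reading: mean HU and SD within the ROI.

    For the liver, three ROIs are placed and their individual SDs kept in
    ``roi_sds``; ``sd_hu`` then holds their arithmetic mean and
    ``n_rois=3``.  All other anatomies use a single ROI.
    """

    anatomy: str
    mean_hu: float
    sd_hu: float
    n_rois: int = 1
    roi_sds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.anatomy not in ANATOMIES:
            raise ValueError(f"unknown anatomy {self.anatomy!r}")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if self.roi_sds is not None and len(self.roi_sds) != self.n_rois:
            raise ValueError("roi_sds length must equal n_rois")


@dataclass
class DoseRecord:
    """Per-patient dose report: CTDIvol (mGy), DLP (mGy·cm), k factor."""

    ctdi_vol: float
    dlp: float
    k_factor: float = 0.015

    def __post_init__(self) -> None:
        if min(self.ctdi_vol, self.dlp, self.k_factor) < 0:
            raise ValueError("dose quantities must be >= 0")

    @property
    def effective_dose(self) -> float:
        """Estimated effective dose in mSv (DLP × k)."""
        return self.dlp * self.k_factor


@dataclass
class PatientRecord:
    """All measurements for one patient, both reconstruction arms."""

    patient_id: str
    sex: str  # "M" | "F"
    body_weight: float  # kg
    bmi: float  # kg/m^2
    measurements: dict  # arm -> anatomy -> ROIMeasurement
    ratings: dict  # arm -> item -> reviewer -> int score 1..5
    dose: DoseRecord

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError("body_weight must be > 0")


def two_point_distribution(mean: float) -> tuple[float, ...]:
    """Probability vector over scores 1–5 with mass on the two integers
    bracketing ``mean`` (a single point if ``mean`` is an integer)."""

    if not 1.0 <= mean <= 5.0:
        raise ValueError("rating mean must be within [1, 5]")
    lo = int(math.floor(mean))
    p = np.zeros(5)
    if lo == mean or lo == 5:
        p[min(lo, 5) - 1] = 1.0
    else:
        frac = mean - lo
        p[lo - 1] = 1.0 - frac
        p[lo] = frac
    return tuple(p)


@dataclass
class CohortSpec:
    """Generating parameters for a paired two-arm cohort.

    ``noise`` maps each anatomy to the across-patient mean/SD of its
    objective noise (ROI SD in HU) per arm; ``cnr`` maps the two CNR sites
    to their across-patient mean/SD per arm; ``tissue_hu`` gives the
    attenuation mean and between-patient SD of the independently drawn
    tissues (psoas, bladder, fat).  ``ratings`` maps item → arm → length-5
    probability vector over the scores.  ``paired_correlation`` couples the
    two arms' draws of each quantity; ``reviewer_agreement`` is the
    probability the second reviewer repeats the first reviewer's score
    rather than drawing independently.
    """

    n_patients: int = 36
    arms: tuple[str, str] = ("MBIR", "DLR")
    noise: dict = field(default_factory=dict)  # anatomy -> ArmPair
    cnr: dict = field(default_factory=dict)  # "liver"/"pelvis" -> ArmPair
    tissue_hu: dict = field(default_factory=dict)  # anatomy -> (mean, sd)
    ratings: dict = field(default_factory=dict)  # item -> arm -> tuple[5]
    paired_correlation: float = 0.5
    reviewer_agreement: float = 0.9
    body_weight: tuple[float, float] = (57.1, 11.7)
    bmi: tuple[float, float] = (22.5, 3.5)
    dlp: tuple[float, float] = (243.2, 106.0)
    ctdi_vol: tuple[float, float] = (4.2, 1.6)
    male_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.paired_correlation < 1:
            raise ValueError("paired_correlation must be in [0, 1)")
        for anatomy, pair in self.noise.items():
            if anatomy not in ANATOMIES:
                raise ValueError(f"unknown anatomy {anatomy!r} in noise spec")
        for item, per_arm in self.ratings.items():
            if item not in RATING_ITEMS:
                raise ValueError(f"unknown rating item {item!r}")
            for arm, probs in per_arm.items():
                p = np.asarray(probs, dtype=float)
                if p.shape != (5,) or np.any(p < 0) or not math.isclose(
                    p.sum(), 1.0, abs_tol=1e-9
                ):
                    raise ValueError(
                        f"ratings[{item!r}][{arm!r}] must be 5 nonnegative "
                        "probabilities summing to 1"
                    )


def default_cohort_spec(
    n_patients: int = 36,
    seed: int = 0,
    paired_correlation: float = 0.5,
) -> CohortSpec:
    """Cohort parameterized like the paired MBIR-vs-DLR reading study.

    Arm A ("MBIR") has lower objective noise but lower subjective quality
    on all items except noise; arm B ("DLR") is noisier but preferred.
    Objective-noise and CNR rows carry the study's across-patient
    means/SDs; rating distributions are two-point distributions matching
    the per-item mean scores.
    """

    noise = {
        "liver": ArmPair(6.4, 0.1, 9.5, 0.1),
        "upper_fat": ArmPair(7.0, 2.3, 8.7, 1.9),
        "psoas": ArmPair(6.4, 1.4, 9.0, 1.4),
        "bladder": ArmPair(6.4, 1.4, 9.2, 1.6),
        "lower_fat": ArmPair(7.4, 1.9, 9.3, 1.7),
        # the organ ROI's own noise is not part of the reported rows;
        # psoas-like values keep the record complete
        "pelvic_organ": ArmPair(6.5, 1.4, 9.0, 1.5),
    }
    cnr = {
        "liver": ArmPair(5.2, 0.0, 4.2, 0.1),
        "pelvis": ArmPair(6.8, 0.2, 5.3, 0.0),
    }
    tissue_hu = {
        "psoas": (55.0, 4.0),
        "bladder": (10.0, 3.0),
        "upper_fat": (-105.0, 6.0),
        "lower_fat": (-105.0, 6.0),
    }
    rating_means = {
        "noise_liver": (4.8, 3.8),
        "noise_pelvis": (4.4, 3.4),
        "diagnostic_confidence": (2.0, 3.8),
        "appearance_liver": (2.2, 4.0),
        "appearance_pelvis": (2.0, 3.8),
        "texture_liver": (2.2, 4.0),
        "texture_pelvis": (2.0, 3.7),
    }
    ratings = {
        item: {
            "MBIR": two_point_distribution(ma),
            "DLR": two_point_distribution(mb),
        }
        for item, (ma, mb) in rating_means.items()
    }
    return CohortSpec(
        n_patients=n_patients,
        noise=noise,
        cnr=cnr,
        tissue_hu=tissue_hu,
        ratings=ratings,
        paired_correlation=paired_correlation,
        seed=seed,
    )


# ---------------------------------------------------------------------------


def _paired_normal(
    rng: np.random.Generator, pair: ArmPair, rho: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """n paired draws (arm A, arm B) at correlation rho."""
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    return pair.mean_a + pair.sd_a * z1, pair.mean_b + pair.sd_b * z2


def generate_cohort(cspec: CohortSpec) -> list[PatientRecord]:
    """Draw a full paired cohort from a :class:`CohortSpec`.

    Returns one :class:`PatientRecord` per patient with both arms filled
    in.  The draw order is fixed, so identical specs (including the seed)
    give identical cohorts.
    """

    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_patients
    arm_a, arm_b = cspec.arms
    rho = cspec.paired_correlation

    # objective noise (ROI SD) per anatomy, paired across arms; SDs cannot
    # be negative, so draws are floored at a small positive value
    noise_draws: dict[str, dict[str, np.ndarray]] = {}
    for anatomy in ANATOMIES:
        pair = cspec.noise.get(anatomy, ArmPair(7.0, 1.5, 9.0, 1.5))
        a, b = _paired_normal(rng, pair, rho, n)
        noise_draws[anatomy] = {arm_a: np.maximum(a, 0.1), arm_b: np.maximum(b, 0.1)}

    # CNR per site, paired across arms
    cnr_draws: dict[str, dict[str, np.ndarray]] = {}
    for site in ("liver", "pelvis"):
        pair = cspec.cnr.get(site, ArmPair(5.0, 0.5, 4.0, 0.5))
        a, b = _paired_normal(rng, pair, rho, n)
        cnr_draws[site] = {arm_a: a, arm_b: b}

    # tissue attenuations shared between arms (reconstruction changes
    # noise, not attenuation)
    tissue_defaults = {
        "psoas": (55.0, 4.0),
        "bladder": (10.0, 3.0),
        "upper_fat": (-105.0, 6.0),
        "lower_fat": (-105.0, 6.0),
    }
    tissue_means: dict[str, np.ndarray] = {}
    for anatomy in ("psoas", "bladder", "upper_fat", "lower_fat"):
        mu, sd = cspec.tissue_hu.get(anatomy, tissue_defaults[anatomy])
        tissue_means[anatomy] = mu + sd * rng.standard_normal(n)

    # liver / pelvic-organ means derived so per-patient CNR equals the draw:
    #   CNR_liver  = (liver - psoas) / upper_fat_sd
    #   CNR_pelvis = (organ - bladder) / lower_fat_sd
    derived_means = {
        "liver": {
            arm: tissue_means["psoas"]
            + cnr_draws["liver"][arm] * noise_draws["upper_fat"][arm]
            for arm in cspec.arms
        },
        "pelvic_organ": {
            arm: tissue_means["bladder"]
            + cnr_draws["pelvis"][arm] * noise_draws["lower_fat"][arm]
            for arm in cspec.arms
        },
    }

    # liver noise: three ROI SDs averaging to the drawn per-patient value
    liver_roi_sds = {
        arm: np.maximum(
            noise_draws["liver"][arm][:, None]
            + 0.3 * (lambda e: e - e.mean(axis=1, keepdims=True))(
                rng.standard_normal((n, 3))
            ),
            0.05,
        )
        for arm in cspec.arms
    }

    # ratings: reviewer 1 from the item/arm distribution; reviewer 2 repeats
    # with probability reviewer_agreement, else redraws
    scores = np.arange(1, 6)
    rating_draws: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for item in RATING_ITEMS:
        rating_draws[item] = {}
        for arm in cspec.arms:
            probs = cspec.ratings.get(item, {}).get(arm)
            if probs is None:
                probs = two_point_distribution(3.0)
            r1 = rng.choice(scores, size=n, p=probs)
            agree = rng.random(n) < cspec.reviewer_agreement
            r2 = np.where(agree, r1, rng.choice(scores, size=n, p=probs))
            rating_draws[item][arm] = {"R1": r1, "R2": r2}

    sexes = np.where(rng.random(n) < cspec.male_fraction, "M", "F")
    weights = np.maximum(cspec.body_weight[0] + cspec.body_weight[1] * rng.standard_normal(n), 30.0)
    bmis = np.maximum(cspec.bmi[0] + cspec.bmi[1] * rng.standard_normal(n), 12.0)
    dlps = np.maximum(cspec.dlp[0] + cspec.dlp[1] * rng.standard_normal(n), 10.0)
    ctdis = np.maximum(cspec.ctdi_vol[0] + cspec.ctdi_vol[1] * rng.standard_normal(n), 0.5)

    records: list[PatientRecord] = []
    for i in range(n):
        measurements: dict[str, dict[str, ROIMeasurement]] = {}
        for arm in cspec.arms:
            per_arm: dict[str, ROIMeasurement] = {}
            for anatomy in ANATOMIES:
                if anatomy in derived_means:
                    mean_hu = float(derived_means[anatomy][arm][i])
                else:
                    mean_hu = float(tissue_means[anatomy][i])
                if anatomy == "liver":
                    roi_sds = tuple(float(s) for s in liver_roi_sds[arm][i])
                    per_arm[anatomy] = ROIMeasurement(
                        anatomy,
                        mean_hu,
                        float(np.mean(roi_sds)),
                        n_rois=3,
                        roi_sds=roi_sds,
                    )
                else:
                    per_arm[anatomy] = ROIMeasurement(
                        anatomy, mean_hu, float(noise_draws[anatomy][arm][i])
                    )
            measurements[arm] = per_arm
        ratings = {
            arm: {
                item: {
                    rev: int(rating_draws[item][arm][rev][i]) for rev in ("R1", "R2")
                }
                for item in RATING_ITEMS
            }
            for arm in cspec.arms
        }
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                sex=str(sexes[i]),
                body_weight=float(weights[i]),
                bmi=float(bmis[i]),
                measurements=measurements,
                ratings=ratings,
                dose=DoseRecord(ctdi_vol=float(ctdis[i]), dlp=float(dlps[i])),
            )
        )
    return records


# ---------------------------------------------------------------------------
# tidy-frame round trips (the CSV interchange schema)


def cohort_to_frames(
    records: list[PatientRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tidy frames ``(measurements, ratings, doses)``.

    Schemas: measurements (patient, arm, anatomy, mean_hu, sd_hu, n_rois);
    ratings (patient, reviewer, arm, item, score); doses (patient,
    ctdi_vol, dlp, k_factor).
    """

    m_rows, r_rows, d_rows = [], [], []
    for rec in records:
        for arm, per_arm in rec.measurements.items():
            for anatomy, m in per_arm.items():
                m_rows.append(
                    {
                        "patient": rec.patient_id,
                        "arm": arm,
                        "anatomy": anatomy,
                        "mean_hu": m.mean_hu,
                        "sd_hu": m.sd_hu,
                        "n_rois": m.n_rois,
                    }
                )
        for arm, per_arm in rec.ratings.items():
            for item, per_rev in per_arm.items():
                for rev, score in per_rev.items():
                    r_rows.append(
                        {
                            "patient": rec.patient_id,
                            "reviewer": rev,
                            "arm": arm,
                            "item": item,
                            "score": score,
                        }
                    )
        d_rows.append(
            {
                "patient": rec.patient_id,
                "ctdi_vol": rec.dose.ctdi_vol,
                "dlp": rec.dose.dlp,
                "k_factor": rec.dose.k_factor,
            }
        )
    return pd.DataFrame(m_rows), pd.DataFrame(r_rows), pd.DataFrame(d_rows)


def records_from_frames(
    measurements: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
    doses: pd.DataFrame | None = None,
) -> list[PatientRecord]:
    """Rebuild :class:`PatientRecord` objects from the tidy CSV schema.

    Demographics absent from the schema are filled with placeholders (they
    do not enter the paired comparisons).
    """

    records = []
    for pid, m_group in measurements.groupby("patient", sort=True):
        meas: dict[str, dict[str, ROIMeasurement]] = {}
        for _, row in m_group.iterrows():
            meas.setdefault(row["arm"], {})[row["anatomy"]] = ROIMeasurement(
                anatomy=row["anatomy"],
                mean_hu=float(row["mean_hu"]),
                sd_hu=float(row["sd_hu"]),
                n_rois=int(row.get("n_rois", 1)),
            )
        rat: dict[str, dict[str, dict[str, int]]] = {}
        if ratings is not None:
            for _, row in ratings[ratings["patient"] == pid].iterrows():
                rat.setdefault(row["arm"], {}).setdefault(row["item"], {})[
                    row["reviewer"]
                ] = int(row["score"])
        if doses is not None and (doses["patient"] == pid).any():
            drow = doses[doses["patient"] == pid].iloc[0]
            dose = DoseRecord(
                ctdi_vol=float(drow["ctdi_vol"]),
                dlp=float(drow["dlp"]),
                k_factor=float(drow.get("k_factor", 0.015)),
            )
        else:
            dose = DoseRecord(ctdi_vol=0.0, dlp=0.0)
        records.append(
            PatientRecord(
                patient_id=str(pid),
                sex="U",
                body_weight=60.0,
                bmi=22.0,
                measurements=meas,
                ratings=rat,
                dose=dose,
            )
        )
    return records
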