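"""Paired comparison of two reconstruction arms and report rendering.

:class:`ArmComparison` is the modelling object for the clinical study
table: built from a list of :class:`~ctiq.cohort.PatientRecord` (or from
the tidy CSV frames), its :meth:`~ArmComparison.fit` produces an
:class:`ArmComparisonResult` with one row per reported quantity —

* objective noise in five anatomies (paired t-test),
* liver and pelvis CNR (paired t-test on per-patient CNRs),
* seven subjective 1–5 items (Wilcoxon signed-rank on per-patient scores,
  reviewer-averaged by default),

each carrying the per-arm mean ± SD and the raw two-sided p-value (no
multiplicity correction, matching how such tables are conventionally
reported).  Inter-reviewer agreement is summarized by weighted kappa over
all items and arms pooled.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical import cnr_liver, cnr_pelvis, patient_noise
from .cohort import RATING_ITEMS, PatientRecord, records_from_frames
from .exceptions import DegenerateDataError
from .stats import StatResult, paired_t, weighted_kappa, wilcoxon_signed_rank

__all__ = ["ArmComparison", "ArmComparisonResult", "compare_arms", "render_report"]

NOISE_ANATOMIES = ("liver", "upper_fat", "psoas", "bladder", "lower_fat")


def _patient_cnrs(records: Sequence[PatientRecord], arm: str) -> dict[str, np.ndarray]:
    liver, pelvis = [], []
    for rec in records:
        m = rec.measurements[arm]
        liver.append(
            cnr_liver(m["liver"].mean_hu, m["psoas"].mean_hu, m["upper_fat"].sd_hu).value
        )
        pelvis.append(
            cnr_pelvis(
                m["pelvic_organ"].mean_hu, m["bladder"].mean_hu, m["lower_fat"].sd_hu
            ).value
        )
    return {"liver": np.array(liver), "pelvis": np.array(pelvis)}


class ArmComparison:
    """Paired image-quality comparison between two reconstruction arms.

    Parameters
    ----------
    records
        Paired patient records; both arms must be present for every
        patient.
    arms
        ``(arm_a, arm_b)`` labels; differences are ``arm_a − arm_b``.
    rating_mode
        ``"reviewer_mean"`` (default): the Wilcoxon test compares
        per-patient scores averaged over the two reviewers.
        ``"per_reviewer"``: patient × reviewer pairs enter individually.
    wilcoxon_mode
        Passed to :func:`ctiq.stats.wilcoxon_signed_rank`.
    """

    def __init__(
        self,
        records: Sequence[PatientRecord],
        arms: tuple[str, str] = ("MBIR", "DLR"),
        rating_mode: str = "reviewer_mean",
        wilcoxon_mode: str = "auto",
    ) -> None:
        if len(records) < 2:
            raise ValueError("paired comparison needs at least 2 patients")
        if rating_mode not in ("reviewer_mean", "per_reviewer"):
            raise ValueError(f"unknown rating_mode {rating_mode!r}")
        missing = [
            r.patient_id
            for r in records
            if not all(arm in r.measurements for arm in arms)
        ]
        if missing:
            raise ValueError(f"patients missing an arm: {missing}")
        self.records = list(records)
        self.arms = arms
        self.rating_mode = rating_mode
        self.wilcoxon_mode = wilcoxon_mode

    @classmethod
    def from_frames(
        cls,
        measurements: pd.DataFrame,
        ratings: pd.DataFrame | None = None,
        doses: pd.DataFrame | None = None,
        **kwargs,
    ) -> "ArmComparison":
        """Build from the tidy CSV interchange schema (see ``ctiq.cohort``)."""
        return cls(records_from_frames(measurements, ratings, doses), **kwargs)

    # -- helpers ----------------------------------------------------------

    def _rating_vectors(self, item: str, arm: str) -> np.ndarray:
        if self.rating_mode == "reviewer_mean":
            return np.array(
                [
                    np.mean(list(r.ratings[arm][item].values()))
                    for r in self.records
                ]
            )
        vals = []
        for r in self.records:
            for rev in sorted(r.ratings[arm][item]):
                vals.append(r.ratings[arm][item][rev])
        return np.array(vals, dtype=float)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "ArmComparisonResult":
        arm_a, arm_b = self.arms
        rows = []
        results: dict[str, StatResult] = {}

        def add_row(group: str, name: str, a: np.ndarray, b: np.ndarray, res: StatResult):
            rows.append(
                {
                    "group": group,
                    "quantity": name,
                    f"{arm_a}_mean": a.mean(),
                    f"{arm_a}_sd": a.std(ddof=1),
                    f"{arm_b}_mean": b.mean(),
                    f"{arm_b}_sd": b.std(ddof=1),
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
            results[name] = res

        for anatomy in NOISE_ANATOMIES:
            a = np.array([patient_noise(r, anatomy, arm_a) for r in self.records])
            b = np.array([patient_noise(r, anatomy, arm_b) for r in self.records])
            add_row("objective_noise", f"noise_{anatomy}", a, b, paired_t(a, b))

        cnr_a = _patient_cnrs(self.records, arm_a)
        cnr_b = _patient_cnrs(self.records, arm_b)
        for site in ("liver", "pelvis"):
            add_row(
                "cnr", f"cnr_{site}", cnr_a[site], cnr_b[site],
                paired_t(cnr_a[site], cnr_b[site]),
            )

        have_ratings = all(
            arm in r.ratings and r.ratings[arm] for r in self.records for arm in self.arms
        )
        if have_ratings:
            for item in RATING_ITEMS:
                a = self._rating_vectors(item, arm_a)
                b = self._rating_vectors(item, arm_b)
                try:
                    res = wilcoxon_signed_rank(a, b, mode=self.wilcoxon_mode)
                except (DegenerateDataError, ValueError):
                    # (nearly) identical scores in both arms: no evidence of
                    # a difference; report a null row rather than failing
                    res = StatResult(
                        test="wilcoxon_signed_rank",
                        statistic=0.0,
                        p_value=1.0,
                        n=len(a),
                        method="degenerate: no informative differences",
                        effect=0.0,
                    )
                # prefixed so subjective noise rows cannot shadow the
                # objective noise rows of the same anatomy
                add_row("subjective", f"subjective_{item}", a, b, res)
            kappa = self.interreviewer_agreement()
        else:
            kappa = None

        return ArmComparisonResult(
            table=pd.DataFrame(rows),
            results=results,
            arms=self.arms,
            n_patients=len(self.records),
            kappa=kappa,
        )

    def interreviewer_agreement(self, weights: str = "linear") -> StatResult:
        """Weighted kappa between the two reviewers, all items/arms pooled."""
        r1, r2 = [], []
        for rec in self.records:
            for arm in self.arms:
                for item in rec.ratings.get(arm, {}):
                    revs = sorted(rec.ratings[arm][item])
                    if len(revs) >= 2:
                        r1.append(rec.ratings[arm][item][revs[0]])
                        r2.append(rec.ratings[arm][item][revs[1]])
        return weighted_kappa(r1, r2, weights=weights)


def compare_arms(
    records: Sequence[PatientRecord],
    arms: tuple[str, str] = ("MBIR", "DLR"),
    **kwargs,
) -> "ArmComparisonResult":
    """Convenience wrapper: ``ArmComparison(records, arms).fit()``."""
    return ArmComparison(records, arms=arms, **kwargs).fit()


@dataclass
class ArmComparisonResult:
    """Comparison table plus the individual test results.

    ``table`` has one row per quantity with per-arm mean/SD, the test
    statistic and the raw p-value; ``results`` maps quantity name to the
    full :class:`~ctiq.stats.StatResult`; ``kappa`` is the pooled
    inter-reviewer agreement (``None`` when no ratings were supplied).
    """

    table: pd.DataFrame
    results: dict
    arms: tuple[str, str]
    n_patients: int
    kappa: StatResult | None = None

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_value"] < alpha]

    def summary(self) -> str:
        arm_a, arm_b = self.arms
        lines = [
            f"Paired comparison {arm_a} vs {arm_b}  (n = {self.n_patients} patients)",
            "-" * 72,
        ]
        for _, row in self.table.iterrows():
            p = row["p_value"]
            p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(
                f"{row['quantity']:<24s} "
                f"{row[f'{arm_a}_mean']:6.1f} ± {row[f'{arm_a}_sd']:4.1f}   "
                f"{row[f'{arm_b}_mean']:6.1f} ± {row[f'{arm_b}_sd']:4.1f}   "
                f"P {p_str}"
            )
        if self.kappa is not None:
            lines.append("-" * 72)
            lines.append(
                f"inter-reviewer weighted kappa: {self.kappa.statistic:.2f} "
                f"({self.kappa.method})"
            )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        out = {
            "arms": list(self.arms),
            "n_patients": self.n_patients,
            "rows": {},
        }
        for name, res in self.results.items():
            out["rows"][name] = {
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": res.n,
                "method": res.method,
                "effect": res.effect,
            }
        if self.kappa is not None:
            out["interreviewer_kappa"] = {
                "value": self.kappa.statistic,
                "method": self.kappa.method,
            }
        return out


# ---------------------------------------------------------------------------
# report bundle


def render_report(
    result: ArmComparisonResult,
    curves: dict | None = None,
    out_dir: str = "report",
    score_frames: pd.DataFrame | None = None,
    make_plots: bool = True,
) -> dict:
    """Write the comparison as a report bundle.

    Produces ``table2.csv`` (the comparison table), ``stats.json`` (full
    test results), one tidy CSV per supplied curve under ``curves/``
    (``curves`` maps a label to a TTF or NPS curve object exposing
    ``to_frame``), an optional score-distribution export
    (``score_distribution.csv``) and PNG figures under ``figs/``.  CSV and
    JSON output is deterministic: re-rendering the same inputs yields
    byte-identical files.
    """

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    table_path = os.path.join(out_dir, "table2.csv")
    result.table.to_csv(table_path, index=False, float_format="%.10g")
    paths["table"] = table_path

    json_path = os.path.join(out_dir, "stats.json")
    with open(json_path, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["stats"] = json_path

    if curves:
        curve_dir = os.path.join(out_dir, "curves")
        os.makedirs(curve_dir, exist_ok=True)
        for label, curve in sorted(curves.items()):
            path = os.path.join(curve_dir, f"{label}.csv")
            curve.to_frame().to_csv(path, index=False, float_format="%.10g")
            paths[f"curve:{label}"] = path

    if score_frames is not None:
        path = os.path.join(out_dir, "score_distribution.csv")
        score_frames.to_csv(path, index=False)
        paths["scores"] = path

    if make_plots:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig_dir = os.path.join(out_dir, "figs")
        os.makedirs(fig_dir, exist_ok=True)
        if curves:
            fig, ax = plt.subplots(figsize=(6, 4))
            for label, curve in sorted(curves.items()):
                frame = curve.to_frame()
                ax.plot(frame.iloc[:, 0], frame.iloc[:, 1], label=label)
            ax.legend(fontsize=8)
            ax.set_xlabel(frame.columns[0])
            ax.set_ylabel(frame.columns[1])
            fig.savefig(os.path.join(fig_dir, "curves.png"), dpi=120)
            plt.close(fig)
            paths["fig:curves"] = os.path.join(fig_dir, "curves.png")

        sub = result.table[result.table["group"] == "subjective"]
        if len(sub):
            arm_a, arm_b = result.arms
            fig, ax = plt.subplots(figsize=(7, 4))
            xs = np.arange(len(sub))
            ax.errorbar(
                xs - 0.1, sub[f"{arm_a}_mean"], yerr=sub[f"{arm_a}_sd"],
                fmt="o", label=arm_a,
            )
            ax.errorbar(
                xs + 0.1, sub[f"{arm_b}_mean"], yerr=sub[f"{arm_b}_sd"],
                fmt="s", label=arm_b,
            )
            ax.axhline(3.0, ls="--", c="grey", lw=0.8)
            ax.set_xticks(xs)
            ax.set_xticklabels(sub["quantity"], rotation=45, ha="right", fontsize=8)
            ax.set_ylabel("score (1-5)")
            ax.set_ylim(0.5, 5.5)
            ax.legend()
            fig.tight_layout()
            fig.savefig(os.path.join(fig_dir, "scores.png"), dpi=120)
            plt.close(fig)
            paths["fig:scores"] = os.path.join(fig_dir, "scores.png")

    return paths
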