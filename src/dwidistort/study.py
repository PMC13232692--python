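"""Cohort analysis as a model/results pair.

:class:`DistortionStudy` is built from the per-patient paired cohort table
(and optionally a rater score table); :meth:`DistortionStudy.fit` estimates
the air-volume threshold, runs the paired comparisons, and returns a
:class:`StudyResults` carrying every statistic plus a formatted summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .air import dichotomize
from .stats import (CohortSummary, GwetResult, LogisticThresholdResult,
                    gwet_ac2, logistic_air_threshold, subgroup_compare)
from .tables import COHORT_COLUMNS, read_cohort_table, read_score_table


class DistortionStudy:
    """Paired supine/prone distortion study on one cohort.

    Parameters
    ----------
    cohort : DataFrame
        Per-patient table with the :data:`~dwidistort.tables.COHORT_COLUMNS`
        schema (paired air volumes, posterior distortion, Likert scores).
    scores : DataFrame, optional
        Long-format subject/rater/item/score table for two-rater agreement.
    likert_cutoff : int
        Likert score from which rectal air counts as appreciable.
    """

    def __init__(self, cohort: pd.DataFrame, scores: pd.DataFrame | None = None,
                 likert_cutoff: int = 4):
        missing = set(COHORT_COLUMNS) - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        self.cohort = cohort.reset_index(drop=True)
        self.scores = scores
        self.likert_cutoff = int(likert_cutoff)

    @classmethod
    def from_csv(cls, cohort_path, scores_path=None, **kwargs) -> "DistortionStudy":
        cohort = read_cohort_table(cohort_path)
        scores = read_score_table(scores_path) if scores_path else None
        return cls(cohort, scores, **kwargs)

    def fit(self, v_thresh: float | None = None) -> "StudyResults":
        """Run the full statistical analysis.

        If ``v_thresh`` is not given it is estimated by logistic regression of
        the appreciable-air judgement on the supine proximal air volume.
        """
        logistic: LogisticThresholdResult | None = None
        if v_thresh is None:
            appreciable = dichotomize(self.cohort["likert_supine"],
                                      self.likert_cutoff)
            logistic = logistic_air_threshold(
                self.cohort["air_supine_cm3"].to_numpy(), appreciable)
            v_thresh = logistic.v_thresh_air
        summary = subgroup_compare(self.cohort, v_thresh)
        agreement: dict[str, GwetResult] = {}
        if self.scores is not None:
            for item, grp in self.scores.groupby("item"):
                wide = grp.pivot(index="subject", columns="rater", values="score")
                if wide.shape[1] == 2 and not wide.isna().any().any():
                    agreement[str(item)] = gwet_ac2(wide.to_numpy(),
                                                    categories=range(1, 6))
        return StudyResults(self, summary, logistic, agreement)


@dataclass
class StudyResults:
    """Estimates, tests and diagnostics of a fitted :class:`DistortionStudy`."""

    model: DistortionStudy
    cohort_summary: CohortSummary
    logistic: LogisticThresholdResult | None
    agreement: dict[str, GwetResult] = field(default_factory=dict)

    @property
    def v_thresh_air(self) -> float:
        return self.cohort_summary.v_thresh_air

    @property
    def scatter(self) -> pd.DataFrame:
        """Long-format air-volume vs distortion table (scatter-plot data)."""
        return self.cohort_summary.scatter

    def to_dict(self) -> dict:
        out = self.cohort_summary.to_dict()
        if self.logistic is not None:
            out["logistic"] = {
                "v_thresh_air_cm3": self.logistic.v_thresh_air,
                "beta0": self.logistic.beta0,
                "beta1": self.logistic.beta1,
                "p_value": self.logistic.p_value,
                "separated": self.logistic.separated,
            }
        out["agreement"] = {
            item: {"ac2": g.coefficient, "benchmark": g.benchmark}
            for item, g in self.agreement.items()
        }
        return out

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        s = self.cohort_summary
        lines = [
            "Paired supine/prone distortion study",
            "=" * 54,
            f"patients: {s.n}    high-air subgroup (supine air > "
            f"{s.v_thresh_air:.2f} cm3): {s.n_subgroup}",
        ]
        if self.logistic is not None:
            note = " (perfect separation)" if self.logistic.separated else ""
            pv = ("n/a" if self.logistic.p_value is None
                  else f"{self.logistic.p_value:.3g}")
            lines.append(f"V_thresh-air = {self.logistic.v_thresh_air:.2f} cm3"
                         f"{note}, slope p = {pv}")
        for title, comps in (("whole cohort", s.whole), ("subgroup", s.subgroup)):
            lines.append("-" * 54)
            lines.append(title)
            for c in comps:
                p = ("n/e" if not c.evaluable or c.p_value is None
                     else f"{c.p_value:.3g}")
                lines.append(
                    f"  {c.variable:<22} supine {c.supine_median:6.2f} "
                    f"({c.supine_q1:.2f}-{c.supine_q3:.2f})  prone "
                    f"{c.prone_median:6.2f} ({c.prone_q1:.2f}-{c.prone_q3:.2f})"
                    f"  p={p}")
        if s.fisher_p_likert is not None:
            lines.append(f"Fisher exact, appreciable air supine vs prone: "
                         f"p = {s.fisher_p_likert:.3g}")
        for item, g in self.agreement.items():
            lines.append(f"Gwet AC2 [{item}]: {g.coefficient:.3f} ({g.benchmark})")
        return "\n".join(lines)


__all__ = ["DistortionStudy", "StudyResults"]
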