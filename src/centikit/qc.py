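"""Level-1 pipeline validation and tracer-suitability checks.

Before calibrating a new tracer, a site's processing pipeline must first
reproduce the reference PiB Centiloid values (Level-1 validation): an OLS
fit of locally computed CL against the published reference CL must have a
slope between 0.98 and 1.02, an intercept between -2 and 2 CL, and
R^2 > 0.98.  A tracer is deemed suitable for Centiloid conversion when its
SUVR correlation with PiB exceeds R^2 = 0.70.

Slope/intercept bounds are inclusive; the R^2 thresholds are strict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TracerCalibration

__all__ = [
    "Level1Criteria",
    "ValidationReport",
    "level1_validate",
    "tracer_suitability",
    "cohort_composition_check",
]


@dataclass(frozen=True)
class Level1Criteria:
    """Numeric thresholds for Level-1 pipeline validation."""

    slope_min: float = 0.98
    slope_max: float = 1.02
    intercept_abs_max: float = 2.0
    r2_min: float = 0.98


@dataclass(frozen=True)
class ValidationReport:
    """Level-1 validation outcome; the criteria used are echoed verbatim."""

    slope: float
    intercept: float
    r_squared: float
    slope_ok: bool
    intercept_ok: bool
    r2_ok: bool
    criteria: Level1Criteria

    @property
    def overall_pass(self) -> bool:
        return self.slope_ok and self.intercept_ok and self.r2_ok

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_ok": self.slope_ok,
            "intercept_ok": self.intercept_ok,
            "r2_ok": self.r2_ok,
            "overall_pass": self.overall_pass,
            "criteria": {
                "slope_range": [self.criteria.slope_min, self.criteria.slope_max],
                "intercept_range": [-self.criteria.intercept_abs_max,
                                    self.criteria.intercept_abs_max],
                "r2_min": self.criteria.r2_min,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        c = self.criteria
        mark = lambda ok: "PASS" if ok else "FAIL"  # noqa: E731
        lines = [
            "Level-1 pipeline validation",
            f"  slope     {self.slope:8.4f}  (allowed {c.slope_min} .. "
            f"{c.slope_max})        {mark(self.slope_ok)}",
            f"  intercept {self.intercept:8.4f}  (allowed "
            f"{-c.intercept_abs_max} .. {c.intercept_abs_max} CL)     "
            f"{mark(self.intercept_ok)}",
            f"  R^2       {self.r_squared:8.4f}  (required > {c.r2_min})"
            f"           {mark(self.r2_ok)}",
            f"  overall: {mark(self.overall_pass)}",
        ]
        return "\n".join(lines)


def level1_validate(local_cl: Sequence[float],
                    reference_cl: Sequence[float],
                    criteria: Level1Criteria = Level1Criteria(),
                    ) -> ValidationReport:
    """Validate a local pipeline against reference Centiloid values.

    Fits local CL as a function of reference CL by OLS and checks the
    slope, intercept and R^2 against the criteria.
    """
    y = np.asarray(local_cl, dtype=float)
    x = np.asarray(reference_cl, dtype=float)
    if x.shape != y.shape:
        raise ValueError(
            f"length mismatch: {y.shape[0]} local vs {x.shape[0]} reference"
        )
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    fit = stats.linregress(x, y)
    slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2
    return ValidationReport(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_ok=criteria.slope_min <= slope <= criteria.slope_max,
        intercept_ok=abs(intercept) <= criteria.intercept_abs_max,
        r2_ok=r2 > criteria.r2_min,
        criteria=criteria,
    )


def tracer_suitability(calib: TracerCalibration,
                       r2_min: float = 0.70) -> tuple[bool, dict]:
    """Tracer-suitability check: inter-tracer R^2 strictly above 0.70.

    Returns the verdict plus an annotated report dict.
    """
    suitable = calib.r_squared > r2_min
    report = {
        "tracer": calib.tracer,
        "r_squared": calib.r_squared,
        "r2_min": r2_min,
        "n_subjects": calib.n_subjects,
        "suitable": suitable,
    }
    return suitable, report


# Cohort-composition recommendations for a calibration study.
MIN_TOTAL = 25
MIN_YHC = 10
MIN_NON_YHC = 15


def cohort_composition_check(table: pd.DataFrame) -> list[str]:
    """Check the calibration cohort against the recommended composition.

    At least 25 subjects in total, of which at least 10 young healthy
    controls (amyloid-negative anchor) and at least 15 subjects likely to
    span intermediate-to-high amyloid burden.  Violations are returned as
    warnings, not errors — these are recommendations, not hard rules.
    """
    subjects = table[["subject_id", "group"]].drop_duplicates("subject_id")
    n_total = len(subjects)
    n_yhc = int((subjects["group"] == "YHC").sum())
    n_other = n_total - n_yhc
    warnings_list = []
    if n_total < MIN_TOTAL:
        warnings_list.append(
            f"cohort has {n_total} subjects; at least {MIN_TOTAL} recommended"
        )
    if n_yhc < MIN_YHC:
        warnings_list.append(
            f"cohort has {n_yhc} young healthy controls; "
            f"at least {MIN_YHC} recommended"
        )
    if n_other < MIN_NON_YHC:
        warnings_list.append(
            f"cohort has {n_other} non-YHC subjects; at least {MIN_NON_YHC} "
            "with intermediate-to-high amyloid burden recommended"
        )
    return warnings_list
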