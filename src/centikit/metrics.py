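"""Cohort summaries, the variance ratio, and test-retest repeatability.

The variance ratio quantifies the scale noise an F-18 tracer adds relative
to PiB: the SD of the tracer's Centiloids divided by the SD of PiB's
Centiloids in the same amyloid-negative young-control group.  Test-retest
percent differences measure the repeatability of the whole quantification
chain on repeat scans of the same subjects, for three measures: SUVR, the
specific-binding proxy SUVR-1, and Centiloids.

All standard deviations use the sample (n-1) convention.  Percent
differences are signed, with the test value as denominator by default
(``denominator="mean"`` switches to the mean-of-pair convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LinearMap

__all__ = [
    "GroupSummary",
    "TestRetestResult",
    "group_summary",
    "variance_ratio",
    "test_retest",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean (+/- SD) SUVR and CL for one group x tracer cell."""

    group: str
    tracer: str
    n: int
    mean_suvr: float
    sd_suvr: float | None
    mean_cl: float
    sd_cl: float | None


def _sd(values: np.ndarray) -> float | None:
    """Sample SD (n-1); None when undefined (n = 1)."""
    if values.size < 2:
        return None
    return float(np.std(values, ddof=1))


def group_summary(table: pd.DataFrame, cl_values) -> list[GroupSummary]:
    """Per-(group, tracer) mean and SD of SUVR and CL.

    ``cl_values`` is an array-like of per-row Centiloid values aligned with
    ``table``.  Summaries are ordered by group then tracer, alphabetically.
    """
    cl = np.asarray(cl_values, dtype=float)
    if cl.shape[0] != len(table):
        raise ValueError(
            f"cl_values length {cl.shape[0]} does not match table "
            f"length {len(table)}"
        )
    work = table.copy()
    work["_cl"] = cl
    out = []
    for (group, tracer), sub in sorted(work.groupby(["group", "tracer"]),
                                       key=lambda kv: kv[0]):
        suvr = sub["suvr"].to_numpy(dtype=float)
        clv = sub["_cl"].to_numpy(dtype=float)
        out.append(
            GroupSummary(
                group=group,
                tracer=tracer,
                n=len(sub),
                mean_suvr=float(suvr.mean()),
                sd_suvr=_sd(suvr),
                mean_cl=float(clv.mean()),
                sd_cl=_sd(clv),
            )
        )
    return out


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def variance_ratio(cl_tracer, cl_pib) -> float:
    """SD(tracer CL) / SD(PiB CL) in the same group, sample SDs.

    Values near 1 mean the F-18 tracer adds little scale noise over PiB
    in amyloid-negative controls.
    """
    a = np.asarray(cl_tracer, dtype=float)
    b = np.asarray(cl_pib, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per vector")
    sd_pib = np.std(b, ddof=1)
    if sd_pib == 0:
        raise ValueError("PiB CL values have zero SD; ratio undefined")
    return float(np.std(a, ddof=1) / sd_pib)


@dataclass(frozen=True)
class TestRetestResult:
    """Signed per-subject % differences for SUVR, SUVR-1 and CL."""

    subject_ids: list[str]
    pct_diff_suvr: np.ndarray
    pct_diff_suvr_minus1: np.ndarray
    pct_diff_cl: np.ndarray

    def _stats(self, values: np.ndarray) -> tuple[float, float]:
        return float(np.nanmean(values)), float(np.nanstd(values, ddof=1))

    def summary(self) -> pd.DataFrame:
        """Mean and SD of the signed % differences, one row per measure."""
        rows = []
        for measure, vals in [
            ("SUVR", self.pct_diff_suvr),
            ("SUVR-1", self.pct_diff_suvr_minus1),
            ("CL", self.pct_diff_cl),
        ]:
            mean, sd = self._stats(vals)
            rows.append({"measure": measure, "mean_pct_diff": mean,
                         "sd_pct_diff": sd, "n": len(self.subject_ids)})
        return pd.DataFrame(rows)

    def per_subject(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "pct_diff_suvr": self.pct_diff_suvr,
                "pct_diff_suvr_minus1": self.pct_diff_suvr_minus1,
                "pct_diff_cl": self.pct_diff_cl,
            }
        )


def _pct_diff(test: np.ndarray, retest: np.ndarray,
              denominator: str) -> np.ndarray:
    if denominator == "test":
        denom = test
    elif denominator == "mean":
        denom = (test + retest) / 2.0
    else:
        raise ValueError(f"denominator must be 'test' or 'mean', got {denominator!r}")
    out = np.full(test.shape, np.nan)
    nonzero = denom != 0
    out[nonzero] = 100.0 * (retest[nonzero] - test[nonzero]) / denom[nonzero]
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} subject(s) have a zero denominator; "
            "their % difference is NaN",
            stacklevel=3,
        )
    return out


def test_retest(test: pd.DataFrame, retest: pd.DataFrame,
                conversion: LinearMap,
                denominator: str = "test") -> TestRetestResult:
    """Per-subject signed % difference between test and retest scans.

    For each subject: 100*(retest - test)/test, applied to the raw SUVR, to
    SUVR-1, and to the Centiloid values obtained through ``conversion``
    (a tracer SUVR -> CL map).  Both tables must contain exactly the same
    subjects.
    """
    t = test.set_index("subject_id")["suvr"]
    r = retest.set_index("subject_id")["suvr"]
    only_t = set(t.index) - set(r.index)
    only_r = set(r.index) - set(t.index)
    if only_t or only_r:
        raise ValueError(
            "subject sets differ between test and retest: "
            f"test-only={sorted(only_t)}, retest-only={sorted(only_r)}"
        )
    ids = list(t.index)
    tv = t.to_numpy(dtype=float)
    rv = r.loc[ids].to_numpy(dtype=float)
    return TestRetestResult(
        subject_ids=ids,
        pct_diff_suvr=_pct_diff(tv, rv, denominator),
        pct_diff_suvr_minus1=_pct_diff(tv - 1.0, rv - 1.0, denominator),
        pct_diff_cl=_pct_diff(np.asarray(conversion(tv)),
                              np.asarray(conversion(rv)), denominator),
    )
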