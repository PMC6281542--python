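"""Centiloid Level-2 calibration mathematics.

The Centiloid (CL) scale is a linear rescaling of PiB SUVR anchored so that
amyloid-negative young controls average 0 CL and typical mild-to-moderate AD
patients average 100 CL:

    CL = 100 * (SUVR_PiB - SUVR_YC0) / (SUVR_AD100 - SUVR_YC0)

A new F-18 tracer is calibrated against PiB by scanning the same subjects
with both tracers and fitting an ordinary-least-squares line

    SUVR_tracer = m * SUVR_PiB + b        (PiB as the independent variable)

Inverting the fit maps any tracer SUVR onto the PiB scale
("PiB-equivalent SUVR"), and composing that inversion with the anchor
transform yields a direct tracer-SUVR -> CL conversion equation, the main
deliverable of a Level-2 calibration.

Alternate processing pipelines (different software producing slightly
different CL values from the same scans) are reconciled by a further linear
standardization fit between paired CL values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearMap",
    "CentiloidAnchors",
    "TracerCalibration",
    "DEFAULT_ANCHORS",
    "fit_tracer_regression",
    "to_pib_calc",
    "suvr_to_centiloid",
    "derive_direct_conversion",
    "fit_standardization",
]


@dataclass(frozen=True)
class LinearMap:
    """An affine map y = slope * x + intercept."""

    slope: float
    intercept: float

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def inverse(self) -> "LinearMap":
        """The inverse map; requires a finite, nonzero slope."""
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError(f"map with slope {self.slope} is not invertible")
        return LinearMap(1.0 / self.slope, -self.intercept / self.slope)

    def rounded(self, ndigits: int = 2) -> "LinearMap":
        """Presentation-rounded copy; internal math stays full precision."""
        return LinearMap(round(self.slope, ndigits), round(self.intercept, ndigits))


@dataclass(frozen=True)
class CentiloidAnchors:
    """PiB SUVR values pinning the 0 and 100 points of the CL scale.

    ``suvr_yc0`` is the young-control group mean (0 CL), ``suvr_ad100`` the
    AD group mean (100 CL).  Defaults are the published GAAIN PiB group
    means, printed to two decimals; unrounded anchors can be supplied when
    available.
    """

    suvr_yc0: float = 1.01
    suvr_ad100: float = 2.08

    def __post_init__(self) -> None:
        if not (self.suvr_ad100 > self.suvr_yc0 > 0):
            raise ValueError(
                f"anchors must satisfy ad100 > yc0 > 0, got "
                f"({self.suvr_yc0}, {self.suvr_ad100})"
            )

    @property
    def span(self) -> float:
        return self.suvr_ad100 - self.suvr_yc0


DEFAULT_ANCHORS = CentiloidAnchors()


@dataclass
class TracerCalibration:
    """A fitted tracer-to-PiB calibration.

    ``pib_to_tracer`` holds the OLS fit SUVR_tracer = m * SUVR_PiB + b;
    ``direct_conversion`` (tracer SUVR -> CL) is populated once anchors are
    supplied via :func:`derive_direct_conversion`.
    """

    tracer: str
    pib_to_tracer: LinearMap
    r_squared: float
    n_subjects: int
    anchors: CentiloidAnchors | None = None
    direct_conversion: LinearMap | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"R^2 must be in [0, 1], got {self.r_squared}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")

    def to_dict(self) -> dict:
        d = {
            "tracer": self.tracer,
            "slope_m": self.pib_to_tracer.slope,
            "intercept_b": self.pib_to_tracer.intercept,
            "r_squared": self.r_squared,
            "n": self.n_subjects,
        }
        if self.anchors is not None:
            d["anchors"] = {"yc0": self.anchors.suvr_yc0,
                            "ad100": self.anchors.suvr_ad100}
        if self.direct_conversion is not None:
            d["direct"] = {"slope": self.direct_conversion.slope,
                           "intercept": self.direct_conversion.intercept}
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "TracerCalibration":
        anchors = None
        direct = None
        if "anchors" in d:
            anchors = CentiloidAnchors(d["anchors"]["yc0"], d["anchors"]["ad100"])
        if "direct" in d:
            direct = LinearMap(d["direct"]["slope"], d["direct"]["intercept"])
        return cls(
            tracer=d["tracer"],
            pib_to_tracer=LinearMap(d["slope_m"], d["intercept_b"]),
            r_squared=d["r_squared"],
            n_subjects=d["n"],
            anchors=anchors,
            direct_conversion=direct,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TracerCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _paired_suvrs(table: pd.DataFrame, tracer: str) -> pd.DataFrame:
    """Subjects with one PiB and one ``tracer`` SUVR each, paired by id."""
    pib = table[table["tracer"] == "PiB"][["subject_id", "suvr"]]
    trc = table[table["tracer"] == tracer][["subject_id", "suvr"]]
    pairs = pib.merge(trc, on="subject_id", suffixes=("_pib", "_tracer"))
    return pairs


def fit_tracer_regression(table: pd.DataFrame,
                          tracer: str = "flutemetamol") -> TracerCalibration:
    """OLS of tracer SUVR on PiB SUVR over subjects scanned with both.

    Pairing is by ``subject_id``; PiB is the independent variable.  The
    reported R^2 is the squared Pearson correlation of the pairs.

    Raises
    ------
    ValueError
        Fewer than 3 paired subjects, or zero variance in the PiB SUVRs.
    """
    pairs = _paired_suvrs(table, tracer)
    n = len(pairs)
    if n < 3:
        raise ValueError(
            f"need at least 3 subjects with both PiB and {tracer} scans, "
            f"found {n}"
        )
    x = pairs["suvr_pib"].to_numpy(dtype=float)
    y = pairs["suvr_tracer"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("PiB SUVRs have zero variance; cannot fit")
    fit = stats.linregress(x, y)
    return TracerCalibration(
        tracer=tracer,
        pib_to_tracer=LinearMap(float(fit.slope), float(fit.intercept)),
        r_squared=float(fit.rvalue) ** 2,
        n_subjects=n,
    )


def to_pib_calc(suvr_tracer, calib: TracerCalibration):
    """Map tracer SUVR(s) to PiB-equivalent SUVR by inverting the fit.

    PiB-Calc SUVR = (SUVR_tracer - b) / m.
    """
    m = calib.pib_to_tracer.slope
    if m == 0:
        raise ValueError("tracer calibration slope is zero; cannot invert")
    result = (np.asarray(suvr_tracer, dtype=float) - calib.pib_to_tracer.intercept) / m
    return float(result) if np.isscalar(suvr_tracer) else result


def suvr_to_centiloid(pib_suvr, anchors: CentiloidAnchors = DEFAULT_ANCHORS):
    """Anchor transform: CL = 100 * (SUVR - yc0) / (ad100 - yc0).

    Exact at the anchors: CL(yc0) = 0 and CL(ad100) = 100.
    """
    result = 100.0 * (np.asarray(pib_suvr, dtype=float) - anchors.suvr_yc0) / anchors.span
    return float(result) if np.isscalar(pib_suvr) else result


def derive_direct_conversion(calib: TracerCalibration,
                             anchors: CentiloidAnchors = DEFAULT_ANCHORS,
                             ) -> TracerCalibration:
    """Closed-form tracer-SUVR -> CL map, stored on a copy of the calibration.

    Composing PiB-equivalent conversion with the anchor transform gives

        slope     = 100 / (m * (ad100 - yc0))
        intercept = -(100 / (ad100 - yc0)) * (b / m + yc0)

    so ``direct(s) == suvr_to_centiloid(to_pib_calc(s))`` identically.
    """
    m = calib.pib_to_tracer.slope
    b = calib.pib_to_tracer.intercept
    if m == 0:
        raise ValueError("tracer calibration slope is zero; cannot invert")
    slope = 100.0 / (m * anchors.span)
    intercept = -(100.0 / anchors.span) * (b / m + anchors.suvr_yc0)
    return replace(
        calib,
        anchors=anchors,
        direct_conversion=LinearMap(slope, intercept),
    )


def fit_standardization(pipeline_cl: Sequence[float],
                        reference_cl: Sequence[float]) -> LinearMap:
    """Fit a pipeline-CL -> standard-CL correction map by OLS.

    ``reference_cl`` (the standard pipeline, e.g. SPM8) is regressed on
    ``pipeline_cl``; applying the returned map to pipeline values puts them
    on the standard scale.  The inverse direction is available via
    :meth:`LinearMap.inverse`.
    """
    x = np.asarray(pipeline_cl, dtype=float)
    y = np.asarray(reference_cl, dtype=float)
    if x.shape != y.shape:
        raise ValueError(
            f"length mismatch: {x.shape[0]} pipeline vs {y.shape[0]} reference"
        )
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("pipeline CL values have zero variance; cannot fit")
    fit = stats.linregress(x, y)
    return LinearMap(float(fit.slope), float(fit.intercept))
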