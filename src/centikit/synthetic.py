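"""Synthetic paired-tracer cohorts and 3-D brain phantoms.

Every stage of the calibration pipeline can be exercised without external
scan data.  Two generators are provided:

* :func:`simulate_cohort` draws a paired PiB + F-18 tracer SUVR cohort with
  the statistical structure of a typical Centiloid calibration study: an
  amyloid-negative young-control group tightly clustered near SUVR 1 and a
  mixed "other" group spanning the dynamic range, with the tracer responding
  linearly to PiB plus measurement noise.
* :func:`make_toy_atlas` / :func:`render_phantom` build abstract box-shaped
  VOI phantoms (a toy cortex over a toy cerebellum) whose ground-truth
  cortex/reference uptake ratio is known exactly, for end-to-end image tests.

Phantom geometry is deliberately abstract: the SUVR and calibration math is
geometry-agnostic, and anatomical VOI templates are external data.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import LinearMap
from .image_voi import SUVR_COLUMNS, VOIAtlas, VolumeGrid

#: Floor applied to simulated SUVRs; keeps tables valid under extreme noise
#: settings.  Never reached under the default noise levels.
SUVR_FLOOR = 0.05

__all__ = [
    "GroupModel",
    "CohortSpec",
    "PhantomSpec",
    "simulate_cohort",
    "simulate_test_retest",
    "make_toy_atlas",
    "render_phantom",
]


@dataclass(frozen=True)
class GroupModel:
    """Normal model for a group's true PiB SUVR, optionally left-truncated."""

    mean: float
    sd: float
    lower: float | None = None  # truncation bound, None = untruncated

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")
        if self.lower is not None and self.lower >= self.mean:
            raise ValueError("truncation bound must lie below the mean")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        if self.lower is None:
            return rng.normal(self.mean, self.sd, size=n)
        a = (self.lower - self.mean) / self.sd
        return stats.truncnorm.rvs(a, np.inf, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


def _default_groups() -> dict[str, GroupModel]:
    # Young controls cluster tightly around the amyloid-negative PiB level;
    # the mixed group spans the clinical SUVR range ~1.0-2.4.
    return {
        "YHC": GroupModel(mean=1.01, sd=0.065),
        "other": GroupModel(mean=1.57, sd=0.53, lower=0.85),
    }


def _default_sizes() -> dict[str, int]:
    return {"YHC": 24, "other": 50}


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a paired-tracer calibration cohort.

    Defaults emulate a 74-subject flutemetamol calibration study: 24 young
    healthy controls plus 50 mixed-diagnosis subjects, a linear tracer
    response SUVR_tracer = 0.77 * SUVR_PiB + 0.22, tracer measurement noise
    of 0.08 SUVR, and PiB measurement noise of 0.02 SUVR.
    """

    group_sizes: dict[str, int] = field(default_factory=_default_sizes)
    pib_suvr_model: dict[str, GroupModel] = field(default_factory=_default_groups)
    tracer_map: LinearMap = LinearMap(0.77, 0.22)
    tracer: str = "flutemetamol"
    tracer_noise_sd: float = 0.08
    pib_noise_sd: float = 0.02
    yhc_extra_noise_sd: float = 0.0  # raise to emulate a variance ratio > 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sd in [("tracer_noise_sd", self.tracer_noise_sd),
                         ("pib_noise_sd", self.pib_noise_sd),
                         ("yhc_extra_noise_sd", self.yhc_extra_noise_sd)]:
            if sd < 0:
                raise ValueError(f"{name} must be non-negative, got {sd}")
        for group, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {group!r} is negative")
            if n > 0 and group not in self.pib_suvr_model:
                raise ValueError(f"no SUVR model for group {group!r}")


def simulate_cohort(spec: CohortSpec = CohortSpec(),
                    ) -> tuple[pd.DataFrame, dict]:
    """Draw one paired cohort; returns (SUVR table, ground truth).

    Per subject: a true PiB SUVR is drawn from the group model; the observed
    PiB SUVR adds Normal(0, pib_noise_sd) measurement noise; the tracer SUVR
    is the linear map of the *true* PiB SUVR plus Normal(0, tracer_noise_sd)
    (plus group-specific extra noise for young controls).  The returned
    table has one PiB and one tracer row per subject; the ground-truth dict
    carries the true map and true SUVRs.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    for group in sorted(spec.group_sizes):
        n = spec.group_sizes[group]
        if n == 0:
            continue
        true_pib = spec.pib_suvr_model[group].sample(n, rng)
        obs_pib = true_pib + rng.normal(0, spec.pib_noise_sd, n) \
            if spec.pib_noise_sd > 0 else true_pib.copy()
        noise_sd = spec.tracer_noise_sd
        tracer = np.asarray(spec.tracer_map(true_pib))
        if noise_sd > 0:
            tracer = tracer + rng.normal(0, noise_sd, n)
        if group == "YHC" and spec.yhc_extra_noise_sd > 0:
            tracer = tracer + rng.normal(0, spec.yhc_extra_noise_sd, n)
        obs_pib = np.maximum(obs_pib, SUVR_FLOOR)
        tracer = np.maximum(tracer, SUVR_FLOOR)
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            rows.append((sid, group, "PiB", "single", obs_pib[i]))
            rows.append((sid, group, spec.tracer, "single", tracer[i]))
            truth_rows.append((sid, group, true_pib[i]))
    table = pd.DataFrame(rows, columns=SUVR_COLUMNS)
    truth = {
        "true_map": {"slope": spec.tracer_map.slope,
                     "intercept": spec.tracer_map.intercept},
        "true_pib_suvr": pd.DataFrame(
            truth_rows, columns=["subject_id", "group", "true_pib_suvr"]
        ),
        "seed": spec.seed,
    }
    return table, truth


def simulate_test_retest(n_subjects: int = 10,
                         base_mean: float = 1.80,
                         base_sd: float = 0.18,
                         retest_noise_sd: float = 0.02,
                         tracer: str = "flutemetamol",
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired test/retest scans for an AD repeatability cohort.

    Test SUVRs are drawn from Normal(base_mean, base_sd); retest adds
    Normal(0, retest_noise_sd) scan-rescan noise.  Defaults emulate a
    10-subject AD cohort centred at SUVR 1.80 (SD 0.18).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    test_suvr = np.maximum(rng.normal(base_mean, base_sd, n_subjects),
                           SUVR_FLOOR)
    retest_suvr = test_suvr + (
        rng.normal(0, retest_noise_sd, n_subjects) if retest_noise_sd > 0
        else 0.0
    )
    retest_suvr = np.maximum(retest_suvr, SUVR_FLOOR)
    ids = [f"TRT{i + 1:03d}" for i in range(n_subjects)]
    test = pd.DataFrame(
        {"subject_id": ids, "group": "AD", "tracer": tracer,
         "session": "test", "suvr": test_suvr}, columns=SUVR_COLUMNS)
    retest = pd.DataFrame(
        {"subject_id": ids, "group": "AD", "tracer": tracer,
         "session": "retest", "suvr": retest_suvr}, columns=SUVR_COLUMNS)
    return test, retest


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model for a toy VOI phantom.

    A toy cortex slab occupies the upper half of the grid and the reference
    regions (toy whole cerebellum, plus any extras such as cerebellar grey
    or pons) sit in disjoint boxes in the lower band.  ``voxel_noise_sd`` is
    a fraction of each region's mean uptake.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    reference_uptake: float = 10.0  # arbitrary activity units
    voxel_noise_sd: float = 0.02    # fraction of the regional mean
    background_fraction: float = 0.05
    extra_reference_regions: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_uptake <= 0:
            raise ValueError("reference uptake must be positive")
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel noise SD must be non-negative")


MIN_REGION_VOXELS = 50


def make_toy_atlas(spec: PhantomSpec = PhantomSpec()) -> VOIAtlas:
    """Build disjoint CTX and WC masks (plus optional extra references).

    Raises when the grid is too small to hold every requested region with
    at least 50 voxels.
    """
    nx, ny, nz = spec.grid_shape
    regions: dict[str, np.ndarray] = {}

    ctx = np.zeros(spec.grid_shape, dtype=bool)
    ctx[nx // 4: 3 * nx // 4, ny // 4: 3 * ny // 4, nz // 2: nz - 2] = True
    regions["CTX"] = ctx

    # Lower band split into side-by-side slots: WC first, extras after.
    names = ["WC", *spec.extra_reference_regions]
    z0, z1 = 2, nz // 4
    y0, y1 = ny // 4, 3 * ny // 4
    x_lo, x_hi = 2, nx - 2
    k = len(names)
    span = x_hi - x_lo
    width = (span - (k - 1)) // k  # 1-voxel gaps between slots
    for i, name in enumerate(names):
        xa = x_lo + i * (width + 1)
        box = np.zeros(spec.grid_shape, dtype=bool)
        box[xa: xa + width, y0: y1, z0: z1] = True
        regions[name] = box

    for name, mask in regions.items():
        if mask.sum() < MIN_REGION_VOXELS:
            raise ValueError(
                f"grid {spec.grid_shape} too small: region {name!r} has "
                f"{int(mask.sum())} voxels (< {MIN_REGION_VOXELS})"
            )
    stacked = np.stack(list(regions.values()))
    if (stacked.sum(axis=0) > 1).any():
        raise AssertionError("internal error: phantom regions overlap")
    return VOIAtlas(grid_shape=spec.grid_shape, regions=regions,
                    affine=np.eye(4))


def render_phantom(target_suvr: float,
                   spec: PhantomSpec = PhantomSpec(),
                   atlas: VOIAtlas | None = None,
                   rng: np.random.Generator | None = None) -> VolumeGrid:
    """Render a phantom whose true cortex/reference uptake ratio is known.

    Cortex voxels are Normal(target_suvr * reference_uptake, noise); every
    reference region is Normal(reference_uptake, noise); the background is a
    low constant.  With zero noise, ``compute_suvr`` recovers ``target_suvr``
    exactly.
    """
    if not target_suvr > 0:
        raise ValueError(f"target SUVR must be positive, got {target_suvr}")
    if atlas is None:
        atlas = make_toy_atlas(spec)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ref = spec.reference_uptake
    vox = np.full(spec.grid_shape, spec.background_fraction * ref)
    for name, mask in atlas.regions.items():
        mean = target_suvr * ref if name == "CTX" else ref
        n = int(mask.sum())
        if spec.voxel_noise_sd > 0:
            vox[mask] = rng.normal(mean, spec.voxel_noise_sd * mean, n)
        else:
            vox[mask] = mean
    return VolumeGrid(voxels=vox, affine=np.eye(4))
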