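"""Template-space PET volumes, VOI atlases and SUVR computation.

All images are assumed to live on a single common template grid (e.g. the
MNI-152 grid used by the standard Centiloid VOIs).  Spatial normalization,
registration and resampling are deliberately out of scope: a shape mismatch
between a volume and the atlas is a hard error, never silently interpolated.

The standardized uptake value ratio (SUVR) of a scan is the mean uptake in a
target region (typically the cortical composite, ``CTX``) divided by the mean
uptake in a reference region (typically the whole cerebellum, ``WC``).  SUVR
is dimensionless and invariant under global rescaling of the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "VOIAtlas",
    "SUVRRecord",
    "BatchResult",
    "load_volume",
    "load_atlas",
    "save_mask",
    "regional_mean",
    "compute_suvr",
    "batch_suvr",
    "read_suvr_table",
    "write_suvr_table",
]

#: Voxels with values strictly above this threshold count as in-mask.
#: Handles VOI maps distributed as probabilistic rather than binary images.
MASK_THRESHOLD = 0.5

#: Fraction of non-finite in-mask voxels above which a warning is emitted.
NONFINITE_WARN_FRACTION = 0.01

#: Maximum element-wise affine discrepancy tolerated silently.
AFFINE_ATOL = 1e-3

SUVR_COLUMNS = ["subject_id", "group", "tracer", "session", "suvr"]

GROUPS = ("YHC", "OHC", "aMCI", "AD", "other")
SESSIONS = ("test", "retest", "single")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar uptake image on a fixed template grid.

    Parameters
    ----------
    voxels
        3-D array of uptake values in arbitrary activity units.
    voxel_size_mm
        Physical voxel edge lengths, all strictly positive.
    affine
        Optional 4x4 voxel-to-world matrix carried along from the NIfTI
        header; used only for a cheap mis-registration guard.
    """

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {vox.ndim}-D")
        if not np.isfinite(vox).any():
            raise ValueError("volume contains no finite voxel")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive: {self.voxel_size_mm}")
        object.__setattr__(self, "voxels", vox)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class VOIAtlas:
    """Named binary VOI masks sharing one grid.

    Typical regions are the Centiloid cortical composite (``CTX``) and the
    whole-cerebellum reference (``WC``); additional reference regions such as
    cerebellar grey or pons can coexist in the same atlas.
    """

    grid_shape: tuple[int, int, int]
    regions: Mapping[str, np.ndarray]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        regions = {}
        for name, mask in self.regions.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(
                    f"mask {name!r} has shape {mask.shape}, "
                    f"atlas grid is {tuple(self.grid_shape)}"
                )
            if not mask.any():
                raise ValueError(f"mask {name!r} is empty")
            regions[name] = mask
        object.__setattr__(self, "regions", regions)
        object.__setattr__(self, "grid_shape", tuple(self.grid_shape))

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def __getitem__(self, name: str) -> np.ndarray:
        return self.regions[name]

    @property
    def names(self) -> list[str]:
        return list(self.regions)


@dataclass(frozen=True)
class SUVRRecord:
    """One SUVR measurement: subject x tracer x session, with a group label."""

    subject_id: str
    group: str
    tracer: str
    session: str
    suvr: float

    def __post_init__(self) -> None:
        if not self.suvr > 0:
            raise ValueError(f"SUVR must be positive, got {self.suvr}")


@dataclass
class BatchResult:
    """Outcome of a batch SUVR run: the table plus per-scan failures."""

    table: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _as_volume(source) -> VolumeGrid:
    """Accept a VolumeGrid, an ndarray, or a NIfTI path."""
    if isinstance(source, VolumeGrid):
        return source
    if isinstance(source, (str, Path)):
        return load_volume(source)
    arr = np.asarray(source, dtype=float)
    return VolumeGrid(voxels=arr)


def load_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI-1 volume (.nii or .nii.gz, gzip autodetected by suffix)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(voxels=data, voxel_size_mm=tuple(float(z) for z in zooms),
                      affine=np.asarray(img.affine))


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    affine = volume.affine
    if affine is None:
        affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def save_mask(mask: np.ndarray, path: str | Path,
              affine: np.ndarray | None = None) -> None:
    """Write a binary mask as NIfTI (uint8, 0/1)."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def load_atlas(mask_sources: Iterable[tuple[str, object]]) -> VOIAtlas:
    """Build a VOI atlas from named mask sources.

    Each source may be a path to a NIfTI mask, an array, or a VolumeGrid.
    Voxels with value > 0.5 are treated as in-mask, so probabilistic maps
    are binarized at the halfway point.

    Raises
    ------
    ValueError
        If mask shapes disagree (both shapes are named) or a mask is empty.
    """
    regions: dict[str, np.ndarray] = {}
    shape: tuple[int, ...] | None = None
    first_name = ""
    affine = None
    for name, source in mask_sources:
        if name in regions:
            raise ValueError(f"duplicate region name {name!r}")
        vol = _as_volume(source)
        if shape is None:
            shape, first_name, affine = vol.shape, name, vol.affine
        elif vol.shape != shape:
            raise ValueError(
                f"mask {name!r} has shape {vol.shape} but mask "
                f"{first_name!r} has shape {shape}"
            )
        mask = vol.voxels > MASK_THRESHOLD
        if not mask.any():
            raise ValueError(f"mask {name!r} is empty after thresholding")
        regions[name] = mask
    if shape is None:
        raise ValueError("no mask sources given")
    return VOIAtlas(grid_shape=shape, regions=regions, affine=affine)


def regional_mean(volume: VolumeGrid | np.ndarray, mask: np.ndarray) -> float:
    """Mean uptake over the in-mask voxels, ignoring non-finite values.

    A warning is emitted when more than 1% of in-mask voxels are non-finite;
    an empty mask, or a mask whose in-mask voxels are all non-finite, is an
    error (it signals corrupt input, not noise).
    """
    vol = _as_volume(volume)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {vol.shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    values = vol.voxels[mask]
    finite = np.isfinite(values)
    n_bad = int((~finite).sum())
    if n_bad == values.size:
        raise ValueError("all in-mask voxels are non-finite")
    if n_bad / values.size > NONFINITE_WARN_FRACTION:
        warnings.warn(
            f"{n_bad}/{values.size} in-mask voxels are non-finite and were "
            "excluded from the regional mean",
            stacklevel=2,
        )
    return float(values[finite].mean())


def _check_affines(a: np.ndarray | None, b: np.ndarray | None, what: str) -> None:
    if a is None or b is None:
        return
    if not np.allclose(a, b, atol=AFFINE_ATOL, rtol=0):
        warnings.warn(
            f"affine headers of {what} differ by more than {AFFINE_ATOL}; "
            "volumes may not be co-registered with the atlas",
            stacklevel=3,
        )


def compute_suvr(volume: VolumeGrid | np.ndarray, atlas: VOIAtlas,
                 target: str = "CTX", reference: str = "WC") -> float:
    """SUVR = mean(target) / mean(reference) on a template-space volume.

    Raises if either region is missing from the atlas or the reference mean
    is non-positive (which would indicate corrupt input).
    """
    vol = _as_volume(volume)
    for name in (target, reference):
        if name not in atlas:
            raise KeyError(
                f"region {name!r} not in atlas (available: {atlas.names})"
            )
    if vol.shape != atlas.grid_shape:
        raise ValueError(
            f"volume shape {vol.shape} does not match atlas grid "
            f"{atlas.grid_shape}"
        )
    _check_affines(vol.affine, atlas.affine, "volume and atlas")
    ref_mean = regional_mean(vol, atlas[reference])
    if ref_mean <= 0:
        raise ValueError(
            f"reference region {reference!r} has non-positive mean "
            f"({ref_mean:g}); input is likely corrupt"
        )
    return regional_mean(vol, atlas[target]) / ref_mean


def batch_suvr(
    scans: Sequence[tuple[Mapping[str, str], object]],
    atlas: VOIAtlas,
    target: str = "CTX",
    reference: str = "WC",
) -> BatchResult:
    """Compute SUVRs for a list of (metadata, volume-source) scans.

    Failures are collected per scan (subject_id, message) rather than
    aborting the whole batch; successful rows keep the input order.
    ``metadata`` must carry subject_id, group, tracer and session keys.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    for meta, source in scans:
        sid = str(meta.get("subject_id", "<unknown>"))
        try:
            suvr = compute_suvr(_as_volume(source), atlas, target, reference)
            rows.append(
                {
                    "subject_id": sid,
                    "group": meta.get("group", "other"),
                    "tracer": meta.get("tracer", "other"),
                    "session": meta.get("session", "single"),
                    "suvr": suvr,
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-scan isolation is the point
            failures.append((sid, str(exc)))
    table = pd.DataFrame(rows, columns=SUVR_COLUMNS)
    return BatchResult(table=table, failures=failures)


def validate_suvr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check SUVR-table structure: columns, positive SUVRs, unique keys."""
    missing = [c for c in SUVR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"SUVR table missing columns: {missing}")
    if len(table) and not (table["suvr"] > 0).all():
        bad = table.loc[~(table["suvr"] > 0), "subject_id"].tolist()
        raise ValueError(f"non-positive SUVR for subjects: {bad}")
    keys = table[["subject_id", "tracer", "session"]]
    if keys.duplicated().any():
        dup = table.loc[keys.duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate (subject, tracer, session) rows: {dup}")
    return table


def read_suvr_table(path: str | Path) -> pd.DataFrame:
    """Read a SUVR table CSV (subject_id,group,tracer,session,suvr)."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    return validate_suvr_table(table)


def write_suvr_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a SUVR table as CSV with SUVRs to 6 decimal places."""
    validate_suvr_table(table)
    out = table.copy()
    out["suvr"] = out["suvr"].map(lambda v: f"{v:.6f}")
    out[SUVR_COLUMNS].to_csv(path, index=False)
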