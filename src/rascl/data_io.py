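"""Reading, writing and validating B-scan volumes and dataset manifests.

A *B-scan volume* is the ordered stack of parallel OCT cross-sections of one
eye, stored on disk as a multi-page grayscale TIFF.  The *manifest* is a CSV
table with one row per eye carrying the diagnosis label and the covariates
used for stratified splitting.  The manifest, not filename conventions, is
authoritative for the central-slice index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .exceptions import DomainError, FormatError

#: canonical manifest schema, in column order
MANIFEST_COLUMNS = [
    "eye_id",
    "patient_id",
    "laterality",
    "diagnosis",
    "age",
    "sex",
    "preop_vision",
    "n_slices",
    "central_slice_index",
    "slice_spacing_um",
    "path",
]

DIAGNOSES = ("FTMH", "ERM", "LAMELLAR")

#: Spectralis export pixel size (axial, lateral) in micrometers
DEFAULT_PIXEL_SIZE_UM = (3.87, 11.38)


@dataclass
class BScanVolume:
    """Ordered grayscale slice stack for one eye.

    ``slices`` is an ``(n, H, W)`` float array with intensities in [0, 1];
    slice order follows acquisition (= TIFF page) order.
    """

    eye_id: str
    slices: np.ndarray
    central_slice_index: int
    slice_spacing_um: float
    pixel_size_um: tuple[float, float] = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise DomainError(f"slices must be a 3-D stack, got ndim={self.slices.ndim}")
        n = self.slices.shape[0]
        if not (0 <= int(self.central_slice_index) < n):
            raise DomainError(
                f"central_slice_index {self.central_slice_index} out of range for {n} slices"
            )
        lo, hi = float(self.slices.min(initial=0.0)), float(self.slices.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise DomainError(f"intensities outside [0,1]: range [{lo}, {hi}]")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.slices.shape[1:])


def read_volume(
    path: str | Path,
    central_index: int,
    spacing: float,
    eye_id: str | None = None,
) -> BScanVolume:
    """Load a single- or multi-page grayscale TIFF as a volume.

    Integer pixel types are rescaled to [0, 1] by dividing by the dtype
    maximum; float pages are required to already lie in [0, 1].  Page order
    is preserved as slice order.  Color pages are rejected rather than
    converted: silent luminance conversion could distort intensities.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except Exception as exc:  # noqa: BLE001 - rewrap any reader failure
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path}: no pages")
    slices = []
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"{path}: page {i} is not grayscale (shape {page.shape})")
        if page.shape != shape0:
            raise FormatError(
                f"{path}: page {i} shape {page.shape} differs from page 0 shape {shape0}"
            )
        if np.issubdtype(page.dtype, np.integer):
            arr = page.astype(np.float64) / float(np.iinfo(page.dtype).max)
        else:
            arr = page.astype(np.float64)
            if arr.min(initial=0.0) < 0 or arr.max(initial=0.0) > 1:
                raise FormatError(f"{path}: page {i} float intensities outside [0,1]")
        slices.append(arr)
    return BScanVolume(
        eye_id=eye_id if eye_id is not None else path.stem,
        slices=np.stack(slices),
        central_slice_index=int(central_index),
        slice_spacing_um=float(spacing),
    )


def write_volume(volume: BScanVolume, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a volume as a multi-page grayscale TIFF (lossless up to quantization)."""
    if bit_depth not in (8, 16):
        raise DomainError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    maxval = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    data = np.round(np.clip(volume.slices, 0.0, 1.0) * maxval).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Manifests


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"eye_id": str, "patient_id": str, "path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns: {missing}")
    return df[MANIFEST_COLUMNS]


@dataclass
class Cohort:
    """In-memory dataset: manifest rows plus their loaded volumes."""

    manifest: pd.DataFrame
    volumes: dict[str, BScanVolume]

    def subset(self, eye_ids: Iterable[str]) -> "Cohort":
        ids = list(eye_ids)
        sub = self.manifest[self.manifest["eye_id"].isin(ids)].reset_index(drop=True)
        return Cohort(sub, {e: self.volumes[e] for e in sub["eye_id"]})

    @property
    def eye_ids(self) -> list[str]:
        return list(self.manifest["eye_id"])

    def __len__(self) -> int:
        return len(self.manifest)


def load_cohort(manifest_path: str | Path, root: str | Path | None = None) -> Cohort:
    """Load every volume referenced by a manifest CSV."""
    manifest = read_manifest(manifest_path)
    root = Path(root) if root is not None else Path(manifest_path).parent
    volumes = {}
    for row in manifest.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        volumes[row.eye_id] = read_volume(
            p, int(row.central_slice_index), float(row.slice_spacing_um), eye_id=row.eye_id
        )
    return Cohort(manifest, volumes)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Dataset integrity findings; an empty report means the dataset is usable."""

    entries: list[dict] = field(default_factory=list)

    def add(self, kind: str, eye_id: str, detail: str) -> None:
        self.entries.append({"kind": kind, "eye_id": eye_id, "detail": detail})

    @property
    def ok(self) -> bool:
        return not self.entries

    def __len__(self) -> int:
        return len(self.entries)


def validate_dataset(manifest: pd.DataFrame, root: str | Path) -> ValidationReport:
    """Check files, shapes, central indices, id uniqueness and patient-eye counts.

    Problems are report entries, never exceptions, so one pass reports every
    issue in a dataset.
    """
    root = Path(root)
    report = ValidationReport()

    dup = manifest["eye_id"][manifest["eye_id"].duplicated()]
    for e in dup.unique():
        report.add("duplicate_eye_id", str(e), "eye_id appears more than once")
    per_patient = manifest.groupby("patient_id")["eye_id"].nunique()
    for pid, n in per_patient.items():
        if n > 2:
            report.add("patient_eye_count", str(pid), f"patient has {n} eyes (max 2)")

    for row in manifest.itertuples():
        eye = str(row.eye_id)
        if row.diagnosis not in DIAGNOSES:
            report.add("bad_diagnosis", eye, f"unknown diagnosis {row.diagnosis!r}")
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        if not p.exists():
            report.add("missing_file", eye, f"file not found: {p}")
            continue
        try:
            vol = read_volume(p, 0, float(row.slice_spacing_um), eye_id=eye)
        except (FormatError, DomainError) as exc:
            report.add("unreadable", eye, str(exc))
            continue
        if vol.n_slices != int(row.n_slices):
            report.add(
                "slice_count_mismatch",
                eye,
                f"manifest says {row.n_slices} slices, file has {vol.n_slices}",
            )
        if not (0 <= int(row.central_slice_index) < vol.n_slices):
            report.add(
                "central_index_out_of_range",
                eye,
                f"central_slice_index {row.central_slice_index} not in [0, {vol.n_slices})",
            )
    return report
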