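"""Readers and writers: images (PNG / NIfTI / DICOM), annotations, cohorts, reports.

Scout images are grayscale in [0, 1] on a 16-bit grid, so the PNG
round-trip is lossless. DICOM input is read-only and enforces the
cohort inclusion rule: scout views whose row pixel spacing differs from
1.0 mm are rejected. Annotations travel as JSON or flat CSV records
``{case_id, start_row, end_row, reference_row}``; both readers validate
the region invariants and report every offending case id.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import AnnotationSource, Region, RegionAnnotation, ScoutImage
from .phantom import PhantomCase, PhantomParams

__all__ = [
    "AnnotationValidationError",
    "read_scout_image",
    "write_scout_image",
    "read_dicom_scout",
    "read_annotations",
    "write_annotations",
    "write_cohort",
    "read_cohort",
    "write_predictions",
    "read_predictions",
    "write_evaluation_report",
]

DICOM_SPACING_MM = 1.0
DICOM_SPACING_TOL = 1e-3


class AnnotationValidationError(ValueError):
    """Raised with the full list of invalid annotation records."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid annotations:\n" + "\n".join(problems))


# ------------------------------------------------------------------ images


def write_scout_image(image: ScoutImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".png":
        data = np.rint(np.clip(image.pixels, 0.0, 1.0) * 65535.0).astype(np.uint16)
        iio.imwrite(path, data)
    elif path.suffix in (".nii", ".gz"):
        img = nib.Nifti1Image(image.pixels.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((image.row_spacing_mm, 1.0))
        nib.save(img, path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def read_scout_image(
    path: str | Path, row_spacing_mm: float = 1.0, case_id: str | None = None
) -> ScoutImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".png":
        data = iio.imread(path)
        if data.ndim == 3:  # collapse any accidental RGB
            data = data[..., 0]
        pixels = data.astype(np.float32) / 65535.0
    elif path.suffix in (".nii", ".gz"):
        img = nib.load(path)
        pixels = np.asarray(img.dataobj, dtype=np.float32)
        row_spacing_mm = float(img.header.get_zooms()[0])
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return ScoutImage(pixels, row_spacing_mm, case_id or path.stem)


def read_dicom_scout(path: str | Path, case_id: str | None = None) -> ScoutImage:
    """Read a DICOM scout view, enforcing the 1.0 mm row-spacing inclusion rule."""
    import pydicom

    ds = pydicom.dcmread(path)
    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is None:
        raise OSError(f"{path}: no pixel spacing metadata")
    row_spacing = float(spacing[0])
    if abs(row_spacing - DICOM_SPACING_MM) > DICOM_SPACING_TOL:
        raise ValueError(
            f"{path}: row pixel spacing {row_spacing} mm violates the inclusion "
            f"rule (scout views must have {DICOM_SPACING_MM} mm spacing)"
        )
    pixels = ds.pixel_array.astype(np.float32)
    peak = pixels.max()
    if peak > 0:
        pixels = pixels / peak
    return ScoutImage(pixels, row_spacing, case_id or str(getattr(ds, "SOPInstanceUID", path)))


# -------------------------------------------------------------- annotations


def _annotation_from_record(rec: dict) -> tuple[str, RegionAnnotation]:
    region = Region(int(rec["start_row"]), int(rec["end_row"]))
    ann = RegionAnnotation(region, int(rec["reference_row"]), AnnotationSource.GROUND_TRUTH)
    return str(rec["case_id"]), ann


def _load_records(records: list[dict]) -> dict[str, RegionAnnotation]:
    out: dict[str, RegionAnnotation] = {}
    problems: list[str] = []
    for rec in records:
        try:
            case_id, ann = _annotation_from_record(rec)
            if case_id in out:
                raise ValueError("duplicate case_id")
            out[case_id] = ann
        except (KeyError, ValueError) as exc:
            problems.append(f"case {rec.get('case_id', '?')}: {exc}")
    if problems:
        raise AnnotationValidationError(problems)
    return out


def read_annotations(path: str | Path) -> dict[str, RegionAnnotation]:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    elif path.suffix == ".csv":
        records = pd.read_csv(path).to_dict("records")
    else:
        raise ValueError(f"unsupported annotation format: {path.suffix}")
    return _load_records(records)


def write_annotations(annotations: dict[str, RegionAnnotation], path: str | Path) -> None:
    path = Path(path)
    records = [
        {
            "case_id": case_id,
            "start_row": ann.region.start_row,
            "end_row": ann.region.end_row,
            "reference_row": ann.reference_row,
        }
        for case_id, ann in annotations.items()
    ]
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1))
    elif path.suffix == ".csv":
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported annotation format: {path.suffix}")


# ------------------------------------------------------------------ cohorts


def write_cohort(
    cases: list[PhantomCase],
    directory: str | Path,
    params: PhantomParams | None = None,
    seed: int | None = None,
    image_format: str = "png",
) -> None:
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    annotations = {}
    for case in cases:
        write_scout_image(case.image, directory / "images" / f"{case.image.case_id}.{image_format}")
        annotations[case.image.case_id] = case.annotation
    write_annotations(annotations, directory / "annotations.csv")
    manifest = {
        "n_cases": len(cases),
        "seed": seed,
        "image_format": image_format,
        "params": None if params is None else params.__dict__,
        "pulmotrunk_version": __version__,
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_cohort(directory: str | Path) -> list[PhantomCase]:
    directory = Path(directory)
    annotations = read_annotations(directory / "annotations.csv")
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    spacing = 1.0
    if manifest.get("params"):
        spacing = float(manifest["params"].get("row_spacing_mm", 1.0))
    fmt = manifest.get("image_format", "png")
    cases = []
    for case_id, ann in annotations.items():
        image = read_scout_image(directory / "images" / f"{case_id}.{fmt}", spacing, case_id)
        cases.append(PhantomCase(image, ann, dict(manifest.get("params") or {})))
    return cases


# ---------------------------------------------------------------- reports


def write_predictions(rows: list[dict], path: str | Path) -> None:
    """Rows: {case_id, selected_row, start_row?, end_row?}."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"case_id", "selected_row"} - set(df.columns)
    if missing:
        raise ValueError(f"predictions file lacks columns: {sorted(missing)}")
    return df


def write_evaluation_report(report: dict[str, "object"], path: str | Path) -> None:
    """One row per method; CSV plus a human-readable .txt alongside."""
    path = Path(path)
    rows = []
    for method, ev in report.items():
        rows.append(
            {
                "method": method,
                "n": ev.n,
                "n_errors": ev.n_errors,
                "accuracy_pct": ev.accuracy_pct,
                "error_distance_mean_mm": None if ev.error_distance_mm is None else ev.error_distance_mm[0],
                "error_distance_sd_mm": None if ev.error_distance_mm is None else ev.error_distance_mm[1],
                "reference_distance_mean_mm": ev.reference_distance_mm[0],
                "reference_distance_sd_mm": ev.reference_distance_mm[1],
                "iou_mean": None if ev.iou is None else ev.iou[0],
                "iou_sd": None if ev.iou is None else ev.iou[1],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    lines = [df.to_string(index=False)]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
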