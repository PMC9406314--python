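"""Reading and writing of all on-disk representations.

Formats:

* cohort manifest — one JSON document listing patients with explicit class
  labels; voxel data inline, in a per-patient delimited file, or as an
  ADC map + VOI mask NIfTI pair (paths relative to the manifest);
* per-patient voxel tables — CSV/TSV, one ADC value per row;
* ADC maps and VOI masks — NIfTI (``.nii`` / ``.nii.gz``) via nibabel;
* histograms — TSV with columns ``bin_left_edge``, ``bin_right_edge``,
  ``count``;
* fitted references, mean-threshold models and metric reports — JSON with
  stable key order so identical inputs produce byte-identical files.

ADC values are standardized internally to 10^-6 mm^2/s. A manifest may
declare ``"adc_units": "1e-3 mm^2/s"``; its values are then scaled by 1000
on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .binning import CLASSES, BinningScheme, Histogram
from .errors import ValidationError

_UNIT_FACTORS = {"1e-6 mm^2/s": 1.0, "1e-3 mm^2/s": 1000.0}


@dataclass(frozen=True, eq=False)
class PatientSample:
    """One lesion's voxel-level ADC values plus identity and true class.

    ``voxels`` are in units of 10^-6 mm^2/s, finite, non-negative and
    non-empty; ``true_class`` is one of PA, WT, MT.
    """

    patient_id: str
    true_class: str
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64).ravel()
        object.__setattr__(self, "voxels", v)
        if not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        if self.true_class not in CLASSES:
            raise ValidationError(
                f"unknown class {self.true_class!r} for patient {self.patient_id!r}; "
                f"expected one of {CLASSES}"
            )
        if v.size == 0:
            raise ValidationError(f"patient {self.patient_id!r} has no voxel values")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"patient {self.patient_id!r} has non-finite voxels")
        if np.any(v < 0):
            raise ValidationError(f"patient {self.patient_id!r} has negative voxels")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientSample):
            return NotImplemented
        return (self.patient_id == other.patient_id
                and self.true_class == other.true_class
                and np.array_equal(self.voxels, other.voxels))


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of patients with unique ids."""

    samples: tuple

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        ids = [s.patient_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dupes}")

    @property
    def class_counts(self) -> dict:
        counts = {c: 0 for c in CLASSES}
        for s in self.samples:
            counts[s.true_class] += 1
        return counts

    @property
    def true_classes(self) -> dict:
        return {s.patient_id: s.true_class for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


# ---------------------------------------------------------------------------
# voxel sources

def read_voxel_table(path: str | Path) -> np.ndarray:
    """Read a one-value-per-row CSV/TSV of ADC values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    sep = "," if "," in text else None  # one value per row; tolerate commas
    values = np.loadtxt(path.open(), comments="#", delimiter=sep, ndmin=1)
    return values.astype(np.float64).ravel()


def write_voxel_table(values: Iterable[float], path: str | Path) -> None:
    v = np.asarray(values, dtype=np.float64)
    np.savetxt(path, v[:, None], fmt="%.17g")


def read_nifti(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)


def write_nifti(array: np.ndarray, path: str | Path) -> None:
    """Write a 3-D array as float64 NIfTI (identity affine)."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.eye(4))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def extract_voxels_from_mask(adc_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Whole-lesion VOI measurement: the ADC values under a binary mask.

    Returns the values at nonzero mask positions in row-major traversal
    order. Mask values other than exactly {0, 1} are rejected rather than
    thresholded, so segmentation errors surface instead of being hidden.
    """
    adc_map = np.ascontiguousarray(np.asarray(adc_map, dtype=np.float64))
    mask = np.ascontiguousarray(np.asarray(mask))
    if adc_map.shape != mask.shape:
        raise ValidationError(
            f"ADC map shape {adc_map.shape} != mask shape {mask.shape}"
        )
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError(
            f"mask must be binary {{0,1}}; found values {uniq[:8]}"
        )
    selected = mask == 1
    if not selected.any():
        raise ValidationError("mask selects no voxels")
    return adc_map[selected]


# ---------------------------------------------------------------------------
# cohort manifest

def read_cohort_manifest(path: str | Path) -> Cohort:
    """Load a JSON cohort manifest, resolving every voxel source.

    Each patient record names ``patient_id``, ``true_class`` and exactly one
    of: ``voxels`` (inline list), ``voxel_file`` (per-patient table), or
    ``adc_map`` + ``voi_mask`` (NIfTI pair). Relative paths are resolved
    against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    units = doc.get("adc_units", "1e-6 mm^2/s")
    if units not in _UNIT_FACTORS:
        raise ValidationError(
            f"unknown adc_units {units!r}; expected one of {sorted(_UNIT_FACTORS)}"
        )
    factor = _UNIT_FACTORS[units]
    base = path.parent
    samples = []
    for rec in doc.get("patients", []):
        pid = rec.get("patient_id")
        cls = rec.get("true_class")
        if "voxels" in rec:
            voxels = np.asarray(rec["voxels"], dtype=np.float64)
        elif "voxel_file" in rec:
            voxels = read_voxel_table(base / rec["voxel_file"])
        elif "adc_map" in rec and "voi_mask" in rec:
            adc = read_nifti(base / rec["adc_map"])
            mask = read_nifti(base / rec["voi_mask"]).astype(np.int64)
            voxels = extract_voxels_from_mask(adc, mask)
        else:
            raise ValidationError(
                f"patient {pid!r}: no voxel source (voxels | voxel_file | "
                f"adc_map+voi_mask)"
            )
        samples.append(PatientSample(patient_id=pid, true_class=cls,
                                     voxels=voxels * factor))
    return Cohort(samples=tuple(samples))


def write_cohort_manifest(cohort: Cohort, out_dir: str | Path,
                          inline: bool = False) -> Path:
    """Write a cohort as ``manifest.json`` (+ per-patient CSVs unless inline)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = []
    for s in cohort:
        rec: dict = {"patient_id": s.patient_id, "true_class": s.true_class}
        if inline:
            rec["voxels"] = [float(v) for v in s.voxels]
        else:
            fname = f"{s.patient_id}.csv"
            write_voxel_table(s.voxels, out_dir / fname)
            rec["voxel_file"] = fname
        patients.append(rec)
    doc = {"adc_units": "1e-6 mm^2/s", "patients": patients}
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# histograms

def write_histogram(hist: Histogram, path: str | Path) -> None:
    edges = hist.scheme.edges()
    lines = [f"# patient_id={hist.patient_id}",
             "bin_left_edge\tbin_right_edge\tcount"]
    for m in range(hist.scheme.n_bins):
        lines.append(f"{edges[m]:.17g}\t{edges[m + 1]:.17g}\t{hist.counts[m]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_histogram(path: str | Path) -> Histogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().splitlines()
    patient_id = None
    for line in text:
        if line.startswith("# patient_id="):
            patient_id = line.split("=", 1)[1]
            break
    frame = pd.read_csv(path, sep="\t", comment="#")
    lefts = frame["bin_left_edge"].to_numpy(dtype=np.float64)
    rights = frame["bin_right_edge"].to_numpy(dtype=np.float64)
    counts = frame["count"].to_numpy(dtype=np.int64)
    if len(lefts) == 0:
        raise ValidationError(f"empty histogram table {path}")
    width = float(rights[0] - lefts[0])
    scheme = BinningScheme(origin=float(lefts[0]), width=width, n_bins=len(lefts))
    return Histogram(patient_id=patient_id or path.stem, scheme=scheme,
                     counts=counts)


# ---------------------------------------------------------------------------
# JSON artifacts (references, models, reports)

def _dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_references(refs: Mapping[str, "ReferencePMF"], path: str | Path) -> None:
    from .reference_model import ReferencePMF  # noqa: F401  (type only)
    _dump_json({c: r.to_dict() for c, r in refs.items()}, path)


def read_references(path: str | Path) -> dict:
    from .reference_model import ReferencePMF
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    return {c: ReferencePMF.from_dict(d) for c, d in doc.items()}


def write_mean_model(model: "MeanClassifierModel", path: str | Path) -> None:
    _dump_json(model.to_dict(), path)


def read_mean_model(path: str | Path):
    from .mean_threshold_classifier import MeanClassifierModel
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return MeanClassifierModel.from_dict(json.loads(path.read_text()))


def write_report(report: "MetricsReport", path: str | Path) -> None:
    """Serialize a metrics report deterministically (stable key order)."""
    _dump_json(report.to_dict(), path)


def read_report(path: str | Path):
    from .evaluation import MetricsReport
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return MetricsReport.from_dict(json.loads(path.read_text()))
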