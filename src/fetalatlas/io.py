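"""NIfTI and cohort-manifest I/O.

Images and integer label maps are NIfTI-1 (``.nii.gz``); displacement and
velocity fields are stored as 5-D NIfTI vector images (x, y, z, 1, 3) with
the displacement-vector intent code, components in world mm.  A cohort is
a directory of per-subject files plus a CSV manifest with the header
``subject_id,age_weeks,image_path,labels_path`` (paths relative to the
manifest).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DisplacementField, VolumetricImage
from .phantom import LABEL_NAMES, SubjectRecord

MANIFEST_HEADER = ["subject_id", "age_weeks", "image_path", "labels_path"]


def save_image(img: VolumetricImage, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(img.data, dtype=np.float32), img.affine),
             str(path))


def load_image(path) -> VolumetricImage:
    ni = nib.load(str(path))
    data = np.asarray(ni.dataobj, dtype=np.float32)
    spacing = np.asarray(ni.header.get_zooms()[:3], dtype=float)
    return VolumetricImage(data, spacing, ni.affine)


def save_labels(labels: np.ndarray, spacing, path, affine=None) -> None:
    img = VolumetricImage(np.zeros_like(labels, dtype=np.float32), spacing, affine)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), img.affine),
             str(path))


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def save_displacement(d: DisplacementField, path) -> None:
    data = d.vectors[:, :, :, np.newaxis, :].astype(np.float32)
    ni = nib.Nifti1Image(data, d.affine)
    ni.header.set_intent(1006)  # NIFTI_INTENT_DISPVECT
    nib.save(ni, str(path))


def load_displacement(path) -> DisplacementField:
    ni = nib.load(str(path))
    data = np.asarray(ni.dataobj, dtype=np.float32)
    if data.ndim == 5:
        data = data[:, :, :, 0, :]
    spacing = np.asarray(ni.header.get_zooms()[:3], dtype=float)
    return DisplacementField(data, spacing, ni.affine)


_PALETTE = [(0, 0, 0), (245, 245, 245), (205, 62, 78), (120, 18, 134),
            (196, 58, 250), (0, 148, 0), (220, 248, 164), (230, 148, 34)]


def write_label_descriptions(path, names: dict[int, str] | None = None) -> None:
    """ITK-SNAP label-description text file."""
    names = names if names is not None else LABEL_NAMES
    lines = ["# ITK-SnAP Label Description File",
             "# IDX -R- -G- -B- -A-- VIS MSH LABEL"]
    for idx in sorted(names):
        r, g, b = _PALETTE[idx % len(_PALETTE)]
        alpha = 0 if idx == 0 else 1
        lines.append(f'{idx:5d} {r:5d} {g:5d} {b:5d} {alpha:9d} {1:3d} {1:3d}'
                     f'    "{names[idx]}"')
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(subjects: list[SubjectRecord], out_dir) -> Path:
    """Write images, label maps, the label LUT, and the manifest CSV.

    Returns the manifest path.  Byte-identical for identical cohorts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        img_name = f"{s.subject_id}.nii.gz"
        save_image(s.image, out / img_name)
        lbl_name = ""
        if s.labels is not None:
            lbl_name = f"{s.subject_id}_labels.nii.gz"
            save_labels(s.labels, s.image.spacing, out / lbl_name,
                        s.image.affine)
        rows.append([s.subject_id, repr(float(s.age_weeks)), img_name, lbl_name])
    write_label_descriptions(out / "labels.txt")
    manifest = out / "cohort.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_HEADER)
        w.writerows(rows)
    return manifest


@dataclass
class ManifestEntry:
    """One manifest row; a stub that can be loaded into a SubjectRecord."""

    subject_id: str
    age_weeks: float
    image_path: Path
    labels_path: Path | None

    def load(self) -> SubjectRecord:
        labels = load_labels(self.labels_path) if self.labels_path else None
        return SubjectRecord(self.subject_id, self.age_weeks,
                             load_image(self.image_path), labels)


def read_manifest(path) -> list[ManifestEntry]:
    """Parse a cohort manifest; rejects duplicate ids and malformed rows."""
    path = Path(path)
    base = path.parent
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty manifest") from None
        if [h.strip() for h in header] != MANIFEST_HEADER:
            raise ValueError(f"{path}:1: expected header "
                             f"{','.join(MANIFEST_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 fields")
            sid = row[0].strip()
            if not sid:
                raise ValueError(f"{path}:{lineno}: empty subject_id")
            if sid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate subject_id {sid!r}")
            seen.add(sid)
            try:
                age = float(row[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: age_weeks {row[1]!r} is not a number"
                ) from None
            lbl = row[3].strip() if len(row) > 3 and row[3].strip() else None
            entries.append(ManifestEntry(sid, age, base / row[2].strip(),
                                         base / lbl if lbl else None))
    return entries


def load_cohort(manifest_path) -> list[SubjectRecord]:
    return [e.load() for e in read_manifest(manifest_path)]
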