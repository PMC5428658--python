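"""Overlap metrics, displacement statistics, and report tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DisplacementField, GridMismatchError, VolumetricImage

#: default gestational-age report bins (weeks): early, mid, late gestation
DEFAULT_AGE_BINS: list[tuple[float, float, str]] = [
    (0.0, 28.0, "<27"),
    (28.0, 35.0, "28-34"),
    (35.0, np.inf, ">=35"),
]


def dice(a: np.ndarray, b: np.ndarray, label: int) -> tuple[float, bool]:
    """Dice similarity coefficient 2|A&B| / (|A| + |B|) for one label.

    Returns ``(dsc, both_empty)``; when the label is absent from both maps
    the overlap is defined as 1.0 with the flag set.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise GridMismatchError("label maps must share a grid")
    am, bm = a == label, b == label
    na, nb = int(am.sum()), int(bm.sum())
    if na + nb == 0:
        return 1.0, True
    return 2.0 * int((am & bm).sum()) / (na + nb), False


@dataclass
class DiceTable:
    rows: pd.DataFrame
    grouping: list[tuple[float, float, str]] | None = None
    missing_subjects: list[str] = field(default_factory=list)

    def per_structure_mean(self) -> pd.Series:
        return self.rows.groupby("structure")["dsc"].mean()

    def per_bin_mean(self) -> pd.DataFrame:
        if "age_bin" not in self.rows:
            raise ValueError("table was built without age bins")
        return self.rows.pivot_table(index="structure", columns="age_bin",
                                     values="dsc", aggfunc="mean")

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def dice_table(auto: dict[str, np.ndarray], reference: dict[str, np.ndarray],
               label_names: dict[int, str],
               ages: dict[str, float] | None = None,
               age_bins: list[tuple[float, float, str]] | None = None) -> DiceTable:
    """Per-subject, per-structure Dice table, optionally grouped by age bin.

    Subjects present in only one of the two maps are reported in
    ``missing_subjects`` and skipped.
    """
    bins = age_bins if age_bins is not None else (DEFAULT_AGE_BINS if ages else None)
    records = []
    missing = sorted(set(auto) ^ set(reference))
    for sid in sorted(set(auto) & set(reference)):
        for lbl, name in label_names.items():
            if lbl == 0:
                continue
            d, flag = dice(auto[sid], reference[sid], lbl)
            rec = {"subject_id": sid, "label": lbl, "structure": name,
                   "dsc": d, "both_empty": flag}
            if ages is not None and bins is not None:
                age = ages[sid]
                rec["age_weeks"] = age
                rec["age_bin"] = next(
                    (nm for lo, hi, nm in bins if lo <= age < hi), "other")
            records.append(rec)
    return DiceTable(pd.DataFrame.from_records(records), bins, missing)


def mean_abs_displacement(fields: list[DisplacementField],
                          weights=None) -> float:
    """Voxelwise mean magnitude (mm) of the weighted sum of fields."""
    if not fields:
        raise ValueError("need at least one field")
    for f in fields[1:]:
        fields[0].require_same_grid(f, "displacement fields")
    if weights is None:
        weights = np.full(len(fields), 1.0 / len(fields))
    weights = np.asarray(weights, dtype=float)
    acc = sum(w * f.vectors.astype(np.float64) for w, f in zip(weights, fields))
    return float(np.sqrt((acc ** 2).sum(axis=-1)).mean())


def sharpness(image: VolumetricImage, mask: np.ndarray | None = None) -> float:
    """Mean finite-difference gradient magnitude within the mask.

    A proxy for the visual crispness of a template: blurring an image
    strictly lowers it.
    """
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("mask is empty")
    gx, gy, gz = np.gradient(np.asarray(image.data, dtype=np.float64),
                             *image.spacing)
    mag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    return float(mag[mask].mean())
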