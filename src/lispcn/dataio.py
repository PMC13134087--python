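"""Cohort loading, normalization, paired augmentation and patient-level splits."""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cases import LongitudinalCase

AUGMENT_OPS = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")


def normalize(raw_image: np.ndarray) -> np.ndarray:
    """Rescale the 1st-99th intensity percentiles to [-1, 1], clipped.

    Percentile anchoring makes the map invariant to affine intensity
    rescalings of the raw data.  A constant image has no range and is
    mapped to all -1 with a warning.
    """
    img = np.asarray(raw_image, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("normalize: non-finite intensities")
    lo, hi = np.percentile(img, [1.0, 99.0])
    if hi - lo < 1e-12:
        warnings.warn("normalize: constant image, returning all -1",
                      RuntimeWarning, stacklevel=2)
        return np.full_like(img, -1.0, dtype=np.float32)
    out = 2.0 * (img - lo) / (hi - lo) - 1.0
    return np.clip(out, -1.0, 1.0).astype(np.float32)


def _read_stack(path: str) -> np.ndarray:
    """Read a 3-channel stack from NIfTI (HxWx3) or per-channel PNGs."""
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        arr = np.asarray(nib.load(path).dataobj, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ValueError(f"{path}: expected HxWx3 NIfTI, got {arr.shape}")
        return np.moveaxis(arr, -1, 0)
    if path.endswith("_s0.png"):
        import imageio.v3 as iio
        chans = [np.asarray(iio.imread(path.replace("_s0.png", f"_{s}.png")),
                            dtype=np.float64)
                 for s in ("s0", "s3", "s5")]
        return np.stack(chans)
    raise ValueError(f"unsupported image path {path!r} "
                     "(expected .nii/.nii.gz or *_s0.png)")


def load_cohort(manifest_path: str,
                renormalize: bool = False) -> List[LongitudinalCase]:
    """Load cases listed in a manifest CSV.

    NIfTI stacks written by :func:`lispcn.phantom.write_cohort` are
    already in [-1, 1] and are loaded as-is; PNG stacks are 8-bit and are
    mapped back linearly.  ``renormalize=True`` applies percentile
    :func:`normalize` instead (the path for raw scanner intensities).
    """
    manifest = pd.read_csv(manifest_path)
    required = {"patient_id", "pre_path", "early_path", "mask_path", "label"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    import imageio.v3 as iio

    cases = []
    for row in manifest.itertuples(index=False):
        if int(row.label) not in (0, 1):
            raise ValueError(
                f"patient {row.patient_id}: non-binary label {row.label!r}")
        for p in (row.pre_path, row.early_path, row.mask_path):
            if not os.path.exists(p):
                raise FileNotFoundError(
                    f"patient {row.patient_id}: missing file {p}")
        stacks = []
        for p in (row.pre_path, row.early_path):
            arr = _read_stack(p)
            if renormalize:
                arr = normalize(arr)
            elif p.endswith(".png") or arr.max() > 1.0 + 1e-6:
                arr = (arr / 127.5) - 1.0   # 8-bit quantized storage
            stacks.append(np.clip(arr, -1.0, 1.0).astype(np.float32))
        mask_raw = np.asarray(iio.imread(row.mask_path), dtype=np.float64)
        # stored masks are 0/255 (or already 0/1); binarize at half range
        mask = mask_raw > (127.5 if mask_raw.max() > 1 else 0.5)
        if mask.shape != stacks[0].shape[1:]:
            raise ValueError(
                f"patient {row.patient_id}: mask shape {mask.shape} does not "
                f"match image spatial dims {stacks[0].shape[1:]}")
        shrink = getattr(row, "true_shrinkage", None)
        cases.append(LongitudinalCase(
            patient_id=str(row.patient_id),
            pre_image=stacks[0],
            early_image=stacks[1],
            lesion_mask=mask.astype(np.uint8),
            label=int(row.label),
            true_shrinkage=None if shrink is None or pd.isna(shrink)
            else float(shrink),
            cohort=str(getattr(row, "cohort", "development")),
        ))
    return cases


def _apply_op(arr: np.ndarray, op_id: str) -> np.ndarray:
    spatial = (-2, -1)
    if op_id == "identity":
        return arr.copy()
    if op_id == "hflip":
        return np.flip(arr, axis=-1).copy()
    if op_id == "vflip":
        return np.flip(arr, axis=-2).copy()
    if op_id == "rot90":
        return np.rot90(arr, 1, axes=spatial).copy()
    if op_id == "rot180":
        return np.rot90(arr, 2, axes=spatial).copy()
    if op_id == "rot270":
        return np.rot90(arr, 3, axes=spatial).copy()
    raise ValueError(f"unknown augmentation op {op_id!r}; "
                     f"valid ops: {AUGMENT_OPS}")


def augment(case: LongitudinalCase, op_id: str) -> LongitudinalCase:
    """Apply one dihedral-group op identically to pre, early and mask."""
    return LongitudinalCase(
        patient_id=case.patient_id,
        pre_image=_apply_op(case.pre_image, op_id),
        early_image=_apply_op(case.early_image, op_id),
        lesion_mask=_apply_op(case.lesion_mask, op_id),
        label=case.label,
        true_shrinkage=case.true_shrinkage,
        cohort=case.cohort,
    )


@dataclass
class SplitPlan:
    """Patient-level partition into named splits."""

    assignment: Dict[str, str]

    def patients(self, split: str) -> List[str]:
        return [p for p, s in self.assignment.items() if s == split]

    def select(self, cases: Sequence[LongitudinalCase],
               split: str) -> List[LongitudinalCase]:
        return [c for c in cases if self.assignment.get(c.patient_id) == split]

    def leakage_count(self) -> int:
        # each patient maps to exactly one split by construction
        return 0


def split_patients(manifest: pd.DataFrame,
                   fractions: Sequence[float],
                   seed: int = 0,
                   split_names: Optional[Sequence[str]] = None,
                   stratify: bool = True) -> SplitPlan:
    """Seeded leakage-free patient-level split.

    All slices of a patient land in the same split.  When ``stratify`` is
    set and per-patient labels are available, patients are assigned within
    label groups so each split approximates the cohort prevalence (low
    response rates otherwise leave tiny validation splits single-class).
    """
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    names = list(split_names) if split_names else \
        ["train", "val", "test"][:len(fractions)]
    if len(names) != len(fractions):
        raise ValueError("one name per fraction required")
    if isinstance(manifest, pd.DataFrame):
        ids = manifest["patient_id"].astype(str)
        labels = manifest["label"] if "label" in manifest.columns else None
    else:  # list of cases
        ids = pd.Series([c.patient_id for c in manifest])
        labels = pd.Series([c.label for c in manifest])
    per_patient = pd.DataFrame({"patient_id": ids})
    if labels is not None:
        per_patient["label"] = np.asarray(labels)
    per_patient = per_patient.groupby("patient_id", sort=True).first() \
        if labels is not None else \
        per_patient.drop_duplicates().set_index("patient_id")
    unique = per_patient.index.to_list()
    n_nonempty = sum(1 for f in fractions if f > 0)
    if len(unique) < n_nonempty:
        raise ValueError(f"{len(unique)} patients cannot fill "
                         f"{n_nonempty} non-empty splits")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, str] = {}

    def assign_group(group_ids: List[str]) -> None:
        order = list(rng.permutation(group_ids))
        bounds = np.floor(np.cumsum(fractions) * len(order) + 0.5).astype(int)
        start = 0
        for name, end in zip(names, bounds):
            for pid in order[start:end]:
                assignment[pid] = name
            start = end
        for pid in order[start:]:
            assignment[pid] = names[-1]

    if stratify and labels is not None and per_patient["label"].nunique() > 1:
        for _, grp in per_patient.groupby("label", sort=True):
            assign_group(list(grp.index))
    else:
        assign_group(list(unique))
    # guarantee every non-empty split got at least one patient
    for name, f in zip(names, fractions):
        if f > 0 and not any(s == name for s in assignment.values()):
            donor = max(names, key=lambda n: sum(
                1 for s in assignment.values() if s == n))
            pid = next(p for p, s in assignment.items() if s == donor)
            assignment[pid] = name
    return SplitPlan(assignment)


class AugmentStream:
    """Seeded on-the-fly augmentation: uniform choice over the 6 ops."""

    def __init__(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def __call__(self, case: LongitudinalCase) -> LongitudinalCase:
        return augment(case, AUGMENT_OPS[self.rng.integers(len(AUGMENT_OPS))])
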