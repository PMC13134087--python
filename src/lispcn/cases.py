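"""Core data container for paired longitudinal imaging cases."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class LongitudinalCase:
    """One patient slice: paired pre-/early-treatment stacks plus metadata.

    ``pre_image`` and ``early_image`` are 3xHxW float arrays in [-1, 1]
    holding the precontrast (S0), peak (S3) and late (S5) dynamic
    contrast-enhanced series as channels.  ``lesion_mask`` is the HxW
    binary support of the pre-treatment tumor.  ``label`` is the binary
    pathological-complete-response indicator.  ``true_shrinkage`` is only
    known for phantom data.
    """

    patient_id: str
    pre_image: np.ndarray
    early_image: np.ndarray
    lesion_mask: np.ndarray
    label: int
    true_shrinkage: Optional[float] = None
    cohort: str = "development"
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pre_image = np.asarray(self.pre_image, dtype=np.float32)
        self.early_image = np.asarray(self.early_image, dtype=np.float32)
        self.lesion_mask = np.asarray(self.lesion_mask)
        if self.pre_image.shape != self.early_image.shape:
            raise ValueError(
                f"case {self.patient_id}: pre {self.pre_image.shape} and "
                f"early {self.early_image.shape} shapes differ")
        if self.pre_image.ndim != 3 or self.pre_image.shape[0] != 3:
            raise ValueError(
                f"case {self.patient_id}: images must be 3xHxW, "
                f"got {self.pre_image.shape}")
        if self.lesion_mask.shape != self.pre_image.shape[1:]:
            raise ValueError(
                f"case {self.patient_id}: mask shape "
                f"{self.lesion_mask.shape} does not match image spatial dims "
                f"{self.pre_image.shape[1:]}")
        if int(self.label) not in (0, 1):
            raise ValueError(f"case {self.patient_id}: label must be 0 or 1, "
                             f"got {self.label!r}")
        self.label = int(self.label)
        for name, img in (("pre", self.pre_image), ("early", self.early_image)):
            if not np.isfinite(img).all():
                raise ValueError(f"case {self.patient_id}: non-finite values "
                                 f"in {name} image")
            if img.min() < -1.0 - 1e-6 or img.max() > 1.0 + 1e-6:
                raise ValueError(f"case {self.patient_id}: {name} image "
                                 "outside [-1, 1]")
        self.lesion_mask = (self.lesion_mask > 0.5).astype(np.uint8)
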