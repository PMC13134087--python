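"""Synthetic longitudinal tumor phantom generator.

Produces paired pre-/early-treatment 3-channel image slices with known
shrinkage and a response label stochastically linked to shrinkage, so the
whole synthesis-and-prediction pipeline can be exercised without any
patient data.

The phantom emulates four properties of breast DCE-MRI under neoadjuvant
chemotherapy:

* an elliptical enhancing lesion on textured parenchyma;
* channel-wise contrast-enhancement ordering (precontrast S0 darker than
  peak S3);
* tumor shrinkage between the two time points (semi-axes scaled by
  ``s`` in (0, 1]);
* a pathological-complete-response label drawn from a logistic link
  ``P(pCR) = sigmoid(kappa * (s_ref - s))`` — stronger shrinkage, higher
  response probability.

Cohort-level sampling ties the lesion's peak enhancement to the latent
responder propensity, so the eventual response is partially predictable
from the pre-treatment image alone — the premise of predicting response
from preoperative MRI.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .cases import LongitudinalCase


@dataclass
class LinkParams:
    """Logistic link from shrinkage ``s`` to response probability.

    ``P(pCR) = sigmoid(kappa * (s_ref - s))``: a tumor that shrinks well
    below ``s_ref`` is likely a responder.
    """

    kappa: float = 12.0
    s_ref: float = 0.7

    def prob(self, s: float) -> float:
        return float(1.0 / (1.0 + np.exp(-self.kappa * (self.s_ref - s))))


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise parameters for one phantom case."""

    image_size: int = 64
    background_smoothness: float = 4.0
    tumor_center: Tuple[float, float] = (32.0, 32.0)
    tumor_axes: Tuple[float, float] = (10.0, 7.0)
    tumor_angle: float = 0.0
    enhancement: Tuple[float, float, float] = (0.2, 0.8, 0.6)
    shrinkage: float = 0.6
    noise_sigma: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        a, b = self.tumor_axes
        if not (0.0 < self.shrinkage <= 1.0):
            raise ValueError(f"shrinkage must be in (0, 1], got {self.shrinkage}")
        if a < 2 or b < 2:
            raise ValueError(f"tumor semi-axes must be >= 2 px, got {self.tumor_axes}")
        r, c = self.tumor_center
        m = max(a, b)
        n = self.image_size
        if r - m < 0 or c - m < 0 or r + m > n - 1 or c + m > n - 1:
            raise ValueError("tumor ellipse exceeds image bounds")
        c0, c3, _ = self.enhancement
        if not c0 < c3:
            raise ValueError(
                f"enhancement must rise from S0 to S3, got c_S0={c0}, c_S3={c3}")


def _ellipse_mask(size: int, center: Tuple[float, float],
                  axes: Tuple[float, float], angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u ** 2 / axes[0] ** 2 + v ** 2 / axes[1] ** 2) <= 1.0


def _background(size: int, smoothness: float,
                rng: np.random.Generator) -> np.ndarray:
    """Parenchyma texture: smoothed white noise rescaled to [-1, 0]."""
    field_ = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), smoothness)
    lo, hi = field_.min(), field_.max()
    if hi - lo < 1e-12:
        return np.full((size, size), -0.5)
    return (field_ - lo) / (hi - lo) - 1.0


def generate_pair(spec: PhantomSpec,
                  response_link: Optional[LinkParams] = None,
                  patient_id: Optional[str] = None,
                  cohort: str = "development") -> LongitudinalCase:
    """Render one paired pre-/early-treatment phantom case.

    Both time points share the same seeded background texture; the early
    image repeats the lesion with its semi-axes scaled by ``spec.shrinkage``
    and receives independent additive noise.  Fully deterministic given
    ``spec.seed``.
    """
    spec.validate()
    link = response_link or LinkParams()
    ss = np.random.SeedSequence(spec.seed)
    rng_bg, rng_noise_pre, rng_noise_early, rng_label = (
        np.random.default_rng(s) for s in ss.spawn(4))

    size = spec.image_size
    bg = _background(size, spec.background_smoothness, rng_bg)
    pre_support = _ellipse_mask(size, spec.tumor_center, spec.tumor_axes,
                                spec.tumor_angle)
    early_axes = (spec.shrinkage * spec.tumor_axes[0],
                  spec.shrinkage * spec.tumor_axes[1])
    early_support = _ellipse_mask(size, spec.tumor_center, early_axes,
                                  spec.tumor_angle)

    def stack(support: np.ndarray, rng_noise: np.random.Generator) -> np.ndarray:
        chans = []
        for contrast in spec.enhancement:
            img = bg + contrast * support
            if spec.noise_sigma > 0:
                img = img + rng_noise.normal(0.0, spec.noise_sigma, img.shape)
            chans.append(img)
        return np.clip(np.stack(chans), -1.0, 1.0).astype(np.float32)

    pre = stack(pre_support, rng_noise_pre)
    early = stack(early_support, rng_noise_early)
    label = int(rng_label.random() < link.prob(spec.shrinkage))
    return LongitudinalCase(
        patient_id=patient_id or f"phantom-{spec.seed:06d}",
        pre_image=pre,
        early_image=early,
        lesion_mask=pre_support.astype(np.uint8),
        label=label,
        true_shrinkage=spec.shrinkage,
        cohort=cohort,
    )


@dataclass
class ShrinkageModel:
    """Bimodal propensity-to-shrinkage map used for cohort sampling.

    A latent responder propensity ``u ~ Uniform(0, 1)`` maps to shrinkage
    through a steep logistic, ``s(u) = s_hi - (s_hi - s_lo) *
    sigmoid(steepness * (u - u0))``: tumors either shrink markedly or
    change little, the typical dichotomy between concentric shrinkage and
    stable disease.  The pivot ``u0`` is calibrated so the expected
    response rate under the label link matches a target prevalence;
    bimodality keeps most cases away from the link's noisy decision
    boundary, so the response stays predictable from pre-treatment
    appearance.
    """

    s_lo: float = 0.25
    s_hi: float = 1.0
    steepness: float = 12.0
    u0: float = 0.5
    jitter: float = 0.02

    def s_of_u(self, u) -> np.ndarray:
        g = 1.0 / (1.0 + np.exp(-self.steepness * (u - self.u0)))
        return self.s_hi - (self.s_hi - self.s_lo) * g

    def expected_prevalence(self, link: LinkParams) -> float:
        u = np.linspace(0.0, 1.0, 20001)
        s = self.s_of_u(u)
        p = 1.0 / (1.0 + np.exp(-link.kappa * (link.s_ref - s)))
        return float(np.trapezoid(p, u))


def calibrate_shrinkage(prevalence_target: float,
                        link: Optional[LinkParams] = None,
                        model: Optional[ShrinkageModel] = None
                        ) -> ShrinkageModel:
    """Solve the propensity pivot ``u0`` giving the target prevalence.

    Raises (rather than silently clipping) when the target response rate
    is unreachable under the label link and shrinkage bounds.
    """
    link = link or LinkParams()
    model = model or ShrinkageModel()
    if not 0.0 < prevalence_target < 1.0:
        raise ValueError("prevalence_target must be in (0, 1)")

    def gap(u0: float) -> float:
        trial = ShrinkageModel(model.s_lo, model.s_hi, model.steepness,
                               u0, model.jitter)
        return trial.expected_prevalence(link) - prevalence_target

    eps = 1e-3
    if gap(1.0 - eps) > 0 or gap(eps) < 0:
        lo_p = ShrinkageModel(model.s_lo, model.s_hi, model.steepness,
                              1.0 - eps).expected_prevalence(link)
        hi_p = ShrinkageModel(model.s_lo, model.s_hi, model.steepness,
                              eps).expected_prevalence(link)
        raise ValueError(
            f"prevalence {prevalence_target} unreachable: attainable range "
            f"is [{lo_p:.3f}, {hi_p:.3f}] under link kappa={link.kappa}, "
            f"s_ref={link.s_ref}, shrinkage in [{model.s_lo}, {model.s_hi}]")
    u0 = brentq(gap, eps, 1.0 - eps, xtol=1e-10)
    return ShrinkageModel(model.s_lo, model.s_hi, model.steepness,
                          float(u0), model.jitter)


def generate_cohort(n: int, prevalence_target: float = 0.2, size: int = 64,
                    seed: int = 0, link: Optional[LinkParams] = None,
                    noise_sigma: float = 0.05, slices_per_patient: int = 3,
                    cohort: str = "development") -> List[LongitudinalCase]:
    """Draw ``n`` seeded phantom patients with calibrated response prevalence.

    Patient-level biology is drawn once: a latent responder propensity
    ``u ~ Uniform(0, 1)`` drives the peak-enhancement contrast and the
    late washout (responders enhance strongly and wash out), and the
    shrinkage ``s`` (through the calibrated bimodal
    :class:`ShrinkageModel`, plus jitter); the pCR label is drawn once
    per patient from the logistic link.  Each patient then contributes
    ``slices_per_patient`` 2-D slices — cross-sections of the same
    lesion at offsets through the tumor (in-plane axes scaled
    accordingly), each on its own parenchyma texture realization, the
    way adjacent scanner slices decorrelate in texture but share the
    tumor's biology and the label.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 patients")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    link = link or LinkParams()
    shrink_model = calibrate_shrinkage(prevalence_target, link)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    slice_seeds = rng.integers(0, 2 ** 31 - 1, size=(n, slices_per_patient))
    cases = []
    for i in range(n):
        u = rng.random()                       # responder propensity
        a = rng.uniform(6.0, 9.0)              # size response-neutral
        b = a * rng.uniform(0.55, 0.95)
        angle = rng.uniform(0.0, np.pi)
        c0 = rng.uniform(0.08, 0.15)
        # peak enhancement and late washout both grade with propensity:
        # strong enhancers with washout kinetics respond more often
        c3 = 0.30 + 0.65 * u + rng.normal(0.0, 0.02)
        c3 = float(np.clip(c3, c0 + 0.05, 1.0))
        c5 = c0 + (0.85 - 0.5 * u) * (c3 - c0)
        s = shrink_model.s_of_u(u) + rng.normal(0.0, shrink_model.jitter)
        s = float(np.clip(s, 0.05, 1.0))
        label = int(rng.random() < link.prob(s))
        margin = a + 2.0
        center = (rng.uniform(margin, size - 1 - margin),
                  rng.uniform(margin, size - 1 - margin))
        # slice offsets through the lesion: cross-section scale factors
        offsets = np.linspace(-0.4, 0.4, slices_per_patient) \
            if slices_per_patient > 1 else np.zeros(1)
        for k in range(slices_per_patient):
            f = float(np.sqrt(1.0 - offsets[k] ** 2))
            jr, jc = rng.normal(0.0, 1.0, 2)   # small slice-to-slice shift
            ctr = (float(np.clip(center[0] + jr, margin, size - 1 - margin)),
                   float(np.clip(center[1] + jc, margin, size - 1 - margin)))
            spec = PhantomSpec(
                image_size=size,
                background_smoothness=4.0,
                tumor_center=ctr,
                tumor_axes=(max(f * a, 2.0), max(f * b, 2.0)),
                tumor_angle=angle,
                enhancement=(c0, c3, c5),
                shrinkage=s,
                noise_sigma=noise_sigma,
                seed=int(slice_seeds[i, k]),
            )
            case = generate_pair(
                spec, link, patient_id=f"P{seed:04d}-{i:04d}", cohort=cohort)
            case.label = label                 # patient-level label
            case.slice_index = k
            cases.append(case)
    return cases


def cohort_manifest(cases: List[LongitudinalCase],
                    directory: Optional[str] = None) -> pd.DataFrame:
    rows = []
    for c in cases:
        stem = f"{c.patient_id}_sl{c.slice_index}"
        rows.append({
            "patient_id": c.patient_id,
            "pre_path": os.path.join(directory or "", f"{stem}_pre.nii.gz"),
            "early_path": os.path.join(directory or "", f"{stem}_early.nii.gz"),
            "mask_path": os.path.join(directory or "", f"{stem}_mask.png"),
            "label": c.label,
            "true_shrinkage": c.true_shrinkage,
            "cohort": c.cohort,
        })
    return pd.DataFrame(rows)


def write_cohort(cases: List[LongitudinalCase], directory: str,
                 image_format: str = "nifti") -> str:
    """Write a cohort to disk and return the manifest CSV path.

    ``image_format='nifti'`` stores each 3-channel stack losslessly as
    float32 ``.nii.gz``; ``'png'`` stores one 8-bit PNG per channel
    (quantized to 1/127 of the [-1, 1] range).  Masks are single PNGs.
    """
    import imageio.v3 as iio
    import nibabel as nib

    if image_format not in ("nifti", "png"):
        raise ValueError(f"unknown image format {image_format!r}")
    os.makedirs(directory, exist_ok=True)
    rows = []
    for c in cases:
        stem = f"{c.patient_id}_sl{c.slice_index}"
        paths = {}
        for tag, img in (("pre", c.pre_image), ("early", c.early_image)):
            if image_format == "nifti":
                p = os.path.join(directory, f"{stem}_{tag}.nii.gz")
                nib.save(nib.Nifti1Image(
                    np.moveaxis(img, 0, -1).astype(np.float32), np.eye(4)), p)
            else:
                p = os.path.join(directory, f"{stem}_{tag}_s0.png")
                for ch, series in enumerate(("s0", "s3", "s5")):
                    q = np.round((img[ch] + 1.0) * 127.5).astype(np.uint8)
                    iio.imwrite(os.path.join(
                        directory, f"{stem}_{tag}_{series}.png"), q)
            paths[tag] = p
        mask_path = os.path.join(directory, f"{stem}_mask.png")
        iio.imwrite(mask_path, (c.lesion_mask * 255).astype(np.uint8))
        rows.append({
            "patient_id": c.patient_id,
            "pre_path": paths["pre"],
            "early_path": paths["early"],
            "mask_path": mask_path,
            "label": c.label,
            "true_shrinkage": c.true_shrinkage,
            "cohort": c.cohort,
        })
    manifest = pd.DataFrame(rows)
    manifest_path = os.path.join(directory, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
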