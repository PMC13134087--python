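"""Adversarial, cycle-consistency, classification and perceptual losses."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import ModelBundle, PerceptualNet
from .nn import tensor as T
from .nn.tensor import Tensor, as_tensor

PROB_EPS = 1e-7


@dataclass
class LossWeights:
    """Weighted combination of the generator-side objective terms.

    ``lambda_cyc`` follows the usual cycle-consistency weighting (10).
    ``lambda_pcp`` weights the paired reconstruction pyramid — the
    analogue of a paired L1 term, conventionally weighted 10-100x the
    adversarial term; 50 sits inside that range.  ``lambda_cls``
    balances the classification gradient against the dense image losses
    at the shared encoder.  A zero weight disables its term exactly
    (the term is reported as 0.0 and contributes no gradient).
    """

    lambda_cyc: float = 10.0
    lambda_cls: float = 5.0
    lambda_pcp: float = 50.0
    gan_mode: str = "least-squares"
    # stage 0 is the image itself (pixel term, the denoising minimizer);
    # stages 1..3 are the frozen conv pyramid
    stage_weights: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)

    def validate(self) -> None:
        if min(self.lambda_cyc, self.lambda_cls, self.lambda_pcp) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.gan_mode not in ("least-squares", "cross-entropy"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")


def adversarial_loss(score_map: Tensor, target_is_real: bool,
                     gan_mode: str = "least-squares") -> Tensor:
    """Patch-level GAN loss against an all-real or all-fake target."""
    score_map = as_tensor(score_map)
    target = 1.0 if target_is_real else 0.0
    if gan_mode == "least-squares":
        diff = score_map - target
        return T.mean(diff * diff)
    if gan_mode == "cross-entropy":
        p = clamp_prob(T.sigmoid(score_map))
        if target_is_real:
            return T.mean(-T.log(p))
        return T.mean(-T.log(1.0 - p))
    raise ValueError(f"unknown gan_mode {gan_mode!r}")


def cycle_loss(x: Tensor, f_of_g_x: Tensor, y: Tensor,
               g_of_f_y: Tensor) -> Tensor:
    """Sum of mean-absolute reconstruction errors of both cycles."""
    x, f_of_g_x = as_tensor(x), as_tensor(f_of_g_x)
    y, g_of_f_y = as_tensor(y), as_tensor(g_of_f_y)
    if x.shape != f_of_g_x.shape or y.shape != g_of_f_y.shape:
        raise ValueError("cycle_loss: shape mismatch")
    return T.mean(T.absolute(f_of_g_x - x)) + T.mean(T.absolute(g_of_f_y - y))


def clamp_prob(prob: Tensor) -> Tensor:
    return T.clamp(prob, PROB_EPS, 1.0 - PROB_EPS)


def classification_loss(prob: Tensor, label: np.ndarray,
                        pos_weight: float = 1.0) -> Tensor:
    """Weighted binary cross-entropy on predicted response probabilities.

    ``pos_weight`` defaults to 1; the trainer sets it to n_neg/n_pos of
    its training split to counter the low response prevalence.
    """
    prob = as_tensor(prob)
    label = np.asarray(label, dtype=np.float64)
    if np.any((label != 0) & (label != 1)):
        raise ValueError("labels must be binary")
    if np.any(prob.data <= 0.0) or np.any(prob.data >= 1.0):
        warnings.warn("classification_loss: probabilities clamped away from "
                      "{0,1}", RuntimeWarning, stacklevel=2)
    p = clamp_prob(prob)
    per_case = -(pos_weight * label * T.log(p)
                 + (1.0 - label) * T.log(1.0 - p))
    return T.mean(per_case)


def perceptual_loss(real: Tensor, fake: Tensor, percnet: PerceptualNet,
                    stage_weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0)
                    ) -> Tensor:
    """Weighted mean-absolute distance between feature pyramids.

    Stage 0 of the pyramid is the image itself, so its weight sets a
    plain pixel L1 term; the remaining stages are the frozen conv
    features.  The pixel term's minimizer given unpredictable acquisition
    noise is the noise-free target, so it both edits and denoises.
    """
    feats_real = percnet(as_tensor(real), include_input=True)
    feats_fake = percnet(as_tensor(fake), include_input=True)
    total: Optional[Tensor] = None
    for w, fr, ff in zip(stage_weights, feats_real, feats_fake):
        if w == 0:
            continue
        term = T.mean(T.absolute(fr.detach() - ff)) * w
        total = term if total is None else total + term
    return total if total is not None else as_tensor(0.0)


def generator_objective(bundle: ModelBundle, batch: Dict[str, np.ndarray],
                        weights: LossWeights, pos_weight: float = 1.0,
                        keep_fakes: Optional[Dict[str, np.ndarray]] = None
                        ) -> Tuple[Tensor, Dict[str, float]]:
    """Full generator-side objective with a per-term breakdown.

    ``adv(G) + adv(F) + l_cyc*cycle + l_cls*cls + l_pcp*pcp``; the
    perceptual term compares G(pre) against the true early image (and
    F(early) against the true pre image when F exists).  The breakdown
    holds each term's weighted contribution, so the terms sum to the total.
    """
    weights.validate()
    pre = Tensor(np.asarray(batch["pre"], dtype=np.float32))
    early = Tensor(np.asarray(batch["early"], dtype=np.float32))
    labels = np.asarray(batch["label"])
    breakdown: Dict[str, float] = {}
    terms: List[Tensor] = []

    fake_early, z = bundle.G(pre, return_latent=True)
    if keep_fakes is not None:
        keep_fakes["fake_early"] = fake_early.data.copy()
    if bundle.D1 is not None:
        adv_g = adversarial_loss(bundle.D1(fake_early), True, weights.gan_mode)
    else:
        adv_g = as_tensor(0.0)
    breakdown["adv_G"] = float(adv_g.data)
    terms.append(adv_g)

    fake_pre = None
    if bundle.F is not None:
        fake_pre = bundle.F(early)
        if keep_fakes is not None:
            keep_fakes["fake_pre"] = fake_pre.data.copy()
        if bundle.D2 is not None:
            adv_f = adversarial_loss(bundle.D2(fake_pre), True, weights.gan_mode)
        else:
            adv_f = as_tensor(0.0)
        breakdown["adv_F"] = float(adv_f.data)
        terms.append(adv_f)
    else:
        breakdown["adv_F"] = 0.0

    if weights.lambda_cyc > 0 and bundle.F is not None:
        rec_pre = bundle.F(fake_early)
        rec_early = bundle.G(fake_pre)
        cyc = cycle_loss(pre, rec_pre, early, rec_early) * weights.lambda_cyc
        breakdown["cycle"] = float(cyc.data)
        terms.append(cyc)
    else:
        breakdown["cycle"] = 0.0

    if weights.lambda_cls > 0:
        prob = bundle.head(z)
        cls = classification_loss(prob, labels, pos_weight) * weights.lambda_cls
        breakdown["cls"] = float(cls.data)
        terms.append(cls)
    else:
        breakdown["cls"] = 0.0

    if weights.lambda_pcp > 0:
        pcp = perceptual_loss(early, fake_early, bundle.percnet,
                              weights.stage_weights)
        if fake_pre is not None:
            pcp = pcp + perceptual_loss(pre, fake_pre, bundle.percnet,
                                        weights.stage_weights)
        pcp = pcp * weights.lambda_pcp
        breakdown["pcp"] = float(pcp.data)
        terms.append(pcp)
    else:
        breakdown["pcp"] = 0.0

    total = terms[0]
    for t in terms[1:]:
        total = total + t
    breakdown["total"] = float(total.data)
    return total, breakdown


def discriminator_objective(disc, real: np.ndarray, fake: np.ndarray,
                            gan_mode: str = "least-squares") -> Tensor:
    """Standard critic loss: real patches toward 1, fake patches toward 0.

    ``fake`` must already be detached from the generator graph (plain
    numpy), so no generator gradient flows through the critic update.
    """
    real_t = Tensor(np.asarray(real, dtype=np.float32))
    fake_t = Tensor(np.asarray(fake, dtype=np.float32))
    loss_real = adversarial_loss(disc(real_t), True, gan_mode)
    loss_fake = adversarial_loss(disc(fake_t), False, gan_mode)
    return (loss_real + loss_fake) * 0.5
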