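"""Quantitative evaluation: image fidelity (SSIM, PSNR), feature-space
similarity (perceptual patch distance, Fréchet distance), classification
metrics with bootstrap uncertainty, model comparison and distribution
comparison tests, and mask overlap (Dice)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
from skimage.metrics import structural_similarity

from .cases import LongitudinalCase
from .network import ModelBundle, PerceptualNet

PSNR_INF = float("inf")


def _to_unit(img: np.ndarray) -> np.ndarray:
    """Map a [-1, 1] image to [0, 1] for fidelity metrics."""
    return (np.asarray(img, dtype=np.float64) + 1.0) / 2.0


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity (Gaussian window 11, sigma 1.5, K1=0.01,
    K2=0.03, data range 1) over the channels of two [-1, 1] stacks."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"ssim: shape mismatch {a.shape} vs {b.shape}")
    au, bu = _to_unit(a), _to_unit(b)
    if au.ndim == 2:
        au, bu = au[None], bu[None]
    vals = [structural_similarity(
        au[c], bu[c], data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03)
        for c in range(au.shape[0])]
    return float(np.mean(vals))


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """``10 log10(1 / MSE)`` in dB on the [0, 1] scale; inf for identity."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"psnr: shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((_to_unit(a) - _to_unit(b)) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return float(10.0 * np.log10(1.0 / mse))


def lpips_like(a: np.ndarray, b: np.ndarray,
               percnet: PerceptualNet,
               stage_weights: Optional[Sequence[float]] = None) -> float:
    """Perceptual patch distance in the frozen feature pyramid.

    Feature maps are unit-normalized along channels per spatial site;
    the squared channel distance is averaged spatially and across stages.
    Zero iff the inputs are identical.
    """
    from .nn.tensor import Tensor
    a3 = np.asarray(a, dtype=np.float32)
    b3 = np.asarray(b, dtype=np.float32)
    if a3.shape != b3.shape:
        raise ValueError("lpips_like: shape mismatch")
    if a3.ndim == 3:
        a3, b3 = a3[None], b3[None]
    fa = percnet(Tensor(a3))
    fb = percnet(Tensor(b3))
    if stage_weights is None:
        stage_weights = [1.0] * len(fa)
    total, wsum = 0.0, 0.0
    for w, xa, xb in zip(stage_weights, fa, fb):
        na = xa.data / (np.linalg.norm(xa.data, axis=1, keepdims=True) + 1e-10)
        nb = xb.data / (np.linalg.norm(xb.data, axis=1, keepdims=True) + 1e-10)
        total += w * float(np.mean(np.sum((na - nb) ** 2, axis=1)))
        wsum += w
    return total / max(wsum, 1e-12)


def fid(features_real: np.ndarray, features_fake: np.ndarray,
        eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature sets.

    ``||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})`` with covariances
    regularized by ``+eps I``; tiny negative numerical residue is clipped
    at zero.
    """
    x = np.asarray(features_real, dtype=np.float64)
    y = np.asarray(features_fake, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("fid expects 2-D (n, dim) feature arrays")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("fid needs at least 2 samples per set")
    mu1, mu2 = x.mean(axis=0), y.mean(axis=0)
    s1 = np.cov(x, rowvar=False) + eps * np.eye(x.shape[1])
    s2 = np.cov(y, rowvar=False) + eps * np.eye(y.shape[1])
    covmean = scipy.linalg.sqrtm(s1 @ s2)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    value = float(np.sum((mu1 - mu2) ** 2)
                  + np.trace(s1 + s2 - 2.0 * covmean))
    return max(value, 0.0)


def auc_rank(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank (Mann-Whitney) statistic; ties get half credit."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    from scipy.stats import rankdata
    ranks = rankdata(probs)  # average ranks give ties half credit
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def classification_metrics(probs: np.ndarray, labels: np.ndarray,
                           threshold: float = 0.5) -> Dict[str, float]:
    """AUC plus confusion-matrix metrics at the given operating point."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    out: Dict[str, float] = {
        "accuracy": (tp + tn) / len(labels),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }
    denom = 2 * tp + fp + fn
    out["f1"] = 2 * tp / denom if denom else 0.0
    if len(np.unique(labels)) == 2:
        out["auc"] = auc_rank(probs, labels)
    else:
        out["auc"] = float("nan")
    return out


def auc_ci(probs: np.ndarray, labels: np.ndarray, n_boot: int = 1000,
           seed: int = 0, level: float = 0.95) -> Tuple[float, float]:
    """Seeded case-level bootstrap percentile interval for the AUC.

    Degenerate resamples (single class) are redrawn.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    auc_rank(probs, labels)  # validates class presence
    rng = np.random.default_rng(seed)
    n = len(labels)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) == 2:
                break
        stats[i] = auc_rank(probs[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compare_auc(probs_a: np.ndarray, probs_b: np.ndarray,
                labels: np.ndarray, n_perm: int = 2000,
                seed: int = 0) -> float:
    """Paired permutation test on the AUC difference of two models.

    Under the null the two models are exchangeable per case, so each
    permutation randomly swaps the two scores case-wise; the two-sided p
    is the fraction of permuted |dAUC| at least as large as observed
    (with the +1 continuity correction, so p is always in (0, 1]).
    """
    pa = np.asarray(probs_a, dtype=np.float64)
    pb = np.asarray(probs_b, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if pa.shape != pb.shape or pa.shape != labels.shape:
        raise ValueError("compare_auc: mismatched lengths")
    observed = abs(auc_rank(pa, labels) - auc_rank(pb, labels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(pa)) < 0.5
        xa = np.where(swap, pb, pa)
        xb = np.where(swap, pa, pb)
        if abs(auc_rank(xa, labels) - auc_rank(xb, labels)) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def permutation_mean_test(x: np.ndarray, y: np.ndarray, n_perm: int = 2000,
                          seed: int = 0) -> float:
    """Two-sided permutation test on the difference of sample means."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    observed = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:len(x)].mean() - perm[len(x):].mean()) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def ecdf(sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    sample = np.sort(np.asarray(sample, dtype=np.float64).ravel())
    return np.searchsorted(sample, grid, side="right") / len(sample)


def feature_distribution_compare(features_real: np.ndarray,
                                 features_fake: np.ndarray,
                                 seed: int = 0, n_perm: int = 2000,
                                 test: str = "mean-permutation",
                                 n_grid: int = 200) -> Dict:
    """Compare pooled 1-D feature samples of real vs synthesized images.

    Returns empirical CDFs and Gaussian kernel-density summaries on a
    shared grid plus a two-sided p-value — by default a seeded
    permutation test on the difference of means; a Kolmogorov-Smirnov
    test is available by flag.
    """
    x = np.asarray(features_real, dtype=np.float64).ravel()
    y = np.asarray(features_fake, dtype=np.float64).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty feature sample")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    from scipy.stats import gaussian_kde, ks_2samp
    densities = {}
    for name, s in (("real", x), ("fake", y)):
        if np.ptp(s) < 1e-12:
            d = np.zeros_like(grid)  # degenerate: KDE undefined
        else:
            d = gaussian_kde(s)(grid)
        densities[name] = d
    if test == "mean-permutation":
        if np.array_equal(np.sort(x), np.sort(y)):
            p = 1.0  # identical samples: every permutation ties
        else:
            p = permutation_mean_test(x, y, n_perm=n_perm, seed=seed)
    elif test == "ks":
        p = float(ks_2samp(x, y).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "grid": grid,
        "ecdf_real": ecdf(x, grid),
        "ecdf_fake": ecdf(y, grid),
        "density_real": densities["real"],
        "density_fake": densities["fake"],
        "p_value": p,
    }


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1, True, False))):
        raise ValueError(f"{name} must be binary, found values {vals[:5]}")
    return m.astype(bool)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """``2|A∩B| / (|A|+|B|)``; two empty masks score 1 by convention."""
    a = _check_binary(mask_a, "mask_a")
    b = _check_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise ValueError("dice: shape mismatch")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / (sa + sb))


@dataclass
class EvalReport:
    """Cohort-level evaluation results."""

    per_case: "object"                # pandas DataFrame
    fid: float
    metrics: Dict[str, float]
    auc_ci95: Tuple[float, float]
    feature_comparison_p: float

    def summary(self) -> Dict[str, float]:
        frame = self.per_case
        out = {
            "ssim_synth": float(frame["ssim_synth"].mean()),
            "ssim_copy": float(frame["ssim_copy"].mean()),
            "psnr_synth": float(np.mean(
                np.clip(frame["psnr_synth"], None, 99.0))),
            "lpips_synth": float(frame["lpips_synth"].mean()),
            "fid": self.fid,
            "feature_comparison_p": self.feature_comparison_p,
        }
        out.update(self.metrics)
        out["auc_ci_lo"], out["auc_ci_hi"] = self.auc_ci95
        return out


def evaluate_bundle(bundle: ModelBundle,
                    cases: Sequence[LongitudinalCase],
                    seed: int = 0, n_boot: int = 1000) -> EvalReport:
    """Full evaluation of a trained bundle on held-out cases.

    Image metrics compare the synthesized early stack ``G(pre)`` with the
    true early stack (and the pre stack itself as the copy-input
    baseline); the Fréchet distance and the feature-distribution test use
    the frozen perceptual network's pooled final-stage features.
    """
    import pandas as pd

    pre = np.stack([c.pre_image for c in cases])
    early = np.stack([c.early_image for c in cases])
    labels = np.array([c.label for c in cases])
    synth = bundle.synthesize(pre)
    probs = bundle.predict_proba(pre)
    rows = []
    for i, c in enumerate(cases):
        rows.append({
            "patient_id": c.patient_id,
            "label": int(labels[i]),
            "prob": float(probs[i]),
            "ssim_synth": ssim(synth[i], early[i]),
            "ssim_copy": ssim(pre[i], early[i]),
            "psnr_synth": psnr(synth[i], early[i]),
            "lpips_synth": lpips_like(synth[i], early[i], bundle.percnet),
        })
    frame = pd.DataFrame(rows)
    feats_real = bundle.percnet.features(early)
    feats_fake = bundle.percnet.features(synth)
    fid_value = fid(feats_real, feats_fake)
    comparison = feature_distribution_compare(
        feats_real.ravel(), feats_fake.ravel(), seed=seed)
    metrics = classification_metrics(probs, labels)
    ci = auc_ci(probs, labels, n_boot=n_boot, seed=seed) \
        if len(np.unique(labels)) == 2 else (float("nan"), float("nan"))
    return EvalReport(per_case=frame, fid=fid_value, metrics=metrics,
                      auc_ci95=ci, feature_comparison_p=comparison["p_value"])
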