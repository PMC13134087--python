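"""Scikit-learn-style estimator facade over the training engine.

:class:`LISPCNModel` is the recommended high-level surface: ``fit`` on a
list of :class:`~lispcn.cases.LongitudinalCase`, ``predict_proba`` for
response probabilities from pre-treatment stacks, ``transform`` for
synthetic early-treatment stacks.  It composes with sklearn model
selection through ``get_params``/``set_params``.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .cases import LongitudinalCase
from .network import ArchConfig, build_bundle
from .objectives import LossWeights
from .trainer import TrainConfig, FinetuneConfig, ablate, finetune, train


def _to_image_array(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        arr = X
    elif len(X) and isinstance(X[0], LongitudinalCase):
        arr = np.stack([c.pre_image for c in X])
    else:
        arr = np.asarray(X, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3, H, W) images, got {arr.shape}")
    return arr.astype(np.float32)


class LISPCNModel(BaseEstimator):
    """Multitask image-synthesis + response-prediction model.

    Parameters mirror the published training protocol: Adam(0.5, 0.99),
    batch size 8, learning rates 2e-3 (GAN) and 1e-4 (classifier head)
    decayed by 0.97 every 50 epochs.  ``ablation`` selects one of the
    reduced variants (``AS-Dec``, ``AS-Dis``, ``AS-GF``, ``AS-Pcp``).

    Attributes set by :meth:`fit`: ``bundle_`` (all trained components),
    ``state_`` (loss history), ``classes_``.
    """

    def __init__(self, epochs: int = 10, max_iterations: Optional[int] = None,
                 batch_size: int = 8, lr_gan: float = 2e-3,
                 lr_cls: float = 1e-4, decay_factor: float = 0.97,
                 decay_every: int = 50, lambda_cyc: float = 10.0,
                 lambda_cls: float = 5.0, lambda_pcp: float = 50.0,
                 gan_mode: str = "least-squares", ablation: str = "none",
                 use_eca: bool = True, augment: bool = True,
                 seed: int = 0):
        self.epochs = epochs
        self.max_iterations = max_iterations
        self.batch_size = batch_size
        self.lr_gan = lr_gan
        self.lr_cls = lr_cls
        self.decay_factor = decay_factor
        self.decay_every = decay_every
        self.lambda_cyc = lambda_cyc
        self.lambda_cls = lambda_cls
        self.lambda_pcp = lambda_pcp
        self.gan_mode = gan_mode
        self.ablation = ablation
        self.use_eca = use_eca
        self.augment = augment
        self.seed = seed

    def _configs(self) -> Tuple[TrainConfig, ArchConfig]:
        cfg = TrainConfig(
            batch_size=self.batch_size, lr_gan=self.lr_gan,
            lr_cls=self.lr_cls, decay_factor=self.decay_factor,
            decay_every=self.decay_every, epochs=self.epochs,
            seed=self.seed, ablation=self.ablation,
            weights=LossWeights(lambda_cyc=self.lambda_cyc,
                                lambda_cls=self.lambda_cls,
                                lambda_pcp=self.lambda_pcp,
                                gan_mode=self.gan_mode),
            augment=self.augment, max_iterations=self.max_iterations)
        arch = ArchConfig(use_eca=self.use_eca)
        return cfg, arch

    def fit(self, X: Sequence[LongitudinalCase], y=None) -> "LISPCNModel":
        """Train on a cohort of paired cases (labels are per-case)."""
        cases = list(X)
        if not cases or not isinstance(cases[0], LongitudinalCase):
            raise ValueError("fit expects a sequence of LongitudinalCase")
        cfg, arch = self._configs()
        cfg = ablate(cfg, cfg.ablation)
        bundle = build_bundle(arch, seed=cfg.seed, ablation=cfg.ablation)
        self.bundle_, self.state_ = train(bundle, cases, cfg)
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "bundle_"):
            raise RuntimeError("model is not fitted; call fit first")

    def predict_proba(self, X) -> np.ndarray:
        """Response probabilities, shape (n, 2), from pre-treatment stacks."""
        self._check_fitted()
        p1 = self.bundle_.predict_proba(_to_image_array(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def transform(self, X) -> np.ndarray:
        """Synthetic early-treatment stacks for pre-treatment inputs."""
        self._check_fitted()
        return self.bundle_.synthesize(_to_image_array(X))

    def finetune(self, X: Sequence[LongitudinalCase], epochs: int = 20,
                 lr: float = 5e-6) -> "LISPCNModel":
        """Head-only fine-tuning (all other parameters frozen)."""
        self._check_fitted()
        cfg, _ = self._configs()
        cfg.finetune = FinetuneConfig(epochs=epochs, lr=lr)
        finetune(self.bundle_, list(X), cfg)
        return self

    def score(self, X, y=None) -> float:
        """Held-out AUC (rank statistic) on labelled cases."""
        from .evalmetrics import auc_rank
        cases = list(X)
        labels = np.array([c.label for c in cases]) if y is None \
            else np.asarray(y)
        return auc_rank(self.predict_proba(cases)[:, 1], labels)
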