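"""Training orchestration: adversarial/classification updates, the
stepped learning-rate schedule, head-only fine-tuning and the four
ablation variants.

The published optimizer settings are used throughout: Adam with
``beta1=0.5, beta2=0.99``, batch size 8, initial learning rates 2e-3 for
the generative-adversarial components and 1e-4 for the classifier head,
both multiplied by 0.97 every 50 epochs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cases import LongitudinalCase
from .dataio import AugmentStream
from .network import ArchConfig, ModelBundle, build_bundle
from .nn import Adam
from .nn.tensor import Tensor
from .objectives import (LossWeights, classification_loss,
                         discriminator_objective, generator_objective)

ABLATIONS = ("none", "AS-Dec", "AS-Dis", "AS-GF", "AS-Pcp")


@dataclass
class FinetuneConfig:
    epochs: int = 20
    lr: float = 5e-6
    scope: str = "classification-head"


@dataclass
class TrainConfig:
    """All training hyperparameters."""

    beta1: float = 0.5
    beta2: float = 0.99
    batch_size: int = 8
    lr_gan: float = 2e-3
    lr_cls: float = 1e-4
    decay_factor: float = 0.97
    decay_every: int = 50
    epochs: int = 10
    seed: int = 0
    ablation: str = "none"
    weights: LossWeights = field(default_factory=LossWeights)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    augment: bool = True
    fake_buffer_size: int = 50
    max_iterations: Optional[int] = None
    weight_decay: float = 0.0
    # optional classification warm-up: the first iterations update
    # encoder+head on the classification loss alone before the joint
    # adversarial phase.  Counts toward max_iterations.  Off by default.
    cls_warmup_iterations: int = 0

    def validate(self) -> None:
        if self.lr_gan <= 0 or self.lr_cls <= 0:
            raise ValueError("learning rates must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"valid: {ABLATIONS}")
        self.weights.validate()


@dataclass
class TrainState:
    """Loss history and bookkeeping for a (resumable) run."""

    epoch: int = 0
    iteration: int = 0
    lr_gan: float = 0.0
    lr_cls: float = 0.0
    history: List[Dict[str, float]] = field(default_factory=list)

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)


def lr_at(epoch: int, base_rate: float, cfg: TrainConfig) -> float:
    """Stepped decay: ``base * decay_factor ** floor(epoch / decay_every)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return base_rate * cfg.decay_factor ** (epoch // cfg.decay_every)


def ablate(cfg: TrainConfig, variant: str) -> TrainConfig:
    """Return a config for one ablation variant.

    ``AS-Dec``: decoder and both generative paths removed — a plain CNN
    classifier.  ``AS-Dis``: discriminators removed, adversarial terms
    zeroed, reconstruction kept.  ``AS-GF``: backward generator F removed,
    cycle term zeroed, paired (perceptual) translation kept.  ``AS-Pcp``:
    perceptual weight zeroed.
    """
    if variant not in ABLATIONS:
        raise ValueError(f"unknown ablation {variant!r}; valid: {ABLATIONS}")
    cfg = replace(cfg, ablation=variant,
                  weights=replace(cfg.weights))
    if variant == "AS-GF":
        cfg.weights.lambda_cyc = 0.0
    elif variant == "AS-Pcp":
        cfg.weights.lambda_pcp = 0.0
    return cfg


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n - batch_size + 1, batch_size):
        yield order[start:start + batch_size]


class _FakeBuffer:
    """Pool of past generator outputs used for critic updates.

    With probability 1/2 a stored fake is returned in place of the fresh
    one (once the pool is warm), which damps critic oscillation.
    """

    def __init__(self, size: int, rng: np.random.Generator) -> None:
        self.size = size
        self.rng = rng
        self.images: List[np.ndarray] = []

    def query(self, fakes: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return fakes
        out = []
        for img in fakes:
            if len(self.images) < self.size:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                idx = int(self.rng.integers(len(self.images)))
                out.append(self.images[idx].copy())
                self.images[idx] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


def _stack_batch(cases: Sequence[LongitudinalCase],
                 idx: np.ndarray,
                 aug: Optional[AugmentStream]) -> Dict[str, np.ndarray]:
    sel = [cases[i] for i in idx]
    if aug is not None:
        sel = [aug(c) for c in sel]
    return {
        "pre": np.stack([c.pre_image for c in sel]),
        "early": np.stack([c.early_image for c in sel]),
        "label": np.array([c.label for c in sel], dtype=np.int64),
    }


def _check_finite(value: float, term: str, iteration: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite loss in term {term!r} at iteration {iteration}; "
            "aborting")


def train(bundle: ModelBundle, cohort: Sequence[LongitudinalCase],
          cfg: TrainConfig) -> Tuple[ModelBundle, TrainState]:
    """Train in place: alternating critic and generator+head updates.

    Two Adam optimizers run on disjoint parameter sets — the GAN
    components (G, F, D1, D2) at ``lr_gan`` and the classifier head at
    ``lr_cls`` — each following the stepped schedule.  All randomness
    (shuffling, augmentation, fake buffer) derives from ``cfg.seed``.
    """
    cfg.validate()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if len(cohort) < cfg.batch_size:
        raise ValueError(f"batch_size {cfg.batch_size} exceeds cohort size "
                         f"{len(cohort)}")
    ss = np.random.SeedSequence(cfg.seed)
    s_shuffle, s_aug, s_buffer = ss.spawn(3)
    rng_shuffle = np.random.default_rng(s_shuffle)
    aug = AugmentStream(int(s_aug.generate_state(1)[0] % (2 ** 31))) \
        if cfg.augment else None
    rng_buffer = np.random.default_rng(s_buffer)

    labels = np.array([c.label for c in cohort])
    n_pos = max(int(labels.sum()), 1)
    pos_weight = float((len(labels) - n_pos) / n_pos) if n_pos else 1.0

    opt_gan = Adam(bundle.trainable_gan_parameters(), cfg.lr_gan,
                   cfg.beta1, cfg.beta2, weight_decay=cfg.weight_decay)
    opt_head = Adam(bundle.head.parameters(), cfg.lr_cls,
                    cfg.beta1, cfg.beta2, weight_decay=cfg.weight_decay)
    opt_disc = None
    discs = [d for d in (bundle.D1, bundle.D2) if d is not None]
    if discs:
        disc_params = [p for d in discs for p in d.parameters()]
        opt_disc = Adam(disc_params, cfg.lr_gan, cfg.beta1, cfg.beta2)
    buffers = {id(d): _FakeBuffer(cfg.fake_buffer_size, rng_buffer)
               for d in discs}

    state = TrainState()
    bundle.train_mode()
    pure_classifier = cfg.ablation == "AS-Dec"
    batches_per_epoch = len(cohort) // cfg.batch_size
    planned = cfg.max_iterations if cfg.max_iterations is not None \
        else cfg.epochs * max(batches_per_epoch, 1)
    # warm-up never eats more than a sixth of a short run
    warmup_iters = min(cfg.cls_warmup_iterations, planned // 6)
    done = False
    for epoch in range(cfg.epochs):
        state.epoch = epoch
        state.lr_gan = lr_at(epoch, cfg.lr_gan, cfg)
        state.lr_cls = lr_at(epoch, cfg.lr_cls, cfg)
        opt_gan.lr = state.lr_gan
        opt_head.lr = state.lr_cls
        if opt_disc is not None:
            opt_disc.lr = state.lr_gan
        for idx in _batches(len(cohort), cfg.batch_size, rng_shuffle):
            batch = _stack_batch(cohort, idx, aug)
            record: Dict[str, float] = {"iteration": state.iteration,
                                        "epoch": epoch,
                                        "lr_gan": state.lr_gan,
                                        "lr_cls": state.lr_cls}
            fakes_cache: Dict[str, np.ndarray] = {}
            warmup = (not pure_classifier
                      and state.iteration < warmup_iters)
            if pure_classifier or warmup:
                z = bundle.G.encoder(Tensor(batch["pre"]))
                loss = classification_loss(bundle.head(z), batch["label"],
                                           pos_weight)
                _check_finite(float(loss.data), "cls", state.iteration)
                opt_gan.zero_grad()
                opt_head.zero_grad()
                loss.backward()
                opt_gan.step()
                opt_head.step()
                record.update(cls=float(loss.data), total=float(loss.data))
            else:
                # -- generator + head update ----------------------------
                total, breakdown = generator_objective(
                    bundle, batch, cfg.weights, pos_weight,
                    keep_fakes=fakes_cache)
                for term, value in breakdown.items():
                    _check_finite(value, term, state.iteration)
                opt_gan.zero_grad()
                opt_head.zero_grad()
                if discs:
                    for d in discs:
                        d.zero_grad()  # adv terms touched critic params
                total.backward()
                opt_gan.step()
                opt_head.step()
                record.update(breakdown)
                # -- critic update on buffered (detached) fakes ---------
                if discs:
                    with_fakes = []
                    if bundle.D1 is not None:
                        with_fakes.append((bundle.D1, batch["early"],
                                           fakes_cache["fake_early"]))
                    if bundle.D2 is not None and bundle.F is not None:
                        with_fakes.append((bundle.D2, batch["pre"],
                                           fakes_cache["fake_pre"]))
                    opt_disc.zero_grad()
                    d_total = 0.0
                    for d, real, fake in with_fakes:
                        pooled = buffers[id(d)].query(fake)
                        d_loss = discriminator_objective(
                            d, real, pooled, cfg.weights.gan_mode)
                        d_loss.backward()
                        d_total += float(d_loss.data)
                    _check_finite(d_total, "disc", state.iteration)
                    opt_disc.step()
                    record["disc"] = d_total
            state.history.append(record)
            state.iteration += 1
            if cfg.max_iterations is not None \
                    and state.iteration >= cfg.max_iterations:
                done = True
                break
        if done:
            break
    return bundle, state


def finetune(bundle: ModelBundle, cohort_subset: Sequence[LongitudinalCase],
             cfg: TrainConfig) -> ModelBundle:
    """Head-only fine-tuning on a small cohort subset.

    Only the classifier head's parameters are updated (Adam at the
    reduced fine-tune rate); every other parameter is bit-identical
    before and after.  Each case contributes the latents of both its real
    pre-treatment stack and its synthesized early-treatment stack
    ``G(pre)``, combined by a fixed averaging adapter before the head.
    """
    cfg.validate()
    if len(cohort_subset) == 0:
        raise ValueError("empty fine-tune subset")
    ft = cfg.finetune
    if ft.scope != "classification-head":
        raise ValueError(f"unsupported finetune scope {ft.scope!r}")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    labels = np.array([c.label for c in cohort_subset])
    n_pos = max(int(labels.sum()), 1)
    pos_weight = float((len(labels) - n_pos) / n_pos) if n_pos else 1.0
    opt = Adam(bundle.head.parameters(), ft.lr, cfg.beta1, cfg.beta2)
    bs = min(cfg.batch_size, len(cohort_subset))
    has_decoder = not type(bundle.G.decoder).__name__.startswith("_Empty")
    for _ in range(ft.epochs):
        for idx in _batches(len(cohort_subset), bs, rng):
            batch = _stack_batch(cohort_subset, idx, None)
            pre = Tensor(batch["pre"])
            z_pre = bundle.G.encoder(pre)
            if has_decoder:
                synth = bundle.G(pre).data  # frozen generator: plain array
                z_syn = bundle.G.encoder(Tensor(synth))
                z = (z_pre + z_syn) * 0.5
            else:
                z = z_pre
            loss = classification_loss(bundle.head(z), batch["label"],
                                       pos_weight)
            opt.zero_grad()
            for m in (bundle.G, bundle.F, bundle.D1, bundle.D2):
                if m is not None:
                    m.zero_grad()
            loss.backward()
            opt.step()
    return bundle


def train_full(cohort: Sequence[LongitudinalCase],
               cfg: Optional[TrainConfig] = None,
               arch: Optional[ArchConfig] = None
               ) -> Tuple[ModelBundle, TrainState]:
    """Build a bundle per the config's ablation flag and train it."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    cfg = ablate(cfg, cfg.ablation)  # normalize weight zeroing
    bundle = build_bundle(arch, seed=cfg.seed, ablation=cfg.ablation)
    return train(bundle, cohort, cfg)
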