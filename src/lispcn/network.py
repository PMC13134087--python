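"""Model components: shared-latent generators, Patch-GAN discriminators,
classifier head on the latent map, and a fixed perceptual feature network.

The forward translator ``G`` maps a pre-treatment 3-channel stack to a
synthetic early-treatment stack; ``F`` maps the other way.  Both are
encoder-decoder pairs whose encoder is three stride-2 convolution stages
with ascending channel widths (default 2, 4, 8), each optionally followed
by an efficient-channel-attention gate.  The classifier head reads the
latent map ``z`` produced by G's encoder through global average pooling
and a small MLP, so synthesis and response prediction share features.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .nn import (Adam, Conv2d, ECA, InstanceNorm2d, LeakyReLU, Linear,
                 Module, ReLU, Sequential, Tanh, Upsample2x, eca_kernel_size)
from .nn import tensor as T
from .nn.tensor import Tensor

__all__ = [
    "ArchConfig", "Encoder", "Decoder", "Generator", "PatchDiscriminator",
    "ClassifierHead", "PerceptualNet", "ModelBundle", "build_encoder",
    "build_bundle", "eca_kernel_size", "save_bundle", "load_bundle",
]


@dataclass
class ArchConfig:
    """Architecture hyperparameters."""

    encoder_channels: Tuple[int, ...] = (2, 4, 8)
    use_eca: bool = True
    residual_generator: bool = True
    norm_encoder: bool = True
    skip_connections: bool = True
    input_skip: bool = False
    disc_channels: Tuple[int, ...] = (8, 16, 32)
    head_hidden: int = 16
    z_pool: str = "mean"
    percnet_channels: Tuple[int, ...] = (8, 16, 32)
    percnet_seed: int = 1234

    def validate(self) -> None:
        ch = self.encoder_channels
        if any(c < 1 for c in ch) or any(a >= b for a, b in zip(ch, ch[1:])):
            raise ValueError(
                f"encoder_channels must be strictly increasing and >= 1, "
                f"got {ch}")
        if self.z_pool != "mean":
            raise ValueError(f"unsupported z_pool {self.z_pool!r}")


class Encoder(Module):
    """Three stride-2 conv stages (norm + leaky ReLU, optional ECA)."""

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator,
                 in_channels: int = 3) -> None:
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.stages: List[Sequential] = []
        c_prev = in_channels
        for i, c in enumerate(cfg.encoder_channels):
            blocks: List[Module] = [
                Conv2d(c_prev, c, kernel=3, stride=2, padding=1, rng=rng)]
            if cfg.norm_encoder:
                # instance norm conditions the shared representation;
                # without it classification learning is unreliable at
                # short iteration budgets
                blocks.append(InstanceNorm2d(c))
            blocks.append(LeakyReLU(0.2))
            if cfg.use_eca:
                blocks.append(ECA(c, rng=rng))
            stage = Sequential(*blocks)
            self._modules[f"stage{i}"] = stage
            self.stages.append(stage)
            c_prev = c
        self.out_channels = c_prev
        self.n_stages = len(cfg.encoder_channels)

    def forward(self, x: Tensor, return_stages: bool = False):
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.n_stages
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} not divisible by {div}")
        acts = []
        for stage in self.stages:
            x = stage(x)
            acts.append(x)
        return (x, acts) if return_stages else x


class Decoder(Module):
    """Mirror of the encoder: nearest-neighbour upsample + conv stages, tanh.

    With ``skip_connections`` the high-resolution encoder stage
    activations are concatenated after each upsampling stage, so the
    decoder can localize its output sharply; the latent map alone (8x8
    for a 64x64 input) has too little spatial resolution to place a
    lesion-scale edit precisely.
    """

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator,
                 out_channels: int = 3) -> None:
        super().__init__()
        widths = list(cfg.encoder_channels)[::-1]  # e.g. (8, 4, 2)
        self.use_skips = cfg.skip_connections
        # skip sources, deepest first: encoder stage i has width ch[i]
        skip_widths = list(cfg.encoder_channels[:-1])[::-1] + [0]
        self.stages: List[Sequential] = []
        c_prev = widths[0]
        plan = list(zip(widths[1:] + [widths[-1]], skip_widths))
        for i, (c, c_skip) in enumerate(plan):
            stage = Sequential(
                Upsample2x(),
                Conv2d(c_prev, c, kernel=3, stride=1, padding=1, rng=rng),
                InstanceNorm2d(c),
                ReLU())
            self._modules[f"stage{i}"] = stage
            self.stages.append(stage)
            c_prev = c + (c_skip if self.use_skips else 0)
        self.input_skip = cfg.input_skip and cfg.skip_connections
        if self.input_skip:
            # full-resolution input skip: lets the decoder correct
            # pixel-level noise (off by default — it strengthens image
            # fidelity but can destabilize the shared classification path)
            c_prev += out_channels
        head_conv = Conv2d(c_prev, out_channels, kernel=3, stride=1,
                           padding=1, rng=rng)
        # small-scale output init: the generator starts near the identity
        # map (residual path), so no clamp saturation at step 0
        head_conv.weight.data *= 0.05
        self.head = Sequential(head_conv, Tanh())

    def forward(self, z: Tensor, skips: Optional[List[Tensor]] = None,
                x_input: Optional[Tensor] = None) -> Tensor:
        h = z
        skip_list = list(skips)[::-1][1:] if skips is not None else []
        for i, stage in enumerate(self.stages):
            h = stage(h)
            if self.use_skips and i < len(skip_list):
                h = T.concat([h, skip_list[i]], axis=1)
        if self.input_skip:
            if x_input is None:
                raise ValueError("decoder with input skip needs the "
                                 "full-resolution input")
            h = T.concat([h, x_input], axis=1)
        return self.head(h)


class Generator(Module):
    """Encoder-decoder image translator with a shared latent map ``z``.

    With ``residual_generator`` (default) the decoder output is a
    bounded correction added to the input, ``clip(x + dec(z), -1, 1)``:
    the latent map is far too small to encode fine background texture,
    so the decoder learns the longitudinal *change* while the residual
    path carries the unchanged anatomy through.
    """

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.residual = cfg.residual_generator
        self.call_count = 0  # instrumented for ablation contracts

    def encode(self, x: Tensor) -> Tensor:
        return self.encoder(x)

    def forward(self, x: Tensor, return_latent: bool = False):
        self.call_count += 1
        z, acts = self.encoder(x, return_stages=True)
        out = self.decoder(z, skips=acts, x_input=x)
        if self.residual:
            out = T.clamp(x + out, -1.0, 1.0)
        return (out, z) if return_latent else out


class PatchDiscriminator(Module):
    """Fully-convolutional patch critic: one score per receptive field.

    No normalization in the first block (cycle-GAN convention); the output
    stays a spatial map — no global pooling — so each score judges a local
    patch of the input.
    """

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator,
                 in_channels: int = 3, norm: bool = True) -> None:
        super().__init__()
        blocks: List[Module] = []
        c_prev = in_channels
        for i, c in enumerate(cfg.disc_channels):
            blocks.append(Conv2d(c_prev, c, kernel=3, stride=2, padding=1,
                                 rng=rng))
            if i > 0 and norm:
                blocks.append(InstanceNorm2d(c))
            blocks.append(LeakyReLU(0.2))
            c_prev = c
        blocks.append(Conv2d(c_prev, 1, kernel=3, stride=1, padding=1, rng=rng))
        self.net = Sequential(*blocks)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class ClassifierHead(Module):
    """pCR probability from the latent map: GAP -> 2-layer MLP -> sigmoid."""

    def __init__(self, cfg: ArchConfig, rng: np.random.Generator) -> None:
        super().__init__()
        c_z = cfg.encoder_channels[-1]
        self.fc1 = Linear(c_z, cfg.head_hidden, rng=rng)
        self.fc2 = Linear(cfg.head_hidden, 1, rng=rng)

    def logit(self, z: Tensor) -> Tensor:
        pooled = T.mean(z, axis=(2, 3))            # (n, C_z)
        h = T.relu(self.fc1(pooled))
        return T.reshape(self.fc2(h), (z.shape[0],))

    def forward(self, z: Tensor) -> Tensor:
        return T.sigmoid(self.logit(z))


class PerceptualNet(Module):
    """Frozen conv pyramid defining a perceptual feature space.

    Weights are seeded at construction and never trained; a pretrained
    feature stack can be loaded from an ``.npz`` file as a drop-in.  Random
    frozen convolutional features still give a valid perceptual distance:
    distinct images map to distinct multi-scale features.
    """

    def __init__(self, seed: int = 1234,
                 channels: Tuple[int, ...] = (8, 16, 32),
                 weights_file: Optional[str] = None) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stages: List[Sequential] = []
        c_prev = 3
        for i, c in enumerate(channels):
            stage = Sequential(
                Conv2d(c_prev, c, kernel=3, stride=2, padding=1, rng=rng),
                ReLU())
            self._modules[f"stage{i}"] = stage
            self.stages.append(stage)
            c_prev = c
        if weights_file is not None:
            with np.load(weights_file) as npz:
                self.load_state_dict(dict(npz))
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x: Tensor, include_input: bool = False) -> List[Tensor]:
        feats = [x] if include_input else []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats

    def features(self, images: np.ndarray) -> np.ndarray:
        """Pooled final-stage feature vectors for an (n, 3, H, W) batch."""
        out = self.forward(Tensor(np.asarray(images, dtype=np.float32)))[-1]
        return out.data.mean(axis=(2, 3))


@dataclass
class ModelBundle:
    """All model components; ``percnet`` is frozen by contract."""

    G: Generator
    F: Optional[Generator]
    D1: Optional[PatchDiscriminator]
    D2: Optional[PatchDiscriminator]
    head: ClassifierHead
    percnet: PerceptualNet
    arch: ArchConfig
    seed: int = 0

    def components(self) -> Dict[str, Module]:
        out: Dict[str, Module] = {"G": self.G, "head": self.head}
        if self.F is not None:
            out["F"] = self.F
        if self.D1 is not None:
            out["D1"] = self.D1
        if self.D2 is not None:
            out["D2"] = self.D2
        return out

    def n_parameters(self, include_percnet: bool = False) -> int:
        n = sum(m.n_parameters() for m in self.components().values())
        if include_percnet:
            n += self.percnet.n_parameters()
        return n

    def trainable_gan_parameters(self) -> List[Tensor]:
        params = list(self.G.parameters())
        if self.F is not None:
            params += self.F.parameters()
        return params

    def train_mode(self) -> None:
        for m in self.components().values():
            m.train()

    def eval_mode(self) -> None:
        for m in self.components().values():
            m.eval()

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 32) -> np.ndarray:
        """pCR probabilities for an (n, 3, H, W) batch of pre-images."""
        images = np.asarray(images, dtype=np.float32)
        was_training = self.head.training
        self.eval_mode()
        out = []
        for start in range(0, len(images), batch_size):
            z = self.G.encoder(Tensor(images[start:start + batch_size]))
            out.append(self.head(z).data.astype(np.float64))
        if was_training:
            self.train_mode()
        return np.concatenate(out)

    def synthesize(self, images: np.ndarray,
                   batch_size: int = 32) -> np.ndarray:
        """Synthetic early-treatment stacks for pre-treatment inputs."""
        images = np.asarray(images, dtype=np.float32)
        was_training = self.G.training
        self.eval_mode()
        out = []
        for start in range(0, len(images), batch_size):
            out.append(self.G(Tensor(images[start:start + batch_size]))
                       .data.astype(np.float32))
        if was_training:
            self.train_mode()
        return np.concatenate(out)

    def state_dict(self) -> Dict:
        state = {name: m.state_dict() for name, m in self.components().items()}
        state["percnet"] = self.percnet.state_dict()
        return state


def build_encoder(cfg: Optional[ArchConfig] = None,
                  seed: int = 0) -> Encoder:
    cfg = cfg or ArchConfig()
    return Encoder(cfg, np.random.default_rng(seed))


def build_bundle(cfg: Optional[ArchConfig] = None, seed: int = 0,
                 ablation: str = "none",
                 percnet_weights: Optional[str] = None) -> ModelBundle:
    """Construct all components with seeded initialization.

    Ablation variants drop components: ``AS-Dec`` keeps only G's encoder
    plus the head (plain classifier; the decoder is still constructed but
    unused paths are removed), ``AS-Dis`` drops both discriminators,
    ``AS-GF`` drops the backward generator F.
    """
    cfg = cfg or ArchConfig()
    cfg.validate()
    if ablation not in ("none", "AS-Dec", "AS-Dis", "AS-GF", "AS-Pcp"):
        raise ValueError(f"unknown ablation {ablation!r}")
    rng = np.random.default_rng(seed)
    G = Generator(cfg, rng)
    F = Generator(cfg, rng)
    D1 = PatchDiscriminator(cfg, rng)
    D2 = PatchDiscriminator(cfg, rng)
    percnet = PerceptualNet(seed=cfg.percnet_seed,
                            channels=cfg.percnet_channels,
                            weights_file=percnet_weights)
    if ablation == "AS-Dec":
        # plain CNN classifier: no generative path at all
        G.decoder = _EmptyDecoder()
        G._modules["decoder"] = G.decoder
        F, D1, D2 = None, None, None
    elif ablation == "AS-Dis":
        D1, D2 = None, None
    elif ablation == "AS-GF":
        F = None
        D2 = None  # only the early-image domain keeps a critic
    return ModelBundle(G=G, F=F, D1=D1, D2=D2, head=ClassifierHead(cfg, rng),
                       percnet=percnet, arch=cfg, seed=seed)


class _EmptyDecoder(Module):
    """Placeholder decoder for the classifier-only ablation."""

    def forward(self, z: Tensor) -> Tensor:
        raise RuntimeError("decoder removed in AS-Dec ablation")


def save_bundle(bundle: ModelBundle, path: str,
                extra: Optional[Dict] = None) -> None:
    payload = {
        "arch": bundle.arch,
        "seed": bundle.seed,
        "ablation": _infer_ablation(bundle),
        "state": bundle.state_dict(),
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def _infer_ablation(bundle: ModelBundle) -> str:
    if isinstance(bundle.G.decoder, _EmptyDecoder):
        return "AS-Dec"
    if bundle.F is None:
        return "AS-GF"
    if bundle.D1 is None:
        return "AS-Dis"
    return "none"


def load_bundle(path: str) -> ModelBundle:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    bundle = build_bundle(payload["arch"], seed=payload["seed"],
                          ablation=payload["ablation"])
    state = payload["state"]
    for name, mod in bundle.components().items():
        mod.load_state_dict(state[name])
    bundle.percnet.load_state_dict(state["percnet"])
    return bundle
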