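"""CycleGAN modality translation: T2-weighted slices to DWI/ADC slices.

Two generators (source->target and target->source) and two PatchGAN
discriminators are trained adversarially with least-squares GAN losses,
cycle-consistency (L1 on source->target->source reconstructions, both
directions) and an identity term.  The generator is a U-Net whose encoder
and decoder levels carry attention residual blocks (residual conv pairs
gated by squeeze-excitation channel attention); skip connections are gated
by the same attention mechanism.  Training is unpaired and 2D slice-wise;
one model translates T2 into exactly one target modality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data_io import Modality, MRVolume, normalize_0_255


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


@dataclass
class GeneratorSpec:
    depth: int = 2  # number of downsampling levels
    base_channels: int = 16
    attention_residual_blocks: int = 1  # per encoder/decoder level
    attention_reduction: int = 4
    normalization: str = "instance"
    output_activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")


@dataclass
class DiscriminatorSpec:
    patch_depth: int = 3  # number of strided conv layers
    base_channels: int = 16

    def __post_init__(self) -> None:
        if self.patch_depth < 2:
            raise ValueError("patch_depth must be >= 2")


@dataclass
class TrainConfig:
    lambda_cycle: float = 10.0
    lambda_identity: float = 5.0
    adversarial_loss: str = "least_squares"
    learning_rate: float = 2e-4
    beta1: float = 0.5
    epochs: int = 10
    batch_size: int = 2
    replay_buffer_size: int = 50
    seed: int = 0
    slice_size: int = 64
    slices_per_case: int = 3  # foreground slices sampled per volume

    def __post_init__(self) -> None:
        for w in (self.lambda_cycle, self.lambda_identity):
            if not np.isfinite(w) or w < 0:
                raise ValueError("loss weights must be finite and >= 0")
        if self.adversarial_loss != "least_squares":
            raise ValueError("only the least-squares adversarial loss is supported")


# ----------------------------------------------------------------------
# building blocks


class ChannelAttention(nn.Module):
    """Squeeze-excitation gate: global average pool -> bottleneck -> sigmoid."""

    def __init__(self, channels: int, reduction: int, rng):
        hidden = max(channels // reduction, 2)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, c = x.shape[0], x.shape[1]
        s = x.mean_axes((2, 3), keepdims=False).reshape((n, c))
        s = self.fc2(self.fc1(s).relu()).sigmoid()
        return x * s.reshape((n, c, 1, 1))


class AttnResBlock(nn.Module):
    """Residual conv pair with instance norm, gated by channel attention."""

    def __init__(self, channels: int, reduction: int, rng):
        self.conv1 = nn.Conv2d(channels, channels, 3, rng=rng)
        self.norm1 = nn.InstanceNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng=rng)
        self.norm2 = nn.InstanceNorm2d(channels)
        self.attn = ChannelAttention(channels, reduction, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.norm1(self.conv1(x)).leaky_relu(0.2)
        h = self.norm2(self.conv2(h))
        return (self.attn(h) + x).leaky_relu(0.2)


class Generator(nn.Module):
    """Attention residual U-Net mapping one slice channel to one channel.

    Input and output live on the [-1, 1] scale; output shape always equals
    input shape (requires square slices with side divisible by 2**depth).
    """

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        b, d, r = spec.base_channels, spec.depth, spec.attention_reduction
        nb = spec.attention_residual_blocks
        self.stem = nn.Conv2d(1, b, 3, rng=rng)
        self.enc_blocks = []
        self.downs = []
        self.skip_gates = []
        for i in range(d):
            ch = b * 2 ** i
            self.enc_blocks.append(
                _BlockStack([AttnResBlock(ch, r, rng) for _ in range(nb)]))
            self.skip_gates.append(ChannelAttention(ch, r, rng))
            self.downs.append(nn.Conv2d(ch, ch * 2, 3, stride=2, rng=rng))
        self.bottleneck = _BlockStack(
            [AttnResBlock(b * 2 ** d, r, rng) for _ in range(nb)])
        self.ups = []
        self.merges = []
        self.dec_blocks = []
        for i in reversed(range(d)):
            ch = b * 2 ** i
            self.ups.append(nn.Conv2d(ch * 2, ch, 3, rng=rng))
            self.merges.append(nn.Conv2d(ch * 2, ch, 3, rng=rng))
            self.dec_blocks.append(
                _BlockStack([AttnResBlock(ch, r, rng) for _ in range(nb)]))
        self.head = nn.Conv2d(b, 1, 3, rng=rng)

    def _check_input(self, x: nn.Tensor) -> None:
        n, c, h, w = x.shape
        div = 2 ** self.spec.depth
        if c != 1 or h != w or h % div != 0:
            raise ValueError(
                f"generator expects square 1-channel slices with side divisible "
                f"by {div}; got shape {(n, c, h, w)}")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        self._check_input(x)
        h = self.stem(x)
        skips = []
        for blk, gate, down in zip(self.enc_blocks, self.skip_gates, self.downs):
            h = blk(h)
            skips.append(gate(h))  # attention-gated skip connection
            h = down(h).leaky_relu(0.2)
        h = self.bottleneck(h)
        for up, merge, blk, skip in zip(self.ups, self.merges, self.dec_blocks,
                                        reversed(skips)):
            h = up(nn.upsample_nearest2x(h)).leaky_relu(0.2)
            h = merge(nn.concat([h, skip], axis=1)).leaky_relu(0.2)
            h = blk(h)
        return self.head(h).tanh()


class _BlockStack(nn.Module):
    def __init__(self, blocks):
        self.blocks = blocks

    def __call__(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class Discriminator(nn.Module):
    """PatchGAN: strided convs ending in a 1-channel patch score map."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        b = spec.base_channels
        self.convs = []
        self.norms = []
        cin = 1
        for i in range(spec.patch_depth):
            cout = b * 2 ** i
            self.convs.append(nn.Conv2d(cin, cout, 4, stride=2, padding=1, rng=rng))
            self.norms.append(nn.InstanceNorm2d(cout) if i > 0 else None)
            cin = cout
        self.head = nn.Conv2d(cin, 1, 4, stride=1, padding=1, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = h.leaky_relu(0.2)
        return self.head(h)


# ----------------------------------------------------------------------
# losses


def cycle_loss(real, reconstructed):
    """Mean absolute difference between a slice and its cycle reconstruction."""
    if isinstance(real, nn.Tensor) or isinstance(reconstructed, nn.Tensor):
        real = real if isinstance(real, nn.Tensor) else nn.Tensor(real)
        reconstructed = (reconstructed if isinstance(reconstructed, nn.Tensor)
                         else nn.Tensor(reconstructed))
        if real.shape != reconstructed.shape:
            raise ValueError(f"shape mismatch {real.shape} vs {reconstructed.shape}")
        return (real - reconstructed).abs().mean()
    real = np.asarray(real)
    reconstructed = np.asarray(reconstructed)
    if real.shape != reconstructed.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {reconstructed.shape}")
    return float(np.abs(real - reconstructed).mean())


def adversarial_losses(dis_out_real, dis_out_fake):
    """Least-squares GAN objectives.

    Returns ``(gen_term, dis_term)`` with
    ``dis_term = 1/2 mean[(D(real)-1)^2] + 1/2 mean[D(fake)^2]`` and
    ``gen_term = mean[(D(fake)-1)^2]``.
    """
    r = np.asarray(dis_out_real.data if isinstance(dis_out_real, nn.Tensor)
                   else dis_out_real, dtype=float)
    f = np.asarray(dis_out_fake.data if isinstance(dis_out_fake, nn.Tensor)
                   else dis_out_fake, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(f))):
        raise ValueError("discriminator outputs must be finite")
    dis_term = 0.5 * float(((r - 1.0) ** 2).mean()) + 0.5 * float((f ** 2).mean())
    gen_term = float(((f - 1.0) ** 2).mean())
    return gen_term, dis_term


def generator_objective(adv, cyc, idt, config: TrainConfig):
    """Total generator loss: adversarial + lambda_cycle * cycle
    + lambda_identity * identity.  With ``lambda_cycle = 0`` the result is
    independent of reconstruction quality by construction."""
    total = adv + config.lambda_cycle * cyc
    if config.lambda_identity > 0 and idt is not None:
        total = total + config.lambda_identity * idt
    return total


def _lsgan_gen(d_fake: nn.Tensor) -> nn.Tensor:
    return (d_fake - 1.0).square().mean()


def _lsgan_dis(d_real: nn.Tensor, d_fake: nn.Tensor) -> nn.Tensor:
    return (d_real - 1.0).square().mean() * 0.5 + d_fake.square().mean() * 0.5


class ReplayBuffer:
    """CycleGAN image pool: discriminators see a history of generated slices."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.items: list[np.ndarray] = []

    def push_and_sample(self, batch: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return batch
        out = []
        for img in batch:
            if len(self.items) < self.size:
                self.items.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                idx = int(self.rng.integers(len(self.items)))
                out.append(self.items[idx].copy())
                self.items[idx] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


# ----------------------------------------------------------------------
# model


@dataclass
class TranslationModel:
    """One source->target CycleGAN with both generators and discriminators."""

    source_modality: Modality
    target_modality: Modality
    gen_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    dis_spec: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    config: TrainConfig = field(default_factory=TrainConfig)
    gen_s2t: Generator | None = None
    gen_t2s: Generator | None = None
    dis_t: Discriminator | None = None
    dis_s: Discriminator | None = None
    trained: bool = False
    loss_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.source_modality = Modality(self.source_modality)
        self.target_modality = Modality(self.target_modality)
        if self.source_modality == self.target_modality:
            raise ValueError("source and target modality must differ")
        if self.gen_s2t is None:
            rng = np.random.default_rng([self.config.seed, 101])
            self.gen_s2t = Generator(self.gen_spec, rng)
            self.gen_t2s = Generator(self.gen_spec, rng)
            self.dis_t = Discriminator(self.dis_spec, rng)
            self.dis_s = Discriminator(self.dis_spec, rng)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for tag, mod in (("gen_s2t", self.gen_s2t), ("gen_t2s", self.gen_t2s),
                         ("dis_t", self.dis_t), ("dis_s", self.dis_s)):
            for k, v in mod.state_dict().items():
                arrays[f"{tag}/{k}"] = v
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "source_modality": self.source_modality.value,
            "target_modality": self.target_modality.value,
            "gen_spec": asdict(self.gen_spec),
            "dis_spec": asdict(self.dis_spec),
            "config": asdict(self.config),
            "trained": self.trained,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)
        if self.loss_log is not None:
            self.loss_log.to_csv(path.with_suffix(".loss.csv"), index=False)
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "TranslationModel":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sc = json.load(fh)
        model = cls(source_modality=sc["source_modality"],
                    target_modality=sc["target_modality"],
                    gen_spec=GeneratorSpec(**sc["gen_spec"]),
                    dis_spec=DiscriminatorSpec(**sc["dis_spec"]),
                    config=TrainConfig(**sc["config"]))
        data = np.load(path.with_suffix(".npz"))
        for tag, mod in (("gen_s2t", model.gen_s2t), ("gen_t2s", model.gen_t2s),
                         ("dis_t", model.dis_t), ("dis_s", model.dis_s)):
            state = {k.split("/", 1)[1]: data[k] for k in data.files
                     if k.startswith(tag + "/")}
            mod.load_state_dict(state)
        model.trained = bool(sc["trained"])
        loss_csv = path.with_suffix(".loss.csv")
        if loss_csv.exists():
            model.loss_log = pd.read_csv(loss_csv)
        return model


# ----------------------------------------------------------------------
# slice plumbing


def to_unit_range(norm_slice: np.ndarray) -> np.ndarray:
    """0-255 display scale -> generator's [-1, 1] scale."""
    return np.asarray(norm_slice, dtype=nn.DTYPE) / 127.5 - 1.0


def from_unit_range(x: np.ndarray) -> np.ndarray:
    """[-1, 1] -> 0-255."""
    return (np.clip(x, -1.0, 1.0) + 1.0) * 127.5


def training_slices(vol: MRVolume, mask: np.ndarray, n_slices: int) -> list[np.ndarray]:
    """Up to ``n_slices`` evenly spaced foreground slices on the [-1,1] scale.

    Slices with no tumor foreground are dropped (they carry no anatomy the
    translator must learn).  The volume is display-normalized first.
    """
    norm = normalize_0_255(vol).voxels
    fg = np.where(mask.any(axis=(0, 1)))[0]
    if fg.size == 0:
        return []
    idx = fg[np.unique(np.linspace(0, fg.size - 1, min(n_slices, fg.size)).astype(int))]
    return [to_unit_range(norm[:, :, z]) for z in idx]


def _as_batch(slices: list[np.ndarray]) -> np.ndarray:
    return np.stack(slices)[:, None, :, :]  # (N, 1, H, W)


# ----------------------------------------------------------------------
# training


def train(model: TranslationModel, source_slices: list[np.ndarray],
          target_slices: list[np.ndarray],
          config: TrainConfig | None = None) -> TranslationModel:
    """Train both cycles on unpaired source/target slices (in [-1, 1]).

    The same generators serve both cycles; discriminators are updated from
    a replay buffer of past generated slices.  Appends a per-epoch loss log
    (adversarial, cycle, identity, discriminator) to ``model.loss_log``.
    """
    cfg = config or model.config
    if not source_slices or not target_slices:
        raise ValueError("training requires non-empty source and target slice sets")
    rng = np.random.default_rng([cfg.seed, 202])
    g_params = model.gen_s2t.parameters() + model.gen_t2s.parameters()
    d_params = model.dis_t.parameters() + model.dis_s.parameters()
    steps_per_epoch = max(1, int(np.ceil(len(source_slices) / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs

    def lin_decay(t):  # constant first half, linear decay to 0 over second half
        half = total_steps / 2.0
        return 1.0 if t <= half else max(0.0, (total_steps - t) / max(half, 1.0))

    opt_g = nn.Adam(g_params, lr=cfg.learning_rate, beta1=cfg.beta1, lr_schedule=lin_decay)
    opt_d = nn.Adam(d_params, lr=cfg.learning_rate, beta1=cfg.beta1, lr_schedule=lin_decay)
    buf_t = ReplayBuffer(cfg.replay_buffer_size, rng)
    buf_s = ReplayBuffer(cfg.replay_buffer_size, rng)

    src = _as_batch(source_slices).astype(nn.DTYPE)
    tgt = _as_batch(target_slices).astype(nn.DTYPE)
    log_rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(src))
        acc = {"loss_gen_adv": 0.0, "loss_cycle": 0.0,
               "loss_identity": 0.0, "loss_dis": 0.0}
        for step in range(steps_per_epoch):
            sel = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            real_s = nn.Tensor(src[sel])
            tsel = rng.integers(0, len(tgt), size=len(sel))
            real_t = nn.Tensor(tgt[tsel])

            # ---- generator update
            fake_t = model.gen_s2t(real_s)
            rec_s = model.gen_t2s(fake_t)
            fake_s = model.gen_t2s(real_t)
            rec_t = model.gen_s2t(fake_s)
            adv = _lsgan_gen(model.dis_t(fake_t)) + _lsgan_gen(model.dis_s(fake_s))
            cyc = cycle_loss(real_s, rec_s) + cycle_loss(real_t, rec_t)
            idt = None
            if cfg.lambda_identity > 0:
                idt = (cycle_loss(real_t, model.gen_s2t(real_t))
                       + cycle_loss(real_s, model.gen_t2s(real_s)))
            loss_g = generator_objective(adv, cyc, idt, cfg)
            idt_val = 0.0 if idt is None else float(idt.data)
            for p in g_params:
                p.grad = None
            loss_g.backward()
            opt_g.step()

            # ---- discriminator update (replay buffer, detached fakes)
            fb_t = nn.Tensor(buf_t.push_and_sample(fake_t.data.copy()))
            fb_s = nn.Tensor(buf_s.push_and_sample(fake_s.data.copy()))
            loss_d = (_lsgan_dis(model.dis_t(real_t), model.dis_t(fb_t))
                      + _lsgan_dis(model.dis_s(real_s), model.dis_s(fb_s)))
            for p in d_params:
                p.grad = None
            loss_d.backward()
            opt_d.step()

            vals = {"loss_gen_adv": float(adv.data), "loss_cycle": float(cyc.data),
                    "loss_identity": idt_val, "loss_dis": float(loss_d.data)}
            if not all(np.isfinite(v) for v in vals.values()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} step {step}: {vals}")
            for k, v in vals.items():
                acc[k] += v
        row = {"epoch": epoch, **{k: v / steps_per_epoch for k, v in acc.items()}}
        log_rows.append(row)
    new_log = pd.DataFrame(log_rows)
    model.loss_log = (new_log if model.loss_log is None
                      else pd.concat([model.loss_log, new_log], ignore_index=True))
    model.trained = True
    return model


def train_on_cohort(model: TranslationModel, cases, config: TrainConfig | None = None
                    ) -> TranslationModel:
    """Convenience wrapper: pull unpaired slices out of phantom cases."""
    cfg = config or model.config
    src, tgt = [], []
    for case in cases:
        vols = case.volumes
        src += training_slices(vols[model.source_modality], case.mask, cfg.slices_per_case)
        tgt += training_slices(vols[model.target_modality], case.mask, cfg.slices_per_case)
    return train(model, src, tgt, cfg)


def synthesize(model: TranslationModel, t2: MRVolume) -> MRVolume:
    """Translate a display-normalized source volume slice-by-slice.

    Output is restacked with the source geometry on the 0-255 scale and
    tagged with the model's target modality.  Inference is deterministic.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained; call train() first")
    x = np.asarray(t2.voxels, dtype=float)
    batch = np.stack([to_unit_range(x[:, :, z]) for z in range(x.shape[2])])[:, None]
    out = model.gen_s2t(nn.Tensor(batch.astype(nn.DTYPE))).data
    vol = np.moveaxis(from_unit_range(out[:, 0]), 0, 2)
    return MRVolume(vol, t2.spacing, model.target_modality)
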