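"""VM-TE-UNet: a Mamba-style U-Net for fracture-lesion segmentation.

The encoder/decoder is built from Vision State Space blocks with Triplet
Attention (VSS-TA): a residual unit that layer-normalizes its input, runs a
four-direction selective-scan state-space mixer (SS2D) over the feature map,
and gates the result with a three-branch rotate-pool-convolve attention.
Patch merging halves resolution between encoder stages; patch expanding
restores it in the decoder. After every decoder hidden layer an Edge Feature
Decoupling Module (EFDM) emits three supervised maps — an edge probability
(Edge-Guided Module, a parallel atrous-convolution stack), a noise map and a
texture map (small convolutional heads) — and optionally feeds the edge
pathway back additively and the noise pathway subtractively into the features.

Deep supervision: one (edge, noise, texture) triple per decoder stage, with
targets block-reduced to each stage's resolution (max for binary edges, mean
for the scalar maps).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .io import DatasetManifest, HUVolume, load_dataset_calibration, read_mask, read_stack
from .losses import LossWeights, total_loss
from .metrics import dsc as dsc_metric
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "NetworkConfig",
    "ForwardOutput",
    "TargetPyramid",
    "TripletAttention",
    "SS2D",
    "VSSTABlock",
    "EFDM",
    "VMTEUNet",
    "build_target_pyramid",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

HU_INPUT_SCALE = 1000.0  # HU are divided by this before entering the network


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and ablation switches.

    The four EFDM/attention flags materialize the ablation lattice: the plain
    VM-UNet-equivalent baseline (attention and all branches off), VM-TA-UNet
    (attention only), and the +EGM / +EGM+NSM / full variants.
    """

    input_channels: int = 1
    num_classes: int = 2
    encoder_depths: tuple[int, ...] = (2, 2, 2, 2)
    stage_dims: tuple[int, ...] = (32, 64, 128, 256)
    patch_size: int = 4
    state_dim: int = 8
    dt_rank: int = 0  # 0 -> auto (dim // 8, at least 1)
    conv_kernel: int = 3  # depthwise conv inside SS2D
    ta_kernel: int = 7
    egm_atrous_rates: tuple[int, ...] = (1, 2, 4, 8)
    efdm_hidden: int = 8
    use_triplet_attention: bool = True
    use_egm: bool = True
    use_nsm: bool = True
    use_tpm: bool = True
    efdm_refine: bool = True
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.encoder_depths) != len(self.stage_dims):
            raise ValueError("encoder_depths and stage_dims must have equal length")
        if self.ta_kernel % 2 != 1:
            raise ValueError("ta_kernel must be odd")
        if any(r < 1 for r in self.egm_atrous_rates):
            raise ValueError("atrous rates must be >= 1")
        if len(self.stage_dims) < 2:
            raise ValueError("need at least two stages")

    @property
    def n_stages(self) -> int:
        return len(self.stage_dims)

    @property
    def downsample_factor(self) -> int:
        return self.patch_size * 2 ** (self.n_stages - 1)

    @property
    def use_efdm(self) -> bool:
        return self.use_egm or self.use_nsm or self.use_tpm

    def vm_unet_equivalent(self) -> "NetworkConfig":
        """Baseline graph: no triplet attention, no EFDM branches."""
        return replace(self, use_triplet_attention=False, use_egm=False, use_nsm=False, use_tpm=False)

    def ablation_variants(self) -> dict[str, "NetworkConfig"]:
        """The four-variant ablation lattice over the EFDM branches."""
        return {
            "vm_ta_unet": replace(self, use_egm=False, use_nsm=False, use_tpm=False),
            "egm": replace(self, use_egm=True, use_nsm=False, use_tpm=False),
            "egm_nsm": replace(self, use_egm=True, use_nsm=True, use_tpm=False),
            "vm_te_unet": replace(self, use_egm=True, use_nsm=True, use_tpm=True),
        }


@dataclass
class ForwardOutput:
    """Network outputs: segmentation logits/probability plus M per-stage triples."""

    seg_logits: Tensor  # (B, num_classes, H, W)
    seg_prob: Tensor  # (B, H, W) foreground probability
    aux: list[tuple[Tensor | None, Tensor | None, Tensor | None]]  # (edge_prob, noise, texture)


@dataclass
class TargetPyramid:
    """Supervision targets aligned with ForwardOutput: full-res ROI plus per-stage triples."""

    roi: np.ndarray  # (B, H, W) float
    aux: list[tuple[np.ndarray, np.ndarray, np.ndarray]]


# -------------------------------------------------------------------- modules
class TripletAttention(nn.Module):
    """Rotate-to-attend attention: three branches each swap one axis pair with
    the channel axis, Z-pool (max + mean) over the leading axis, convolve, and
    gate the permuted input with a sigmoid; branch outputs are averaged."""

    # axis permutations applied to (B, C, H, W); each is its own inverse
    _PERMS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 2, 1))

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("triplet-attention kernel must be odd")
        self.convs = [
            nn.Conv2d(2, 1, kernel, rng, padding=kernel // 2, bias=True) for _ in self._PERMS
        ]

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        outs = []
        for perm, conv in zip(self._PERMS, self.convs):
            xp = x.transpose(perm)
            pooled = nn.concat([xp.max(axis=1, keepdims=True), xp.mean(axis=1, keepdims=True)], axis=1)
            gate = conv(pooled).sigmoid()  # in (0,1), broadcast over leading axis
            outs.append((xp * gate).transpose(perm))
        return outs

    def forward(self, x: Tensor) -> Tensor:
        outs = self.branch_outputs(x)
        return (outs[0] + outs[1] + outs[2]) * (1.0 / 3.0)


def _inv_softplus(x: np.ndarray) -> np.ndarray:
    return x + np.log(-np.expm1(-x))


class SS2D(nn.Module):
    """Four-direction selective-scan mixer over a 2-D feature map.

    The map is unfolded row-major, column-major and their reverses; each
    sequence runs through an input-dependent state-space recurrence; the four
    results are folded back, summed, layer-normalized and gated by a SiLU
    pathway from the input projection.
    """

    def __init__(self, dim: int, state_dim: int, rng: np.random.Generator,
                 conv_kernel: int = 3, dt_rank: int = 0):
        super().__init__()
        self.dim = dim
        self.state_dim = state_dim
        self.dt_rank = dt_rank if dt_rank > 0 else max(1, dim // 8)
        self.in_proj = nn.Conv2d(dim, 2 * dim, 1, rng)
        self.dwconv = nn.Conv2d(dim, dim, conv_kernel, rng, padding=conv_kernel // 2, depthwise=True)
        self.x_projs = [nn.Linear(dim, self.dt_rank + 2 * state_dim, rng, bias=False) for _ in range(4)]
        self.dt_projs = [nn.Linear(self.dt_rank, dim, rng) for _ in range(4)]
        for lin in self.dt_projs:  # softplus(bias) spread over [1e-3, 1e-1]
            dt = np.exp(rng.uniform(math.log(1e-3), math.log(1e-1), size=dim))
            lin.bias.data = _inv_softplus(dt)
        self.A_logs = [nn.Parameter(np.tile(np.log(np.arange(1, state_dim + 1, dtype=np.float64)), (dim, 1)))
                       for _ in range(4)]
        self.Ds = [nn.Parameter(np.ones(dim)) for _ in range(4)]
        self.out_norm = nn.LayerNorm(dim)
        self.out_proj = nn.Conv2d(dim, dim, 1, rng)

    def _unfold(self, x: Tensor, direction: int) -> Tensor:
        B, C, H, W = x.shape
        if direction in (0, 2):
            seq = x.reshape(B, C, H * W)
        else:
            seq = x.transpose(0, 1, 3, 2).reshape(B, C, H * W)
        if direction >= 2:
            seq = seq.flip(2)
        return seq

    def _fold(self, seq: Tensor, direction: int, H: int, W: int) -> Tensor:
        B, C, _ = seq.shape
        if direction >= 2:
            seq = seq.flip(2)
        if direction in (0, 2):
            return seq.reshape(B, C, H, W)
        return seq.reshape(B, C, W, H).transpose(0, 1, 3, 2)

    def scan_directions(self, x: Tensor) -> list[Tensor]:
        """Per-direction scan responses folded back to (B, C, H, W), pre-mixing."""
        B, C, H, W = x.shape
        outs = []
        for k in range(4):
            u = self._unfold(x, k)  # (B, C, L)
            x_dbl = u.transpose(0, 2, 1) @ self.x_projs[k].weight  # (B, L, R+2N)
            R, N = self.dt_rank, self.state_dim
            dt = (x_dbl[:, :, :R] @ self.dt_projs[k].weight + self.dt_projs[k].bias).softplus()
            dt = dt.transpose(0, 2, 1)  # (B, C, L)
            Bm = x_dbl[:, :, R:R + N].transpose(0, 2, 1)  # (B, N, L)
            Cm = x_dbl[:, :, R + N:].transpose(0, 2, 1)
            A = -(self.A_logs[k].exp())
            y = F.selective_scan(u, dt, A, Bm, Cm, self.Ds[k])
            outs.append(self._fold(y, k, H, W))
        return outs

    def forward(self, x: Tensor) -> Tensor:
        xz = self.in_proj(x)
        x1, z = xz[:, : self.dim], xz[:, self.dim:]
        x1 = self.dwconv(x1).silu()
        ys = self.scan_directions(x1)
        y = ys[0] + ys[1] + ys[2] + ys[3]
        y = self.out_norm(y) * z.silu()
        return self.out_proj(y)


class VSSTABlock(nn.Module):
    """Residual VSS block, optionally gated by triplet attention:
    ``x + TA(SS2D(LN(x)))``."""

    def __init__(self, dim: int, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(dim)
        self.ss2d = SS2D(dim, cfg.state_dim, rng, conv_kernel=cfg.conv_kernel, dt_rank=cfg.dt_rank)
        self.attn = TripletAttention(cfg.ta_kernel, rng) if cfg.use_triplet_attention else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.ss2d(self.norm(x))
        if self.attn is not None:
            y = self.attn(y)
        return x + y


class PatchEmbed(nn.Module):
    def __init__(self, in_ch: int, dim: int, patch_size: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, dim, patch_size, rng, stride=patch_size)
        self.norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.proj(x))


def _space_to_depth(x: Tensor, s: int) -> Tensor:
    B, C, H, W = x.shape
    x = x.reshape(B, C, H // s, s, W // s, s)
    x = x.transpose(0, 1, 3, 5, 2, 4)
    return x.reshape(B, C * s * s, H // s, W // s)


def _depth_to_space(x: Tensor, s: int) -> Tensor:
    B, C, H, W = x.shape
    x = x.reshape(B, C // (s * s), s, s, H, W)
    x = x.transpose(0, 1, 4, 2, 5, 3)
    return x.reshape(B, C // (s * s), H * s, W * s)


class PatchMerging(nn.Module):
    def __init__(self, dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Conv2d(4 * dim, out_dim, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.reduce(self.norm(_space_to_depth(x, 2)))


class PatchExpand(nn.Module):
    def __init__(self, dim: int, out_dim: int, rng: np.random.Generator, scale: int = 2):
        super().__init__()
        self.scale = scale
        self.expand = nn.Conv2d(dim, out_dim * scale * scale, 1, rng, bias=False)
        self.norm = nn.LayerNorm(out_dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(_depth_to_space(self.expand(x), self.scale))


class EFDM(nn.Module):
    """Edge Feature Decoupling Module.

    EGM: parallel atrous convolutions fused to a one-channel edge map.
    NSM / TPM: conv-norm-ReLU heads emitting one-channel noise / texture maps.
    When refinement is on, the edge pathway is added to and the noise pathway
    subtracted from the features.
    """

    def __init__(self, dim: int, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        h = cfg.efdm_hidden
        self.use_egm, self.use_nsm, self.use_tpm = cfg.use_egm, cfg.use_nsm, cfg.use_tpm
        self.refine = cfg.efdm_refine
        if self.use_egm:
            self.atrous = [
                nn.Conv2d(dim, h, 3, rng, padding=r, dilation=r) for r in cfg.egm_atrous_rates
            ]
            self.egm_bn = nn.BatchNorm2d(h * len(cfg.egm_atrous_rates))
            self.egm_head = nn.Conv2d(h * len(cfg.egm_atrous_rates), 1, 1, rng)
            self.egm_back = nn.Conv2d(h * len(cfg.egm_atrous_rates), dim, 1, rng, bias=False)
        if self.use_nsm:
            self.nsm_conv = nn.Conv2d(dim, h, 3, rng, padding=1)
            self.nsm_bn = nn.BatchNorm2d(h)
            self.nsm_head = nn.Conv2d(h, 1, 1, rng)
            self.nsm_back = nn.Conv2d(h, dim, 1, rng, bias=False)
        if self.use_tpm:
            self.tpm_conv = nn.Conv2d(dim, h, 3, rng, padding=1)
            self.tpm_bn = nn.BatchNorm2d(h)
            self.tpm_head = nn.Conv2d(h, 1, 1, rng)

    def forward(self, x: Tensor) -> tuple[Tensor | None, Tensor | None, Tensor | None, Tensor]:
        edge_prob = y_n = y_t = None
        refined = x
        if self.use_egm:
            feats = nn.concat([conv(x) for conv in self.atrous], axis=1)
            feats = self.egm_bn(feats).relu()
            edge_prob = self.egm_head(feats).sigmoid()[:, 0]  # (B, h, w)
            if self.refine:
                refined = refined + self.egm_back(feats)
        if self.use_nsm:
            nf = self.nsm_bn(self.nsm_conv(x)).relu()
            y_n = self.nsm_head(nf)[:, 0]
            if self.refine:
                refined = refined - self.nsm_back(nf)
        if self.use_tpm:
            tf = self.tpm_bn(self.tpm_conv(x)).relu()
            y_t = self.tpm_head(tf)[:, 0]
        return edge_prob, y_n, y_t, refined


class VMTEUNet(nn.Module):
    """Encoder-decoder of VSS-TA blocks with per-decoder-stage EFDM supervision."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = cfg.stage_dims
        self.patch_embed = PatchEmbed(cfg.input_channels, dims[0], cfg.patch_size, rng)
        self.enc_stages = [
            [VSSTABlock(dims[i], cfg, rng) for _ in range(cfg.encoder_depths[i])]
            for i in range(cfg.n_stages)
        ]
        self.downs = [PatchMerging(dims[i], dims[i + 1], rng) for i in range(cfg.n_stages - 1)]
        dec_depths = tuple(reversed(cfg.encoder_depths))[1:]
        self.ups = [PatchExpand(dims[i + 1], dims[i], rng) for i in reversed(range(cfg.n_stages - 1))]
        self.dec_stages = [
            [VSSTABlock(dims[i], cfg, rng) for _ in range(dec_depths[j])]
            for j, i in enumerate(reversed(range(cfg.n_stages - 1)))
        ]
        self.efdms = (
            [EFDM(dims[i], cfg, rng) for i in reversed(range(cfg.n_stages - 1))]
            if cfg.use_efdm else []
        )
        self.final_expand = PatchExpand(dims[0], dims[0], rng, scale=cfg.patch_size)
        self.head = nn.Conv2d(dims[0], cfg.num_classes, 1, rng)

    @property
    def num_decoder_stages(self) -> int:
        return self.cfg.n_stages - 1

    def forward(self, x) -> ForwardOutput:
        x = nn.as_tensor(x)
        if x.ndim == 3:  # (B, H, W) -> single channel
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        B, C, H, W = x.shape
        f = self.cfg.downsample_factor
        if H % f or W % f:
            raise ValueError(f"input spatial size {(H, W)} must be a multiple of {f}")
        feat = self.patch_embed(x)
        skips = []
        for i, stage in enumerate(self.enc_stages):
            for block in stage:
                feat = block(feat)
            if i < len(self.downs):
                skips.append(feat)
                feat = self.downs[i](feat)
        aux: list[tuple[Tensor | None, Tensor | None, Tensor | None]] = []
        for j, up in enumerate(self.ups):
            feat = up(feat) + skips[-(j + 1)]
            for block in self.dec_stages[j]:
                feat = block(feat)
            if self.efdms:
                edge_prob, y_n, y_t, feat = self.efdms[j](feat)
                aux.append((edge_prob, y_n, y_t))
            else:
                aux.append((None, None, None))
        feat = self.final_expand(feat)
        logits = self.head(feat)
        prob = (logits[:, 1] - logits[:, 0]).sigmoid()
        return ForwardOutput(seg_logits=logits, seg_prob=prob, aux=aux)


# ---------------------------------------------------------- target pyramids
def _block_reduce(arr: np.ndarray, f: int, how: str) -> np.ndarray:
    B, H, W = arr.shape
    r = arr.reshape(B, H // f, f, W // f, f)
    return r.max(axis=(2, 4)) if how == "max" else r.mean(axis=(2, 4))


def build_target_pyramid(
    roi: np.ndarray,
    edge: np.ndarray,
    noise: np.ndarray,
    texture: np.ndarray,
    cfg: NetworkConfig,
) -> TargetPyramid:
    """Downsample full-resolution targets to each decoder stage's resolution.

    Binary edges are max-reduced (so thin boundaries survive); the scalar noise
    and texture maps are area-averaged.
    """
    roi = np.asarray(roi, dtype=np.float64)
    aux = []
    n_dec = len(cfg.stage_dims) - 1
    for j in range(n_dec):
        f = cfg.patch_size * 2 ** (n_dec - 1 - j)
        aux.append(
            (
                _block_reduce(np.asarray(edge, dtype=np.float64), f, "max"),
                _block_reduce(np.asarray(noise, dtype=np.float64), f, "mean"),
                _block_reduce(np.asarray(texture, dtype=np.float64), f, "mean"),
            )
        )
    return TargetPyramid(roi=roi, aux=aux)


# ------------------------------------------------------------- training loop
def save_checkpoint(model: VMTEUNet, path: str | Path) -> None:
    """Single-archive checkpoint: weights plus the full network config as JSON."""
    state = model.state_dict()
    cfg_dict = asdict(model.cfg)
    np.savez(Path(path), __config__=np.array(json.dumps(cfg_dict)), **state)


def load_checkpoint(path: str | Path) -> VMTEUNet:
    archive = np.load(Path(path), allow_pickle=False)
    cfg_dict = json.loads(str(archive["__config__"]))
    cfg_dict["loss_weights"] = LossWeights(**cfg_dict["loss_weights"])
    for key in ("encoder_depths", "stage_dims", "egm_atrous_rates"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = VMTEUNet(NetworkConfig(**cfg_dict))
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model


def _samples_from_manifest(manifest: DatasetManifest, split: str, aux_params=None) -> list:
    """Lesion-containing slices of a split, with derived auxiliary masks."""
    from .phantom import TrainingSample, derive_aux_masks

    samples = []
    cal, voxel_size = load_dataset_calibration(manifest.root)
    for entry in manifest.select(split=split):
        vol = read_stack(manifest.resolve(entry.image_path), cal=cal, voxel_size_mm=voxel_size)
        roi = read_mask(manifest.resolve(entry.roi_path), image_shape=vol.shape)
        for s in range(vol.shape[0]):
            if not roi[s].any():
                continue
            edge, m_n, m_t = derive_aux_masks(vol.data[s], roi[s], **(aux_params or {}))
            samples.append(
                TrainingSample(
                    image=vol.data[s], roi=roi[s], edge_gt=edge, noise_gt=m_n, texture_gt=m_t,
                    subject_id=entry.subject_id, day=entry.day, group=entry.group,
                )
            )
    return samples


def _batch_arrays(samples: Sequence) -> np.ndarray:
    return np.stack([s.image for s in samples])[:, None] / HU_INPUT_SCALE


def train(
    data: DatasetManifest | Sequence,
    cfg: NetworkConfig,
    epochs: int = 100,
    out_dir: str | Path = "runs",
    lr: float = 1e-5,
    batch_size: int = 16,
    max_steps: int | None = None,
    seed: int = 0,
    val_data: Sequence | None = None,
) -> dict:
    """Train the network; returns a summary with the log and checkpoint paths.

    ``data`` is either a dataset manifest (its train/val splits are used,
    lesion-containing slices only) or an explicit sequence of TrainingSamples.
    Defaults follow the reference training recipe: Adam, learning rate 1e-5,
    batch size 16. The best-validation-DSC checkpoint is kept; training loss
    and validation DSC/HD95 are logged per epoch to CSV.
    """
    from .metrics import hausdorff

    if isinstance(data, DatasetManifest):
        train_samples = _samples_from_manifest(data, "train")
        val_samples = _samples_from_manifest(data, "val")
    else:
        train_samples = list(data)
        val_samples = list(val_data) if val_data is not None else []
    if not train_samples:
        raise ValueError("training split is empty")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = VMTEUNet(cfg)
    opt = nn.Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed)

    pyramids = [
        build_target_pyramid(s.roi[None], s.edge_gt[None], s.noise_gt[None], s.texture_gt[None], cfg)
        for s in train_samples
    ]

    log_rows = []
    best_val = -1.0
    best_loss = float("inf")
    ckpt_path = out_dir / "checkpoint.npz"
    steps_done = 0
    for epoch in range(epochs):
        if max_steps is not None and steps_done >= max_steps:
            break
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), batch_size):
            if max_steps is not None and steps_done >= max_steps:
                break
            idx = order[start:start + batch_size]
            batch = [train_samples[i] for i in idx]
            images = _batch_arrays(batch)
            targets = TargetPyramid(
                roi=np.stack([train_samples[i].roi for i in idx]).astype(np.float64),
                aux=[
                    tuple(np.concatenate([pyramids[i].aux[j][m] for i in idx]) for m in range(3))
                    for j in range(model.num_decoder_stages)
                ],
            )
            out = model.forward(images)
            loss, breakdown = total_loss(out, targets, cfg.loss_weights)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"non-finite loss at step {steps_done}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            steps_done += 1
        train_loss = float(np.mean(losses)) if losses else float("nan")

        val_dsc = val_hd95 = float("nan")
        if val_samples:
            model.eval()
            dscs, hds = [], []
            for s in val_samples:
                pred = predict(model, s.image[None])[0]
                dscs.append(dsc_metric(pred, s.roi))
                try:
                    _, h95 = hausdorff(pred, s.roi)
                    hds.append(h95)
                except ValueError:
                    pass
            model.train()
            val_dsc = float(np.mean(dscs))
            val_hd95 = float(np.mean(hds)) if hds else float("nan")
            if val_dsc > best_val:
                best_val = val_dsc
                save_checkpoint(model, ckpt_path)
        else:
            if train_loss < best_loss:
                best_loss = train_loss
                save_checkpoint(model, ckpt_path)
        log_rows.append({"epoch": epoch, "train_loss": train_loss, "val_dsc": val_dsc, "val_hd95": val_hd95})

    log_path = out_dir / "training_log.csv"
    with open(log_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_dsc", "val_hd95"])
        writer.writeheader()
        writer.writerows(log_rows)
    return {
        "checkpoint": ckpt_path,
        "log": log_path,
        "model": model,
        "history": log_rows,
        "steps": steps_done,
        "best_val_dsc": best_val if val_samples else None,
    }


def predict(model_or_ckpt: VMTEUNet | str | Path, stack, batch_size: int = 8) -> np.ndarray:
    """Per-slice lesion masks (argmax over class logits) for an image stack.

    ``stack`` is an HUVolume or an (S, H, W) array in HU; returns (S, H, W) bool.
    """
    model = model_or_ckpt if isinstance(model_or_ckpt, VMTEUNet) else load_checkpoint(model_or_ckpt)
    data = stack.data if isinstance(stack, HUVolume) else np.asarray(stack, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"stack must be (slices, rows, cols), got shape {data.shape}")
    was_training = model.training
    model.eval()
    masks = []
    for start in range(0, data.shape[0], batch_size):
        x = data[start:start + batch_size][:, None] / HU_INPUT_SCALE
        out = model.forward(x)
        masks.append(np.argmax(out.seg_logits.data, axis=1).astype(bool))
    model.train(was_training)
    return np.concatenate(masks, axis=0)
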