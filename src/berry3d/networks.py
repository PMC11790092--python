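"""Depth and pose estimators and their joint unsupervised training loop.

The depth network is an encoder-decoder with skip connections and
multi-scale side predictions (the DispNet family); its prediction layers use
the activation ``1 / (alpha * sigmoid(x) + beta)`` with ``alpha = 10`` and
``beta = 0.01``, which confines every predicted depth to the open interval
``(1/(alpha+beta), 1/beta)`` and keeps it positive.  The pose network stacks
seven stride-2 convolutions over the channel-concatenated views, maps to
``6 * (N - 1)`` channels with a 1x1 convolution, and global-average-pools to
one six-vector (3 Euler angles, 3 translations) per source view.

Both run on the numpy autodiff engine in :mod:`berry3d.autodiff`; training
is plain Adam on CPU and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, conv2d, upsample_nearest2d
from .camera import CameraIntrinsics, UOCMCamera, fov_mask
from .transforms import RigidTransform
from .viewsynth import LossWeights, pose_vector_to_rt, reprojection_loss_t, total_loss_t

__all__ = [
    "DepthNetworkConfig",
    "PoseNetworkConfig",
    "TrainingConfig",
    "DepthNetwork",
    "PoseNetwork",
    "build_depth_network",
    "build_pose_network",
    "train",
    "fit_pose",
    "save_checkpoint",
    "load_checkpoint",
]


# -- configs -------------------------------------------------------------

@dataclass(frozen=True)
class DepthNetworkConfig:
    """Encoder widths, side-prediction scales and output-activation constants.

    The implied depth range is (1/(act_alpha + act_beta), 1/act_beta).
    ``init_depth`` sets the prediction-layer bias so an untrained network
    starts near a plausible scene depth instead of the range edge.
    """

    encoder_widths: tuple = (32, 64, 128, 256, 512, 512, 512)
    n_scales: int = 4
    act_alpha: float = 10.0
    act_beta: float = 0.01
    init_depth: float = 5.0

    def __post_init__(self) -> None:
        if self.act_alpha <= 0 or self.act_beta <= 0:
            raise ValueError("activation constants must be positive")
        lo, hi = self.depth_range
        if not (0 < lo < hi < np.inf):
            raise ValueError("implied depth range is not positive and finite")
        if not lo < self.init_depth < hi:
            raise ValueError(f"init_depth {self.init_depth} outside range ({lo}, {hi})")
        if not 1 <= self.n_scales <= len(self.encoder_widths):
            raise ValueError("n_scales must be between 1 and the number of levels")

    @property
    def depth_range(self) -> tuple[float, float]:
        return 1.0 / (self.act_alpha + self.act_beta), 1.0 / self.act_beta

    @classmethod
    def tiny(cls) -> "DepthNetworkConfig":
        """A small configuration for 64x64 CPU experiments."""
        return cls(encoder_widths=(16, 32, 64, 128), n_scales=2, init_depth=3.0)


@dataclass(frozen=True)
class PoseNetworkConfig:
    """Seven stride-2 conv widths and the number of views N (target + sources)."""

    n_views: int = 3
    conv_widths: tuple = (16, 32, 64, 128, 256, 256, 256)
    angle_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.n_views < 2:
            raise ValueError("n_views must be >= 2")
        if len(self.conv_widths) != 7:
            raise ValueError("the pose encoder uses exactly seven stride-2 convolutions")

    @property
    def out_channels(self) -> int:
        return 6 * (self.n_views - 1)

    @classmethod
    def tiny(cls) -> "PoseNetworkConfig":
        """Small configuration for short CPU runs.

        With adaptive optimizers the per-step parameter movement is on the
        order of the learning rate, so the 0.01 output scaling used for long
        large-scale trainings would make realistic inter-frame rotations
        unreachable within a few hundred steps; the tiny config therefore
        predicts raw radians.
        """
        return cls(conv_widths=(16, 32, 64, 64, 128, 128, 128), angle_scale=1.0)


@dataclass(frozen=True)
class TrainingConfig:
    """Joint-training hyperparameters.

    ``d_min``/``d_max`` are applied as a hard clamp on predicted depth before
    warping; note the output activation already bounds depth to about
    (0.0999, 100), so with the defaults only the lower bound can engage.
    """

    epochs: int = 10
    max_iterations: int | None = None
    batch_size: int = 1
    learning_rate: float = 1e-4
    pose_learning_rate: float | None = None  # defaults to learning_rate
    weights: LossWeights = field(default_factory=LossWeights)
    d_min: float = 1.0
    d_max: float = 100.0
    seed: int = 0
    loss_scales: int = 1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")

    @classmethod
    def tiny(cls, seed: int = 0, max_iterations: int = 200) -> "TrainingConfig":
        """Conditions for the scaled-down 64x64 CPU run.

        A two-speed schedule (depth 1e-3, pose 1e-2) compensates for the
        pooled pose gradients being weaker than the per-pixel depth
        gradients over a short run; the smoothness weight is raised to 0.02
        to suppress depth noise the short run cannot average away; the loss
        is applied at two scales.
        """
        return cls(epochs=10_000, max_iterations=max_iterations, batch_size=1,
                   learning_rate=1e-3, pose_learning_rate=1e-2, seed=seed,
                   weights=LossWeights(alpha_pe=0.85, lambda_smooth=0.02),
                   loss_scales=2)


# -- layers --------------------------------------------------------------

class _Conv:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int = 3, stride: int = 1, bias_init: float = 0.0,
                 zero_init: bool = False):
        fan_in = c_in * k * k
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, 1.0, size=(c_out, c_in, k, k)) * scale, requires_grad=True)
        self.b = Tensor(np.full(c_out, bias_init, dtype=float), requires_grad=True)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


def _frame_to_nchw(frame: np.ndarray) -> Tensor:
    arr = np.asarray(frame, float)
    if arr.ndim == 2:
        arr = arr[..., None]
    return Tensor(arr.transpose(2, 0, 1)[None])


# -- depth network -------------------------------------------------------

class DepthNetwork:
    """Encoder-decoder depth estimator with multi-scale side predictions."""

    def __init__(self, cfg: DepthNetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.encoder_widths
        self.enc: list[_Conv] = []
        c_prev = 3
        for c in widths:
            self.enc.append(_Conv(rng, c_prev, c, stride=2))
            c_prev = c
        # prediction bias putting the initial depth at cfg.init_depth
        sig = (1.0 / cfg.init_depth - cfg.act_beta) / cfg.act_alpha
        bias0 = float(np.log(sig / (1.0 - sig)))
        self.dec: list[_Conv] = []
        self.pred: list[_Conv | None] = []
        n_levels = len(widths)
        for i in range(n_levels - 1, -1, -1):
            c_skip = widths[i - 1] if i > 0 else 0
            c_in = widths[i] if i == n_levels - 1 else widths[i]
            c_out = widths[i - 1] if i > 0 else widths[0] // 2
            self.dec.append(_Conv(rng, c_in + c_skip if i > 0 else c_in, c_out))
            level_from_full = i  # 0 = full resolution
            if level_from_full < cfg.n_scales:
                # zero-initialized prediction layer: the untrained network
                # emits a constant depth of cfg.init_depth everywhere
                self.pred.append(_Conv(rng, c_out, 1, bias_init=bias0, zero_init=True))
            else:
                self.pred.append(None)

    @property
    def params(self) -> list[Tensor]:
        out = []
        for conv in self.enc + self.dec:
            out.extend(conv.params)
        for conv in self.pred:
            if conv is not None:
                out.extend(conv.params)
        return out

    def _activation(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        return 1.0 / (x.sigmoid() * cfg.act_alpha + cfg.act_beta)

    def forward(self, frame: np.ndarray) -> list[Tensor]:
        """Depth maps at full and side scales, finest first.

        The input (H, W, 3) must have H and W divisible by 2**levels.
        """
        x = _frame_to_nchw(frame)
        h, w = x.shape[-2:]
        factor = 2 ** len(self.enc)
        if h % factor or w % factor:
            raise ValueError(f"input size {(h, w)} not divisible by {factor}")
        skips = []
        for conv in self.enc:
            x = conv(x).relu()
            skips.append(x)
        preds: list[Tensor] = []
        n_levels = len(self.enc)
        for idx, (conv, pred) in enumerate(zip(self.dec, self.pred)):
            level = n_levels - 1 - idx  # encoder level being restored
            x = upsample_nearest2d(x)
            if level > 0:
                x = concat([x, skips[level - 1]], axis=1)
            x = conv(x).relu()
            if pred is not None:
                d = self._activation(pred(x))
                preds.append(d.reshape(d.shape[-2], d.shape[-1]))
        preds.reverse()  # finest first
        return preds

    def predict(self, frame: np.ndarray) -> np.ndarray:
        """Full-resolution depth map (numpy, no gradients)."""
        return self.forward(frame)[0].value


# -- pose network --------------------------------------------------------

class PoseNetwork:
    """Seven stride-2 convolutions, 1x1 head with 6(N-1) channels, global pooling."""

    def __init__(self, cfg: PoseNetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.convs: list[_Conv] = []
        c_prev = 3 * cfg.n_views
        for c in cfg.conv_widths:
            self.convs.append(_Conv(rng, c_prev, c, stride=2))
            c_prev = c
        # zero-initialized head: the untrained network predicts the identity pose
        self.head = _Conv(rng, c_prev, cfg.out_channels, k=1, zero_init=True)

    @property
    def params(self) -> list[Tensor]:
        out = []
        for conv in self.convs + [self.head]:
            out.extend(conv.params)
        return out

    def forward(self, target: np.ndarray, sources: list[np.ndarray]) -> list[Tensor]:
        """Six-vector pose tensors, one per source view."""
        if len(sources) != self.cfg.n_views - 1:
            raise ValueError(f"expected {self.cfg.n_views - 1} source views, got {len(sources)}")
        x = concat([_frame_to_nchw(f) for f in [target] + list(sources)], axis=1)
        if x.shape[1] != 3 * self.cfg.n_views:
            raise ValueError(f"channel count {x.shape[1]} != 3 * n_views")
        for conv in self.convs:
            x = conv(x).relu()
        x = self.head(x)                      # (1, 6(N-1), h', w')
        x = x.mean(axis=(2, 3)).reshape(-1)   # global average pooling
        return [x[6 * i:6 * i + 6] for i in range(self.cfg.n_views - 1)]

    def predict(self, target: np.ndarray, sources: list[np.ndarray]) -> list[RigidTransform]:
        out = []
        for vec in self.forward(target, sources):
            r, t = pose_vector_to_rt(vec, angle_scale=self.cfg.angle_scale)
            out.append(RigidTransform(rotation=r.value, translation=t.value))
        return out


def build_depth_network(cfg: DepthNetworkConfig, seed: int = 0) -> DepthNetwork:
    return DepthNetwork(cfg, seed=seed)


def build_pose_network(cfg: PoseNetworkConfig, seed: int = 0) -> PoseNetwork:
    return PoseNetwork(cfg, seed=seed)


# -- optimizer -----------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# -- training ------------------------------------------------------------

def _triplets(n_frames: int) -> list[tuple[int, int, int]]:
    """(t-1, t, t+1) index triplets; frames lacking both neighbors are skipped."""
    return [(t - 1, t, t + 1) for t in range(1, n_frames - 1)]


def _downsample2(img: np.ndarray) -> np.ndarray:
    """2x2 box average of an (H, W, C) image."""
    h, w = img.shape[:2]
    return img[:h - h % 2, :w - w % 2].reshape(h // 2, 2, w // 2, 2, -1).mean(axis=(1, 3))


def _scaled_camera(cam: UOCMCamera, factor: int) -> UOCMCamera:
    """Camera for an image downsampled by an integer factor (pixel-center aware)."""
    intr = cam.intrinsics
    s = 1.0 / factor
    return UOCMCamera(
        intrinsics=CameraIntrinsics(
            fx=intr.fx * s, fy=intr.fy * s,
            cx=(intr.cx + 0.5) * s - 0.5, cy=(intr.cy + 0.5) * s - 0.5),
        xi=cam.xi,
        image_size=(cam.height // factor, cam.width // factor),
    )


def _clamped_depth(depth: Tensor, tcfg: TrainingConfig) -> Tensor:
    return depth.clip(tcfg.d_min, tcfg.d_max)


class NonFiniteLossError(RuntimeError):
    """Training aborted on a non-finite loss value."""


def train(frames: list[np.ndarray], cam: UOCMCamera, tcfg: TrainingConfig,
          depth_cfg: DepthNetworkConfig | None = None,
          pose_cfg: PoseNetworkConfig | None = None,
          val_frames: list[np.ndarray] | None = None):
    """Jointly train depth and pose networks on consecutive-frame triplets.

    Minimizes ``L_reprojection + lambda_smooth * L_smoothness`` with Adam.
    Returns ``(depth_net, pose_net, history)`` where history is a dict with
    per-iteration training losses and (if ``val_frames``) validation
    reprojection losses sampled at the start and end of training.
    """
    if len(frames) < 3:
        raise ValueError("training requires at least 3 frames")
    depth_cfg = depth_cfg or DepthNetworkConfig.tiny()
    pose_cfg = pose_cfg or PoseNetworkConfig.tiny()
    rng = np.random.default_rng(tcfg.seed)
    depth_net = DepthNetwork(depth_cfg, seed=tcfg.seed)
    pose_net = PoseNetwork(pose_cfg, seed=tcfg.seed + 1)
    pose_lr = tcfg.pose_learning_rate if tcfg.pose_learning_rate is not None else tcfg.learning_rate
    opt_d = Adam(depth_net.params, lr=tcfg.learning_rate)
    opt_p = Adam(pose_net.params, lr=pose_lr)
    trips = _triplets(len(frames))
    n_scales = min(tcfg.loss_scales, depth_cfg.n_scales)
    cams = [cam] + [_scaled_camera(cam, 2**s) for s in range(1, n_scales)]
    valids = [fov_mask(c) for c in cams]
    # pre-computed image pyramids (plain data, no gradients)
    pyramids: list[list[np.ndarray]] = [[np.asarray(f, float)] for f in frames]
    for pyr in pyramids:
        for _ in range(1, n_scales):
            pyr.append(_downsample2(pyr[-1]))
    history = {"train_loss": [], "val_loss": []}

    def val_loss() -> float:
        if not val_frames:
            return np.nan
        total = 0.0
        vtrips = _triplets(len(val_frames))
        for tm, t, tp in vtrips:
            depth = _clamped_depth(depth_net.forward(val_frames[t])[0], tcfg)
            vecs = pose_net.forward(val_frames[t], [val_frames[tm], val_frames[tp]])
            poses = [pose_vector_to_rt(vec, pose_net.cfg.angle_scale) for vec in vecs]
            loss = reprojection_loss_t(val_frames[t], [val_frames[tm], val_frames[tp]],
                                       depth, poses, cam,
                                       LossWeights(tcfg.weights.alpha_pe, 0.0), valids[0])
            total += loss.item()
        return total / len(vtrips)

    history["val_loss"].append(val_loss())
    n_iter = 0
    max_iter = tcfg.max_iterations if tcfg.max_iterations is not None else np.inf
    done = False
    queue: list[int] = []
    for _epoch in range(tcfg.epochs):
        queue.extend(rng.permutation(len(trips)).tolist())
        while len(queue) >= tcfg.batch_size:
            batch, queue = queue[:tcfg.batch_size], queue[tcfg.batch_size:]
            loss = None
            for idx in batch:
                tm, t, tp = trips[idx]
                target = frames[t]
                depths = depth_net.forward(target)
                vecs = pose_net.forward(target, [frames[tm], frames[tp]])
                poses = [pose_vector_to_rt(vec, pose_net.cfg.angle_scale) for vec in vecs]
                for s in range(n_scales):
                    term = total_loss_t(
                        pyramids[t][s], [pyramids[tm][s], pyramids[tp][s]],
                        _clamped_depth(depths[s], tcfg), poses, cams[s],
                        tcfg.weights, valids[s]) * (1.0 / n_scales)
                    loss = term if loss is None else loss + term
            loss = loss * (1.0 / tcfg.batch_size)
            if not np.isfinite(loss.item()):
                raise NonFiniteLossError(
                    f"non-finite loss {loss.item()} at iteration {n_iter}")
            opt_d.zero_grad()
            opt_p.zero_grad()
            loss.backward()
            opt_d.step()
            opt_p.step()
            history["train_loss"].append(loss.item())
            n_iter += 1
            if n_iter >= max_iter:
                done = True
                break
        if done:
            break
    history["val_loss"].append(val_loss())
    return depth_net, pose_net, history


def fit_pose(target: np.ndarray, source: np.ndarray, depth: np.ndarray,
             cam: UOCMCamera, w: LossWeights | None = None,
             iterations: int = 150, lr: float = 2e-3,
             init: np.ndarray | None = None) -> tuple[RigidTransform, list[float]]:
    """Direct pose-only fit: optimize one 6-vector against a frozen depth map.

    Minimizes the photometric reconstruction error of the target from the
    source with the given (e.g. ground-truth) depth; useful to validate the
    differentiable warp independently of the networks.
    """
    w = w or LossWeights(lambda_smooth=0.0)
    valid = fov_mask(cam) & np.isfinite(depth)
    vec = Tensor(np.zeros(6) if init is None else np.asarray(init, float),
                 requires_grad=True)
    opt = Adam([vec], lr=lr)
    losses = []
    d_t = Tensor(np.asarray(depth, float))
    for _ in range(iterations):
        pose = pose_vector_to_rt(vec, angle_scale=1.0)
        loss = reprojection_loss_t(target, [source], d_t, [pose], cam, w, valid)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    r, t = pose_vector_to_rt(vec.detach(), angle_scale=1.0)
    return RigidTransform(rotation=r.value, translation=t.value), losses


# -- checkpoints ---------------------------------------------------------

def save_checkpoint(path: str | Path, depth_net: DepthNetwork,
                    pose_net: PoseNetwork) -> None:
    """Self-describing archive: configs (JSON) + weights (npz)."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(depth_net.params):
        arrays[f"depth_{i}"] = p.data
    for i, p in enumerate(pose_net.params):
        arrays[f"pose_{i}"] = p.data
    meta = json.dumps({
        "depth_cfg": asdict(depth_net.cfg),
        "pose_cfg": asdict(pose_net.cfg),
    })
    arrays["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[DepthNetwork, PoseNetwork]:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    dcfg = dict(meta["depth_cfg"])
    pcfg = dict(meta["pose_cfg"])
    dcfg["encoder_widths"] = tuple(dcfg["encoder_widths"])
    pcfg["conv_widths"] = tuple(pcfg["conv_widths"])
    depth_net = DepthNetwork(DepthNetworkConfig(**dcfg))
    pose_net = PoseNetwork(PoseNetworkConfig(**pcfg))
    for i, p in enumerate(depth_net.params):
        p.data = data[f"depth_{i}"]
    for i, p in enumerate(pose_net.params):
        p.data = data[f"pose_{i}"]
    return depth_net, pose_net
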