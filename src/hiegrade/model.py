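"""Three-branch convolutional network for grading TFD images.

Three parallel convolutional branches read the 256 x 112 log-TFD image
along the time direction (8 x 1 kernels), the frequency direction (1 x 8)
and jointly (8 x 8); their feature maps are concatenated and merged by
further convolution/pooling stages, a global average, and two fully
connected layers ending in a 4-way softmax over HIE grades 1-4.

The printed feature-map flow for the default configuration is

    input (256, 112) -> each branch (128, 56, 10) -> concat (128, 56, 30)
    -> merge conv (64, 28, 60) -> pool+norm (32, 14, 60) -> conv/pool
    -> global average (60) -> FC 60 -> FC 4 -> softmax

and construction fails, naming the offending stage, if any stage deviates
from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from . import nn
from .tfd import TfdMatrix

__all__ = [
    "CnnConfig",
    "GradePrediction",
    "ThreeBranchCnn",
    "build_model",
    "predict_segment",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

GRADES = (1, 2, 3, 4)


@dataclass(frozen=True)
class CnnConfig:
    """Architecture hyper-parameters (defaults are the published network)."""

    input_shape: tuple[int, int] = (256, 112)
    branch_filters: int = 10
    time_kernel: tuple[int, int] = (8, 1)
    freq_kernel: tuple[int, int] = (1, 8)
    joint_kernel: tuple[int, int] = (8, 8)
    branch_pool: tuple[int, int] = (4, 4)
    branch_pool_stride: tuple[int, int] = (2, 2)
    merge_filters: int = 60
    merge_kernel: tuple[int, int] = (4, 4)
    merge_stride: tuple[int, int] = (2, 2)
    late_pool: tuple[int, int] = (2, 2)
    late_pool_stride: tuple[int, int] = (2, 2)
    final_kernel: tuple[int, int] = (2, 2)
    fc_sizes: tuple[int, int] = (60, 4)
    seed: int = 0

    # feature-map sizes the published description prints for the defaults
    _expected_flow: tuple = field(
        default=(
            ("branch output", (10, 128, 56)),
            ("concatenation", (30, 128, 56)),
            ("merge convolution", (60, 64, 28)),
            ("late pool + norm", (60, 32, 14)),
            ("global average", (60,)),
        ),
        repr=False,
    )


@dataclass
class GradePrediction:
    """Per-segment class probabilities over grades 1-4."""

    probs: np.ndarray
    label: int
    segment: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float).ravel()
        if self.probs.size != len(GRADES):
            raise ValueError("need one probability per grade")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


class ShapeFlowError(RuntimeError):
    """A constructed stage deviates from the printed feature-map flow."""


class ThreeBranchCnn:
    """The grading network: three parallel branches, merge trunk, MLP head."""

    def __init__(self, cfg: CnnConfig | None = None):
        self.cfg = cfg = cfg or CnnConfig()
        rng = np.random.default_rng(cfg.seed)
        nf = cfg.branch_filters

        def branch(kernel, tag):
            conv = nn.Conv2d(1, nf, kernel, rng=rng, name=f"{tag}.conv")
            conv.needs_input_grad = False  # reads the raw image
            return nn.Sequential(
                conv,
                nn.ReLU(),
                nn.MaxPool2d(cfg.branch_pool, cfg.branch_pool_stride),
                nn.BatchNorm2d(nf, name=f"{tag}.bnorm"),
            )

        self.time_branch = branch(cfg.time_kernel, "time")
        self.freq_branch = branch(cfg.freq_kernel, "freq")
        self.joint_branch = branch(cfg.joint_kernel, "joint")
        mf = cfg.merge_filters
        self.trunk = nn.Sequential(
            nn.Conv2d(3 * nf, mf, cfg.merge_kernel, stride=cfg.merge_stride,
                      rng=rng, name="merge.conv"),
            nn.ReLU(),
            nn.MaxPool2d(cfg.late_pool, cfg.late_pool_stride),
            nn.BatchNorm2d(mf, name="merge.bnorm"),
            nn.Conv2d(mf, mf, cfg.final_kernel, rng=rng, name="final.conv"),
            nn.ReLU(),
            nn.MaxPool2d(cfg.late_pool, cfg.late_pool_stride),
            nn.GlobalAvgPool(),
        )
        self.head = nn.Sequential(
            nn.Dense(mf, cfg.fc_sizes[0], rng=rng, name="fc1"),
            nn.ReLU(),
            nn.Dense(cfg.fc_sizes[0], cfg.fc_sizes[1], rng=rng, name="fc2"),
        )
        self._validate_shapes()

    # -- shape bookkeeping -------------------------------------------------
    def shape_flow(self) -> list[tuple[str, tuple]]:
        """Named (channels, height, width) sizes at the key stages."""
        h, w = self.cfg.input_shape
        b = self.time_branch.out_shape((1, h, w))
        cat = (3 * b[0], b[1], b[2])
        merge = self.trunk.layers[0].out_shape(cat)
        s = merge
        for layer in self.trunk.layers[1:4]:  # ReLU, pool, batch norm
            s = layer.out_shape(s)
        late = s
        for layer in self.trunk.layers[4:]:
            s = layer.out_shape(s)
        return [
            ("branch output", b),
            ("concatenation", cat),
            ("merge convolution", merge),
            ("late pool + norm", late),
            ("global average", s),
        ]

    def _validate_shapes(self) -> None:
        for branch, nm in ((self.time_branch, "time"), (self.freq_branch, "freq"),
                           (self.joint_branch, "joint")):
            got = branch.out_shape((1, *self.cfg.input_shape))
            want = self.time_branch.out_shape((1, *self.cfg.input_shape))
            if got != want:
                raise ShapeFlowError(
                    f"{nm} branch produces {got}, expected {want}"
                )
        if self.cfg.input_shape == (256, 112):
            actual = dict(self.shape_flow())
            for stage, want in self.cfg._expected_flow:
                got = actual.get(stage)
                if got != want:
                    raise ShapeFlowError(
                        f"stage {stage!r} produces {got}, printed flow "
                        f"requires {want}"
                    )

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of images (B, H, W); H, W = time, frequency."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]  # single input channel
        if x.shape[2:] != self.cfg.input_shape:
            raise ValueError(
                f"input {x.shape[2:]} does not match configured shape "
                f"{self.cfg.input_shape}"
            )
        t = self.time_branch.forward(x, training=training)
        f = self.freq_branch.forward(x, training=training)
        j = self.joint_branch.forward(x, training=training)
        cat = np.concatenate([t, f, j], axis=1)
        feat = self.trunk.forward(cat, training=training)
        return self.head.forward(feat, training=training)

    def backward(self, grad_logits: np.ndarray) -> None:
        """Accumulate parameter gradients (input gradient is not formed)."""
        g = self.head.backward(grad_logits)
        g = self.trunk.backward(g)
        nf = self.cfg.branch_filters
        self.time_branch.backward(g[:, :nf])
        self.freq_branch.backward(g[:, nf : 2 * nf])
        self.joint_branch.backward(g[:, 2 * nf :])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, training=False))

    def parameters(self):
        out = []
        for part in (self.time_branch, self.freq_branch, self.joint_branch,
                     self.trunk, self.head):
            out.extend(part.parameters())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: val.copy() for name, val, _ in self.parameters()}
        for part in (self.time_branch, self.freq_branch, self.joint_branch,
                     self.trunk):
            for layer in part.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    state[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                    state[f"{layer.name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, val, _ in self.parameters():
            val[...] = state[name]
        for part in (self.time_branch, self.freq_branch, self.joint_branch,
                     self.trunk):
            for layer in part.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean[...] = state[f"{layer.name}.running_mean"]
                    layer.running_var[...] = state[f"{layer.name}.running_var"]


def build_model(cfg: CnnConfig | None = None) -> ThreeBranchCnn:
    """Construct the network, verifying the printed feature-map flow."""
    return ThreeBranchCnn(cfg)


def predict_segment(model: ThreeBranchCnn, tfd: TfdMatrix | np.ndarray) -> GradePrediction:
    """Grade probabilities for one TFD image."""
    if isinstance(tfd, TfdMatrix):
        values, meta = tfd.values, tfd.meta
    else:
        values, meta = np.asarray(tfd), {}
    if values.shape != model.cfg.input_shape:
        raise ValueError(
            f"TFD shape {values.shape} does not match model input "
            f"{model.cfg.input_shape}"
        )
    probs = model.predict_proba(values[None])[0]
    probs = probs / probs.sum()
    return GradePrediction(
        probs=probs, label=GRADES[int(np.argmax(probs))], segment=dict(meta)
    )


def count_parameters(model: ThreeBranchCnn, per_layer: bool = False):
    """Total trainable scalars, optionally broken down per parameter array."""
    sizes = {name: int(val.size) for name, val, _ in model.parameters()}
    total = sum(sizes.values())
    return (total, sizes) if per_layer else total


def save_checkpoint(model: ThreeBranchCnn, path) -> None:
    cfg = asdict(model.cfg)
    cfg.pop("_expected_flow", None)
    np.savez(path, __config__=json.dumps(cfg), **model.state_dict())


def load_checkpoint(path) -> ThreeBranchCnn:
    data = np.load(path, allow_pickle=False)
    cfg_raw = json.loads(str(data["__config__"]))
    for key in ("input_shape", "time_kernel", "freq_kernel", "joint_kernel",
                "branch_pool", "branch_pool_stride", "merge_kernel",
                "merge_stride", "late_pool", "late_pool_stride",
                "final_kernel", "fc_sizes"):
        cfg_raw[key] = tuple(cfg_raw[key])
    model = ThreeBranchCnn(CnnConfig(**cfg_raw))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
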