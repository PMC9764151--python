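"""1D pre-activation residual networks over 120-sample heartbeats.

The full-size variant mirrors the canonical ResNet-50 table with temporal
(1D) convolutions: a stride-2 stem (kernel 7) plus max-pooling, four stages
of pre-activation bottleneck blocks laid out (3, 4, 6, 3) with base widths
(64, 128, 256, 512) and 4x channel expansion, global average pooling and a
two-class fully connected head — 50 weighted layers in all.  Counting
convention: stem convolution + main-path block convolutions + final fully
connected layer; shortcut projections are not counted, as is conventional.

A shallow ``resnet18_1d`` variant (basic blocks, 18 weighted layers, optional
width scaling) exists so the whole pipeline trains in minutes on one CPU;
every downstream stage is variant-agnostic.

Inside each block the pre-activation ordering is batch-norm -> ReLU ->
convolution; with a 120-sample input the temporal length at the last stage
is 4, which is also the resolution of the saliency maps derived from it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (Adam, BatchNorm1d, Conv1d, GlobalAvgPool, Linear, MaxPool1d,
                  Param, ReLU, softmax)
from .errors import InvalidArgumentError

_BLOCK_CONVS = {"bottleneck": 3, "basic": 2}


@dataclass(frozen=True)
class NetworkSpec:
    variant: str
    block: str  # "bottleneck" | "basic"
    stage_blocks: tuple[int, ...]
    stage_widths: tuple[int, ...]
    input_length: int = 120
    in_channels: int = 1
    num_classes: int = 2
    stem_width: int = 64
    stem_kernel: int = 7
    block_kernel: int = 3

    def __post_init__(self) -> None:
        if self.block not in _BLOCK_CONVS:
            raise InvalidArgumentError(f"unknown block type {self.block!r}")
        if len(self.stage_blocks) != len(self.stage_widths):
            raise InvalidArgumentError("stage layout and widths differ in length")
        if any(b < 1 for b in self.stage_blocks) or any(
                w < 1 for w in self.stage_widths):
            raise InvalidArgumentError("stage layout entries must be >= 1")

    @property
    def expansion(self) -> int:
        return 4 if self.block == "bottleneck" else 1

    @property
    def feature_channels(self) -> int:
        return self.stage_widths[-1] * self.expansion


def resnet50_1d(input_length: int = 120, num_classes: int = 2) -> NetworkSpec:
    return NetworkSpec(variant="resnet50_1d", block="bottleneck",
                       stage_blocks=(3, 4, 6, 3), stage_widths=(64, 128, 256, 512),
                       input_length=input_length, num_classes=num_classes)


def resnet18_1d(input_length: int = 120, num_classes: int = 2,
                width_scale: float = 1.0) -> NetworkSpec:
    widths = tuple(max(4, int(round(w * width_scale))) for w in (64, 128, 256, 512))
    return NetworkSpec(variant="resnet18_1d", block="basic",
                       stage_blocks=(2, 2, 2, 2), stage_widths=widths,
                       input_length=input_length, num_classes=num_classes,
                       stem_width=widths[0])


def weighted_layer_count(spec: NetworkSpec) -> int:
    """Convolutions on the main path plus the final fully connected layer."""
    return 1 + _BLOCK_CONVS[spec.block] * sum(spec.stage_blocks) + 1


class _PreActBlock:
    """Pre-activation residual block (bottleneck or basic)."""

    def __init__(self, spec: NetworkSpec, cin: int, width: int, stride: int,
                 rng: np.random.Generator):
        cout = width * spec.expansion
        k = spec.block_kernel
        self.has_proj = stride != 1 or cin != cout
        self.bn1, self.relu1 = BatchNorm1d(cin), ReLU()
        if spec.block == "bottleneck":
            self.convs = [Conv1d(cin, width, 1, rng=rng),
                          Conv1d(width, width, k, stride, k // 2, rng=rng),
                          Conv1d(width, cout, 1, rng=rng)]
            self.bns = [BatchNorm1d(width), BatchNorm1d(width)]
        else:
            self.convs = [Conv1d(cin, width, k, stride, k // 2, rng=rng),
                          Conv1d(width, cout, k, 1, k // 2, rng=rng)]
            self.bns = [BatchNorm1d(width)]
        self.relus = [ReLU() for _ in self.bns]
        self.proj = Conv1d(cin, cout, 1, stride, rng=rng) if self.has_proj else None

    def modules(self) -> dict[str, object]:
        mods = {"bn1": self.bn1}
        for i, c in enumerate(self.convs, start=1):
            mods[f"conv{i}"] = c
        for i, bn in enumerate(self.bns, start=2):
            mods[f"bn{i}"] = bn
        if self.proj is not None:
            mods["proj"] = self.proj
        return mods

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(x, train))
        shortcut = self.proj.forward(h, train) if self.has_proj else x
        for conv, bn, relu in zip(self.convs, self.bns + [None],
                                  self.relus + [None]):
            h = conv.forward(h, train)
            if bn is not None:
                h = relu.forward(bn.forward(h, train))
        return h + shortcut

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = dy
        for conv, bn, relu in zip(reversed(self.convs),
                                  [None] + list(reversed(self.bns)),
                                  [None] + list(reversed(self.relus))):
            if bn is not None:
                d = bn.backward(relu.backward(d))
            d = conv.backward(d)
        if self.has_proj:
            d = d + self.proj.backward(dy)
            return self.bn1.backward(self.relu1.backward(d))
        return self.bn1.backward(self.relu1.backward(d)) + dy


class ResNet1D:
    """Pre-activation residual network; forward caches enough for backprop
    and for saliency (last-stage activations and their gradients)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stem = Conv1d(spec.in_channels, spec.stem_width, spec.stem_kernel,
                           stride=2, pad=spec.stem_kernel // 2, rng=rng)
        self.pool = MaxPool1d(3, 2, 1)
        self.stages: list[list[_PreActBlock]] = []
        cin = spec.stem_width
        for s, (nblocks, width) in enumerate(zip(spec.stage_blocks,
                                                 spec.stage_widths)):
            blocks = []
            for b in range(nblocks):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(_PreActBlock(spec, cin, width, stride, rng))
                cin = width * spec.expansion
            self.stages.append(blocks)
        self.final_bn, self.final_relu = BatchNorm1d(cin), ReLU()
        self.gap = GlobalAvgPool()
        self.fc = Linear(cin, spec.num_classes, rng=rng)
        self.frozen_stages = 0  # stem + this many leading stages held fixed
        self._features: np.ndarray | None = None
        self._feature_grad: np.ndarray | None = None
        self._pooled: np.ndarray | None = None

    # ---- parameter registry -------------------------------------------------
    def _named_modules(self) -> list[tuple[str, object]]:
        mods: list[tuple[str, object]] = [("stem", self.stem)]
        for s, blocks in enumerate(self.stages, start=1):
            for b, block in enumerate(blocks):
                for name, mod in block.modules().items():
                    mods.append((f"stage{s}.block{b}.{name}", mod))
        mods.append(("final_bn", self.final_bn))
        mods.append(("head.fc", self.fc))
        return mods

    def named_parameters(self) -> dict[str, Param]:
        out = {}
        for prefix, mod in self._named_modules():
            for name, p in mod.params().items():
                out[f"{prefix}.{name}"] = p
        return out

    def named_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, mod in self._named_modules():
            for name, b in mod.buffers().items():
                out[f"{prefix}.{name}"] = b
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.value.copy() for k, p in self.named_parameters().items()}
        state.update({k: b.copy() for k, b in self.named_buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffer_owners = {}
        for prefix, mod in self._named_modules():
            for name in mod.buffers():
                buffer_owners[f"{prefix}.{name}"] = (mod, name)
        expected = set(params) | set(buffer_owners)
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise InvalidArgumentError(
                f"state dict mismatch (missing {sorted(missing)[:3]}, "
                f"extra {sorted(extra)[:3]})")
        for k, p in params.items():
            # copy: the model must never alias (and mutate) checkpoint arrays
            p.value = np.array(state[k], dtype=p.value.dtype, order="C")
            p.grad = np.zeros_like(p.value)
        for k, (mod, name) in buffer_owners.items():
            mod.set_buffer(name, state[k])

    def set_frozen_stages(self, n_stages: int) -> None:
        """Freeze stem + the first ``n_stages`` stages (weights, BN affine
        parameters and BN running statistics)."""
        if n_stages >= len(self.stages):
            raise InvalidArgumentError("frozen prefix must leave a trainable stage")
        self.frozen_stages = n_stages
        frozen_prefixes = self.frozen_parameter_prefixes(n_stages)
        for name, p in self.named_parameters().items():
            p.frozen = any(name.startswith(pref) for pref in frozen_prefixes)

    @staticmethod
    def frozen_parameter_prefixes(n_stages: int) -> tuple[str, ...]:
        return ("stem.",) + tuple(f"stage{s}." for s in range(1, n_stages + 1))

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[1] != self.spec.in_channels or \
                x.shape[2] != self.spec.input_length:
            raise InvalidArgumentError(
                f"expected input shape (*, {self.spec.in_channels}, "
                f"{self.spec.input_length}), got {x.shape}")
        # frozen prefix runs in evaluation mode so its BN statistics never move
        h = self.stem.forward(x, train and self.frozen_stages == 0)
        h = self.pool.forward(h)
        for s, blocks in enumerate(self.stages, start=1):
            stage_train = train and s > self.frozen_stages
            for block in blocks:
                h = block.forward(h, stage_train)
        self._features = h
        h = self.final_relu.forward(self.final_bn.forward(h, train))
        pooled = self.gap.forward(h)
        self._pooled = pooled
        return self.fc.forward(pooled)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.fc.backward(dlogits)
        d = self.gap.backward(d)
        d = self.final_bn.backward(self.final_relu.backward(d))
        self._feature_grad = d
        for blocks in reversed(self.stages):
            for block in reversed(blocks):
                d = block.backward(d)
        d = self.pool.backward(d)
        return self.stem.backward(d)

    def zero_grad(self) -> None:
        for p in self.named_parameters().values():
            p.grad[...] = 0

    @property
    def pooled_features(self) -> np.ndarray:
        """Global-average-pooled last-stage features from the last forward."""
        if self._pooled is None:
            raise InvalidArgumentError("run a forward pass first")
        return self._pooled


def build_network(spec: NetworkSpec, seed: int = 0) -> ResNet1D:
    """Randomly initialized network; identical spec + seed give identical
    weights."""
    return ResNet1D(spec, seed=seed)


def forward_probs(model: ResNet1D, beats: np.ndarray) -> np.ndarray:
    """Per-beat class probabilities (softmax over 2 logits), evaluation mode."""
    return softmax(model.forward(np.asarray(beats), train=False))


def feature_maps_and_grads(model: ResNet1D, beat: np.ndarray, class_index: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Last-stage activations and the gradient of one class score w.r.t.
    them, both of shape (channels, temporal positions)."""
    if not 0 <= class_index < model.spec.num_classes:
        raise InvalidArgumentError(f"class index {class_index} out of range")
    beat = np.asarray(beat, dtype=np.float32).reshape(1, -1)
    model.zero_grad()
    logits = model.forward(beat, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_index] = 1.0
    model.backward(dlogits)
    return model._features[0].copy(), model._feature_grad[0].copy()


@dataclass
class Checkpoint:
    """Architecture + weights + freeze mask, serialized as a directory of
    one JSON spec and one .npy file per named array (framework-portable)."""

    spec: NetworkSpec
    weights: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    freeze_mask: dict[str, bool] = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        (path / "weights").mkdir(parents=True, exist_ok=True)
        (path / "spec.json").write_text(json.dumps(asdict(self.spec), indent=2))
        (path / "meta.json").write_text(json.dumps(self.meta, indent=2, default=str))
        (path / "freeze.json").write_text(json.dumps(self.freeze_mask, indent=2))
        for name, arr in self.weights.items():
            np.save(path / "weights" / f"{name}.npy", arr)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        raw = json.loads((path / "spec.json").read_text())
        raw["stage_blocks"] = tuple(raw["stage_blocks"])
        raw["stage_widths"] = tuple(raw["stage_widths"])
        spec = NetworkSpec(**raw)
        meta = json.loads((path / "meta.json").read_text())
        freeze = json.loads((path / "freeze.json").read_text())
        weights = {f.stem: np.load(f) for f in sorted((path / "weights").glob("*.npy"))}
        return cls(spec=spec, weights=weights, meta=meta, freeze_mask=freeze)

    def build_model(self) -> ResNet1D:
        model = build_network(self.spec, seed=int(self.meta.get("seed", 0)))
        model.load_state_dict(self.weights)
        return model


def checkpoint_from_model(model: ResNet1D, meta: dict | None = None
                          ) -> Checkpoint:
    state = model.state_dict()
    mask = {name: p.frozen for name, p in model.named_parameters().items()}
    mask.update({name: True for name in model.named_buffers()
                 if any(name.startswith(pref) for pref in
                        model.frozen_parameter_prefixes(model.frozen_stages))})
    return Checkpoint(spec=model.spec, weights=state, meta=meta or {},
                      freeze_mask=mask)


def make_optimizer(model: ResNet1D, lr: float) -> Adam:
    return Adam(model.named_parameters(), lr=lr)
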