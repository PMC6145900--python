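"""Network architectures: BoxNet, SmallNet and the merged DualNet.

BoxNet consumes the dimension-preserving bounding-box input through a
VGG-style stack of 3D convolution blocks with progressively increasing filter
counts, each block being convolution -> batch norm -> leaky ReLU (alpha=0.03)
-> max pool, followed by fully connected layers.  SmallNet consumes the
size-invariant cube and ends its convolutional stack with a 1x1x1 bottleneck
convolution and a 1x1x1 network-in-network convolution to limit parameters.
DualNet concatenates the two branches' penultimate representations and feeds
shared dense layers; the binary HPV/p16 covariate can optionally be merged by
concatenation at the first shared dense layer.  The output head is always two
independent sigmoid units — nodal-metastasis and extranodal-extension
probabilities (multi-label, not mutually exclusive).

Exact per-layer filter counts are configuration, not architecture: they live
in :class:`ModelSpec`, with a full-resolution default and a reduced ``desk``
default sized for CPU experiments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    MaxPool3D,
    Param,
    Sequential,
    bce_with_logits,
    sigmoid,
)

__all__ = ["ConvBlock", "ModelSpec", "Network", "build_boxnet", "build_smallnet", "build_dualnet", "build_model"]


@dataclass(frozen=True)
class ConvBlock:
    filters: int
    kernel: int = 3
    pool: tuple[int, int, int] = (2, 2, 2)


def _full_box_blocks() -> list[ConvBlock]:
    # z-pooling skipped in the third block to respect the thin slice axis.
    return [
        ConvBlock(32, 3, (2, 2, 2)),
        ConvBlock(64, 3, (2, 2, 2)),
        ConvBlock(128, 3, (2, 2, 1)),
        ConvBlock(256, 3, (2, 2, 2)),
    ]


def _full_small_blocks() -> list[ConvBlock]:
    return [ConvBlock(32), ConvBlock(64), ConvBlock(128)]


@dataclass(frozen=True)
class ModelSpec:
    """All architecture hyperparameters in one serialisable place."""

    variant: str = "dualnet"  # boxnet | smallnet | dualnet
    box_shape: tuple[int, int, int] = (118, 118, 32)
    small_shape: tuple[int, int, int] = (32, 32, 32)
    box_blocks: tuple[ConvBlock, ...] = field(default_factory=lambda: tuple(_full_box_blocks()))
    small_blocks: tuple[ConvBlock, ...] = field(default_factory=lambda: tuple(_full_small_blocks()))
    bottleneck_filters: int = 64
    nin_filters: int = 128
    branch_dense: int = 256
    dense_widths: tuple[int, ...] = (256,)
    box_initial_pool: tuple[int, int, int] = (1, 1, 1)
    small_initial_pool: tuple[int, int, int] = (1, 1, 1)
    leaky_alpha: float = 0.03
    dropout_conv: float = 0.2
    dropout_dense: float = 0.5
    l2_coeff: float = 1e-4
    merge_hpv: bool = False
    scale: str = "full"  # full | desk

    def __post_init__(self) -> None:
        if self.variant not in ("boxnet", "smallnet", "dualnet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name, blocks in (("box", self.box_blocks), ("small", self.small_blocks)):
            filters = [b.filters for b in blocks]
            if any(b <= a for a, b in zip(filters, filters[1:])):
                raise ValueError(
                    f"{name} branch filter counts must be strictly increasing, got {filters}"
                )
        if self.bottleneck_filters >= self.small_blocks[-1].filters:
            raise ValueError("bottleneck must have fewer filters than the preceding layer")

    @classmethod
    def desk(cls, variant: str = "dualnet", merge_hpv: bool = False) -> "ModelSpec":
        """Reduced configuration: filters divided by 4, box input 32x32x16."""
        return cls(
            variant=variant,
            box_shape=(32, 32, 16),
            small_shape=(16, 16, 16),
            box_blocks=(ConvBlock(8, 3, (2, 2, 2)), ConvBlock(16, 3, (2, 2, 2))),
            small_blocks=(ConvBlock(8, 3, (2, 2, 2)), ConvBlock(16, 3, (2, 2, 2))),
            box_initial_pool=(2, 2, 1),
            small_initial_pool=(2, 2, 2),
            bottleneck_filters=8,
            nin_filters=16,
            branch_dense=32,
            dense_widths=(32,),
            merge_hpv=merge_hpv,
            scale="desk",
        )


def _branch(
    blocks: tuple[ConvBlock, ...],
    in_shape: tuple[int, int, int],
    spec: ModelSpec,
    rng: np.random.Generator,
    bottleneck: bool = False,
    initial_pool: tuple[int, int, int] = (1, 1, 1),
) -> tuple[Sequential, int]:
    """Build one convolutional branch; returns (layers, feature width).

    ``initial_pool`` optionally downsamples the raw input before the first
    convolution — a cheap way to trade spatial resolution for speed at desk
    scale.
    """
    layers: list = []
    cin = 1
    shape = np.array(in_shape)
    if any(p > 1 for p in initial_pool):
        layers.append(MaxPool3D(initial_pool))
        shape = shape // np.array(initial_pool)
    for blk in blocks:
        layers += [
            Conv3D(cin, blk.filters, blk.kernel, rng),
            BatchNorm(blk.filters),
            LeakyReLU(spec.leaky_alpha),
            MaxPool3D(blk.pool),
        ]
        if spec.dropout_conv > 0:
            layers.append(Dropout(spec.dropout_conv))
        cin = blk.filters
        shape = shape // np.array(blk.pool)
    if bottleneck:
        layers += [
            Conv3D(cin, spec.bottleneck_filters, 1, rng),
            LeakyReLU(spec.leaky_alpha),
            Conv3D(spec.bottleneck_filters, spec.nin_filters, 1, rng),
            LeakyReLU(spec.leaky_alpha),
        ]
        cin = spec.nin_filters
    flat = int(cin * np.prod(shape))
    layers += [
        Flatten(),
        Dense(flat, spec.branch_dense, rng),
        LeakyReLU(spec.leaky_alpha),
    ]
    if spec.dropout_dense > 0:
        layers.append(Dropout(spec.dropout_dense))
    return Sequential(layers), spec.branch_dense


class Network:
    """A built model: named convolutional branches plus a shared dense head.

    Forward contract: ``predict_proba(box=..., small=..., hpv=...)`` returns
    ``(p_nm, p_ene)`` pairs in (0, 1)^2.  Inference is deterministic for fixed
    parameters (running batch-norm statistics, dropout off).
    """

    def __init__(self, spec: ModelSpec, branches: dict[str, Sequential], head: Sequential):
        self.spec = spec
        self.branches = branches
        self.head = head

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for seq in self.branches.values():
            out += seq.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        state = [p.v.copy() for p in self.params()]
        for seq in list(self.branches.values()) + [self.head]:
            for layer in seq.layers:
                if isinstance(layer, BatchNorm):
                    state.append(layer.running_mean.copy())
                    state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, state[: len(params)]):
            p.v = v.copy()
        i = len(params)
        for seq in list(self.branches.values()) + [self.head]:
            for layer in seq.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean = state[i].copy()
                    layer.running_var = state[i + 1].copy()
                    i += 2

    def save(self, path) -> None:
        np.savez_compressed(path, *self.get_state())

    def load(self, path) -> None:
        with np.load(path) as npz:
            self.set_state([npz[k] for k in npz.files])

    # -- forward / backward -------------------------------------------------
    def _required(self) -> list[str]:
        return list(self.branches)

    def _forward_features(self, inputs: dict, train: bool, rng) -> np.ndarray:
        feats = []
        self._widths = []
        from .nn import DTYPE

        for name, seq in self.branches.items():
            x = np.asarray(inputs[name], dtype=DTYPE)
            if x.ndim == 4:
                x = x[:, None]
            f = seq.forward(x, train=train, rng=rng)
            feats.append(f)
            self._widths.append(f.shape[1])
        if self.spec.merge_hpv:
            hpv = np.asarray(inputs["hpv"], dtype=np.float64).reshape(-1, 1)
            feats.append(hpv)
            self._widths.append(1)
        return np.concatenate(feats, axis=1)

    def forward_logits(self, inputs: dict, train: bool = False, rng=None) -> np.ndarray:
        feat = self._forward_features(inputs, train, rng)
        return self.head.forward(feat, train=train, rng=rng)

    def predict_proba(self, **inputs) -> np.ndarray:
        """Inference-mode probabilities ``(N, 2)`` for (nm, ene)."""
        missing = [k for k in self._required() if k not in inputs or inputs[k] is None]
        if missing:
            raise ValueError(f"{self.spec.variant} forward requires inputs: {missing}")
        if self.spec.merge_hpv and inputs.get("hpv") is None:
            raise ValueError("merge_hpv model requires an 'hpv' input")
        return sigmoid(self.forward_logits(inputs, train=False))

    def l2_penalty(self) -> float:
        return float(
            self.spec.l2_coeff * sum((p.v**2).sum() for p in self.params() if p.decay)
        )

    def loss(self, inputs: dict, targets: np.ndarray, train: bool = False, rng=None) -> float:
        logits = self.forward_logits(inputs, train=train, rng=rng)
        data_loss, _ = bce_with_logits(logits, targets)
        return data_loss + self.l2_penalty()

    def loss_and_backward(self, inputs: dict, targets: np.ndarray, rng) -> float:
        """Training-mode forward + backward; returns the total (regularised) loss."""
        logits = self.forward_logits(inputs, train=True, rng=rng)
        data_loss, dlogits = bce_with_logits(logits, targets)
        dfeat = self.head.backward(dlogits)
        offset = 0
        for (name, seq), w in zip(self.branches.items(), self._widths):
            seq.backward(dfeat[:, offset : offset + w])
            offset += w
        # hpv column (if any) receives no gradient sink.
        for p in self.params():
            if p.decay:
                p.g += 2.0 * self.spec.l2_coeff * p.v
        return data_loss + self.l2_penalty()

    def make_optimizer(self) -> Adam:
        return Adam(self.params())

    def clone(self) -> "Network":
        return copy.deepcopy(self)


def build_boxnet(spec: ModelSpec, seed: int = 0) -> Network:
    if spec.variant != "boxnet":
        raise ValueError("spec.variant must be 'boxnet'")
    rng = np.random.default_rng(seed)
    branch, width = _branch(spec.box_blocks, spec.box_shape, spec, rng, initial_pool=spec.box_initial_pool)
    head = _head(spec, width, rng)
    return Network(spec, {"box": branch}, head)


def build_smallnet(spec: ModelSpec, seed: int = 0) -> Network:
    if spec.variant != "smallnet":
        raise ValueError("spec.variant must be 'smallnet'")
    rng = np.random.default_rng(seed)
    branch, width = _branch(
        spec.small_blocks, spec.small_shape, spec, rng, bottleneck=True,
        initial_pool=spec.small_initial_pool,
    )
    head = _head(spec, width, rng)
    return Network(spec, {"small": branch}, head)


def build_dualnet(spec: ModelSpec, seed: int = 0) -> Network:
    if spec.variant != "dualnet":
        raise ValueError("spec.variant must be 'dualnet'")
    if not spec.box_blocks or not spec.small_blocks:
        raise ValueError("dualnet requires both branch block lists")
    rng = np.random.default_rng(seed)
    box, wb = _branch(spec.box_blocks, spec.box_shape, spec, rng, initial_pool=spec.box_initial_pool)
    small, ws = _branch(
        spec.small_blocks, spec.small_shape, spec, rng, bottleneck=True,
        initial_pool=spec.small_initial_pool,
    )
    head = _head(spec, wb + ws, rng)
    return Network(spec, {"box": box, "small": small}, head)


def _head(spec: ModelSpec, feature_width: int, rng: np.random.Generator) -> Sequential:
    layers: list = []
    nin = feature_width + (1 if spec.merge_hpv else 0)
    for w in spec.dense_widths:
        layers += [Dense(nin, w, rng), LeakyReLU(spec.leaky_alpha)]
        if spec.dropout_dense > 0:
            layers.append(Dropout(spec.dropout_dense))
        nin = w
    layers.append(Dense(nin, 2, rng))  # logits for (nm, ene)
    return Sequential(layers)


def build_model(spec: ModelSpec, seed: int = 0) -> Network:
    return {"boxnet": build_boxnet, "smallnet": build_smallnet, "dualnet": build_dualnet}[
        spec.variant
    ](spec, seed)
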