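"""Multi-trait CNN regressors for plot imagery.

Three variants share one architecture and differ only in input channels:
``rgb`` (3), ``dsm`` (1) and ``rgb_dsm`` (early fusion, 4).  The network is
two parts: a nonlinear feature extractor ending in a bottleneck of
``feature_dim`` (default 30) units, and a purely linear regression head
mapping the bottleneck to the five traits, estimates = X W + 1 b^T.

The exact published layer stack is not available; the default here — five
conv-batchnorm-ReLU-maxpool blocks, flatten, two hidden linear layers, a
linear bottleneck with non-affine batch norm, and the linear head — is a
documented reconstruction totalling 14 weighted layers (5 conv + 5 affine
batch norm + 4 linear) and is fully overridable through :class:`ModelSpec`.
The non-affine bottleneck norm keeps the 30 features approximately
standardised during training while leaving the head's linear algebra exact
at inference.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..exceptions import ShapeError
from .layers import (
    BatchNorm1d,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Flatten,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
)

_VARIANT_CHANNELS = {"rgb": 3, "dsm": 1, "rgb_dsm": 4}


@dataclass
class ConvBlockSpec:
    filters: int
    kernel: int = 3
    pool: bool = True


def _default_blocks() -> list[ConvBlockSpec]:
    return [
        ConvBlockSpec(8),
        ConvBlockSpec(16),
        ConvBlockSpec(24),
        ConvBlockSpec(32),
        ConvBlockSpec(32),
    ]


@dataclass
class ModelSpec:
    """Architecture description for one CNN variant."""

    variant: str = "rgb_dsm"
    conv_blocks: list[ConvBlockSpec] = field(default_factory=_default_blocks)
    hidden_dims: tuple[int, ...] = (128, 64)
    feature_dim: int = 30
    output_dim: int = 5
    dropout_rate: float = 0.1
    use_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.variant not in _VARIANT_CHANNELS:
            raise ValueError(
                f"variant must be one of {sorted(_VARIANT_CHANNELS)}, got {self.variant!r}"
            )

    @property
    def input_channels(self) -> int:
        return _VARIANT_CHANNELS[self.variant]


@dataclass
class LatentFeatureMatrix:
    """n x feature_dim bottleneck features with standardisation statistics.

    ``X`` holds the features exactly as the linear head sees them; the
    scaling statistics (computed on a reference set, typically the training
    fold) standardise them for PCA.
    """

    X: np.ndarray
    scaling_mean: np.ndarray
    scaling_sd: np.ndarray

    def scaled(self, X: np.ndarray | None = None) -> np.ndarray:
        """Standardise ``X`` (default: own features) with the stored stats."""
        x = self.X if X is None else np.asarray(X)
        return (x - self.scaling_mean) / self.scaling_sd


class TraitCNN:
    """A built model: feature extractor + linear regression head."""

    def __init__(self, spec: ModelSpec, input_hw: tuple[int, int], seed: int = 0) -> None:
        self.spec = spec
        self.input_hw = tuple(input_hw)
        self.seed = seed
        rng = np.random.default_rng(seed)

        h, w = self.input_hw
        c = spec.input_channels
        layers: list = []
        for i, blk in enumerate(spec.conv_blocks):
            layers.append(Conv2d(c, blk.filters, blk.kernel, rng))
            if spec.use_batchnorm:
                layers.append(BatchNorm2d(blk.filters))
            layers.append(ReLU())
            if blk.pool:
                if h % 2 or w % 2:
                    raise ShapeError(
                        f"conv block {i}: spatial size {h}x{w} not divisible by 2 "
                        "before max pooling"
                    )
                layers.append(MaxPool2d())
                h, w = h // 2, w // 2
                if h < 1 or w < 1:
                    raise ShapeError(f"conv block {i}: spatial size collapsed to 0")
            c = blk.filters
        layers.append(Flatten())
        dim = c * h * w
        for j, hd in enumerate(spec.hidden_dims):
            layers.append(Linear(dim, hd, rng))
            layers.append(ReLU())
            if spec.dropout_rate > 0:
                layers.append(Dropout(spec.dropout_rate, seed=seed + 101 + j))
            dim = hd
        layers.append(Linear(dim, spec.feature_dim, rng))
        # non-affine norm keeps bottleneck features ~standardised in training
        layers.append(BatchNorm1d(spec.feature_dim, affine=False))
        self.extractor = Sequential(layers)
        self.head = Linear(spec.feature_dim, spec.output_dim, rng)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Map a batch (N, C, H, W) to (features N x 30, estimates N x 5)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise ShapeError(f"expected (N, C, H, W), got {x.shape}")
        if x.shape[1] != self.spec.input_channels:
            raise ShapeError(
                f"{self.spec.variant} variant expects {self.spec.input_channels} "
                f"channels, got {x.shape[1]}"
            )
        if x.shape[2:] != self.input_hw:
            raise ShapeError(
                f"model built for {self.input_hw} inputs, got {x.shape[2:]}"
            )
        features = self.extractor.forward(x, training).astype(np.float64)
        # float64 head keeps the linear algebra exact for downstream identities
        estimates = self.head.forward(features, training)
        return features, estimates

    def __call__(self, x: np.ndarray, training: bool = False):
        return self.forward(x, training)

    def backward(self, destimates: np.ndarray) -> None:
        dfeatures = self.head.backward(destimates)
        self.extractor.backward(dfeatures.astype(np.float32))

    # -- weights ------------------------------------------------------------

    @property
    def W(self) -> np.ndarray:
        """Head weight matrix (feature_dim x output_dim)."""
        return self.head.params["W"]

    @property
    def b(self) -> np.ndarray:
        """Head bias vector (output_dim,)."""
        return self.head.params["b"]

    def parameters(self):
        yield from (( ("ex", i, n), layer) for (i, n), layer in self.extractor.parameters())
        for name in self.head.params:
            yield ("head", 0, name), self.head

    @property
    def n_parameters(self) -> int:
        total = sum(
            layer.params[key[-1]].size for key, layer in self.parameters()
        )
        return int(total)

    @property
    def n_weighted_layers(self) -> int:
        """Count of layers carrying trainable weights (conv, affine norm, linear)."""
        count = sum(1 for layer in self.extractor.layers if layer.params)
        return count + 1  # + head

    def state_dict(self) -> dict:
        return {
            "extractor": self.extractor.state_dict(),
            "head": self.head.state_dict(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.extractor.load_state_dict(state["extractor"])
        self.head.load_state_dict(state["head"])

    def clone_state(self) -> dict:
        return copy.deepcopy(self.state_dict())


def build_model(spec: ModelSpec, input_hw: tuple[int, int], seed: int = 0) -> TraitCNN:
    """Construct a :class:`TraitCNN`; raises ShapeError naming the offending
    conv block when the input size is incompatible with the pooling stack."""
    return TraitCNN(spec, input_hw, seed=seed)


def extract_features(
    model: TraitCNN,
    images: np.ndarray,
    reference: np.ndarray | None = None,
    batch_size: int = 64,
) -> LatentFeatureMatrix:
    """Extract bottleneck features (eval mode) with scaling statistics.

    ``reference`` (default: ``images``) supplies the rows on which the
    mean/sd used for later standardisation are computed — pass the training
    fold to keep test rows out of the statistics.  Applying the model head to
    the returned ``X`` reproduces the model's own estimates exactly.
    """

    def _batched(arr: np.ndarray) -> np.ndarray:
        outs = [
            model.forward(arr[i : i + batch_size], training=False)[0]
            for i in range(0, len(arr), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    X = _batched(np.asarray(images, dtype=np.float32)).astype(np.float64)
    ref = (
        X
        if reference is None
        else _batched(np.asarray(reference, dtype=np.float32)).astype(np.float64)
    )
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return LatentFeatureMatrix(X=X, scaling_mean=mean, scaling_sd=sd)
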