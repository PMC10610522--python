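"""Compact four-chamber segmentation U-Net and its parameter audit.

The network is the classic contraction/expansion encoder-decoder with skip
concatenations, at reduced width: four contraction blocks of 16/32/64/128
channels, a 256-channel bottleneck, a mirrored expansion path, and a final
3x3 (to 8 channels) + 1x1 classification head over 5 classes (background +
left ventricle, left atrium, right ventricle, right atrium).  Every
convolution is followed by a rectifier and then batch normalization —
including, deliberately, the final 1x1 classification convolution, matching
the reference configuration this implementation audits against.  Upsampling
uses 2x2 stride-2 transposed convolutions with bias and no normalization.

A 128x128 single-channel input halves four times to an 8x8 bottleneck and
returns to 128x128x5 raw class scores.  ``audit_parameters`` reports the
trainable-parameter count of every parameterized operation, block by block,
measured from the actual weight arrays; ``REFERENCE_PARAMETER_COUNTS`` is
the published per-operation table for the reference configuration, used by
the CLI to diff an instantiated model against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "UNetSpec",
    "BlockAudit",
    "UNet",
    "build_unet",
    "audit_parameters",
    "predict_labelmap",
    "save_checkpoint",
    "load_checkpoint",
    "REFERENCE_PARAMETER_COUNTS",
]

CONV_OP = "Conv2d 3x3, ReLU, BatchNorm2d"
FINAL_OP = "Conv2d 1x1, ReLU, BatchNorm2d"
UP_OP = "ConvTranspose2d"

#: Published per-operation trainable-parameter counts of the reference
#: four-chamber U-Net configuration (block, operation, count).
REFERENCE_PARAMETER_COUNTS = (
    ("Contraction 1", CONV_OP, 192),
    ("Contraction 1", CONV_OP, 2352),
    ("Contraction 2", CONV_OP, 4704),
    ("Contraction 2", CONV_OP, 9312),
    ("Contraction 3", CONV_OP, 18624),
    ("Contraction 3", CONV_OP, 37056),
    ("Contraction 4", CONV_OP, 74112),
    ("Contraction 4", CONV_OP, 147840),
    ("Bottleneck", CONV_OP, 295680),
    ("Bottleneck", CONV_OP, 590592),
    ("Bottleneck", UP_OP, 262400),
    ("Expansion 4", CONV_OP, 442752),
    ("Expansion 4", CONV_OP, 147840),
    ("Expansion 4", UP_OP, 65664),
    ("Expansion 3", CONV_OP, 110784),
    ("Expansion 3", CONV_OP, 37056),
    ("Expansion 3", UP_OP, 16448),
    ("Expansion 2", CONV_OP, 27744),
    ("Expansion 2", CONV_OP, 9312),
    ("Expansion 2", UP_OP, 4128),
    ("Expansion 1", CONV_OP, 6960),
    ("Expansion 1", CONV_OP, 2352),
    ("Final", CONV_OP, 1176),
    ("Final", FINAL_OP, 55),
)

REFERENCE_TOTAL_PARAMETERS = sum(c for _, _, c in REFERENCE_PARAMETER_COUNTS)


@dataclass(frozen=True)
class UNetSpec:
    """Architecture description of the segmentation network."""

    input_size: tuple = (128, 128, 1)
    contraction_channels: tuple = (16, 32, 64, 128)
    bottleneck_channels: int = 256
    expansion_channels: tuple = (128, 64, 32, 16)
    final_intermediate_channels: int = 8
    num_classes: int = 5
    conv_kernel: int = 3
    final_kernel: int = 1
    upsample_kernel: int = 2
    batch_norm: bool = True

    def validate(self) -> None:
        if tuple(self.expansion_channels) != tuple(self.contraction_channels)[::-1]:
            raise ValueError(
                "expansion channel widths must mirror the contraction widths"
            )
        h, w = self.input_size[0], self.input_size[1]
        depth = len(self.contraction_channels)
        if h % (2**depth) or w % (2**depth) or min(h, w) < 2**depth:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2^{depth} "
                "(spatial size halves at each contraction)"
            )
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.upsample_kernel != 2:
            raise ValueError("upsampling is fixed at 2x2 stride 2")

    @property
    def bottleneck_size(self) -> tuple:
        d = 2 ** len(self.contraction_channels)
        return (self.input_size[0] // d, self.input_size[1] // d)


@dataclass
class BlockAudit:
    """Per-block parameter accounting (operation label, count) pairs."""

    block_name: str
    operations: list = field(default_factory=list)

    @property
    def block_total(self) -> int:
        return sum(c for _, c in self.operations)


class _ConvUnit:
    """Convolution -> ReLU -> BatchNorm, the repeated parameterized op."""

    def __init__(self, cin, cout, k, rng, label):
        self.conv = nn.Conv2d(cin, cout, k=k, rng=rng)
        self.relu = nn.ReLU()
        self.bn = nn.BatchNorm(cout)
        self.label = label

    @property
    def params(self):
        return self.conv.params + self.bn.params

    def forward(self, x, training=False):
        return self.bn.forward(
            self.relu.forward(self.conv.forward(x, training), training), training
        )

    def backward(self, dy):
        return self.conv.backward(self.relu.backward(self.bn.backward(dy)))


class UNet:
    """The assembled network; built via :func:`build_unet`."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.conv_kernel
        cc = list(spec.contraction_channels)
        ec = list(spec.expansion_channels)
        self.contractions = []
        cin = spec.input_size[2]
        for i, c in enumerate(cc):
            ops = [
                _ConvUnit(cin, c, k, rng, CONV_OP),
                _ConvUnit(c, c, k, rng, CONV_OP),
            ]
            self.contractions.append(ops)
            cin = c
        self.pools = [nn.MaxPool2() for _ in cc]
        cb = spec.bottleneck_channels
        self.bottleneck = [
            _ConvUnit(cc[-1], cb, k, rng, CONV_OP),
            _ConvUnit(cb, cb, k, rng, CONV_OP),
        ]
        self.upconvs = [nn.ConvTranspose2d(cb, cb, rng=rng)]
        self.expansions = []
        prev_up = cb
        for i, c in enumerate(ec):
            skip = cc[len(cc) - 1 - i]
            ops = [
                _ConvUnit(prev_up + skip, c, k, rng, CONV_OP),
                _ConvUnit(c, c, k, rng, CONV_OP),
            ]
            self.expansions.append(ops)
            if i < len(ec) - 1:
                self.upconvs.append(nn.ConvTranspose2d(c, c, rng=rng))
            prev_up = c
        cf = spec.final_intermediate_channels
        self.final = [
            _ConvUnit(ec[-1], cf, k, rng, CONV_OP),
            _ConvUnit(cf, spec.num_classes, spec.final_kernel, rng, FINAL_OP),
        ]

    # -- parameters ---------------------------------------------------
    def parameters(self):
        out = []
        for ops in self.contractions + [self.bottleneck] + self.expansions + [self.final]:
            for op in ops:
                out.extend(op.params)
        for up in self.upconvs:
            out.extend(up.params)
        return out

    def total_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------
    def forward(self, x, training=False):
        """Map (N, H, W, 1) inputs to (N, H, W, num_classes) scores."""
        skips = []
        h = x
        for ops, pool in zip(self.contractions, self.pools):
            for op in ops:
                h = op.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        for op in self.bottleneck:
            h = op.forward(h, training)
        for i, ops in enumerate(self.expansions):
            up = self.upconvs[i].forward(h, training)
            skip = skips[len(skips) - 1 - i]
            h = np.concatenate([up, skip], axis=-1)
            for op in ops:
                h = op.forward(h, training)
        for op in self.final:
            h = op.forward(h, training)
        return h

    def backward(self, dlogits):
        d = dlogits
        for op in reversed(self.final):
            d = op.backward(d)
        dskips = []  # dskips[j] accumulates the concat gradient of skips[j]
        for i in range(len(self.expansions) - 1, -1, -1):
            for op in reversed(self.expansions[i]):
                d = op.backward(d)
            up_c = self.upconvs[i].cout
            dup, dskip = d[..., :up_c], d[..., up_c:]
            dskips.append(dskip)  # expansion i consumed skips[n-1-i]; i descends
            d = self.upconvs[i].backward(np.ascontiguousarray(dup))
        for op in reversed(self.bottleneck):
            d = op.backward(d)
        for i in range(len(self.contractions) - 1, -1, -1):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            for op in reversed(self.contractions[i]):
                d = op.backward(d)
        return d

    # -- inference ----------------------------------------------------
    def predict(self, frames):
        """Argmax class map for a batch of normalized (N, H, W) frames."""
        x = np.asarray(frames, dtype=np.float32)[..., None]
        logits = self.forward(x, training=False)
        return logits.argmax(axis=-1).astype(np.uint8)


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Instantiate the network from an architecture spec (seeded init)."""
    return UNet(spec or UNetSpec(), seed=seed)


def _unit_count(op: _ConvUnit) -> int:
    return sum(p.size for p in op.params)


def audit_parameters(model: UNet):
    """Measure per-operation trainable-parameter counts, block by block.

    Counts are taken from the actual weight arrays, not from formulas, so
    the audit certifies the network that was really built.
    """
    audits = []
    names = [f"Contraction {i+1}" for i in range(len(model.contractions))]
    for name, ops in zip(names, model.contractions):
        audits.append(BlockAudit(name, [(op.label, _unit_count(op)) for op in ops]))
    b = BlockAudit("Bottleneck", [(op.label, _unit_count(op)) for op in model.bottleneck])
    b.operations.append((UP_OP, sum(p.size for p in model.upconvs[0].params)))
    audits.append(b)
    n_exp = len(model.expansions)
    for i, ops in enumerate(model.expansions):
        e = BlockAudit(
            f"Expansion {n_exp - i}", [(op.label, _unit_count(op)) for op in ops]
        )
        if i + 1 < len(model.upconvs):
            e.operations.append(
                (UP_OP, sum(p.size for p in model.upconvs[i + 1].params))
            )
        audits.append(e)
    audits.append(
        BlockAudit("Final", [(op.label, _unit_count(op)) for op in model.final])
    )
    return audits


def predict_labelmap(model: UNet, frame: np.ndarray) -> np.ndarray:
    """Per-pixel argmax label map for one normalized frame.

    ``frame`` must match the spec's input size with values in [0, 1].
    Ties in the class scores resolve to the lowest class index.
    """
    frame = np.asarray(frame)
    expect = model.spec.input_size[:2]
    if frame.ndim != 2 or frame.shape != tuple(expect):
        raise ValueError(f"expected a {expect[0]}x{expect[1]} single-channel frame")
    if frame.min() < 0 or frame.max() > 1:
        raise ValueError("frame must be normalized to [0, 1]")
    return model.predict(frame[None])[0]


# -- checkpointing ----------------------------------------------------

def _named_params(model: UNet):
    groups = (
        [(f"contraction{i+1}", ops) for i, ops in enumerate(model.contractions)]
        + [("bottleneck", model.bottleneck)]
        + [(f"expansion{len(model.expansions)-i}", ops) for i, ops in enumerate(model.expansions)]
        + [("final", model.final)]
    )
    out = []
    for gname, ops in groups:
        for j, op in enumerate(ops):
            for layer, lname in ((op.conv, "conv"), (op.bn, "bn")):
                for p in layer.params:
                    out.append((f"{gname}.{j}.{lname}.{p.name}", p))
            out.append((f"{gname}.{j}.bn.running_mean", op.bn.running_mean))
            out.append((f"{gname}.{j}.bn.running_var", op.bn.running_var))
    for i, up in enumerate(model.upconvs):
        for p in up.params:
            out.append((f"up{i}.{p.name}", p))
    return out


def save_checkpoint(model: UNet, path) -> None:
    """Serialize weights + architecture spec; the file is self-describing."""
    arrays = {}
    for name, p in _named_params(model):
        arrays[name] = p.data if isinstance(p, nn.Param) else p
    arrays["__spec__"] = np.frombuffer(
        json.dumps(asdict(model.spec)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__spec__"]).decode())
        for key in ("input_size", "contraction_channels", "expansion_channels"):
            meta[key] = tuple(meta[key])
        model = UNet(UNetSpec(**meta))
        for name, p in _named_params(model):
            if isinstance(p, nn.Param):
                p.data[...] = data[name]
            else:
                p[...] = data[name]
    return model
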