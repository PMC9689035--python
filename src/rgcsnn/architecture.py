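"""The U-type spiking segmentation network and classifier builders.

The segmentation network is a fully convolutional encoder–decoder of
spiking layers unrolled over T simulation steps:

* a convolutional spike encoder (two 7×7 convs + RGC layer, 24 channels);
* a contracting path of four skip-concatenation (SC) modules, each two
  3×3 conv + RGC layers whose output is channel-concatenated with the
  module input (doubling the width), followed by 2×2 average pooling —
  24→48→96→192→384 channels while 256→16 spatially;
* a pyramid pooling module (PPM) at the bottleneck: adaptive average
  pooling to 1×1, 2×2, 3×3 and 6×6 bins, a 1×1 conv per branch, bilinear
  upsampling back, concatenation with the input (768 channels) and a 1×1
  compression conv back to 384, re-spiked by an RGC layer;
* an expansive path of four stages (bilinear ×2 upsample, concatenate
  the matching SC output, two 3×3 conv + RGC layers), and a final 3×3
  prediction conv producing real-valued per-class evidence each step.

Per-pixel classification is by rate decoding: evidence is accumulated
over the T steps and the class with the larger total wins (ties go to
the lowest class index).

Decoder stage widths are a free design quantity; the defaults
(232, 116, 58, 29) are calibrated so the default network stores ≈16.6 MB
of float32 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .encoder import EncoderConfig, SpikeEncoder, _he_init
from .neuron import NeuronParams, SpikingLayer

__all__ = [
    "NetworkConfig", "SegmentationOutput", "RGCUNet", "SCModule",
    "ContractingPath", "PyramidPooling", "ExpansivePath",
    "decode_prediction", "model_size", "build_classifier", "ClassifierNet",
]


@dataclass
class NetworkConfig:
    t_steps: int = 8
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    channel_plan: tuple = (24, 48, 96, 192, 384)
    decoder_plan: tuple = (232, 116, 58, 29)
    sc_kernel: int = 3
    ppm_bins: tuple = (1, 2, 3, 6)
    ppm_branch_channels: int = 96
    n_classes: int = 2
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self):
        plan = tuple(self.channel_plan)
        for a, b in zip(plan, plan[1:]):
            if b != 2 * a:
                raise ValueError(
                    f"channel plan {plan} must double at every stage "
                    "(SC concatenation arithmetic)")
        if self.encoder.out_channels != plan[0]:
            raise ValueError("encoder out_channels must equal the first stage width")
        if len(self.decoder_plan) != len(plan) - 1:
            raise ValueError("decoder plan must have one width per expansive stage")


@dataclass
class SegmentationOutput:
    """Per-class discharge totals over the simulation window and the mask."""

    spike_counts: np.ndarray  # [n_classes, H, W]
    mask: np.ndarray          # [H, W] class indices


class _Conv:
    def __init__(self, rng, c_in, c_out, k):
        self.w = ag.parameter(_he_init(rng, c_out, c_in, k))
        self.b = ag.parameter(np.zeros(c_out))
        self.k = k

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        return ag.conv2d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]

    def n_params(self):
        return self.w.data.size + self.b.data.size


class SCModule:
    """Skip-concatenation block: Concat(RGC2(RGC1(x)), x), doubling channels."""

    def __init__(self, rng, channels, kernel, neuron: NeuronParams, relaxed=False):
        self.conv1 = _Conv(rng, channels, channels, kernel)
        self.conv2 = _Conv(rng, channels, channels, kernel)
        self.rgc1 = SpikingLayer(neuron, relaxed=relaxed)
        self.rgc2 = SpikingLayer(neuron, relaxed=relaxed)

    def forward(self, x: ag.Tensor) -> ag.Tensor:
        """Stacked spikes [T, ..., c, H, W] -> [T, ..., 2c, H, W]."""
        h = self.rgc1.forward_stacked(self.conv1(x))
        h = self.rgc2.forward_stacked(self.conv2(h))
        return ag.concat([h, x], axis=-3)

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class ContractingPath:
    """Four SC modules, each followed by 2×2 average pooling."""

    def __init__(self, rng, cfg: NetworkConfig, relaxed=False):
        self.modules = [
            SCModule(rng, c, cfg.sc_kernel, cfg.neuron, relaxed=relaxed)
            for c in cfg.channel_plan[:-1]
        ]

    def forward(self, x: ag.Tensor):
        """Returns (bottleneck, list of pre-pool SC outputs), all stacked."""
        skips = []
        for mod in self.modules:
            sc_out = mod.forward(x)
            skips.append(sc_out)
            x = ag.avg_pool2d(sc_out, 2)
        return x, skips

    def parameters(self):
        return [p for m in self.modules for p in m.parameters()]


class PyramidPooling:
    """Multi-scale pooling branches fused with the input, then re-spiked.

    Branch internals are real-valued (averaging destroys binarity); the
    compressed 384-channel map re-enters the spiking regime through an
    RGC layer so the decoder again receives binary activations.
    """

    def __init__(self, rng, cfg: NetworkConfig, relaxed=False):
        c = cfg.channel_plan[-1]
        bc = cfg.ppm_branch_channels
        self.bins = tuple(cfg.ppm_bins)
        self.branch_convs = [_Conv(rng, c, bc, 1) for _ in self.bins]
        self.compress = _Conv(rng, c + bc * len(self.bins), c, 1)
        self.rgc = SpikingLayer(cfg.neuron, relaxed=relaxed)
        self.concat_channels = c + bc * len(self.bins)

    def forward(self, x: ag.Tensor) -> ag.Tensor:
        H, W = x.data.shape[-2:]
        branches = [x]
        for bin_size, conv in zip(self.bins, self.branch_convs):
            pooled = ag.adaptive_avg_pool2d(x, bin_size)
            branches.append(ag.bilinear_resize(conv(pooled), (H, W)))
        fused = self.compress(ag.concat(branches, axis=-3))
        return self.rgc.forward_stacked(fused)

    def parameters(self):
        ps = [p for c in self.branch_convs for p in c.parameters()]
        return ps + self.compress.parameters()


class ExpansivePath:
    """Four upsample–concatenate–convolve stages plus the prediction conv."""

    def __init__(self, rng, cfg: NetworkConfig, relaxed=False):
        skip_channels = list(cfg.channel_plan[1:])[::-1]  # 384, 192, 96, 48
        in_c = cfg.channel_plan[-1]
        self.stages = []
        for skip_c, out_c in zip(skip_channels, cfg.decoder_plan):
            conv1 = _Conv(rng, in_c + skip_c, out_c, cfg.sc_kernel)
            conv2 = _Conv(rng, out_c, out_c, cfg.sc_kernel)
            self.stages.append((conv1, SpikingLayer(cfg.neuron, relaxed=relaxed),
                                conv2, SpikingLayer(cfg.neuron, relaxed=relaxed)))
            in_c = out_c
        self.predict_conv = _Conv(rng, in_c, cfg.n_classes, cfg.sc_kernel)

    def forward(self, bottleneck: ag.Tensor, skips) -> ag.Tensor:
        x = bottleneck
        for (conv1, rgc1, conv2, rgc2), skip in zip(self.stages, skips[::-1]):
            H, W = x.data.shape[-2:]
            up = ag.bilinear_resize(x, (2 * H, 2 * W))
            if skip.data.shape[-2:] != up.data.shape[-2:]:
                raise ValueError(
                    f"skip spatial size {skip.data.shape[-2:]} does not "
                    f"match upsampled size {up.data.shape[-2:]}")
            merged = ag.concat([up, skip], axis=-3)
            x = rgc1.forward_stacked(conv1(merged))
            x = rgc2.forward_stacked(conv2(x))
        return self.predict_conv(x)  # [T, ..., n_classes, H, W] evidence

    def parameters(self):
        ps = []
        for conv1, _, conv2, _ in self.stages:
            ps += conv1.parameters() + conv2.parameters()
        return ps + self.predict_conv.parameters()


class RGCUNet:
    """Full U-type spiking segmentation network."""

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0,
                 relaxed: bool = False):
        self.cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(seed)
        self.encoder = SpikeEncoder(self.cfg.encoder, rng, relaxed=relaxed)
        self.contracting = ContractingPath(rng, self.cfg, relaxed=relaxed)
        self.ppm = PyramidPooling(rng, self.cfg, relaxed=relaxed)
        self.expansive = ExpansivePath(rng, self.cfg, relaxed=relaxed)

    def parameters(self):
        return (self.encoder.parameters() + self.contracting.parameters()
                + self.ppm.parameters() + self.expansive.parameters())

    def forward(self, images: ag.Tensor, trace: dict | None = None) -> ag.Tensor:
        """images [..., 3, H, W] -> per-step class evidence [T, ..., n_classes, H, W]."""
        H, W = images.data.shape[-2:]
        n_stages = len(self.cfg.channel_plan) - 1
        div = 2 ** n_stages
        if H % div or W % div:
            raise ValueError(f"spatial size {(H, W)} must be divisible by {div}")
        enc = self.encoder.forward(images)
        bottleneck, skips = self.contracting.forward(enc)
        fused = self.ppm.forward(bottleneck)
        logits = self.expansive.forward(fused, skips)
        if trace is not None:
            trace["encoder"] = enc.data
            trace["bottleneck"] = bottleneck.data
            trace["ppm"] = fused.data
            trace["skips"] = [sk.data for sk in skips]
        return logits

    def predict(self, image: np.ndarray) -> SegmentationOutput:
        """Segment a single image [3, H, W] in [0, 1]."""
        logits = self.forward(ag.tensor(np.asarray(image, dtype=np.float64)))
        return decode_prediction(logits.data)

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def summary(self) -> list[tuple[str, int]]:
        """(component, parameter count) rows for reporting."""
        rows = [("encoder (2× conv7×7 + RGC)",
                 sum(p.data.size for p in self.encoder.parameters()))]
        for i, m in enumerate(self.contracting.modules):
            rows.append((f"SC module {i + 1} (2× conv3×3 + RGC, concat)",
                         sum(p.data.size for p in m.parameters())))
        rows.append(("pyramid pooling module",
                     sum(p.data.size for p in self.ppm.parameters())))
        for i, (c1, _, c2, _) in enumerate(self.expansive.stages):
            rows.append((f"expansive stage {i + 1}",
                         c1.n_params() + c2.n_params()))
        rows.append(("prediction conv", self.expansive.predict_conv.n_params()))
        return rows


def decode_prediction(class_maps: np.ndarray) -> SegmentationOutput:
    """Rate decoding: sum per-class evidence over time, argmax per pixel.

    ``class_maps``: [T, n_classes, H, W] (binary discharges or real
    evidence).  Ties break toward the lowest class index.
    """
    class_maps = np.asarray(class_maps)
    if class_maps.ndim != 4:
        raise ValueError("expected class maps [T, n_classes, H, W]")
    counts = class_maps.sum(axis=0)
    mask = np.argmax(counts, axis=0)
    return SegmentationOutput(spike_counts=counts, mask=mask)


def model_size(cfg: NetworkConfig | None = None):
    """Trainable parameter count and float32 byte size of the network."""
    net = RGCUNet(cfg or NetworkConfig(), seed=0)
    count = net.n_params()
    return count, count * 4


# ---------------------------------------------------------------------------
# Table-style classifier builders (RGC vs LIF benchmark topologies)

_TOPOLOGIES = {
    # Encoding-RGC-AP-RGC-AP-RGC-RGC-Out
    "mnist": ["enc", "rgc", "ap", "rgc", "ap", "rgc", "rgc", "out"],
    # Encoding-RGC-RGC-Out
    "n_mnist": ["enc", "rgc", "rgc", "out"],
    # Encoding-AP-RGC-RGC-AP-RGC-AP-RGC-Out
    "dvs128": ["enc", "ap", "rgc", "rgc", "ap", "rgc", "ap", "rgc", "out"],
}


class ClassifierNet:
    """Sequential spiking classifier with a rate-decoded dense head."""

    def __init__(self, layer_spec, in_channels=1, width=16, n_classes=10,
                 input_size=16, t_steps=8, neuron: NeuronParams | None = None,
                 seed: int = 0, relaxed: bool = False):
        self.spec = list(layer_spec)
        self.t_steps = t_steps
        self.neuron_params = neuron or NeuronParams()
        rng = np.random.default_rng(seed)
        self.convs = []
        self.layers = []
        size = input_size
        c = in_channels
        for kind in self.spec:
            if kind == "enc":
                conv = _Conv(rng, c, width, 3)
                self.convs.append(conv)
                self.layers.append(("enc", conv, SpikingLayer(self.neuron_params, relaxed)))
                c = width
            elif kind == "rgc":
                conv = _Conv(rng, c, width, 3)
                self.convs.append(conv)
                self.layers.append(("rgc", conv, SpikingLayer(self.neuron_params, relaxed)))
                c = width
            elif kind == "ap":
                self.layers.append(("ap", None, None))
                size //= 2
            elif kind == "out":
                feat = c * size * size
                self.fc_w = ag.parameter(
                    rng.normal(0, np.sqrt(2.0 / feat), size=(feat, n_classes)))
                self.fc_b = ag.parameter(np.zeros(n_classes))
                self.layers.append(("out", None, None))
            else:
                raise ValueError(f"unknown layer kind {kind!r}")

    def parameters(self):
        ps = [p for c in self.convs for p in c.parameters()]
        return ps + [self.fc_w, self.fc_b]

    def forward(self, images: ag.Tensor) -> ag.Tensor:
        """images [B, C, H, W] -> class logits [B, n_classes] (rate-decoded)."""
        x = None
        for kind, conv, neuron_layer in self.layers:
            if kind == "enc":
                x = neuron_layer.forward_stacked(
                    ag.tile_steps(conv(images), self.t_steps))
            elif kind == "rgc":
                x = neuron_layer.forward_stacked(conv(x))
            elif kind == "ap":
                x = ag.avg_pool2d(x, 2)
            elif kind == "out":
                T, B = x.data.shape[:2]
                flat = _reshape(x, (T, B, -1))
                logits = ag.linear(flat, self.fc_w, self.fc_b)
                return _sum_axis0(logits)
        raise ValueError("topology has no 'out' stage")

    def predict(self, images: np.ndarray) -> np.ndarray:
        logits = self.forward(ag.tensor(np.asarray(images, dtype=np.float64)))
        return np.argmax(logits.data, axis=-1)


def _reshape(x: ag.Tensor, shape) -> ag.Tensor:
    out = x.data.reshape(shape)

    def bwd(g):
        ag._accum(x, g.reshape(x.data.shape))

    return ag.Tensor(out, parents=(x,), backward_fn=bwd)


def _sum_axis0(x: ag.Tensor) -> ag.Tensor:
    out = x.data.sum(axis=0)

    def bwd(g):
        ag._accum(x, np.broadcast_to(g, x.data.shape))

    return ag.Tensor(out, parents=(x,), backward_fn=bwd)


def build_classifier(dataset_name: str, neuron_mode: str = "rgc", **kwargs) -> ClassifierNet:
    """Build the benchmark classifier topology for a dataset family.

    ``dataset_name``: one of 'mnist', 'n_mnist', 'dvs128'; ``neuron_mode``
    selects RGC dynamics or the LIF baseline for every spiking layer.
    """
    name = dataset_name.lower().replace("-", "_")
    if name not in _TOPOLOGIES:
        raise ValueError(f"unknown dataset {dataset_name!r}; "
                         f"choose from {sorted(_TOPOLOGIES)}")
    if neuron_mode not in ("rgc", "lif"):
        raise ValueError(f"unknown neuron mode {neuron_mode!r}")
    neuron = kwargs.pop("neuron", None) or NeuronParams(mode=neuron_mode)
    if neuron.mode != neuron_mode:
        neuron = NeuronParams(**{**neuron.to_dict(), "mode": neuron_mode})
    return ClassifierNet(_TOPOLOGIES[name], neuron=neuron, **kwargs)
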