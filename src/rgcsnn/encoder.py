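"""Convolutional spike encoding.

A trainable perceptron — two stacked 7×7 'same' convolutions with no
intermediate nonlinearity — maps an RGB image to a 24-channel map of
analog input currents.  The same current map drives a layer of RGC
neurons at every one of the T simulation steps (a static image is a
constant external current), and the per-step spike maps stacked over
time form the binary spike train consumed by the rest of the network.
Unlike a fixed pre-trained encoder, these convolution weights receive
gradients and train jointly with the segmentation network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .neuron import NeuronParams, SpikingLayer, SpikeTrain

__all__ = ["EncoderConfig", "SpikeEncoder", "encode"]


@dataclass
class EncoderConfig:
    in_channels: int = 3
    out_channels: int = 24
    kernel: int = 7
    t_steps: int = 8
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd (same-size convolution)")
        if self.t_steps < 1:
            raise ValueError("t_steps must be >= 1")


def _he_init(rng: np.random.Generator, o: int, c: int, k: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(o, c, k, k))


class SpikeEncoder:
    """Two 7×7 convolutions feeding an RGC layer over T steps."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None,
                 relaxed: bool = False):
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        c_in, c_out, k = cfg.in_channels, cfg.out_channels, cfg.kernel
        self.w1 = ag.parameter(_he_init(rng, c_out, c_in, k))
        self.b1 = ag.parameter(np.zeros(c_out))
        self.w2 = ag.parameter(_he_init(rng, c_out, c_out, k))
        self.b2 = ag.parameter(np.zeros(c_out))
        self.neuron = SpikingLayer(cfg.neuron, relaxed=relaxed)

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def forward(self, image: ag.Tensor) -> ag.Tensor:
        """image [..., C_in, H, W] -> stacked spikes [T, ..., C_out, H, W].

        The static current map is injected at every simulation step.
        """
        current = ag.conv2d(ag.conv2d(image, self.w1, self.b1), self.w2, self.b2)
        return self.neuron.forward_stacked(
            ag.tile_steps(current, self.cfg.t_steps))


def encode(image: np.ndarray, cfg: EncoderConfig,
           encoder: SpikeEncoder | None = None) -> SpikeTrain:
    """Encode an RGB image [C, H, W] in [0, 1] into a binary spike train.

    A fresh randomly-initialised encoder is used unless one is supplied;
    in the full network the encoder is a trained component.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[0] != cfg.in_channels:
        raise ValueError(
            f"expected image [{cfg.in_channels}, H, W], got {image.shape}")
    if image.shape[1] < cfg.kernel or image.shape[2] < cfg.kernel:
        raise ValueError("image smaller than the convolution kernel")
    if image.min() < 0 or image.max() > 1:
        warnings.warn("image values outside [0, 1]", stacklevel=2)
    enc = encoder or SpikeEncoder(cfg)
    out = enc.forward(ag.tensor(image))
    return SpikeTrain(values=out.data.astype(np.float64), t_steps=cfg.t_steps)
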