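"""YAML round-tripping for the composite run configuration.

A single seed governs every source of randomness in a run; the resolved
configuration is written beside each run's outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path

import yaml

from .architecture import NetworkConfig
from .data import AugmentPolicy
from .encoder import EncoderConfig
from .neuron import NeuronParams
from .synthetic import SynthConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)
    synth: SynthConfig = field(default_factory=SynthConfig)
    data_dir: str = "data"
    out_dir: str = "runs"

    def __post_init__(self):
        # the run seed flows into every component seed
        self.train.seed = self.seed
        self.augment.seed = self.seed
        self.synth.seed = self.seed

    def to_dict(self) -> dict:
        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        net = d.get("network", {})
        enc = net.get("encoder", {})
        if "neuron" in enc:
            enc["neuron"] = NeuronParams(**enc["neuron"])
        if enc:
            net["encoder"] = EncoderConfig(**_tupled(enc))
        if "neuron" in net:
            net["neuron"] = NeuronParams(**net["neuron"])
        d["network"] = NetworkConfig(**_tupled(net))
        train = d.get("train", {})
        if "jitter_policy" in train:
            train["jitter_policy"] = AugmentPolicy(**_tupled(train["jitter_policy"]))
        d["train"] = TrainConfig(**train)
        d["augment"] = AugmentPolicy(**_tupled(d.get("augment", {})))
        d["synth"] = SynthConfig(**_tupled(d.get("synth", {})))
        return cls(**d)


_TUPLE_KEYS = {
    "channel_plan", "decoder_plan", "ppm_bins", "brightness", "contrast",
    "saturation", "sharpness", "skin_tone_range", "lesion_count",
    "lesion_radius",
}


def _plain(obj):
    """Dataclass/tuple tree -> YAML-safe lists and scalars."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _tupled(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if k in _TUPLE_KEYS and isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
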