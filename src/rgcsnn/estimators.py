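"""scikit-learn style estimators wrapping the spiking networks.

``RGCSNNSegmenter`` is a per-pixel classifier: ``fit(X, y)`` takes RGB
images ``[n, 3, H, W]`` in [0, 1] and binary masks ``[n, H, W]``
(class 0 = lesion), trains the U-type spiking network with
surrogate-gradient Adam, and ``predict`` returns masks by rate decoding.
``RGCSNNClassifier`` wraps the benchmark image-classifier topologies
(RGC or LIF neurons).  Both follow the sklearn parameter protocol and
compose with ``clone`` and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autograd as ag

from .architecture import NetworkConfig, RGCUNet, build_classifier
from .encoder import EncoderConfig
from .neuron import NeuronParams
from .training import TrainConfig, train, train_classifier, evaluate
from .data import LabeledImage
from .metrics import evaluate_masks

__all__ = ["RGCSNNSegmenter", "RGCSNNClassifier"]

_CALIBRATED_DECODER = (232, 116, 58, 29)
_DEFAULT_PLAN = (24, 48, 96, 192, 384)


def _resolve_decoder(channel_plan, decoder_plan):
    if decoder_plan is not None:
        return tuple(decoder_plan)
    if tuple(channel_plan) == _DEFAULT_PLAN:
        return _CALIBRATED_DECODER
    return tuple(reversed(channel_plan[:-1]))


class RGCSNNSegmenter(BaseEstimator, ClassifierMixin):
    """U-type RGC spiking network for binary semantic segmentation.

    Parameters
    ----------
    channel_plan : tuple
        Widths of the contracting stages; each must double its
        predecessor.  The default is the full-scale published plan;
        reduced plans (e.g. ``(8, 16, 32, 64, 128)``) train at desk scale.
    decoder_plan : tuple or None
        Expansive-stage widths; ``None`` selects the calibrated default
        for the full plan and a mirrored plan otherwise.
    t_steps : int
        Simulation steps (default 8).
    neuron_mode : str
        ``"rgc"`` or the ``"lif"`` baseline.
    lr, epochs, batch_size : float, int, int
        Adam learning rate, training epochs, mini-batch size.
    online_jitter : bool
        Re-draw one colour jitter per image per batch during training.
    target_pa : float or None
        Early-stop once validation pixel accuracy reaches this value
        (requires validation data in ``fit``).
    random_state : int
        Seed for initialisation, shuffling and jitter draws.
    """

    def __init__(self, channel_plan=_DEFAULT_PLAN, decoder_plan=None,
                 t_steps=8, neuron_mode="rgc", lr=1e-4, epochs=30,
                 batch_size=8, online_jitter=True, target_pa=None,
                 v_th=0.5, a1=1.0, g_l=0.1, random_state=0):
        self.channel_plan = channel_plan
        self.decoder_plan = decoder_plan
        self.t_steps = t_steps
        self.neuron_mode = neuron_mode
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.online_jitter = online_jitter
        self.target_pa = target_pa
        self.v_th = v_th
        self.a1 = a1
        self.g_l = g_l
        self.random_state = random_state

    def _network_config(self) -> NetworkConfig:
        neuron = NeuronParams(v_th=self.v_th, a1=self.a1, g_l=self.g_l,
                              mode=self.neuron_mode)
        plan = tuple(self.channel_plan)
        enc = EncoderConfig(out_channels=plan[0], t_steps=self.t_steps,
                            neuron=neuron)
        return NetworkConfig(t_steps=self.t_steps, encoder=enc,
                             channel_plan=plan,
                             decoder_plan=_resolve_decoder(plan, self.decoder_plan),
                             neuron=neuron)

    @staticmethod
    def _to_items(X, y) -> list[LabeledImage]:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[1] != 3:
            raise ValueError(f"X must be [n, 3, H, W], got {X.shape}")
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ValueError(f"y shape {y.shape} does not match X {X.shape}")
        return [LabeledImage(image=xi, mask=yi, id=str(i))
                for i, (xi, yi) in enumerate(zip(X, y))]

    def fit(self, X, y, validation_data=None):
        """Train on images X [n, 3, H, W] and masks y [n, H, W]."""
        items = self._to_items(X, y)
        val_items = None
        if validation_data is not None:
            val_items = self._to_items(*validation_data)
        cfg = TrainConfig(lr=self.lr, epochs=self.epochs,
                          batch_size=self.batch_size, seed=self.random_state,
                          online_jitter=self.online_jitter)
        self.config_ = self._network_config()
        self.model_ = RGCUNet(self.config_, seed=self.random_state)
        self.n_params_ = self.model_.n_params()
        _, self.history_ = train(self.model_, items, cfg,
                                 test_items=val_items,
                                 target_pa=self.target_pa)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted masks [n, H, W] by rate decoding."""
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the estimator before predicting")
        X = np.asarray(X, dtype=np.float64)
        masks = []
        for s in range(0, len(X), max(1, self.batch_size)):
            logits = self.model_.forward(ag.tensor(X[s:s + self.batch_size]))
            evidence = logits.data.sum(axis=0)
            masks.append(np.argmax(evidence, axis=1))
        return np.concatenate(masks)

    def score(self, X, y) -> float:
        """Pixel accuracy on (X, y)."""
        return evaluate_masks(np.asarray(y), self.predict(X)).pa

    def evaluate(self, X, y):
        """Full metrics report (confusion, PA, mean IoU, Dice)."""
        report = evaluate_masks(np.asarray(y), self.predict(X))
        report.param_count = getattr(self, "n_params_", None)
        report.param_bytes = (self.n_params_ * 4
                              if getattr(self, "n_params_", None) else None)
        return report


class RGCSNNClassifier(BaseEstimator, ClassifierMixin):
    """Spiking image classifier with the benchmark sequential topologies.

    ``topology`` selects the layer sequence associated with a dataset
    family ('mnist', 'n_mnist', 'dvs128'); ``neuron_mode`` chooses RGC
    dynamics or the LIF baseline with identical topology.
    """

    def __init__(self, topology="mnist", neuron_mode="rgc", width=16,
                 t_steps=8, lr=1e-3, epochs=5, batch_size=32,
                 random_state=0):
        self.topology = topology
        self.neuron_mode = neuron_mode
        self.width = width
        self.t_steps = t_steps
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if X.ndim != 4:
            raise ValueError(f"X must be [n, C, H, W], got {X.shape}")
        self.classes_ = np.unique(y)
        self.model_ = build_classifier(
            self.topology, self.neuron_mode, in_channels=X.shape[1],
            width=self.width, n_classes=int(self.classes_.max()) + 1,
            input_size=X.shape[2], t_steps=self.t_steps,
            seed=self.random_state)
        cfg = TrainConfig(lr=self.lr, epochs=self.epochs,
                          batch_size=self.batch_size, seed=self.random_state,
                          online_jitter=False)
        test_X = test_y = None
        if validation_data is not None:
            test_X, test_y = validation_data
        _, self.history_ = train_classifier(self.model_, X, y, cfg,
                                            test_images=test_X,
                                            test_labels=test_y)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the estimator before predicting")
        X = np.asarray(X, dtype=np.float64)
        out = []
        for s in range(0, len(X), max(1, self.batch_size)):
            out.append(self.model_.predict(X[s:s + self.batch_size]))
        return np.concatenate(out)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())
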