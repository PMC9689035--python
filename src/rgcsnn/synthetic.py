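"""Synthetic labelled wound images and a digit-style classification task.

The wound generator emulates the gross statistics of clinical burn
photographs — a skin-tone background with low-frequency texture, one to
three irregular reddish-brown lesion blobs (ellipses whose boundary
radius is perturbed by a random low-order Fourier series), and additive
Gaussian device noise.  Lesion colour partially overlaps the skin-tone
range (a difficulty knob) so that segmentation is colour-separable but
not trivial.  Pixels inside a lesion carry class 0, everything else
class 1, matching the burn/non-burn labelling convention.

The digit generator renders the ten digits as seven-segment glyphs with
random sub-pixel shifts, per-pixel noise and amplitude jitter — a
self-contained stand-in classification task for benchmarking the RGC
neuron against the LIF baseline when the standard digit/event datasets
are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import LabeledImage

__all__ = ["SynthConfig", "generate", "generate_split", "generate_digits"]


@dataclass
class SynthConfig:
    n_images: int = 100
    size: int = 64
    seed: int = 0
    skin_tone_range: tuple = ((0.45, 0.85), (0.30, 0.65), (0.25, 0.55))  # per-channel RGB
    lesion_count: tuple = (1, 3)
    lesion_radius: tuple = (0.12, 0.30)   # fraction of image size
    lesion_redness: float = 0.55          # blend weight toward lesion colour
    boundary_irregularity: float = 0.35   # Fourier perturbation amplitude
    noise_sigma: float = 0.02
    difficulty: float = 0.35              # 0 = fully separable lesion colour

    def __post_init__(self):
        if self.size % 16:
            raise ValueError("size must be divisible by 16 (network constraint)")


def _lesion_mask(rng: np.random.Generator, size: int, cfg: SynthConfig) -> np.ndarray:
    """Irregular blob: ellipse with Fourier-perturbed boundary radius."""
    cy, cx = rng.uniform(0.2, 0.8, 2) * size
    r0 = rng.uniform(*cfg.lesion_radius) * size
    aspect = rng.uniform(0.6, 1.4)
    theta0 = rng.uniform(0, 2 * np.pi)
    n_modes = 4
    amps = rng.normal(0, cfg.boundary_irregularity / n_modes, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    ry = np.cos(theta0) * dy + np.sin(theta0) * dx
    rx = -np.sin(theta0) * dy + np.cos(theta0) * dx
    dist = np.sqrt((ry / aspect) ** 2 + (rx * aspect) ** 2)
    ang = np.arctan2(ry, rx)
    boundary = r0 * (1.0 + sum(a * np.cos((k + 1) * ang + p)
                               for k, (a, p) in enumerate(zip(amps, phases))))
    return dist <= np.maximum(boundary, 1.0)


def _one_image(rng: np.random.Generator, cfg: SynthConfig) -> LabeledImage:
    size = cfg.size
    base = np.array([rng.uniform(lo, hi) for lo, hi in cfg.skin_tone_range])
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), sigma=size / 8)
    texture = texture / (np.abs(texture).max() + 1e-9) * 0.05
    img = base[:, None, None] + texture[None]

    mask = np.ones((size, size), dtype=np.uint8)
    n_lesions = int(rng.integers(cfg.lesion_count[0], cfg.lesion_count[1] + 1))
    for _ in range(n_lesions):
        blob = _lesion_mask(rng, size, cfg)
        mask[blob] = 0
        # reddish-brown lesion colour, pulled toward skin tone by difficulty
        lesion_rgb = np.array([rng.uniform(0.55, 0.85),
                               rng.uniform(0.05, 0.30),
                               rng.uniform(0.05, 0.25)])
        lesion_rgb = (1 - cfg.difficulty) * lesion_rgb + cfg.difficulty * base
        w = cfg.lesion_redness
        img[:, blob] = (1 - w) * img[:, blob] + w * lesion_rgb[:, None]

    img = img + rng.normal(0, cfg.noise_sigma, img.shape)
    return LabeledImage(image=np.clip(img, 0, 1), mask=mask, id="")


def generate(cfg: SynthConfig) -> list[LabeledImage]:
    """Generate ``cfg.n_images`` labelled wound images, deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    items = []
    for i in range(cfg.n_images):
        item = _one_image(rng, cfg)
        item.id = f"synth_{i:05d}"
        items.append(item)
    return items


def generate_split(cfg: SynthConfig, train_frac: float = 5 / 6):
    """Deterministic disjoint train/test split of a generated set."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    items = generate(cfg)
    n_train = int(round(len(items) * train_frac))
    n_train = min(max(n_train, 1), len(items) - 1)
    perm = np.random.default_rng(cfg.seed + 1).permutation(len(items))
    train = [items[i] for i in perm[:n_train]]
    test = [items[i] for i in perm[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# digit-style classification task

_SEGMENTS = {  # seven-segment truth table per digit
    0: "abcdef", 1: "bc", 2: "abdeg", 3: "abcdg", 4: "bcfg",
    5: "acdfg", 6: "acdefg", 7: "abc", 8: "abcdefg", 9: "abcdfg",
}


def _glyph(digit: int, size: int) -> np.ndarray:
    """Render a seven-segment digit glyph on a size×size canvas."""
    canvas = np.zeros((size, size))
    m = max(2, size // 8)          # margin
    t = max(1, size // 10)         # stroke thickness
    top, mid, bot = m, size // 2, size - m
    left, right = m, size - m
    segs = {
        "a": (slice(top, top + t), slice(left, right)),
        "g": (slice(mid - t // 2, mid - t // 2 + t), slice(left, right)),
        "d": (slice(bot - t, bot), slice(left, right)),
        "f": (slice(top, mid), slice(left, left + t)),
        "b": (slice(top, mid), slice(right - t, right)),
        "e": (slice(mid, bot), slice(left, left + t)),
        "c": (slice(mid, bot), slice(right - t, right)),
    }
    for s in _SEGMENTS[digit]:
        canvas[segs[s]] = 1.0
    return canvas


def generate_digits(n_samples: int, size: int = 16, seed: int = 0,
                    noise: float = 0.15, max_shift: int = 2):
    """Noisy shifted seven-segment digits.

    Returns ``(images [n, 1, size, size] in [0, 1], labels [n])``.
    """
    rng = np.random.default_rng(seed)
    glyphs = np.stack([_glyph(d, size) for d in range(10)])
    labels = rng.integers(0, 10, n_samples)
    images = np.empty((n_samples, 1, size, size))
    for i, lab in enumerate(labels):
        g = glyphs[lab] * rng.uniform(0.6, 1.0)
        dy, dx = rng.integers(-max_shift, max_shift + 1, 2)
        g = np.roll(np.roll(g, dy, axis=0), dx, axis=1)
        g = g + rng.normal(0, noise, g.shape)
        images[i, 0] = np.clip(g, 0, 1)
    return images, labels
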