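"""Synthetic testbed: deterministic toy encoders and image generators.

The encoders under test here are analytic functions of local image-patch
statistics, not trained networks, so their unsafe regions are provable in
closed form.  This makes every other module testable end to end with no
downloads and no model checkpoints, while preserving the structure of the
real problem: a black-box map from a grayscale image to per-electrode
stimulation parameters on a retinal (15×15, three parameters per
electrode) or cortical (60 mapped channels of a 96-electrode array,
amplitudes only) device.

Planted violation certificates for the retinal toy (defaults, retinal
limits ε1 = 628 nC, ε2 = 6000 µA, ε3 = 100):

* all-zero image → zero amplitude everywhere → fully safe;
* all-white image → a = 100 µA on all 225 electrodes → Σa = 22500 µA >
  ε2 (instantaneous-current violation);
* period-2 vertical grating → per patch mean 0.5, std 0.5, edge energy 1
  → f = 120 Hz, p = 40.45 ms, a = 50 µA → 2pf/1000 ≈ 9.7 > 1 (physically
  impossible pulse) and p·a ≈ 2022 nC > ε1 (charge violation);
* full-contrast checkerboard → edge energy 2 → p = 80.45 ms with
  a = 50 µA → p·a ≈ 4022 nC > ε1 (charge violation).

Dense images (more than 100 non-black patches) additionally co-activate
more electrodes than ε3 allows, so the active-electrode constraint fires
on most bright inputs — mirroring how real encoders violate aggregate
limits even under ordinary stimuli.

The cortical toy plants active-electrode and instantaneous-current
violations for dense bright images and keeps its fixed (f, p) pulse shape
feasible so PI can never fire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constraints import ElectrodeArraySpec, StimulationVector
from .mutation import ImageInput

__all__ = [
    "ToyEncoderSpec",
    "ToyRetinalEncoder",
    "ToyCorticalEncoder",
    "MLPEncoder",
    "generate_images",
    "default_seed_images",
    "RETINAL_ARRAY",
    "CORTICAL_ARRAY",
]

RETINAL_ARRAY = ElectrodeArraySpec(
    n_electrodes=225,
    layout_label="15x15 epiretinal, 400 µm pitch",
    params_per_electrode=3,
)

CORTICAL_ARRAY = ElectrodeArraySpec(
    n_electrodes=96,
    layout_label="10x10 Utah, 0.4 mm pitch (60 mapped channels)",
    params_per_electrode=1,
    shared_frequency=300.0,   # Hz: 2·p·f = 102 << 1000, always feasible
    shared_pulse_duration=0.17,  # ms
)


@dataclass(frozen=True)
class ToyEncoderSpec:
    """Gains and offsets of the analytic toy encoders.

    Per electrode patch with mean µ, std σ and edge energy e:
    a = a0 + g_a·µ (µA), f = f0 + g_f·σ (Hz), p = p0 + g_p·e (ms).
    Defaults are chosen so an all-zero image is fully safe and the planted
    violation certificates in the module docstring hold analytically.
    """

    a0: float = 0.0
    g_a: float = 100.0
    f0: float = 20.0
    g_f: float = 200.0
    p0: float = 0.45
    g_p: float = 40.0


def patch_stats(pixels: np.ndarray, grid: tuple[int, int]) -> tuple[np.ndarray, ...]:
    """Per-patch mean, population std, and edge energy for an image split
    into a grid of equal patches.

    Edge energy is mean |∂x| + mean |∂y| of the patch (np.gradient).
    Returns three flat arrays of length grid[0]*grid[1] (row-major).
    """
    h, w = pixels.shape
    gy, gx = grid
    if h % gy or w % gx:
        raise ValueError(f"image {pixels.shape} not divisible into {grid} patches")
    ph, pw = h // gy, w // gx
    patches = pixels.reshape(gy, ph, gx, pw).transpose(0, 2, 1, 3)
    flat = patches.reshape(gy * gx, ph, pw)
    mean = flat.mean(axis=(1, 2))
    std = flat.std(axis=(1, 2))
    dys, dxs = np.gradient(flat, axis=(1, 2))
    edge = np.abs(dxs).mean(axis=(1, 2)) + np.abs(dys).mean(axis=(1, 2))
    return mean, std, edge


class ToyRetinalEncoder:
    """Analytic 15×15 retinal toy: three parameters per electrode from the
    statistics of its 2×2 image patch (default image size 30×30)."""

    def __init__(
        self,
        spec: ToyEncoderSpec = ToyEncoderSpec(),
        array_spec: ElectrodeArraySpec = RETINAL_ARRAY,
        grid: tuple[int, int] = (15, 15),
    ) -> None:
        if grid[0] * grid[1] != array_spec.n_electrodes:
            raise ValueError("patch grid must match electrode count")
        self.spec = spec
        self.array_spec = array_spec
        self.grid = grid
        self.image_shape = (30, 30)

    def encode(self, image: ImageInput) -> StimulationVector:
        mean, std, edge = patch_stats(image.pixels, self.grid)
        s = self.spec
        return StimulationVector(
            frequency=s.f0 + s.g_f * std,
            pulse_duration=s.p0 + s.g_p * edge,
            amplitude=s.a0 + s.g_a * mean,
            array_spec=self.array_spec,
        )


class ToyCorticalEncoder:
    """Analytic cortical toy: amplitudes only, on 60 mapped channels of a
    96-electrode array; frequency and pulse duration are fixed feasible
    constants of the device (default image size 40×24, 10×6 patch grid).

    Dense bright images activate all 60 mapped channels (over the
    30-electrode co-activation limit) and push total current over ε2.
    """

    def __init__(
        self,
        g_a: float = 110.0,
        array_spec: ElectrodeArraySpec = CORTICAL_ARRAY,
        grid: tuple[int, int] = (10, 6),
        n_mapped: int = 60,
    ) -> None:
        self.g_a = g_a
        self.array_spec = array_spec
        self.grid = grid
        self.n_mapped = n_mapped
        self.image_shape = (40, 24)
        # fixed assignment of the first n_mapped channels to patches
        self.mapped = np.arange(n_mapped)

    def encode(self, image: ImageInput) -> StimulationVector:
        mean, _, _ = patch_stats(image.pixels, self.grid)
        a = np.zeros(self.array_spec.n_electrodes)
        a[self.mapped] = self.g_a * mean[: self.n_mapped]
        return StimulationVector.amplitudes_only(a, self.array_spec)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class MLPEncoder:
    """Small fixed-weight MLP encoder exposing per-layer activations — the
    white-box target for the neuron-coverage baselines.

    Two ReLU hidden layers (default 32 units each); outputs are squashed
    by a sigmoid into valid stimulation ranges (f ∈ [0, f_max], p ∈
    [0, p_max], a ∈ [0, a_max]).  Weights are drawn once from
    ``weight_seed`` so the encoder is a pure function of (image, seed).
    """

    def __init__(
        self,
        image_shape: tuple[int, int] = (30, 30),
        array_spec: ElectrodeArraySpec = RETINAL_ARRAY,
        hidden: int = 32,
        weight_seed: int = 7,
        f_max: float = 200.0,
        p_max: float = 10.0,
        a_max: float = 100.0,
    ) -> None:
        rng = np.random.default_rng(weight_seed)
        d = int(np.prod(image_shape))
        n_out = 3 * array_spec.n_electrodes
        self.image_shape = image_shape
        self.array_spec = array_spec
        self.scales = (f_max, p_max, a_max)
        self.W1 = rng.standard_normal((hidden, d)) / np.sqrt(d)
        self.b1 = rng.standard_normal(hidden) * 0.1
        self.W2 = rng.standard_normal((hidden, hidden)) / np.sqrt(hidden)
        self.b2 = rng.standard_normal(hidden) * 0.1
        self.W3 = rng.standard_normal((n_out, hidden)) / np.sqrt(hidden)
        self.b3 = rng.standard_normal(n_out) * 0.1
        self.layer_sizes = (hidden, hidden)

    def encode_with_activations(
        self, image: ImageInput
    ) -> tuple[StimulationVector, list[np.ndarray]]:
        x = image.pixels.ravel()
        h1 = _relu(self.W1 @ x + self.b1)
        h2 = _relu(self.W2 @ h1 + self.b2)
        raw = self.W3 @ h2 + self.b3
        squashed = 1.0 / (1.0 + np.exp(-raw))
        n = self.array_spec.n_electrodes
        f_max, p_max, a_max = self.scales
        stim = StimulationVector(
            frequency=squashed[:n] * f_max,
            pulse_duration=squashed[n : 2 * n] * p_max,
            amplitude=squashed[2 * n :] * a_max,
            array_spec=self.array_spec,
        )
        return stim, [h1, h2]

    def encode(self, image: ImageInput) -> StimulationVector:
        return self.encode_with_activations(image)[0]


IMAGE_KINDS = ("blank", "white", "grating", "blobs", "noise", "checker")


def generate_images(
    kind: str,
    height: int,
    width: int,
    rng: Optional[np.random.Generator] = None,
    *,
    period: int = 2,
    contrast: float = 1.0,
    horizontal: bool = False,
    n_blobs: int = 3,
    radius: float = 3.0,
    level: float = 1.0,
    input_id: Optional[str] = None,
) -> ImageInput:
    """Deterministic parametric image generators for seeds and fixtures.

    kinds: ``blank`` (all zeros), ``white`` (all ``level``), ``grating``
    (square wave of the given period and contrast, vertical stripes unless
    ``horizontal``), ``blobs`` (Gaussian bumps at RNG positions),
    ``noise`` (uniform pixels), ``checker`` (period-1 checkerboard at the
    given contrast).
    """
    if height < 1 or width < 1:
        raise ValueError("dimensions must be positive")
    if kind not in IMAGE_KINDS:
        raise ValueError(f"unknown image kind {kind!r}; valid: {IMAGE_KINDS}")
    if kind == "blank":
        px = np.zeros((height, width))
    elif kind == "white":
        if not 0.0 <= level <= 1.0:
            raise ValueError("level must be in [0, 1]")
        px = np.full((height, width), float(level))
    elif kind == "grating":
        if period < 1 or not 0.0 <= contrast <= 1.0:
            raise ValueError("grating needs period >= 1 and contrast in [0, 1]")
        axis = np.arange(height if horizontal else width)
        stripe = ((axis // (period // 2 if period >= 2 else 1)) % 2).astype(float)
        wave = stripe * contrast
        px = np.tile(wave[:, None], (1, width)) if horizontal else np.tile(
            wave[None, :], (height, 1)
        )
    elif kind == "blobs":
        if rng is None:
            raise ValueError("blobs generator needs an rng")
        if n_blobs < 0 or radius <= 0:
            raise ValueError("blobs need n_blobs >= 0 and radius > 0")
        yy, xx = np.mgrid[0:height, 0:width]
        px = np.zeros((height, width))
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, height), rng.uniform(0, width)
            px += level * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius**2))
        px = np.clip(px, 0.0, 1.0)
    elif kind == "noise":
        if rng is None:
            raise ValueError("noise generator needs an rng")
        px = rng.uniform(0.0, level, size=(height, width))
    else:  # checker
        yy, xx = np.mgrid[0:height, 0:width]
        px = ((yy + xx) % 2).astype(float) * contrast
    return ImageInput(
        pixels=px, input_id=input_id or f"{kind}", lineage="seed"
    )


def default_seed_images(
    height: int = 30, width: int = 30, seed: int = 0
) -> list[ImageInput]:
    """Six mild seed images for discovery experiments: mostly-safe inputs
    (dim, low-contrast) from which the fuzzer must drift toward unsafe
    regions.  Mirrors the six-seed protocol of the comparison experiments
    at desk scale."""
    rng = np.random.default_rng(seed)
    return [
        generate_images("blank", height, width, input_id="seed-blank"),
        generate_images("white", height, width, level=0.15, input_id="seed-dim"),
        generate_images(
            "grating", height, width, period=4, contrast=0.15, input_id="seed-grating"
        ),
        generate_images(
            "blobs", height, width, rng, n_blobs=3, radius=4.0, level=0.5,
            input_id="seed-blobs",
        ),
        generate_images(
            "noise", height, width, rng, level=0.1, input_id="seed-noise"
        ),
        generate_images(
            "checker", height, width, contrast=0.08, input_id="seed-checker"
        ),
    ]
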