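"""Image mutation and seed scheduling for the fuzzing loop.

Mutants are produced by applying one randomly chosen image transformation
per call — translation, rotation, scaling, shearing, brightness or
contrast adjustment, Gaussian blur, additive noise, or sparse pixel-level
perturbation — with parameters drawn from configurable ranges.  Pixel
values are clamped to [0, 1] and image dimensions never change.

Seeds are scheduled probabilistically: a seed selected g times carries
weight max(1 − g/γ, p_min), so fresh seeds are preferred but no seed is
ever starved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "ImageInput",
    "SeedEntry",
    "SeedSet",
    "SchedulerParams",
    "MutationRanges",
    "TRANSFORM_KINDS",
    "seed_selection_probability",
    "choose_seed",
    "mutate",
    "random_image",
    "local_perturb",
]


@dataclass(frozen=True)
class ImageInput:
    """A grayscale test image with provenance.

    ``pixels`` is a 2-D float array with values in [0, 1].  ``lineage``
    records the parent input id and the transform that produced this image
    ("seed" and "random" mark corpus entries and fully random images).
    """

    pixels: np.ndarray
    input_id: str
    lineage: str = "seed"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixels contain non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("pixels must lie in [0, 1]")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SeedEntry:
    """A corpus entry: the image, its selection count g and the number of
    violating mutants it has spawned."""

    image: ImageInput
    g: int = 0
    violations_spawned: int = 0


class SeedSet:
    """Ordered seed corpus with unique input ids."""

    def __init__(self, entries: Optional[list[SeedEntry]] = None) -> None:
        self._entries: list[SeedEntry] = []
        self._ids: set[str] = set()
        for e in entries or []:
            self.add(e)

    def add(self, entry: SeedEntry) -> None:
        if entry.image.input_id in self._ids:
            raise ValueError(f"duplicate seed id {entry.image.input_id!r}")
        self._ids.add(entry.image.input_id)
        self._entries.append(entry)

    def add_image(self, image: ImageInput) -> SeedEntry:
        entry = SeedEntry(image=image)
        self.add(entry)
        return entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[SeedEntry]:
        return iter(self._entries)

    def __getitem__(self, idx: int) -> SeedEntry:
        return self._entries[idx]

    @property
    def ids(self) -> list[str]:
        return [e.image.input_id for e in self._entries]


@dataclass(frozen=True)
class SchedulerParams:
    """Seed-scheduler knobs: γ scales how quickly a seed's priority decays
    with repeated selection; p_min keeps every seed selectable."""

    gamma: float = 20.0
    p_min: float = 0.05

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (0.0 < self.p_min < 1.0):
            raise ValueError("p_min must be in (0, 1)")


def seed_selection_probability(g: int, params: SchedulerParams) -> float:
    """Unnormalized selection weight of a seed chosen ``g`` times before:
    max(1 − g/γ, p_min).  Nonincreasing in g, floored at p_min."""
    if g < 0:
        raise ValueError("selection count g must be >= 0")
    return max(1.0 - g / params.gamma, params.p_min)


def choose_seed(
    seeds: SeedSet, params: SchedulerParams, rng: np.random.Generator
) -> SeedEntry:
    """Draw one seed with probability proportional to its weight and
    increment its selection count."""
    if len(seeds) == 0:
        raise ValueError("cannot choose from an empty seed set")
    weights = np.array([seed_selection_probability(e.g, params) for e in seeds])
    probs = weights / weights.sum()
    idx = int(rng.choice(len(seeds), p=probs))
    entry = seeds[idx]
    entry.g += 1
    return entry


@dataclass(frozen=True)
class MutationRanges:
    """Parameter ranges for the image transforms (all configurable)."""

    translate_frac: float = 0.10      # max shift, fraction of side length
    rotate_deg: float = 15.0          # max |rotation| (degrees)
    scale_range: tuple[float, float] = (0.85, 1.15)
    shear_deg: float = 10.0           # max |shear| (degrees)
    brightness: float = 0.2           # max |additive shift|
    contrast_range: tuple[float, float] = (0.7, 1.3)
    blur_sigma: tuple[float, float] = (0.5, 2.0)   # Gaussian blur σ (px)
    noise_sigma: tuple[float, float] = (0.01, 0.05)
    perturb_amplitude: float = 0.05   # sup-norm bound of pixel perturbation
    perturb_fraction: float = 0.05    # fraction of pixels perturbed


TRANSFORM_KINDS = (
    "translation",
    "rotation",
    "scaling",
    "shearing",
    "brightness",
    "contrast",
    "blur",
    "noise",
    "pixel_perturbation",
)


def _warp(pixels: np.ndarray, tf: sktransform.ProjectiveTransform) -> np.ndarray:
    # borders exposed by geometric transforms are filled with black
    return sktransform.warp(
        pixels, tf.inverse, order=1, mode="constant", cval=0.0, preserve_range=True
    )


def _centered(pixels: np.ndarray, tf: sktransform.AffineTransform):
    h, w = pixels.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    shift = sktransform.AffineTransform(translation=-center)
    unshift = sktransform.AffineTransform(translation=center)
    return shift + tf + unshift


def apply_transform(
    pixels: np.ndarray,
    kind: str,
    rng: np.random.Generator,
    ranges: MutationRanges,
) -> np.ndarray:
    """Apply one named transform with randomly drawn parameters; result is
    clamped to [0, 1] and keeps the input shape."""
    h, w = pixels.shape
    if kind == "translation":
        dy = rng.uniform(-ranges.translate_frac, ranges.translate_frac) * h
        dx = rng.uniform(-ranges.translate_frac, ranges.translate_frac) * w
        out = _warp(pixels, sktransform.AffineTransform(translation=(dx, dy)))
    elif kind == "rotation":
        angle = rng.uniform(-ranges.rotate_deg, ranges.rotate_deg)
        tf = _centered(pixels, sktransform.AffineTransform(rotation=np.deg2rad(angle)))
        out = _warp(pixels, tf)
    elif kind == "scaling":
        s = rng.uniform(*ranges.scale_range)
        tf = _centered(pixels, sktransform.AffineTransform(scale=(s, s)))
        out = _warp(pixels, tf)
    elif kind == "shearing":
        shear = np.deg2rad(rng.uniform(-ranges.shear_deg, ranges.shear_deg))
        tf = _centered(pixels, sktransform.AffineTransform(shear=shear))
        out = _warp(pixels, tf)
    elif kind == "brightness":
        out = pixels + rng.uniform(-ranges.brightness, ranges.brightness)
    elif kind == "contrast":
        gain = rng.uniform(*ranges.contrast_range)
        out = (pixels - 0.5) * gain + 0.5
    elif kind == "blur":
        sigma = rng.uniform(*ranges.blur_sigma)
        out = ndimage.gaussian_filter(pixels, sigma=sigma)
    elif kind == "noise":
        sigma = rng.uniform(*ranges.noise_sigma)
        out = pixels + rng.normal(0.0, sigma, size=pixels.shape)
    elif kind == "pixel_perturbation":
        out = _pixel_perturb(
            pixels, rng, ranges.perturb_amplitude, ranges.perturb_fraction
        )
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    return np.clip(out, 0.0, 1.0)


def _pixel_perturb(
    pixels: np.ndarray,
    rng: np.random.Generator,
    amplitude: float,
    fraction: float,
) -> np.ndarray:
    n = pixels.size
    n_perturb = max(1, int(round(fraction * n))) if amplitude > 0 else 0
    out = pixels.copy().ravel()
    if n_perturb:
        idx = rng.choice(n, size=n_perturb, replace=False)
        out[idx] += rng.uniform(-amplitude, amplitude, size=n_perturb)
    return out.reshape(pixels.shape)


_counter = 0


def _next_id(prefix: str) -> str:
    global _counter
    _counter += 1
    return f"{prefix}-{_counter:08d}"


def mutate(
    image: ImageInput,
    rng: np.random.Generator,
    ranges: MutationRanges = MutationRanges(),
    input_id: Optional[str] = None,
) -> ImageInput:
    """Produce one mutant by a single uniformly chosen transform.

    ``input_id`` may be supplied by the caller (the fuzzer assigns ids
    from a per-run counter so runs are reproducible); otherwise a
    process-global counter is used.
    """
    kind = TRANSFORM_KINDS[int(rng.integers(len(TRANSFORM_KINDS)))]
    out = apply_transform(image.pixels, kind, rng, ranges)
    return ImageInput(
        pixels=out,
        input_id=input_id if input_id is not None else _next_id("mut"),
        lineage=f"{image.input_id}:{kind}",
    )


def random_image(
    height: int,
    width: int,
    rng: np.random.Generator,
    input_id: Optional[str] = None,
) -> ImageInput:
    """A fully random image: independent uniform pixels in [0, 1]."""
    if height < 1 or width < 1:
        raise ValueError("dimensions must be positive")
    return ImageInput(
        pixels=rng.uniform(0.0, 1.0, size=(height, width)),
        input_id=input_id if input_id is not None else _next_id("rand"),
        lineage="random",
    )


def local_perturb(
    image: ImageInput,
    rng: np.random.Generator,
    amplitude: float = 0.05,
    fraction: float = 0.05,
    input_id: Optional[str] = None,
) -> ImageInput:
    """Bounded pixel-level perturbation (sup-norm ≤ amplitude on at most
    ``fraction`` of pixels) — near-duplicates of the seed."""
    out = np.clip(_pixel_perturb(image.pixels, rng, amplitude, fraction), 0.0, 1.0)
    return ImageInput(
        pixels=out,
        input_id=input_id if input_id is not None else _next_id("local"),
        lineage=f"{image.input_id}:local_perturb",
    )
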