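"""Coverage metrics steering the fuzzer.

All metrics share one incremental interface: a :class:`CoverageState`
tracks a set of covered *cells* (hashable bin identifiers) out of a fixed
total, so ``Cov = covered / total ∈ [0, 1]`` and never decreases.  For a
candidate test the state is queried two-phase: :meth:`CoverageState.peek`
computes the cells the candidate would newly cover without mutating
anything; :meth:`CoverageState.commit` applies them.  This keeps the
seed-admission check ("does this mutant strictly increase coverage?")
side-effect free when the mutant is rejected.

Three metric families are provided:

* basic strategies (``B-N``, ``B-A``, ``B-FR``, ``B-Local``) that use no
  real coverage signal;
* white-box neuron-coverage baselines (``N-NC``, ``N-KMNC``, ``N-NBC``,
  ``N-SNAC``, ``N-TKNC``) over per-layer activations;
* black-box violation-output metrics (``VO-KMVP``, ``VO-KMOC``,
  ``VO-KMVP-V``, ``VO-VCC``, ``I-KMIC``, ``I-Div-approx``) over safety
  proportions, raw outputs, or input features.

Binning convention: K equal-width bins over [lo, hi), half-open with the
topmost bin closed at hi; values below lo or at/above hi are assigned to
the outermost bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Optional, Sequence

import numpy as np

from .constraints import (
    AGGREGATE_CONSTRAINTS,
    ELECTRODE_CONSTRAINTS,
    Constraint,
    SafetyLimits,
    StimulationVector,
    proportions_by_constraint,
)
from .mutation import ImageInput

__all__ = [
    "METRIC_IDS",
    "BinningSpec",
    "ProfiledRanges",
    "TestObservation",
    "CoverageState",
    "make_metric",
    "preprocess_ranges",
    "bin_index",
    "RandomProjector",
]

METRIC_IDS = (
    "B-N",
    "B-A",
    "B-FR",
    "B-Local",
    "N-NC",
    "N-KMNC",
    "N-NBC",
    "N-SNAC",
    "N-TKNC",
    "VO-KMVP",
    "VO-KMOC",
    "VO-KMVP-V",
    "VO-VCC",
    "I-KMIC",
    "I-Div-approx",
)


@dataclass(frozen=True)
class BinningSpec:
    """K equal-width bins over [range_lo, range_hi)."""

    K: int
    range_lo: float = 0.0
    range_hi: float = 2.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.range_lo < self.range_hi:
            raise ValueError("range_lo must be < range_hi")


def bin_index(value: float, K: int, lo: float, hi: float) -> int:
    """Bin of ``value`` among K equal-width bins over [lo, hi).

    Half-open bins [lo_k, lo_{k+1}); values < lo clamp to bin 0 and values
    >= hi clamp to bin K-1 (the outermost bins).  Degenerate ranges
    (hi <= lo) put everything in the top bin.
    """
    if hi <= lo:
        return K - 1
    if value < lo:
        return 0
    if value >= hi:
        return K - 1
    return min(int((value - lo) / (hi - lo) * K), K - 1)


@dataclass
class ProfiledRanges:
    """Observed value ranges from a profiling pass over the encoder.

    ``output_lo/hi`` bound every output dimension; ``neuron_lo/hi`` (when
    the encoder is white-box) bound every neuron's activation per layer;
    ``feature_lo/hi`` bound the projected input features used by
    I-Div-approx.
    """

    output_lo: Optional[np.ndarray] = None
    output_hi: Optional[np.ndarray] = None
    neuron_lo: Optional[list[np.ndarray]] = None
    neuron_hi: Optional[list[np.ndarray]] = None
    feature_lo: Optional[np.ndarray] = None
    feature_hi: Optional[np.ndarray] = None


class RandomProjector:
    """Fixed seeded random linear map from image pixels to a small feature
    space — a deterministic, download-free stand-in feature extractor for
    the approximate-diversity coverage metric.  Any callable
    image -> 1-D feature vector can replace it."""

    def __init__(self, image_shape: tuple[int, int], n_features: int = 32,
                 seed: int = 12345) -> None:
        rng = np.random.default_rng(seed)
        d = int(np.prod(image_shape))
        self.matrix = rng.standard_normal((n_features, d)) / np.sqrt(d)
        self.n_features = n_features

    def __call__(self, image: ImageInput) -> np.ndarray:
        return self.matrix @ image.pixels.ravel()


@dataclass
class TestObservation:
    """Everything a metric may need to know about one executed test."""

    __test__ = False  # not a pytest case, despite the name

    image: ImageInput
    stim: StimulationVector
    proportions: dict[Constraint, np.ndarray]
    activations: Optional[list[np.ndarray]] = None

    @classmethod
    def from_test(
        cls,
        image: ImageInput,
        stim: StimulationVector,
        limits: SafetyLimits,
        activations: Optional[list[np.ndarray]] = None,
    ) -> "TestObservation":
        return cls(
            image=image,
            stim=stim,
            proportions=proportions_by_constraint(stim, limits),
            activations=activations,
        )


class CoverageState:
    """Incremental bin-occupancy coverage.

    Subclasses implement :meth:`cells` mapping an observation to the set
    of cells it occupies; this base class handles peek/commit bookkeeping
    and the Cov value.  ``total`` may be ``None`` for strategies without a
    finite cell universe (B-A), in which case Cov is 1 once any test has
    been seen.
    """

    metric_id: str = ""

    def __init__(self, total: Optional[int]) -> None:
        self.total = total
        self.covered: set[Hashable] = set()

    def cells(self, obs: TestObservation) -> set[Hashable]:
        raise NotImplementedError

    # -- two-phase interface ------------------------------------------------
    def peek(self, obs: TestObservation) -> set[Hashable]:
        """Cells the observation would newly cover (state unchanged)."""
        return self.cells(obs) - self.covered

    def gain(self, obs: TestObservation) -> bool:
        """Would adding this test strictly increase covered count?"""
        return bool(self.peek(obs))

    def commit(self, new_cells: set[Hashable]) -> None:
        self.covered |= new_cells

    def observe(self, obs: TestObservation) -> bool:
        """Peek and commit in one step; returns whether coverage grew."""
        new = self.peek(obs)
        self.commit(new)
        return bool(new)

    @property
    def coverage(self) -> float:
        if self.total is None:
            return 1.0 if self.covered else 0.0
        if self.total == 0:
            return 0.0
        return len(self.covered) / self.total


# --------------------------------------------------------------------------
# basic strategies


class NeverAdmit(CoverageState):
    """B-N / B-FR / B-Local: no coverage signal, nothing is ever admitted."""

    def __init__(self, metric_id: str = "B-N") -> None:
        super().__init__(total=1)
        self.metric_id = metric_id

    def cells(self, obs: TestObservation) -> set[Hashable]:
        return set()


class AlwaysAdmit(CoverageState):
    """B-A: every new test counts as new coverage and is admitted."""

    metric_id = "B-A"

    def __init__(self) -> None:
        super().__init__(total=None)

    def cells(self, obs: TestObservation) -> set[Hashable]:
        return {("test", obs.image.input_id)}


# --------------------------------------------------------------------------
# violation-output metrics


class VOKMVPCoverage(CoverageState):
    """Bins the violation proportion α/c of every constraint.

    Cells are (constraint, bin) for aggregate constraints and
    (constraint, electrode, bin) for electrode-wise ones;
    total = K·|V_A| + K·|V_E|·|I|.
    """

    metric_id = "VO-KMVP"

    def __init__(self, n_electrodes: int, binning: BinningSpec) -> None:
        self.binning = binning
        self.n_electrodes = n_electrodes
        total = binning.K * len(AGGREGATE_CONSTRAINTS) + binning.K * len(
            ELECTRODE_CONSTRAINTS
        ) * n_electrodes
        super().__init__(total=total)

    def _bin(self, value: float) -> Optional[int]:
        return bin_index(value, self.binning.K, self.binning.range_lo,
                         self.binning.range_hi)

    def cells(self, obs: TestObservation) -> set[Hashable]:
        out: set[Hashable] = set()
        for c in AGGREGATE_CONSTRAINTS:
            props = obs.proportions.get(c)
            if props is None:
                raise ValueError(f"missing proportion for constraint {c}")
            b = self._bin(float(props[0]))
            if b is not None:
                out.add((c.value, b))
        for c in ELECTRODE_CONSTRAINTS:
            props = obs.proportions.get(c)
            if props is None:
                raise ValueError(f"missing proportion for constraint {c}")
            if len(props) != self.n_electrodes:
                raise ValueError("proportion length does not match array size")
            for i, v in enumerate(props):
                b = self._bin(float(v))
                if b is not None:
                    out.add((c.value, i, b))
        return out


class VOKMVPVCoverage(VOKMVPCoverage):
    """Like VO-KMVP but only over the violating region: bin support
    [1, range_hi]; safe proportions (≤ 1) contribute nothing."""

    metric_id = "VO-KMVP-V"

    def __init__(self, n_electrodes: int, binning: BinningSpec) -> None:
        super().__init__(n_electrodes, BinningSpec(binning.K, 1.0,
                                                   max(binning.range_hi, 1.0 + 1e-12)))

    def _bin(self, value: float) -> Optional[int]:
        if value <= 1.0:
            return None
        return bin_index(value, self.binning.K, self.binning.range_lo,
                         self.binning.range_hi)


class VOKMOCCoverage(CoverageState):
    """Bins every encoder output dimension over its profiled range."""

    metric_id = "VO-KMOC"

    def __init__(self, ranges: ProfiledRanges, K: int = 50) -> None:
        if ranges.output_lo is None or ranges.output_hi is None:
            raise ValueError("VO-KMOC requires profiled output ranges")
        self.lo = np.asarray(ranges.output_lo, dtype=float)
        self.hi = np.asarray(ranges.output_hi, dtype=float)
        self.K = K
        super().__init__(total=K * len(self.lo))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        vals = obs.stim.flat()
        if len(vals) != len(self.lo):
            raise ValueError(
                f"output has {len(vals)} dimensions, ranges profile {len(self.lo)}"
            )
        return {
            (o, bin_index(float(vals[o]), self.K, self.lo[o], self.hi[o]))
            for o in range(len(vals))
        }


class VOVCCCoverage(CoverageState):
    """Tracks which constraint types have been violated at least once."""

    metric_id = "VO-VCC"

    def __init__(self, constraints: Sequence[Constraint] = tuple(Constraint)) -> None:
        self.constraints = tuple(constraints)
        super().__init__(total=len(self.constraints))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        out: set[Hashable] = set()
        for c in self.constraints:
            props = obs.proportions.get(c)
            if props is not None and np.any(np.asarray(props) > 1.0):
                out.add(c.value)
        return out


class IKMICCoverage(CoverageState):
    """Bins each pixel's value over [0, 1]: cells are (pixel, bin)."""

    metric_id = "I-KMIC"

    def __init__(self, image_shape: tuple[int, int], K: int = 10) -> None:
        self.image_shape = image_shape
        self.K = K
        super().__init__(total=K * int(np.prod(image_shape)))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        if obs.image.shape != self.image_shape:
            raise ValueError("image shape does not match configured dimensions")
        px = obs.image.pixels.ravel()
        bins = np.minimum((px * self.K).astype(int), self.K - 1)
        return set(zip(range(px.size), bins.tolist()))


class IDivApproxCoverage(CoverageState):
    """Bins a projected feature space of the input image (approximate test
    diversity); same bin arithmetic as VO-KMOC applied to features."""

    metric_id = "I-Div-approx"

    def __init__(
        self,
        projector: Callable[[ImageInput], np.ndarray],
        ranges: ProfiledRanges,
        K: int = 50,
    ) -> None:
        if ranges.feature_lo is None or ranges.feature_hi is None:
            raise ValueError("I-Div-approx requires profiled feature ranges")
        self.projector = projector
        self.lo = np.asarray(ranges.feature_lo, dtype=float)
        self.hi = np.asarray(ranges.feature_hi, dtype=float)
        self.K = K
        super().__init__(total=K * len(self.lo))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        feats = np.asarray(self.projector(obs.image), dtype=float)
        if len(feats) != len(self.lo):
            raise ValueError("feature dimensionality does not match profile")
        return {
            (j, bin_index(float(feats[j]), self.K, self.lo[j], self.hi[j]))
            for j in range(len(feats))
        }


# --------------------------------------------------------------------------
# neuron-coverage baselines (white-box)


def _require_activations(obs: TestObservation) -> list[np.ndarray]:
    if obs.activations is None:
        raise ValueError(
            "this metric needs a white-box encoder exposing activations"
        )
    return obs.activations


def _n_neurons(layers: list[np.ndarray]) -> int:
    return int(sum(len(a) for a in layers))


class NeuronCoverage(CoverageState):
    """N-NC: a neuron is covered once its per-layer min-max-scaled
    activation exceeds threshold t on some test."""

    metric_id = "N-NC"

    def __init__(self, layer_sizes: Sequence[int], threshold: float = 0.75) -> None:
        self.threshold = threshold
        self.layer_sizes = tuple(layer_sizes)
        super().__init__(total=int(sum(layer_sizes)))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        out: set[Hashable] = set()
        for li, act in enumerate(_require_activations(obs)):
            lo, hi = float(act.min()), float(act.max())
            scaled = (act - lo) / (hi - lo) if hi > lo else np.zeros_like(act)
            for ni in np.flatnonzero(scaled > self.threshold):
                out.add((li, int(ni)))
        return out


class KMNCCoverage(CoverageState):
    """N-KMNC: K bins per neuron over its profiled [low, high] range;
    activations outside the range are not counted (they belong to the
    boundary metrics)."""

    metric_id = "N-KMNC"

    def __init__(self, ranges: ProfiledRanges, K: int = 1000) -> None:
        if ranges.neuron_lo is None or ranges.neuron_hi is None:
            raise ValueError("N-KMNC requires profiled neuron ranges")
        self.lo = ranges.neuron_lo
        self.hi = ranges.neuron_hi
        self.K = K
        super().__init__(total=K * _n_neurons(ranges.neuron_lo))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        out: set[Hashable] = set()
        for li, act in enumerate(_require_activations(obs)):
            lo, hi = self.lo[li], self.hi[li]
            for ni, v in enumerate(act):
                if lo[ni] <= v <= hi[ni]:
                    if hi[ni] > lo[ni]:
                        b = min(int((v - lo[ni]) / (hi[ni] - lo[ni]) * self.K),
                                self.K - 1)
                    else:
                        b = 0
                    out.add((li, ni, b))
        return out


class NBCCoverage(CoverageState):
    """N-NBC: covers the {below-low, above-high} corner cases per neuron."""

    metric_id = "N-NBC"

    def __init__(self, ranges: ProfiledRanges) -> None:
        if ranges.neuron_lo is None or ranges.neuron_hi is None:
            raise ValueError("N-NBC requires profiled neuron ranges")
        self.lo = ranges.neuron_lo
        self.hi = ranges.neuron_hi
        super().__init__(total=2 * _n_neurons(ranges.neuron_lo))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        out: set[Hashable] = set()
        for li, act in enumerate(_require_activations(obs)):
            for ni in np.flatnonzero(act < self.lo[li]):
                out.add((li, int(ni), "low"))
            for ni in np.flatnonzero(act > self.hi[li]):
                out.add((li, int(ni), "high"))
        return out


class SNACCoverage(CoverageState):
    """N-SNAC: covers neurons driven above their profiled maximum."""

    metric_id = "N-SNAC"

    def __init__(self, ranges: ProfiledRanges) -> None:
        if ranges.neuron_hi is None:
            raise ValueError("N-SNAC requires profiled neuron ranges")
        self.hi = ranges.neuron_hi
        super().__init__(total=_n_neurons(ranges.neuron_hi))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        out: set[Hashable] = set()
        for li, act in enumerate(_require_activations(obs)):
            for ni in np.flatnonzero(act > self.hi[li]):
                out.add((li, int(ni)))
        return out


class TKNCCoverage(CoverageState):
    """N-TKNC: covers neurons that ever rank in their layer's top-K."""

    metric_id = "N-TKNC"

    def __init__(self, layer_sizes: Sequence[int], K: int = 1) -> None:
        self.K = K
        super().__init__(total=int(sum(layer_sizes)))

    def cells(self, obs: TestObservation) -> set[Hashable]:
        out: set[Hashable] = set()
        for li, act in enumerate(_require_activations(obs)):
            k = min(self.K, len(act))
            top = np.argsort(act, kind="stable")[::-1][:k]
            for ni in top:
                out.add((li, int(ni)))
        return out


# --------------------------------------------------------------------------
# profiling and construction


def preprocess_ranges(
    profiling_inputs: Sequence[ImageInput],
    encoder,
    projector: Optional[Callable[[ImageInput], np.ndarray]] = None,
) -> ProfiledRanges:
    """Run the encoder on a profiling set and record per-dimension output
    ranges, per-neuron activation bounds (white-box encoders only), and
    per-feature bounds when a projector is supplied."""
    if not profiling_inputs:
        raise ValueError("profiling set must be non-empty")
    out_lo = out_hi = None
    neuron_lo: Optional[list[np.ndarray]] = None
    neuron_hi: Optional[list[np.ndarray]] = None
    feat_lo = feat_hi = None
    white_box = hasattr(encoder, "encode_with_activations")
    for img in profiling_inputs:
        if white_box:
            stim, acts = encoder.encode_with_activations(img)
        else:
            stim, acts = encoder.encode(img), None
        vals = stim.flat()
        if out_lo is None:
            out_lo, out_hi = vals.copy(), vals.copy()
        else:
            np.minimum(out_lo, vals, out=out_lo)
            np.maximum(out_hi, vals, out=out_hi)
        if acts is not None:
            if neuron_lo is None:
                neuron_lo = [a.copy() for a in acts]
                neuron_hi = [a.copy() for a in acts]
            else:
                for j, a in enumerate(acts):
                    np.minimum(neuron_lo[j], a, out=neuron_lo[j])
                    np.maximum(neuron_hi[j], a, out=neuron_hi[j])
        if projector is not None:
            feats = np.asarray(projector(img), dtype=float)
            if feat_lo is None:
                feat_lo, feat_hi = feats.copy(), feats.copy()
            else:
                np.minimum(feat_lo, feats, out=feat_lo)
                np.maximum(feat_hi, feats, out=feat_hi)
    return ProfiledRanges(
        output_lo=out_lo,
        output_hi=out_hi,
        neuron_lo=neuron_lo,
        neuron_hi=neuron_hi,
        feature_lo=feat_lo,
        feature_hi=feat_hi,
    )


#: Metrics that need a profiling pass before fuzzing.
RANGE_BASED_METRICS = {"VO-KMOC", "I-Div-approx", "N-KMNC", "N-NBC", "N-SNAC"}
#: Metrics that need white-box activation access.
WHITE_BOX_METRICS = {"N-NC", "N-KMNC", "N-NBC", "N-SNAC", "N-TKNC"}


def make_metric(
    metric_id: str,
    *,
    n_electrodes: int,
    image_shape: tuple[int, int],
    binning: Optional[BinningSpec] = None,
    ranges: Optional[ProfiledRanges] = None,
    layer_sizes: Optional[Sequence[int]] = None,
    projector: Optional[Callable[[ImageInput], np.ndarray]] = None,
    kmoc_k: int = 50,
    kmnc_k: int = 1000,
    kmic_k: int = 10,
    nc_threshold: float = 0.75,
    tknc_k: int = 1,
) -> CoverageState:
    """Construct the coverage state for a metric id with its defaults."""
    if metric_id not in METRIC_IDS:
        raise ValueError(
            f"unknown metric {metric_id!r}; valid ids: {', '.join(METRIC_IDS)}"
        )
    binning = binning or BinningSpec(K=50, range_lo=0.0, range_hi=2.0)
    if metric_id in ("B-N", "B-FR", "B-Local"):
        return NeverAdmit(metric_id)
    if metric_id == "B-A":
        return AlwaysAdmit()
    if metric_id == "VO-KMVP":
        return VOKMVPCoverage(n_electrodes, binning)
    if metric_id == "VO-KMVP-V":
        return VOKMVPVCoverage(n_electrodes, binning)
    if metric_id == "VO-VCC":
        return VOVCCCoverage()
    if metric_id == "I-KMIC":
        return IKMICCoverage(image_shape, K=kmic_k)
    if metric_id in RANGE_BASED_METRICS and ranges is None:
        raise ValueError(f"{metric_id} requires profiled ranges (run preprocessing)")
    if metric_id == "VO-KMOC":
        return VOKMOCCoverage(ranges, K=kmoc_k)
    if metric_id == "I-Div-approx":
        proj = projector or RandomProjector(image_shape)
        if ranges.feature_lo is None:
            raise ValueError("I-Div-approx requires profiled feature ranges")
        return IDivApproxCoverage(proj, ranges, K=kmoc_k)
    # neuron metrics
    if metric_id in ("N-NC", "N-TKNC"):
        if layer_sizes is None:
            raise ValueError(f"{metric_id} requires layer sizes of a white-box encoder")
        if metric_id == "N-NC":
            return NeuronCoverage(layer_sizes, threshold=nc_threshold)
        return TKNCCoverage(layer_sizes, K=tknc_k)
    if metric_id == "N-KMNC":
        return KMNCCoverage(ranges, K=kmnc_k)
    if metric_id == "N-NBC":
        return NBCCoverage(ranges)
    if metric_id == "N-SNAC":
        return SNACCoverage(ranges)
    raise AssertionError("unreachable")
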