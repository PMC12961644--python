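"""Diversity measures over discovered violations.

A large violation count alone says little: a fuzzer can hammer one unsafe
input with thousands of near-duplicates.  Two complementary measures
quantify how *spread out* the violations actually are:

* **Geometric diversity (GD)** — the determinant of the Gram matrix of
  stacked input-feature vectors, det(A Aᵀ).  Larger values mean the
  violating inputs are more linearly independent in feature space.  Rows
  are L2-normalized before the determinant (raw-scale determinants
  overflow or underflow immediately), and the determinant is computed via
  a log-determinant factorization for stability.

* **Violation-space diversity (STD)** — the Euclidean norm of the
  per-column population standard deviations of the violation-space
  matrix, whose row for each violating test concatenates, per electrode,
  the violation degrees of the electrode-wise constraints and the
  normalized amplitude.  High values mean violations vary across the
  electrode array rather than clustering on one channel.

Because both measures depend on sample size, the reporting protocol
computes each on a few random subsets of fixed size (default five subsets
of 200 violations) and reports the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from skimage import transform as sktransform

from .constraints import Constraint
from .fuzzer import FoundViolation
from .mutation import ImageInput

__all__ = [
    "default_feature_extractor",
    "feature_matrix",
    "geometric_diversity",
    "violation_space_matrix",
    "violation_space_std",
    "subsampled_diversity",
    "DiversityResult",
    "combined_score",
]


def default_feature_extractor(image: ImageInput) -> np.ndarray:
    """Deterministic, download-free image features: 14×14 downsampled
    pixels concatenated with a 16-bin intensity histogram
    (density-normalized), 212 dimensions total.

    The dimensionality deliberately exceeds the default diversity subset
    size (200): the Gram determinant of n feature rows is identically
    zero when n exceeds the feature dimension, so a smaller extractor
    would degenerate the geometric-diversity channel.  A pretrained-CNN
    extractor can be plugged in anywhere a
    ``Callable[[ImageInput], np.ndarray]`` is accepted; this default
    keeps GD's comparative role without any model checkpoint.
    """
    small = sktransform.resize(
        image.pixels, (14, 14), order=1, mode="reflect", anti_aliasing=True
    )
    hist, _ = np.histogram(image.pixels, bins=16, range=(0.0, 1.0))
    hist = hist / max(image.pixels.size, 1)
    return np.concatenate([small.ravel(), hist])


def feature_matrix(
    images: Sequence[ImageInput],
    extractor: Callable[[ImageInput], np.ndarray] = default_feature_extractor,
    normalize: bool = True,
) -> np.ndarray:
    """Stack feature vectors of the images into a matrix (rows = inputs),
    optionally L2-normalizing each row."""
    if not images:
        raise ValueError("feature_matrix needs at least one image")
    rows = np.vstack([np.asarray(extractor(img), dtype=float) for img in images])
    if normalize:
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        rows = rows / norms
    return rows


def geometric_diversity(features: np.ndarray, return_log: bool = False):
    """det(A Aᵀ) of a feature matrix A (rows = violating inputs).

    Computed as exp(slogdet) for stability; rank-deficient Gram matrices
    (duplicate rows, or more rows than columns) give 0 (log-det −inf).
    """
    A = np.asarray(features, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("features must be a non-empty 2-D matrix")
    gram = A @ A.T
    sign, logdet = np.linalg.slogdet(gram)
    rank_deficient = (
        A.shape[0] > A.shape[1] or np.linalg.matrix_rank(A) < A.shape[0]
    )
    if sign <= 0 or rank_deficient:
        gd, ld = 0.0, -np.inf
    else:
        gd, ld = float(np.exp(logdet)), float(logdet)
    return (gd, ld) if return_log else gd


def violation_space_matrix(
    violations: Sequence[FoundViolation],
    n_electrodes: int,
    amp_max: float,
) -> np.ndarray:
    """Rows = violating tests; columns concatenate, per electrode,
    [degree_PI, degree_CD, amplitude/amp_max clamped to [0, 1]], so the
    column count is always 3·|I|."""
    if amp_max <= 0:
        raise ValueError("amp_max must be positive")
    rows = []
    for v in violations:
        deg_pi = v.record.degrees.get(Constraint.PI, np.zeros(n_electrodes))
        deg_cd = v.record.degrees.get(Constraint.CD, np.zeros(n_electrodes))
        amp = np.clip(v.stim.amplitude / amp_max, 0.0, 1.0)
        row = np.column_stack([deg_pi, deg_cd, amp]).ravel()
        rows.append(row)
    if not rows:
        return np.zeros((0, 3 * n_electrodes))
    return np.vstack(rows)


def violation_space_std(matrix: np.ndarray) -> float:
    """Euclidean norm of the per-column population standard deviations of
    the violation-space matrix."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] == 0:
        raise ValueError("violation-space matrix must have at least one row")
    stds = M.std(axis=0)  # population std (divide by n)
    return float(np.linalg.norm(stds))


@dataclass
class DiversityResult:
    """Subsampled diversity summary.

    ``gd_mean`` is the raw Gram determinant, which underflows to ~0 for
    any realistically sized subset (the determinant of n L2-normalized
    rows shrinks exponentially in n); ``gd_log_mean`` — the mean
    log-determinant, −inf when any subset is rank-deficient — is the
    statistic to compare across strategies.
    """

    gd_mean: float
    std_mean: float
    gd_log_mean: float
    gd_per_subset: list[float]
    std_per_subset: list[float]
    gd_log_per_subset: list[float]
    n_violations: int
    insufficient: bool = False  # fewer violations than one full subset


def subsampled_diversity(
    violations: Sequence[FoundViolation],
    n_electrodes: int,
    amp_max: float,
    rng: np.random.Generator,
    k_subsets: int = 5,
    subset_size: int = 200,
    extractor: Callable[[ImageInput], np.ndarray] = default_feature_extractor,
) -> DiversityResult:
    """Mean GD and violation-space STD over random subsets of violations.

    Samples ``k_subsets`` subsets of ``subset_size`` without replacement
    (within each subset).  With fewer violations than one subset, all are
    used once; with zero violations the result is (0, 0) with a warning.
    """
    n = len(violations)
    if n == 0:
        warnings.warn("no violations: diversity defined as (0, 0)")
        return DiversityResult(0.0, 0.0, -np.inf, [], [], [], 0,
                               insufficient=True)
    if n <= subset_size:
        subsets = [list(range(n))]
        insufficient = n < subset_size
    else:
        subsets = [
            rng.choice(n, size=subset_size, replace=False).tolist()
            for _ in range(k_subsets)
        ]
        insufficient = False
    gds, stds, lds = [], [], []
    for idx in subsets:
        subset = [violations[i] for i in idx]
        feats = feature_matrix([v.image for v in subset], extractor=extractor)
        gd, ld = geometric_diversity(feats, return_log=True)
        gds.append(gd)
        lds.append(ld)
        vs = violation_space_matrix(subset, n_electrodes, amp_max)
        stds.append(violation_space_std(vs))
    return DiversityResult(
        gd_mean=float(np.mean(gds)),
        std_mean=float(np.mean(stds)),
        gd_log_mean=float(np.mean(lds)),
        gd_per_subset=gds,
        std_per_subset=stds,
        gd_log_per_subset=lds,
        n_violations=n,
        insufficient=insufficient,
    )


def _minmax(values: np.ndarray, lo: Optional[float], hi: Optional[float]) -> np.ndarray:
    """Linear [0,1] normalization; an all-equal channel contributes 0.
    When a frozen baseline (lo, hi) is supplied, values outside it may map
    outside [0, 1].  Non-finite entries (e.g. a −inf log-determinant for a
    rank-deficient subset) normalize to the channel floor 0."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        return np.zeros_like(values)
    lo = float(np.min(values[finite])) if lo is None else lo
    hi = float(np.max(values[finite])) if hi is None else hi
    if hi <= lo:
        return np.zeros_like(values)
    out = np.zeros_like(values)
    out[finite] = (values[finite] - lo) / (hi - lo)
    out[values == np.inf] = 1.0
    return out


def combined_score(
    violation_counts: Sequence[float],
    gd_values: Sequence[float],
    std_values: Sequence[float],
    diversity_weight: float = 0.5,
    baseline: Optional[dict[str, tuple[float, float]]] = None,
) -> np.ndarray:
    """Per-strategy combined score: equally weighted average of the
    min-max-normalized violation count and a combined diversity score
    (itself the ``diversity_weight``-weighted mix of normalized GD and
    normalized violation-space STD).

    ``baseline`` may freeze the normalization ranges per channel
    ({"violations"|"gd"|"std": (lo, hi)}), in which case scores above 1
    are possible.  Channels with no spread contribute 0 for everyone.
    """
    counts = np.asarray(violation_counts, dtype=float)
    gds = np.asarray(gd_values, dtype=float)
    stds = np.asarray(std_values, dtype=float)
    if not (len(counts) == len(gds) == len(stds)):
        raise ValueError("all channels must have one value per strategy")
    if baseline is None and len(counts) < 2:
        raise ValueError("normalization needs >= 2 strategies or a frozen baseline")
    baseline = baseline or {}
    nv = _minmax(counts, *(baseline.get("violations", (None, None))))
    ngd = _minmax(gds, *(baseline.get("gd", (None, None))))
    nstd = _minmax(stds, *(baseline.get("std", (None, None))))
    diversity = diversity_weight * ngd + (1.0 - diversity_weight) * nstd
    return (nv + diversity) / 2.0
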