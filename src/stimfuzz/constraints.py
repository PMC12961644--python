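"""Biophysical safety constraints for electrode-based neurostimulation.

A stimulus encoder maps a sensory input to per-electrode stimulation
parameters: pulse frequency ``f`` (Hz), pulse duration ``p`` (ms) and
amplitude ``a`` (µA) of a charge-balanced biphasic pulse train.  Safe
operation is expressed as a set of inequality constraints ``V_k(y) <= 0``;
a configuration with any ``V_k(y) > 0`` is a safety violation.

Four clinically motivated constraints are implemented:

``PI``  physically impossible pulse: each biphasic pulse (two phases of
        duration ``p``) must fit in the period ``1000/f`` ms, so
        ``V_PI = 2 p - 1000/f`` per electrode.
``CD``  per-electrode charge: ``V_CD = p·a - ε1``, with ``p·a`` in nC
        (µA · ms = nC).
``IC``  total instantaneous current: ``V_IC = Σ a_i - ε2`` (µA).
``AE``  simultaneously active electrodes: ``V_AE = Σ [a_i > 0] - ε3``.

Each constraint also has a dimensionless *violation proportion* ``α/c``
(quantity over its limit): values ≤ 1 are safe, > 1 violate.  For PI the
proportion is ``2 p f / 1000`` (α = 2p against the period c = 1000/f).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Constraint",
    "Severity",
    "ElectrodeArraySpec",
    "StimulationVector",
    "SafetyLimits",
    "RETINAL_LIMITS",
    "CORTICAL_LIMITS",
    "ConstraintResult",
    "ViolationRecord",
    "check_physically_impossible",
    "check_charge_density",
    "check_instantaneous_current",
    "check_active_electrodes",
    "evaluate_all",
    "violation_degree",
    "classify_severity",
    "write_violations_jsonl",
    "write_violations_csv",
]


class Constraint(str, Enum):
    """Identifier of a safety constraint."""

    PI = "PI"  # physically impossible pulse (per electrode)
    CD = "CD"  # charge density / per-electrode charge (per electrode)
    IC = "IC"  # instantaneous current (aggregate)
    AE = "AE"  # active electrode count (aggregate)


#: Constraints evaluated per electrode.
ELECTRODE_CONSTRAINTS = (Constraint.PI, Constraint.CD)
#: Constraints evaluated on the whole array.
AGGREGATE_CONSTRAINTS = (Constraint.IC, Constraint.AE)


class Severity(str, Enum):
    SAFE = "safe"
    MARGINAL = "marginal"
    MODERATE = "moderate"
    CATASTROPHIC = "catastrophic"


#: Severity strata: up to 5% over the limit is marginal, up to 30% over is
#: moderate, beyond that catastrophic.  Boundaries are closed on the upper
#: end of each class.
MARGINAL_UPPER = 1.05
MODERATE_UPPER = 1.30


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """Geometry-agnostic description of an electrode array.

    Parameters
    ----------
    n_electrodes
        Number of electrodes ``|I|`` (>= 1).
    layout_label
        Free-text description, e.g. ``"15x15 epiretinal, 400 µm pitch"``.
    params_per_electrode
        3 when the encoder controls (f, p, a) per electrode, 1 when it
        controls amplitude only and frequency / pulse duration are fixed
        shared constants of the device.
    shared_frequency, shared_pulse_duration
        The fixed f (Hz) and p (ms) for 1-parameter arrays; ignored for
        3-parameter arrays.
    """

    n_electrodes: int
    layout_label: str = ""
    params_per_electrode: int = 3
    shared_frequency: Optional[float] = None
    shared_pulse_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.params_per_electrode not in (1, 3):
            raise ValueError("params_per_electrode must be 1 or 3")
        if self.params_per_electrode == 1:
            if self.shared_frequency is None or self.shared_pulse_duration is None:
                raise ValueError(
                    "1-parameter arrays need shared_frequency and "
                    "shared_pulse_duration"
                )

    @classmethod
    def from_yaml(cls, stream: IO[str] | str) -> "ElectrodeArraySpec":
        data = yaml.safe_load(stream)
        return cls(**data)


@dataclass(frozen=True)
class StimulationVector:
    """Per-electrode stimulation parameters produced by an encoder.

    ``frequency`` (Hz), ``pulse_duration`` (ms) and ``amplitude`` (µA) are
    1-D arrays of length ``array_spec.n_electrodes``; all entries must be
    finite and non-negative.
    """

    frequency: np.ndarray
    pulse_duration: np.ndarray
    amplitude: np.ndarray
    array_spec: ElectrodeArraySpec

    def __post_init__(self) -> None:
        n = self.array_spec.n_electrodes
        for name in ("frequency", "pulse_duration", "amplitude"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
            object.__setattr__(self, name, arr)

    @classmethod
    def from_arrays(
        cls,
        frequency: Iterable[float],
        pulse_duration: Iterable[float],
        amplitude: Iterable[float],
        array_spec: ElectrodeArraySpec,
    ) -> "StimulationVector":
        return cls(
            np.asarray(frequency, dtype=float),
            np.asarray(pulse_duration, dtype=float),
            np.asarray(amplitude, dtype=float),
            array_spec,
        )

    @classmethod
    def amplitudes_only(
        cls, amplitude: Iterable[float], array_spec: ElectrodeArraySpec
    ) -> "StimulationVector":
        """Build a vector for a 1-parameter array: shared f and p are
        broadcast from the array spec."""
        if array_spec.params_per_electrode != 1:
            raise ValueError("amplitudes_only requires a 1-parameter array spec")
        n = array_spec.n_electrodes
        f = np.full(n, float(array_spec.shared_frequency))
        p = np.full(n, float(array_spec.shared_pulse_duration))
        return cls(f, p, np.asarray(amplitude, dtype=float), array_spec)

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of active electrodes (strictly positive amplitude)."""
        return self.amplitude > 0

    def flat(self) -> np.ndarray:
        """Flat output vector [f_1..f_n, p_1..p_n, a_1..a_n] (3-param) or
        amplitudes only (1-param) — the encoder's output dimensions."""
        if self.array_spec.params_per_electrode == 1:
            return self.amplitude.copy()
        return np.concatenate([self.frequency, self.pulse_duration, self.amplitude])


@dataclass(frozen=True)
class SafetyLimits:
    """Device safety limits (all strictly positive).

    eps1_charge: per-electrode charge limit ε1 (nC).
    eps2_current: total instantaneous current limit ε2 (µA).
    eps3_active: maximum simultaneously active electrodes ε3 (count).
    """

    eps1_charge: float
    eps2_current: float
    eps3_active: int

    def __post_init__(self) -> None:
        if self.eps1_charge <= 0 or self.eps2_current <= 0 or self.eps3_active <= 0:
            raise ValueError("all safety limits must be strictly positive")

    @classmethod
    def from_yaml(cls, stream: IO[str] | str) -> "SafetyLimits":
        data = yaml.safe_load(stream)
        if isinstance(data, str):
            return PRESETS[data.upper()]
        if "preset" in data:
            return PRESETS[data["preset"].upper()]
        return cls(**data)


#: Epiretinal preset: 0.628 µC per-electrode charge (628 nC), 6 mA total
#: current, 100 simultaneously active electrodes.
RETINAL_LIMITS = SafetyLimits(eps1_charge=628.0, eps2_current=6000.0, eps3_active=100)
#: Intracortical (Utah array) preset: 20.4 nC, 3.6 mA, 30 active electrodes.
CORTICAL_LIMITS = SafetyLimits(eps1_charge=20.4, eps2_current=3600.0, eps3_active=30)

PRESETS = {"RETINAL": RETINAL_LIMITS, "CORTICAL": CORTICAL_LIMITS}


@dataclass(frozen=True)
class ConstraintResult:
    """Evaluated constraint: signed value ``V`` and proportion ``α/c``.

    ``is_violation`` is equivalent to ``value_V > 0`` and (for positive
    limits) to ``proportion > 1``.
    """

    constraint_id: Constraint
    scope: str  # "aggregate" | "per_electrode"
    value_V: float
    proportion: float
    electrode_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scope not in ("aggregate", "per_electrode"):
            raise ValueError(f"invalid scope {self.scope!r}")
        if (self.scope == "per_electrode") != (self.electrode_index is not None):
            raise ValueError("electrode_index present iff scope is per_electrode")

    @property
    def is_violation(self) -> bool:
        return self.value_V > 0

    @property
    def severity(self) -> Severity:
        return classify_severity(self.proportion)

    def to_dict(self) -> dict:
        return {
            "constraint": self.constraint_id.value,
            "scope": self.scope,
            "electrode": self.electrode_index,
            "value_V": float(self.value_V),
            "proportion": float(self.proportion),
            "is_violation": self.is_violation,
            "severity": self.severity.value,
        }


@dataclass
class ViolationRecord:
    """A test input whose output violates at least one constraint.

    ``results`` holds only the violating :class:`ConstraintResult` entries;
    ``degrees`` the per-electrode violation intensities max(0, α/c − 1) for
    the electrode-wise constraints; ``severity`` the worst severity reached
    per violated constraint.
    """

    input_id: str
    results: list[ConstraintResult]
    degrees: dict[Constraint, np.ndarray] = field(default_factory=dict)
    severity: dict[Constraint, Severity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.results:
            raise ValueError("ViolationRecord requires at least one violation")

    @property
    def constraints_violated(self) -> set[Constraint]:
        return {r.constraint_id for r in self.results}

    def to_dict(self) -> dict:
        return {
            "input_id": self.input_id,
            "results": [r.to_dict() for r in self.results],
            "severity": {k.value: v.value for k, v in sorted(self.severity.items())},
        }


def _per_electrode_results(
    constraint: Constraint, value_V: np.ndarray, proportion: np.ndarray
) -> list[ConstraintResult]:
    return [
        ConstraintResult(
            constraint_id=constraint,
            scope="per_electrode",
            electrode_index=i,
            value_V=float(value_V[i]),
            proportion=float(proportion[i]),
        )
        for i in range(len(value_V))
    ]


def pi_arrays(stim: StimulationVector) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized V_PI values and proportions (one entry per electrode).

    Only electrodes that are active (a > 0) *and* pulsing (f > 0) can host
    a physically impossible pulse; all others get V = -1000/f (or a safe 0
    placeholder when f = 0) and proportion 0.
    """
    f, p, a = stim.frequency, stim.pulse_duration, stim.amplitude
    evaluable = (a > 0) & (f > 0)
    value = np.zeros_like(f)
    proportion = np.zeros_like(f)
    with np.errstate(divide="ignore"):
        period = np.where(f > 0, 1000.0 / np.where(f > 0, f, 1.0), np.inf)
    value[evaluable] = 2.0 * p[evaluable] - period[evaluable]
    proportion[evaluable] = 2.0 * p[evaluable] * f[evaluable] / 1000.0
    # inactive / zero-frequency electrodes deliver no pulse train: safe.
    value[~evaluable] = np.minimum(value[~evaluable], 0.0)
    return value, proportion


def check_physically_impossible(stim: StimulationVector) -> list[ConstraintResult]:
    """Per-electrode physically-impossible-pulse check: V = 2p − 1000/f (ms).

    Electrodes with zero amplitude or zero frequency deliver no pulses and
    are reported safe with proportion 0.
    """
    value, proportion = pi_arrays(stim)
    return _per_electrode_results(Constraint.PI, value, proportion)


def cd_arrays(
    stim: StimulationVector, limits: SafetyLimits
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized V_CD values (nC) and proportions per electrode."""
    charge = stim.pulse_duration * stim.amplitude  # µA·ms = nC
    return charge - limits.eps1_charge, charge / limits.eps1_charge


def check_charge_density(
    stim: StimulationVector, limits: SafetyLimits
) -> list[ConstraintResult]:
    """Per-electrode charge check: V = p·a − ε1, with p·a in nC."""
    value, proportion = cd_arrays(stim, limits)
    return _per_electrode_results(Constraint.CD, value, proportion)


def check_instantaneous_current(
    stim: StimulationVector, limits: SafetyLimits
) -> ConstraintResult:
    """Aggregate instantaneous-current check: V = Σ a_i − ε2 (µA)."""
    total = float(np.sum(stim.amplitude))
    return ConstraintResult(
        constraint_id=Constraint.IC,
        scope="aggregate",
        value_V=total - limits.eps2_current,
        proportion=total / limits.eps2_current,
    )


def check_active_electrodes(
    stim: StimulationVector, limits: SafetyLimits
) -> ConstraintResult:
    """Aggregate co-activation check: V = Σ [a_i > 0] − ε3."""
    count = int(np.sum(stim.active))
    return ConstraintResult(
        constraint_id=Constraint.AE,
        scope="aggregate",
        value_V=float(count - limits.eps3_active),
        proportion=count / limits.eps3_active,
    )


def evaluate_all(
    stim: StimulationVector,
    limits: SafetyLimits,
    input_id: str = "",
) -> tuple[list[ConstraintResult], Optional[ViolationRecord]]:
    """Evaluate all four constraints; return every result plus a
    :class:`ViolationRecord` iff at least one constraint is violated."""
    results: list[ConstraintResult] = []
    results.extend(check_physically_impossible(stim))
    results.extend(check_charge_density(stim, limits))
    results.append(check_instantaneous_current(stim, limits))
    results.append(check_active_electrodes(stim, limits))

    violating = [r for r in results if r.is_violation]
    if not violating:
        return results, None

    pi_val, pi_prop = pi_arrays(stim)
    cd_val, cd_prop = cd_arrays(stim, limits)
    degrees = {
        Constraint.PI: np.maximum(0.0, pi_prop - 1.0),
        Constraint.CD: np.maximum(0.0, cd_prop - 1.0),
    }
    severity: dict[Constraint, Severity] = {}
    for r in violating:
        s = r.severity
        prev = severity.get(r.constraint_id)
        if prev is None or _severity_rank(s) > _severity_rank(prev):
            severity[r.constraint_id] = s
    record = ViolationRecord(
        input_id=input_id, results=violating, degrees=degrees, severity=severity
    )
    return results, record


def proportions_by_constraint(
    stim: StimulationVector, limits: SafetyLimits
) -> dict[Constraint, np.ndarray]:
    """All violation proportions of a test, keyed by constraint.

    Electrode-wise constraints map to arrays of length |I|, aggregate
    constraints to length-1 arrays.  This is the input the violation-output
    coverage metrics consume.
    """
    _, pi_prop = pi_arrays(stim)
    _, cd_prop = cd_arrays(stim, limits)
    ic = check_instantaneous_current(stim, limits)
    ae = check_active_electrodes(stim, limits)
    return {
        Constraint.PI: pi_prop,
        Constraint.CD: cd_prop,
        Constraint.IC: np.array([ic.proportion]),
        Constraint.AE: np.array([ae.proportion]),
    }


def violation_degree(result: ConstraintResult) -> float:
    """Degree of violation intensity max(0, α/c − 1) for a per-electrode
    result; zero for safe electrodes, raising usage error on aggregates."""
    if result.scope != "per_electrode":
        raise ValueError("violation_degree is defined for per-electrode results")
    return max(0.0, result.proportion - 1.0)


def _severity_rank(s: Severity) -> int:
    return [
        Severity.SAFE,
        Severity.MARGINAL,
        Severity.MODERATE,
        Severity.CATASTROPHIC,
    ].index(s)


def classify_severity(proportion: float) -> Severity:
    """Stratify a violation proportion: ≤1 safe, (1, 1.05] marginal,
    (1.05, 1.30] moderate, >1.30 catastrophic."""
    if not np.isfinite(proportion) or proportion < 0:
        raise ValueError(f"proportion must be finite and >= 0, got {proportion}")
    if proportion <= 1.0:
        return Severity.SAFE
    if proportion <= MARGINAL_UPPER:
        return Severity.MARGINAL
    if proportion <= MODERATE_UPPER:
        return Severity.MODERATE
    return Severity.CATASTROPHIC


def write_violations_jsonl(records: Sequence[ViolationRecord], fh: IO[str]) -> None:
    """Serialize violation records as JSON lines (sorted keys, stable)."""
    for rec in records:
        fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


def write_violations_csv(records: Sequence[ViolationRecord], fh: IO[str]) -> None:
    """Flat CSV: one row per violating constraint result."""
    writer = csv.writer(fh)
    writer.writerow(
        ["input_id", "constraint", "electrode", "value_V", "proportion", "severity"]
    )
    for rec in records:
        for r in rec.results:
            writer.writerow(
                [
                    rec.input_id,
                    r.constraint_id.value,
                    "" if r.electrode_index is None else r.electrode_index,
                    repr(r.value_V),
                    repr(r.proportion),
                    r.severity.value,
                ]
            )
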