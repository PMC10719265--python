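"""Pure functions for 15N pool bookkeeping and N2O isotopologue pairing.

Under single-pool production, an N2O molecule is assembled from two N atoms
drawn independently from a substrate pool whose 15N atom fraction is ``F``.
The isotopologue shares (mass 44/45/46) are then binomial in ``F``, which
lets the unlabeled (mass-44) production rate be inferred from the doubly
labeled (mass-46) accumulation: ``r44 = r46 * ((1 - F) / F)**2``.  The gross
production rate attributable to the labeled substrate is the sum of the
three isotopologue rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "PoolComposition",
    "IsotopologueRates",
    "InvalidPoolError",
    "atom_fraction",
    "pairing_probabilities",
    "infer_mass44_rate",
    "total_n2o_rate",
    "binomial_consistency",
]

_SPECIES = ("NH4", "NO2", "NO3")


class InvalidPoolError(ValueError):
    """Raised for pool compositions outside the usable domain."""


@dataclass(frozen=True)
class PoolComposition:
    """Substrate pool after tracer addition.

    Parameters
    ----------
    ambient_14n : float
        Ambient (natural) substrate concentration, umol L-1. Must be >= 0.
    tracer_15n : float
        Added 15N tracer concentration, umol L-1. Must be > 0.
    species : str
        One of ``NH4``, ``NO2``, ``NO3``.
    """

    ambient_14n: float
    tracer_15n: float
    species: str = "NH4"

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise InvalidPoolError(
                f"species must be one of {_SPECIES}, got {self.species!r}"
            )
        if not math.isfinite(self.ambient_14n) or self.ambient_14n < 0:
            raise InvalidPoolError(
                f"ambient_14n must be finite and >= 0, got {self.ambient_14n}"
            )
        if not math.isfinite(self.tracer_15n) or self.tracer_15n <= 0:
            raise InvalidPoolError(
                f"tracer_15n must be finite and > 0, got {self.tracer_15n}"
            )
        if self.ambient_14n == 0:
            # F = 1 breaks the mass-44 inference (division by (1-F) ratio
            # degenerates); a pure-tracer pool is not a usable design.
            raise InvalidPoolError(
                "pure-tracer pool: ambient_14n = 0 gives atom fraction 1, "
                "outside the open interval (0, 1)"
            )

    @property
    def total(self) -> float:
        return self.ambient_14n + self.tracer_15n


def atom_fraction(pool: PoolComposition) -> float:
    """15N atom fraction F = tracer / (ambient + tracer), in (0, 1)."""
    return pool.tracer_15n / (pool.ambient_14n + pool.tracer_15n)


def _check_fraction(f: float) -> None:
    if not (0.0 < f < 1.0):
        raise ValueError(f"atom fraction must lie in (0, 1), got {f}")


def pairing_probabilities(f: float) -> tuple[float, float, float]:
    """Binomial isotopologue probabilities (p44, p45, p46) at atom fraction F.

    p44 = (1-F)^2, p45 = 2 F (1-F), p46 = F^2; the three sum to 1 exactly.
    """
    _check_fraction(f)
    q = 1.0 - f
    p44 = q * q
    p46 = f * f
    # p44 + p46 >= 0.5 on (0,1), so 1 - (p44 + p46) is exact (Sterbenz);
    # the triple then sums to 1 within one rounding of the addition order
    p45 = 1.0 - (p44 + p46)
    return p44, p45, p46


def infer_mass44_rate(r46: float, pool: PoolComposition) -> float:
    """Unlabeled-N2O production rate inferred from the 46N2O rate.

    ``r44 = r46 * ((1-F)/F)**2`` — algebraically the squared ratio of the
    ambient to tracer concentrations of the labeled pool.
    """
    f = atom_fraction(pool)
    _check_fraction(f)
    if r46 < 0:
        warnings.warn(
            "negative 46N2O rate clamped to 0 (below-detection isotopologue)",
            stacklevel=2,
        )
        r46 = 0.0
    return r46 * ((1.0 - f) / f) ** 2


@dataclass
class IsotopologueRates:
    """Per-isotopologue N2O production rates for one labeling experiment.

    ``r_total_molecules`` is in molecule units (nmol N2O L-1 d-1);
    ``r_total_n`` multiplies by 2 for N units (nmol N L-1 d-1).
    """

    r44: float
    r45: float
    r46: float
    r_total_molecules: float = field(init=False)
    r_total_n: float = field(init=False)
    below_detection: bool = False
    method: str = "r46-inferred"

    def __post_init__(self) -> None:
        self.r_total_molecules = self.r44 + self.r45 + self.r46
        self.r_total_n = 2.0 * self.r_total_molecules


def total_n2o_rate(
    r45: float,
    r46: float,
    pool: PoolComposition,
    *,
    r45_below_detection: bool = False,
    r46_below_detection: bool = False,
) -> IsotopologueRates:
    """Gross N2O production from measured 45/46 isotopologue rates.

    The default path infers the mass-44 rate from ``r46`` and sums the
    three isotopologues.  When ``r46`` is below detection but ``r45`` is
    not, the total is instead scaled from ``r45`` alone through its
    binomial share (``method='r45-scaled'``).  When both channels are
    below detection the total is 0 and flagged.
    """
    f = atom_fraction(pool)
    _check_fraction(f)
    for name, value in (("r45", r45), ("r46", r46)):
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")

    if r45_below_detection and r46_below_detection:
        return IsotopologueRates(0.0, 0.0, 0.0, below_detection=True)

    if r46_below_detection:
        # fall back on the singly labeled channel: total = r45 / p45
        _, p45, _ = pairing_probabilities(f)
        total = max(r45, 0.0) / p45
        p44, _, p46 = pairing_probabilities(f)
        return IsotopologueRates(
            total * p44, max(r45, 0.0), total * p46, method="r45-scaled"
        )

    r45 = max(r45, 0.0) if not r45_below_detection else 0.0
    r44 = infer_mass44_rate(r46, pool)
    return IsotopologueRates(r44, r45, max(r46, 0.0))


def binomial_consistency(r45: float, r46: float, pool: PoolComposition) -> float:
    """Diagnostic ratio: observed r45/r46 over the binomial expectation.

    Returns ~1 under single-pool binomial production.  Deviations indicate
    e.g. hybrid formation across two pools; the value is reported for QC
    only and never used to alter rates.  Returns NaN when r46 is 0.
    """
    f = atom_fraction(pool)
    _check_fraction(f)
    if r46 <= 0:
        return float("nan")
    expected = 2.0 * (1.0 - f) / f
    return (r45 / r46) / expected
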