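"""Forward simulation of incubation and station tables with known truth.

The generator mirrors the inference model run in reverse: labeled products
accumulate linearly at ``true_rate * F``; N2O isotopologues accumulate at a
molecule rate split binomially in the substrate atom fraction, optionally
blended toward a two-pool ("hybrid") pairing in which one N atom comes from
the labeled pool and the other from an unlabeled partner pool.  Gaussian
noise (relative sd with an absolute floor) is applied and negative
concentrations are truncated at zero with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .isotope_model import PoolComposition, atom_fraction, pairing_probabilities
from .rate_estimation import (
    PRODUCT_ANALYTE,
    N2O_PROCESS,
    SUBSTRATE_SPECIES,
    IncubationSeries,
)

__all__ = [
    "Scenario",
    "simulate_incubation",
    "simulate_station_profile",
    "pairing_oracle",
    "hybrid_pairing_probabilities",
    "true_molecule_rate",
]

_LABELS = ("15NH4", "15NO2", "15NO3")

#: default pools chosen so the tracer is ~38/31/14 % of the final pool,
#: the study-wide mean enrichments of the three labeling designs
_DEFAULT_POOLS = {
    "NH4": (3.26, 2.0),
    "NO2": (4.45, 2.0),
    "NO3": (61.4, 10.0),
}

_DEFAULT_RATES = {
    "AO": 50.0,
    "NO": 30.0,
    "NR": 20.0,
    "N2O-NH4": 0.5,
    "N2O-NO2": 0.8,
    "N2O-NO3": 1.2,
}


@dataclass
class Scenario:
    """Ground-truth parameterization for the synthetic generator.

    ``true_rates`` are in nmol N L-1 d-1 for all six processes.  ``pools``
    maps species to ``(ambient_14n, tracer_15n)`` in umol L-1.  The noise
    model is ``sd = max(noise_rel * value, noise_floor)`` per observation.
    ``hybrid_fraction`` moves N2O pairing away from the single-pool
    binomial toward one-labeled-atom molecules.
    """

    true_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RATES)
    )
    pools: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_POOLS)
    )
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0)
    replicates: int = 3
    noise_rel: float = 0.05
    noise_floor: float = 1e-4
    noise_mode: str = "proportional"
    baseline_frac: float = 0.0
    hybrid_fraction: float = 0.0
    seed: int = 0
    station: str = "SYN1"
    depth_m: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_mode not in ("proportional", "uniform"):
            raise ValueError("noise_mode must be 'proportional' or 'uniform'")
        if self.baseline_frac < 0:
            raise ValueError("baseline_frac must be >= 0")
        if not 0.0 <= self.hybrid_fraction <= 1.0:
            raise ValueError("hybrid_fraction must lie in [0, 1]")
        if self.noise_rel < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        if len(self.timepoints_h) < 2:
            raise ValueError("need >= 2 timepoints")
        for rate in self.true_rates.values():
            if rate < 0:
                raise ValueError("true rates must be >= 0")

    def pool(self, species: str) -> PoolComposition:
        ambient, tracer = self.pools[species]
        return PoolComposition(ambient, tracer, species)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints_h"] = list(self.timepoints_h)
        d["pools"] = {k: list(v) for k, v in self.pools.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if "timepoints_h" in d:
            d["timepoints_h"] = tuple(float(t) for t in d["timepoints_h"])
        if "pools" in d:
            d["pools"] = {k: tuple(v) for k, v in d["pools"].items()}
        return cls(**d)


def hybrid_pairing_probabilities(
    f: float, hybrid_fraction: float
) -> tuple[float, float, float]:
    """Isotopologue shares blended between single-pool and two-pool pairing.

    The two-pool (hybrid) component pairs one atom from the labeled pool
    (P(15N) = F) with one from an unlabeled partner pool (P(15N) = 0):
    shares (1-F, F, 0).
    """
    p44, p45, p46 = pairing_probabilities(f)
    h = hybrid_fraction
    return (
        (1 - h) * p44 + h * (1 - f),
        (1 - h) * p45 + h * f,
        (1 - h) * p46,
    )


def true_molecule_rate(rate_n: float, hybrid_fraction: float) -> float:
    """Molecule production rate delivering ``rate_n`` nmol labeled-pool N.

    Binomial molecules carry 2 N atoms from the labeled pool, hybrid
    molecules carry 1, so R_molec = R_N / (2 - h).
    """
    return rate_n / (2.0 - hybrid_fraction)


def _noisy(
    clean_signal: np.ndarray, rng: np.random.Generator, scenario: Scenario
) -> tuple[np.ndarray, int]:
    """Apply the scenario noise model and nonnegativity truncation.

    ``proportional``: sd = max(noise_rel * value, noise_floor) per point.
    ``uniform``: one sd for the whole course, noise_rel times the signal
    amplitude (the regime in which the OLS fit is exactly calibrated).
    A baseline of ``baseline_frac`` times the amplitude is added before
    noising, standing in for pre-existing labeled background/carryover.
    """
    amplitude = float(clean_signal.max() - clean_signal.min())
    values = clean_signal + scenario.baseline_frac * amplitude
    if scenario.noise_mode == "proportional":
        sd = np.maximum(scenario.noise_rel * values, scenario.noise_floor)
    else:
        sd = max(scenario.noise_rel * amplitude, scenario.noise_floor)
    noisy = values + rng.normal(0.0, 1.0, size=values.shape) * sd
    truncated = int(np.sum(noisy < 0))
    return np.maximum(noisy, 0.0), truncated


def simulate_incubation(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> dict[str, IncubationSeries]:
    """Generate all six labeled incubation experiments for a scenario.

    Returns a dict keyed by process name (``AO`` ... ``N2O-NO3``).  Each
    transformation series holds its 15N product analyte; each N2O series
    holds the 45/46 isotopologue channels.  Concentrations are nmol L-1.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    t_grid = np.repeat(
        np.asarray(scenario.timepoints_h, dtype=float), scenario.replicates
    )
    t_days = t_grid / 24.0
    out: dict[str, IncubationSeries] = {}

    for label in _LABELS:
        species = SUBSTRATE_SPECIES[label]
        pool = scenario.pool(species)
        f = atom_fraction(pool)
        meta = dict(
            pools={species: pool},
            station=scenario.station,
            depth_m=scenario.depth_m,
        )

        process, analyte = PRODUCT_ANALYTE[label]
        true_rate = scenario.true_rates.get(process, 0.0)
        clean = true_rate * f * t_days
        noisy, n_trunc = _noisy(clean, rng, scenario)
        series = IncubationSeries(label, {analyte: (t_grid.copy(), noisy)}, **meta)
        series.truncated_points = n_trunc
        out[process] = series

        n2o_process = N2O_PROCESS[label]
        rate_n = scenario.true_rates.get(n2o_process, 0.0)
        r_molec = true_molecule_rate(rate_n, scenario.hybrid_fraction)
        _, p45, p46 = hybrid_pairing_probabilities(f, scenario.hybrid_fraction)
        c45 = r_molec * p45 * t_days
        c46 = r_molec * p46 * t_days
        n45, trunc45 = _noisy(c45, rng, scenario)
        n46, trunc46 = _noisy(c46, rng, scenario)
        n2o_series = IncubationSeries(
            label,
            {"45N2O": (t_grid.copy(), n45), "46N2O": (t_grid.copy(), n46)},
            **{**meta, "pools": {species: pool}},
        )
        n2o_series.truncated_points = trunc45 + trunc46
        out[n2o_process] = n2o_series

    return out


def simulate_station_profile(
    n_stations: int = 5,
    depths: Iterable[float] = (2.0, 10.0, 20.0),
    seed: int = 0,
    temperature_range: tuple[float, float] = (10.0, 30.0),
    salinity_range: tuple[float, float] = (0.0, 35.0),
    do_range_umol: tuple[float, float] = (16.0, 300.0),
    n2o_range_nmol: tuple[float, float] = (6.0, 60.0),
    wind_range: tuple[float, float] = (2.0, 10.0),
    n2o_rate_range: tuple[float, float] = (0.1, 10.0),
    x_air_ppb: float = 332.0,
) -> pd.DataFrame:
    """Draw a station table spanning configured hydrographic gradients.

    Every depth row carries hydrography, DO, N2O and a volumetric N2O
    production rate; the shallowest row per station carries wind speed and
    the atmospheric mixing ratio for flux computation.
    """
    rng = np.random.default_rng(seed)
    depths = sorted(depths)
    rows = []
    for i in range(n_stations):
        name = f"SYN{i + 1}"
        wind = rng.uniform(*wind_range)
        for j, depth in enumerate(depths):
            rows.append(
                {
                    "station": name,
                    "depth_m": depth,
                    "temperature_c": rng.uniform(*temperature_range),
                    "salinity_psu": rng.uniform(*salinity_range),
                    "do_umol": rng.uniform(*do_range_umol),
                    "n2o_nmol": rng.uniform(*n2o_range_nmol),
                    "n2o_rate_nmol_n_d": rng.uniform(*n2o_rate_range),
                    "wind_u10_ms": wind if j == 0 else np.nan,
                    "x_air_ppb": x_air_ppb if j == 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pairing_oracle(
    f: float, n_molecules: int, seed: int = 0
) -> tuple[float, float, float]:
    """Brute-force pairing check: empirical isotopologue frequencies.

    Simulates each molecule as two independent atoms with P(15N) = ``f``
    and counts mass 44/45/46 outcomes.  Independent of
    :func:`~n2otrace.isotope_model.pairing_probabilities`.
    """
    if n_molecules < 1:
        raise ValueError("need >= 1 molecule")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    heavy = (rng.random((n_molecules, 2)) < f).sum(axis=1)
    counts = np.bincount(heavy, minlength=3)
    return tuple(counts / n_molecules)  # type: ignore[return-value]
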