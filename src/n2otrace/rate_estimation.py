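"""Rate estimation from replicated time-course incubations.

Rates are the OLS slopes of labeled-product accumulation versus time,
pooling replicates as independent points, divided by the 15N atom fraction
of the labeled substrate pool (the tracer dilution factor).  N2O production
additionally runs the isotopologue inference in :mod:`~n2otrace.isotope_model`.

Times are hours in, rates are per day out (factor of exactly 24).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .isotope_model import (
    IsotopologueRates,
    PoolComposition,
    atom_fraction,
    total_n2o_rate,
)

__all__ = [
    "IncubationSeries",
    "RateEstimate",
    "InsufficientDesignError",
    "HOURS_PER_DAY",
    "PROCESSES",
    "PRODUCT_ANALYTE",
    "N2O_PROCESS",
    "fit_timecourse",
    "transformation_rate",
    "n2o_production_rate",
    "station_rate_table",
]

HOURS_PER_DAY = 24.0

#: the six processes, in reporting order
PROCESSES = ("AO", "NO", "NR", "N2O-NH4", "N2O-NO2", "N2O-NO3")

#: substrate label -> (transformation process, product analyte measured)
PRODUCT_ANALYTE: Mapping[str, tuple[str, str]] = {
    "15NH4": ("AO", "15NO2"),
    "15NO2": ("NO", "15NO3"),
    "15NO3": ("NR", "15NO2"),
}

#: substrate label -> N2O production process
N2O_PROCESS: Mapping[str, str] = {
    "15NH4": "N2O-NH4",
    "15NO2": "N2O-NO2",
    "15NO3": "N2O-NO3",
}

SUBSTRATE_SPECIES = {"15NH4": "NH4", "15NO2": "NO2", "15NO3": "NO3"}


class InsufficientDesignError(ValueError):
    """Raised when a time course cannot support a slope fit."""


@dataclass
class IncubationSeries:
    """One labeled-substrate incubation experiment.

    ``data`` maps analyte name (``15NO2``, ``15NO3``, ``45N2O``, ``46N2O``)
    to a pair of equal-length arrays ``(time_h, concentration)`` holding all
    replicate observations in long form.  ``pools`` maps species to the t0
    :class:`PoolComposition` (at minimum the labeled substrate's own pool).
    """

    substrate_label: str
    data: dict[str, tuple[np.ndarray, np.ndarray]]
    pools: dict[str, PoolComposition]
    station: str = ""
    depth_m: float = 0.0
    size_fraction: str = ""
    enrichment_factor: float = 1.0
    units: str = "nmol N L-1 d-1"

    def __post_init__(self) -> None:
        if self.substrate_label not in PRODUCT_ANALYTE:
            raise ValueError(f"unknown substrate_label {self.substrate_label!r}")
        for analyte, (t, y) in self.data.items():
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if t.shape != y.shape or t.ndim != 1:
                raise ValueError(f"{analyte}: time and value arrays must match 1-D")
            if np.any(t < 0):
                raise ValueError(f"{analyte}: negative times")
            if np.any(y < 0):
                raise ValueError(f"{analyte}: negative concentrations")
            self.data[analyte] = (t, y)

    @property
    def substrate_pool(self) -> PoolComposition:
        return self.pools[SUBSTRATE_SPECIES[self.substrate_label]]

    def atom_fraction(self) -> float:
        return atom_fraction(self.substrate_pool)


@dataclass
class RateEstimate:
    """A rate with its standard error and detection handling.

    ``value`` is 0 when ``below_detection`` is set, but ``se`` is retained
    so the non-detection can still enter propagated uncertainties.
    """

    value: float
    se: float
    p_slope: float
    process: str
    below_detection: bool = False
    n_points: int = 0
    units: str = "nmol N L-1 d-1"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")


def fit_timecourse(
    series: IncubationSeries, analyte: str
) -> tuple[float, float, float]:
    """OLS slope of concentration vs time for one analyte, per day.

    Replicates are pooled as independent points.  Returns
    ``(slope, se, p)`` where ``p`` is the two-sided p-value for slope = 0.
    """
    if analyte not in series.data:
        raise KeyError(f"analyte {analyte!r} not present in series")
    t, y = series.data[analyte]
    if np.unique(t).size < 2:
        raise InsufficientDesignError(
            f"{analyte}: need >= 2 distinct timepoints, got {np.unique(t).size}"
        )
    res = stats.linregress(t, y)
    slope = res.slope * HOURS_PER_DAY
    se = res.stderr * HOURS_PER_DAY
    p = res.pvalue
    if math.isnan(p):  # exact fit with 0 residual df upstream of scipy
        p = 0.0 if slope != 0 else 1.0
    return slope, se, p


def transformation_rate(
    series: IncubationSeries, alpha: float = 0.05
) -> RateEstimate:
    """Gross N-transformation rate from a 15N-product time course.

    rate = slope / F, where F is the substrate 15N atom fraction.  A slope
    whose p-value is >= ``alpha`` is reported as 0 with the below-detection
    flag (its scaled se is retained).  Significant negative slopes are kept
    negative and annotated, not zeroed.
    """
    process, analyte = PRODUCT_ANALYTE[series.substrate_label]
    if analyte not in series.data:
        raise ValueError(
            f"series labeled {series.substrate_label} lacks product analyte "
            f"{analyte!r} (configuration error)"
        )
    slope, se, p = fit_timecourse(series, analyte)
    f = series.atom_fraction()
    value = slope / f
    se_scaled = se / f
    n = series.data[analyte][0].size
    if p >= alpha:
        return RateEstimate(
            0.0, se_scaled, p, process, below_detection=True, n_points=n,
            units=series.units,
        )
    notes = ""
    if value < 0:
        notes = "consumption-dominated: significant negative slope"
        warnings.warn(f"{process}: {notes}", stacklevel=2)
    return RateEstimate(
        value, se_scaled, p, process, n_points=n, units=series.units, notes=notes
    )


def n2o_production_rate(
    series: IncubationSeries, alpha: float = 0.05
) -> tuple[RateEstimate, IsotopologueRates]:
    """Gross N2O production rate from 45/46 isotopologue time courses.

    Fits each isotopologue channel independently; channels with
    p >= ``alpha`` or negative slopes are treated as below detection.
    The total combines measured r45, r46 and the inferred r44, reported in
    N units (2 x molecule rate).  The first-order propagated se is
    ``se_tot^2 = se45^2 + (1 + ((1-F)/F)^2)^2 * se46^2`` (molecule units).
    """
    for analyte in ("45N2O", "46N2O"):
        if analyte not in series.data:
            raise ValueError(f"series lacks isotopologue channel {analyte!r}")
    s45, se45, p45 = fit_timecourse(series, "45N2O")
    s46, se46, p46 = fit_timecourse(series, "46N2O")
    bd45 = p45 >= alpha or s45 < 0
    bd46 = p46 >= alpha or s46 < 0

    pool = series.substrate_pool
    f = series.atom_fraction()
    iso = total_n2o_rate(
        max(s45, 0.0),
        max(s46, 0.0),
        pool,
        r45_below_detection=bd45,
        r46_below_detection=bd46,
    )
    ratio2 = ((1.0 - f) / f) ** 2
    se_mol = math.sqrt(se45**2 + (1.0 + ratio2) ** 2 * se46**2)
    process = N2O_PROCESS[series.substrate_label]
    n = series.data["45N2O"][0].size
    est = RateEstimate(
        iso.r_total_n,
        2.0 * se_mol,
        min(p45, p46),
        process,
        below_detection=iso.below_detection,
        n_points=n,
        units=series.units,
        notes=iso.method if iso.method != "r46-inferred" else "",
    )
    return est, iso


def station_rate_table(estimates: list[RateEstimate]) -> pd.DataFrame:
    """Assemble per-station rate estimates into one row per process.

    Processes not supplied appear with ``present = False`` and NaN values
    (absent, never zero).  Duplicate processes are an error.
    """
    seen: dict[str, RateEstimate] = {}
    for est in estimates:
        if est.process in seen:
            raise ValueError(f"duplicate process entry {est.process!r}")
        if est.process not in PROCESSES:
            raise ValueError(f"unknown process {est.process!r}")
        seen[est.process] = est
    rows = []
    for process in PROCESSES:
        est = seen.get(process)
        if est is None:
            rows.append(
                {
                    "process": process,
                    "present": False,
                    "value": np.nan,
                    "se": np.nan,
                    "p_slope": np.nan,
                    "below_detection": False,
                    "n_points": 0,
                    "units": "",
                    "notes": "",
                }
            )
        else:
            rows.append(
                {
                    "process": process,
                    "present": True,
                    "value": est.value,
                    "se": est.se,
                    "p_slope": est.p_slope,
                    "below_detection": est.below_detection,
                    "n_points": est.n_points,
                    "units": est.units,
                    "notes": est.notes,
                }
            )
    table = pd.DataFrame(rows)
    if not estimates:
        table = table.iloc[0:0]
    return table
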