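"""Derived statistics: yields, source fractions, size spectra, screens.

Ratio uncertainties use first-order (delta-method) propagation assuming
independent errors; a Monte-Carlo mode is provided for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rate_estimation import RateEstimate

__all__ = [
    "SizeFractionSet",
    "ProfileRecord",
    "FractionalContributions",
    "n2o_yield",
    "fractional_contributions",
    "pn_normalized_rates",
    "nir_amoa_ratio",
    "pearson_screen",
    "compare_rates_ttest",
    "depth_integrated_ratio",
]

_GENE_KEYS = ("amoA_archaeal", "amoA_bacterial", "nirS", "nirK")


@dataclass
class SizeFractionSet:
    """Rates, particle mass and gene copies for one size class at a station."""

    size_class: str
    rates: dict[str, RateEstimate]
    pn_mass: float  # umol N L-1
    tsm: float = float("nan")  # mg L-1
    gene_copies: dict[str, float] = field(default_factory=dict)
    enrichment_factor: float = 1.0
    station: str = ""

    def __post_init__(self) -> None:
        for key, copies in self.gene_copies.items():
            if key not in _GENE_KEYS:
                raise ValueError(f"unknown gene key {key!r}")
            if copies < 0:
                raise ValueError(f"gene copies must be >= 0 ({key})")


@dataclass(frozen=True)
class ProfileRecord:
    """Volumetric N2O production at one depth."""

    depth: float  # m
    rate_total_n2o: float  # nmol N L-1 d-1

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def n2o_yield(
    rate_n2o: RateEstimate, rate_no2_production: RateEstimate
) -> tuple[float, float] | None:
    """N2O yield: percent N2O-N produced per NO2--N produced.

    The denominator is the NO2--producing transformation paired with the
    N2O pathway (ammonia oxidation or nitrate reduction).  Returns
    ``(yield_pct, se_pct)`` with first-order ratio propagation, or ``None``
    when the denominator is nonpositive or below detection (undefined,
    never reported as 0).
    """
    b = rate_no2_production.value
    if rate_no2_production.below_detection or b <= 0:
        return None
    a = rate_n2o.value
    y = 100.0 * a / b
    if a == 0.0:
        se = 100.0 * rate_n2o.se / b
    else:
        rel2 = (rate_n2o.se / a) ** 2 + (rate_no2_production.se / b) ** 2
        se = abs(y) * math.sqrt(rel2)
    return y, se


@dataclass(frozen=True)
class FractionalContributions:
    """Oxidative vs reductive share of total N2O production."""

    f_ao: float
    f_red: float
    sd_ao: float
    sd_red: float


def fractional_contributions(
    rate_table: pd.DataFrame, method: str = "delta", n_draws: int = 10_000,
    seed: int | None = None,
) -> FractionalContributions | None:
    """Fraction of N2O from ammonia oxidation vs the reductive pathways.

    Takes a :func:`~n2otrace.rate_estimation.station_rate_table` frame and
    uses its N2O-NH4, N2O-NO2 and N2O-NO3 rows.  ``f_ao + f_red = 1``
    exactly whenever defined.  ``method='delta'`` propagates the three
    (independent) rate errors first order; ``method='mc'`` draws Gaussian
    perturbations instead.  Returns ``None`` when the total is <= 0.
    """
    idx = rate_table.set_index("process")
    vals, ses = [], []
    for process in ("N2O-NH4", "N2O-NO2", "N2O-NO3"):
        row = idx.loc[process]
        if not row["present"]:
            raise ValueError(f"rate table lacks process {process}")
        vals.append(float(row["value"]))
        ses.append(float(row["se"]))
    a, b, c = vals
    sa, sb, sc_ = ses
    total = a + b + c
    if total <= 0:
        return None
    f_ao = a / total
    f_red = 1.0 - f_ao

    if method == "delta":
        # d f_ao/da = (b+c)/T^2 ; d f_ao/db = d f_ao/dc = -a/T^2
        var = ((b + c) ** 2 * sa**2 + a**2 * (sb**2 + sc_**2)) / total**4
        sd = math.sqrt(var)
    elif method == "mc":
        rng = np.random.default_rng(seed)
        draws = rng.normal(
            loc=[a, b, c], scale=[sa, sb, sc_], size=(n_draws, 3)
        )
        tot = draws.sum(axis=1)
        ok = tot > 0
        sd = float(np.std(draws[ok, 0] / tot[ok], ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return FractionalContributions(f_ao=f_ao, f_red=f_red, sd_ao=sd, sd_red=sd)


def pn_normalized_rates(fractions: list[SizeFractionSet]) -> pd.DataFrame:
    """Per-size-class rates normalized to particulate nitrogen content.

    Each rate is divided by the class's PN mass; units become
    nmol N (umol PN)-1 d-1.  Classes with PN <= 0 are skipped.
    """
    rows = []
    for sfs in fractions:
        if sfs.pn_mass <= 0:
            import warnings

            warnings.warn(
                f"size class {sfs.size_class}: nonpositive PN, skipped",
                stacklevel=2,
            )
            continue
        for process, est in sfs.rates.items():
            rows.append(
                {
                    "station": sfs.station,
                    "size_class": sfs.size_class,
                    "enrichment_factor": sfs.enrichment_factor,
                    "process": process,
                    "rate_per_pn": est.value / sfs.pn_mass,
                    "se_per_pn": est.se / sfs.pn_mass,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "station",
            "size_class",
            "enrichment_factor",
            "process",
            "rate_per_pn",
            "se_per_pn",
        ],
    )


def nir_amoa_ratio(fraction: SizeFractionSet) -> float:
    """Denitrifier-to-nitrifier gene copy ratio (nirS+nirK)/(amoA total).

    Returns NaN when total amoA copies are 0 (undefined).
    """
    g = fraction.gene_copies
    amoa = g.get("amoA_archaeal", 0.0) + g.get("amoA_bacterial", 0.0)
    nir = g.get("nirS", 0.0) + g.get("nirK", 0.0)
    if amoa <= 0:
        return float("nan")
    return nir / amoa


def pearson_screen(
    env_table: pd.DataFrame,
    rate_table: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 3,
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation screen between two column sets.

    Rows are aligned on index; missing values are handled pairwise-
    complete.  Returns ``(r, p, r_masked)`` frames indexed by rate column
    with env columns; ``r_masked`` blanks cells with p >= ``alpha`` (after
    optional Benjamini-Hochberg adjustment) or undefined correlations.
    """
    env_table, rate_table = env_table.align(rate_table, join="inner", axis=0)
    r = pd.DataFrame(index=rate_table.columns, columns=env_table.columns, dtype=float)
    p = pd.DataFrame(index=rate_table.columns, columns=env_table.columns, dtype=float)
    for rc in rate_table.columns:
        for ec in env_table.columns:
            x = env_table[ec].astype(float)
            y = rate_table[rc].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                r.loc[rc, ec] = np.nan
                p.loc[rc, ec] = np.nan
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r.loc[rc, ec] = res.statistic
            p.loc[rc, ec] = res.pvalue
    p_eff = p.copy()
    if bh_correction:
        flat = p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[ok] = stats.false_discovery_control(flat[ok])
        p_eff = pd.DataFrame(
            adj.reshape(p.shape), index=p.index, columns=p.columns
        )
    masked = r.where(p_eff < alpha)
    return r, p, masked


def compare_rates_ttest(bulk: np.ndarray, treated: np.ndarray) -> float:
    """Two-sided two-sample Student's t-test p-value (equal variance).

    Degenerate case: both groups with zero variance and equal means -> 1.
    """
    bulk = np.asarray(bulk, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if bulk.size < 2 or treated.size < 2:
        raise ValueError("need >= 2 replicates in each group")
    if np.ptp(bulk) == 0 and np.ptp(treated) == 0:
        return 1.0 if bulk[0] == treated[0] else 0.0
    return float(stats.ttest_ind(bulk, treated, equal_var=True).pvalue)


def depth_integrate(profile: list[ProfileRecord], depth_limit: float) -> float:
    """Trapezoidal depth integral of volumetric rate, umol N m-2 d-1.

    The shallowest rate is extended to the surface (0 m) and the deepest
    to ``depth_limit``.  1 nmol L-1 d-1 over 1 m equals 1 umol m-2 d-1,
    so the numeric conversion factor is unity.
    """
    if len(profile) < 2:
        raise ValueError("need >= 2 depths to integrate")
    depths = np.array([p.depth for p in profile], dtype=float)
    rates = np.array([p.rate_total_n2o for p in profile], dtype=float)
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")
    if depth_limit < depths[-1]:
        raise ValueError("depth_limit shallower than deepest record")
    z = np.concatenate(([0.0], depths, [depth_limit]))
    r = np.concatenate(([rates[0]], rates, [rates[-1]]))
    return float(np.trapezoid(r, z))


def depth_integrated_ratio(
    profile: list[ProfileRecord], flux: float, depth_limit: float
) -> float:
    """Depth-integrated water-column N2O production as a percent of flux.

    ``flux`` is the air-sea N2O flux in umol m-2 d-1; returns NaN when the
    flux is nonpositive (ratio undefined).
    """
    if flux <= 0:
        return float("nan")
    areal = depth_integrate(profile, depth_limit)
    return 100.0 * areal / flux
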