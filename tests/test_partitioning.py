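import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from n2otrace.partitioning import (
    ProfileRecord,
    SizeFractionSet,
    compare_rates_ttest,
    depth_integrate,
    depth_integrated_ratio,
    fractional_contributions,
    n2o_yield,
    nir_amoa_ratio,
    pearson_screen,
    pn_normalized_rates,
)
from n2otrace.rate_estimation import RateEstimate, station_rate_table


def est(process, value, se=0.0, below_detection=False):
    return RateEstimate(value, se, 0.001, process, below_detection=below_detection)


def n2o_table(a, b, c, sa=0.0, sb=0.0, sc_=0.0):
    return station_rate_table(
        [
            est("N2O-NH4", a, sa),
            est("N2O-NO2", b, sb),
            est("N2O-NO3", c, sc_),
        ]
    )


class TestN2OYield:
    def test_pre_median_scale(self):
        # 0.05 N2O-N per 100 NO2--N produced -> 0.05 %
        y, _ = n2o_yield(est("N2O-NH4", 0.05), est("AO", 100.0))
        assert y == pytest.approx(0.05)

    def test_zero_numerator(self):
        y, se = n2o_yield(est("N2O-NH4", 0.0, se=0.01), est("AO", 10.0))
        assert y == 0.0
        assert se > 0

    def test_undefined_for_flagged_denominator(self):
        assert n2o_yield(est("N2O-NO3", 1.0),
                         est("NR", 0.0, below_detection=True)) is None
        assert n2o_yield(est("N2O-NO3", 1.0), est("NR", 0.0)) is None

    def test_scale_invariance(self):
        y1, _ = n2o_yield(est("N2O-NO3", 0.2), est("NR", 100.0))
        y2, _ = n2o_yield(est("N2O-NO3", 2000.0), est("NR", 1_000_000.0))
        assert y1 == pytest.approx(y2)

    def test_round_trip_nr_yield(self):
        # generator-style construction at the reported NO3- reduction scale
        nr = 500.0
        target = 0.22
        y, se = n2o_yield(
            est("N2O-NO3", nr * target / 100.0, se=0.01), est("NR", nr, se=10.0)
        )
        assert y == pytest.approx(target, rel=1e-9)
        assert se > 0

    def test_delta_method_se(self):
        a, b, sa, sb = 1.0, 50.0, 0.1, 2.0
        _, se = n2o_yield(est("N2O-NH4", a, sa), est("AO", b, sb))
        expect = 100 * a / b * math.sqrt((sa / a) ** 2 + (sb / b) ** 2)
        assert se == pytest.approx(expect)


class TestFractionalContributions:
    def test_quarter(self):
        frac = fractional_contributions(n2o_table(1.0, 1.0, 2.0))
        assert frac.f_ao == pytest.approx(0.25)
        assert frac.f_red == pytest.approx(0.75)

    def test_pure_oxidative(self):
        frac = fractional_contributions(n2o_table(3.0, 0.0, 0.0))
        assert frac.f_ao == 1.0
        assert frac.f_red == 0.0

    def test_sum_is_exactly_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c = rng.uniform(0.01, 5.0, 3)
            frac = fractional_contributions(n2o_table(a, b, c))
            assert frac.f_ao + frac.f_red == 1.0
            assert 0.0 <= frac.f_ao <= 1.0

    def test_zero_total_undefined(self):
        assert fractional_contributions(n2o_table(0.0, 0.0, 0.0)) is None

    def test_delta_matches_monte_carlo(self):
        # relative errors < 20%: delta-method sd within 10% of MC sd
        table = n2o_table(2.0, 3.0, 5.0, sa=0.3, sb=0.45, sc_=0.6)
        delta = fractional_contributions(table, method="delta")
        mc = fractional_contributions(table, method="mc", n_draws=10_000, seed=1)
        assert delta.sd_ao == pytest.approx(mc.sd_ao, rel=0.10)

    def test_reductive_round_trip(self):
        # construction at the reported JLE median: reductive share 64%
        total = 10.0
        frac = fractional_contributions(
            n2o_table(0.36 * total, 0.3 * total, 0.34 * total,
                      sa=0.1, sb=0.1, sc_=0.1)
        )
        assert frac.f_red == pytest.approx(0.64)
        assert frac.sd_red > 0


class TestSizeSpectrum:
    def _sfs(self, size, rate_red, rate_ox, pn, genes=None, **kw):
        return SizeFractionSet(
            size_class=size,
            rates={
                "N2O-NH4": est("N2O-NH4", rate_ox, 0.01),
                "N2O-NO3": est("N2O-NO3", rate_red, 0.01),
            },
            pn_mass=pn,
            gene_copies=genes or {},
            **kw,
        )

    def test_simple_normalization(self):
        out = pn_normalized_rates([self._sfs("0.2-3", 10.0, 10.0, 5.0)])
        assert (out["rate_per_pn"] == 2.0).all()

    def test_doubling_pn_halves(self):
        a = pn_normalized_rates([self._sfs("0.2-3", 10.0, 10.0, 5.0)])
        b = pn_normalized_rates([self._sfs("0.2-3", 10.0, 10.0, 10.0)])
        assert (b["rate_per_pn"].to_numpy()
                == a["rate_per_pn"].to_numpy() / 2).all()

    def test_zero_pn_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = pn_normalized_rates(
                [self._sfs("0.2-3", 1.0, 1.0, 0.0), self._sfs("3-20", 1.0, 1.0, 2.0)]
            )
        assert set(out["size_class"]) == {"3-20"}

    def test_large_particles_rank_higher_per_pn(self):
        # large particles given 3x the per-PN reductive rate
        small = self._sfs("0.2-3", rate_red=2.0, rate_ox=2.0, pn=4.0)
        large = self._sfs("20-160", rate_red=1.5, rate_ox=0.5, pn=1.0)
        out = pn_normalized_rates([small, large])
        red = out[out["process"] == "N2O-NO3"].set_index("size_class")
        assert red.loc["20-160", "rate_per_pn"] > red.loc["0.2-3", "rate_per_pn"]

    def test_nir_amoa_unit_ratio(self):
        sfs = self._sfs("0.2-3", 1, 1, 1,
                        genes={"nirS": 60, "nirK": 40,
                               "amoA_archaeal": 50, "amoA_bacterial": 50})
        assert nir_amoa_ratio(sfs) == pytest.approx(1.0)

    def test_nir_amoa_no_nirk(self):
        sfs = self._sfs("0.2-3", 1, 1, 1,
                        genes={"nirS": 100, "amoA_archaeal": 25,
                               "amoA_bacterial": 25})
        assert nir_amoa_ratio(sfs) == pytest.approx(2.0)

    def test_nir_amoa_zero_amoa_undefined(self):
        sfs = self._sfs("0.2-3", 1, 1, 1, genes={"nirS": 100})
        assert math.isnan(nir_amoa_ratio(sfs))

    def test_ratio_correlates_with_reductive_fraction(self):
        # 12 synthetic fractions with nir:amoA rising along the spectrum
        rng = np.random.default_rng(11)
        ratios, f_reds = [], []
        for i in range(12):
            nir = 50.0 * (1 + i) + rng.normal(0, 5)
            amoa = 100.0
            sfs = self._sfs(
                f"class{i}", rate_red=0.2 + 0.1 * i, rate_ox=1.0, pn=1.0,
                genes={"nirS": max(nir, 1.0), "amoA_archaeal": amoa},
            )
            ratios.append(nir_amoa_ratio(sfs))
            red = sfs.rates["N2O-NO3"].value
            f_reds.append(red / (red + sfs.rates["N2O-NH4"].value))
        r, p = stats.pearsonr(ratios, f_reds)
        assert r > 0
        assert p < 0.05

    def test_negative_gene_copies_rejected(self):
        with pytest.raises(ValueError):
            self._sfs("0.2-3", 1, 1, 1, genes={"nirS": -5})


class TestPearsonScreen:
    def test_perfect_correlation(self):
        x = pd.DataFrame({"env": [1.0, 2.0, 3.0, 4.0, 5.0]})
        y = pd.DataFrame({"rate": [2.0, 4.0, 6.0, 8.0, 10.0]})
        r, p, masked = pearson_screen(x, y)
        assert r.loc["rate", "env"] == pytest.approx(1.0)
        assert p.loc["rate", "env"] < 0.05
        assert masked.loc["rate", "env"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = pd.DataFrame({"env": [1.0, 2.0, 3.0, 4.0]})
        y = pd.DataFrame({"rate": [4.0, 3.0, 2.0, 1.0]})
        r, _, _ = pearson_screen(x, y)
        assert r.loc["rate", "env"] == pytest.approx(-1.0)

    def test_constant_column_masked(self):
        x = pd.DataFrame({"env": [1.0, 1.0, 1.0, 1.0]})
        y = pd.DataFrame({"rate": [1.0, 2.0, 3.0, 4.0]})
        r, p, masked = pearson_screen(x, y)
        assert math.isnan(r.loc["rate", "env"])
        assert math.isnan(masked.loc["rate", "env"])

    def test_pairwise_complete(self):
        x = pd.DataFrame({"env": [1.0, 2.0, np.nan, 4.0, 5.0]})
        y = pd.DataFrame({"rate": [2.0, 4.0, 100.0, 8.0, 10.0]})
        r, _, _ = pearson_screen(x, y)
        assert r.loc["rate", "env"] == pytest.approx(1.0)

    def test_insufficient_pairs_masked(self):
        x = pd.DataFrame({"env": [1.0, 2.0, np.nan, np.nan]})
        y = pd.DataFrame({"rate": [2.0, 4.0, 1.0, 3.0]})
        r, _, _ = pearson_screen(x, y)
        assert math.isnan(r.loc["rate", "env"])

    def test_false_positive_rate(self):
        # independent Gaussians at n=48: per-cell rejection ~5%
        rng = np.random.default_rng(202)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = pd.DataFrame({"env": rng.normal(size=48)})
            y = pd.DataFrame({"rate": rng.normal(size=48)})
            _, p, _ = pearson_screen(x, y)
            if p.loc["rate", "env"] < 0.05:
                hits += 1
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(hits / n_sim - 0.05) < 2.576 * se


class TestTTest:
    def test_identical_groups(self):
        assert compare_rates_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_degenerate_equal(self):
        assert compare_rates_ttest([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_clearly_different(self):
        p = compare_rates_ttest([1.0, 1.1, 0.9], [5.0, 5.1, 4.9])
        # closed-form check: pooled sd 0.1, t = 4/(0.1*sqrt(2/3)), df=4
        t_stat = 4.0 / (0.1 * math.sqrt(2.0 / 3.0))
        expect = 2 * stats.t.sf(t_stat, df=4)
        assert p == pytest.approx(expect, rel=1e-9)
        assert p < 0.05

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            compare_rates_ttest([1.0], [2.0, 3.0])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(404)
        n_sim = 1000
        hits = sum(
            compare_rates_ttest(rng.normal(size=3), rng.normal(size=3)) < 0.05
            for _ in range(n_sim)
        )
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(hits / n_sim - 0.05) < 2.576 * se


class TestDepthIntegration:
    def test_uniform_rate(self):
        profile = [ProfileRecord(2.0, 1.0), ProfileRecord(8.0, 1.0)]
        assert depth_integrate(profile, 10.0) == pytest.approx(10.0)

    def test_ratio_100_when_equal(self):
        profile = [ProfileRecord(2.0, 1.0), ProfileRecord(8.0, 1.0)]
        assert depth_integrated_ratio(profile, 10.0, 10.0) == pytest.approx(100.0)

    def test_linear_profile_closed_form(self):
        # rate = 2 + 0.5 z between observed depths; ends extended flat
        profile = [ProfileRecord(0.0, 2.0), ProfileRecord(10.0, 7.0)]
        expect = (2.0 + 7.0) / 2 * 10.0  # trapezoid 0-10 m
        assert depth_integrate(profile, 10.0) == pytest.approx(expect)

    def test_surface_and_bottom_extension(self):
        profile = [ProfileRecord(5.0, 4.0), ProfileRecord(10.0, 2.0)]
        expect = 4.0 * 5.0 + (4.0 + 2.0) / 2 * 5.0 + 2.0 * 10.0
        assert depth_integrate(profile, 20.0) == pytest.approx(expect)

    def test_nonpositive_flux_undefined(self):
        profile = [ProfileRecord(2.0, 1.0), ProfileRecord(8.0, 1.0)]
        assert math.isnan(depth_integrated_ratio(profile, 0.0, 10.0))

    def test_seven_percent_construction(self):
        # profile + flux tuned so production is ~7% of the air-sea flux
        profile = [ProfileRecord(2.0, 0.14), ProfileRecord(10.0, 0.14)]
        flux = 20.0  # umol m-2 d-1
        ratio = depth_integrated_ratio(profile, flux, 10.0)
        assert ratio == pytest.approx(7.0)

    def test_bad_profiles(self):
        with pytest.raises(ValueError):
            depth_integrate([ProfileRecord(2.0, 1.0)], 10.0)
        with pytest.raises(ValueError):
            depth_integrate(
                [ProfileRecord(8.0, 1.0), ProfileRecord(2.0, 1.0)], 10.0
            )
        with pytest.raises(ValueError):
            depth_integrate(
                [ProfileRecord(2.0, 1.0), ProfileRecord(8.0, 1.0)], 5.0
            )
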