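"""Metabolite/parent ratio series and Mann-Kendall trend assessment."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kendalltau

import bcfkit as bk
from bcfkit.exceptions import InsufficientDataError
from bcfkit.metabolism import _s_statistic
from conftest import make_series


def enumerate_mk_pvalues(x):
    """Brute-force oracle: exact tail probabilities over all orderings."""
    x = np.asarray(x, float)
    s_obs = _s_statistic(x)
    all_s = [_s_statistic(np.asarray(p)) for p in permutations(x)]
    total = len(all_s)
    if s_obs >= 0:
        p_one = sum(1 for s in all_s if s >= s_obs) / total
    else:
        p_one = sum(1 for s in all_s if s <= s_obs) / total
    p_two = sum(1 for s in all_s if abs(s) >= abs(s_obs)) / total
    return p_one, p_two


class TestMannKendall:
    def test_monotone_published_ratio_sequence(self):
        # norfluoxetine/fluoxetine ratios at the high exposure level
        r = bk.mann_kendall([0.24, 0.30, 0.74, 0.92])
        assert r.tau == 1.0
        assert r.direction == "increasing"
        assert r.p_one_sided == pytest.approx(1 / 24)
        assert r.p_two_sided == pytest.approx(1 / 12)

    def test_non_monotone_published_sequence(self):
        # desmethylcitalopram/citalopram: rises through 24 h, then falls
        r = bk.mann_kendall([0.47, 0.78, 0.15, 0.26])
        assert abs(r.tau) < 1
        assert r.direction == "none"

    def test_constant_sequence_degenerate(self):
        r = bk.mann_kendall([0.5, 0.5, 0.5, 0.5])
        assert r.tau == 0.0 and r.s == 0 and r.direction == "none"
        assert r.p_two_sided == 1.0

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            bk.mann_kendall([1.0, 2.0])

    @given(x=st.lists(st.floats(0.01, 10, allow_nan=False), min_size=4, max_size=4,
                      unique=True))
    def test_exact_p_matches_enumeration_n4(self, x):
        r = bk.mann_kendall(x)
        p_one, p_two = enumerate_mk_pvalues(x)
        assert r.p_one_sided == pytest.approx(p_one)
        assert r.p_two_sided == pytest.approx(p_two)

    @given(x=st.lists(st.sampled_from([0.1, 0.2, 0.3]), min_size=4, max_size=6))
    def test_exact_p_with_ties_matches_enumeration(self, x):
        if len(set(x)) == 1:
            return  # degenerate case checked separately
        r = bk.mann_kendall(x)
        p_one, p_two = enumerate_mk_pvalues(x)
        assert r.p_one_sided == pytest.approx(p_one)
        assert r.p_two_sided == pytest.approx(p_two)

    @given(x=st.lists(st.floats(0.01, 10), min_size=5, max_size=7, unique=True))
    def test_tau_and_exact_p_agree_with_reference_implementation(self, x):
        r = bk.mann_kendall(x)
        tau_ref, p_ref = kendalltau(np.arange(len(x)), x, method="exact")
        assert r.tau == pytest.approx(tau_ref)
        assert r.p_two_sided == pytest.approx(p_ref)


class TestRatioSeries:
    def test_simple_ratios(self):
        parent = make_series("flx", "organism", [6.0, 24.0], [100.0, 200.0])
        met = make_series("nflx", "organism", [6.0, 24.0], [100.0, 0.0])
        rs = bk.ratio_series(parent, met)
        assert list(rs.defined_ratios) == pytest.approx([1.0, 0.0])

    def test_censored_parent_time_flagged_not_fabricated(self):
        parent = make_series("flx", "organism", [6.0, 24.0], [3.0, 200.0],
                             censoring=["below_lod", "none"])
        met = make_series("nflx", "organism", [6.0, 24.0], [50.0, 100.0])
        rs = bk.ratio_series(parent, met)
        row6 = rs.data[rs.data["time_h"] == 6.0].iloc[0]
        assert not row6["defined"] and np.isnan(row6["ratio"])
        assert any("undefined" in n for n in rs.notes)

    def test_disjoint_times_omitted_with_note(self):
        parent = make_series("flx", "organism", [6.0, 24.0, 45.0], [10, 20, 30])
        met = make_series("nflx", "organism", [6.0, 24.0], [1.0, 2.0])
        rs = bk.ratio_series(parent, met)
        assert list(rs.data["time_h"]) == [6.0, 24.0]
        assert any("omitted" in n for n in rs.notes)

    @given(lam=st.floats(0.01, 100))
    def test_scale_invariance(self, lam):
        t = [6.0, 24.0, 45.0, 48.0]
        p = np.array([100.0, 200.0, 300.0, 400.0])
        m = np.array([10.0, 50.0, 120.0, 200.0])
        r1 = bk.ratio_series(make_series("p", "organism", t, p),
                             make_series("m", "organism", t, m))
        r2 = bk.ratio_series(make_series("p", "organism", t, lam * p),
                             make_series("m", "organism", t, lam * m))
        assert r2.defined_ratios.to_numpy() == pytest.approx(
            r1.defined_ratios.to_numpy(), rel=1e-12)

    def test_generated_conversion_gives_rising_ratio(self):
        """With internal conversion on and slower metabolite elimination, the
        noise-free metabolite/parent ratio rises through the uptake phase."""
        cfg = bk.SimulationConfig(
            analytes=(bk.AnalyteKinetics("p", k1=5.0, k2=0.05, metabolite="m",
                                         conversion_k=0.02, metabolite_k2=0.02),),
            nominal_cw=80.0, noise_cv=0.0, water_decay=0.0, seed=0)
        ds = bk.generate_dataset(cfg)
        rs = bk.ratio_series(ds.body["p"], ds.body["m"])
        ratios = rs.defined_ratios.to_numpy()
        assert np.all(ratios > 0)
        assert np.all(np.diff(ratios) > 0)
        assert bk.ratio_trend(rs).direction == "increasing"

    def test_zero_conversion_never_yields_spurious_trend(self):
        cfg = bk.SimulationConfig(
            analytes=(bk.AnalyteKinetics("p", k1=5.0, k2=0.05, metabolite="m",
                                         conversion_k=0.0, metabolite_k2=0.02),),
            nominal_cw=80.0, seed=3)
        ds = bk.generate_dataset(cfg)
        assert "m" not in ds.body  # no conversion -> no metabolite series
        # force-simulate the metabolite anyway: identically zero, so any
        # assembled ratio series is flat and trendless
        from bcfkit.synthetic import true_metabolite_conc
        truth = true_metabolite_conc(cfg, cfg.analytes[0], [6.0, 24.0, 45.0, 48.0])
        assert np.all(truth == 0.0)


class TestRatioTrend:
    def test_requires_three_defined_ratios(self):
        parent = make_series("p", "organism", [6.0, 24.0], [100.0, 200.0])
        met = make_series("m", "organism", [6.0, 24.0], [10.0, 30.0])
        rs = bk.ratio_series(parent, met)
        with pytest.raises(InsufficientDataError):
            bk.ratio_trend(rs)

    def test_accepts_plain_sequence(self):
        assert bk.ratio_trend([0.14, 1.02, 0.91, 0.83]).direction == "none"
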