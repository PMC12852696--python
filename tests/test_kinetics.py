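"""Cumulative-EdU and FlashTag/EdU G1 kinetics."""

import numpy as np
import pandas as pd
import pytest

from neurotransit.kinetics import (
    compare_fractions_mw,
    cumulative_edu_curve,
    cycle_model_curve,
    fit_cycle_model,
    g1_exit_curve,
    g1_summary,
    pulse_s_fraction,
)
from neurotransit.records import validate_cells
from neurotransit.simulate import LineageParams, sample_cells, simulate_lineage


def _cells(rows):
    df = pd.DataFrame(rows)
    return validate_cells(df)


def _row(cid, emb="e1", cond="ctl", tp=1.0, **markers):
    base = dict(cell_id=cid, embryo_id=emb, condition=cond, timepoint_h=tp,
                gfp_pos=True, prb_pos=True, edu_pos=False, ft_pos=True, hucd_pos=False)
    base.update(markers)
    return base


class TestLabelingCurves:
    def test_saturated_denominator_gives_fraction_one(self):
        cells = _cells([_row(f"c{i}", edu_pos=True) for i in range(5)])
        curve = cumulative_edu_curve(cells)
        assert curve.summary["mean"].iloc[0] == 1.0

    def test_zero_denominator_embryo_is_absent(self):
        cells = _cells(
            [_row("c1", emb="e1", edu_pos=True), _row("c2", emb="e2", prb_pos=False)]
        )
        curve = cumulative_edu_curve(cells)
        assert set(curve.per_embryo["embryo_id"]) == {"e1"}

    def test_sd_undefined_with_single_embryo(self):
        cells = _cells([_row("c1"), _row("c2")])
        assert np.isnan(cumulative_edu_curve(cells).summary["sd"].iloc[0])


class TestSimulatedCumulativeKinetics:
    @pytest.fixture(scope="class")
    def async_sim(self):
        # fixed durations Tc=12 (G1=4, S=6, G2/M=2), ideal marker, all-PP
        params = LineageParams(
            n_founders=3000, horizon_h=8.0, m_g1_h=4.0, sigma_g1=1e-9,
            ts_h=6.0, tg2m_h=2.0, prb_lag_h=0.0, p_pp=1.0, p_pn=0.0, p_nn=0.0,
        )
        return simulate_lineage(params, seed=3)

    def test_initial_labeling_index_is_ts_over_tc(self, async_sim):
        s = sample_cells(async_sim, 0.05)
        frac = cumulative_edu_curve(s).summary["mean"].iloc[0]
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_saturation_by_tc_minus_ts(self, async_sim):
        s = sample_cells(async_sim, 6.0)
        frac = cumulative_edu_curve(s).summary["mean"].iloc[0]
        assert frac >= 0.99

    def test_one_hour_pulse_index(self):
        # growing population: exact index is (Ts+1)/(Tc+1), within 0.05 of
        # the static textbook (Ts+1)/Tc
        params = LineageParams(
            n_founders=6000, horizon_h=2.0, m_g1_h=4.0, sigma_g1=1e-9,
            ts_h=6.0, tg2m_h=2.0, prb_lag_h=0.0, p_pp=1.0, p_pn=0.0, p_nn=0.0,
            edu_intervals=((0.0, 1.0),),
        )
        sim = simulate_lineage(params, seed=4)
        s = sample_cells(sim, 1.0)
        summary, _ = pulse_s_fraction(s)
        frac = summary["mean"].iloc[0]
        assert frac == pytest.approx(7.0 / 13.0, abs=0.02)
        assert abs(frac - 7.0 / 12.0) < 0.06

    def test_shorter_cycle_raises_pulse_fraction(self):
        fracs = []
        for g1 in (6.0, 3.0):
            params = LineageParams(
                n_founders=3000, horizon_h=2.0, m_g1_h=g1, sigma_g1=1e-9,
                ts_h=6.0, tg2m_h=2.0, prb_lag_h=0.0, p_pp=1.0, p_pn=0.0, p_nn=0.0,
                edu_intervals=((0.0, 1.0),),
            )
            s = sample_cells(simulate_lineage(params, seed=5), 1.0)
            fracs.append(pulse_s_fraction(s)[0]["mean"].iloc[0])
        assert fracs[1] > fracs[0]


class TestCycleModelFit:
    def test_noiseless_recovery_within_one_percent(self):
        t = np.array([1, 4, 7, 10, 12, 14, 17], dtype=float)
        fit = fit_cycle_model(t, cycle_model_curve(t, 12, 6, 1.0))
        assert abs(fit.Tc_h - 12) / 12 < 0.01
        assert abs(fit.Ts_h - 6) / 6 < 0.01

    def test_growth_fraction_recovered(self):
        t = np.array([1, 4, 7, 10, 12, 14, 17], dtype=float)
        fit = fit_cycle_model(t, cycle_model_curve(t, 12, 6, 0.8))
        assert fit.growth_fraction == pytest.approx(0.8, abs=0.02)

    def test_constant_saturated_curve_flags_degenerate(self):
        t = np.array([0.5, 2, 4, 8], dtype=float)
        fit = fit_cycle_model(t, np.ones(4))
        assert fit.degenerate

    def test_invariant_to_timepoint_reordering(self):
        t = np.array([1, 4, 7, 10, 12, 14, 17], dtype=float)
        f = cycle_model_curve(t, 12, 6, 0.9)
        fit1 = fit_cycle_model(t, f)
        perm = np.array([3, 0, 6, 2, 5, 1, 4])
        fit2 = fit_cycle_model(t[perm], f[perm])
        assert fit1.Tc_h == pytest.approx(fit2.Tc_h)
        assert fit1.Ts_h == pytest.approx(fit2.Ts_h)

    def test_too_few_timepoints_raise(self):
        with pytest.raises(ValueError):
            fit_cycle_model([1, 2, 3], [0.1, 0.2, 0.3])


class TestG1Summary:
    def test_linear_interpolation_of_median(self):
        g = g1_summary([4.0, 8.0], [0.0, 1.0])
        assert g.median_g1_h == pytest.approx(6.0)

    def test_plateau_undefined_when_never_reached(self):
        g = g1_summary([2, 4, 6], [0.1, 0.3, 0.6], eps=0.0)
        assert np.isnan(g.plateau_time_h)
        assert "plateau_undefined" in g.flags

    def test_median_undefined_flagged(self):
        g = g1_summary([2, 4], [0.0, 0.2])
        assert np.isnan(g.median_g1_h)
        assert "median_undefined" in g.flags

    def test_isotonic_correction_makes_cdf_monotone(self):
        g = g1_summary([2, 4, 6, 8], [0.1, 0.35, 0.3, 0.9])
        assert (np.diff(g.cdf["fraction"]) >= -1e-12).all()


class TestG1ExitCurve:
    def test_no_cell_before_minimum_g1(self):
        params = LineageParams(
            n_founders=4000, horizon_h=3.0, m_g1_h=8.0, sigma_g1=0.25, ft_window_h=0.25
        )
        sim = simulate_lineage(params, seed=6)
        s = sample_cells(sim, 2.5)
        s = s[s["ft_pos"].astype(bool)]
        curve = g1_exit_curve(s)
        assert curve.summary["mean"].iloc[0] == pytest.approx(0.0, abs=0.01)

    def test_identical_g1_produces_step_at_g(self):
        params = LineageParams(
            n_founders=20000, horizon_h=7.0, m_g1_h=5.0, sigma_g1=1e-9, ft_window_h=0.25
        )
        sim = simulate_lineage(params, seed=7)
        fracs = []
        for t in (4.5, 5.5):
            s = sample_cells(sim, t)
            s = s[s["ft_pos"].astype(bool)]
            fracs.append(g1_exit_curve(s).summary["mean"].iloc[0])
        assert fracs[0] == pytest.approx(0.0, abs=0.01)   # just before G1 + window
        assert fracs[1] == pytest.approx(1.0, abs=0.01)   # just after


def test_compare_fractions_requires_two_embryos():
    cells = _cells(
        [_row("c1", emb="e1", cond="a"), _row("c2", emb="e1", cond="b"),
         _row("c3", emb="e2", cond="b")]
    )
    curve = cumulative_edu_curve(cells)
    with pytest.raises(ValueError):
        compare_fractions_mw(curve, "a", "b", 1.0)
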