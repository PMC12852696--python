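"""Sister-pair identification, classification and comparisons."""

import numpy as np
import pandas as pd
import pytest

from neurotransit.pairs import (
    SisterPair,
    chi_square_2x3,
    classify_pairs,
    identify_pairs,
    neuron_fraction_in_cohort,
    prb_plateau_check,
)
from neurotransit.records import validate_cells
from neurotransit.simulate import LineageParams, sample_pair_cells, simulate_lineage


def _cells(rows):
    return validate_cells(pd.DataFrame(rows))


def _cell(cid, x=0.0, y=0.0, z=0.0, gfp=100.0, ft=100.0, prb=True, hucd=False, emb="e1"):
    return dict(
        cell_id=cid, embryo_id=emb, condition="ctl", timepoint_h=6.0,
        gfp_pos=True, prb_pos=prb, edu_pos=False, ft_pos=True, hucd_pos=hucd,
        x_um=x, y_um=y, z_um=z, gfp_int=gfp, ft_int=ft,
    )


class TestIdentifyPairs:
    def test_two_isolated_identical_cells_pair(self):
        cells = _cells([_cell("a"), _cell("b", x=10.0)])
        pairs, unmatched = identify_pairs(cells)
        assert len(pairs) == 1 and not unmatched
        assert (pairs[0].cell_a, pairs[0].cell_b) == ("a", "b")

    def test_distant_cells_do_not_pair(self):
        cells = _cells([_cell("a"), _cell("b", x=100.0)])
        pairs, unmatched = identify_pairs(cells)
        assert not pairs and set(unmatched) == {"a", "b"}

    def test_dissimilar_intensity_rejected(self):
        cells = _cells([_cell("a", gfp=100.0), _cell("b", x=5.0, gfp=10.0)])
        pairs, _ = identify_pairs(cells)
        assert not pairs

    def test_three_equal_cells_form_one_pair_by_lexicographic_tie_break(self):
        # equilateral triangle, identical intensities -> equal scores
        h = 10.0 * np.sqrt(3) / 2
        cells = _cells(
            [_cell("c3", x=0.0), _cell("c1", x=10.0), _cell("c2", x=5.0, y=h)]
        )
        pairs, unmatched = identify_pairs(cells)
        assert len(pairs) == 1
        assert (pairs[0].cell_a, pairs[0].cell_b) == ("c1", "c2")
        assert unmatched == ["c3"]

    def test_simulated_pairing_precision_and_recall(self):
        params = LineageParams(
            n_founders=26000, horizon_h=7.0, tissue_width_um=10000.0,
            tissue_depth_um=250.0, m_g1_h=8.0, sigma_g1=0.6, ft_window_h=0.25,
        )
        sim = simulate_lineage(params, seed=2)
        cells, true_pairs = sample_pair_cells(sim, 6.0, contaminant_frac=0.2, seed=2)
        found, _ = identify_pairs(cells)
        fs = {(p.cell_a, p.cell_b) for p in found}
        tp = set(true_pairs)
        assert len(fs & tp) / len(fs) >= 0.95
        assert len(fs & tp) / len(tp) >= 0.90


class TestClassifyPairs:
    def _pair(self):
        return [SisterPair("a", "b", 1.0, 1.0, 5.0)]

    def test_mode_mapping(self):
        for pa, pb, mode in [(True, True, "PP"), (True, False, "PN"), (False, False, "NN")]:
            cells = _cells([_cell("a", prb=pa), _cell("b", x=5.0, prb=pb)])
            dist = classify_pairs(self._pair(), cells)
            assert getattr(dist, f"n_{mode}") == 1

    def test_symmetric_in_pair_order(self):
        cells = _cells([_cell("a", prb=False), _cell("b", x=5.0, prb=True)])
        d1 = classify_pairs([SisterPair("a", "b", 1, 1, 5)], cells)
        d2 = classify_pairs([SisterPair("b", "a", 1, 1, 5)], cells)
        assert d1.n_PN == d2.n_PN == 1

    def test_missing_marker_counts_undetermined(self):
        cells = _cells([_cell("a"), _cell("b", x=5.0, prb=None)])
        dist = classify_pairs(self._pair(), cells)
        assert dist.n_undetermined == 1
        assert dist.n_PP + dist.n_PN + dist.n_NN + dist.n_undetermined == 1

    def test_refuses_without_plateau_unless_forced(self):
        cells = _cells([_cell("a"), _cell("b", x=5.0)])
        with pytest.raises(ValueError):
            classify_pairs(self._pair(), cells, plateau_ok=False)
        dist = classify_pairs(self._pair(), cells, plateau_ok=False, force=True)
        assert dist.n_PP == 1

    def test_hucd_marker_inverts_mapping(self):
        cells = _cells([_cell("a", hucd=True), _cell("b", x=5.0, hucd=True)])
        dist = classify_pairs(self._pair(), cells, marker="hucd")
        assert dist.n_NN == 1


class TestPlateauCheck:
    def test_identical_distributions_stable_from_first(self):
        cells = _cells([_cell("a"), _cell("b", x=5.0)] )
        pairs = [SisterPair("a", "b", 1, 1, 5)]
        cohorts = {t: (pairs, cells) for t in (2.0, 4.0, 6.0)}
        rep = prb_plateau_check(cohorts, min_pairs=1)
        assert rep.stable_from_h == 2.0

    def test_simulated_all_pp_cohort_stabilizes_after_lag(self):
        params = LineageParams(
            n_founders=12000, horizon_h=9.0, tissue_width_um=6000.0, tissue_depth_um=200.0,
            p_pp=1.0, p_pn=0.0, p_nn=0.0, prb_lag_h=2.0, ft_window_h=0.25,
        )
        sim = simulate_lineage(params, seed=3)
        cohorts = {}
        for t in (1.0, 2.0, 3.0, 4.5, 6.0, 8.0):
            cells, tp = sample_pair_cells(sim, t, seed=3)
            cohorts[t] = ([SisterPair(a, b, 1, 1, 0) for a, b in tp], cells)
        rep = prb_plateau_check(cohorts)
        table = rep.table.set_index("timepoint_h")
        assert table.loc[1.0, "frac_2"] == 0.0
        assert table.loc[6.0, "frac_2"] == pytest.approx(1.0, abs=0.02)
        assert rep.stable_from_h is not None and rep.stable_from_h >= 2.0

    def test_too_few_timepoints_raise(self):
        with pytest.raises(ValueError):
            prb_plateau_check({1.0: ([], None), 2.0: ([], None)})


def test_mode_count_partition_invariant():
    cells = _cells(
        [_cell("a"), _cell("b", x=5.0), _cell("c", x=50.0, prb=None), _cell("d", x=55.0)]
    )
    pairs = [SisterPair("a", "b", 1, 1, 5), SisterPair("c", "d", 1, 1, 5)]
    dist = classify_pairs(pairs, cells)
    assert dist.n_PP + dist.n_PN + dist.n_NN + dist.n_undetermined == len(pairs)


class TestNeuronFraction:
    def test_zero_when_no_hucd(self):
        cells = _cells([_cell("a"), _cell("b", x=5.0)])
        per_embryo, _ = neuron_fraction_in_cohort(cells)
        assert per_embryo["fraction"].iloc[0] == 0.0

    def test_increasing_nn_probability_increases_neuron_fraction(self):
        fracs = []
        for p_nn in (0.1, 0.4, 0.7):
            params = LineageParams(
                n_founders=8000, horizon_h=21.0, p_pp=1.0 - p_nn - 0.2, p_pn=0.2,
                p_nn=p_nn, hucd_delay_h=9.0, ft_window_h=0.25,
            )
            sim = simulate_lineage(params, seed=8)
            from neurotransit.simulate import sample_cells

            s = sample_cells(sim, 20.0)
            s = s[s["ft_pos"].astype(bool)]
            per_embryo, _ = neuron_fraction_in_cohort(s)
            fracs.append(per_embryo["fraction"].mean())
        assert fracs[0] < fracs[1] < fracs[2]
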