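"""Contracts of the synthetic-data generators."""

import numpy as np
import pytest

from neurotransit.simulate import (
    CountsSimParams,
    LineageParams,
    StackSimParams,
    sample_cells,
    simulate_counts,
    simulate_image_stack,
    simulate_lineage,
)


class TestCountsGenerator:
    def test_same_seed_identical_different_seed_differs(self):
        p = CountsSimParams(n_cells=100, n_genes=120)
        a, _ = simulate_counts(p, seed=1)
        b, _ = simulate_counts(p, seed=1)
        c, _ = simulate_counts(p, seed=2)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_poisson_limit_variance_to_mean(self):
        p = CountsSimParams(
            n_cells=5000, n_genes=60, dispersion=0.0,
            program_fractions={"flat": 0.9}, include_signatures=False,
            contaminant_frac=0.0, lib_sigma=1e-9,
        )
        cm, truth = simulate_counts(p, seed=3)
        flat = truth.genes["program"] == "flat"
        counts = cm.counts[flat.to_numpy()]
        means = counts.mean(axis=1)
        ratio = counts.var(axis=1, ddof=1) / means
        assert np.all(np.abs(ratio[means > 2] - 1.0) < 0.08)

    def test_mid_peak_gene_is_unimodal_with_interior_mode(self):
        p = CountsSimParams(n_cells=3000, n_genes=150, contaminant_frac=0.0, shape_jitter=0.0)
        cm, truth = simulate_counts(p, seed=4)
        t = truth.cells["maturation"].to_numpy()
        mid_idx = np.flatnonzero((truth.genes["program"] == "mid").to_numpy())[:5]
        bins = np.clip((t * 10).astype(int), 0, 9)
        for gi in mid_idx:
            prof = np.array([cm.counts[gi][bins == b].mean() for b in range(10)])
            mode = int(np.argmax(prof))
            assert 2 <= mode <= 7

    def test_truth_tables_align_with_matrix(self):
        cm, truth = simulate_counts(CountsSimParams(n_cells=80, n_genes=120), seed=5)
        assert list(truth.cells.index) == list(cm.cell_ids)
        assert list(truth.genes.index) == list(cm.gene_ids)


class TestLineageGenerator:
    @pytest.fixture(scope="class")
    def sim(self):
        return simulate_lineage(LineageParams(n_founders=800, horizon_h=14.0), seed=1)

    def test_deterministic_per_seed(self):
        p = LineageParams(n_founders=200, horizon_h=10.0)
        a = simulate_lineage(p, seed=2).cells
        b = simulate_lineage(p, seed=2).cells
        assert a.equals(b)

    def test_lineage_conservation(self, sim):
        cells = sim.cells
        for t in (0.0, 5.0, 12.0):
            alive = ((cells["birth_h"] <= t) & (t < cells["division_h"])).sum()
            births = ((cells["birth_h"] <= t) & (cells["mother_id"] >= 0)).sum()
            divisions = (
                (cells["division_h"] <= t) & np.isfinite(cells["division_h"])
            ).sum()
            assert alive == 800 + births - divisions

    def test_every_daughter_has_mother_mode_and_sister(self, sim):
        daughters = sim.cells[sim.cells["mother_id"] >= 0]
        assert (daughters["mother_mode"].isin(["PP", "PN", "NN"])).all()
        assert (daughters["sister_id"] >= 0).all()

    def test_ft_only_from_divisions_inside_window(self, sim):
        cells = sim.cells.set_index("cell_id")
        w = sim.params.ft_window_h
        ft = cells[cells["ft"]]
        assert len(ft) > 0
        # founders are never labeled; first-generation labeled daughters were
        # born inside the window; later generations inherit from an ft mother
        assert (ft["mother_id"] >= 0).all()
        first_gen = ft[ft["generation"] == 1]
        assert ((first_gen["birth_h"] >= 0) & (first_gen["birth_h"] <= w)).all()
        later = ft[ft["generation"] > 1]
        if len(later):
            assert cells.loc[later["mother_id"], "ft"].all()
        # conversely, every unlabeled first-generation daughter was born
        # outside the window
        non_ft_g1 = cells[(~cells["ft"]) & (cells["generation"] == 1)]
        assert not ((non_ft_g1["birth_h"] >= 0) & (non_ft_g1["birth_h"] <= w)).any()

    def test_all_terminal_divisions_leave_no_cycling_ft_cells(self):
        params = LineageParams(n_founders=2000, horizon_h=7.0, p_pp=0.0, p_pn=0.0, p_nn=1.0)
        sim = simulate_lineage(params, seed=3)
        s = sample_cells(sim, 6.0)
        ft = s[s["ft_pos"].astype(bool)]
        assert len(ft) > 0
        assert not (ft["prb_pos"].fillna(False)).any()

    def test_knockdown_cdf_dominates_control_after_4p5(self):
        from neurotransit.kinetics import g1_exit_curve
        from neurotransit.simulate.lineage import control_g1_params, knockdown_g1_params
        import pandas as pd

        frames = []
        for prm, seed in ((control_g1_params(n_founders=12000, horizon_h=11.0), 1),
                          (knockdown_g1_params(n_founders=12000, horizon_h=11.0), 2)):
            sim = simulate_lineage(prm, seed=seed)
            for t in (4.5, 6.5, 8.5, 10.5):
                s = sample_cells(sim, t)
                s = s[s["ft_pos"].astype(bool)].copy()
                s["cell_id"] = s["cell_id"] + f"_{t}"
                frames.append(s)
        curve = g1_exit_curve(pd.concat(frames, ignore_index=True))
        ctl = curve.condition("control").set_index("timepoint_h")["mean"]
        kd = curve.condition("cdkn1c_sh").set_index("timepoint_h")["mean"]
        assert (kd >= ctl - 0.02).all()

    def test_neurons_never_divide(self, sim):
        neurons = sim.cells[sim.cells["is_neuron"]]
        assert np.isinf(neurons["division_h"]).all()


class TestStackGenerator:
    def test_zero_nuclei_gives_background_only(self):
        stack, truth = simulate_image_stack(StackSimParams(n_nuclei=0), seed=1)
        assert truth.empty
        # background + noise only: no pixel wildly above background scale
        assert stack.pixels.max() < 250.0

    def test_zero_tilt_alignment_is_identity_up_to_crop(self):
        from neurotransit.imaging import align_apical_surface

        p = StackSimParams(n_nuclei=5, surface_tilt_deg=0.0, poisson_noise=False, noise_gauss_sd=0.0)
        stack, _ = simulate_image_stack(p, seed=2)
        out = align_apical_surface(stack, stack.surface_line)
        row0 = int(round(p.surface_offset_px))
        assert np.allclose(out.pixels, stack.pixels[:, :, row0:, :], atol=1e-6)

    def test_deterministic_per_seed(self):
        a, _ = simulate_image_stack(StackSimParams(n_nuclei=10), seed=4)
        b, _ = simulate_image_stack(StackSimParams(n_nuclei=10), seed=4)
        assert np.array_equal(a.pixels, b.pixels)
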