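"""Agent-based neurogenesis lineage simulator.

Cells progress through G1 -> S -> G2/M and divide with mode probabilities
(p_PP, p_PN, p_NN); progenitor daughters re-enter G1 (duration drawn from a
lognormal), neuron daughters become postmitotic.  Labeling and markers:

* FlashTag marks the daughters of divisions occurring inside a short
  window after injection (default 0.3 h) and is inherited by all progeny;
* EdU is incorporated when a cell's S phase overlaps an exposure interval,
  and the label is inherited (DNA label);
* pRb is detectable on progenitors from a fixed early-G1 lag after birth
  (and always once S phase has begun), through the rest of the cycle;
  neurons are pRb-negative;
* HuC/D appears on neurons a fixed delay after their (terminal) birth.

Founders start asynchronously at a steady-state cycle position (uniform in
their own cycle).  No apoptosis and no cycle re-entry of neurons.  The
simulator emits per-cell ground truth next to every observable table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LineageParams",
    "LineageSim",
    "simulate_lineage",
    "sample_cells",
    "sample_pair_cells",
    "control_g1_params",
    "knockdown_g1_params",
]

INF = np.inf


@dataclass(frozen=True)
class LineageParams:
    n_founders: int = 2000
    n_embryos: int = 4
    horizon_h: float = 12.0
    condition: str = "control"
    # phase durations (h): G1 lognormal around its median, S and G2/M fixed.
    # An optional slow subpopulation (g1_long_frac) models neurogenic
    # progenitors with a much longer G1 alongside fast proliferative ones.
    m_g1_h: float = 8.0
    sigma_g1: float = 0.6
    g1_long_frac: float = 0.0
    m_g1_long_h: float = 16.0
    sigma_g1_long: float = 0.3
    ts_h: float = 6.0
    tg2m_h: float = 2.0
    # division-mode probabilities
    p_pp: float = 0.25
    p_pn: float = 0.50
    p_nn: float = 0.25
    # markers and labels
    prb_lag_h: float = 2.0
    hucd_delay_h: float = 9.0
    ft_window_h: float = 0.3
    edu_intervals: tuple[tuple[float, float], ...] = ((0.0, INF),)
    # tissue geometry / intensities
    tissue_width_um: float = 500.0
    tissue_depth_um: float = 60.0
    apical_y_um: float = 5.0          # divisions occur at the apical surface
    neuron_speed_um_h: float = 2.5    # basal translocation speed of neurons
    neuron_migration_lag_h: float = 2.0
    sister_jitter_um: float = 3.0
    gfp_sister_sigma: float = 0.10
    ft_sister_sigma: float = 0.08

    def __post_init__(self):
        if abs(self.p_pp + self.p_pn + self.p_nn - 1.0) > 1e-9:
            raise ValueError("division-mode probabilities must sum to 1")
        for d in (self.m_g1_h, self.ts_h, self.tg2m_h):
            if d <= 0:
                raise ValueError("phase durations must be > 0")


def control_g1_params(**overrides) -> LineageParams:
    """Calibrated control condition: mixed fast/slow G1, overall median 8 h.

    70% proliferative progenitors (G1 lognormal, median ~6.97 h, sigma 0.25)
    plus 30% neurogenic progenitors with a long G1 (median 16 h, sigma 0.3);
    the mixture's median is 8.0 h and ~31% of progenitors are still in G1
    at 10 h 30 after mitosis.
    """
    base = dict(
        condition="control",
        m_g1_h=6.9679,
        sigma_g1=0.25,
        g1_long_frac=0.30,
        m_g1_long_h=16.0,
        sigma_g1_long=0.30,
        ft_window_h=0.25,
    )
    base.update(overrides)
    return LineageParams(**base)


def knockdown_g1_params(**overrides) -> LineageParams:
    """Calibrated Cdkn1c-knockdown condition: short, sharp G1 (median 5.5 h)."""
    base = dict(
        condition="cdkn1c_sh",
        m_g1_h=5.5,
        sigma_g1=0.25,
        g1_long_frac=0.0,
        ft_window_h=0.25,
        p_pp=0.55,
        p_pn=0.35,
        p_nn=0.10,
    )
    base.update(overrides)
    return LineageParams(**base)


@dataclass
class LineageSim:
    params: LineageParams
    cells: pd.DataFrame  # one row per cell ever alive (founders + daughters)
    seed: int


def _own_edu_time(birth, g1, ts, is_neuron, intervals):
    """Earliest time the cell's own S phase overlaps an EdU exposure."""
    t = np.full(birth.shape, INF)
    s0 = birth + g1
    s1 = s0 + ts
    for e0, e1 in intervals:
        lo = np.maximum(s0, e0)
        hi = np.minimum(s1, e1)
        ok = (lo <= hi) & ~is_neuron
        t = np.where(ok, np.minimum(t, lo), t)
    return t


def simulate_lineage(params: LineageParams, seed: int = 0) -> LineageSim:
    p = params
    rng = np.random.default_rng(seed)

    def draw_g1(n):
        fast = np.exp(rng.normal(np.log(p.m_g1_h), p.sigma_g1, n))
        if p.g1_long_frac <= 0:
            return fast
        slow = np.exp(rng.normal(np.log(p.m_g1_long_h), p.sigma_g1_long, n))
        return np.where(rng.random(n) < p.g1_long_frac, slow, fast)

    # founders
    n = p.n_founders
    g1 = draw_g1(n)
    tc = g1 + p.ts_h + p.tg2m_h
    age0 = rng.uniform(0, tc)
    cols = {
        "cell_id": np.arange(n),
        "embryo_id": np.arange(n) % p.n_embryos,
        "mother_id": np.full(n, -1),
        "sister_id": np.full(n, -1),
        "birth_h": -age0,
        "g1_h": g1,
        "is_neuron": np.zeros(n, dtype=bool),
        "ft": np.zeros(n, dtype=bool),
        "edu_inherited_h": np.full(n, INF),
        "mother_mode": np.array([""] * n, dtype=object),
        "x_um": rng.uniform(0, p.tissue_width_um, n),
        "z_um": rng.uniform(0, p.tissue_depth_um, n),
        "y_prog_um": rng.uniform(5.0, 40.0, n),
        "gfp_int": rng.lognormal(np.log(500.0), 0.5, n),
        "ft_int": rng.lognormal(np.log(30.0), 0.4, n),
        "generation": np.zeros(n, dtype=int),
    }
    gen = pd.DataFrame(cols)
    all_gens = []
    next_id = n
    mode_names = np.array(["PP", "PN", "NN"], dtype=object)

    while len(gen):
        prog = ~gen["is_neuron"].to_numpy()
        div_t = np.where(prog, gen["birth_h"].to_numpy() + gen["g1_h"].to_numpy() + p.ts_h + p.tg2m_h, INF)
        gen = gen.assign(division_h=div_t)
        gen = gen.assign(
            edu_own_h=_own_edu_time(
                gen["birth_h"].to_numpy(),
                gen["g1_h"].to_numpy(),
                p.ts_h,
                gen["is_neuron"].to_numpy(),
                p.edu_intervals,
            )
        )
        all_gens.append(gen)
        dividing = gen[(gen["division_h"] <= p.horizon_h) & ~gen["is_neuron"]]
        if not len(dividing):
            break
        m = len(dividing)
        modes = rng.choice(3, size=m, p=[p.p_pp, p.p_pn, p.p_nn])
        div_time = dividing["division_h"].to_numpy()
        labeled = (div_time >= 0.0) & (div_time <= p.ft_window_h)
        ft_mother = dividing["ft"].to_numpy() | labeled
        edu_pass = np.minimum(dividing["edu_inherited_h"].to_numpy(), dividing["edu_own_h"].to_numpy())
        # FT-labeled mothers acquire a bright shared dye intensity
        mother_ft_int = np.where(labeled, rng.lognormal(np.log(1000.0), 0.3, m), dividing["ft_int"].to_numpy())
        mother_gfp = dividing["gfp_int"].to_numpy()

        # daughter identity per mode: PP -> (P,P); PN -> shuffled (P,N); NN -> (N,N)
        neuron_a = modes == 2
        neuron_b = modes == 2
        pn = modes == 1
        flip = rng.random(m) < 0.5
        neuron_a = neuron_a | (pn & flip)
        neuron_b = neuron_b | (pn & ~flip)

        d_rows = []
        ids_a = np.arange(next_id, next_id + m)
        ids_b = np.arange(next_id + m, next_id + 2 * m)
        next_id += 2 * m
        for which, ids, sids, is_neu in (
            ("a", ids_a, ids_b, neuron_a),
            ("b", ids_b, ids_a, neuron_b),
        ):
            k = m
            g1_d = draw_g1(k)
            d = pd.DataFrame(
                {
                    "cell_id": ids,
                    "embryo_id": dividing["embryo_id"].to_numpy(),
                    "mother_id": dividing["cell_id"].to_numpy(),
                    "sister_id": sids,
                    "birth_h": div_time,
                    "g1_h": np.where(is_neu, np.nan, g1_d),
                    "is_neuron": is_neu,
                    "ft": ft_mother,
                    "edu_inherited_h": edu_pass,
                    "mother_mode": mode_names[modes],
                    "x_um": dividing["x_um"].to_numpy() + rng.normal(0, p.sister_jitter_um, k),
                    "z_um": dividing["z_um"].to_numpy() + rng.normal(0, p.sister_jitter_um, k),
                    # daughters are born at the apical surface, next to each other
                    "y_prog_um": p.apical_y_um + np.abs(rng.normal(0, p.sister_jitter_um, k)),
                    "gfp_int": mother_gfp * np.exp(rng.normal(0, p.gfp_sister_sigma, k)),
                    "ft_int": mother_ft_int * np.exp(rng.normal(0, p.ft_sister_sigma, k)),
                    "generation": dividing["generation"].to_numpy() + 1,
                }
            )
            d_rows.append(d)
        gen = pd.concat(d_rows, ignore_index=True)

    cells = pd.concat(all_gens, ignore_index=True)
    cells["edu_time_h"] = np.minimum(cells["edu_inherited_h"], cells["edu_own_h"])
    return LineageSim(params=params, cells=cells, seed=seed)


def _alive_at(cells: pd.DataFrame, t: float) -> np.ndarray:
    return (cells["birth_h"].to_numpy() <= t) & (t < cells["division_h"].to_numpy())


def sample_cells(sim: LineageSim, timepoint_h: float, id_prefix: str = "") -> pd.DataFrame:
    """Observable cell table (records format + truth columns) at one timepoint."""
    p = sim.params
    t = float(timepoint_h)
    df = sim.cells.loc[_alive_at(sim.cells, t)].copy()
    neu = df["is_neuron"].to_numpy()
    age = t - df["birth_h"].to_numpy()
    prb_on = np.where(neu, False, age >= np.minimum(p.prb_lag_h, df["g1_h"].to_numpy()))
    phase = np.select(
        [neu, age < df["g1_h"].to_numpy(), age < df["g1_h"].to_numpy() + p.ts_h],
        ["neuron", "G1", "S"],
        default="G2M",
    )
    out = pd.DataFrame(
        {
            "cell_id": [f"{id_prefix}c{int(i)}" for i in df["cell_id"]],
            "embryo_id": [f"e{int(e)}" for e in df["embryo_id"]],
            "condition": p.condition,
            "timepoint_h": t,
            "gfp_pos": True,
            "prb_pos": prb_on.astype(bool),
            "edu_pos": (df["edu_time_h"].to_numpy() <= t),
            "ft_pos": df["ft"].to_numpy(),
            "hucd_pos": neu & (age >= p.hucd_delay_h),
            "x_um": df["x_um"].to_numpy(),
            "y_um": np.where(
                neu,
                df["y_prog_um"].to_numpy()
                + p.neuron_speed_um_h * np.maximum(age - p.neuron_migration_lag_h, 0.0),
                df["y_prog_um"].to_numpy(),
            ),
            "z_um": df["z_um"].to_numpy(),
            "gfp_int": df["gfp_int"].to_numpy(),
            "ft_int": df["ft_int"].to_numpy(),
            # ground truth
            "true_g1_h": df["g1_h"].to_numpy(),
            "true_phase": phase,
            "true_mother_mode": df["mother_mode"].to_numpy(),
            "true_birth_h": df["birth_h"].to_numpy(),
            "true_sister_id": [
                f"{id_prefix}c{int(s)}" if s >= 0 else "" for s in df["sister_id"]
            ],
            "true_is_neuron": neu,
        }
    )
    for c in ("gfp_pos", "prb_pos", "edu_pos", "ft_pos", "hucd_pos"):
        out[c] = out[c].astype("boolean")
    return out.reset_index(drop=True)


def sample_pair_cells(
    sim: LineageSim,
    timepoint_h: float,
    contaminant_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """FT+ GFP+ cells at a timepoint, plus optional unpaired contaminants.

    Contaminants are FT-bright singleton cells with independent intensities
    and positions (emulating cells whose sister left the section).  Returns
    the cell table and the list of true sister pairs present in it.
    """
    rng = np.random.default_rng(seed)
    obs = sample_cells(sim, timepoint_h)
    ftcells = obs[obs["ft_pos"].fillna(False).to_numpy(dtype=bool)].copy()
    present = set(ftcells["cell_id"])
    true_pairs = sorted(
        {
            tuple(sorted((r.cell_id, r.true_sister_id)))
            for r in ftcells.itertuples()
            if r.true_sister_id and r.true_sister_id in present
        }
    )
    n_extra = int(round(contaminant_frac * len(ftcells)))
    if n_extra:
        p = sim.params
        extra = pd.DataFrame(
            {
                "cell_id": [f"contam{i}" for i in range(n_extra)],
                "embryo_id": rng.choice(ftcells["embryo_id"].unique(), n_extra),
                "condition": p.condition,
                "timepoint_h": float(timepoint_h),
                "gfp_pos": True,
                "prb_pos": rng.random(n_extra) < 0.5,
                "edu_pos": False,
                "ft_pos": True,
                "hucd_pos": False,
                "x_um": rng.uniform(0, p.tissue_width_um, n_extra),
                "y_um": rng.uniform(5, 60, n_extra),
                "z_um": rng.uniform(0, p.tissue_depth_um, n_extra),
                "gfp_int": rng.lognormal(np.log(500.0), 0.5, n_extra),
                "ft_int": rng.lognormal(np.log(1000.0), 0.3, n_extra),
                "true_g1_h": np.nan,
                "true_phase": "contaminant",
                "true_mother_mode": "",
                "true_birth_h": np.nan,
                "true_sister_id": "",
                "true_is_neuron": False,
            }
        )
        for c in ("gfp_pos", "prb_pos", "edu_pos", "ft_pos", "hucd_pos"):
            extra[c] = extra[c].astype("boolean")
        ftcells = pd.concat([ftcells, extra], ignore_index=True)
    return ftcells.reset_index(drop=True), true_pairs
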