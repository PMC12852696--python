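"""Cell-cycle kinetics from cumulative-EdU and FlashTag-synchronized cohorts.

Two labeling designs are covered:

* cumulative EdU in an asynchronous progenitor population: the fraction of
  EdU+ cells among cycling (pRb+, GFP+) cells rises from ~Ts/Tc to a
  plateau at the growth fraction by t = Tc - Ts; a classical saturating
  model ``f(t) = GF * min(1, (Ts + t) / Tc)`` can be fitted to quantify it;

* FlashTag-synchronized cohorts with continuous EdU: daughters of mothers
  dividing at injection incorporate EdU when they enter S phase, so the
  fraction EdU+ among FT+ pRb+ GFP+ cells at time t estimates P(G1 <= t) —
  a direct per-cohort G1-duration distribution.

The embryo is the statistical unit throughout: fractions are computed per
embryo and conditions are compared across embryos (Mann-Whitney or t test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression

from .stats import MannWhitneyResult, mann_whitney

__all__ = [
    "LabelingCurve",
    "CycleFit",
    "G1Stats",
    "cumulative_edu_curve",
    "g1_exit_curve",
    "pulse_s_fraction",
    "cycle_model_curve",
    "fit_cycle_model",
    "g1_summary",
    "compare_fractions_mw",
]


@dataclass
class LabelingCurve:
    """Per-embryo and condition-level labeling fractions over timepoints."""

    per_embryo: pd.DataFrame  # condition, timepoint_h, embryo_id, numerator, denominator, fraction
    summary: pd.DataFrame     # condition, timepoint_h, mean, sd, n_embryos, n_cells

    def condition(self, name: str) -> pd.DataFrame:
        return self.summary[self.summary["condition"] == name].sort_values("timepoint_h")


def _fraction_curve(
    cells: pd.DataFrame, denom_mask: pd.Series, numer_mask: pd.Series
) -> LabelingCurve:
    df = cells.loc[denom_mask.fillna(False).to_numpy(dtype=bool)].copy()
    df["_num"] = numer_mask.loc[df.index].fillna(False).to_numpy(dtype=bool)
    rows = []
    for (cond, tp, emb), grp in df.groupby(["condition", "timepoint_h", "embryo_id"], sort=True):
        den = len(grp)
        rows.append((cond, float(tp), emb, int(grp["_num"].sum()), den, grp["_num"].sum() / den))
    per_embryo = pd.DataFrame(
        rows, columns=["condition", "timepoint_h", "embryo_id", "numerator", "denominator", "fraction"]
    )
    # embryos contributing zero denominator at a (condition, timepoint) simply
    # do not appear; warn if an embryo present elsewhere is absent at some tp
    summ = []
    for (cond, tp), grp in per_embryo.groupby(["condition", "timepoint_h"], sort=True):
        n_emb = len(grp)
        summ.append(
            (
                cond,
                float(tp),
                grp["fraction"].mean(),
                grp["fraction"].std(ddof=1) if n_emb >= 2 else np.nan,
                n_emb,
                int(grp["denominator"].sum()),
            )
        )
    summary = pd.DataFrame(
        summ, columns=["condition", "timepoint_h", "mean", "sd", "n_embryos", "n_cells"]
    )
    return LabelingCurve(per_embryo=per_embryo, summary=summary)


def cumulative_edu_curve(cells: pd.DataFrame) -> LabelingCurve:
    """Fraction EdU+ among pRb+ GFP+ cells, per embryo then averaged.

    Cells with a missing denominator marker are excluded.
    """
    denom = cells["gfp_pos"].fillna(False) & cells["prb_pos"].fillna(False)
    if int(denom.sum()) == 0:
        raise ValueError("no pRb+ GFP+ cells in the table")
    return _fraction_curve(cells, denom, cells["edu_pos"])


def g1_exit_curve(cells: pd.DataFrame) -> LabelingCurve:
    """Fraction EdU+ among FT+ pRb+ GFP+ cells: the cohort's G1 exit cdf."""
    denom = (
        cells["gfp_pos"].fillna(False)
        & cells["prb_pos"].fillna(False)
        & cells["ft_pos"].fillna(False)
    )
    if int(denom.sum()) == 0:
        raise ValueError("no FT+ pRb+ GFP+ cells in the table")
    return _fraction_curve(cells, denom, cells["edu_pos"])


def pulse_s_fraction(cells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """1-h EdU pulse design: per-condition S-phase fraction and t tests.

    Returns the condition summary (mean +- SD across embryos) and, when two
    or more conditions are present, unpaired two-sample t tests between
    every condition pair.
    """
    curve = cumulative_edu_curve(cells)
    tests = {}
    conds = list(pd.unique(curve.per_embryo["condition"]))
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            fa = curve.per_embryo.loc[curve.per_embryo["condition"] == a, "fraction"]
            fb = curve.per_embryo.loc[curve.per_embryo["condition"] == b, "fraction"]
            if len(fa) >= 2 and len(fb) >= 2:
                t, p = sps.ttest_ind(fa, fb, equal_var=True)
                tests[f"{a}_vs_{b}"] = {"t": float(t), "p": float(p)}
    return curve.summary, tests


# -- cumulative-labeling model -------------------------------------------


@dataclass
class CycleFit:
    Tc_h: float
    Ts_h: float
    growth_fraction: float
    rss: float
    plateau_observed: bool = True
    degenerate: bool = False


def cycle_model_curve(t, Tc_h: float, Ts_h: float, growth_fraction: float = 1.0) -> np.ndarray:
    """Classical cumulative labeling index GF * min(1, (Ts + t) / Tc)."""
    t = np.asarray(t, dtype=float)
    return growth_fraction * np.minimum(1.0, (Ts_h + t) / Tc_h)


def fit_cycle_model(timepoints, fractions) -> CycleFit:
    """Bounded least-squares fit of the saturating cumulative-labeling model.

    Deterministic 5x5 multi-start grid over (Tc, S-fraction); the growth
    fraction starts at the plateau level.  Ts < Tc is enforced through the
    S-fraction parameterization.  If the data never flatten (largest
    timepoint < fitted Tc - Ts), Tc is only a lower bound and the fit is
    flagged ``plateau_observed=False``; a curve already saturated at the
    first timepoint is flagged ``degenerate`` (Ts -> Tc limit).
    """
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 timepoints to fit the cycle model")
    order = np.argsort(t)
    t, f = t[order], f[order]
    t_max = t.max()
    gf0 = float(np.clip(f.max(), 1e-3, 1.0))

    def resid(theta):
        tc, sfrac, gf = theta
        return cycle_model_curve(t, tc, sfrac * tc, gf) - f

    best = None
    for tc0 in np.linspace(max(t_max * 0.5, 1.0), t_max * 2.5, 5):
        for s0 in np.linspace(0.1, 0.9, 5):
            res = optimize.least_squares(
                resid,
                x0=[tc0, s0, gf0],
                bounds=([0.5, 0.01, 1e-3], [10 * t_max, 0.995, 1.0]),
                method="trf",
            )
            if best is None or res.cost < best.cost - 1e-12:
                best = res
    tc, sfrac, gf = best.x
    ts = sfrac * tc
    rss = float(2 * best.cost)
    plateau_observed = (tc - ts) <= t_max + 1e-9
    # saturated from the first timepoint: Ts -> Tc limit, parameters not identifiable
    degenerate = bool(f[0] >= 0.99 * gf)
    return CycleFit(
        Tc_h=float(tc),
        Ts_h=float(ts),
        growth_fraction=float(gf),
        rss=rss,
        plateau_observed=bool(plateau_observed),
        degenerate=degenerate,
    )


# -- G1 summary ----------------------------------------------------------


@dataclass
class G1Stats:
    cdf: pd.DataFrame          # timepoint_h, fraction (isotonic-corrected)
    median_g1_h: float         # NaN when the cdf never crosses 0.5
    plateau_time_h: float      # NaN when never within eps of 1
    plateau_level: float
    flags: dict = field(default_factory=dict)


def g1_summary(timepoints, fractions, eps: float = 0.02) -> G1Stats:
    """Median G1 and plateau landmarks from a (possibly jittery) exit curve.

    The raw per-timepoint fractions are projected onto a non-decreasing
    curve (isotonic regression) before the median is interpolated at 0.5
    and the plateau is located as the first timepoint with fraction
    >= 1 - eps.
    """
    t = np.asarray(timepoints, dtype=float)
    f = np.asarray(fractions, dtype=float)
    order = np.argsort(t)
    t, f = t[order], f[order]
    iso = IsotonicRegression(y_min=0.0, y_max=1.0).fit_transform(t, f)
    flags = {}
    if np.any(iso >= 0.5) and np.any(iso <= 0.5):
        median = float(np.interp(0.5, iso, t))
    elif iso[0] > 0.5:
        median = float(t[0])
        flags["median_left_censored"] = True
    else:
        median = np.nan
        flags["median_undefined"] = True
    at_plateau = iso >= 1.0 - eps
    if at_plateau.any():
        plateau_time = float(t[np.argmax(at_plateau)])
    else:
        plateau_time = np.nan
        flags["plateau_undefined"] = True
    return G1Stats(
        cdf=pd.DataFrame({"timepoint_h": t, "fraction": iso}),
        median_g1_h=median,
        plateau_time_h=plateau_time,
        plateau_level=float(iso[-1]),
        flags=flags,
    )


def compare_fractions_mw(
    curve: LabelingCurve, cond_a: str, cond_b: str, timepoint_h: float
) -> MannWhitneyResult:
    """Mann-Whitney test between two conditions' per-embryo fractions."""
    pe = curve.per_embryo
    sel = np.isclose(pe["timepoint_h"], timepoint_h)
    fa = pe.loc[sel & (pe["condition"] == cond_a), "fraction"].to_numpy()
    fb = pe.loc[sel & (pe["condition"] == cond_b), "fraction"].to_numpy()
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("need >= 2 embryos per condition at the tested timepoint")
    return mann_whitney(fa, fb)
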