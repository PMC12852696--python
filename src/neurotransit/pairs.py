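"""Sister-pair identification and mode-of-division classification.

Pairs of sister cells in a FlashTag cohort are recognized by the criteria
the experimenters apply visually — similar GFP and FT intensities and a
small separation consistent with the radial organization of clones — made
explicit as tolerance parameters and a deterministic mutual-best matching.
Classification into PP / PN / NN division modes reads the pRb status of
the two sisters, and is only meaningful once the pRb-positivity plateau
has been reached (checked with :func:`prb_plateau_check`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ChiSquareResult, chi_square_modes

__all__ = [
    "SisterPair",
    "ModeDistribution",
    "PlateauReport",
    "identify_pairs",
    "classify_pairs",
    "prb_plateau_check",
    "chi_square_2x3",
    "neuron_fraction_in_cohort",
]

MODES = ("PP", "PN", "NN")


@dataclass
class SisterPair:
    cell_a: str
    cell_b: str
    gfp_similarity: float
    ft_similarity: float
    separation_um: float
    mode: str = "undetermined"


@dataclass
class ModeDistribution:
    n_PP: int
    n_PN: int
    n_NN: int
    n_undetermined: int = 0
    condition: str | None = None
    n_embryos: int | None = None

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_PP, self.n_PN, self.n_NN])

    @property
    def proportions(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError("no classified pairs")
        return self.counts / tot


@dataclass
class PlateauReport:
    table: pd.DataFrame          # timepoint_h, frac_0, frac_1, frac_2, n_pairs, reliable
    stable_from_h: float | None  # earliest timepoint with TV to the next < delta
    flags: dict = field(default_factory=dict)


def _ratio(a: float, b: float) -> float:
    hi = max(a, b)
    return (min(a, b) / hi) if hi > 0 else 0.0


def identify_pairs(
    cells: pd.DataFrame,
    gfp_tol: float = 0.5,
    ft_tol: float = 0.5,
    max_dist_um: float = 30.0,
) -> tuple[list[SisterPair], list[str]]:
    """Greedy mutual-best matching of FT+ GFP+ cells into sister pairs.

    Candidate edges require min/max intensity ratios >= the tolerances in
    both channels and separation <= ``max_dist_um``.  Edges are accepted in
    decreasing order of a composite score (product of the two intensity
    ratios divided by 1 + distance/max_dist); score ties break on the
    lexicographically smallest (cell_id, cell_id) pair, so matching is
    fully deterministic.  Returns (pairs, unmatched_cell_ids).
    """
    sel = cells["ft_pos"].fillna(False) & cells["gfp_pos"].fillna(False)
    df = cells.loc[sel.to_numpy(dtype=bool)]
    for col in ("gfp_int", "ft_int", "x_um", "y_um", "z_um"):
        if col not in df.columns or df[col].isna().any():
            raise ValueError(f"pair identification requires column '{col}' without missing values")
    ids = df["cell_id"].to_numpy()
    xyz = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    gfp = df["gfp_int"].to_numpy(dtype=float)
    ft = df["ft_int"].to_numpy(dtype=float)

    edges = []
    n = len(df)
    for i in range(n):
        d = np.linalg.norm(xyz[i + 1 :] - xyz[i], axis=1)
        for off in np.flatnonzero(d <= max_dist_um):
            j = i + 1 + off
            rg = _ratio(gfp[i], gfp[j])
            rf = _ratio(ft[i], ft[j])
            if rg >= gfp_tol and rf >= ft_tol:
                score = rg * rf / (1.0 + d[off] / max_dist_um)
                a, b = sorted((str(ids[i]), str(ids[j])))
                edges.append((-score, a, b, rg, rf, float(d[off]), i, j))
    edges.sort()
    used = np.zeros(n, dtype=bool)
    pairs = []
    for negscore, a, b, rg, rf, dist, i, j in edges:
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        pairs.append(SisterPair(cell_a=a, cell_b=b, gfp_similarity=rg, ft_similarity=rf, separation_um=dist))
    unmatched = [str(c) for c in ids[~used]]
    return pairs, unmatched


def classify_pairs(
    pairs: list[SisterPair],
    cells: pd.DataFrame,
    marker: str = "prb",
    plateau_ok: bool = True,
    force: bool = False,
    condition: str | None = None,
) -> ModeDistribution:
    """Count PP / PN / NN pairs from the sisters' marker statuses.

    With ``marker="prb"``: (+,+) -> PP, mixed -> PN, (-,-) -> NN.  With
    ``marker="hucd"`` the mapping is inverted relative to progenitor
    identity (HuC/D marks neurons): (+,+) -> NN, mixed -> PN, (-,-) -> PP.
    Pairs with a missing status on either sister are counted undetermined
    and excluded from the distribution.  Classification is refused when the
    pRb plateau has not been validated, unless ``force=True``.
    """
    if not plateau_ok and not force:
        raise ValueError("pRb plateau not validated for this timepoint; pass force=True to override")
    col = {"prb": "prb_pos", "hucd": "hucd_pos"}[marker]
    status = cells.set_index("cell_id")[col]
    counts = {"PP": 0, "PN": 0, "NN": 0}
    undetermined = 0
    for p in pairs:
        a = status.get(p.cell_a, pd.NA)
        b = status.get(p.cell_b, pd.NA)
        if pd.isna(a) or pd.isna(b):
            p.mode = "undetermined"
            undetermined += 1
            continue
        n_pos = int(bool(a)) + int(bool(b))
        if marker == "hucd":
            n_pos = 2 - n_pos
        p.mode = {2: "PP", 1: "PN", 0: "NN"}[n_pos]
        counts[p.mode] += 1
    n_embryos = None
    if "embryo_id" in cells.columns:
        pair_cells = {c for p in pairs for c in (p.cell_a, p.cell_b)}
        n_embryos = cells.loc[cells["cell_id"].isin(pair_cells), "embryo_id"].nunique()
    return ModeDistribution(
        n_PP=counts["PP"],
        n_PN=counts["PN"],
        n_NN=counts["NN"],
        n_undetermined=undetermined,
        condition=condition,
        n_embryos=n_embryos,
    )


def prb_plateau_check(
    cohorts: dict[float, tuple[list[SisterPair], pd.DataFrame]],
    delta: float = 0.05,
    min_pairs: int = 20,
) -> PlateauReport:
    """Distribution of 0/1/2-pRb+ pairs over timepoints and its stability.

    ``cohorts`` maps timepoint (h) to (pairs, cell table).  Successive
    timepoints whose distributions differ by total-variation distance
    < ``delta`` are considered stable; the report gives the earliest such
    timepoint.  Timepoints with fewer than ``min_pairs`` classified pairs
    are flagged unreliable.
    """
    if len(cohorts) < 3:
        raise ValueError("plateau check needs >= 3 timepoints")
    rows = []
    for tp in sorted(cohorts):
        pairs, cells = cohorts[tp]
        status = cells.set_index("cell_id")["prb_pos"]
        tally = np.zeros(3)
        for p in pairs:
            a, b = status.get(p.cell_a, pd.NA), status.get(p.cell_b, pd.NA)
            if pd.isna(a) or pd.isna(b):
                continue
            tally[int(bool(a)) + int(bool(b))] += 1
        n = int(tally.sum())
        dist = tally / n if n > 0 else np.full(3, np.nan)
        rows.append((float(tp), *dist, n, n >= min_pairs))
    table = pd.DataFrame(rows, columns=["timepoint_h", "frac_0", "frac_1", "frac_2", "n_pairs", "reliable"])
    stable_from = None
    flags = {}
    dists = table[["frac_0", "frac_1", "frac_2"]].to_numpy()
    tv = np.array(
        [0.5 * np.nansum(np.abs(dists[i + 1] - dists[i])) for i in range(len(table) - 1)]
    )
    # earliest timepoint from which every later transition stays below delta
    for i in range(len(tv)):
        if np.all(tv[i:] < delta):
            stable_from = float(table["timepoint_h"].iloc[i])
            break
    if not table["reliable"].all():
        flags["unreliable_timepoints"] = table.loc[~table["reliable"], "timepoint_h"].tolist()
    return PlateauReport(table=table, stable_from_h=stable_from, flags=flags)


def chi_square_2x3(dist_a: ModeDistribution, dist_b: ModeDistribution) -> ChiSquareResult:
    """Pearson chi-square between two PP/PN/NN distributions (df = 2)."""
    return chi_square_modes(dist_a.counts, dist_b.counts)


def neuron_fraction_in_cohort(cells: pd.DataFrame) -> tuple[pd.DataFrame, ChiSquareResult | None]:
    """Fraction HuC/D+ among FT+ GFP+ cells per embryo, plus a pooled test.

    With exactly two conditions, the pooled 2x2 (HuC/D+ / HuC/D-) table is
    compared by chi-square; per-embryo fractions report the spread.
    """
    sel = cells["ft_pos"].fillna(False) & cells["gfp_pos"].fillna(False)
    df = cells.loc[sel.to_numpy(dtype=bool)].copy()
    if df["hucd_pos"].isna().any():
        raise ValueError("hucd_pos missing for some FT+ GFP+ cells")
    df["_pos"] = df["hucd_pos"].astype(bool)
    rows = []
    for (cond, emb), grp in df.groupby(["condition", "embryo_id"], sort=True):
        rows.append((cond, emb, int(grp["_pos"].sum()), len(grp), grp["_pos"].mean()))
    per_embryo = pd.DataFrame(rows, columns=["condition", "embryo_id", "n_pos", "n_total", "fraction"])
    test = None
    conds = list(pd.unique(per_embryo["condition"]))
    if len(conds) == 2:
        a = df[df["condition"] == conds[0]]["_pos"]
        b = df[df["condition"] == conds[1]]["_pos"]
        test = chi_square_modes(
            [int(a.sum()), int((~a).sum())],
            [int(b.sum()), int((~b).sum())],
        )
    return per_embryo, test
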