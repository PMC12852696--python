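"""Negative-binomial differential expression on raw UMI counts.

Per gene, a NB GLM with log link and log-library-size offset is fitted with
and without the group term; the likelihood-ratio statistic is referred to
chi-square(1).  The NB dispersion is estimated per gene by method of moments
on offset-adjusted counts, with a small floor for near-Poisson genes.
The same machinery, with pseudotime-bin indicators as the design, provides
the variation test used to select genes for pseudotime clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrix import CountMatrix
from .stats import bh_adjust

__all__ = [
    "moments_dispersion",
    "nb_differential_expression",
    "select_varying_genes",
]

DISPERSION_FLOOR = 1e-8


def moments_dispersion(y: np.ndarray, size_factors: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha of var = mu + alpha * mu^2.

    Computed on rate-adjusted counts y / s so that library-size variation
    does not inflate the estimate.
    """
    r = y / size_factors
    m = r.mean()
    if m <= 0:
        return DISPERSION_FLOOR
    v = r.var(ddof=1)
    return float(max(DISPERSION_FLOOR, (v - m) / m**2))


def _lrt_one_gene(y, X_full, X_null, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=alpha)
    try:
        fit1 = sm.GLM(y, X_full, family=fam, offset=offset).fit(maxiter=100)
        fit0 = sm.GLM(y, X_null, family=fam, offset=offset).fit(maxiter=100)
    except Exception:
        return np.nan, np.nan, np.nan
    lr = 2.0 * (fit1.llf - fit0.llf)
    lr = max(lr, 0.0)
    df = X_full.shape[1] - X_null.shape[1]
    from scipy.stats import chi2

    p = float(chi2.sf(lr, df))
    coef = float(fit1.params[-1]) if X_full.shape[1] == 2 else np.nan
    return lr, p, coef


def nb_differential_expression(
    cm: CountMatrix,
    labels: pd.Series | np.ndarray,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test between two cell groups.

    ``contrast = (group_b, group_a)`` tests group_b relative to group_a
    (log2 fold change is b over a).  Requires raw counts; genes that are
    all-zero in both groups are excluded and reported with ``tested=False``.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=cm.cell_ids)
    b_name, a_name = contrast
    sel = labels.isin([a_name, b_name]).to_numpy()
    if sel.sum() < 4:
        raise ValueError("need cells in both contrast groups")
    sub = cm.subset_cells(sel)
    grp = (labels[sel] == b_name).to_numpy(dtype=float)
    if grp.sum() < 2 or (1 - grp).sum() < 2:
        raise ValueError("each contrast group needs >= 2 cells")
    total = sub.counts.sum(axis=0).astype(float)
    if np.any(total == 0):
        raise ValueError("zero-UMI cell in contrast; filter cells first")
    offset = np.log(total)
    size = total / total.mean()
    X_full = np.column_stack([np.ones_like(grp), grp])
    X_null = X_full[:, :1]

    rows = []
    for gi in range(sub.n_genes):
        y = sub.counts[gi].astype(float)
        tested = y.sum() > 0
        if not tested:
            rows.append((sub.gene_ids[gi], np.nan, np.nan, np.nan, np.nan, False))
            continue
        alpha = moments_dispersion(y, size)
        lr, p, coef = _lrt_one_gene(y, X_full, X_null, offset, alpha)
        log2fc = coef / np.log(2.0) if np.isfinite(coef) else np.nan
        rows.append((sub.gene_ids[gi], log2fc, lr, p, alpha, True))
    res = pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "lr_stat", "pvalue", "dispersion", "tested"]
    ).set_index("gene_id")
    tested_mask = res["tested"] & res["pvalue"].notna()
    res["padj"] = np.nan
    res.loc[tested_mask, "padj"] = bh_adjust(res.loc[tested_mask, "pvalue"].to_numpy())
    return res


def select_varying_genes(
    cm: CountMatrix,
    pseudotime: pd.Series,
    n_bins: int = 10,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """LR test of binned pseudotime means versus a constant model, per gene.

    Cells are split into equal-occupancy pseudotime bins; an NB GLM with bin
    indicators (log-total offset) is compared against the intercept-only
    model.  Genes with BH-adjusted p < ``alpha_level`` are flagged
    ``varying=True`` and feed the pseudotime gene clustering.
    """
    pt = pd.Series(pseudotime).reindex(pd.Index(cm.cell_ids)).to_numpy(dtype=float)
    if np.any(~np.isfinite(pt)):
        raise ValueError("pseudotime missing for some cells")
    order = np.argsort(np.argsort(pt, kind="mergesort"))
    bins = np.minimum((order * n_bins) // cm.n_cells, n_bins - 1)
    total = cm.counts.sum(axis=0).astype(float)
    offset = np.log(total)
    size = total / total.mean()
    X_full = np.column_stack(
        [np.ones(cm.n_cells)] + [(bins == b).astype(float) for b in range(1, n_bins)]
    )
    X_null = X_full[:, :1]
    rows = []
    for gi in range(cm.n_genes):
        y = cm.counts[gi].astype(float)
        if y.sum() == 0:
            rows.append((cm.gene_ids[gi], np.nan, np.nan, False))
            continue
        disp = moments_dispersion(y, size)
        lr, p, _ = _lrt_one_gene(y, X_full, X_null, offset, disp)
        rows.append((cm.gene_ids[gi], lr, p, True))
    res = pd.DataFrame(rows, columns=["gene_id", "lr_stat", "pvalue", "tested"]).set_index("gene_id")
    mask = res["tested"] & res["pvalue"].notna()
    res["padj"] = np.nan
    res.loc[mask, "padj"] = bh_adjust(res.loc[mask, "pvalue"].to_numpy())
    res["varying"] = res["padj"] < alpha_level
    return res
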