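"""Log-normalization and confounder regression.

Normalization is the standard library-size log transform
``x -> ln(1 + scale * x / total)``.  Confounders (cell-cycle phase scores,
sex covariates, ...) are regressed out gene-wise by OLS, separately within
the "cycling" (S + G2/M) and "non-cycling" (G1/G0) groups so that the
proliferative/post-mitotic contrast itself is preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = ["log_normalize", "regress_confounders", "assign_cycle_groups"]

DEFAULT_SCALE = 10_000.0

# Configurable cell-cycle gene lists (chick symbols; short defaults chosen
# among classic S / G2-M markers so synthetic matrices can plant them).
S_PHASE_GENES = ("Rrm2", "Pcna", "Mcm5", "Gins2", "Cdc6")
G2M_GENES = ("Ube2c", "Cenpa", "Hmgb2", "Ccnb2", "Cdk1", "Top2a")


def log_normalize(cm: CountMatrix, scale_factor: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Library-size log normalization; genes x cells DataFrame.

    Raises on zero-UMI cells (they should have been removed by QC).
    """
    total = cm.counts.sum(axis=0).astype(float)
    if np.any(total == 0):
        raise ValueError("zero-UMI cell encountered; run cell filtering first")
    norm = np.log1p(scale_factor * cm.counts / total[None, :])
    return pd.DataFrame(norm, index=pd.Index(cm.gene_ids, name="gene_id"),
                        columns=pd.Index(cm.cell_ids, name="cell_id"))


def assign_cycle_groups(
    norm: pd.DataFrame,
    s_genes=S_PHASE_GENES,
    g2m_genes=G2M_GENES,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Label cells "cycling" (S or G2/M score > 0) or "non_cycling".

    Phase scores are binned-control module scores over configurable gene
    lists; a cell is cycling when either phase score is positive.
    """
    from .scoring import module_score
    from .matrix import SignatureSet

    present = set(norm.index)
    s_list = tuple(g for g in s_genes if g in present)
    g2m_list = tuple(g for g in g2m_genes if g in present)
    if not s_list and not g2m_list:
        raise ValueError("no cell-cycle genes present in the matrix")
    scores = []
    if s_list:
        scores.append(module_score(norm, SignatureSet("S", s_list), n_bins=n_bins, n_ctrl=n_ctrl, seed=seed))
    if g2m_list:
        scores.append(module_score(norm, SignatureSet("G2M", g2m_list), n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1))
    peak = pd.concat(scores, axis=1).max(axis=1)
    return pd.Series(np.where(peak > 0, "cycling", "non_cycling"), index=norm.columns, name="cycle_group")


def _design_matrix(cov: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(cov))]
    for c in cov.columns:
        col = cov[c]
        if col.dtype.kind in "biufc":
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
    return np.column_stack(cols)


def regress_confounders(
    norm: pd.DataFrame,
    covariates: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Gene-wise OLS residuals against covariates, within each group.

    Collinear covariate columns are dropped with a warning (via column-pivoted
    rank detection).  Residuals have mean ~ 0 per gene within each group.
    """
    if not covariates.index.equals(norm.columns.to_frame().index) and not np.array_equal(
        covariates.index.to_numpy(), norm.columns.to_numpy()
    ):
        raise ValueError("covariates index must match matrix cells")
    if groups is None:
        groups = pd.Series("all", index=norm.columns)
    out = np.empty_like(norm.to_numpy(dtype=float))
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        X = _design_matrix(covariates.loc[mask])
        # drop collinear columns
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        if not keep.all():
            warnings.warn("dropped collinear covariate columns")
            X = X[:, keep]
        Y = norm.to_numpy(dtype=float)[:, mask].T  # cells x genes
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out[:, mask] = (Y - X @ beta).T
    return pd.DataFrame(out, index=norm.index, columns=norm.columns)
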