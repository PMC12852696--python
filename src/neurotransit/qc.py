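"""Cell- and gene-level quality control and contaminant exclusion.

The fixed order of operations is: cell QC -> gene filter -> marker-based
exclusion of non-neural cells -> normalization (see ``normalize``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    MESODERM_MARKERS,
    NEURAL_CREST_MARKERS,
    CountMatrix,
    QCThresholds,
)

__all__ = ["compute_qc", "filter_cells", "filter_genes", "marker_exclude", "FilterReport"]


@dataclass
class FilterReport:
    """Per-rule removal counts from a filtering step."""

    n_before: int
    n_after: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n_before": self.n_before, "n_after": self.n_after, "removed": dict(self.removed)}


def compute_qc(cm: CountMatrix) -> pd.DataFrame:
    """Per-cell table of UMI totals and mitochondrial / hemoglobin fractions.

    Zero-UMI cells get fractions of 0 and ``zero_umi=True`` (they are removed
    by :func:`filter_cells` regardless of thresholds).
    """
    total = cm.counts.sum(axis=0).astype(float)
    mito = cm.counts[cm.is_mito, :].sum(axis=0).astype(float)
    hgb = cm.counts[cm.is_hemoglobin, :].sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        hgb_frac = np.where(total > 0, hgb / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "umi_total": total,
            "mito_frac": mito_frac,
            "hemoglobin_frac": hgb_frac,
            "zero_umi": total == 0,
        },
        index=pd.Index(cm.cell_ids, name="cell_id"),
    )


def filter_cells(
    cm: CountMatrix, qc: pd.DataFrame, thr: QCThresholds | None = None
) -> tuple[CountMatrix, FilterReport]:
    """Remove cells outside the UMI percentile band or above composition caps.

    Percentiles are computed on the provided cells' UMI totals.  Order of
    retained cells is preserved.  Raises if every cell would be removed.
    """
    thr = thr or QCThresholds()
    if qc.shape[0] != cm.n_cells or not np.array_equal(qc.index.to_numpy(), cm.cell_ids):
        raise ValueError("qc table does not match the matrix cells")
    total = qc["umi_total"].to_numpy()
    lo = np.percentile(total, thr.umi_low_pct)
    hi = np.percentile(total, thr.umi_high_pct)
    bad_low = total < lo
    bad_high = total > hi
    bad_mito = qc["mito_frac"].to_numpy() > thr.mito_max_frac
    bad_hgb = qc["hemoglobin_frac"].to_numpy() > thr.hemoglobin_max_frac
    bad_zero = qc["zero_umi"].to_numpy()
    keep = ~(bad_low | bad_high | bad_mito | bad_hgb | bad_zero)
    if not keep.any():
        raise ValueError("cell filtering removed every cell; thresholds are inconsistent with the data")
    report = FilterReport(
        n_before=cm.n_cells,
        n_after=int(keep.sum()),
        removed={
            "umi_low": int(bad_low.sum()),
            "umi_high": int(bad_high.sum()),
            "mito": int(bad_mito.sum()),
            "hemoglobin": int(bad_hgb.sum()),
            "zero_umi": int(bad_zero.sum()),
        },
    )
    return cm.subset_cells(keep), report


def filter_genes(cm: CountMatrix, thr: QCThresholds | None = None) -> tuple[CountMatrix, FilterReport]:
    """Keep genes detected with >= gene_min_count UMIs in >= gene_min_cells cells."""
    thr = thr or QCThresholds()
    n_detected = (cm.counts >= thr.gene_min_count).sum(axis=1)
    keep = n_detected >= thr.gene_min_cells
    if not keep.any():
        raise ValueError("gene filtering removed every gene")
    report = FilterReport(
        n_before=cm.n_genes,
        n_after=int(keep.sum()),
        removed={"low_detection": int((~keep).sum())},
    )
    return cm.subset_genes(keep), report


def marker_exclude(
    cm: CountMatrix,
    marker_sets: dict[str, tuple[str, ...]] | None = None,
    min_umis: int = 1,
) -> tuple[CountMatrix, FilterReport]:
    """Remove cells expressing non-neural lineage markers.

    A cell is removed when its summed UMIs over any single marker set reach
    ``min_umis``.  Missing marker genes warn rather than fail.
    """
    if marker_sets is None:
        marker_sets = {"mesoderm": MESODERM_MARKERS, "neural_crest": NEURAL_CREST_MARKERS}
    removed = {}
    bad = np.zeros(cm.n_cells, dtype=bool)
    for name, genes in marker_sets.items():
        idx = cm.gene_index(genes, missing="warn")
        if idx.size == 0:
            warnings.warn(f"no markers of set '{name}' present in matrix")
            removed[name] = 0
            continue
        set_bad = cm.counts[idx, :].sum(axis=0) >= min_umis
        removed[name] = int(set_bad.sum())
        bad |= set_bad
    keep = ~bad
    if not keep.any():
        raise ValueError("marker exclusion removed every cell")
    report = FilterReport(n_before=cm.n_cells, n_after=int(keep.sum()), removed=removed)
    return cm.subset_cells(keep), report
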