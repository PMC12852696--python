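"""Gene x cell count matrix container and on-disk formats.

The container is a thin immutable-ish wrapper over a dense integer numpy
array (genes as rows, matching the dense-CSV convention) plus gene/cell
identifiers and per-gene mitochondrial / hemoglobin flags.  Matrices are
read and written either as Matrix Market (MTX + genes.tsv + barcodes.tsv,
the 10x convention) via scipy.io, or as dense CSV with genes as rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "SignatureSet",
    "PROGENITOR_GENES",
    "NEURON_GENES",
    "NEUROGENIC_GENES",
    "MESODERM_MARKERS",
    "NEURAL_CREST_MARKERS",
    "default_signatures",
    "read_mtx",
    "read_dense_csv",
    "write_mtx",
    "write_dense_csv",
]

# Signature gene lists of the chick spinal-cord progenitor -> neuron axis.
# Overridable wherever a SignatureSet is accepted; Tis21 is the Btg2 alias.
PROGENITOR_GENES = ("Sox2", "Notch1", "Rrm2", "Hmgb2", "Cenpa", "Ube2c", "Hes5")
NEURON_GENES = ("Tubb3", "Stmn2", "Stmn3", "Nova1", "Rtn1", "Mapt")
NEUROGENIC_GENES = ("Tis21", "Dll1", "Hes6", "NeuroG1", "NeuroG2", "Gadd45g")

MESODERM_MARKERS = ("Foxc1", "Foxc2", "Twist1", "Twist2", "Meox1", "Meox2")
NEURAL_CREST_MARKERS = ("Sox10",)

#: default gene-name rules used to flag mitochondrial / hemoglobin genes
MITO_PREFIXES = ("MT-", "mt-", "MT_")
HEMOGLOBIN_PREFIXES = ("HBA", "HBB", "HBE", "HBZ", "HBG")


@dataclass(frozen=True)
class SignatureSet:
    """A named gene signature (P, N or PN by default; any name allowed)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")


def default_signatures() -> dict[str, SignatureSet]:
    return {
        "P": SignatureSet("P", PROGENITOR_GENES),
        "N": SignatureSet("N", NEURON_GENES),
        "PN": SignatureSet("PN", NEUROGENIC_GENES),
    }


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level quality-control thresholds.

    Defaults reproduce the study conditions: cells outside the
    [0.5, 99.9] UMI percentile band, above 20% mitochondrial or 0.3%
    hemoglobin UMI content are removed; genes must be detected (>= 1 UMI)
    in at least 3 cells.
    """

    umi_low_pct: float = 0.5
    umi_high_pct: float = 99.9
    mito_max_frac: float = 0.20
    hemoglobin_max_frac: float = 0.003
    gene_min_cells: int = 3
    gene_min_count: int = 1

    def __post_init__(self):
        if not (0 <= self.umi_low_pct < self.umi_high_pct <= 100):
            raise ValueError("need 0 <= umi_low_pct < umi_high_pct <= 100")
        for frac in (self.mito_max_frac, self.hemoglobin_max_frac):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.gene_min_cells < 0 or self.gene_min_count < 0:
            raise ValueError("gene thresholds must be non-negative")


@dataclass
class CountMatrix:
    """Dense genes x cells UMI count matrix with identifiers and gene flags."""

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_mito: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_hemoglobin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-d (genes x cells)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if self.gene_ids.shape != (n_genes,) or self.cell_ids.shape != (n_cells,):
            raise ValueError("id vectors do not match counts dimensions")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name}_ids")
        if self.is_mito is None:
            self.is_mito = np.array(
                [str(g).upper().startswith(tuple(p.upper() for p in MITO_PREFIXES)) for g in self.gene_ids]
            )
        if self.is_hemoglobin is None:
            self.is_hemoglobin = np.array(
                [str(g).upper().startswith(HEMOGLOBIN_PREFIXES) for g in self.gene_ids]
            )
        self.is_mito = np.asarray(self.is_mito, dtype=bool)
        self.is_hemoglobin = np.asarray(self.is_hemoglobin, dtype=bool)
        if self.is_mito.shape != (n_genes,) or self.is_hemoglobin.shape != (n_genes,):
            raise ValueError("gene flags do not match the number of genes")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str], missing: str = "warn") -> np.ndarray:
        """Row indices of ``genes``; missing genes warn+drop or raise."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx, absent = [], []
        for g in genes:
            if g in lookup:
                idx.append(lookup[g])
            else:
                absent.append(g)
        if absent:
            if missing == "error":
                raise KeyError(f"genes absent from matrix: {absent}")
            warnings.warn(f"genes absent from matrix, dropped: {absent}")
        return np.asarray(idx, dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        return replace(
            self,
            counts=self.counts[:, mask_or_idx],
            cell_ids=self.cell_ids[mask_or_idx],
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        return replace(
            self,
            counts=self.counts[mask_or_idx, :],
            gene_ids=self.gene_ids[mask_or_idx],
            is_mito=self.is_mito[mask_or_idx],
            is_hemoglobin=self.is_hemoglobin[mask_or_idx],
        )

    def to_anndata(self):
        """Cells x genes AnnData view (for interop with scanpy workflows)."""
        import anndata

        ad = anndata.AnnData(
            X=self.counts.T.astype(np.float32),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(
                {"is_mito": self.is_mito, "is_hemoglobin": self.is_hemoglobin},
                index=pd.Index(self.gene_ids, name="gene_id"),
            ),
        )
        return ad


# -- IO -------------------------------------------------------------------

def read_mtx(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    mat = scipy.io.mmread(str(mtx_path))
    counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
    return CountMatrix(counts=np.rint(counts).astype(np.int64), gene_ids=genes, cell_ids=cells)


def read_dense_csv(path) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        counts=df.to_numpy(),
        gene_ids=df.index.astype(str).to_numpy(),
        cell_ids=df.columns.astype(str).to_numpy(),
    )


def write_mtx(cm: CountMatrix, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), scipy.sparse.coo_matrix(cm.counts))
    pd.Series(cm.gene_ids).to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def write_dense_csv(cm: CountMatrix, path) -> None:
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids).to_csv(path)
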