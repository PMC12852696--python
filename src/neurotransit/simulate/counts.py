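"""Negative-binomial count simulator for the progenitor -> neuron continuum.

Each neural cell carries a latent maturation coordinate t ~ Uniform(0, 1);
gene expression follows per-program temporal templates (early-high
progenitor genes, mid-peak neurogenic genes, late-high neuron genes, a
cell-cycle-linked program, flat housekeeping and unstructured noise genes).
Counts are NB(mean = libsize * relative rate, dispersion), with planted
mitochondrial and hemoglobin loads and an optional admixture of mesoderm /
neural-crest contaminant cells expressing their lineage markers.  Ground
truth (maturation, state, program membership) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ..matrix import (
    MESODERM_MARKERS,
    NEURAL_CREST_MARKERS,
    NEUROGENIC_GENES,
    NEURON_GENES,
    PROGENITOR_GENES,
    CountMatrix,
)

__all__ = ["CountsSimParams", "CountsTruth", "simulate_counts", "temporal_programs", "SHAPES"]


def _early(t):
    return 1.0 / (1.0 + np.exp((t - 0.35) / 0.08))


def _mid(t):
    return np.exp(-((t - 0.5) ** 2) / (2 * 0.12**2))


def _late(t):
    return 1.0 / (1.0 + np.exp(-(t - 0.65) / 0.08))


def _midlate(t):
    # Cdkn1c-like: peaks later and broader than the neurogenic (mid) program,
    # then fades again in mature cells
    return np.exp(-((t - 0.55) ** 2) / (2 * 0.135**2))


SHAPES: dict[str, Callable] = {
    "early": _early,
    "mid": _mid,
    "late": _late,
    "midlate": _midlate,
    "flat": lambda t: np.ones_like(t),
}


def temporal_programs(k: int, width: float = 0.55) -> dict[str, Callable]:
    """k evenly spaced bump templates along maturation (Fig-1C-like programs)."""
    centers = (np.arange(k) + 0.5) / k
    sd = width / k

    def make(c):
        return lambda t: np.exp(-((t - c) ** 2) / (2 * sd**2))

    return {f"T{i + 1}": make(c) for i, c in enumerate(centers)}


@dataclass
class CountsSimParams:
    n_cells: int = 1500
    n_genes: int = 500
    dispersion: float = 0.3
    lib_mean: float = 8000.0          # mean UMI per cell (lognormal)
    lib_sigma: float = 0.35
    #: fraction of generic genes per temporal program; remainder -> "noise"
    program_fractions: dict[str, float] = field(
        default_factory=lambda: {"early": 0.10, "mid": 0.10, "late": 0.10, "cycle": 0.08, "flat": 0.32}
    )
    custom_shapes: dict[str, Callable] | None = None
    include_signatures: bool = True
    sig_strength: float = 3.0         # amplitude multiplier of signature genes
    modulation_floor: float = 0.05
    #: per-gene temporal jitter: genes in a program share a template but not
    #: an identical profile (center shift sd, in maturation units)
    shape_jitter: float = 0.05
    n_mito: int = 10
    mito_load: float = 0.05
    n_hemoglobin: int = 4
    hemoglobin_load: float = 0.001
    n_high_mito_cells: int = 0
    high_mito_load: float = 0.5
    contaminant_frac: float = 0.0
    marker_load: float = 0.02         # UMI share of lineage markers in contaminants


@dataclass
class CountsTruth:
    cells: pd.DataFrame   # cell_id, maturation, state, cycle_phase
    genes: pd.DataFrame   # gene_id, program


def _state_of(t: np.ndarray) -> np.ndarray:
    return np.select([t < 1 / 3, t < 2 / 3], ["P", "PN"], default="N")


def simulate_counts(params: CountsSimParams, seed: int = 0) -> tuple[CountMatrix, CountsTruth]:
    """Deterministic per (params, seed).  Returns (CountMatrix, truth)."""
    p = params
    rng = np.random.default_rng(seed)
    shapes = dict(SHAPES)
    if p.custom_shapes:
        shapes.update(p.custom_shapes)

    # -- gene roster ------------------------------------------------------
    gene_ids: list[str] = []
    programs: list[str] = []
    if p.include_signatures:
        for g in PROGENITOR_GENES:
            gene_ids.append(g), programs.append("early")
        for g in NEURON_GENES:
            gene_ids.append(g), programs.append("late")
        for g in NEUROGENIC_GENES:
            gene_ids.append(g), programs.append("mid")
        gene_ids.append("Cdkn1c"), programs.append("midlate")
    for g in MESODERM_MARKERS:
        gene_ids.append(g), programs.append("mesoderm_marker")
    for g in NEURAL_CREST_MARKERS:
        gene_ids.append(g), programs.append("neural_crest_marker")
    for i in range(p.n_mito):
        gene_ids.append(f"MT-G{i + 1}"), programs.append("mito")
    for i in range(p.n_hemoglobin):
        gene_ids.append(f"HBA{i + 1}"), programs.append("hemoglobin")
    n_generic = p.n_genes - len(gene_ids)
    if n_generic < 10:
        raise ValueError("n_genes too small for the requested roster")
    frac_sum = sum(p.program_fractions.values())
    if frac_sum > 1.0 + 1e-9:
        raise ValueError("program fractions exceed 1")
    assigned = 0
    for name, frac in p.program_fractions.items():
        k = int(round(frac * n_generic))
        for i in range(k):
            gene_ids.append(f"{name.upper()}{i + 1}"), programs.append(name)
        assigned += k
    for i in range(n_generic - assigned):
        gene_ids.append(f"NOISE{i + 1}"), programs.append("noise")
    programs_arr = np.asarray(programs, dtype=object)
    n_genes = len(gene_ids)

    # -- cells ------------------------------------------------------------
    n_contam = int(round(p.contaminant_frac * p.n_cells))
    n_neural = p.n_cells - n_contam
    maturation = np.full(p.n_cells, np.nan)
    maturation[:n_neural] = rng.uniform(0, 1, n_neural)
    is_contam = np.zeros(p.n_cells, dtype=bool)
    is_contam[n_neural:] = True
    contam_kind = np.array([""] * p.n_cells, dtype=object)
    if n_contam:
        contam_kind[n_neural:] = rng.choice(["mesoderm", "neural_crest"], size=n_contam)
    cycle_phase = rng.choice(["G1", "S", "G2M"], size=p.n_cells, p=[0.6, 0.25, 0.15])
    libsize = rng.lognormal(np.log(p.lib_mean) - p.lib_sigma**2 / 2, p.lib_sigma, p.n_cells)

    # -- relative rates ---------------------------------------------------
    base = rng.lognormal(0.0, 1.0, n_genes)
    rate = np.empty((n_genes, p.n_cells))
    t_safe = np.where(np.isnan(maturation), 0.5, maturation)
    cyc = np.where(cycle_phase == "G1", 0.15, 1.0)
    for gi in range(n_genes):
        prog = programs_arr[gi]
        amp = base[gi]
        if prog in shapes:
            shift = rng.normal(0, p.shape_jitter) if p.shape_jitter > 0 else 0.0
            mod = p.modulation_floor + (1 - p.modulation_floor) * shapes[prog](t_safe - shift)
            if prog != "flat" and gene_ids[gi] in set(
                PROGENITOR_GENES + NEURON_GENES + NEUROGENIC_GENES + ("Cdkn1c",)
            ):
                amp = p.sig_strength * (1.0 + base[gi])
        elif prog == "cycle":
            mod = p.modulation_floor + (1 - p.modulation_floor) * cyc
        elif prog in ("noise", "mito", "hemoglobin"):
            mod = np.ones(p.n_cells)
        elif prog.endswith("_marker"):
            mod = np.ones(p.n_cells)
        else:
            raise ValueError(f"unknown program '{prog}'")
        rate[gi] = amp * mod
    # neural programs are silent in contaminants; markers silent in neural cells
    temporal = np.isin(programs_arr, list(shapes.keys())) & (programs_arr != "flat")
    rate[np.ix_(temporal, is_contam)] = p.modulation_floor * base[temporal, None]
    meso = programs_arr == "mesoderm_marker"
    crest = programs_arr == "neural_crest_marker"
    rate[meso | crest, :] = 0.0

    # -- composition: markers, mito, hemoglobin get fixed UMI shares ------
    mito = programs_arr == "mito"
    hgb = programs_arr == "hemoglobin"
    plain = ~(mito | hgb | meso | crest)
    mito_load = np.full(p.n_cells, p.mito_load)
    if p.n_high_mito_cells:
        hi = rng.choice(np.flatnonzero(~is_contam), size=p.n_high_mito_cells, replace=False)
        mito_load[hi] = p.high_mito_load
    marker_share = np.where(is_contam, p.marker_load, 0.0)
    rest = 1.0 - mito_load - p.hemoglobin_load - marker_share

    col_sum = rate[plain].sum(axis=0)
    rate[plain] *= rest / col_sum
    mito_w = rng.lognormal(0, 0.5, int(mito.sum()))
    rate[mito] = np.outer(mito_w / mito_w.sum(), mito_load)
    hgb_w = rng.lognormal(0, 0.5, int(hgb.sum()))
    rate[hgb] = np.outer(hgb_w / hgb_w.sum(), np.full(p.n_cells, p.hemoglobin_load))
    if n_contam:
        meso_cells = is_contam & (contam_kind == "mesoderm")
        crest_cells = is_contam & (contam_kind == "neural_crest")
        meso_w = rng.lognormal(0, 0.5, int(meso.sum()))
        rate[np.ix_(meso, meso_cells)] = np.outer(meso_w / meso_w.sum(), np.full(int(meso_cells.sum()), p.marker_load))
        rate[np.ix_(crest, crest_cells)] = p.marker_load / max(int(crest.sum()), 1)

    mean = rate * libsize[None, :]

    # -- NB sampling (gamma-Poisson); dispersion -> 0 is Poisson ----------
    disp = np.full(n_genes, p.dispersion)
    disp[programs_arr == "noise"] = p.dispersion * 4 + 0.1
    counts = np.empty((n_genes, p.n_cells), dtype=np.int64)
    for gi in range(n_genes):
        mu = mean[gi]
        a = disp[gi]
        if a < 1e-8:
            counts[gi] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / a, scale=np.maximum(mu, 1e-12) * a)
            counts[gi] = rng.poisson(lam)

    cell_ids = np.array([f"cell{i:05d}" for i in range(p.n_cells)], dtype=object)
    cm = CountMatrix(counts=counts, gene_ids=np.array(gene_ids, dtype=object), cell_ids=cell_ids)
    state = np.where(is_contam, contam_kind, _state_of(t_safe))
    truth = CountsTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "maturation": maturation,
                "state": state,
                "cycle_phase": cycle_phase,
                "is_contaminant": is_contam,
                "libsize": libsize,
                "mito_load": mito_load,
            }
        ).set_index("cell_id"),
        genes=pd.DataFrame({"gene_id": gene_ids, "program": programs_arr}).set_index("gene_id"),
    )
    return cm, truth
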