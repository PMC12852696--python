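"""Signature (module) scoring and P / PN / N state classification.

A module score is the mean normalized expression of the signature genes
minus the mean of expression-matched control genes: genes are ranked by
their mean expression across cells and split into bins; each signature gene
contributes controls drawn at random from its own bin.  This controls for
the tendency of highly expressed genes to score high everywhere.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import SignatureSet, default_signatures

__all__ = ["module_score", "score_table", "classify_states", "STATE_ORDER"]

#: deterministic tie-break priority for state labels
STATE_ORDER = ("P", "PN", "N")


def module_score(
    norm: pd.DataFrame,
    sig: SignatureSet,
    n_bins: int = 25,
    n_ctrl: int | None = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control signature score per cell (genes x cells input).

    ``n_ctrl`` controls are drawn per signature gene from its expression bin
    (with replacement when the bin holds fewer genes; without otherwise);
    ``n_ctrl=None`` uses the gene's whole bin.  Deterministic given ``seed``.
    Signature genes absent from the matrix warn and are dropped; an empty
    intersection is an error.
    """
    genes = [g for g in sig.genes if g in norm.index]
    absent = [g for g in sig.genes if g not in norm.index]
    if absent:
        warnings.warn(f"signature '{sig.name}': genes absent, dropped: {absent}")
    if not genes:
        raise ValueError(f"signature '{sig.name}': no genes present in matrix")

    X = norm.to_numpy(dtype=float)
    gene_mean = X.mean(axis=1)
    order = np.argsort(gene_mean, kind="mergesort")
    bin_of = np.empty(norm.shape[0], dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(norm.index)}
    sig_idx = np.array([gene_pos[g] for g in genes])
    ctrl_idx: list[np.ndarray] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        if n_ctrl is None:
            draw = pool
        else:
            replace = pool.size < n_ctrl
            draw = rng.choice(pool, size=n_ctrl, replace=replace)
        ctrl_idx.append(draw)
    ctrl = np.concatenate(ctrl_idx)
    score = X[sig_idx].mean(axis=0) - X[ctrl].mean(axis=0)
    return pd.Series(score, index=norm.columns, name=f"score_{sig.name}")


def score_table(
    norm: pd.DataFrame,
    signatures: dict[str, SignatureSet] | None = None,
    n_bins: int = 25,
    n_ctrl: int | None = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """P / N / PN scores per cell plus the argmax state label."""
    signatures = signatures or default_signatures()
    cols = {}
    for i, (name, sig) in enumerate(signatures.items()):
        cols[f"score_{name}"] = module_score(norm, sig, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i)
    table = pd.DataFrame(cols)
    table["state_label"] = classify_states(table)
    return table


def classify_states(scores: pd.DataFrame) -> pd.Series:
    """Argmax of z-scored (score_P, score_PN, score_N); ties break P > PN > N."""
    cols = [f"score_{s}" for s in STATE_ORDER]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ValueError(f"missing score columns: {missing}")
    Z = np.empty((len(scores), len(cols)))
    for j, c in enumerate(cols):
        v = scores[c].to_numpy(dtype=float)
        sd = v.std()
        Z[:, j] = (v - v.mean()) / sd if sd > 0 else 0.0
    # argmax returns the first maximal index; column order encodes the tie-break
    labels = np.asarray(STATE_ORDER, dtype=object)[np.argmax(Z, axis=1)]
    return pd.Series(labels, index=scores.index, name="state_label")
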