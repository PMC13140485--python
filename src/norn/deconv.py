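"""Reference-based spot deconvolution by Poisson mixture maximum likelihood.

Each spot's counts are modelled as depth * sum_k w_jk s_gk, a probabilistic
mixture of an unknown number of cells of the reference types: w_j lives on
the simplex and s_k are reference signatures normalized to sum 1 over
genes. The simplex-constrained Poisson (equivalently multinomial) MLE is
found with multiplicative EM updates, which preserve the simplex exactly
and increase the log-likelihood monotonically at every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from norn.spots import _dense_counts

logger = logging.getLogger(__name__)

_EPS = 1e-12


def load_signatures(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and row-normalize a (cell types x genes) signature table."""
    if (df.to_numpy() < 0).any():
        raise ValueError("signatures must be non-negative")
    sums = df.sum(axis=1)
    if (sums <= 0).any():
        bad = sums[sums <= 0].index.tolist()
        raise ValueError(f"signature rows with zero total: {bad}")
    return df.div(sums, axis=0)


@dataclass
class ProportionMatrix:
    """Fitted spot compositions with convergence diagnostics."""

    weights: pd.DataFrame  # spots x cell types, rows on the simplex
    converged: pd.Series
    log_likelihood: pd.Series  # final multinomial log-likelihood per spot
    n_iter: int
    genes_used: list[str]

    @property
    def cell_types(self) -> list[str]:
        return list(self.weights.columns)


def _select_genes(
    X: np.ndarray, gene_idx: pd.Index, ref: pd.DataFrame, var_quantile: float, min_genes: int
) -> np.ndarray:
    shared = gene_idx.intersection(ref.columns)
    if len(shared) < min_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between counts and reference; "
            f"need at least {min_genes}"
        )
    pos = gene_idx.get_indexer(shared)
    var = X[:, pos].var(axis=0)
    k = max(int(np.ceil(len(shared) * (1.0 - var_quantile))), min_genes)
    keep = np.argsort(-var, kind="stable")[:k]
    return pos[np.sort(keep)]


def fit_proportions(
    counts,
    ref: pd.DataFrame,
    max_iter: int = 500,
    tol: float = 1e-8,
    var_quantile: float = 0.5,
    min_genes: int = 25,
) -> ProportionMatrix:
    """Maximum-likelihood cell-type proportions for every spot.

    Genes are restricted to those shared with the reference and, by
    default, to the top half by count variance (``var_quantile=0.5``;
    set 0 to keep all shared genes). Weights start uniform, so the fit is
    deterministic; iteration stops at a relative log-likelihood change
    below ``tol`` or at ``max_iter`` (non-convergence is flagged per spot,
    not fatal).
    """
    X, spot_idx, gene_idx = _dense_counts(counts)
    ref = load_signatures(ref)
    use = _select_genes(X, gene_idx, ref, var_quantile, min_genes)
    genes_used = list(gene_idx[use])

    Xs = X[:, use]
    S = ref[genes_used].to_numpy()  # K x G on the selected panel
    S = S / np.maximum(S.sum(axis=1, keepdims=True), _EPS)  # renormalize on panel
    n, K = Xs.shape[0], S.shape[0]

    W = np.full((n, K), 1.0 / K)
    totals = Xs.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every spot must have positive depth on the shared gene panel")

    def loglik(W):
        M = W @ S
        return (Xs * np.log(np.maximum(M, _EPS))).sum(axis=1)

    ll = loglik(W)
    converged = np.zeros(n, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        M = np.maximum(W @ S, _EPS)
        W = W * ((Xs / M) @ S.T)
        W /= W.sum(axis=1, keepdims=True)
        new_ll = loglik(W)
        rel = np.abs(new_ll - ll) / np.maximum(np.abs(ll), 1.0)
        converged = rel < tol
        ll = new_ll
        if converged.all():
            break
    if not converged.all():
        logger.warning("%d spots did not converge in %d iterations", int((~converged).sum()), max_iter)

    return ProportionMatrix(
        weights=pd.DataFrame(W, index=spot_idx, columns=ref.index),
        converged=pd.Series(converged, index=spot_idx),
        log_likelihood=pd.Series(ll, index=spot_idx),
        n_iter=it,
        genes_used=genes_used,
    )


def em_trajectory(x: np.ndarray, S: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Log-likelihood trace of the EM updates for a single spot; exposed so
    monotonicity can be checked directly."""
    x = np.asarray(x, dtype=float)
    S = np.asarray(S, dtype=float)
    S = S / np.maximum(S.sum(axis=1, keepdims=True), _EPS)
    K = S.shape[0]
    w = np.full(K, 1.0 / K)
    trace = []
    for _ in range(n_iter):
        m = np.maximum(w @ S, _EPS)
        trace.append(float((x * np.log(m)).sum()))
        w = w * (S @ (x / m))
        w /= w.sum()
    trace.append(float((x * np.log(np.maximum(w @ S, _EPS))).sum()))
    return np.asarray(trace)


def dominant_type(props: ProportionMatrix | pd.DataFrame, min_weight: float | None = None) -> pd.Series:
    """Most abundant cell type per spot (argmax weight).

    Ties break to the earlier type in column order. With ``min_weight``,
    spots whose top weight falls below the floor are labelled ``"mixed"``.
    """
    W = props.weights if isinstance(props, ProportionMatrix) else props
    arr = W.to_numpy()
    idx = np.argmax(arr, axis=1)  # first maximum wins: deterministic tie rule
    labels = pd.Series(np.asarray(W.columns)[idx], index=W.index, name="dominant_type")
    if min_weight is not None:
        labels[arr.max(axis=1) < min_weight] = "mixed"
    return labels


def composition_profile(
    props: ProportionMatrix | pd.DataFrame, selection
) -> pd.DataFrame:
    """Per-type weight distribution over a spot selection.

    Five-number summary plus mean of each cell type's weight across the
    selected spots (e.g. the Epo+ spots); the mean column doubles as the
    pie-style average composition of the subset. Empty selections are an
    error.
    """
    W = props.weights if isinstance(props, ProportionMatrix) else props
    mask = getattr(selection, "mask", selection)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty spot selection")
    sub = W.to_numpy()[mask]
    return pd.DataFrame(
        {
            "mean": sub.mean(axis=0),
            "min": sub.min(axis=0),
            "q25": np.percentile(sub, 25, axis=0),
            "median": np.median(sub, axis=0),
            "q75": np.percentile(sub, 75, axis=0),
            "max": sub.max(axis=0),
            "n_selected": int(mask.sum()),
        },
        index=pd.Index(W.columns, name="cell_type"),
    )
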