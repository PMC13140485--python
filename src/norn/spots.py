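"""Spot-level normalization, Epo+ spot selection and differential expression.

Counts are variance-stabilized into negative-binomial Pearson residuals
under a depth-offset model: per gene g and spot j the expected count is
mu_gj = exp(beta_g) * m_j with m_j the spot depth, the per-gene
overdispersion theta_g is estimated by method of moments and regularized by
kernel-smoothing log theta against log mean expression, and residuals
r_gj = (x_gj - mu_gj) / sqrt(mu_gj + mu_gj^2 / theta_g) are clipped to
+/- sqrt(n_spots). Spots positive for a gene (canonically Epo) are selected
by a strict residual threshold (> 0.8), and groups of spots are compared
by a rank-sum test on residuals with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_THETA_MAX = 1e6
_THETA_MIN = 1e-3


@dataclass
class ResidualMatrix:
    """Clipped NB Pearson residuals with the fitted per-gene model."""

    residuals: pd.DataFrame  # spots x genes
    gene_mean: pd.Series  # fitted exp(beta_g), counts per unit depth
    theta: pd.Series  # regularized dispersion
    clip: float

    @property
    def genes(self) -> pd.Index:
        return self.residuals.columns


def _dense_counts(counts, genes=None, spots=None) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Coerce AnnData / DataFrame / array input to (spots x genes) dense."""
    if isinstance(counts, AnnData):
        X = counts.X
        X = X.toarray() if sparse.issparse(X) else np.asarray(X)
        return X.astype(float), counts.obs_names, counts.var_names
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts.index, counts.columns
    X = np.asarray(counts, dtype=float)
    spots = pd.RangeIndex(X.shape[0]) if spots is None else pd.Index(spots)
    genes = pd.RangeIndex(X.shape[1]) if genes is None else pd.Index(genes)
    return X, spots, genes


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1e-3)
    return 0.9 * scale * n ** (-0.2)


def _regularize_theta(theta_raw: np.ndarray, log_mean: np.ndarray) -> np.ndarray:
    """Gaussian-kernel regression of log10 theta on log10 mean expression."""
    logt = np.log10(np.clip(theta_raw, _THETA_MIN, _THETA_MAX))
    if len(logt) < 3 or np.allclose(log_mean, log_mean[0]):
        return 10.0 ** np.full_like(logt, np.median(logt))
    bw = _silverman_bandwidth(log_mean)
    d = log_mean[:, None] - log_mean[None, :]
    w = np.exp(-0.5 * (d / bw) ** 2)
    smoothed = (w @ logt) / w.sum(axis=1)
    return 10.0**smoothed


def pearson_residuals(counts, clip: float | None = None) -> ResidualMatrix:
    """Depth-offset NB Pearson residuals with regularized dispersion.

    Accepts an AnnData (spots x genes), DataFrame or array. Genes with zero
    total count get all-zero residual rows and are excluded from dispersion
    regularization (logged). The clip bound defaults to sqrt(n_spots).
    """
    X, spot_idx, gene_idx = _dense_counts(counts)
    n_spots, n_genes = X.shape
    if n_spots < 2:
        raise ValueError("need at least 2 spots")
    depth = X.sum(axis=1)
    if np.any(depth <= 0):
        raise ValueError("every spot must have positive depth")
    if clip is None:
        clip = float(np.sqrt(n_spots))

    total = depth.sum()
    gene_tot = X.sum(axis=0)
    expressed = gene_tot > 0
    if (~expressed).any():
        logger.info("%d genes with zero total count: residuals set to 0", int((~expressed).sum()))

    # mu_gj = exp(beta_g) * m_j; Poisson/NB MLE of the intercept under the
    # depth offset is total_g / total depth
    rate = np.zeros(n_genes)
    rate[expressed] = gene_tot[expressed] / total
    mu = depth[:, None] * rate[None, :]

    # method-of-moments theta per gene, then kernel regularization
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (mu**2).sum(axis=0)
        den = ((X - mu) ** 2 - mu).sum(axis=0)
    theta_raw = np.full(n_genes, _THETA_MAX)
    pos = expressed & (den > 0)
    theta_raw[pos] = np.clip(num[pos] / den[pos], _THETA_MIN, _THETA_MAX)

    theta = np.full(n_genes, _THETA_MAX)
    if expressed.sum() >= 1:
        log_mean = np.log10(gene_tot[expressed] / n_spots)
        theta[expressed] = _regularize_theta(theta_raw[expressed], log_mean)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(mu + mu**2 / theta[None, :])
        res = np.where(denom > 0, (X - mu) / np.where(denom > 0, denom, 1.0), 0.0)
    res = np.clip(res, -clip, clip)
    res[:, ~expressed] = 0.0

    return ResidualMatrix(
        residuals=pd.DataFrame(res, index=spot_idx, columns=gene_idx),
        gene_mean=pd.Series(rate, index=gene_idx, name="rate"),
        theta=pd.Series(theta, index=gene_idx, name="theta"),
        clip=clip,
    )


def normalize(adata: AnnData, clip: float | None = None) -> ResidualMatrix:
    """Compute residuals for an AnnData and store them in
    ``adata.layers['pearson_residuals']`` (plus per-gene fit in ``var``)."""
    rm = pearson_residuals(adata, clip=clip)
    adata.layers["pearson_residuals"] = rm.residuals.to_numpy()
    adata.var["sct_rate"] = rm.gene_mean.to_numpy()
    adata.var["sct_theta"] = rm.theta.to_numpy()
    adata.uns["sct_clip"] = rm.clip
    return rm


@dataclass
class SpotSelection:
    """Boolean spot mask from a strict residual threshold on one gene."""

    mask: np.ndarray
    gene: str
    threshold: float

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def select_positive_spots(
    residuals: ResidualMatrix | pd.DataFrame, gene: str, threshold: float = 0.8
) -> SpotSelection:
    """Select spots with normalized expression strictly above the threshold
    (the canonical rule: Epo residual > 0.8). 0.80 is excluded, 0.81 is
    selected."""
    df = residuals.residuals if isinstance(residuals, ResidualMatrix) else residuals
    if gene not in df.columns:
        raise ValueError(f"gene {gene!r} not present")
    mask = df[gene].to_numpy(dtype=float) > threshold
    return SpotSelection(mask=mask, gene=gene, threshold=threshold)


def marker_panel_summary(
    residuals: ResidualMatrix | pd.DataFrame,
    selection: SpotSelection | np.ndarray,
    panel: list[str],
) -> pd.DataFrame:
    """Distribution of panel-gene expression in selected spots, on the
    all-spots z-scale.

    Residuals are z-standardized per gene over ALL spots (mean 0, SD 1);
    the five-number summary plus mean is then taken within the selection,
    so values above zero mean above-average expression relative to every
    spot on the slide. Absent panel genes are reported in the log and
    skipped; an empty selection is an error.
    """
    df = residuals.residuals if isinstance(residuals, ResidualMatrix) else residuals
    mask = selection.mask if isinstance(selection, SpotSelection) else np.asarray(selection, bool)
    if mask.sum() == 0:
        raise ValueError("empty spot selection")
    present = [g for g in panel if g in df.columns]
    absent = [g for g in panel if g not in df.columns]
    if absent:
        logger.warning("panel genes absent from matrix: %s", absent)
    if not present:
        raise ValueError("no panel genes present")

    sub = df[present].to_numpy(dtype=float)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (sub - mean) / sd
    zs = z[mask]
    summary = pd.DataFrame(
        {
            "mean": zs.mean(axis=0),
            "min": zs.min(axis=0),
            "q25": np.percentile(zs, 25, axis=0),
            "median": np.median(zs, axis=0),
            "q75": np.percentile(zs, 75, axis=0),
            "max": zs.max(axis=0),
            "n_selected": int(mask.sum()),
        },
        index=pd.Index(present, name="gene"),
    )
    return summary


def differential_expression(
    residuals: ResidualMatrix | pd.DataFrame,
    counts,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_spots: int = 5,
) -> pd.DataFrame:
    """Rank-sum differential expression between two spot groups.

    Per gene: two-sided Mann-Whitney rank-sum on residuals, BH-adjusted q,
    the residual-mean difference (A - B) as effect size, and the log2 fold
    change of depth-normalized mean counts (pseudocount 1 per 10k). Genes
    detected in fewer than ``min_spots`` spots are flagged (column
    ``low_detection``), not dropped. Groups of size < 3 trigger a warning
    and the exact rank-sum null.
    """
    df = residuals.residuals if isinstance(residuals, ResidualMatrix) else residuals
    X, _, gene_idx = _dense_counts(counts)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if group_a.sum() == 0 or group_b.sum() == 0:
        raise ValueError("both groups must be non-empty")

    ra = df.to_numpy(dtype=float)[group_a]
    rb = df.to_numpy(dtype=float)[group_b]
    method = "auto"
    if min(group_a.sum(), group_b.sum()) < 3:
        warnings.warn(
            "a group has fewer than 3 spots; using the exact rank-sum null",
            stacklevel=2,
        )
        method = "exact"
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(ra, rb, axis=0, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # constant genes: no evidence

    depth = X.sum(axis=1)
    cpa = X[group_a].sum(axis=0) / depth[group_a].sum() * 1e4
    cpb = X[group_b].sum(axis=0) / depth[group_b].sum() * 1e4
    lfc = np.log2((cpa + 1.0) / (cpb + 1.0))
    q = benjamini_hochberg(p)

    table = pd.DataFrame(
        {
            "delta_residual": ra.mean(axis=0) - rb.mean(axis=0),
            "log2_fc": lfc,
            "p": p,
            "q": q,
            "low_detection": (X > 0).sum(axis=0) < min_spots,
        },
        index=pd.Index(df.columns, name="gene"),
    )
    return table.sort_values(["q", "p"], kind="stable")


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
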