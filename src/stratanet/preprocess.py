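"""Count filtering, normalisation, unwanted-variation estimation,
sample-outlier detection and covariate adjustment.

The processing chain mirrors standard bulk RNA-seq practice for
case/control brain cohorts: genes expressed at low levels in any
(sex, phenotype) group are removed, counts are transformed to log2
counts-per-million, a factor of unwanted variation is estimated from
spike-in control genes by SVD, samples with anomalously low standardized
network connectivity are flagged, and technical/clinical covariates are
regressed out before network construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "NormalizedExpression",
    "filter_low_expression",
    "log_cpm",
    "estimate_unwanted_factors",
    "detect_outlier_samples",
    "adjust_covariates",
]


@dataclass
class ExpressionStudy:
    """A count matrix with sample metadata; the pipeline's universal input.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``metadata`` is indexed by sample id and aligned with the columns of
    ``counts``; ``control_gene_ids`` names spike-in genes assumed to carry
    only unwanted variation.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    control_gene_ids: list = field(default_factory=list)
    removed_genes: list = field(default_factory=list)

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if list(self.counts.columns) != list(self.metadata.index):
            raise ValueError("counts columns and metadata index disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.control_gene_ids) - set(self.counts.index)
        if missing:
            raise ValueError(f"control genes absent from matrix: {sorted(missing)}")

    @property
    def gene_ids(self):
        return list(self.counts.index)

    @property
    def sample_ids(self):
        return list(self.counts.columns)

    def subset_samples(self, sample_ids) -> "ExpressionStudy":
        sample_ids = list(sample_ids)
        return ExpressionStudy(
            counts=self.counts[sample_ids],
            metadata=self.metadata.loc[sample_ids],
            control_gene_ids=list(self.control_gene_ids),
            removed_genes=list(self.removed_genes),
        )


@dataclass
class NormalizedExpression:
    """log2-CPM expression with optional precision weights and estimated
    unwanted-variation factors (samples x k)."""

    logexpr: pd.DataFrame
    metadata: pd.DataFrame
    weights: pd.DataFrame | None = None
    unwanted_factors: pd.DataFrame | None = None
    control_gene_ids: list = field(default_factory=list)

    @property
    def gene_ids(self):
        return list(self.logexpr.index)

    @property
    def sample_ids(self):
        return list(self.logexpr.columns)

    def subset_samples(self, sample_ids) -> "NormalizedExpression":
        sample_ids = list(sample_ids)
        return NormalizedExpression(
            logexpr=self.logexpr[sample_ids],
            metadata=self.metadata.loc[sample_ids],
            weights=None if self.weights is None else self.weights[sample_ids],
            unwanted_factors=(
                None
                if self.unwanted_factors is None
                else self.unwanted_factors.loc[sample_ids]
            ),
            control_gene_ids=list(self.control_gene_ids),
        )


def filter_low_expression(
    study: ExpressionStudy, min_count: int = 5, low_fraction: float = 0.20
) -> ExpressionStudy:
    """Remove genes expressed at low levels in any (sex, phenotype) group.

    A gene is removed iff, in at least one group, the fraction of samples
    with fewer than ``min_count`` reads is >= ``low_fraction``.  The
    strictest reading of the per-group rule: failing one group is enough.
    """
    meta = study.metadata
    groups = meta.groupby(["sex", "phenotype"], observed=True).groups
    for key, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {key}")
    counts = study.counts
    drop = np.zeros(len(counts), dtype=bool)
    for key, idx in groups.items():
        sub = counts[list(idx)].to_numpy()
        frac_low = (sub < min_count).mean(axis=1)
        drop |= frac_low >= low_fraction
    kept = counts.index[~drop]
    removed = list(counts.index[drop])
    logger.info("filter_low_expression: removed %d/%d genes", len(removed), len(counts))
    return ExpressionStudy(
        counts=counts.loc[kept],
        metadata=meta,
        control_gene_ids=[g for g in study.control_gene_ids if g in set(kept)],
        removed_genes=removed,
    )


def log_cpm(
    study: ExpressionStudy, prior_count: float = 0.5, compute_weights: bool = False
) -> NormalizedExpression:
    """log2 counts-per-million with a prior count.

    ``logexpr[g, s] = log2((count + prior) / (libsize + 2 * prior) * 1e6)``.

    With ``compute_weights`` the mean-variance trend is modelled as in
    voom: per-gene sqrt residual standard deviations are lowess-smoothed
    against mean log2 count, the trend is interpolated at each
    observation's fitted log2 count and inverted to a precision weight.
    The default keeps weights off so that the same unweighted matrix
    feeds both differential expression and network construction.
    """
    counts = study.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, l in zip(study.sample_ids, lib) if l <= 0]
        raise ValueError(f"zero library size for samples: {bad}")
    logexpr = np.log2((counts + prior_count) / (lib + 2 * prior_count)[None, :] * 1e6)
    logexpr = pd.DataFrame(logexpr, index=study.counts.index, columns=study.counts.columns)
    weights = None
    if compute_weights:
        weights = _voom_like_weights(counts, lib, logexpr.to_numpy())
        weights = pd.DataFrame(weights, index=logexpr.index, columns=logexpr.columns)
    return NormalizedExpression(
        logexpr=logexpr,
        metadata=study.metadata,
        weights=weights,
        control_gene_ids=list(study.control_gene_ids),
    )


def _voom_like_weights(counts, lib, logexpr):
    from statsmodels.nonparametric.smoothers_lowess import lowess

    mean_logcpm = logexpr.mean(axis=1)
    mean_logcount = mean_logcpm + np.log2(lib.mean()) - np.log2(1e6)
    sd = logexpr.std(axis=1, ddof=1)
    sqrt_sd = np.sqrt(np.maximum(sd, 1e-12))
    fit = lowess(sqrt_sd, mean_logcount, frac=0.5, return_sorted=True)
    fx, fy = fit[:, 0], np.maximum(fit[:, 1], 1e-6)
    # per-observation fitted log-count, then interpolate the trend
    obs_logcount = logexpr + np.log2(lib)[None, :] - np.log2(1e6)
    trend = np.interp(obs_logcount, fx, fy)
    return 1.0 / trend**4


def estimate_unwanted_factors(
    norm: NormalizedExpression, control_gene_ids=None, k: int = 1
) -> NormalizedExpression:
    """Estimate k factors of unwanted variation from control genes.

    The samples x controls matrix of gene-centred log expression is
    decomposed by SVD; the first ``k`` left singular vectors are stored in
    ``unwanted_factors``.  Sign convention: the first nonzero entry of
    each factor is positive.  This is the control-gene (RUVg-style)
    variant; the first factor is the one carried into downstream designs.
    """
    if control_gene_ids is None:
        control_gene_ids = norm.control_gene_ids
    control_gene_ids = [g for g in control_gene_ids if g in norm.logexpr.index]
    if k >= len(control_gene_ids):
        raise ValueError(
            f"k={k} requires more than {len(control_gene_ids)} control genes"
        )
    X = norm.logexpr.loc[control_gene_ids].to_numpy().T  # samples x controls
    X = X - X.mean(axis=0, keepdims=True)  # centre each control gene
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    W = U[:, :k] * s[:k]
    for j in range(k):
        col = W[:, j]
        nz = np.flatnonzero(col != 0)
        if nz.size and col[nz[0]] < 0:
            W[:, j] = -col
    factors = pd.DataFrame(
        W, index=norm.sample_ids, columns=[f"W{j + 1}" for j in range(k)]
    )
    return NormalizedExpression(
        logexpr=norm.logexpr,
        metadata=norm.metadata,
        weights=norm.weights,
        unwanted_factors=factors,
        control_gene_ids=list(norm.control_gene_ids),
    )


def detect_outlier_samples(
    norm: NormalizedExpression, z_threshold: float = -3.5
) -> list:
    """Flag samples whose standardized sample-network connectivity Z.k is
    strictly below ``z_threshold``.

    The sample network is built from Euclidean distance on log expression
    with adjacency ``1 - dist / max(dist)``; connectivity is the row sum
    excluding self.
    """
    X = norm.logexpr.to_numpy().T  # samples x genes
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    dist = np.sqrt(d2)
    dmax = dist.max()
    if dmax == 0:
        warnings.warn("degenerate sample network: all samples identical")
        return []
    adj = 1.0 - dist / dmax
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    sd = k.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate sample network: connectivity has zero variance")
        return []
    zk = (k - k.mean()) / sd
    return [s for s, z in zip(norm.sample_ids, zk) if z < z_threshold]


def _build_design(metadata: pd.DataFrame, covariate_names, unwanted_factors=None):
    """Design matrix for covariate adjustment: intercept, one-hot categorical
    contrasts (lexicographic levels, first as reference), numeric columns
    as-is, plus any unwanted-variation factors."""
    n = len(metadata)
    cols = {"intercept": np.ones(n)}
    for name in covariate_names:
        if name not in metadata.columns:
            raise ValueError(f"covariate {name!r} absent from metadata")
        col = metadata[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).to_numpy(float)
        else:
            cols[name] = col.to_numpy(dtype=float)
    if unwanted_factors is not None:
        for c in unwanted_factors.columns:
            cols[str(c)] = unwanted_factors[c].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate collinear columns by incremental rank
        bad = []
        acc = []
        for j, name in enumerate(names):
            trial = np.column_stack(acc + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(acc) + 1:
                acc.append(X[:, j])
            else:
                bad.append(name)
        raise ValueError(f"collinear covariate design; redundant columns: {bad}")
    return X, names


def adjust_covariates(
    norm: NormalizedExpression, covariate_names, metadata: pd.DataFrame | None = None
) -> NormalizedExpression:
    """Regress covariates (and any stored unwanted-variation factors) out
    of every gene, preserving per-gene means.

    Intended for network construction; differential expression instead
    includes the covariates in its design.  With no covariates and no
    stored factors the input is returned unchanged.
    """
    if metadata is None:
        metadata = norm.metadata
    if not covariate_names and norm.unwanted_factors is None:
        return norm
    X, _ = _build_design(metadata, covariate_names, norm.unwanted_factors)
    Y = norm.logexpr.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid.T + norm.logexpr.to_numpy().mean(axis=1, keepdims=True)
    return NormalizedExpression(
        logexpr=pd.DataFrame(
            adjusted, index=norm.logexpr.index, columns=norm.logexpr.columns
        ),
        metadata=norm.metadata,
        weights=norm.weights,
        unwanted_factors=norm.unwanted_factors,
        control_gene_ids=list(norm.control_gene_ids),
    )
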