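"""Per-gene linear models, DEG calling, signed ranking metric, DEG
overlap statistics and top-DEG hierarchical clustering.

Each gene is fit by ordinary least squares against a design with sex and
phenotype as factors (optionally their interaction) plus covariates.  By
default residual variances are moderated towards a common prior by an
empirical-Bayes method-of-moments scheme: the prior degrees of freedom
and prior variance are estimated from the spread of log sample variances
(matching the distributional identities of the scaled-inverse-chi-square
model), posterior variances are the df-weighted blend, and t statistics
are recomputed with augmented degrees of freedom.  Significance is
nominal — DEGs are genes with p <= 0.05, uncorrected — and the ranking
metric used for overlap maps is -log10(p) signed by the t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .preprocess import NormalizedExpression, _build_design

__all__ = [
    "DesignSpec",
    "DEResult",
    "fit_gene_models",
    "de_within_sex",
    "call_degs",
    "overlap_degs",
    "OverlapStats",
    "cluster_top_degs",
    "ClusterResult",
]

P_FLOOR = 1e-300  # protects -log10(p) from p == 0


@dataclass(frozen=True)
class DesignSpec:
    """Model specification for per-gene linear fits.

    ``factors`` are metadata columns treated as categorical main effects
    (lexicographic first level as reference); ``interaction=True`` adds
    the sex x phenotype product term; ``covariates`` enter as given
    (categoricals one-hot).  ``contrast`` names a design coefficient or
    supplies an explicit coefficient vector.
    """

    factors: tuple = ("sex", "phenotype")
    interaction: bool = False
    covariates: tuple = ()
    contrast: object = "phenotype[MDD]"
    include_unwanted: bool = True


@dataclass
class DEResult:
    """Per-gene differential-expression summary for one contrast."""

    table: pd.DataFrame  # columns: log2fc, t, p, rank_metric
    df_residual: float
    df_prior: float
    moderated: bool
    contrast_name: str

    @property
    def log2fc(self):
        return self.table["log2fc"]

    @property
    def p(self):
        return self.table["p"]

    @property
    def rank_metric(self):
        return self.table["rank_metric"]

    def ranked_genes(self):
        """Gene ids ordered by rank metric descending, ties lexicographic."""
        rm = self.table["rank_metric"]
        return sorted(self.table.index, key=lambda g: (-rm.at[g], g))


def _design_matrix(norm: NormalizedExpression, design: DesignSpec):
    meta = norm.metadata
    cov = list(design.covariates)
    X, names = _build_design(
        meta,
        list(design.factors) + cov,
        norm.unwanted_factors if design.include_unwanted else None,
    )
    if design.interaction:
        fa, fb = design.factors[0], design.factors[1]
        cols_a = [i for i, n in enumerate(names) if n.startswith(f"{fa}[")]
        cols_b = [i for i, n in enumerate(names) if n.startswith(f"{fb}[")]
        extra, extra_names = [], []
        for i in cols_a:
            for j in cols_b:
                extra.append(X[:, i] * X[:, j])
                extra_names.append(f"{names[i]}:{names[j]}")
        if extra:
            X = np.column_stack([X] + extra)
            names = names + extra_names
    return X, names


def _contrast_vector(contrast, names):
    if isinstance(contrast, str):
        if contrast not in names:
            raise ValueError(
                f"contrast {contrast!r} not among coefficients {names}"
            )
        c = np.zeros(len(names))
        c[names.index(contrast)] = 1.0
        return c, contrast
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(names),):
        raise ValueError("contrast vector length does not match design")
    return c, "custom"


def _fit_inverse_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in the standard
    empirical-Bayes variance-shrinkage derivation)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def moments_prior(s2: np.ndarray, df: float):
    """Method-of-moments estimate of (prior df, prior variance) from the
    sample variances of a family of genes sharing residual df.

    Under s2_g ~ s0^2 * chi^2_df / df scaled by gene variances drawn from a
    scaled inverse chi-square with d0 df, log s2 has variance
    trigamma(df/2) + trigamma(d0/2) and mean log s0^2 + digamma shifts.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e_gamma = special.digamma(df / 2) - np.log(df / 2)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(z.mean() - e_gamma))
    d0 = 2 * _fit_inverse_trigamma(evar)
    mean_z = z.mean()
    log_s0 = mean_z - e_gamma + (special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(np.exp(log_s0))


def fit_gene_models(
    norm: NormalizedExpression, design: DesignSpec | None = None, moderate: bool = True
) -> DEResult:
    """OLS per gene for one contrast, optionally variance-moderated.

    Returns a :class:`DEResult` with log2 fold change (the contrast
    estimate), t statistic, p value and the signed ranking metric
    ``-log10(p) * sign(t)``.
    """
    if design is None:
        design = DesignSpec()
    X, names = _design_matrix(norm, design)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"{n} samples cannot identify {k} coefficients")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    c, cname = _contrast_vector(design.contrast, names)
    Y = norm.logexpr.to_numpy().T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - k
    s2 = (resid**2).sum(axis=0) / df
    effect = c @ beta
    c_var = float(c @ XtX_inv @ c)

    d0 = 0.0
    if moderate:
        d0, s0_2 = moments_prior(s2, df)
        if np.isinf(d0):
            post_s2 = np.full_like(s2, s0_2)
        else:
            post_s2 = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + (0.0 if np.isinf(d0) else d0)
    else:
        post_s2 = s2
        df_total = df
    zero_var = post_s2 <= 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} genes with zero residual variance")
        post_s2 = np.where(zero_var, np.finfo(float).tiny, post_s2)
    se = np.sqrt(post_s2 * c_var)
    t = effect / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, P_FLOOR, 1.0)
    rank_metric = -np.log10(p) * np.sign(t)
    table = pd.DataFrame(
        {"log2fc": effect, "t": t, "p": p, "rank_metric": rank_metric},
        index=norm.logexpr.index,
    )
    return DEResult(
        table=table,
        df_residual=float(df),
        df_prior=float(d0) if moderate else 0.0,
        moderated=moderate,
        contrast_name=cname,
    )


def de_within_sex(
    norm: NormalizedExpression, sex: str, covariates=(), moderate: bool = True
) -> DEResult:
    """MDD - CTRL differential expression within one sex.

    Subsets the samples to ``sex`` and tests the phenotype coefficient,
    so male and female signatures are estimated with their own residual
    variances (equivalent to a full sex x phenotype interaction model
    with sex-specific dispersions).
    """
    ids = [s for s in norm.sample_ids if norm.metadata.at[s, "sex"] == sex]
    if not ids:
        raise ValueError(f"no samples with sex {sex!r}")
    sub = norm.subset_samples(ids)
    spec = DesignSpec(
        factors=("phenotype",), covariates=tuple(covariates),
        contrast="phenotype[MDD]",
    )
    return fit_gene_models(sub, spec, moderate=moderate)


def call_degs(de: DEResult, alpha: float = 0.05):
    """Nominal DEG call: p <= alpha (inclusive), split by fold-change sign.

    Returns ``{"up": set, "down": set}``; genes with log2fc == 0 at the
    threshold are not directional and are excluded from both sets.
    """
    sig = de.table[de.table["p"] <= alpha]
    up = set(sig.index[sig["log2fc"] > 0])
    down = set(sig.index[sig["log2fc"] < 0])
    return {"up": up, "down": down}


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    overlap: int
    jaccard_pct: float
    fisher_p: float
    odds_ratio: float


def overlap_degs(set_a, set_b, background_size: int) -> OverlapStats:
    """Overlap of two gene sets against a common background.

    Percentage is Jaccard (|A∩B| / |A∪B| * 100); p is a one-sided Fisher
    exact test for enrichment from the 2x2 membership table.
    """
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if background_size < len(union):
        raise ValueError("background smaller than the union of the sets")
    inter = len(set_a & set_b)
    table = [
        [inter, len(set_a) - inter],
        [len(set_b) - inter, background_size - len(union)],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    pct = 100.0 * inter / len(union) if union else 0.0
    return OverlapStats(
        n_a=len(set_a), n_b=len(set_b), overlap=inter,
        jaccard_pct=pct, fisher_p=float(p), odds_ratio=float(odds),
    )


@dataclass
class ClusterResult:
    genes: list
    gene_order: list
    sample_order: list
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    matrix: pd.DataFrame  # reordered for heat-mapping
    symptom_annotation: pd.DataFrame | None


def _corr_distance(X: np.ndarray, axis_ids) -> np.ndarray:
    """1 - Pearson correlation distance between rows; constant rows get
    zero correlation with everything (warned)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    const = norms == 0
    if const.any():
        warnings.warn(
            f"constant vectors set to zero correlation: "
            f"{[axis_ids[i] for i in np.flatnonzero(const)]}"
        )
    norms[const] = 1.0
    V = Xc / norms[:, None]
    corr = np.clip(V @ V.T, -1.0, 1.0)
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    return 1.0 - corr


def cluster_top_degs(
    norm: NormalizedExpression,
    de: DEResult,
    symptom_labels: pd.DataFrame | None = None,
    n_top: int = 200,
) -> ClusterResult:
    """Complete-linkage hierarchical clustering, on 1 - Pearson
    correlation, of the ``n_top`` strongest (smallest p) DEGs.

    Samples are clustered the same way on their profiles over those
    genes; the returned matrix is reordered on both axes, with symptom
    annotation carried along for heat-mapping.
    """
    if n_top > len(de.table):
        raise ValueError(f"n_top={n_top} exceeds {len(de.table)} genes")
    ranked = sorted(de.table.index, key=lambda g: (de.table.at[g, "p"], g))
    top = ranked[:n_top]
    X = norm.logexpr.loc[top].to_numpy()
    gene_d = _corr_distance(X, top)
    sample_d = _corr_distance(X.T, list(norm.sample_ids))
    gene_Z = hierarchy.linkage(squareform(gene_d, checks=False), method="complete")
    sample_Z = hierarchy.linkage(squareform(sample_d, checks=False), method="complete")
    gene_order = [top[i] for i in hierarchy.leaves_list(gene_Z)]
    sample_ids = list(norm.sample_ids)
    sample_order = [sample_ids[i] for i in hierarchy.leaves_list(sample_Z)]
    matrix = norm.logexpr.loc[gene_order, sample_order]
    ann = None
    if symptom_labels is not None:
        ann = symptom_labels.loc[sample_order]
    return ClusterResult(
        genes=top, gene_order=gene_order, sample_order=sample_order,
        gene_linkage=gene_Z, sample_linkage=sample_Z, matrix=matrix,
        symptom_annotation=ann,
    )
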