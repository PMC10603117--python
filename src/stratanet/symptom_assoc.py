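"""Association of binary clinical symptoms with module eigengenes and
individual genes, plus gene-set enrichment of modules.

Symptoms exist only for patients, so associations are computed within
the MDD samples of a sex stratum.  The module-level statistic is the
point-biserial correlation between the 0/1 symptom and the eigengene;
family-wise adjustment uses a max-T permutation scheme: the symptom
vector is permuted and the maximum |r| across modules recorded, giving
a single null distribution per symptom.  Gene significance (GS) is the
point-biserial of each gene with the symptom; GS-vs-kME correlation
within a module shows whether the genes driving the module also carry
the symptom signal.  Enrichment of modules for DEG or symptom-gene sets
uses one-sided Fisher exact tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "point_biserial",
    "module_symptom_association",
    "gene_significance",
    "gs_kme_correlation",
    "module_enrichment_fet",
    "gmt_enrichment",
    "read_gmt",
]


def point_biserial(symptom, values):
    """Point-biserial correlation of a 0/1 vector with continuous values.

    Mathematically identical to the Pearson correlation of the 0/1
    coding with the values; the parametric p comes from the t transform
    with n - 2 degrees of freedom.
    """
    y = np.asarray(symptom, dtype=float)
    x = np.asarray(values, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("symptom vector must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("constant symptom vector")
    if np.allclose(x, x[0]):
        raise ValueError("constant values vector")
    r, p = stats.pearsonr(y, x)
    return float(r), float(p)


def _pb_matrix(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorised point-biserial r of binary y with each column of X.
    Constant columns get r = 0."""
    yc = y - y.mean()
    yn = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=0, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=0))
    const = xn == 0
    xn[const] = 1.0
    r = (yc @ Xc) / (yn * xn)
    r[const] = 0.0
    return np.clip(r, -1.0, 1.0)


@dataclass
class AssociationRecord:
    module: str
    symptom: str
    sex: str
    r_pb: float
    p_perm: float
    n_used: int


def module_symptom_association(
    ME: pd.DataFrame,
    symptoms: pd.DataFrame,
    sex_stratum: str = "pooled",
    n_perm: int = 1000,
    seed: int = 0,
    min_class_size: int = 3,
):
    """Point-biserial ME-symptom associations with max-T permutation p.

    ``ME`` rows must already be restricted to the MDD samples of the
    stratum; ``symptoms`` is aligned, one 0/1/NA column per symptom.
    For each symptom, samples with missing values are dropped, both
    classes must have at least ``min_class_size`` members, and the same
    ``n_perm`` permutations serve every module: each permutation records
    the maximum |r| across modules, so ``p_perm`` is family-wise
    adjusted.  Returns (table, skipped) where skipped records symptoms
    not tested and why.
    """
    rng = np.random.default_rng(seed)
    records, skipped = [], {}
    for sym in symptoms.columns:
        col = symptoms[sym]
        mask = col.notna()
        ids = list(symptoms.index[mask])
        y = col[mask].astype(float).to_numpy()
        n0, n1 = int((y == 0).sum()), int((y == 1).sum())
        if n0 < min_class_size or n1 < min_class_size:
            skipped[sym] = f"class sizes {n0}/{n1} below minimum {min_class_size}"
            continue
        X = ME.loc[ids].to_numpy(dtype=float)
        r_obs = _pb_matrix(y, X)
        null_max = np.empty(n_perm)
        for b in range(n_perm):
            null_max[b] = np.abs(_pb_matrix(rng.permutation(y), X)).max()
        for j, mod in enumerate(ME.columns):
            p_perm = (1 + int((null_max >= abs(r_obs[j])).sum())) / (n_perm + 1)
            records.append(
                AssociationRecord(
                    module=str(mod), symptom=str(sym), sex=sex_stratum,
                    r_pb=float(r_obs[j]), p_perm=float(p_perm), n_used=len(y),
                )
            )
    table = pd.DataFrame([vars(r) for r in records])
    return table, skipped


def gene_significance(expr: pd.DataFrame, symptom: pd.Series, alpha: float = 0.05):
    """Per-gene point-biserial GS with a symptom.

    Returns (GS: Series, associated: set of genes with nominal parametric
    p < alpha, flags: Series marking constant genes whose GS is set to 0).
    """
    mask = symptom.notna()
    ids = list(symptom.index[mask])
    y = symptom[mask].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("constant symptom vector")
    X = expr[ids].to_numpy(dtype=float).T  # samples x genes
    const = X.std(axis=0) == 0
    gs = _pb_matrix(y, X)
    n = len(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = gs * np.sqrt((n - 2) / np.maximum(1 - gs**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[const] = 1.0
    GS = pd.Series(gs, index=expr.index, name="GS")
    flags = pd.Series(const, index=expr.index, name="constant_gene")
    if const.any():
        warnings.warn(f"{int(const.sum())} constant genes: GS set to 0")
    associated = set(expr.index[(p < alpha) & ~const])
    return GS, associated, flags


def gs_kme_correlation(GS: pd.Series, kME: pd.Series, module_genes):
    """Correlation of gene significance with module membership over the
    genes of one module, with the fitted line and 95% confidence band of
    the mean.  ``kME`` is the single-module membership column.

    Returns a dict with r, p, slope, intercept, and band (DataFrame with
    kme, fit, lo, hi per module gene, sorted by kme).
    """
    genes = [g for g in module_genes if g in GS.index]
    if len(genes) < 3:
        raise ValueError("module must have at least 3 genes with GS values")
    x = kME.loc[genes].to_numpy(dtype=float)
    if x.ndim > 1:
        raise ValueError("pass kME as a single-module Series")
    y = GS.loc[genes].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate variance in kME or GS")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = (resid**2).sum() / (n - 2)
    XtX_inv = np.linalg.inv(X.T @ X)
    se_fit = np.sqrt(s2 * np.einsum("ij,jk,ik->i", X, XtX_inv, X))
    tcrit = stats.t.ppf(0.975, n - 2)
    fit = X @ beta
    band = pd.DataFrame(
        {"kme": x, "fit": fit, "lo": fit - tcrit * se_fit, "hi": fit + tcrit * se_fit},
        index=genes,
    ).sort_values("kme")
    return {
        "r": float(r), "p": float(p),
        "slope": float(beta[1]), "intercept": float(beta[0]), "band": band,
    }


def module_enrichment_fet(module_genes, target_genes, background, correction: str = "none"):
    """One-sided Fisher exact enrichment of a module for a target set.

    Returns (odds_ratio, p, p_adj); with ``correction='none'`` p_adj is
    p.  For families of tests use :func:`enrichment_table` or
    :func:`gmt_enrichment`, which apply Benjamini-Hochberg jointly.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    module = set(module_genes) & background
    target = set(target_genes) & background
    if set(module_genes) - background or set(target_genes) - background:
        raise ValueError("module and target must be subsets of the background")
    inter = len(module & target)
    table = [
        [inter, len(module) - inter],
        [len(target) - inter, len(background) - len(module | target)],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    if inter == 0:
        odds = 0.0
    p_adj = p if correction == "none" else float(multipletests([p], method="fdr_bh")[1][0])
    return float(odds), float(p), float(p_adj)


def enrichment_table(module_sets: dict, target_sets: dict, background) -> pd.DataFrame:
    """All module x target Fisher tests with joint BH correction."""
    rows = []
    for mname, mgenes in module_sets.items():
        for tname, tgenes in target_sets.items():
            odds, p, _ = module_enrichment_fet(mgenes, tgenes, background)
            inter = len(set(mgenes) & set(tgenes) & set(background))
            rows.append(
                {"module": mname, "target": tname, "overlap": inter,
                 "odds_ratio": odds, "p": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def read_gmt(path) -> dict:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> ...

    Returns {term: (description, gene set)}; malformed lines raise with
    their line number.
    """
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected term, description "
                    f"and at least one gene"
                )
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not term or not genes:
                raise ValueError(f"malformed GMT line {lineno}: empty term or gene list")
            terms[term] = (desc, set(genes))
    return terms


def gmt_enrichment(module_genes, gmt_path, background) -> pd.DataFrame:
    """Fisher enrichment of a module against every term of a GMT file.

    Terms are reduced to the background before testing; terms disjoint
    from the background are skipped (recorded in the ``skipped`` column
    attribute).  BH correction is applied across the tested terms.
    """
    background = set(background)
    module = set(module_genes) & background
    terms = read_gmt(gmt_path)
    rows, skipped = [], []
    for term, (desc, genes) in terms.items():
        tset = genes & background
        if not tset:
            skipped.append(term)
            continue
        odds, p, _ = module_enrichment_fet(module, tset, background)
        rows.append(
            {"term": term, "description": desc, "term_size": len(tset),
             "overlap": len(module & tset), "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "term"]).reset_index(drop=True)
    out.attrs["skipped_terms"] = skipped
    return out
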