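"""Weighted gene co-expression network construction and module detection.

The network is built per stratum (a sex, phenotype, or pooled sample
set): biweight midcorrelation between all gene pairs, an unsigned
adjacency ``|cor|^beta`` with the soft power chosen by approximate
scale-free fit, a topological overlap matrix (TOM), average-linkage
clustering of ``1 - TOM`` and a tree-based dynamic cut into modules of
at least ``min_size`` genes.  Module eigengenes are first principal
components of the standardised member expression; module membership
(kME) is the correlation of each gene with an eigengene; intramodular
connectivity (kIM) is the summed adjacency to fellow members, and the
top 5% of members by kIM are the module's hub genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "bicor_matrix",
    "pick_soft_threshold",
    "adjacency_and_tom",
    "detect_modules",
    "module_eigengenes",
    "kme_and_kim",
    "build_network",
]

UNASSIGNED = "unassigned"

# classic module colour palette, assigned in decreasing size order
_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def _color_label(i: int) -> str:
    return _COLORS[i] if i < len(_COLORS) else f"module{i + 1}"


def bicor_matrix(expr: pd.DataFrame, c: float = 9.0) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs.

    ``expr`` is genes x samples.  Each gene is centred at its median and
    weighted by Tukey's biweight ``w = (1 - u^2)^2`` for ``|u| < 1`` with
    ``u = (x - median) / (c * MAD)``; correlations are normalised inner
    products of the weighted deviations.  Genes with zero median absolute
    deviation cannot be weighted and fall back to Pearson (logged).
    """
    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 4:
        raise ValueError("biweight midcorrelation needs at least 4 samples")
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    if zero_mad.any():
        logger.info(
            "bicor_matrix: %d genes with zero MAD fall back to Pearson",
            int(zero_mad.sum()),
        )
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = (X - med) / (c * safe_mad)
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    V = (X - med) * w
    # Pearson fallback rows: plain mean-centred deviations
    if zero_mad.any():
        Xc = X - X.mean(axis=1, keepdims=True)
        V[zero_mad] = Xc[zero_mad]
    norms = np.sqrt((V**2).sum(axis=1, keepdims=True))
    degenerate = norms[:, 0] == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant genes: correlations set to 0"
        )
    norms[degenerate] = 1.0
    V = V / norms
    R = np.clip(V @ V.T, -1.0, 1.0)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=expr.index, columns=expr.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Signed R^2 of the log-log regression of the connectivity
    distribution: log10 p(k) on log10 mean(k) over equal-width
    connectivity bins (the standard scale-free fit index).
    Returns (signed r^2, slope); degenerate connectivity gives (0, 0)."""
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]) or (k <= 0).all():
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        chunk = k[idx == b]
        if chunk.size == 0:
            continue
        mk = chunk.mean()
        pk = chunk.size / k.size
        if mk > 0 and pk > 0:
            xs.append(np.log10(mk))
            ys.append(np.log10(pk))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.allclose(xs, xs[0]):
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    r2 = float(r**2)
    signed = -r2 if slope > 0 else r2
    return signed, float(slope)


def pick_soft_threshold(
    cor_matrix: pd.DataFrame,
    powers=tuple(range(1, 21)),
    target_r2: float = 0.8,
):
    """Choose the soft power: smallest beta whose unsigned adjacency gives
    an approximately scale-free connectivity distribution (signed R^2 >=
    ``target_r2``); if none qualifies, the argmax-R^2 power is returned
    with ``reached_target=False``.  The full fit table accompanies the
    choice."""
    A0 = np.abs(cor_matrix.to_numpy(dtype=float))
    if A0.shape[0] < 30:
        raise ValueError("need at least 30 genes to assess scale-free fit")
    np.fill_diagonal(A0, 0.0)
    rows = []
    for beta in powers:
        A = A0**beta
        k = A.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append(
            {
                "power": beta, "sft_r2": r2, "slope": slope,
                "mean_k": float(k.mean()), "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    hit = table[table["sft_r2"] >= target_r2]
    if len(hit):
        beta = int(hit.iloc[0]["power"])
        reached = True
    else:
        beta = int(table.loc[table["sft_r2"].idxmax(), "power"])
        reached = False
        warnings.warn(
            f"no power reached scale-free R^2 {target_r2}; using argmax beta={beta}"
        )
    return beta, table, reached


def adjacency_and_tom(cor_matrix: pd.DataFrame, beta: int):
    """Unsigned soft adjacency and topological overlap matrix.

    ``a_ij = |cor_ij|^beta`` with zero diagonal;
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with unit diagonal.  Both are symmetric with entries in [0, 1].
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = np.abs(cor_matrix.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    ids = cor_matrix.index
    return (
        pd.DataFrame(A, index=ids, columns=ids),
        pd.DataFrame(tom, index=ids, columns=ids),
    )


def _linkage_heights(Z):
    return Z[:, 2]


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 50,
    cut_height_quantile: float = 0.99,
    min_gap: float = 0.04,
    coherence_quantile: float = 0.75,
):
    """Tree-based dynamic cut of the average-linkage TOM dendrogram.

    A static cut is placed at ``cut_height_quantile`` of the merge-height
    range; subtrees below it are candidate branches.  A branch is
    accepted as a module when it has at least ``min_size`` members and is
    coherent: the height at which it attaches to the rest of the tree
    exceeds the median of its internal merge heights by at least
    ``min_gap``.  The median criterion tolerates the straggler chains
    average linkage produces at the top of a tight branch, while a
    continuum of noise merges (internal heights hugging the attach
    height) is rejected and the search descends.  An accepted branch is
    split into sub-modules only where both children are themselves
    coherent modules.  Everything else is ``unassigned``; labels are
    colour-style strings in decreasing size order.

    Returns (labels: Series gene -> module, linkage matrix).
    """
    genes = list(tom.index)
    n = len(genes)
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    if n < 2 * min_size:
        warnings.warn(
            f"{n} genes < 2*min_size={2 * min_size}: single-module fallback"
        )
        labels = pd.Series([_color_label(0)] * n, index=genes, name="module")
        return labels, Z

    heights = _linkage_heights(Z)
    hmin, hmax = float(heights.min()), float(heights.max())
    cut = hmin + cut_height_quantile * (hmax - hmin)

    # node bookkeeping: nodes 0..n-1 are leaves, n+i is the cluster made
    # at merge i with height Z[i, 2]
    height = np.zeros(2 * n - 1)
    height[n:] = heights
    children = {n + i: (int(Z[i, 0]), int(Z[i, 1])) for i in range(n - 1)}

    def subtree_size(node):
        return 1 if node < n else int(Z[node - n, 3])

    # internal merge-height quantile per node, bottom-up (merge the
    # smaller child's height list into the larger one's)
    internal: dict = {}
    med = np.full(2 * n - 1, np.nan)
    for i in range(n - 1):
        node = n + i
        l, r = children[node]
        hl = internal.pop(l, [])
        hr = internal.pop(r, [])
        if len(hl) < len(hr):
            hl, hr = hr, hl
        hl.extend(hr)
        hl.append(heights[i])
        internal[node] = hl
        med[node] = float(np.quantile(hl, coherence_quantile))

    def leaves(node):
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(children[v])
        return out

    assignments = {}
    module_id = [0]

    def make_module(node):
        for leaf in leaves(node):
            assignments[leaf] = module_id[0]
        module_id[0] += 1

    def coherent(node, attach):
        return (
            subtree_size(node) >= min_size
            and node >= n
            and (attach - med[node]) >= min_gap
        )

    # explicit stack: dendrograms of weakly structured data chain deeply
    stack = [(2 * n - 2, np.inf)]
    while stack:
        node, attach = stack.pop()
        if subtree_size(node) < min_size:
            continue  # too small: leaves stay unassigned
        h = height[node]
        l, r = children[node]
        if h > cut:
            stack.append((l, h))
            stack.append((r, h))
            continue
        if coherent(node, attach):
            if coherent(l, h) and coherent(r, h):
                stack.append((l, h))
                stack.append((r, h))
            else:
                make_module(node)
        else:
            stack.append((l, h))
            stack.append((r, h))

    # relabel by decreasing size, colour-style
    sizes = {}
    for leaf, m in assignments.items():
        sizes[m] = sizes.get(m, 0) + 1
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    rename = {m: _color_label(i) for i, m in enumerate(order)}
    labels = pd.Series(UNASSIGNED, index=genes, name="module", dtype=object)
    for leaf, m in assignments.items():
        labels.iloc[leaf] = rename[m]
    n_mod = len(order)
    logger.info(
        "detect_modules: %d modules, %d/%d genes unassigned",
        n_mod, int((labels == UNASSIGNED).sum()), n,
    )
    return labels, Z


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series):
    """First principal component of each module's standardised expression.

    Returns (ME: samples x modules DataFrame, variance explained: Series).
    The eigengene sign is aligned so its correlation with the module's
    average expression profile is non-negative.  Zero-variance member
    genes are dropped with a warning.
    """
    samples = expr.columns
    mes, varexp = {}, {}
    for mod in sorted(set(modules) - {UNASSIGNED}):
        members = modules.index[modules == mod]
        X = expr.loc[members].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=1)
        if (sd == 0).any():
            warnings.warn(f"module {mod}: dropping {(sd == 0).sum()} constant genes")
            X = X[sd > 0]
            sd = sd[sd > 0]
        if X.shape[0] < 2:
            raise ValueError(f"module {mod} has fewer than 2 usable genes")
        Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        U, s, Vt = np.linalg.svd(Xs.T, full_matrices=False)  # samples x genes
        me = U[:, 0]
        avg = Xs.mean(axis=0)
        if np.dot(me, avg) < 0:
            me = -me
        mes[mod] = me
        varexp[mod] = float(s[0] ** 2 / (s**2).sum())
    ME = pd.DataFrame(mes, index=samples)
    return ME, pd.Series(varexp, name="variance_explained")


def kme_and_kim(
    expr: pd.DataFrame,
    ME: pd.DataFrame,
    adjacency: pd.DataFrame,
    modules: pd.Series,
    hub_fraction: float = 0.05,
):
    """Module membership, intramodular connectivity and hub genes.

    kME[g, m] is the Pearson correlation of gene g with eigengene m; kIM
    is a gene's summed adjacency to the other members of its own module
    (undefined, NaN, for unassigned genes); hubs are the top
    ``ceil(hub_fraction * size)`` members by kIM (at least one), ties
    broken lexicographically.
    """
    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=1))
    xn[xn == 0] = 1.0
    M = ME.to_numpy(dtype=float)
    Mc = M - M.mean(axis=0, keepdims=True)
    mn = np.sqrt((Mc**2).sum(axis=0))
    mn[mn == 0] = 1.0
    kme = (Xc / xn[:, None]) @ (Mc / mn[None, :])
    kME = pd.DataFrame(
        np.clip(kme, -1, 1), index=expr.index, columns=ME.columns
    )
    kIM = pd.Series(np.nan, index=expr.index, name="kIM")
    hubs = {}
    A = adjacency
    for mod in ME.columns:
        members = list(modules.index[modules == mod])
        sub = A.loc[members, members].to_numpy(dtype=float)
        k = sub.sum(axis=1)  # diagonal is zero by construction
        kIM.loc[members] = k
        n_hub = max(1, int(np.ceil(hub_fraction * len(members))))
        ranked = sorted(zip(members, k), key=lambda gk: (-gk[1], gk[0]))
        hubs[mod] = [g for g, _ in ranked[:n_hub]]
    return kME, kIM, hubs


@dataclass
class CoexpressionNetwork:
    """A fitted co-expression network for one stratum."""

    stratum: str
    beta: int
    sft_table: pd.DataFrame
    reached_target_r2: bool
    modules: pd.Series  # gene -> label ("unassigned" reserved)
    linkage: np.ndarray
    ME: pd.DataFrame
    variance_explained: pd.Series
    kME: pd.DataFrame
    kIM: pd.Series
    hubs: dict
    adjacency: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def module_sizes(self) -> pd.Series:
        return self.modules[self.modules != UNASSIGNED].value_counts()


def build_network(
    expr: pd.DataFrame,
    stratum: str = "all",
    beta: int | None = None,
    min_size: int = 50,
    powers=tuple(range(1, 21)),
    target_r2: float = 0.8,
    min_gap: float = 0.02,
    keep_adjacency: bool = True,
) -> CoexpressionNetwork:
    """Full network construction for one expression matrix (genes x
    samples): bicor -> soft power -> adjacency/TOM -> modules ->
    eigengenes -> kME/kIM/hubs."""
    cor = bicor_matrix(expr)
    if beta is None:
        beta, sft, reached = pick_soft_threshold(cor, powers, target_r2)
    else:
        sft, reached = pd.DataFrame(), True
    A, tom = adjacency_and_tom(cor, beta)
    modules, Z = detect_modules(tom, min_size=min_size, min_gap=min_gap)
    ME, varexp = module_eigengenes(expr, modules)
    kME, kIM, hubs = kme_and_kim(expr, ME, A, modules)
    return CoexpressionNetwork(
        stratum=stratum, beta=beta, sft_table=sft, reached_target_r2=reached,
        modules=modules, linkage=Z, ME=ME, variance_explained=varexp,
        kME=kME, kIM=kIM, hubs=hubs,
        adjacency=A if keep_adjacency else None,
    )
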