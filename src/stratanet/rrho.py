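"""Rank-rank hypergeometric overlap (RRHO) maps.

Two differential-expression signatures are each ranked by the signed
metric -log10(p) * sign(t), most up-regulated first.  For every pair of
rank thresholds the overlap of the two top lists is scored by an
upper-tail hypergeometric p-value, the full matrix is corrected by the
Benjamini-Yekutieli procedure, and cells are labelled by the direction
of regulation on each axis (up/up, down/down or discordant).  With both
lists ordered from up- to down-regulated, concordant up-regulation
accumulates near the origin corner of the map and concordant
down-regulation in the opposite corner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["RankedSignature", "RRHOMap", "compute_rrho", "hypergeom_tail", "adjust_by"]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class RankedSignature:
    """Genes ordered by rank metric descending (ties lexicographic)."""

    genes: tuple
    scores: tuple

    @classmethod
    def from_scores(cls, scores) -> "RankedSignature":
        """Build from a mapping / Series of gene -> signed rank metric."""
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            genes=tuple(g for g, _ in items), scores=tuple(float(s) for _, s in items)
        )

    @classmethod
    def from_de(cls, de) -> "RankedSignature":
        return cls.from_scores(dict(de.table["rank_metric"]))

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in signature")
        diffs = np.diff(self.scores)
        if (diffs > 0).any():
            raise ValueError("scores not in descending order")

    def restrict(self, universe) -> "RankedSignature":
        keep = set(universe)
        pairs = [(g, s) for g, s in zip(self.genes, self.scores) if g in keep]
        return RankedSignature(
            genes=tuple(g for g, _ in pairs), scores=tuple(s for _, s in pairs)
        )


@dataclass
class RRHOMap:
    step: int
    thresholds: np.ndarray  # rank cut points shared by both axes
    overlap: np.ndarray  # counts at each threshold pair (A rows, B cols)
    raw_p: np.ndarray
    adj_neglog_p: np.ndarray
    quadrant: np.ndarray  # labels: "up/up", "down/down", "discordant"
    n_universe: int
    dropped_a: list
    dropped_b: list

    def max_signal(self):
        """(max adjusted -log10 p, threshold pair, quadrant label)."""
        i, j = np.unravel_index(np.argmax(self.adj_neglog_p), self.adj_neglog_p.shape)
        return float(self.adj_neglog_p[i, j]), (int(self.thresholds[i]), int(self.thresholds[j])), str(self.quadrant[i, j])


def hypergeom_tail(N: int, k_a: int, k_b: int, overlap: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap) for the overlap
    of a k_a-set and a k_b-set drawn from N items, computed in log space.
    """
    if not (0 <= k_a <= N and 0 <= k_b <= N):
        raise ValueError("list sizes must lie in [0, N]")
    if not (0 <= overlap <= min(k_a, k_b)):
        raise ValueError(
            f"overlap {overlap} impossible for sizes {k_a}, {k_b} of {N}"
        )
    if overlap <= max(0, k_a + k_b - N):
        return 1.0
    logp = stats.hypergeom.logsf(overlap - 1, N, k_a, k_b)
    return float(max(np.exp(logp), P_FLOOR))


def _hypergeom_sf_matrix(N, KA, KB, OV):
    """Upper-tail hypergeometric p for every cell of a threshold map,
    accumulated from cached log-gamma tables (much faster than cellwise
    scipy calls on ~100 x 100 maps)."""
    from scipy.special import gammaln

    lg = gammaln(np.arange(N + 2, dtype=float))

    def log_comb(a, b):
        return lg[a + 1] - lg[b + 1] - lg[a - b + 1]

    upper = np.minimum(KA, KB)
    lower = np.maximum(0, KA + KB - N)
    denom = log_comb(np.full_like(KA, N), KB)
    S = np.zeros(KA.shape)
    for x in range(int(OV.min()), int(upper.max()) + 1):
        active = (OV <= x) & (x <= upper) & (x >= lower)
        if not active.any():
            continue
        logpmf = (
            log_comb(KA[active], x)
            + log_comb(N - KA[active], KB[active] - x)
            - denom[active]
        )
        S[active] += np.exp(logpmf)
    S[OV <= lower] = 1.0
    return np.clip(S, P_FLOOR, 1.0)


def adjust_by(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (harmonic-number inflation),
    monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    flat = p.ravel()
    adj = multipletests(flat, method="fdr_by")[1]
    return adj.reshape(p.shape)


def compute_rrho(
    sig_a: RankedSignature, sig_b: RankedSignature, step: int | None = None
) -> RRHOMap:
    """RRHO map between two signed signatures.

    Non-shared genes are dropped (logged) and N is the intersection
    size; the default step yields a map of roughly 100 x 100 cells.
    """
    shared = set(sig_a.genes) & set(sig_b.genes)
    if not shared:
        raise ValueError("signatures share no genes")
    dropped_a = [g for g in sig_a.genes if g not in shared]
    dropped_b = [g for g in sig_b.genes if g not in shared]
    if dropped_a or dropped_b:
        logger.info(
            "compute_rrho: dropped %d genes from A, %d from B",
            len(dropped_a), len(dropped_b),
        )
    a = sig_a.restrict(shared)
    b = sig_b.restrict(shared)
    N = len(shared)
    if step is None:
        step = max(1, N // 100)
    if step >= N:
        raise ValueError(f"step {step} must be smaller than universe {N}")

    thresholds = np.arange(step, N + 1, step)
    rank_b = {g: i for i, g in enumerate(b.genes)}
    rb_of_a = np.array([rank_b[g] for g in a.genes])
    # joint histogram of (binned rank in A, binned rank in B), then 2D
    # cumsum; ranks at or beyond the last threshold never enter any cell
    nbin = len(thresholds)
    rank_a = np.arange(N)
    in_range = (rank_a < thresholds[-1]) & (rb_of_a < thresholds[-1])
    bin_a = rank_a[in_range] // step
    bin_b = rb_of_a[in_range] // step
    H = np.zeros((nbin, nbin), dtype=np.int64)
    np.add.at(H, (bin_a, bin_b), 1)
    overlap = H.cumsum(axis=0).cumsum(axis=1)
    ka = thresholds
    KA, KB = np.meshgrid(ka, ka, indexing="ij")
    raw_p = _hypergeom_sf_matrix(N, KA, KB, overlap)
    adj = adjust_by(raw_p)
    adj_neglog = -np.log10(np.clip(adj, P_FLOOR, 1.0))

    sign_a = np.sign(np.asarray(a.scores))
    sign_b = np.sign(np.asarray(b.scores))

    def _axis_dir(signs, t):
        # direction of the marginal gene at each threshold: the region of
        # the list a threshold cell sits in
        s = signs[min(t, len(signs)) - 1]
        return "up" if s > 0 else "down"

    quadrant = np.empty((nbin, nbin), dtype=object)
    for i in range(nbin):
        da = _axis_dir(sign_a, int(ka[i]))
        for j in range(nbin):
            db = _axis_dir(sign_b, int(ka[j]))
            quadrant[i, j] = f"{da}/{db}" if da == db else "discordant"

    return RRHOMap(
        step=int(step), thresholds=ka, overlap=overlap, raw_p=raw_p,
        adj_neglog_p=adj_neglog, quadrant=quadrant, n_universe=N,
        dropped_a=dropped_a, dropped_b=dropped_b,
    )


def plot_rrho(rrho_map: RRHOMap, path=None, title: str = "RRHO"):
    """Heat-map of the BY-adjusted -log10 p matrix (axis origin at the
    most up-regulated end of both lists)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        rrho_map.adj_neglog_p, origin="lower", aspect="auto", cmap="magma",
        extent=[0, rrho_map.n_universe, 0, rrho_map.n_universe],
    )
    ax.set_xlabel("rank in signature B (up → down)")
    ax.set_ylabel("rank in signature A (up → down)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="-log10 adjusted p")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
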