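"""Mutual-information reverse engineering of transcriptional regulons.

The engine estimates pairwise mutual information with an adaptive-
partitioning estimator on copula-transformed data, calibrates it against a
piecewise null model (empirical body + robust log-linear tail) fitted on
shuffled marginals, prunes each candidate network by FDR and then by the
data processing inequality (the weakest edge of every three-gene clique is
indirect), and integrates several subsampled networks into a consensus.
Consensus edges become weighted regulons: association weights are the
copula transform of the (occurrence count, mutual information) ordering and
association modes are full-data Spearman correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .regulon import Regulon, RegulonSet

__all__ = [
    "apmi",
    "MutualInfoNullModel",
    "fit_mi_null",
    "infer_subnetwork",
    "dpi_prune",
    "ConsensusNetwork",
    "consensus",
    "network_to_regulons",
    "ARACNe3",
    "SUBSAMPLE_FRACTION",
]

logger = logging.getLogger(__name__)

#: Fraction of profiles used per subnetwork: the probability that a given
#: sample appears at least once in a bootstrap, 1 - 1/e.  Subsampling this
#: fraction *without* replacement decorrelates subnetworks like
#: bootstrapping does, without the duplicated points that bias the MI
#: estimator.
SUBSAMPLE_FRACTION = 1.0 - 1.0 / np.e


def _copula(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x) / (x.size + 1.0)


def _apmi_core(u, v, chi2_crit, min_pts):
    """Adaptive quadrant partitioning on copula-uniform points in (0,1)^2.

    A cell is split at its midpoint into four quadrants while the
    chi-squared uniformity statistic of the quadrant counts exceeds
    ``chi2_crit`` and the cell still holds ``min_pts`` points; the root
    cell is always split once, so the estimate is a continuous random
    variable under independence rather than having an atom at zero.
    Each leaf contributes n_c/n * ln[(n_c/n) / (p_x * p_y)] where p_x,
    p_y are the fractions of *all* points falling in the cell's x- and
    y-intervals (the marginal-count correction).
    """
    n = u.size
    us = np.sort(u)
    vs = np.sort(v)
    mi = 0.0
    stack = [(0.0, 1.0, 0.0, 1.0, np.arange(n), True)]
    while stack:
        x0, x1, y0, y1, idx, force = stack.pop()
        nc = idx.size
        if nc == 0:
            continue
        if force or nc >= min_pts:
            xm = 0.5 * (x0 + x1)
            ym = 0.5 * (y0 + y1)
            ux = u[idx]
            vy = v[idx]
            right = ux >= xm
            top = vy >= ym
            q = [idx[~right & ~top], idx[right & ~top], idx[~right & top], idx[right & top]]
            counts = np.array([a.size for a in q], dtype=float)
            expected = nc / 4.0
            chi2 = np.sum((counts - expected) ** 2) / expected
            if force or chi2 > chi2_crit:
                stack.append((x0, xm, y0, ym, q[0], False))
                stack.append((xm, x1, y0, ym, q[1], False))
                stack.append((x0, xm, ym, y1, q[2], False))
                stack.append((xm, x1, ym, y1, q[3], False))
                continue
        pxy = nc / n
        px = (np.searchsorted(us, x1) - np.searchsorted(us, x0)) / n
        py = (np.searchsorted(vs, y1) - np.searchsorted(vs, y0)) / n
        if px > 0 and py > 0:
            mi += pxy * np.log(pxy / (px * py))
    return max(mi, 0.0)


def apmi(x, y, alpha: float = 0.05, min_pts: int = 8, copula: bool = True) -> float:
    """Adaptive-partitioning mutual information estimate in nats.

    Inputs are copula-transformed to uniform marginals (rank/(n+1))
    unless already supplied that way.  A constant vector carries no
    information: returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: mutual information set to 0", stacklevel=2)
        return 0.0
    u = _copula(x) if copula else x
    v = _copula(y) if copula else y
    crit = stats.chi2.ppf(1.0 - alpha, df=3)
    return _apmi_core(u, v, crit, min_pts)


@dataclass(frozen=True)
class MutualInfoNullModel:
    """Piecewise null distribution of MI between independent marginals.

    The body is the empirical survival function of the null draws up to
    their 95th percentile; beyond it, the tail is log10-linear in MI with
    a Theil-Sen (median-of-slopes) fitted slope, anchored at the junction
    so the p-value is continuous and nonincreasing by construction.
    """

    null_sorted: np.ndarray
    q95: float
    tail_slope: float
    junction_p: float
    n_samples: int

    @property
    def n_null(self) -> int:
        return self.null_sorted.size

    def pvalue(self, mi) -> np.ndarray:
        mi = np.atleast_1d(np.asarray(mi, dtype=float))
        n = self.n_null
        body = (n - np.searchsorted(self.null_sorted, mi, side="left")) / n
        body = np.maximum(body, 1.0 / n)
        tail = self.junction_p * 10.0 ** (self.tail_slope * (mi - self.q95))
        p = np.where(mi <= self.q95, body, np.minimum(tail, self.junction_p))
        return np.clip(p, np.finfo(float).tiny, 1.0)


def fit_mi_null(
    n_samples: int,
    n_pairs: int = 1_000_000,
    seed=None,
    alpha: float = 0.05,
    min_pts: int = 8,
) -> MutualInfoNullModel:
    """Fit the null MI model from shuffled copula-transformed marginals."""
    if n_pairs < 1000:
        raise ValueError("need at least 1000 null pairs to fit the tail")
    rng = np.random.default_rng(seed)
    grid = np.arange(1, n_samples + 1) / (n_samples + 1.0)
    crit = stats.chi2.ppf(1.0 - alpha, df=3)
    null = np.empty(n_pairs)
    for i in range(n_pairs):
        null[i] = _apmi_core(grid, rng.permutation(grid), crit, min_pts)
    null.sort()
    q95 = float(np.quantile(null, 0.95))
    n = null.size
    junction_p = (n - np.searchsorted(null, q95, side="left")) / n
    tail_vals = null[null > q95]
    # empirical log10 tail probability at each tail draw
    tail_p = (n - np.searchsorted(null, tail_vals, side="left")) / n
    uniq, first = np.unique(tail_vals, return_index=True)
    logp = np.log10(tail_p[first])
    if uniq.size < 3:
        raise ValueError("too few distinct tail values to fit the tail")
    slope = stats.theilslopes(logp, uniq).slope
    if slope >= 0:
        warnings.warn("non-decreasing null tail fit; clamping slope", stacklevel=2)
        slope = -1e-9
    return MutualInfoNullModel(null, q95, float(slope), float(junction_p), n_samples)


def _pair_mi(mat: np.ndarray, reg_rows, crit, min_pts):
    """MI of every (regulator row, other row) pair of a copula matrix."""
    n_genes = mat.shape[0]
    out = {}
    for ri in reg_rows:
        u = mat[ri]
        for gi in range(n_genes):
            if gi == ri:
                continue
            out[(ri, gi)] = _apmi_core(u, mat[gi], crit, min_pts)
    return out


def infer_subnetwork(
    mat: pd.DataFrame,
    regulators,
    null_model: MutualInfoNullModel,
    fdr: float = 0.05,
    seed=None,
    alpha: float = 0.05,
    min_pts: int = 8,
    subsample: bool = True,
) -> pd.DataFrame:
    """One candidate network: subsample, estimate MI, prune by FDR.

    Subsamples ``round(n * (1 - 1/e))`` profiles without replacement,
    estimates MI for every regulator-target pair, converts to p-values
    under the null model, and keeps edges passing Benjamini-Hochberg at
    ``fdr``.  Returns columns ``regulator, target, mi``.
    """
    from statsmodels.stats.multitest import multipletests

    genes = np.asarray(mat.index, dtype=object)
    reg_idx = pd.Index(genes).get_indexer(np.asarray(regulators, dtype=object))
    if np.any(reg_idx < 0):
        raise ValueError("regulators must be a subset of the matrix genes")
    X = mat.to_numpy(dtype=float)
    n = X.shape[1]
    if subsample:
        k = int(round(n * SUBSAMPLE_FRACTION))
        if k < 8:
            raise ValueError("fewer than 8 subsampled profiles")
        rng = np.random.default_rng(seed)
        cols = rng.choice(n, size=k, replace=False)
        X = X[:, cols]
    cop = stats.rankdata(X, axis=1) / (X.shape[1] + 1.0)
    crit = stats.chi2.ppf(1.0 - alpha, df=3)
    mi = _pair_mi(cop, reg_idx, crit, min_pts)
    pairs = list(mi.keys())
    mi_vals = np.array([mi[p] for p in pairs])
    pvals = null_model.pvalue(mi_vals)
    keep = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    rows = [
        (genes[ri], genes[gi], m)
        for (ri, gi), m, k_ in zip(pairs, mi_vals, keep)
        if k_
    ]
    return pd.DataFrame(rows, columns=["regulator", "target", "mi"])


def dpi_prune(edges: pd.DataFrame) -> pd.DataFrame:
    """Data-processing-inequality pruning on the undirected skeleton.

    For every three-gene clique the minimum-MI edge is marked (all tied
    minima are marked) and all marked edges are removed in one pass, so
    the operation is deterministic and idempotent on its own output.
    """
    if edges.empty:
        return edges.copy()
    und = {}
    for reg, tgt, mi in edges[["regulator", "target", "mi"]].itertuples(index=False):
        key = (reg, tgt) if reg <= tgt else (tgt, reg)
        und.setdefault(key, mi)
    adj: dict = {}
    for (a, b) in und:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    doomed = set()
    for (a, b) in und:
        common = adj[a] & adj[b]
        for c in common:
            if not (a < c and b < c):  # visit each triangle once, via its max node
                continue
            tri = [(a, b), tuple(sorted((a, c))), tuple(sorted((b, c)))]
            mis = [und[e] for e in tri]
            lo = min(mis)
            doomed.update(e for e, m in zip(tri, mis) if m == lo)
    mask = [
        ((r, t) if r <= t else (t, r)) not in doomed
        for r, t in edges[["regulator", "target"]].itertuples(index=False)
    ]
    return edges.loc[mask].reset_index(drop=True)


@dataclass(frozen=True)
class ConsensusNetwork:
    """Union of pruned subnetworks with per-edge support statistics."""

    edges: pd.DataFrame  # regulator, target, count, mi, spearman
    n_subnetworks: int

    def __post_init__(self):
        e = self.edges
        if e.duplicated(["regulator", "target"]).any():
            raise ValueError("duplicate edges in consensus network")
        if (e["count"] < 1).any() or (e["count"] > self.n_subnetworks).any():
            raise ValueError("edge occurrence counts outside [1, n_subnetworks]")


def consensus(
    mat: pd.DataFrame,
    regulators,
    fdr: float = 0.05,
    max_nets: int = 30,
    min_targets: int = 50,
    seed=None,
    null_model: MutualInfoNullModel | None = None,
    n_null_pairs: int = 1_000_000,
    alpha: float = 0.05,
    min_pts: int = 8,
) -> ConsensusNetwork:
    """Integrate FDR- and DPI-pruned subnetworks into a consensus.

    Subnetworks are generated until either ``max_nets`` is reached or
    every regulator has accumulated ``min_targets`` unique targets.  The
    final per-edge MI and Spearman correlation are estimated once from
    the full matrix.
    """
    regulators = np.asarray(regulators, dtype=object)
    n = mat.shape[1]
    k = int(round(n * SUBSAMPLE_FRACTION))
    rng = np.random.default_rng(seed)
    if null_model is None:
        null_model = fit_mi_null(
            k, n_null_pairs, seed=rng.integers(2**31), alpha=alpha, min_pts=min_pts
        )
    counts: dict = {}
    per_reg: dict = {r: set() for r in regulators}
    n_done = 0
    for _ in range(max_nets):
        sub = infer_subnetwork(
            mat,
            regulators,
            null_model,
            fdr=fdr,
            seed=rng.integers(2**31),
            alpha=alpha,
            min_pts=min_pts,
        )
        sub = dpi_prune(sub)
        n_done += 1
        for reg, tgt in sub[["regulator", "target"]].itertuples(index=False):
            counts[(reg, tgt)] = counts.get((reg, tgt), 0) + 1
            per_reg[reg].add(tgt)
        if all(len(t) >= min_targets for t in per_reg.values()):
            break
    else:
        if not all(len(t) >= min_targets for t in per_reg.values()):
            warnings.warn(
                f"stopping after {n_done} subnetworks with some regulators below "
                f"{min_targets} unique targets",
                stacklevel=2,
            )
    if not counts:
        raise ValueError("no edges survived pruning in any subnetwork")
    # final estimates on the full matrix
    genes = pd.Index(mat.index)
    X = mat.to_numpy(dtype=float)
    cop = stats.rankdata(X, axis=1) / (X.shape[1] + 1.0)
    crit = stats.chi2.ppf(1.0 - alpha, df=3)
    rows = []
    for (reg, tgt), cnt in counts.items():
        ri, gi = genes.get_loc(reg), genes.get_loc(tgt)
        mi = _apmi_core(cop[ri], cop[gi], crit, min_pts)
        rho = stats.spearmanr(X[ri], X[gi]).statistic
        rows.append((reg, tgt, cnt, mi, rho))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "count", "mi", "spearman"])
    edges = edges.sort_values(["regulator", "target"], ignore_index=True)
    return ConsensusNetwork(edges, n_done)


def network_to_regulons(net: ConsensusNetwork) -> RegulonSet:
    """Consensus edges -> weighted regulons.

    Targets of each regulator are ordered by (occurrence count, final
    MI); the association weight is the copula transform of that ordering
    (rank/(N+1), average rank on exact ties) and the association mode is
    the full-data Spearman correlation.
    """
    out = RegulonSet()
    for reg, grp in net.edges.groupby("regulator", sort=False):
        cnt = grp["count"].to_numpy(float)
        mi = grp["mi"].to_numpy(float)
        order = np.lexsort((mi, cnt))
        ranks = np.empty(cnt.size)
        ranks[order] = np.arange(1, cnt.size + 1)
        # average ranks over exact (count, mi) ties
        key = pd.Series(list(zip(cnt, mi)))
        ranks = pd.Series(ranks).groupby(key).transform("mean").to_numpy()
        aw = ranks / (cnt.size + 1.0)
        am = np.clip(grp["spearman"].to_numpy(float), -1.0, 1.0)
        out.add(Regulon(reg, grp["target"].to_numpy(dtype=object), aw, am))
    return out


class ARACNe3(BaseEstimator):
    """Consensus network inference as a scikit-learn style estimator.

    Parameters mirror :func:`consensus`; ``fit`` expects a genes-by-
    samples DataFrame of non-negative normalized expression and exposes
    ``network_`` (the consensus edge table) and ``regulons_`` (weighted
    gene sets ready for enrichment analysis).
    """

    def __init__(
        self,
        regulators=None,
        fdr: float = 0.05,
        max_nets: int = 30,
        min_targets: int = 50,
        n_null_pairs: int = 1_000_000,
        alpha: float = 0.05,
        min_pts: int = 8,
        random_state=None,
    ):
        self.regulators = regulators
        self.fdr = fdr
        self.max_nets = max_nets
        self.min_targets = min_targets
        self.n_null_pairs = n_null_pairs
        self.alpha = alpha
        self.min_pts = min_pts
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if self.regulators is None:
            raise ValueError("regulators must be supplied")
        net = consensus(
            X,
            self.regulators,
            fdr=self.fdr,
            max_nets=self.max_nets,
            min_targets=self.min_targets,
            seed=self.random_state,
            n_null_pairs=self.n_null_pairs,
            alpha=self.alpha,
            min_pts=self.min_pts,
        )
        self.network_ = net
        self.regulons_ = network_to_regulons(net)
        return self


def read_network(path) -> ConsensusNetwork:
    df = pd.read_csv(path, sep="\t")
    n_sub = int(df["count"].max()) if len(df) else 1
    return ConsensusNetwork(df, max(n_sub, 1))


def write_network(net: ConsensusNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)
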