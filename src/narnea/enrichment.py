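"""Analytical gene set enrichment with weighted regulons.

The test statistic combines two scores computed over the gene set members
in a rank/sign transformed differential signature:

* directed score   DES = sum aw * am * (r * s)
* undirected score UES = sum aw * (1 - |am|) * r

Under the maximum-entropy null (members independently and uniformly placed
over the G signature entries, with replacement) both are sums of i.i.d.
draws from the realized (r, s) multiset, so their null mean, variance and
covariance are exact finite-sample quantities (functions of the signature
moments m_rs, m_r, m_r2, m_r2s) and each standardized score is
asymptotically standard normal by the Lindeberg CLT.  A variance-weighted
rotation yields two uncorrelated standard-normal statistics NES+ and NES-
aimed at positive and negative enrichment; their one-tailed p-values are
independent under the null, so the final two-sided p-value is the Sidak
combination p = 1 - (1 - min(p+, p-))**2 and the final NES is the normal
quantile carrying the direction of the stronger tail.

The effect size (PES) rescales NES by the most extreme NES achievable by
re-placing the gene set members on distinct signature entries, so PES lies
in [-1, 1] with expectation 0 under the null.  Leading-edge analysis ranks
the members by their post hoc contribution, deliberately ignoring the
association weights so that member selection is not biased by a priori
importance.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .regulon import Regulon, RegulonSet, validate_regulon
from .signature import DifferentialSignature, RankSignSignature, rank_sign_transform

__all__ = [
    "NaRnEA",
    "narnea",
    "raw_scores",
    "normalize_scores",
    "combine_scores",
    "significance",
    "proportional_enrichment",
    "pes_confidence_interval",
    "leading_edge",
    "lindeberg_diagnostic",
]

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny
_NES_CLAMP = float(-special.ndtri(_TINY))  # |quantile| at machine underflow


# ---------------------------------------------------------------------------
# core scores


def raw_scores(rss: RankSignSignature, reg: Regulon, idx: np.ndarray | None = None):
    """Observed (DES, UES) for a regulon in a transformed signature."""
    if idx is None:
        idx = rss.index_of(reg.targets)
    r = rss.r[idx]
    rs = r * rss.s[idx]
    des = float(np.sum(reg.aw * reg.am * rs))
    ues = float(np.sum(reg.aw * (1.0 - np.abs(reg.am)) * r))
    return des, ues


def _null_moments(rss: RankSignSignature, reg: Regulon):
    """Exact null mean/variance of (DES, UES) and their covariance."""
    wd = reg.aw * reg.am
    wu = reg.aw * (1.0 - np.abs(reg.am))
    mu_d = float(np.sum(wd) * rss.m_rs)
    var_d = float(np.sum(wd * wd) * (rss.m_r2 - rss.m_rs**2))
    mu_u = float(np.sum(wu) * rss.m_r)
    var_u = float(np.sum(wu * wu) * (rss.m_r2 - rss.m_r**2))
    cov = float(np.sum(wd * wu) * (rss.m_r2s - rss.m_rs * rss.m_r))
    return mu_d, var_d, mu_u, var_u, cov


def normalize_scores(rss: RankSignSignature, reg: Regulon, des: float, ues: float):
    """Standardize the raw scores under the null.

    Returns ``(ndes, nues, phi)``.  A branch with zero null variance (all
    am = 0 kills the directed branch; all |am| = 1 kills the undirected
    one) is reported as NaN and phi as NaN; downstream the surviving
    branch alone determines significance.
    """
    mu_d, var_d, mu_u, var_u, cov = _null_moments(rss, reg)
    ndes = (des - mu_d) / np.sqrt(var_d) if var_d > 0 else np.nan
    nues = (ues - mu_u) / np.sqrt(var_u) if var_u > 0 else np.nan
    if var_d > 0 and var_u > 0:
        phi = cov / np.sqrt(var_d * var_u)
    else:
        phi = np.nan
    return ndes, nues, phi


def combine_scores(ndes: float, nues: float, phi: float):
    """Rotate (NDES, NUES) into the uncorrelated pair (NES+, NES-)."""
    if not np.isfinite(phi) or abs(phi) >= 1.0:
        raise ValueError(f"degenerate regulon: |phi| >= 1 (phi={phi})")
    nes_pos = (ndes + nues) / np.sqrt(2.0 + 2.0 * phi)
    nes_neg = (ndes - nues) / np.sqrt(2.0 - 2.0 * phi)
    return nes_pos, nes_neg


def significance(nes_pos: float, nes_neg: float, ndes: float | None = None):
    """One-tailed p-values, combined two-sided p, and the final NES.

    Tail probabilities are carried in log space so extreme scores stay
    representable; the reported p is clamped to the open interval (0, 1)
    at machine precision and |NES| is clamped at the quantile of the
    smallest positive float.  When the two tails tie exactly, the sign of
    NES is taken from the directed branch.
    """
    log_p_pos = stats.norm.logsf(nes_pos)  # P(Z > nes_pos)
    log_p_neg = stats.norm.logcdf(nes_neg)  # P(Z < nes_neg)
    p_pos = float(np.exp(log_p_pos))
    p_neg = float(np.exp(log_p_neg))
    log_m = min(log_p_pos, log_p_neg)
    m = np.exp(log_m)
    # p = 1 - (1 - m)^2 = m * (2 - m), computed in log space
    log_p = log_m + np.log(2.0 - m)
    p = float(np.clip(np.exp(log_p), _TINY, 1.0 - np.finfo(float).epsneg))
    if log_p_pos < log_p_neg:
        positive = True
    elif log_p_pos > log_p_neg:
        positive = False
    else:
        positive = (ndes if ndes is not None and np.isfinite(ndes) else 0.0) >= 0.0
    magnitude = float(-special.ndtri_exp(log_p - np.log(2.0)))
    magnitude = min(magnitude, _NES_CLAMP)
    nes = magnitude if positive else -magnitude
    return p_pos, p_neg, p, nes


def _one_branch_significance(score: float):
    """Two-sided significance when only one score branch has variance."""
    log_tail = stats.norm.logsf(abs(score))
    p = float(np.clip(2.0 * np.exp(log_tail), _TINY, 1.0 - np.finfo(float).epsneg))
    nes = float(np.clip(score, -_NES_CLAMP, _NES_CLAMP))
    p_pos = float(np.exp(stats.norm.logsf(score)))
    return p_pos, 1.0 - p_pos, p, nes


def lindeberg_diagnostic(rss: RankSignSignature, reg: Regulon) -> float:
    """Largest per-member fraction of the null variance, over both branches.

    A share near 1/N indicates a well balanced gene set; a share close to
    one means a single member dominates and the normal approximation of
    the null may be poor.
    """
    vd = (reg.aw * reg.am) ** 2 * (rss.m_r2 - rss.m_rs**2)
    vu = (reg.aw * (1.0 - np.abs(reg.am))) ** 2 * (rss.m_r2 - rss.m_r**2)
    shares = []
    for v in (vd, vu):
        tot = v.sum()
        if tot > 0:
            shares.append(float(v.max() / tot))
    return max(shares) if shares else np.nan


# ---------------------------------------------------------------------------
# extremal placement and effect size


class _SignedPools:
    """Signature positions bucketed by sign, each sorted by rank descending.

    Used by the greedy extremal-placement search: within a sign bucket the
    value of a position to any member is a fixed coefficient times its
    rank, so each member's best available position is at one end of one
    bucket (rearrangement argument).
    """

    def __init__(self, rss: RankSignSignature):
        r, s = rss.r, rss.s
        self.r_desc = {}
        for cls in (1, -1, 0):
            vals = r[s == cls]
            vals = np.sort(vals)[::-1]
            self.r_desc[cls] = vals

    def fresh_pointers(self):
        # [hi, lo] inclusive index window per class
        return {cls: [0, len(vals) - 1] for cls, vals in self.r_desc.items()}


def _greedy_extremal_placement(pools: _SignedPools, coef_dir, coef_und, order):
    """Assign members to distinct positions maximizing
    ``sum coef_dir[g]*(r*s) + coef_und[g]*r`` greedily.

    Members are processed in decreasing coefficient magnitude; each takes
    the best position still available.  Returns the placed (r, s) arrays
    in member order.
    """
    ptr = pools.fresh_pointers()
    arrs = pools.r_desc
    n = len(coef_dir)
    r_out = np.empty(n)
    s_out = np.empty(n, dtype=np.int8)
    for g in order:
        cd = coef_dir[g]
        cu = coef_und[g]
        best_val = None
        best = None
        for cls in (1, -1, 0):
            hi, lo = ptr[cls]
            if hi > lo:
                continue
            coef = cd * cls + cu  # value per unit rank in this bucket
            if coef >= 0:
                val = coef * arrs[cls][hi]
                pick = ("hi", cls, arrs[cls][hi])
            else:
                val = coef * arrs[cls][lo]
                pick = ("lo", cls, arrs[cls][lo])
            if best_val is None or val > best_val:
                best_val = val
                best = pick
        if best is None:
            raise ValueError("regulon larger than signature: no positions left")
        end, cls, rv = best
        if end == "hi":
            ptr[cls][0] += 1
        else:
            ptr[cls][1] -= 1
        r_out[g] = rv
        s_out[g] = cls
    return r_out, s_out


def _nes_of_placement(rss, reg, r_placed, s_placed):
    des = float(np.sum(reg.aw * reg.am * r_placed * s_placed))
    ues = float(np.sum(reg.aw * (1.0 - np.abs(reg.am)) * r_placed))
    ndes, nues, phi = normalize_scores(rss, reg, des, ues)
    if not np.isfinite(phi):
        branch = ndes if np.isfinite(ndes) else nues
        return _one_branch_significance(branch)[3]
    nes_pos, nes_neg = combine_scores(ndes, nues, phi)
    return significance(nes_pos, nes_neg, ndes)[3]


def _extremal_nes(rss, reg, pools: _SignedPools, direction: int) -> float:
    """NES of the best (direction=+1) or worst (direction=-1) placement
    of the regulon members on distinct signature entries."""
    _, var_d, _, var_u, _ = _null_moments(rss, reg)
    sd = np.sqrt(var_d) if var_d > 0 else np.inf
    su = np.sqrt(var_u) if var_u > 0 else np.inf
    # contributions to NES+ (direction +1) or to -NES- (direction -1)
    coef_dir = direction * reg.aw * reg.am / sd
    coef_und = reg.aw * (1.0 - np.abs(reg.am)) / su
    magnitude = np.abs(coef_dir) + coef_und
    order = np.argsort(-magnitude, kind="stable")
    r_placed, s_placed = _greedy_extremal_placement(pools, coef_dir, coef_und, order)
    return _nes_of_placement(rss, reg, r_placed, s_placed)


def proportional_enrichment(
    rss: RankSignSignature,
    reg: Regulon,
    nes: float,
    pools: _SignedPools | None = None,
) -> float:
    """Effect size: NES relative to the extremal achievable NES.

    The extremal NES re-places the members on distinct signature entries
    (a real gene set occupies distinct genes, unlike the with-replacement
    null) chosen greedily per the rearrangement argument, and reruns the
    full score pipeline on that placement.
    """
    if reg.size > rss.n_genes:
        raise ValueError("regulon larger than signature")
    if nes == 0:
        raise ValueError("effect size undefined for NES = 0")
    if pools is None:
        pools = _SignedPools(rss)
    extremal = _extremal_nes(rss, reg, pools, +1 if nes > 0 else -1)
    if extremal == 0 or not np.isfinite(extremal):
        return np.nan
    return float(np.clip(nes / abs(extremal), -1.0, 1.0))


def pes_confidence_interval(
    rss: RankSignSignature,
    reg: Regulon,
    n_boot: int = 200,
    seed=None,
    conf: float = 0.95,
):
    """Bootstrap (members, with replacement) confidence interval for PES.

    The interval is normal-theory on the Fisher-z scale and back-
    transformed, which respects the [-1, 1] range of the effect size.
    """
    if reg.size < 2:
        raise ValueError("need at least 2 targets to bootstrap")
    rng = np.random.default_rng(seed)
    pools = _SignedPools(rss)
    idx_full = rss.index_of(reg.targets)
    point = _pes_of_member_sample(rss, reg, pools, idx_full, np.arange(reg.size))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, reg.size, reg.size)
        boots[b] = _pes_of_member_sample(rss, reg, pools, idx_full, take)
    zclip = 1.0 - 1e-12
    zb = np.arctanh(np.clip(boots, -zclip, zclip))
    z0 = np.arctanh(np.clip(point, -zclip, zclip))
    sd = float(np.std(zb, ddof=1))
    if sd == 0:
        warnings.warn("all bootstrap effect sizes identical; zero-width interval", stacklevel=2)
        return float(point), float(point)
    half = stats.norm.ppf(0.5 + conf / 2.0) * sd
    return float(np.tanh(z0 - half)), float(np.tanh(z0 + half))


def _pes_of_member_sample(rss, reg, pools, idx_full, take):
    sub = Regulon.__new__(Regulon)  # bypass uniqueness check: bootstrap repeats members
    object.__setattr__(sub, "regulator", reg.regulator)
    object.__setattr__(sub, "targets", reg.targets[take])
    object.__setattr__(sub, "aw", reg.aw[take])
    object.__setattr__(sub, "am", reg.am[take])
    idx = idx_full[take]
    des, ues = raw_scores(rss, sub, idx)
    ndes, nues, phi = normalize_scores(rss, sub, des, ues)
    if not np.isfinite(phi):
        branch = ndes if np.isfinite(ndes) else nues
        nes = _one_branch_significance(branch)[3]
    else:
        nes = significance(*combine_scores(ndes, nues, phi), ndes)[3]
    if nes == 0:
        return 0.0
    return proportional_enrichment(rss, sub, nes, pools)


# ---------------------------------------------------------------------------
# leading edge


def leading_edge(
    rss: RankSignSignature, reg: Regulon, nes: float, adjust: str = "bh"
) -> pd.DataFrame:
    """Per-member leading-edge scores and one-tailed p-values.

    LES weighs each member's realized (rank, sign) by its association
    mode, oriented by the sign of the enrichment; the p-value is the
    fraction of signature positions scoring at least as high under the
    same member-specific weighting, so p >= 1/G always.  Association
    weights are deliberately not used.
    """
    if nes == 0:
        raise ValueError("leading edge undefined for NES = 0")
    from .evaluation import multiple_testing

    idx = rss.index_of(reg.targets)
    sign = 1.0 if nes > 0 else -1.0
    r = rss.r[idx]
    rs = r * rss.s[idx]
    abs_am = np.abs(reg.am)
    les = (1.0 - abs_am) * r + sign * reg.am * rs
    all_r = rss.r[None, :]
    all_rs = (rss.r * rss.s)[None, :]
    pos_scores = (1.0 - abs_am)[:, None] * all_r + sign * reg.am[:, None] * all_rs
    p = (pos_scores >= les[:, None]).mean(axis=1)
    out = pd.DataFrame(
        {
            "regulator": reg.regulator,
            "target": reg.targets,
            "les": les,
            "p": p,
            "p_adj": multiple_testing(p, method=adjust),
        }
    )
    return out.sort_values("les", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# estimator and pipeline

_RESULT_COLUMNS = [
    "regulator",
    "size",
    "des",
    "ues",
    "ndes",
    "nues",
    "phi",
    "nes",
    "pes",
    "p",
    "p_bh",
    "p_bonf",
    "lindeberg_share",
]


class NaRnEA(BaseEstimator):
    """Gene set enrichment of weighted regulons in a differential signature.

    Parameters
    ----------
    regulons : RegulonSet
        Regulator -> weighted target set mapping to test.
    min_size : int, default 30
        Minimum surviving targets per regulon; below it the normal
        calibration of the score is not guaranteed (warn, or error when
        ``strict``).
    strict : bool, default False
        Raise instead of warning on undersized regulons.
    compute_pes : bool, default True
        Also compute the proportional (effect size) score.
    compute_leading_edge : bool, default False
        Compute per-member leading-edge results for every regulon.
    adjust : {"bh", "bonferroni"}, default "bh"
        Adjustment used for the leading-edge p-values.
    lindeberg_threshold : float, default 0.10
        Warn when one member carries more than this share of a null
        variance branch.

    Attributes
    ----------
    results_ : DataFrame
        One row per regulon with scores, p-values and adjusted p-values.
    leading_edge_ : DataFrame or None
        Per-member leading-edge table when requested.
    """

    def __init__(
        self,
        regulons: RegulonSet | None = None,
        min_size: int = 30,
        strict: bool = False,
        compute_pes: bool = True,
        compute_leading_edge: bool = False,
        adjust: str = "bh",
        lindeberg_threshold: float = 0.10,
    ):
        self.regulons = regulons
        self.min_size = min_size
        self.strict = strict
        self.compute_pes = compute_pes
        self.compute_leading_edge = compute_leading_edge
        self.adjust = adjust
        self.lindeberg_threshold = lindeberg_threshold

    def fit(self, X, y=None):
        """Run the enrichment test of every regulon against signature ``X``.

        ``X`` may be a :class:`DifferentialSignature`, a gene-indexed
        Series of z-values, or an already transformed
        :class:`RankSignSignature`.
        """
        from .evaluation import multiple_testing

        if self.regulons is None or len(self.regulons) == 0:
            raise ValueError("no regulons supplied")
        rss = _as_rank_sign(X)
        pools = _SignedPools(rss) if self.compute_pes else None
        rows = []
        ledges = []
        unbalanced = []
        for reg in self.regulons.values():
            try:
                reg_v = validate_regulon(reg, rss.gene_ids, self.min_size, self.strict)
            except ValueError as err:
                logger.warning("skipping regulon %s: %s", reg.regulator, err)
                continue
            row = self._score_one(rss, reg_v, pools)
            rows.append(row)
            if (
                np.isfinite(row["lindeberg_share"])
                and row["lindeberg_share"] > self.lindeberg_threshold
            ):
                unbalanced.append(reg.regulator)
            if self.compute_leading_edge and row["nes"] != 0:
                ledges.append(leading_edge(rss, reg_v, row["nes"], self.adjust))
        if not rows:
            raise ValueError("no regulon could be scored")
        if unbalanced:
            logger.warning(
                "%d regulon(s) have one member carrying more than %.0f%% of a null "
                "variance branch (e.g. %s); their normal calibration may be degraded",
                len(unbalanced),
                100 * self.lindeberg_threshold,
                ", ".join(map(str, unbalanced[:3])),
            )
        res = pd.DataFrame(rows)
        res["p_bh"] = multiple_testing(res["p"].to_numpy(), method="bh")
        res["p_bonf"] = multiple_testing(res["p"].to_numpy(), method="bonferroni")
        self.results_ = res[_RESULT_COLUMNS]
        self.leading_edge_ = (
            pd.concat(ledges, ignore_index=True) if ledges else None
        )
        return self

    def _score_one(self, rss, reg, pools):
        idx = rss.index_of(reg.targets)
        des, ues = raw_scores(rss, reg, idx)
        ndes, nues, phi = normalize_scores(rss, reg, des, ues)
        share = lindeberg_diagnostic(rss, reg)
        if not np.isfinite(phi):
            logger.warning(
                "regulon %s: degenerate score branch; using the surviving branch",
                reg.regulator,
            )
            branch = ndes if np.isfinite(ndes) else nues
            p_pos, p_neg, p, nes = _one_branch_significance(branch)
        else:
            nes_pos, nes_neg = combine_scores(ndes, nues, phi)
            p_pos, p_neg, p, nes = significance(nes_pos, nes_neg, ndes)
        pes = np.nan
        if pools is not None and nes != 0:
            pes = proportional_enrichment(rss, reg, nes, pools)
        return {
            "regulator": reg.regulator,
            "size": reg.size,
            "des": des,
            "ues": ues,
            "ndes": ndes,
            "nues": nues,
            "phi": phi,
            "nes": nes,
            "pes": pes,
            "p": p,
            "p_bh": np.nan,
            "p_bonf": np.nan,
            "lindeberg_share": share,
        }

    def transform(self, X) -> np.ndarray:
        """NES matrix for one or many signatures.

        ``X`` is a gene-indexed Series (one signature) or a genes-by-
        signatures DataFrame; returns an array of shape
        (n_signatures, n_regulons) of final enrichment scores, e.g. a
        protein-activity matrix when the regulons are regulatory target
        sets.
        """
        if isinstance(X, pd.DataFrame):
            cols = [X[c] for c in X.columns]
        else:
            cols = [X]
        est = NaRnEA(
            regulons=self.regulons,
            min_size=self.min_size,
            strict=self.strict,
            compute_pes=False,
        )
        mats = []
        for col in cols:
            est.fit(col)
            mats.append(est.results_["nes"].to_numpy())
        return np.vstack(mats)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def _as_rank_sign(X) -> RankSignSignature:
    if isinstance(X, RankSignSignature):
        return X
    if isinstance(X, DifferentialSignature):
        return rank_sign_transform(X)
    if isinstance(X, pd.Series):
        return rank_sign_transform(DifferentialSignature.from_series(X))
    raise TypeError(
        "expected a DifferentialSignature, RankSignSignature, or gene-indexed Series"
    )


def narnea(
    sig,
    regulons: RegulonSet,
    min_size: int = 30,
    strict: bool = False,
    compute_pes: bool = True,
    leading_edge: bool = False,
    adjust: str = "bh",
):
    """Functional front-end over :class:`NaRnEA`.

    Returns ``results`` (one row per regulon) or, when ``leading_edge``
    is requested, ``(results, leading_edge_table)``.
    """
    est = NaRnEA(
        regulons=regulons,
        min_size=min_size,
        strict=strict,
        compute_pes=compute_pes,
        compute_leading_edge=leading_edge,
        adjust=adjust,
    ).fit(sig)
    if leading_edge:
        return est.results_, est.leading_edge_
    return est.results_
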