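"""Validation analyses: agreement tables, calibration, null diagnostics.

Covers the cross-platform agreement analysis (ordered 3x3 contingency
tables of UP/NS/DOWN calls compared with Kendall's tau-b and a chi-squared
test), type-I-error calibration of the enrichment test on random and
totally-null gene sets, standard-normality checks of the null score
distribution, and the diagnostics that expose why phenotype-permutation
null signatures stay correlated with the original signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import NaRnEA
from .signature import DifferentialSignature
from .synthetic import random_regulons, synth_signature

__all__ = [
    "CATEGORIES",
    "TCGA_CPTAC_AGREEMENT",
    "classify_calls",
    "ContingencyResult",
    "contingency_analysis",
    "multiple_testing",
    "binomial_ci",
    "calibration_suite",
    "shuffled_null_diagnostics",
]

#: Ordered call categories for the agreement analysis.
CATEGORIES = ("DOWN", "NS", "UP")

#: Published 3x3 agreement tables between transcriptome-inferred differential
#: protein activity (rows) and mass-spectrometry differential protein
#: abundance (columns) for three TCGA/CPTAC cancer cohorts.  Axes are
#: ordered DOWN < NS < UP.
TCGA_CPTAC_AGREEMENT = {
    "LUAD": np.array([[204, 71, 40], [142, 131, 190], [77, 91, 279]]),
    "COAD": np.array([[111, 25, 18], [153, 66, 101], [104, 45, 167]]),
    "HNSC": np.array([[117, 71, 50], [95, 168, 187], [43, 97, 270]]),
}


def classify_calls(
    results: pd.DataFrame,
    effect_column: str,
    threshold: float = 0.05,
    method: str = "bh",
    p_column: str = "p",
) -> pd.Series:
    """UP / DOWN / NS calls from p-values and a signed effect column.

    UP means adjusted p strictly below the threshold with positive
    effect, DOWN the same with negative effect, NS otherwise (boundary
    p == threshold is NS).
    """
    p_adj = multiple_testing(results[p_column].to_numpy(), method=method)
    effect = results[effect_column].to_numpy(dtype=float)
    calls = np.where(
        (p_adj < threshold) & (effect > 0),
        "UP",
        np.where((p_adj < threshold) & (effect < 0), "DOWN", "NS"),
    )
    return pd.Series(pd.Categorical(calls, categories=list(CATEGORIES), ordered=True),
                     index=results.index, name="call")


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    residual_z: np.ndarray  # adjusted standardized residuals
    cell_fwer: np.ndarray  # Bonferroni-corrected per-cell significance
    chi2: float
    dof: int
    p: float
    tau_b: float
    tau_b_ci: tuple[float, float]


def contingency_analysis(observed, conf: float = 0.95) -> ContingencyResult:
    """Ordered 3x3 agreement analysis.

    Expected counts come from the independence model row*col/N; per-cell
    departures use the adjusted standardized residual
    (O-E)/sqrt(E(1-row/N)(1-col/N)) with two-sided normal p-values,
    Bonferroni-corrected across the 9 cells.  Overall association is the
    chi-squared statistic (dof 4) and Kendall's tau-b with both axes
    ordered DOWN < NS < UP (tie-corrected; normal-approximation CI).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (3, 3) or np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("observed must be a 3x3 table of nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    N = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / N
    denom = np.sqrt(expected * (1 - row[:, None] / N) * (1 - col[None, :] / N))
    z = (obs - expected) / denom
    cell_p = 2.0 * stats.norm.sf(np.abs(z))
    cell_fwer = np.minimum(cell_p * 9.0, 1.0)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=4))
    # tau-b on the expanded ordinal pairs
    rows_v = np.repeat(np.arange(3), obs.sum(axis=1).astype(int))
    cols_v = np.concatenate(
        [np.repeat(np.arange(3), obs[i].astype(int)) for i in range(3)]
    )
    tau = stats.kendalltau(rows_v, cols_v)
    tau_b = float(tau.statistic)
    se = _tau_b_se(obs)
    zq = stats.norm.ppf(0.5 + conf / 2.0)
    ci = (tau_b - zq * se, tau_b + zq * se)
    return ContingencyResult(
        obs.astype(int), expected, z, cell_fwer, chi2, 4, p, tau_b, ci
    )


def _tau_b_se(obs: np.ndarray) -> float:
    """Asymptotic standard error of tau-b for a contingency table.

    Uses the null-model perturbation variance sqrt(v0)/ (see Kendall &
    Gibbons): v0 = (4N + 10) / (9 N (N - 1)) corrected for ties in both
    margins through the tau-b denominator.
    """
    N = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n0 = N * (N - 1) / 2.0
    n1 = np.sum(row * (row - 1) / 2.0)
    n2 = np.sum(col * (col - 1) / 2.0)
    v0 = N * (N - 1) * (2 * N + 5)
    vt = np.sum(row * (row - 1) * (2 * row + 5))
    vu = np.sum(col * (col - 1) * (2 * col + 5))
    v1 = np.sum(row * (row - 1)) * np.sum(col * (col - 1)) / (2.0 * N * (N - 1))
    v2 = (
        np.sum(row * (row - 1) * (row - 2))
        * np.sum(col * (col - 1) * (col - 2))
        / (9.0 * N * (N - 1) * (N - 2))
    )
    var_num = (v0 - vt - vu) / 18.0 + v1 + v2
    return float(np.sqrt(var_num) / np.sqrt(n0 - n1) / np.sqrt(n0 - n2))


def multiple_testing(pvals, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjusted p-values (bounded by 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if method == "bh":
        return multipletests(pvals, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(pvals * pvals.size, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson (exact) confidence interval for a proportion."""
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=conf, method="exact")
    return float(ci.low), float(ci.high)


def calibration_suite(
    G: int,
    n_sets: int,
    size_range: tuple[int, int],
    seed=None,
    alpha: float = 0.05,
    compute_pes: bool = False,
) -> dict:
    """Type-I-error and null-distribution calibration of the enrichment test.

    Draws a null signature of G i.i.d. standard-normal values and
    ``n_sets`` random gene sets (copula-uniform weights, uniform modes),
    runs the enrichment pipeline, and reports the raw false-positive
    fraction at ``alpha``, the counts significant after BH and
    Bonferroni adjustment, and one-sample Kolmogorov-Smirnov statistics
    of NES against N(0, 1) and of p against Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    sig = synth_signature(G, seed=rng.integers(2**31))
    regs = random_regulons(n_sets, size_range, sig.gene_ids, seed=rng.integers(2**31))
    res = NaRnEA(regulons=regs, compute_pes=compute_pes).fit(sig).results_
    p = res["p"].to_numpy()
    nes = res["nes"].to_numpy()
    return {
        "fpr_raw": float(np.mean(p < alpha)),
        "n_sig_bh": int(np.sum(multiple_testing(p, "bh") < alpha)),
        "n_sig_bonf": int(np.sum(multiple_testing(p, "bonferroni") < alpha)),
        "ks_stat_nes": float(stats.kstest(nes, "norm").statistic),
        "ks_p_nes": float(stats.kstest(nes, "norm").pvalue),
        "ks_stat_p": float(stats.kstest(p, "uniform").statistic),
        "n_sets": int(len(res)),
        "results": res,
    }


def shuffled_null_diagnostics(
    null_sigs: list,
    original_sig: DifferentialSignature,
) -> pd.DataFrame:
    """Correlation of permutation null signatures with the original one.

    For each (null signature, imbalance record) pair, computes the
    Spearman correlation of null vs original z-values with its two-sided
    p-value and a Bonferroni-corrected significance flag, plus the
    association (Spearman) of those correlations with the net phenotype
    imbalance across the permutations.
    """
    orig = original_sig.to_series()
    rows = []
    for sig, record in null_sigs:
        aligned = sig.to_series().reindex(orig.index)
        rho, p = stats.spearmanr(aligned.to_numpy(), orig.to_numpy())
        rows.append(
            {
                "rho": float(rho),
                "p": float(p),
                "net_imbalance": record["net_imbalance"],
            }
        )
    df = pd.DataFrame(rows)
    m = len(df)
    df["significant_fwer"] = np.minimum(df["p"] * m, 1.0) < 0.05
    if df["net_imbalance"].nunique() > 1:
        assoc = stats.spearmanr(df["rho"], df["net_imbalance"])
        df.attrs["rho_imbalance_spearman"] = float(assoc.statistic)
        df.attrs["rho_imbalance_p"] = float(assoc.pvalue)
    return df
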