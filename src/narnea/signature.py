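"""Differential gene expression signatures and the rank/sign transform.

A differential signature assigns every gene a real value z comparing a test
phenotype against a reference phenotype (positive = higher in test).  The
enrichment statistic does not consume z directly; it consumes the
nonparametric transform (r, s) where r is the rank of |z| (ascending,
average rank on ties) and s = sign(z).  All null moments of the enrichment
scores are functions of the realized (r, s) vectors, so they are carried on
the transformed signature object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DifferentialSignature",
    "RankSignSignature",
    "mwu_signature",
    "rank_sign_transform",
    "read_signature",
    "write_signature",
    "read_expression",
]


@dataclass(frozen=True)
class DifferentialSignature:
    """Per-gene real differential expression values.

    Parameters
    ----------
    gene_ids : ndarray of str
        Unique gene identifiers.
    values : ndarray of float
        One finite real value per gene; positive means higher in the test
        phenotype.
    """

    gene_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        genes = np.asarray(self.gene_ids, dtype=object)
        vals = np.asarray(self.values, dtype=float)
        if genes.shape != vals.shape or genes.ndim != 1:
            raise ValueError("gene_ids and values must be 1-D and equal length")
        if genes.size < 2:
            raise ValueError("a signature needs at least 2 genes")
        if len(pd.unique(genes)) != genes.size:
            raise ValueError("duplicate gene identifiers in signature")
        if not np.all(np.isfinite(vals)):
            raise ValueError("signature values must be finite")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.gene_ids, name="z")

    @classmethod
    def from_series(cls, s: pd.Series) -> "DifferentialSignature":
        return cls(np.asarray(s.index, dtype=object), s.to_numpy(dtype=float))


@dataclass(frozen=True)
class RankSignSignature:
    """Rank/sign transformed signature with its maximum-entropy null moments.

    ``r`` holds ranks of |z| in [1, G] (average rank on ties) and ``s`` the
    signs in {-1, 0, +1}.  The four moments are the empirical means over the
    G signature entries of r*s, r, r**2 and (r**2)*s; under the null each
    gene-set member occupies one of the G entries uniformly and
    independently, so these are the exact per-member null moments.
    """

    gene_ids: np.ndarray
    r: np.ndarray
    s: np.ndarray
    m_rs: float = field(init=False)
    m_r: float = field(init=False)
    m_r2: float = field(init=False)
    m_r2s: float = field(init=False)

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        s = np.asarray(self.s, dtype=np.int8)
        object.__setattr__(self, "gene_ids", np.asarray(self.gene_ids, dtype=object))
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "s", s)
        rs = r * s
        object.__setattr__(self, "m_rs", float(rs.mean()))
        object.__setattr__(self, "m_r", float(r.mean()))
        object.__setattr__(self, "m_r2", float((r * r).mean()))
        object.__setattr__(self, "m_r2s", float((r * r * s).mean()))

    @property
    def n_genes(self) -> int:
        return self.r.size

    def index_of(self, genes) -> np.ndarray:
        """Positions of ``genes`` in this signature (error on misses)."""
        lookup = pd.Index(self.gene_ids)
        idx = lookup.get_indexer(np.asarray(genes, dtype=object))
        if np.any(idx < 0):
            missing = np.asarray(genes, dtype=object)[idx < 0][:5]
            raise KeyError(f"genes absent from signature: {list(missing)}")
        return idx


def rank_sign_transform(sig: DifferentialSignature) -> RankSignSignature:
    """Map z-values to (rank of |z|, sign of z).

    Ranks ascend with |z| and ties receive the average rank, so the rank sum
    G(G+1)/2 is conserved exactly.  sign(0) = 0: such genes carry rank mass
    into undirected terms but nothing into signed terms.
    """
    r = stats.rankdata(np.abs(sig.values), method="average")
    s = np.sign(sig.values).astype(np.int8)
    return RankSignSignature(sig.gene_ids, r, s)


def _tie_term(mat: np.ndarray) -> np.ndarray:
    """Per-row sum of t**3 - t over tied groups (for the MWU variance)."""
    srt = np.sort(mat, axis=1)
    out = np.zeros(mat.shape[0])
    for i in range(mat.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        t = counts[counts > 1].astype(float)
        if t.size:
            out[i] = np.sum(t**3 - t)
    return out


def mwu_signature(test, ref) -> DifferentialSignature:
    """Mann-Whitney differential signature: z per gene, test vs reference.

    z_g = (U_g - n1*n2/2) / sigma_U with the tie-corrected normal
    approximation; z > 0 iff the gene tends to be higher in the test
    phenotype.  Genes constant across all samples get z = 0 with a warning.

    ``test`` and ``ref`` are genes-by-samples DataFrames sharing the same
    gene index (any order), each with at least two samples.
    """
    test = _as_frame(test)
    ref = _as_frame(ref)
    if set(test.index) != set(ref.index):
        raise ValueError("test and reference matrices must share the same gene set")
    ref = ref.loc[test.index]
    n1, n2 = test.shape[1], ref.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per phenotype")
    combined = np.hstack([test.to_numpy(float), ref.to_numpy(float)])
    n = n1 + n2
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = _tie_term(combined)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros(combined.shape[0])
    ok = var > 0
    z[ok] = (u1[ok] - mu) / np.sqrt(var[ok])
    if np.any(~ok):
        warnings.warn(
            f"{int(np.sum(~ok))} gene(s) constant across all samples; z set to 0",
            stacklevel=2,
        )
    return DifferentialSignature(np.asarray(test.index, dtype=object), z)


def mwu_pvalues(test, ref) -> pd.Series:
    """Two-sided normal-approximation p-values for the MWU signature."""
    sig = mwu_signature(test, ref)
    p = 2.0 * stats.norm.sf(np.abs(sig.values))
    return pd.Series(p, index=sig.gene_ids, name="p")


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        if x.index.has_duplicates or x.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        return x
    raise TypeError("expected a genes-by-samples DataFrame")


# ---------------------------------------------------------------------------
# I/O: signature TSV has columns `gene`, `z`; expression TSV/CSV has the gene
# id in the first column and one column per sample.


def read_signature(path) -> DifferentialSignature:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "z"}.issubset(df.columns):
        raise ValueError("signature file needs columns 'gene' and 'z'")
    return DifferentialSignature(
        df["gene"].to_numpy(dtype=object), df["z"].to_numpy(dtype=float)
    )


def write_signature(sig: DifferentialSignature, path) -> None:
    pd.DataFrame({"gene": sig.gene_ids, "z": sig.values}).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return _as_frame(df)
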