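"""Weighted gene sets (regulons): representation, validation, weights, I/O.

A regulon is the target set of one regulatory protein.  Each target carries
an Association Weight (aw > 0, dependence strength) and an Association Mode
(am in [-1, 1], direction/monotonicity of regulation).  Literature gene
sets without weights are loaded with aw = 1, am = 1 for all members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Regulon",
    "RegulonSet",
    "copula_weights",
    "validate_regulon",
    "read_regulons",
    "write_regulons",
    "read_gene_lists",
]


@dataclass(frozen=True)
class Regulon:
    regulator: str
    targets: np.ndarray
    aw: np.ndarray
    am: np.ndarray

    def __post_init__(self):
        targets = np.asarray(self.targets, dtype=object)
        aw = np.asarray(self.aw, dtype=float)
        am = np.asarray(self.am, dtype=float)
        if not (targets.shape == aw.shape == am.shape) or targets.ndim != 1:
            raise ValueError("targets, aw, am must be 1-D arrays of equal length")
        if targets.size == 0:
            raise ValueError(f"regulon {self.regulator!r} has no targets")
        if len(pd.unique(targets)) != targets.size:
            raise ValueError(f"regulon {self.regulator!r} has duplicate targets")
        if np.any(aw <= 0) or not np.all(np.isfinite(aw)):
            raise ValueError(f"regulon {self.regulator!r}: association weights must be > 0")
        if np.any(np.abs(am) > 1) or not np.all(np.isfinite(am)):
            raise ValueError(f"regulon {self.regulator!r}: association modes must lie in [-1, 1]")
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "aw", aw)
        object.__setattr__(self, "am", am)

    @property
    def size(self) -> int:
        return self.targets.size

    def subset(self, mask: np.ndarray) -> "Regulon":
        return Regulon(self.regulator, self.targets[mask], self.aw[mask], self.am[mask])


class RegulonSet(dict):
    """Mapping regulator id -> :class:`Regulon` (insertion ordered)."""

    def __init__(self, regulons=()):
        super().__init__()
        for reg in regulons:
            self.add(reg)

    def add(self, reg: Regulon) -> None:
        if reg.regulator in self:
            raise ValueError(f"duplicate regulator id {reg.regulator!r}")
        self[reg.regulator] = reg

    @property
    def universe(self) -> np.ndarray:
        seen: dict = {}
        for reg in self.values():
            for t in reg.targets:
                seen.setdefault(t, None)
        return np.asarray(list(seen), dtype=object)


def copula_weights(raw_scores) -> np.ndarray:
    """Rank-uniform ("copula") association weights: rank / (N + 1).

    Maps any positive raw ordering score to weights in (0, 1) with an
    approximately uniform empirical distribution, which keeps gene sets
    well balanced enough for the central limit theorem behind the
    analytical null (no single member dominates the null variance).  Ties
    receive the average rank; the output is invariant under rescaling of
    the raw scores.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size < 1:
        raise ValueError("need at least one raw score")
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise ValueError("raw scores must be positive finite reals")
    ranks = stats.rankdata(raw, method="average")
    return ranks / (raw.size + 1.0)


def validate_regulon(reg: Regulon, sig_genes, min_size: int = 30, strict: bool = False) -> Regulon:
    """Drop targets absent from the signature; enforce a minimum size.

    Below ``min_size`` surviving targets the standard-normal calibration of
    the enrichment score is not guaranteed; this warns (or raises when
    ``strict``) rather than silently proceeding.
    """
    genes = pd.Index(np.asarray(sig_genes, dtype=object))
    mask = genes.get_indexer(reg.targets) >= 0
    if not mask.any():
        raise ValueError(f"regulon {reg.regulator!r} shares no genes with the signature")
    out = reg if mask.all() else reg.subset(mask)
    if out.size < min_size:
        msg = (
            f"regulon {reg.regulator!r} has {out.size} targets in the signature "
            f"(minimum {min_size}); normal calibration of the score is not guaranteed"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_regulons(path) -> RegulonSet:
    """Read a 4-column TSV ``regulator  target  aw  am`` (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target", "aw", "am"}
    if not required.issubset(df.columns):
        raise ValueError(f"regulon file needs columns {sorted(required)}")
    bad_aw = df.index[~(df["aw"] > 0)]
    if len(bad_aw):
        raise ValueError(f"non-positive association weight at row {bad_aw[0] + 2}")
    bad_am = df.index[df["am"].abs() > 1]
    if len(bad_am):
        raise ValueError(f"association mode outside [-1, 1] at row {bad_am[0] + 2}")
    out = RegulonSet()
    for regulator, grp in df.groupby("regulator", sort=False):
        out.add(
            Regulon(
                regulator,
                grp["target"].to_numpy(dtype=object),
                grp["aw"].to_numpy(dtype=float),
                grp["am"].to_numpy(dtype=float),
            )
        )
    return out


def write_regulons(regs: RegulonSet, path) -> None:
    frames = [
        pd.DataFrame(
            {"regulator": reg.regulator, "target": reg.targets, "aw": reg.aw, "am": reg.am}
        )
        for reg in regs.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gene_lists(path) -> RegulonSet:
    """Read plain gene lists: ``set_id<TAB>gene`` rows, or one-gene-per-line
    for a single unnamed set.  All members get aw = 1, am = 1 (equal-weight
    literature gene sets)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                rows.append(("geneset", parts[0]))
            else:
                rows.append((parts[0], parts[1]))
    df = pd.DataFrame(rows, columns=["regulator", "target"])
    out = RegulonSet()
    for regulator, grp in df.groupby("regulator", sort=False):
        genes = grp["target"].to_numpy(dtype=object)
        out.add(Regulon(regulator, genes, np.ones(genes.size), np.ones(genes.size)))
    return out
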