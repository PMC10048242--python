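"""Synthetic inputs with the statistical structure the method assumes.

These generators produce (a) null signatures of i.i.d. values, (b) random
gene sets matching the null-model construction (random complement swaps of
a template), (c) "totally null" gene sets drawn only from non-differential
genes, (d) signatures with a programmed enrichment of given gene sets, and
(e) expression matrices with known regulator->target dependencies for
exercising the network inference engine.  Everything is deterministic
under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regulon import Regulon, RegulonSet, copula_weights
from .signature import DifferentialSignature, mwu_signature

__all__ = [
    "synth_signature",
    "random_regulons",
    "tn_regulons",
    "active_regulons",
    "GroundTruthNetwork",
    "synth_expression",
    "shuffled_null_signatures",
]


def synth_signature(G: int, seed=None, dist: str = "normal") -> DifferentialSignature:
    """Null differential signature of G i.i.d. draws (standard normal by
    default; "uniform" gives Uniform(-1, 1))."""
    rng = np.random.default_rng(seed)
    if dist == "normal":
        z = rng.standard_normal(G)
    elif dist == "uniform":
        z = rng.uniform(-1.0, 1.0, G)
    else:
        raise ValueError(f"unknown distribution {dist!r}")
    genes = np.array([f"g{i}" for i in range(G)], dtype=object)
    return DifferentialSignature(genes, z)


def random_regulons(
    n_sets: int,
    size_range: tuple[int, int],
    universe,
    seed=None,
    template: RegulonSet | None = None,
) -> RegulonSet:
    """Random gene sets with copula-uniform weights and uniform modes.

    Without a template, ``n_sets`` member sets are drawn uniformly from
    the universe with sizes uniform over ``size_range``; weights are the
    copula transform of a random ordering and modes are Uniform(-1, 1).
    With a template ("swap mode", the null-model construction), each
    template regulon's members are replaced by an equal number of genes
    drawn from the complement of the member set, keeping its aw/am.
    """
    rng = np.random.default_rng(seed)
    universe = np.asarray(universe, dtype=object)
    out = RegulonSet()
    if template is not None:
        uindex = pd.Index(universe)
        for reg in template.values():
            member = np.zeros(universe.size, dtype=bool)
            idx = uindex.get_indexer(reg.targets)
            member[idx[idx >= 0]] = True
            pool = universe[~member]
            swapped = rng.choice(pool, size=reg.size, replace=False)
            out.add(Regulon(reg.regulator, swapped, reg.aw, reg.am))
        return out
    lo, hi = size_range
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        aw = copula_weights(rng.permutation(size) + 1.0)
        am = rng.uniform(-1.0, 1.0, size)
        out.add(Regulon(f"set{i}", members, aw, am))
    return out


def tn_regulons(
    sig: DifferentialSignature,
    n_sets: int,
    size_range: tuple[int, int],
    seed=None,
    test=None,
    ref=None,
    p_threshold: float = 0.50,
) -> RegulonSet:
    """Gene sets drawn only from central, non-differential genes.

    The eligible pool is genes whose two-sided Mann-Whitney p-value
    (test vs ref) exceeds ``p_threshold``; without expression matrices,
    the signature-only stand-in takes genes with |z| below the median.
    """
    rng = np.random.default_rng(seed)
    if test is not None and ref is not None:
        from .signature import mwu_pvalues

        p = mwu_pvalues(test, ref)
        pool = np.asarray(p.index[p.to_numpy() > p_threshold], dtype=object)
    else:
        absz = np.abs(sig.values)
        pool = sig.gene_ids[absz < np.median(absz)]
    if pool.size < size_range[1]:
        raise ValueError("central-gene pool smaller than the largest requested set")
    out = RegulonSet()
    lo, hi = size_range
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(pool, size=size, replace=False)
        aw = copula_weights(rng.permutation(size) + 1.0)
        am = rng.uniform(-1.0, 1.0, size)
        out.add(Regulon(f"tn{i}", members, aw, am))
    return out


def active_regulons(
    sig_base: DifferentialSignature,
    regs: RegulonSet,
    effect: float,
    seed=None,
) -> DifferentialSignature:
    """Signature with a programmed positive enrichment of given gene sets.

    Each target's z is shifted by ``effect * aw * sign(am)``, pushing
    positively regulated targets up and negatively regulated ones down —
    the mode-consistent pattern of an activated regulator.  ``effect = 0``
    returns the base signature unchanged.  Shifts from overlapping
    regulons accumulate.
    """
    z = sig_base.values.copy()
    index = pd.Index(sig_base.gene_ids)
    for reg in regs.values():
        idx = index.get_indexer(reg.targets)
        if np.any(idx < 0):
            raise KeyError(f"regulon {reg.regulator!r} has targets outside the signature")
        np.add.at(z, idx, effect * reg.aw * np.sign(reg.am))
    return DifferentialSignature(sig_base.gene_ids, z)


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Known regulator->target dependencies for expression simulation."""

    regulators: np.ndarray  # regulator ids
    targets: dict  # regulator -> array of target ids
    strength: dict  # regulator -> array in (0, 1]
    direction: dict  # regulator -> array in {-1, +1}
    decoys: np.ndarray  # ids of pure-noise genes

    @classmethod
    def random(
        cls,
        n_regulators: int,
        n_targets: int,
        n_decoys: int,
        seed=None,
        strength_range: tuple[float, float] = (0.6, 1.0),
    ) -> "GroundTruthNetwork":
        rng = np.random.default_rng(seed)
        regs = np.array([f"R{i}" for i in range(n_regulators)], dtype=object)
        targets, strength, direction = {}, {}, {}
        k = 0
        for r in regs:
            targets[r] = np.array([f"T{k + j}" for j in range(n_targets)], dtype=object)
            strength[r] = rng.uniform(*strength_range, n_targets)
            direction[r] = rng.choice([-1, 1], n_targets)
            k += n_targets
        decoys = np.array([f"D{i}" for i in range(n_decoys)], dtype=object)
        return cls(regs, targets, strength, direction, decoys)

    def true_edges(self) -> set:
        return {
            (r, t) for r in self.regulators for t in self.targets[r]
        }


def synth_expression(
    net: GroundTruthNetwork,
    n_samples: int,
    noise: float = 0.5,
    seed=None,
    reporter_noise: float = 0.1,
) -> pd.DataFrame:
    """Expression matrix realizing the ground-truth dependencies.

    Each regulator has a latent standard-normal activity per sample; its
    own transcript reports that activity with a little noise, and each
    target is ``direction * strength * activity + noise * eps``.  Values
    are mapped through exp() to non-negative abundances (a monotone map,
    so rank-based analyses are unaffected).  Decoy genes are pure noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ids = []
    for r in net.regulators:
        act = rng.standard_normal(n_samples)
        rows.append(act + reporter_noise * rng.standard_normal(n_samples))
        ids.append(r)
        st = net.strength[r]
        dr = net.direction[r]
        eps = rng.standard_normal((st.size, n_samples))
        rows.append(dr[:, None] * st[:, None] * act[None, :] + noise * eps)
        ids.extend(net.targets[r])
    if net.decoys.size:
        rows.append(rng.standard_normal((net.decoys.size, n_samples)))
        ids.extend(net.decoys)
    X = np.exp(np.vstack([np.atleast_2d(v) for v in rows]))
    cols = [f"s{j}" for j in range(n_samples)]
    return pd.DataFrame(X, index=pd.Index(ids, name="gene"), columns=cols)


def shuffled_null_signatures(
    test: pd.DataFrame, ref: pd.DataFrame, n_perm: int, seed=None
):
    """Phenotype-label permutation null signatures with imbalance records.

    All samples are pooled and randomly relabeled preserving the group
    sizes; for each permutation the Mann-Whitney signature of null-test
    vs null-reference is computed, together with how many original test
    samples landed in each null group (the imbalance that correlates
    null signatures with the original one when a real phenotype
    difference exists).

    Returns a list of ``(DifferentialSignature, record)`` where the
    record has keys ``n_test_in_null_test``, ``n_test_in_null_ref``,
    ``net_imbalance`` (test-sample excess of the null test group,
    normalized to [-1, 1]).
    """
    if list(test.index) != list(ref.index):
        ref = ref.loc[test.index]
    pooled = pd.concat([test, ref], axis=1)
    n1 = test.shape[1]
    n = pooled.shape[1]
    is_test = np.arange(n) < n1
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null_test = pooled.iloc[:, perm[:n1]]
        null_ref = pooled.iloc[:, perm[n1:]]
        sig = mwu_signature(null_test, null_ref)
        a = int(is_test[perm[:n1]].sum())
        b = int(is_test[perm[n1:]].sum())
        record = {
            "n_test_in_null_test": a,
            "n_test_in_null_ref": b,
            "net_imbalance": (a / n1) - (b / (n - n1)),
        }
        out.append((sig, record))
    return out
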