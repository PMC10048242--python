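import itertools

import numpy as np
import pytest
from scipy import stats

from narnea.enrichment import (
    NaRnEA,
    combine_scores,
    leading_edge,
    lindeberg_diagnostic,
    narnea,
    normalize_scores,
    pes_confidence_interval,
    proportional_enrichment,
    raw_scores,
    significance,
    _null_moments,
)
from narnea.regulon import Regulon, RegulonSet, copula_weights
from narnea.signature import DifferentialSignature, rank_sign_transform


def _regulon(targets, aw, am, name="r"):
    return Regulon(
        name,
        np.asarray(targets, dtype=object),
        np.asarray(aw, dtype=float),
        np.asarray(am, dtype=float),
    )


def _random_signature(G, seed):
    rng = np.random.default_rng(seed)
    return rank_sign_transform(
        DifferentialSignature(
            np.array([f"g{i}" for i in range(G)], dtype=object), rng.normal(size=G)
        )
    )


class TestRawScores:
    def test_worked_example(self, rss5, reg5):
        des, ues = raw_scores(rss5, reg5)
        assert des == pytest.approx(4.5)
        assert ues == pytest.approx(4.5)

    def test_pure_modes_zero_one_branch(self, rss5):
        monotone = _regulon(["g1", "g5"], [1, 1], [1, -1])
        assert raw_scores(rss5, monotone)[1] == 0.0
        undirected = _regulon(["g1", "g5"], [1, 1], [0, 0])
        assert raw_scores(rss5, undirected)[0] == 0.0


class TestEnumerationOracle:
    """Exhaustive check of the analytical null moments.

    The null places each member independently and uniformly over the G
    signature entries (with replacement), so for tiny G and regulon size
    N the empirical moments over all G**N placements must equal the
    analytical formulas essentially to machine precision.
    """

    @pytest.mark.parametrize("G,seed", [(4, 0), (5, 1), (6, 2)])
    @pytest.mark.parametrize("n_targets", [1, 2, 3])
    def test_moments_match_enumeration(self, G, seed, n_targets):
        rng = np.random.default_rng(seed)
        rss = _random_signature(G, seed + 100)
        aw = rng.uniform(0.2, 1.0, n_targets)
        am = rng.uniform(-1.0, 1.0, n_targets)
        reg = _regulon([f"g{i}" for i in range(n_targets)], aw, am)
        rs = rss.r * rss.s
        des_all, ues_all = [], []
        for placement in itertools.product(range(G), repeat=n_targets):
            idx = np.asarray(placement)
            des_all.append(np.sum(aw * am * rs[idx]))
            ues_all.append(np.sum(aw * (1 - np.abs(am)) * rss.r[idx]))
        des_all = np.asarray(des_all)
        ues_all = np.asarray(ues_all)
        mu_d, var_d, mu_u, var_u, cov = _null_moments(rss, reg)
        scale = rss.m_r2 * np.sum(aw)  # natural magnitude for tolerances
        assert des_all.mean() == pytest.approx(mu_d, abs=1e-12 * scale)
        assert des_all.var() == pytest.approx(var_d, abs=1e-12 * scale**2)
        assert ues_all.mean() == pytest.approx(mu_u, abs=1e-12 * scale)
        assert ues_all.var() == pytest.approx(var_u, abs=1e-12 * scale**2)
        emp_cov = np.mean(des_all * ues_all) - des_all.mean() * ues_all.mean()
        assert emp_cov == pytest.approx(cov, abs=1e-12 * scale**2)


class TestNormalizeAndCombine:
    def test_worked_example(self, rss5, reg5):
        ndes, nues, phi = normalize_scores(rss5, reg5, 4.5, 4.5)
        assert ndes == pytest.approx(3.1 / np.sqrt(4.52), abs=1e-10)
        assert nues == pytest.approx(1.5)
        assert phi == pytest.approx(1.4 / np.sqrt(4.52), abs=1e-10)
        nes_pos, nes_neg = combine_scores(ndes, nues, phi)
        assert nes_pos == pytest.approx(1.6242, abs=1e-4)
        assert nes_neg == pytest.approx(-0.0507, abs=1e-4)

    def test_phi_strictly_inside_unit_interval(self):
        rss = _random_signature(200, 3)
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            reg = _regulon(
                rng.choice(rss.gene_ids, n, replace=False),
                rng.uniform(0.1, 1, n),
                rng.uniform(-0.99, 0.99, n),
            )
            _, _, phi = normalize_scores(rss, reg, *raw_scores(rss, reg))
            assert -1 < phi < 1

    def test_null_monte_carlo_standardization(self):
        rss = _random_signature(500, 5)
        rng = np.random.default_rng(6)
        n = 40
        aw = copula_weights(np.arange(1.0, n + 1))
        am = rng.uniform(-1, 1, n)
        reg = _regulon(rss.gene_ids[:n], aw, am)
        mu_d, var_d, mu_u, var_u, cov = _null_moments(rss, reg)
        B = 100_000
        draws = rng.integers(0, rss.n_genes, (B, n))
        rs = (rss.r * rss.s)[draws]
        r = rss.r[draws]
        ndes = ((aw * am * rs).sum(1) - mu_d) / np.sqrt(var_d)
        nues = ((aw * (1 - np.abs(am)) * r).sum(1) - mu_u) / np.sqrt(var_u)
        se = 3.0 / np.sqrt(B)
        assert abs(ndes.mean()) < se and abs(nues.mean()) < se
        assert abs(ndes.var() - 1) < 3 * np.sqrt(2 / B) * 2
        assert abs(nues.var() - 1) < 3 * np.sqrt(2 / B) * 2
        # rotated scores: unit variance, uncorrelated, independent tails
        phi = cov / np.sqrt(var_d * var_u)
        nes_pos = (ndes + nues) / np.sqrt(2 + 2 * phi)
        nes_neg = (ndes - nues) / np.sqrt(2 - 2 * phi)
        assert abs(nes_pos.var() - 1) < 0.03
        assert abs(nes_neg.var() - 1) < 0.03
        assert abs(np.corrcoef(nes_pos, nes_neg)[0, 1]) < se
        p_pos = stats.norm.sf(nes_pos)
        p_neg = stats.norm.cdf(nes_neg)
        assert abs(np.corrcoef(p_pos, p_neg)[0, 1]) < se

    def test_degenerate_phi_errors(self):
        with pytest.raises(ValueError, match="phi"):
            combine_scores(1.0, 1.0, 1.0)


class TestSignificance:
    def test_zero_scores(self):
        p_pos, p_neg, p, nes = significance(0.0, 0.0, ndes=1.0)
        assert p_pos == pytest.approx(0.5)
        assert p_neg == pytest.approx(0.5)
        assert p == pytest.approx(0.75)
        assert nes > 0  # tie broken by the directed branch sign

    def test_worked_example(self, rss5, reg5):
        ndes, nues, phi = normalize_scores(rss5, reg5, *raw_scores(rss5, reg5))
        p_pos, p_neg, p, nes = significance(*combine_scores(ndes, nues, phi), ndes)
        assert p_pos == pytest.approx(0.0522, abs=2e-4)
        assert p_neg == pytest.approx(0.4798, abs=2e-4)
        assert p == pytest.approx(0.1017, abs=5e-4)
        assert nes == pytest.approx(1.637, abs=2e-3)

    def test_sidak_combination_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = rng.normal(size=2) * 3
            p_pos, p_neg, p, _ = significance(a, b)
            assert p == pytest.approx(1 - (1 - min(p_pos, p_neg)) ** 2, rel=1e-9)

    def test_extreme_scores_stay_finite(self):
        p_pos, p_neg, p, nes = significance(60.0, 50.0, ndes=5.0)
        assert 0 < p < 1
        assert np.isfinite(nes) and nes > 30


class TestProportionalEnrichment:
    def test_worked_example_is_maximal(self, rss5, reg5):
        res = narnea(
            DifferentialSignature(rss5.gene_ids, rss5.r * rss5.s),  # same ranks/signs
            RegulonSet([reg5]),
            min_size=2,
        )
        assert res.loc[0, "pes"] == pytest.approx(1.0)

    def test_exhaustive_extremal_check(self, rss5, reg5):
        """Greedy extremal placement matches brute force over all C(5,2)
        ordered placements of the two targets on distinct entries."""
        best = -np.inf
        rs = rss5.r * rss5.s
        for i, j in itertools.permutations(range(5), 2):
            des = 0.5 * (rs[i] + rs[j])
            ues = 0.5 * (rss5.r[i] + rss5.r[j])
            ndes, nues, phi = normalize_scores(rss5, reg5, des, ues)
            nes = significance(*combine_scores(ndes, nues, phi), ndes)[3]
            best = max(best, nes)
        obs = significance(
            *combine_scores(*normalize_scores(rss5, reg5, *raw_scores(rss5, reg5))),
        )[3]
        assert proportional_enrichment(rss5, reg5, obs) == pytest.approx(obs / best)
        assert obs / best == pytest.approx(1.0)  # observed placement is the best

    def test_greedy_matches_bruteforce_homogeneous_modes(self):
        """With a shared association mode the extremal placement is a pure
        rearrangement problem, so the greedy must be exactly optimal."""
        rng = np.random.default_rng(8)
        for seed in range(5):
            rss = _random_signature(7, seed + 10)
            n = 3
            aw = rng.uniform(0.2, 1, n)
            am = np.full(n, rng.uniform(-1, 1))
            reg = _regulon(rss.gene_ids[:n], aw, am)
            rs = rss.r * rss.s
            best, worst = -np.inf, np.inf
            for comb in itertools.permutations(range(7), n):
                idx = np.asarray(comb)
                des = float(np.sum(aw * am * rs[idx]))
                ues = float(np.sum(aw * (1 - np.abs(am)) * rss.r[idx]))
                ndes, nues, phi = normalize_scores(rss, reg, des, ues)
                if not np.isfinite(phi):
                    continue
                nes = significance(*combine_scores(ndes, nues, phi), ndes)[3]
                best = max(best, nes)
                worst = min(worst, nes)
            obs = significance(
                *combine_scores(*normalize_scores(rss, reg, *raw_scores(rss, reg))),
            )[3]
            if obs != 0:
                pes = proportional_enrichment(rss, reg, obs)
                expected = obs / abs(best) if obs > 0 else obs / abs(worst)
                assert pes == pytest.approx(np.clip(expected, -1, 1), abs=1e-9)

    def test_bounded_and_mean_zero_under_null(self):
        rss = _random_signature(300, 11)
        rng = np.random.default_rng(12)
        n = 30
        aw = copula_weights(np.arange(1.0, n + 1))
        am = rng.uniform(-1, 1, n)
        pes_vals = []
        for _ in range(300):
            members = rng.choice(rss.gene_ids, n, replace=False)
            reg = _regulon(members, aw, am)
            des, ues = raw_scores(rss, reg)
            ndes, nues, phi = normalize_scores(rss, reg, des, ues)
            nes = significance(*combine_scores(ndes, nues, phi), ndes)[3]
            if nes != 0:
                pes_vals.append(proportional_enrichment(rss, reg, nes))
        pes_vals = np.asarray(pes_vals)
        assert np.all(np.abs(pes_vals) <= 1.0)
        assert abs(pes_vals.mean()) < 3 * pes_vals.std() / np.sqrt(pes_vals.size)

    def test_sign_symmetry_of_nes_and_pes(self):
        rng = np.random.default_rng(13)
        G = 400
        genes = np.array([f"g{i}" for i in range(G)], dtype=object)
        z = rng.normal(size=G)
        n = 40
        reg = _regulon(
            genes[:n], copula_weights(np.arange(1.0, n + 1)), rng.uniform(-1, 1, n)
        )
        regs = RegulonSet([reg])
        res_pos = narnea(DifferentialSignature(genes, z), regs, min_size=2)
        res_neg = narnea(DifferentialSignature(genes, -z), regs, min_size=2)
        assert res_pos.loc[0, "nes"] == pytest.approx(-res_neg.loc[0, "nes"], rel=1e-6)
        assert res_pos.loc[0, "pes"] == pytest.approx(-res_neg.loc[0, "pes"], rel=1e-4)


class TestPESConfidenceInterval:
    def _setup(self, n, seed):
        rss = _random_signature(500, seed)
        rng = np.random.default_rng(seed + 1)
        reg = _regulon(
            rss.gene_ids[:n], copula_weights(np.arange(1.0, n + 1)), rng.uniform(-1, 1, n)
        )
        return rss, reg

    def test_interval_contains_point_and_is_seeded(self):
        rss, reg = self._setup(30, 20)
        des, ues = raw_scores(rss, reg)
        nes = significance(
            *combine_scores(*normalize_scores(rss, reg, des, ues)),
        )[3]
        pes = proportional_enrichment(rss, reg, nes)
        lo, hi = pes_confidence_interval(rss, reg, n_boot=100, seed=0)
        assert lo <= pes <= hi
        assert (lo, hi) == pes_confidence_interval(rss, reg, n_boot=100, seed=0)

    def test_width_shrinks_with_size(self):
        widths = []
        for n in (30, 100, 300):
            rss, reg = self._setup(n, 21)
            lo, hi = pes_confidence_interval(rss, reg, n_boot=80, seed=1)
            widths.append(hi - lo)
        assert widths[2] < widths[0]


class TestLeadingEdge:
    def test_worked_example_enumeration(self, rss5, reg5):
        table = leading_edge(rss5, reg5, nes=1.6)
        g5 = table.set_index("target").loc["g5"]
        assert g5["les"] == pytest.approx(5.0)
        assert g5["p"] == pytest.approx(1 / 5)

    def test_zero_mode_reduces_to_rank_tail(self):
        rss = _random_signature(50, 30)
        reg = _regulon(rss.gene_ids[:5], np.full(5, 0.7), np.zeros(5))
        table = leading_edge(rss, reg, nes=2.0).set_index("target")
        idx = rss.index_of(reg.targets)
        for t, i in zip(reg.targets, idx):
            assert table.loc[t, "les"] == pytest.approx(rss.r[i])
            assert table.loc[t, "p"] == pytest.approx(np.mean(rss.r >= rss.r[i]))

    def test_p_at_least_one_over_G(self):
        rss = _random_signature(80, 31)
        rng = np.random.default_rng(32)
        reg = _regulon(
            rss.gene_ids[:20], rng.uniform(0.1, 1, 20), rng.uniform(-1, 1, 20)
        )
        for nes in (1.5, -1.5):
            table = leading_edge(rss, reg, nes=nes)
            assert (table["p"] >= 1 / 80 - 1e-12).all()

    def test_requires_nonzero_nes(self, rss5, reg5):
        with pytest.raises(ValueError, match="undefined"):
            leading_edge(rss5, reg5, nes=0.0)


class TestLindebergDiagnostic:
    def test_equal_weights_share_is_one_over_n(self):
        rss = _random_signature(100, 40)
        n = 25
        reg = _regulon(rss.gene_ids[:n], np.full(n, 0.3), np.full(n, 0.5))
        assert lindeberg_diagnostic(rss, reg) == pytest.approx(1 / n)

    def test_dominant_weight_flags(self):
        rss = _random_signature(100, 41)
        aw = np.full(10, 0.01)
        aw[0] = 1.0
        reg = _regulon(rss.gene_ids[:10], aw, np.full(10, 0.5))
        assert lindeberg_diagnostic(rss, reg) > 0.9

    def test_copula_regulon_is_balanced(self):
        rss = _random_signature(1000, 42)
        n = 50
        reg = _regulon(
            rss.gene_ids[:n], copula_weights(np.arange(1.0, n + 1)), np.full(n, 0.5)
        )
        assert lindeberg_diagnostic(rss, reg) < 0.10


class TestPipeline:
    def test_degenerate_branches_fall_back(self, rss5):
        sig = DifferentialSignature(rss5.gene_ids, [2.0, -1.0, 0.5, -0.2, 3.0])
        pure = RegulonSet(
            [
                _regulon(["g1", "g5"], [1, 1], [1, 1], "monotone"),
                _regulon(["g1", "g5"], [1, 1], [0, 0], "undirected"),
            ]
        )
        res = narnea(sig, pure, min_size=2).set_index("regulator")
        assert np.isnan(res.loc["monotone", "phi"])
        assert res.loc["monotone", "nes"] == pytest.approx(res.loc["monotone", "ndes"])
        assert res.loc["undirected", "nes"] == pytest.approx(
            res.loc["undirected", "nues"]
        )

    def test_column_snapshot_and_determinism(self, sig5, reg5):
        regs = RegulonSet([reg5])
        res1 = narnea(sig5, regs, min_size=2)
        res2 = narnea(sig5, regs, min_size=2)
        assert list(res1.columns) == [
            "regulator", "size", "des", "ues", "ndes", "nues", "phi",
            "nes", "pes", "p", "p_bh", "p_bonf", "lindeberg_share",
        ]
        assert res1.equals(res2)

    def test_power_increases_with_effect(self):
        from narnea.synthetic import active_regulons, random_regulons, synth_signature

        base = synth_signature(2000, seed=50)
        regs = random_regulons(20, (50, 50), base.gene_ids, seed=51)
        medians = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            sig = active_regulons(base, regs, effect)
            res = narnea(sig, regs, compute_pes=False)
            medians.append(res["nes"].median())
        assert medians == sorted(medians)
        assert medians[-1] > medians[0] + 2

    def test_empty_regulon_set_errors(self, sig5):
        with pytest.raises(ValueError, match="no regulons"):
            narnea(sig5, RegulonSet())

    def test_sklearn_params_roundtrip(self):
        est = NaRnEA(min_size=10, adjust="bonferroni")
        params = est.get_params()
        assert params["min_size"] == 10
        est2 = NaRnEA().set_params(**params)
        assert est2.get_params() == params

    def test_transform_returns_activity_matrix(self):
        import pandas as pd

        from narnea.synthetic import random_regulons, synth_signature

        sigs = {
            f"c{j}": synth_signature(300, seed=60 + j).to_series() for j in range(3)
        }
        X = pd.DataFrame(sigs)
        regs = random_regulons(4, (30, 40), X.index.to_numpy(dtype=object), seed=70)
        mat = NaRnEA(regulons=regs).fit(X["c0"]).transform(X)
        assert mat.shape == (3, 4)
        assert np.all(np.isfinite(mat))
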