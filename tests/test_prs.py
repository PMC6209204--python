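import math

import numpy as np
import pandas as pd
import pytest

from pedprio.pedigree import Individual, Pedigree
from pedprio.prs import (
    DEFAULT_THRESHOLDS,
    DosageMatrix,
    PrsAssociation,
    clump,
    expected_kinship,
    grm,
    polygenic_residuals,
    prs_association,
    score,
    threshold_sweep,
)
from pedprio.simulate import (
    SimConfig,
    simulate_array,
    simulate_gwas,
    simulate_pedigree,
    simulate_prs_cohort,
)


def _dosage(df_values, ids, snps, chroms=None, pos=None):
    n = len(snps)
    meta = pd.DataFrame(
        {
            "chrom": chroms or ["1"] * n,
            "pos": pos or list(range(1000, 1000 + 1000 * n, 1000)),
        },
        index=pd.Index(snps, name="snp"),
    )
    return DosageMatrix(pd.DataFrame(df_values, index=ids, columns=snps), meta)


def _stats(snps, betas, ps, chroms=None, pos=None):
    n = len(snps)
    return pd.DataFrame(
        {
            "snp": snps,
            "chrom": chroms or ["1"] * n,
            "pos": pos or list(range(1000, 1000 + 1000 * n, 1000)),
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "beta": betas,
            "p": ps,
        }
    )


class TestClump:
    def test_perfect_ld_keeps_smaller_p(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.5, 50).astype(float)
        geno = _dosage(np.column_stack([x, x]), [f"i{k}" for k in range(50)], ["a", "b"])
        stats = _stats(["a", "b"], [0.1, 0.1], [1e-9, 1e-5])
        assert clump(stats, geno) == ["a"]

    def test_different_chromosomes_both_kept(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.5, 50).astype(float)
        geno = _dosage(
            np.column_stack([x, x]), [f"i{k}" for k in range(50)], ["a", "b"],
            chroms=["1", "2"], pos=[1000, 1000],
        )
        stats = _stats(["a", "b"], [0.1, 0.1], [1e-9, 1e-5], chroms=["1", "2"], pos=[1000, 1000])
        assert set(clump(stats, geno)) == {"a", "b"}

    def test_matches_brute_force_greedy_on_ld_block(self):
        rng = np.random.default_rng(5)
        n, m = 200, 10
        z = rng.binomial(1, 0.5, (n, 2))
        G = np.empty((n, m))
        for j in range(m):
            latent = z[:, 0] if j < 5 else z[:, 1]
            flip = rng.random(n) < 0.15
            G[:, j] = np.where(flip, 1 - latent, latent) + rng.binomial(1, 0.5, n)
        snps = [f"s{j}" for j in range(m)]
        pos = list(range(10_000, 10_000 + 1000 * m, 1000))
        geno = _dosage(G, [f"i{k}" for k in range(n)], snps, pos=pos)
        ps = rng.uniform(1e-8, 1e-2, m)
        stats = _stats(snps, [0.1] * m, ps, pos=pos)

        kept = clump(stats, geno, r2_max=0.1, window_kb=500)

        # independent greedy oracle over the full correlation matrix
        C = np.corrcoef(G, rowvar=False) ** 2
        order = sorted(range(m), key=lambda j: (ps[j], snps[j]))
        removed, expect = set(), []
        for j in order:
            if j in removed:
                continue
            expect.append(snps[j])
            for t in range(m):
                if t != j and t not in removed and snps[t] not in expect:
                    if abs(pos[t] - pos[j]) <= 500_000 and C[j, t] > 0.1:
                        removed.add(t)
        assert kept == expect

    def test_no_overlap_is_error(self):
        geno = _dosage([[0.0]], ["i0"], ["a"])
        stats = _stats(["zzz"], [0.1], [0.5])
        with pytest.raises(ValueError, match="shared"):
            clump(stats, geno)


class TestScore:
    def test_extremes_hit_bounds(self):
        geno = _dosage([[0.0, 0.0], [2.0, 2.0]], ["lo", "hi"], ["a", "b"])
        stats = _stats(["a", "b"], [0.2, 0.4], [1e-9, 1e-9])
        res = score(geno, stats, 0.05)
        assert res.scores["lo"] == pytest.approx(0.0)
        assert res.scores["hi"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        geno = _dosage([[1.0, 2.0]], ["i1"], ["a", "b"])
        stats = _stats(["a", "b"], [0.1, 0.3], [1e-9, 1e-9])
        assert score(geno, stats, 0.05).scores["i1"] == pytest.approx(0.875)

    def test_zero_snps_flags_undefined(self):
        geno = _dosage([[1.0]], ["i1"], ["a"])
        stats = _stats(["a"], [0.1], [0.5])
        res = score(geno, stats, 1e-8)
        assert res.undefined and res.n_snps == 0

    def test_snp_reorder_invariance(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.4, (20, 6)).astype(float)
        snps = [f"s{j}" for j in range(6)]
        geno = _dosage(G, [f"i{k}" for k in range(20)], snps)
        stats = _stats(snps, rng.normal(size=6), rng.uniform(1e-6, 0.04, 6))
        a = score(geno, stats, 0.05).scores
        b = score(geno, stats.iloc[::-1].reset_index(drop=True), 0.05).scores
        assert np.allclose(a, b)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.4, (20, 4)).astype(float)
        snps = [f"s{j}" for j in range(4)]
        geno = _dosage(G, [f"i{k}" for k in range(20)], snps)
        betas = np.abs(rng.normal(size=4)) + 0.05
        stats = _stats(snps, betas, [1e-6] * 4)
        base = score(geno, stats, 0.05).scores
        # flip snp 2: negate beta and complement the dosage
        G2 = G.copy()
        G2[:, 2] = 2 - G2[:, 2]
        geno2 = _dosage(G2, [f"i{k}" for k in range(20)], snps)
        stats2 = stats.copy()
        stats2.loc[2, "beta"] = -stats2.loc[2, "beta"]
        assert np.allclose(base, score(geno2, stats2, 0.05).scores)

    def test_scores_always_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            m = rng.integers(1, 8)
            G = rng.binomial(2, rng.uniform(0.05, 0.95), (15, m)).astype(float)
            snps = [f"s{j}" for j in range(m)]
            geno = _dosage(G, [f"i{k}" for k in range(15)], snps)
            stats = _stats(snps, rng.normal(size=m), rng.uniform(1e-8, 0.04, m))
            s = score(geno, stats, 0.05).scores.to_numpy()
            assert (s >= -1e-12).all() and (s <= 1 + 1e-12).all()


class TestKinship:
    def test_identical_rows_match_diagonal(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.5, 30).astype(float)
        geno = _dosage(np.vstack([x, x]), ["a", "b"], [f"s{j}" for j in range(30)])
        K = grm(geno)
        assert K.values[0, 1] == pytest.approx(K.values[0, 0])

    def test_unrelated_panel_mean_off_diagonal_near_zero(self):
        rng = np.random.default_rng(1)
        n, m = 100, 2000
        G = rng.binomial(2, rng.uniform(0.1, 0.9, m), (n, m)).astype(float)
        K = grm(_dosage(G, [f"i{k}" for k in range(n)], [f"s{j}" for j in range(m)]))
        off = K.values[np.triu_indices(n, 1)]
        # centring at sample frequencies makes rows sum to ~0, so the mean
        # off-diagonal carries a deterministic -1/(n-1) finite-sample offset
        se = off.std() / math.sqrt(len(off))
        assert abs(off.mean() + 1.0 / (n - 1)) < 3 * se + 1e-3
        assert abs(off.mean()) < 2.0 / n

    def test_parent_offspring_relatedness_half(self):
        # gene-dropped genotypes over 30 independent trios: GRM parent-child
        # entries average ~ 0.5 (sample-frequency centring needs many
        # unrelated families to be unbiased)
        trios = []
        for t in range(30):
            trios += [
                Individual(f"f{t}"),
                Individual(f"m{t}"),
                Individual(f"c{t}", f"f{t}", f"m{t}"),
            ]
        ped = Pedigree(trios)
        cfg = SimConfig(seed=8, n_array_snps=10_000, ld_block_size=1)
        dos, _ = simulate_array(ped, cfg, np.random.default_rng(8))
        K = grm(dos)
        pos = {iid: i for i, iid in enumerate(K.ids)}
        vals = [
            K.values[pos[f"c{t}"], pos[p + str(t)]]
            for t in range(30)
            for p in ("f", "m")
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_monomorphic_only_is_error(self):
        geno = _dosage([[2.0], [2.0]], ["a", "b"], ["s0"])
        with pytest.raises(ValueError, match="polymorphic"):
            grm(geno)

    def test_expected_kinship_parent_child(self, sib_pair_pedigree):
        K = expected_kinship(sib_pair_pedigree)
        pos = {iid: i for i, iid in enumerate(K.ids)}
        assert K.values[pos["s1"], pos["f"]] == pytest.approx(0.25)
        assert K.values[pos["s1"], pos["s2"]] == pytest.approx(0.25)
        assert K.values[pos["f"], pos["m"]] == pytest.approx(0.0)


class TestPolygenicModel:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        from pedprio.prs import KinshipMatrix

        K = KinshipMatrix(np.eye(n), [f"i{k}" for k in range(n)], source="genomic")
        fit = polygenic_residuals(y, x[:, None], K)
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        ols_resid = y - X @ beta_ols
        # with A = I the variance split is unidentifiable and the model
        # collapses to the zero-genetic-variance boundary: plain OLS
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)
        assert fit.sigma_g2 == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.residuals.to_numpy(), ols_resid, atol=1e-6)
        full = polygenic_residuals(y, x[:, None], K, residual_type="full")
        assert np.allclose(full.residuals.to_numpy(), ols_resid, atol=1e-6)

    def test_heritability_recovery_on_pedigree(self, three_generation_pedigree):
        # phenotype with sigma_g2 = sigma_e2 = 1 on stacked pedigree copies
        base = expected_kinship(three_generation_pedigree)
        A = 2 * base.values
        n_rep, h2s = 60, []
        rng = np.random.default_rng(42)
        from scipy.linalg import cholesky

        from pedprio.prs import KinshipMatrix

        n = A.shape[0]
        L = cholesky(A + 1e-10 * np.eye(n), lower=True)
        blocks = 12  # 12 independent family copies per replicate
        ids = [f"i{k}" for k in range(n * blocks)]
        Abig = np.kron(np.eye(blocks), A)
        K = KinshipMatrix(Abig, ids, source="genomic")
        for _ in range(n_rep):
            g = np.concatenate([L @ rng.normal(size=n) for _ in range(blocks)])
            y = g + rng.normal(size=n * blocks)
            fit = polygenic_residuals(y, None, K)
            h2s.append(fit.h2)
        assert 0.3 <= float(np.median(h2s)) <= 0.7

    def test_singular_covariates_error(self):
        from pedprio.prs import KinshipMatrix

        K = KinshipMatrix(np.eye(10), [f"i{k}" for k in range(10)])
        x = np.ones(10)
        with pytest.raises(ValueError, match="singular"):
            polygenic_residuals(np.arange(10.0), np.column_stack([x, x]), K)


class TestAssociation:
    def test_perfect_association(self):
        x = np.linspace(0.1, 0.9, 30)
        res = prs_association(2.0 * x, x, n_boot=100, n_perm=500, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_perm <= 1.0 / 501 + 1e-9
        assert res.ci95[0] <= res.slope <= res.ci95[1]

    def test_constant_prs_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            PrsAssociation(np.arange(5.0), np.ones(5))

    def test_default_settings_echoed(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = PrsAssociation(y, x).fit(n_boot=2000, n_perm=10000, seed=7)
        assert (res.n_boot, res.n_perm, res.seed) == (2000, 10000, 7)

    def test_bootstrap_ci_coverage(self):
        rng = np.random.default_rng(3)
        n, true_slope, covered = 50, 1.5, 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=n)
            y = true_slope * x + rng.normal(size=n)
            res = prs_association(y, x, n_boot=400, n_perm=1, seed=int(rng.integers(2**31)))
            covered += res.ci95[0] <= true_slope <= res.ci95[1]
        assert 0.90 <= covered / n_rep <= 0.99

    def test_permutation_agrees_with_analytic_p(self):
        rng = np.random.default_rng(4)
        n = 100
        x = rng.normal(size=n)
        y = 0.2 * x + rng.normal(size=n)
        res = prs_association(y, x, n_boot=50, n_perm=4000, seed=9)
        assert abs(res.p_perm - res.p_one_sided) < 0.02


class TestThresholdSweep:
    def test_ten_thresholds_ten_results(self):
        cfg = SimConfig(seed=21)
        rng = np.random.default_rng(21)
        stats_df, truth = simulate_gwas(cfg, rng)
        dos, liab, _ = simulate_prs_cohort(stats_df, truth, cfg, 120, rng)
        sweep = threshold_sweep(dos, stats_df, liab, n_boot=50, n_perm=99, seed=1)
        assert len(sweep.results) == len(DEFAULT_THRESHOLDS)
        frame = sweep.to_frame()
        assert list(frame["threshold"]) == list(DEFAULT_THRESHOLDS)

    def test_bonferroni_flag_stricter_than_nominal(self):
        # a nominal p of 0.027 is significant at 0.05 but not at 0.05/10
        from pedprio.prs import AssocResult, SweepResult

        res = [
            AssocResult(t, 1.0, 1.0, 0.1, (0.0, 2.0), 0.027, 0.03, 10, 10, 0)
            for t in DEFAULT_THRESHOLDS
        ]
        sweep = SweepResult(res)
        assert not any(sweep.bonferroni_significant)
        res2 = [
            AssocResult(t, 1.0, 1.0, 0.1, (0.0, 2.0), 0.004, 0.004, 10, 10, 0)
            for t in DEFAULT_THRESHOLDS
        ]
        assert all(SweepResult(res2).bonferroni_significant)

    def test_empty_thresholds_flagged_undefined(self):
        geno = _dosage([[1.0], [0.0]], ["a", "b"], ["s0"])
        stats = _stats(["s0"], [0.1], [0.9])
        sweep = threshold_sweep(geno, stats, [0.0, 1.0], thresholds=(1e-8, 1e-7))
        assert all(r.undefined for r in sweep.results)
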