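import math

import numpy as np
import pandas as pd
import pytest

from pedprio.npl import (
    FamilyScore,
    InheritanceModel,
    MarkerPanel,
    MendelianError,
    inheritance_posterior,
    kong_cox,
    ld_prune,
    marker_qc,
    max_attainable_lod,
    npl_scan,
    npl_scores,
)
from pedprio.pedigree import Individual, Pedigree

from conftest import gene_drop_marker


def _panel(G, ids, markers, chroms, pos, freq=None):
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": pos}, index=pd.Index(markers, name="marker")
    )
    if freq is not None:
        meta["freq"] = freq
    return MarkerPanel(pd.DataFrame(G, index=ids, columns=markers), meta)


class TestMarkerQc:
    def test_low_call_rate_removed_and_boundary_maf_kept(self):
        # m1: MAF 0.15; m2: one het of 10 = MAF exactly 0.05; m3: 90% called
        G = np.column_stack(
            [
                [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                [np.nan, 1, 1, 1, 0, 0, 1, 0, 1, 0],
            ]
        ).astype(float)
        ids = [f"i{k}" for k in range(10)]
        panel = _panel(G, ids, ["m1", "m2", "m3"], ["1"] * 3, [1, 2, 3])
        out = marker_qc(panel, min_call=0.95, min_maf=0.05)
        assert "m3" not in out.markers  # 90% call rate
        assert "m2" in out.markers  # MAF exactly at the threshold is kept
        assert "m1" in out.markers

    def test_all_pass_unchanged(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.5, (20, 5)).astype(float)
        panel = _panel(G, [f"i{k}" for k in range(20)], [f"m{j}" for j in range(5)],
                       ["1"] * 5, list(range(5)))
        assert marker_qc(panel).markers == panel.markers


class TestLdPrune:
    def test_duplicate_pair_keeps_one(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.5, 40).astype(float)
        panel = _panel(np.column_stack([x, x]), [f"i{k}" for k in range(40)],
                       ["a", "b"], ["1", "1"], [1000, 2000])
        out = ld_prune(panel)
        assert out.markers == ["a"]

    def test_independent_markers_all_kept(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.5, (200, 6)).astype(float)
        panel = _panel(G, [f"i{k}" for k in range(200)], [f"m{j}" for j in range(6)],
                       ["1"] * 6, list(range(0, 6_000_000, 1_000_000)))
        out = ld_prune(panel, window_kb=500, r2_max=0.05)
        assert out.markers == panel.markers

    def test_post_hoc_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        n, m = 150, 30
        latent = rng.binomial(1, 0.5, (n, 3))
        G = np.empty((n, m))
        for j in range(m):
            z = latent[:, j // 10]
            flip = rng.random(n) < 0.2
            G[:, j] = np.where(flip, 1 - z, z) + rng.binomial(1, 0.5, n)
        pos = list(range(0, m * 10_000, 10_000))
        panel = _panel(G, [f"i{k}" for k in range(n)], [f"m{j}" for j in range(m)],
                       ["1"] * m, pos)
        out = ld_prune(panel, window_kb=500, r2_max=0.1)
        kept = out.markers
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                pa = out.meta.loc[kept[a], "pos"]
                pb = out.meta.loc[kept[b], "pos"]
                if abs(pb - pa) <= 500_000:
                    r = np.corrcoef(out.genotypes[kept[a]], out.genotypes[kept[b]])[0, 1]
                    assert r**2 <= 0.1 + 1e-12


class TestInheritancePosterior:
    def test_fully_informative_sib_pair_ibd2(self, sib_pair_pedigree):
        freq = {a: 0.25 for a in "ABCD"}
        dist = inheritance_posterior(
            sib_pair_pedigree,
            {"f": ("A", "B"), "m": ("C", "D"), "s1": ("A", "C"), "s2": ("A", "C")},
            freq,
        )
        m = dist.model
        sp = m.s_pairs(["s1", "s2"])
        assert float(dist.probs[sp == 2].sum()) == pytest.approx(1.0)

    def test_untyped_pedigree_uniform(self, sib_pair_pedigree):
        dist = inheritance_posterior(sib_pair_pedigree, {}, {"A": 0.5, "B": 0.5})
        assert np.allclose(dist.probs, 1.0 / len(dist.probs))

    def test_sibs_aa_matches_nine_configuration_oracle(self, sib_pair_pedigree):
        # both sibs AA, parents untyped, freq(A) = 1/2: brute-force summation
        # over parental genotype configurations gives IBD posterior
        # proportional to (1/4 * 1/16, 1/2 * 1/8, 1/4 * 1/4) = (1, 4, 4)/9.
        dist = inheritance_posterior(
            sib_pair_pedigree, {"s1": ("A", "A"), "s2": ("A", "A")}, {"A": 0.5, "B": 0.5}
        )
        sp = dist.model.s_pairs(["s1", "s2"])
        post = [float(dist.probs[sp == k].sum()) for k in (0, 1, 2)]
        assert np.allclose(post, [1 / 9, 4 / 9, 4 / 9])

    def test_mendelian_inconsistency_names_the_trio(self, sib_pair_pedigree):
        genos = {"f": ("A", "A"), "m": ("A", "A"), "s1": ("A", "B"), "s2": ("A", "A")}
        with pytest.raises(MendelianError, match="s1"):
            inheritance_posterior(sib_pair_pedigree, genos, {"A": 0.5, "B": 0.5})

    def test_enumeration_bound_enforced(self):
        inds = [Individual("f"), Individual("m")] + [
            Individual(f"k{j}", "f", "m") for j in range(8)
        ]
        with pytest.raises(ValueError, match="meiosis bits"):
            InheritanceModel(Pedigree(inds))

    def test_posterior_matches_gene_drop_frequencies(self, sib_trio_pedigree):
        """Conditional inheritance-vector frequencies from Monte-Carlo gene
        dropping must match the exact posterior within 3 SE."""
        rng = np.random.default_rng(123)
        freq = {"A": 0.5, "B": 0.5}
        target = {
            "f": ("A", "B"),
            "m": ("A", "B"),
            "s1": ("A", "B"),
            "s2": ("A", "B"),
            "s3": ("A", "A"),
        }
        m = InheritanceModel(sib_trio_pedigree)
        dist = inheritance_posterior(m, target, freq)

        n_drops = 100_000
        # vectorized drops: founder alleles and meiosis bits
        fa = rng.integers(0, 2, (n_drops, 4))  # f/m slots (A=0, B=1)
        bits = rng.integers(0, 2, (n_drops, 6))
        sib_alleles = np.empty((n_drops, 3, 2), dtype=int)
        for s in range(3):
            pat = np.where(bits[:, 2 * s] == 0, fa[:, 0], fa[:, 1])
            mat = np.where(bits[:, 2 * s + 1] == 0, fa[:, 2], fa[:, 3])
            sib_alleles[:, s, 0], sib_alleles[:, s, 1] = pat, mat

        def match_geno(pair, want):
            w = sorted(0 if a == "A" else 1 for a in want)
            s = np.sort(pair, axis=1)
            return (s[:, 0] == w[0]) & (s[:, 1] == w[1])

        ok = match_geno(fa[:, :2], target["f"]) & match_geno(fa[:, 2:], target["m"])
        for s, sid in enumerate(["s1", "s2", "s3"]):
            ok &= match_geno(sib_alleles[:, s, :], target[sid])
        kept_bits = bits[ok]
        n_kept = len(kept_bits)
        assert n_kept > 500
        vec_idx = (kept_bits * (1 << np.arange(6))).sum(axis=1)
        counts = np.bincount(vec_idx, minlength=64)
        freqs = counts / n_kept
        for v in range(64):
            p = dist.probs[v]
            se = math.sqrt(max(p * (1 - p), 1e-12) / n_kept)
            assert abs(freqs[v] - p) <= 3 * se + 1e-3


class TestNplScores:
    def test_informative_sib_pair_z_is_sqrt_two(self, sib_pair_pedigree):
        dist = inheritance_posterior(
            sib_pair_pedigree,
            {"f": ("A", "B"), "m": ("C", "D"), "s1": ("A", "C"), "s2": ("A", "C")},
            {a: 0.25 for a in "ABCD"},
        )
        z_all, z_pairs = npl_scores(dist, ["s1", "s2"])
        assert z_pairs == pytest.approx(math.sqrt(2))
        # for a single affected pair the two statistics coincide
        assert z_all == pytest.approx(z_pairs)

    def test_uninformative_marker_scores_zero(self, sib_pair_pedigree):
        dist = inheritance_posterior(sib_pair_pedigree, {}, {"A": 0.5, "B": 0.5})
        assert npl_scores(dist, ["s1", "s2"]) == pytest.approx((0.0, 0.0))

    def test_fewer_than_two_affected_is_error(self, sib_pair_pedigree):
        dist = inheritance_posterior(sib_pair_pedigree, {}, {"A": 0.5, "B": 0.5})
        with pytest.raises(ValueError):
            npl_scores(dist, ["s1"])


def _sib_pair_null(ped):
    m = InheritanceModel(ped)
    s = m.s_pairs(["s1", "s2"])
    return m.standardized_null(s)


class TestKongCox:
    def test_boundary_null(self, sib_pair_pedigree):
        null = _sib_pair_null(sib_pair_pedigree)
        for model in ("linear", "exponential"):
            res = kong_cox([FamilyScore(-0.8, null)], model=model)
            assert res.lod == 0.0 and res.p == 0.5 and res.delta_hat == 0.0

    def test_exponential_matches_grid_search_oracle(self, sib_pair_pedigree):
        null = _sib_pair_null(sib_pair_pedigree)
        z = math.sqrt(2)
        res = kong_cox([FamilyScore(z, null)], model="exponential")
        # independent grid search over delta at step 1e-4
        vals, probs = null
        deltas = np.arange(0.0, 30.0, 1e-4)
        ll = deltas * z - np.log(np.exp(deltas[:, None] * vals[None, :]) @ probs)
        lod_grid = ll.max() / math.log(10)
        assert res.lod == pytest.approx(lod_grid, abs=1e-4)

    def test_linear_model_respects_support_bound(self, sib_pair_pedigree):
        null = _sib_pair_null(sib_pair_pedigree)
        z = math.sqrt(2)
        res = kong_cox([FamilyScore(z, null)], model="linear")
        # delta is capped where 1 + delta * z_min hits zero: LOD = log10(2)
        assert res.lod == pytest.approx(math.log10(2), abs=1e-6)

    def test_family_order_invariance(self, sib_pair_pedigree):
        null = _sib_pair_null(sib_pair_pedigree)
        fams = [FamilyScore(1.2, null), FamilyScore(-0.3, null), FamilyScore(0.7, null)]
        a = kong_cox(fams, model="exponential")
        b = kong_cox(fams[::-1], model="exponential")
        assert a.lod == pytest.approx(b.lod, abs=1e-9)

    def test_all_zero_scores_zero_lod(self, sib_pair_pedigree):
        null = _sib_pair_null(sib_pair_pedigree)
        res = kong_cox([FamilyScore(0.0, null)] * 3, model="exponential")
        assert res.lod == 0.0


class TestMaxAttainableLod:
    def test_sib_pair_ceiling_composition(self, sib_pair_pedigree):
        null = _sib_pair_null(sib_pair_pedigree)
        direct = kong_cox([FamilyScore(math.sqrt(2), null)], model="exponential")
        ceiling = max_attainable_lod(sib_pair_pedigree, ["s1", "s2"], statistic="pairs")
        assert ceiling == pytest.approx(direct.lod, abs=1e-6)

    def test_single_affected_zero_ceiling(self, sib_pair_pedigree):
        assert max_attainable_lod(sib_pair_pedigree, ["s1"]) == 0.0

    def test_ceiling_monotone_in_affected_sibs(self):
        lods = []
        for n_aff in (2, 3, 4):
            inds = [Individual("f"), Individual("m")] + [
                Individual(f"k{j}", "f", "m") for j in range(n_aff)
            ]
            ped = Pedigree(inds)
            lods.append(max_attainable_lod(ped, [f"k{j}" for j in range(n_aff)]))
        assert lods[0] <= lods[1] <= lods[2]
        assert lods[0] < lods[2]


class TestNullCalibration:
    def test_gene_dropped_null_markers(self, three_generation_pedigree):
        """Mean Z_all near zero and variance in the imperfect-informativeness
        band on seeded gene-dropped null markers (six-allele markers)."""
        ped = three_generation_pedigree
        m = InheritanceModel(ped)
        affected = ["5", "6"]
        s = m.s_all(affected)
        mu, sd = m.null_moments(s)
        alleles = tuple("abcdef")
        freq = {a: 1 / 6 for a in alleles}
        rng = np.random.default_rng(7)
        zs = []
        for _ in range(300):
            al = gene_drop_marker(ped, freq, rng, alleles)
            probs = m.posterior({i: al[i] for i in ped.members()}, freq)
            zs.append((float(probs @ s) - mu) / sd)
        assert -0.1 <= float(np.mean(zs)) <= 0.1
        assert 0.7 <= float(np.var(zs)) <= 1.1


class TestNplScan:
    def test_scan_output_shape_and_bounds(self, sib_pair_pedigree):
        # markers gene-dropped through the pedigree (Mendelian-consistent)
        rng = np.random.default_rng(5)
        ids = sib_pair_pedigree.members()
        cols = []
        for _ in range(4):
            al = gene_drop_marker(sib_pair_pedigree, {"a": 0.5, "r": 0.5}, rng)
            cols.append([sum(x == "a" for x in al[i]) for i in ids])
        G = np.array(cols, dtype=float).T
        panel = _panel(G, ids, [f"m{j}" for j in range(4)], ["1"] * 4,
                       [1_000_000 * j for j in range(4)], freq=[0.5] * 4)
        res = npl_scan(panel, sib_pair_pedigree, affected=["s1", "s2"])
        assert list(res.columns) == ["marker", "z_all", "z_pairs", "lod_linear", "exLOD", "p"]
        assert (res["exLOD"] >= 0).all() and (res["lod_linear"] >= 0).all()
        assert res["p"].between(0, 1).all()
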