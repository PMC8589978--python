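"""f-statistics against loop oracles, jackknife algebra, BH, PCA, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ovipop.genotypes import GenotypeTable, SNPPanel
from ovipop.popgen import (allele_freqs, bh_adjust, block_jackknife,
                           compare_affinity_groups, correlate_f3, d_statistic,
                           outgroup_f3, pca_fit, pca_project)


def random_table(rng, n_snps=100, pops=("O", "A", "B", "C"), n_per_pop=4,
                 pseudo_pops=(), missing_rate=0.1):
    rows = [{"snp_id": f"s{j}", "chrom": str(1 + j % 3),
             "pos": 1 + 1000 * (j // 3), "ref": "A", "alt": "C"}
            for j in range(n_snps)]
    panel = SNPPanel(pd.DataFrame(rows))
    ids, populations, ploidy, data = [], [], [], []
    for pop in pops:
        hap = pop in pseudo_pops
        for i in range(n_per_pop):
            ids.append(f"{pop}{i}")
            populations.append(pop)
            ploidy.append(1 if hap else 2)
            dos = rng.integers(0, 2 if hap else 3, n_snps)
            dos[rng.random(n_snps) < missing_rate] = -1
            data.append(dos)
    return GenotypeTable(panel, ids, populations, np.array(ploidy),
                         np.array(data, dtype=np.int8))


def loop_freq(table, pop, j):
    """Independent per-site allele-frequency recount."""
    alt = obs = 0
    for i, p in enumerate(table.populations):
        if p != pop:
            continue
        d = table.data[i, j]
        if d == -1:
            continue
        alt += d
        obs += table.ploidy[i]
    return (alt / obs) if obs else None


class TestAlleleFreqs:
    def test_single_het_diploid(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_snps=1, pops=("P",), n_per_pop=1,
                         missing_rate=0.0)
        t.data[0, 0] = 1
        freqs, counts = allele_freqs(t, ["P"])
        assert freqs[0, 0] == 0.5 and counts[0, 0] == 2

    def test_pseudohaploid_single_observation(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_snps=1, pops=("P",), n_per_pop=1,
                         pseudo_pops=("P",), missing_rate=0.0)
        t.data[0, 0] = 1
        freqs, counts = allele_freqs(t, ["P"])
        assert freqs[0, 0] == 1.0 and counts[0, 0] == 1

    def test_matches_loop_recount(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, pseudo_pops=("A",))
        freqs, _ = allele_freqs(t, ["O", "A", "B"])
        for pi, pop in enumerate(["O", "A", "B"]):
            for j in range(t.n_snps):
                expect = loop_freq(t, pop, j)
                if expect is None:
                    assert np.isnan(freqs[pi, j])
                else:
                    assert freqs[pi, j] == pytest.approx(expect, abs=1e-15)

    def test_unknown_population_rejected(self):
        t = random_table(np.random.default_rng(3))
        with pytest.raises(ValueError, match="unknown"):
            allele_freqs(t, ["nope"])


def loop_f3(table, o, a, b):
    terms = []
    for j in range(table.n_snps):
        fo, fa, fb = (loop_freq(table, p, j) for p in (o, a, b))
        if None in (fo, fa, fb):
            continue
        terms.append((fo - fa) * (fo - fb))
    return float(np.mean(terms))


def loop_d(table, w, x, y, z):
    num = den = 0.0
    for j in range(table.n_snps):
        f = [loop_freq(table, p, j) for p in (w, x, y, z)]
        if None in f:
            continue
        fw, fx, fy, fz = f
        num += (fw - fx) * (fy - fz)
        den += (fw + fx - 2 * fw * fx) * (fy + fz - 2 * fy * fz)
    return num / den


class TestFStatistics:
    def test_f3_single_site_worked_example(self):
        """f3 with o=1.0, a=0.2, b=0.4 equals (0.8)(0.6) = 0.48."""
        panel = SNPPanel(pd.DataFrame([{"snp_id": "s", "chrom": "1",
                                        "pos": 1, "ref": "A", "alt": "C"}]))
        data = np.array([[2], [2], [0], [1], [0], [1], [0], [2], [1], [1],
                         [0], [0]], dtype=np.int8)
        # O: 1.0 (two hom-alt); A: 0.2 (five inds, sum 2/10); B: 0.4 (sum 4/10)
        pops = ["O"] * 2 + ["A"] * 5 + ["B"] * 5
        t = GenotypeTable(panel, [f"i{k}" for k in range(12)], pops,
                          np.full(12, 2), data)
        res = outgroup_f3(t, "O", "A", "B", jackknife=False)
        assert res.value == pytest.approx(0.48, abs=1e-15)

    def test_f3_self_comparison_nonnegative(self):
        rng = np.random.default_rng(4)
        t = random_table(rng)
        res = outgroup_f3(t, "O", "A", "A", jackknife=False)
        assert res.value >= 0

    @pytest.mark.parametrize("seed", range(5))
    def test_f3_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_table(rng)
        res = outgroup_f3(t, "O", "A", "B", jackknife=False)
        assert res.value == pytest.approx(loop_f3(t, "O", "A", "B"),
                                          rel=1e-12)

    def test_d_maximal_abba(self):
        panel = SNPPanel(pd.DataFrame([{"snp_id": "s", "chrom": "1",
                                        "pos": 1, "ref": "A", "alt": "C"}]))
        data = np.array([[2], [0], [2], [0]], dtype=np.int8)
        t = GenotypeTable(panel, list("wxyz"), ["W", "X", "Y", "Z"],
                          np.full(4, 2), data)
        res = d_statistic(t, "W", "X", "Y", "Z", jackknife=False)
        assert res.value == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_d_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        t = random_table(rng, n_snps=500)
        res = d_statistic(t, "O", "A", "B", "C", jackknife=False)
        assert res.value == pytest.approx(loop_d(t, "O", "A", "B", "C"),
                                          rel=1e-12)

    def test_d_antisymmetry_exact(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n_snps=300)
        d1 = d_statistic(t, "O", "A", "B", "C").value
        d2 = d_statistic(t, "A", "O", "B", "C").value
        d3 = d_statistic(t, "O", "A", "C", "B").value
        assert d1 == -d2 == -d3

    def test_d_bounded_when_denominator_positive(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            t = random_table(np.random.default_rng(seed), n_snps=200)
            res = d_statistic(t, "O", "A", "B", "C", jackknife=False)
            assert -1.0 <= res.value <= 1.0
        del rng

    def test_zero_usable_sites_rejected(self):
        t = random_table(np.random.default_rng(7), n_snps=5,
                         missing_rate=0.0)
        t.data[[i for i, p in enumerate(t.populations) if p == "A"], :] = -1
        with pytest.raises(ValueError, match="usable"):
            outgroup_f3(t, "O", "A", "B")


class TestBlockJackknife:
    def test_equal_blocks_match_delete_one_formula(self):
        """Equal block sizes reduce to the classic delete-one jackknife."""
        rng = np.random.default_rng(8)
        terms = rng.normal(size=200)
        chrom = np.repeat([str(c) for c in range(10)], 20)
        pos = np.tile(np.arange(20) * 10 + 1, 10)
        est, se = block_jackknife(terms, chrom, pos, block_size=1000)
        # independent delete-one recomputation
        thetas = np.array([
            np.delete(terms.reshape(10, 20), g, axis=0).mean()
            for g in range(10)])
        g = 10
        se_oracle = np.sqrt((g - 1) / g * ((thetas - thetas.mean()) ** 2).sum())
        assert est == pytest.approx(terms.mean(), rel=1e-12)
        assert se == pytest.approx(se_oracle, rel=1e-12)

    def test_homogeneous_blocks_have_zero_se(self):
        terms = np.full(60, 0.7)
        chrom = np.repeat(["1", "2", "3"], 20)
        pos = np.tile(np.arange(20) + 1, 3)
        _, se = block_jackknife(terms, chrom, pos, block_size=1000)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            block_jackknife(np.ones(10), ["1"] * 10, np.arange(10) + 1,
                            block_size=1000)

    def test_se_scales_with_block_count(self):
        """Jackknife SE ~ 1/sqrt(n_blocks) for i.i.d. site terms."""
        rng = np.random.default_rng(9)
        ses = {}
        for g in (10, 40):
            terms = rng.normal(size=g * 50)
            chrom = np.repeat([str(c) for c in range(g)], 50)
            pos = np.tile(np.arange(50) + 1, g)
            ses[g] = block_jackknife(terms, chrom, pos, block_size=1000)[1]
        assert ses[40] < ses[10]


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_derived_four_value_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_on_random_input(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(10)
        for _ in range(5):
            p = rng.random(25)
            expect = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expect, rtol=1e-12)

    def test_output_dominates_input_and_caps(self):
        rng = np.random.default_rng(11)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def cluster_table(rng, n_snps=500, sep=3.0, n=10):
    rows = [{"snp_id": f"s{j}", "chrom": "1", "pos": j + 1,
             "ref": "A", "alt": "C"} for j in range(n_snps)]
    panel = SNPPanel(pd.DataFrame(rows))
    f1 = np.clip(rng.beta(0.8, 0.8, n_snps), 0.02, 0.98)
    shift = rng.choice([-1, 1], n_snps) * sep * 0.1
    f2 = np.clip(f1 + shift, 0.02, 0.98)
    data = np.concatenate([rng.binomial(2, f1, (n, n_snps)),
                           rng.binomial(2, f2, (n, n_snps))]).astype(np.int8)
    ids = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    pops = ["grp1"] * n + ["grp2"] * n
    return GenotypeTable(panel, ids, pops, np.full(2 * n, 2), data)


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(12)
        t = cluster_table(rng)
        model = pca_fit(t)
        pc1 = model.coordinates["PC1"]
        g1 = pc1[model.coordinates["population"] == "grp1"]
        g2 = pc1[model.coordinates["population"] == "grp2"]
        assert g1.max() < g2.min() or g2.max() < g1.min()

    def test_explained_variance_nonincreasing(self):
        t = cluster_table(np.random.default_rng(13))
        model = pca_fit(t)
        assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()

    def test_loadings_orthonormal(self):
        t = cluster_table(np.random.default_rng(14))
        model = pca_fit(t, n_components=5)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_sign_invariance_up_to_component(self):
        t = cluster_table(np.random.default_rng(15))
        m1, m2 = pca_fit(t), pca_fit(t)
        np.testing.assert_allclose(np.abs(m1.loadings), np.abs(m2.loadings))

    def test_projection_identity_for_fit_individual(self):
        t = cluster_table(np.random.default_rng(16))
        model = pca_fit(t, n_components=6)
        dos = t.diploid_scale()[0].astype(float)
        coords = pca_project(model, dos, snp_ids=t.panel.snp_ids)
        expect = model.coordinates.iloc[0].drop("population").to_numpy(float)
        np.testing.assert_allclose(coords, expect, atol=1e-8)

    def test_all_missing_sample_rejected(self):
        t = cluster_table(np.random.default_rng(17))
        model = pca_fit(t)
        with pytest.raises(ValueError, match="usable"):
            pca_project(model, np.full(t.n_snps, -1.0),
                        snp_ids=t.panel.snp_ids)

    def test_monomorphic_input_rejected(self):
        rows = [{"snp_id": f"s{j}", "chrom": "1", "pos": j + 1,
                 "ref": "A", "alt": "C"} for j in range(5)]
        panel = SNPPanel(pd.DataFrame(rows))
        t = GenotypeTable(panel, ["a", "b", "c"], ["p"] * 3, np.full(3, 2),
                          np.full((3, 5), 2, np.int8))
        with pytest.raises(ValueError, match="polymorphic"):
            pca_fit(t)


class TestGroupComparisons:
    def test_u_statistic_matches_enumeration(self):
        x = [0.184, 0.190, 0.170, 0.201]
        y = [0.176, 0.160, 0.188, 0.150]
        u_enum = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        u_scipy, _ = mannwhitneyu(x, y, alternative="two-sided")
        values = pd.Series(dict(zip("abcdefgh", x + y)))
        groups = pd.Series({k: ("w" if k in "abcd" else "e")
                            for k in "abcdefgh"})
        res = compare_affinity_groups(values, groups)
        assert res.u_statistic == u_enum == u_scipy
        assert res.medians["w"] > res.medians["e"]

    def test_identical_groups_not_significant(self):
        vals = pd.Series({f"p{i}": v for i, v in
                          enumerate([0.1, 0.2, 0.3, 0.4] * 2)})
        groups = pd.Series({f"p{i}": ("a" if i < 4 else "b")
                            for i in range(8)})
        res = compare_affinity_groups(vals, groups)
        assert res.p_value > 0.9

    def test_empty_group_rejected(self):
        vals = pd.Series({"p0": 0.1, "p1": 0.2})
        groups = pd.Series({"p0": "a", "p1": "a"})
        with pytest.raises(ValueError):
            compare_affinity_groups(vals, groups)

    def test_correlate_identical_and_reversed(self):
        v = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        rho, _ = correlate_f3(v, v)
        assert rho == pytest.approx(1.0)
        rho2, _ = correlate_f3(v, pd.Series(
            {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}))
        assert rho2 == pytest.approx(-1.0)

    def test_correlate_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlate_f3(pd.Series([1.0, 2.0, 3.0]),
                         pd.Series([1.0, 2.0]))
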