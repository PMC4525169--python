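import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelgwas import simulate as sim
from panelgwas.gwas import (
    _kw_from_samples,
    group_variants,
    kw_test,
    run_gwas,
    single_locus_r2,
)
from panelgwas.quantgen import line_means
from panelgwas.tables import MISSING

from conftest import make_genotypes, make_phenotypes


def loci_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "locus_id"])


class TestGroupVariants:
    def test_non_overlapping_snps_separate_groups(self):
        g = make_genotypes(
            [["A", "C"], ["A", "T"], ["G", "C"], ["G", "T"]],
            loci=loci_df([("2L", 100, 100, "v1"), ("2L", 300, 300, "v2")]),
        )
        groups = group_variants(g, min_allele_count=1)
        assert len(groups) == 2
        assert sorted(groups[0].alleles) == ["A", "G"]

    def test_overlapping_snp_and_deletion_merge(self):
        # deletion spans 100-110, SNP at 105 -> one composite group
        g = make_genotypes(
            [["del", "A"], ["del", "A"], ["ref", "C"], ["ref", "C"]],
            loci=loci_df([("2L", 100, 110, "indel"), ("2L", 105, 105, "snp")]),
        )
        groups = group_variants(g, min_allele_count=1)
        assert len(groups) == 1
        assert set(groups[0].alleles) == {"del|A", "ref|C"}
        assert groups[0].member_ids == ["indel", "snp"]

    def test_minor_allele_count_filter(self):
        # 140 lines, minor count 9 -> dropped; minor count 10 -> kept
        rows = [["A", "A"] for _ in range(140)]
        for i in range(9):
            rows[i][0] = "G"
        for i in range(10):
            rows[i][1] = "G"
        g = make_genotypes(rows,
                           loci=loci_df([("2L", 100, 100, "v1"),
                                         ("2L", 300, 300, "v2")]))
        groups = group_variants(g, min_allele_count=10)
        assert [gr.locus_id for gr in groups] == ["v2"]
        assert groups[0].allele_counts == {"A": 130, "G": 10}

    def test_missing_line_excluded_from_group(self):
        g = make_genotypes(
            [["A"], [MISSING], ["G"], ["G"]],
            loci=loci_df([("2L", 100, 100, "v1")]),
        )
        groups = group_variants(g, min_allele_count=1)
        assert groups[0].labels.isna().sum() == 1

    def test_partition_property(self):
        geno = sim.simulate_panel(
            sim.PanelSimSpec(n_lines=60, n_loci=40, frac_multiallelic=0.2,
                             seed=0)
        )
        groups = group_variants(geno, min_allele_count=1)
        members = [m for gr in groups for m in gr.member_ids]
        assert len(members) == len(set(members))
        assert set(members) <= set(geno.loci["locus_id"])


def brute_force_kw(samples):
    """Independent rank-based oracle: explicit loops, no scipy."""
    pooled = []
    for gi, s in enumerate(samples):
        for v in s:
            pooled.append((v, gi))
    vals = sorted(v for v, _ in pooled)
    n = len(vals)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and vals[j] == vals[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        ranks[vals[i]] = avg
        i = j
    rank_sums = [0.0] * len(samples)
    for v, gi in pooled:
        rank_sums[gi] += ranks[v]
    h = 12.0 / (n * (n + 1)) * sum(
        rank_sums[gi] ** 2 / len(samples[gi]) for gi in range(len(samples))
    ) - 3 * (n + 1)
    ties = 0.0
    seen = {}
    for v, _ in pooled:
        seen[v] = seen.get(v, 0) + 1
    for t in seen.values():
        ties += t ** 3 - t
    denom = 1 - ties / (n ** 3 - n)
    if denom == 0:
        return 0.0, len(samples) - 1, 1.0
    h /= denom
    return h, len(samples) - 1, float(stats.chi2.sf(h, len(samples) - 1))


class TestKruskalWallis:
    def test_textbook_two_group_example(self):
        h, df, p = _kw_from_samples([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert h == pytest.approx(27 / 7, abs=1e-9)  # 3.857
        assert df == 1
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_values_h_zero(self):
        h, _, p = _kw_from_samples([np.ones(4), np.ones(3)])
        assert h == 0.0 and p == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 5)
            samples = [rng.integers(0, 6, rng.integers(3, 9)).astype(float)
                       for _ in range(k)]
            if len(set(np.concatenate(samples))) == 1:
                continue
            h, df, p = _kw_from_samples(samples)
            try:
                h2, p2 = stats.kruskal(*samples)
            except ValueError:  # all identical
                continue
            assert h == pytest.approx(h2, abs=1e-10)
            assert p == pytest.approx(p2, abs=1e-10)

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        samples = [rng.random(6), rng.random(8)]
        h1, _, p1 = _kw_from_samples(samples)
        h2, _, p2 = _kw_from_samples([np.arcsin(np.sqrt(s)) for s in samples])
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_kw_test_units(self, tiny_genotypes, tiny_phenotypes):
        groups = group_variants(tiny_genotypes, min_allele_count=1)
        rep = kw_test(groups[0], tiny_phenotypes, unit="replicate")
        lm = kw_test(groups[0], tiny_phenotypes, unit="line_mean")
        assert rep.n_lines == lm.n_lines == 4
        assert rep.df == lm.df == 1
        assert rep.H != lm.H  # pooled replicates vs one value per line


@pytest.fixture(scope="module")
def null_panel():
    geno = sim.simulate_panel(
        sim.PanelSimSpec(n_lines=40, n_loci=30, maf_range=(0.25, 0.5),
                         seed=10)
    )
    pheno, _ = sim.simulate_phenotypes(
        geno, sim.PhenoSimSpec(V_line_extra=0.02, V_rep=0.005, seed=11),
    )
    return geno, pheno


class TestRunGwas:

    def test_seed_reproducible(self, null_panel):
        geno, pheno = null_panel
        a1, f1 = run_gwas(geno, pheno, min_allele_count=5, B=100, seed=42)
        a2, f2 = run_gwas(geno, pheno, min_allele_count=5, B=100, seed=42)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_seed_required(self, null_panel):
        geno, pheno = null_panel
        with pytest.raises(Exception, match="seed"):
            run_gwas(geno, pheno, B=100)

    def test_permutation_p_lower_bound(self, null_panel):
        geno, pheno = null_panel
        B = 100
        assoc, _ = run_gwas(geno, pheno, min_allele_count=5, B=B, seed=1)
        assert (assoc["p_permutation"] >= 1.0 / (B + 1)).all()
        assert (assoc["p_permutation"] <= 1.0).all()

    def test_fdr_hits_monotone_in_threshold(self, null_panel):
        geno, pheno = null_panel
        _, fdr = run_gwas(geno, pheno, min_allele_count=5, B=100, seed=2)
        assert fdr["observed_hits"].is_monotonic_increasing
        assert (fdr["fdr"].dropna() >= 0).all()
        assert (fdr["fdr"].dropna() <= 1).all()

    def test_planted_qtl_is_top_hit(self):
        geno = sim.simulate_panel(
            sim.PanelSimSpec(n_lines=140, n_loci=50, maf_range=(0.3, 0.5),
                             seed=12)
        )
        lid = geno.loci["locus_id"].iloc[5]
        al = sorted(set(geno.alleles[lid]))
        pheno, _ = sim.simulate_phenotypes(
            geno,
            sim.PhenoSimSpec(qtl_loci={lid: {al[0]: -0.12, al[1]: 0.12}},
                             V_line_extra=0.01, V_rep=0.005, seed=13),
        )
        assoc, _ = run_gwas(geno, pheno, B=200, seed=14)
        top = assoc.nsmallest(5, "p_asymptotic")["locus_id"].tolist()
        assert lid in top

    def test_missing_calls_use_subset_permutation_path(self, null_panel):
        geno, pheno = null_panel
        alleles = geno.alleles.copy()
        # blank out a few calls at the first two loci
        for i, col in enumerate(alleles.columns[:2]):
            alleles.iloc[2 * i: 2 * i + 3,
                         alleles.columns.get_loc(col)] = MISSING
        from panelgwas.tables import GenotypeTable

        geno2 = GenotypeTable(line_ids=geno.line_ids, loci=geno.loci.copy(),
                              alleles=alleles)
        a1, _ = run_gwas(geno2, pheno, min_allele_count=5, B=100, seed=4)
        a2, _ = run_gwas(geno2, pheno, min_allele_count=5, B=100, seed=4)
        pd.testing.assert_frame_equal(a1, a2)
        sub = a1[a1["locus_id"].isin(list(alleles.columns[:2]))]
        assert (sub["n_lines"] < geno.n_lines).all()
        assert (sub["p_permutation"] >= 1 / 101).all()

    def test_asymptotic_and_permutation_p_agree_under_null(self, null_panel):
        geno, pheno = null_panel
        assoc, _ = run_gwas(geno, pheno, min_allele_count=5, B=400, seed=3)
        r = np.corrcoef(assoc["p_asymptotic"], assoc["p_permutation"])[0, 1]
        assert r > 0.95


class TestSingleLocusR2:
    def test_perfect_partition_saturated(self):
        g = make_genotypes([["A"], ["G"]],
                           loci=loci_df([("2L", 100, 100, "v1")]))
        groups = group_variants(g, min_allele_count=1)
        lm = pd.DataFrame({"mean": [0.2, 0.8]}, index=["L1", "L2"])
        res = single_locus_r2(groups[0], lm)
        assert res.r2 == 1.0 and res.saturated

    def test_null_mean_matches_closed_form(self):
        # E[R2] = (k-1)/(n-1) for an uninformative k-level factor
        rng = np.random.default_rng(4)
        n, k = 140, 2
        rows = [["A"] if i < 70 else ["G"] for i in range(n)]
        g = make_genotypes(rows, loci=loci_df([("2L", 100, 100, "v1")]))
        groups = group_variants(g, min_allele_count=1)
        r2s = []
        for _ in range(300):
            lm = pd.DataFrame({"mean": rng.normal(size=n)},
                              index=g.line_ids)
            r2s.append(single_locus_r2(groups[0], lm).r2)
        assert np.mean(r2s) == pytest.approx((k - 1) / (n - 1), abs=0.004)

    def test_known_variance_share_recovered(self):
        geno = sim.simulate_panel(
            sim.PanelSimSpec(n_lines=140, n_loci=10, maf_range=(0.4, 0.5),
                             seed=15)
        )
        lid = geno.loci["locus_id"].iloc[0]
        al = sorted(set(geno.alleles[lid]))
        r2s = []
        for i in range(60):
            pheno, truth = sim.simulate_phenotypes(
                geno,
                sim.PhenoSimSpec(qtl_loci={lid: {al[0]: -0.1, al[1]: 0.1}},
                                 V_line_extra=0.05, V_rep=0.01,
                                 n_flies_per_rep=200, seed=100 + i),
            )
            lm = line_means(pheno, scale="angular")
            groups = group_variants(geno, min_allele_count=10)
            grp = next(g for g in groups if g.locus_id == lid)
            r2s.append(single_locus_r2(grp, lm).r2)
        v_q = truth.qtl_variance[lid]
        share = v_q / (v_q + 0.05 + (0.01 + 1 / 800) / 3)
        assert np.mean(r2s) == pytest.approx(share, abs=0.05)
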