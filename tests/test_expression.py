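import numpy as np
import pandas as pd
import pytest

from panelgwas import simulate as sim
from panelgwas.errors import ValidationError
from panelgwas.expression import (
    differential_expression,
    pca_samples,
    rpkm,
    top_variance_genes,
)
from panelgwas.tables import ExpressionMatrix


def _counts(mat, tx, samples):
    return pd.DataFrame(np.asarray(mat, dtype=float), index=tx, columns=samples)


class TestRpkm:
    def test_worked_example(self):
        # count 10, length 1 kb, library 1e6 -> RPKM 10
        counts = _counts([[10], [999990]], ["t1", "t2"], ["s1"])
        lengths = pd.Series({"t1": 1000, "t2": 5000})
        t2g = pd.Series({"t1": "gA", "t2": "gB"})
        expr = rpkm(counts, lengths, t2g)
        assert expr.values.loc["gA", "s1"] == pytest.approx(10.0)

    def test_gene_is_mean_over_transcripts(self):
        # engineer two transcripts of one gene with RPKM 4 and 6
        lib = 1e6
        counts = _counts([[4], [6], [lib - 10]], ["t1", "t2", "t3"], ["s1"])
        lengths = pd.Series({"t1": 1000, "t2": 1000, "t3": 2000})
        t2g = pd.Series({"t1": "gA", "t2": "gA", "t3": "gB"})
        expr = rpkm(counts, lengths, t2g)
        assert expr.values.loc["gA", "s1"] == pytest.approx(5.0)

    def test_zero_library_errors(self):
        counts = _counts([[0], [0]], ["t1", "t2"], ["s1"])
        with pytest.raises(ValidationError, match="library"):
            rpkm(counts, pd.Series({"t1": 100, "t2": 100}),
                 pd.Series({"t1": "g1", "t2": "g2"}))

    def test_doubling_counts_leaves_rpkm_invariant(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng.integers(1, 100, (5, 3)),
                         [f"t{i}" for i in range(5)], ["a", "b", "c"])
        lengths = pd.Series(rng.integers(200, 3000, 5),
                            index=counts.index)
        t2g = pd.Series([f"g{i}" for i in range(5)], index=counts.index)
        e1 = rpkm(counts, lengths, t2g)
        e2 = rpkm(counts * 2, lengths, t2g)
        np.testing.assert_allclose(e1.values, e2.values, rtol=1e-12)


class TestTopVariance:
    def _expr(self, mat, genes):
        return ExpressionMatrix(
            values=pd.DataFrame(mat, index=genes,
                                columns=[f"s{i}" for i in range(mat.shape[1])])
        )

    def test_identity_when_k_equals_n_genes(self):
        rng = np.random.default_rng(1)
        e = self._expr(rng.lognormal(size=(10, 4)), [f"g{i}" for i in range(10)])
        sub = top_variance_genes(e, k=10)
        assert sub.gene_ids == e.gene_ids

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(2)
        mat = rng.lognormal(size=(5, 6))
        mat[2] = 3.0
        e = self._expr(mat, [f"g{i}" for i in range(5)])
        sub = top_variance_genes(e, k=4)
        assert "g2" not in sub.gene_ids

    def test_planted_high_variance_module_selected(self):
        expr, _, truth = sim.simulate_expression(
            sim.ExprSimSpec(
                n_genes=500,
                modules=[sim.ModuleSpec(size=20, within_correlation=0.8,
                                        treatment_shift=4.0)],
                seed=3,
            )
        )
        sub = top_variance_genes(expr, k=100)
        module_genes = set(truth[truth == "module1"].index)
        assert module_genes <= set(sub.gene_ids)

    def test_order_preserved_and_k_validated(self):
        rng = np.random.default_rng(4)
        e = self._expr(rng.lognormal(size=(6, 4)), [f"g{i}" for i in range(6)])
        sub = top_variance_genes(e, k=3)
        positions = [e.gene_ids.index(g) for g in sub.gene_ids]
        assert positions == sorted(positions)
        with pytest.raises(ValidationError):
            top_variance_genes(e, k=7)


class TestPca:
    def test_identical_samples_have_zero_variance(self):
        vals = pd.DataFrame(
            np.tile(np.arange(1.0, 6.0)[:, None], (1, 2)),
            index=[f"g{i}" for i in range(5)], columns=["s1", "s2"],
        )
        _, frac = pca_samples(ExpressionMatrix(values=vals))
        assert np.allclose(frac, 0.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.lognormal(size=(30, 8)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(8)])
        _, frac = pca_samples(ExpressionMatrix(values=vals))
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fraction_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.lognormal(size=(20, 6)),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(6)])
        _, f1 = pca_samples(ExpressionMatrix(values=vals))
        perm = vals.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2)
        _, f2 = pca_samples(ExpressionMatrix(values=perm))
        np.testing.assert_allclose(f1, f2, rtol=1e-8)

    def test_treatment_on_pc1_class_on_pc2(self):
        # strong broad treatment signal, weaker class signal
        expr, meta, _ = sim.simulate_expression(
            sim.ExprSimSpec(
                n_genes=300,
                modules=[
                    sim.ModuleSpec(size=150, within_correlation=0.6,
                                   treatment_shift=5.0),
                    sim.ModuleSpec(size=60, within_correlation=0.6,
                                   class_shift=3.0),
                ],
                seed=7,
            )
        )
        scores, frac = pca_samples(expr)
        md = meta.table.set_index("sample_id")
        tr = (md.loc[scores.index, "treatment"] == "challenged").to_numpy()
        cl = (md.loc[scores.index, "susceptibility_class"] == "resistant").to_numpy()
        pc1, pc2 = scores["PC1"].to_numpy(), scores["PC2"].to_numpy()

        def separates(score, mask):
            return (min(score[mask].min(), -1e18) > score[~mask].max()
                    or score[mask].max() < score[~mask].min()
                    or abs(score[mask].mean() - score[~mask].mean())
                    > 2 * (score[mask].std() + score[~mask].std()) / 2)

        assert separates(pc1, tr)
        assert separates(pc2, cl)
        assert frac[0] > frac[1]


class TestDifferentialExpression:
    def _labels(self, expr):
        md = expr.meta.table.set_index("sample_id")
        return md["treatment"], md["line_id"]

    def test_fold_threshold_rule(self):
        rng = np.random.default_rng(8)
        n = 2000
        base = rng.normal(6, 0.05, size=(n, 8))
        mat = base.copy()
        mat[:50, 4:] += np.log2(1.5)  # significant but below two-fold
        vals = pd.DataFrame(2.0 ** mat, index=[f"g{i}" for i in range(n)],
                            columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=vals.columns)
        res = differential_expression(
            ExpressionMatrix(values=vals), labels, adj_p_max=0.05,
            min_fold=2.0, normalize=False,
        )
        assert res.iloc[:50]["adj_p"].max() < 0.05
        assert not res.iloc[:50]["passes"].any()

    def test_planted_two_and_half_fold_recovered(self):
        rng = np.random.default_rng(9)
        n = 2000
        base = rng.normal(6, 0.35, size=(n, 16))
        mat = base.copy()
        mat[:50, 8:] += np.log2(2.5)
        vals = pd.DataFrame(2.0 ** mat, index=[f"g{i}" for i in range(n)],
                            columns=[f"s{i}" for i in range(16)])
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=vals.columns)
        res = differential_expression(
            ExpressionMatrix(values=vals), labels, adj_p_max=0.05,
            min_fold=2.0, normalize=False,
        )
        assert res.iloc[:50]["passes"].sum() >= 45
        assert res.iloc[50:]["passes"].sum() <= 0.05 * (n - 50)

    def test_null_passes_near_zero(self):
        rng = np.random.default_rng(10)
        totals = []
        for i in range(20):
            vals = pd.DataFrame(
                2.0 ** rng.normal(6, 0.4, size=(500, 8)),
                index=[f"g{i}" for i in range(500)],
                columns=[f"s{j}" for j in range(8)],
            )
            labels = pd.Series(["a"] * 4 + ["b"] * 4, index=vals.columns)
            res = differential_expression(ExpressionMatrix(values=vals),
                                          labels, normalize=False)
            totals.append(int(res["passes"].sum()))
        assert np.mean(totals) < 1.0

    def test_bh_monotone_and_adjusted_geq_raw(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(
            2.0 ** rng.normal(6, 0.4, size=(200, 8)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(8)],
        )
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=vals.columns)
        res = differential_expression(ExpressionMatrix(values=vals), labels)
        assert (res["adj_p"] >= res["p"] - 1e-15).all()
        srt = res.sort_values("p")
        assert srt["adj_p"].is_monotonic_increasing

    def test_paired_design_and_zero_variance(self):
        expr, meta, _ = sim.simulate_expression(
            sim.ExprSimSpec(n_genes=50, modules=[], seed=12)
        )
        vals = expr.values.copy()
        vals.iloc[0] = 7.0  # constant gene
        expr = ExpressionMatrix(values=vals, meta=meta)
        md = meta.table.set_index("sample_id")
        res = differential_expression(expr, md["treatment"],
                                      paired_by=md["line_id"],
                                      normalize=False)
        assert res.iloc[0]["zero_variance"]
        assert res.iloc[0]["p"] == 1.0
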