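"""PCA signal, mixture genotyping, regression, correction, trait clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import arraycnv as ac
from arraycnv.association import CnvrSignal
from arraycnv.studies import association_type1_error, mixture_recovery


def region(chrom="chr1", start=10_000, end=30_000, cnvr_id="CNVR001"):
    return ac.CnvRegion(cnvr_id, chrom, start, end, "loss")


def signal_from(values, prefix="S"):
    idx = [f"{prefix}{i}" for i in range(len(values))]
    return CnvrSignal("CNVR001", pd.Series(np.asarray(values, float), idx))


class TestExtractSignal:
    def test_single_probe_cnvr_scores_equal_probe_row(self, flat_probes):
        sm = ac.simulate_self_self(flat_probes, ac.NoiseModel(0.1, 0.0), 3,
                                   n_samples=12)
        r = region(start=int(flat_probes["pos"][5]),
                   end=int(flat_probes["pos"][5]))
        sig = ac.extract_cnvr_signal(sm, r)
        np.testing.assert_array_equal(sig.scores.to_numpy(), sm.values[5, :])

    def test_rank_one_signal_perfectly_correlated_with_any_probe(self,
                                                                 flat_probes):
        rng = np.random.default_rng(0)
        samplewise = rng.normal(size=20)
        values = np.zeros((len(flat_probes), 20))
        idx = (flat_probes["pos"].to_numpy() >= 10_000) & \
            (flat_probes["pos"].to_numpy() <= 30_000)
        values[idx, :] = samplewise  # identical across member probes
        sm = ac.SignalMatrix(flat_probes, [f"S{i}" for i in range(20)], values)
        sig = ac.extract_cnvr_signal(sm, region())
        r = np.corrcoef(sig.scores, samplewise)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # orientation follows the mean signal

    def test_multiprobe_score_separates_dosage_groups_better(self,
                                                             flat_probes):
        rng = np.random.default_rng(1)
        n, n_probes_in = 60, 20
        dosage = np.repeat([-1.0, 0.0, 0.585], n // 3)
        pos = flat_probes["pos"].to_numpy()
        idx = np.flatnonzero((pos >= 10_000) & (pos <= 34_000))[:n_probes_in]
        values = rng.normal(0, 0.15, (len(flat_probes), n))
        values[idx, :] += dosage
        sm = ac.SignalMatrix(flat_probes, [f"S{i}" for i in range(n)], values)
        sig = ac.extract_cnvr_signal(
            sm, region(end=int(pos[idx[-1]])))

        def f_ratio(x):
            groups = [x[i * 20:(i + 1) * 20] for i in range(3)]
            within = np.mean([np.var(g) for g in groups])
            between = np.var([np.mean(g) for g in groups])
            return between / within

        single = f_ratio(values[idx[0], :])
        assert f_ratio(sig.scores.to_numpy()) > single

    def test_no_probes_in_span_errors(self, flat_probes):
        sm = ac.simulate_self_self(flat_probes, ac.NoiseModel(0.1, 0.0), 3,
                                   n_samples=12)
        with pytest.raises(ValueError, match="no probes"):
            ac.extract_cnvr_signal(sm, region(chrom="chr9"))


class TestGenotypeCnvr:
    def test_constant_scores_give_single_component_baseline(self):
        fit, assigns = ac.genotype_cnvr(signal_from(np.zeros(30)), 0)
        assert fit.n_components == 1 and fit.converged
        assert {a.genotype_class for a in assigns} == {2}
        assert all(a.expected_dosage == 2.0 for a in assigns)

    def test_three_separated_clusters_recovered(self):
        accs = mixture_recovery(n_replicates=5, seed=3, n=150)
        assert accs.mean() >= 0.99

    def test_component_means_strictly_increasing_and_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-1, .05, 50), rng.normal(0, .05, 50),
                            rng.normal(.585, .05, 50)])
        fit, assigns = ac.genotype_cnvr(signal_from(x), 4)
        assert list(fit.means) == sorted(fit.means)
        assert sum(fit.weights) == pytest.approx(1.0)
        for a in assigns:
            assert sum(a.posteriors) == pytest.approx(1.0)

    def test_overlapping_clusters_fail_convergence_in_majority(self):
        bad = 0
        reps = 11
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(-0.2, 0.4, 50),
                                rng.normal(0.0, 0.4, 50),
                                rng.normal(0.2, 0.4, 50)])
            fit, _ = ac.genotype_cnvr(signal_from(x), seed)
            bad += not fit.converged
        assert bad > reps / 2

    def test_labels_invariant_to_constant_shift(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-1, .05, 50), rng.normal(0, .05, 100)])
        _, a1 = ac.genotype_cnvr(signal_from(x), 5)
        _, a2 = ac.genotype_cnvr(signal_from(x + 7.5), 5)
        assert [a.genotype_class for a in a1] == [a.genotype_class for a in a2]

    def test_cross_check_against_sklearn_mixture(self):
        """Independent EM route: sklearn recovers the same component means."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-1, .05, 50), rng.normal(0, .05, 50),
                            rng.normal(.585, .05, 50)])
        fit, _ = ac.genotype_cnvr(signal_from(x), 6)
        gm = GaussianMixture(3, random_state=0, n_init=5).fit(x[:, None])
        sk_means = np.sort(gm.means_.ravel())
        assert np.allclose(sk_means, fit.means, atol=0.02)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="10 samples"):
            ac.genotype_cnvr(signal_from(np.arange(5)), 0)


class TestAssociate:
    def test_trait_equal_to_dosage_is_perfectly_explained(self):
        rng = np.random.default_rng(0)
        d = pd.Series(rng.choice([1.0, 2.0, 3.0], 47),
                      index=[f"S{i}" for i in range(47)], name="CNVR001")
        res = ac.associate(d, d.astype(float), "Milk")
        assert res.variance_explained == pytest.approx(1.0)
        assert res.p_value < 1e-10
        assert res.beta == pytest.approx(1.0)

    def test_constant_dosage_is_untestable(self):
        d = pd.Series(2.0, index=[f"S{i}" for i in range(20)], name="x")
        y = pd.Series(np.random.default_rng(1).normal(size=20), index=d.index)
        res = ac.associate(d, y, "Milk")
        assert not res.testable
        assert res.p_value == 1.0 and res.beta == 0.0

    def test_type1_error_calibrated(self):
        p = association_type1_error(n_replicates=400, seed=2)
        assert abs((p < 0.05).mean() - 0.05) < 0.03

    def test_null_pvalues_uniform(self):
        from scipy import stats
        p = association_type1_error(n_replicates=1000, seed=3)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_equal_weights_wls_matches_ols(self):
        rng = np.random.default_rng(5)
        d = rng.choice([1.0, 2.0, 3.0], 60)
        y = 0.4 * d + rng.normal(size=60)
        idx = [f"S{i}" for i in range(60)]
        ds = pd.Series(d, index=idx, name="x")
        ys = pd.Series(y, index=idx)
        ols = ac.associate(ds, ys, "t")
        wls = ac.associate(ds, ys, "t",
                           weights=pd.Series(0.7, index=idx))
        assert wls.beta == pytest.approx(ols.beta)
        assert wls.se == pytest.approx(ols.se)
        assert wls.p_value == pytest.approx(ols.p_value)

    def test_regression_r2_equals_squared_dosage_trait_correlation(self):
        rng = np.random.default_rng(4)
        d = rng.choice([1.0, 2.0, 3.0], 100)
        y = 0.5 * d + rng.normal(size=100)
        idx = [f"S{i}" for i in range(100)]
        res = ac.associate(pd.Series(d, index=idx, name="x"),
                           pd.Series(y, index=idx), "t")
        assert res.variance_explained == pytest.approx(
            np.corrcoef(d, y)[0, 1] ** 2)


class TestBonferroni:
    def _result(self, p):
        return ac.AssociationResult("CNVR001", "Milk", 47, 1.0, 0.1, p, True)

    def test_corrected_p_arithmetic(self):
        (r,) = ac.bonferroni_correct([self._result(0.001)], 297)
        assert r.p_bonferroni == pytest.approx(0.297)
        assert not r.significant
        (r,) = ac.bonferroni_correct([self._result(1e-6)], 297)
        assert r.p_bonferroni == pytest.approx(2.97e-4)
        assert r.significant

    def test_capped_at_one(self):
        (r,) = ac.bonferroni_correct([self._result(0.5)], 297)
        assert r.p_bonferroni == 1.0

    @pytest.mark.parametrize("m", [1, 5, 297])
    def test_corrected_significant_subset_of_nominal(self, m):
        rng = np.random.default_rng(m)
        results = [self._result(p) for p in rng.uniform(0, 0.2, 50)]
        corrected = ac.bonferroni_correct(results, m)
        for r in corrected:
            if r.significant:
                assert r.p_value < 0.05


class TestVarianceExplained:
    def test_identity_and_sign_invariance(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=50), index=range(50))
        assert ac.variance_explained(x, x) == pytest.approx(1.0)
        assert ac.variance_explained(x, -x) == pytest.approx(1.0)

    def test_constant_input_warns_and_returns_zero(self):
        x = pd.Series(np.ones(10), index=range(10))
        y = pd.Series(np.arange(10.0), index=range(10))
        with pytest.warns(UserWarning):
            assert ac.variance_explained(x, y) == 0.0


class TestClusterTraits:
    @staticmethod
    def _block_p_matrix(rng, sizes, n_cnvrs=60, strength=3.0):
        """CNVRs affect whole trait blocks -> correlated -log10 p columns."""
        n_traits = sum(sizes)
        blocks = np.repeat(np.arange(len(sizes)), sizes)
        logp = rng.exponential(0.3, size=(n_cnvrs, n_traits))
        for i in range(n_cnvrs):
            b = rng.integers(0, len(sizes))
            logp[i, blocks == b] += rng.exponential(strength)
        cols = [f"T{j}" for j in range(n_traits)]
        return pd.DataFrame(10.0 ** (-logp), columns=cols), blocks

    def test_duplicated_trait_column_merges_first(self):
        rng = np.random.default_rng(1)
        p = pd.DataFrame(rng.uniform(0.001, 1, size=(20, 3)),
                         columns=["A", "B", "C"])
        p["Bdup"] = p["B"]
        Z, traits, order = ac.cluster_traits(p)
        # the first (lowest) merge joins the identical twins at distance 0
        i, j, dist = int(Z[0, 0]), int(Z[0, 1]), Z[0, 2]
        assert dist == pytest.approx(0.0)
        assert {traits[i], traits[j]} == {"B", "Bdup"}

    def test_anticorrelated_blocks_split_at_top(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        logp = np.column_stack([base, base * 0.9, -base, -base * 1.1]) * 2
        p = pd.DataFrame(10.0 ** (-np.abs(logp) - 0.1 * (logp < 0)),
                         columns=["a1", "a2", "b1", "b2"])
        # craft: columns a* correlated, b* anti-correlated with a*
        X = np.column_stack([base, base + rng.normal(0, .1, 40),
                             -base, -base + rng.normal(0, .1, 40)])
        p = pd.DataFrame(10.0 ** (-(X - X.min() + 0.1)),
                         columns=["a1", "a2", "b1", "b2"])
        Z, traits, order = ac.cluster_traits(p)
        labels = fcluster(Z, 2, criterion="maxclust")
        by = {t: l for t, l in zip(traits, labels)}
        assert by["a1"] == by["a2"] != by["b1"] == by["b2"]

    def test_four_block_model_recovered(self):
        """Synthetic 6/9/8/18 trait blocks recovered with ARI >= 0.8."""
        from sklearn.metrics import adjusted_rand_score

        sizes = (6, 9, 8, 18)
        aris = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p, blocks = self._block_p_matrix(rng, sizes)
            Z, traits, order = ac.cluster_traits(p)
            labels = fcluster(Z, 4, criterion="maxclust")
            aris.append(adjusted_rand_score(blocks, labels))
        assert np.mean(aris) >= 0.8

    def test_constant_column_warns(self):
        rng = np.random.default_rng(3)
        p = pd.DataFrame(rng.uniform(0.001, 1, size=(15, 3)),
                         columns=["A", "B", "C"])
        p["flat"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            Z, traits, order = ac.cluster_traits(p)
        assert set(order) == set(p.columns)
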