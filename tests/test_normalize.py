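"""TMM factors, expression transforms and voom-style precision weights."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from tcresponse import normalize
from tcresponse.containers import CountExperiment
from tcresponse.simulate import SimulationConfig, simulate_counts


def make_exp(counts: np.ndarray) -> CountExperiment:
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=[f"s{i}" for i in range(counts.shape[1])],
    )
    times = (["0", "0.5h", "3h"] * counts.shape[1])[: counts.shape[1]]
    design = pd.DataFrame(
        {"time": times, "replicate": range(counts.shape[1])},
        index=counts.columns.rename("sample_id"),
    )
    return CountExperiment(counts, design)


class TestFilter:
    def test_zero_threshold_is_identity(self, toy_experiment):
        out = normalize.filter_low_counts(toy_experiment, min_cpm=0, min_samples=0)
        pd.testing.assert_frame_equal(out.counts, toy_experiment.counts)

    def test_all_zero_gene_removed(self):
        exp = make_exp(np.array([[0, 0], [5, 5]]))
        out = normalize.filter_low_counts(exp, min_cpm=1, min_samples=1)
        assert list(out.gene_ids) == ["g1"]

    def test_matches_direct_rule(self):
        counts = np.array([[0, 1], [10, 0], [3, 3], [0, 0], [100, 100]])
        exp = make_exp(counts)
        min_cpm, min_samples = 50_000, 2
        out = normalize.filter_low_counts(exp, min_cpm, min_samples)
        lib = counts.sum(axis=0)
        expected = [
            f"g{i}"
            for i in range(5)
            if sum(counts[i, s] / lib[s] * 1e6 >= min_cpm for s in range(2))
            >= min_samples
        ]
        assert list(out.gene_ids) == expected


def brute_force_tmm(obs, ref, logratio_trim=0.30, abs_trim=0.05):
    """Independent re-derivation of the doubly trimmed weighted mean."""
    n_obs, n_ref = obs.sum(), ref.sum()
    rows = []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m = np.log2((o / n_obs) / (r / n_ref))
            a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
            v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
            rows.append((m, a, v))
    M = np.array([r[0] for r in rows])
    A = np.array([r[1] for r in rows])
    V = np.array([r[2] for r in rows])
    n = len(M)
    lo_m, lo_a = np.floor(n * logratio_trim) + 1, np.floor(n * abs_trim) + 1
    keep = (
        (rankdata(M) >= lo_m) & (rankdata(M) <= n + 1 - lo_m)
        & (rankdata(A) >= lo_a) & (rankdata(A) <= n + 1 - lo_a)
    )
    return 2 ** (np.sum(M[keep] / V[keep]) / np.sum(1 / V[keep]))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80, 120, 30, 7])
        counts = pd.DataFrame(np.column_stack([col] * 3), columns=list("abc"))
        assert np.allclose(normalize.tmm_factors(counts), 1.0)

    def test_pure_depth_change_absorbed_by_library_size(self):
        col = np.array([10, 50, 200, 5, 80, 120, 30, 7])
        counts = pd.DataFrame({"a": col, "b": 4 * col})
        assert np.allclose(normalize.tmm_factors(counts), 1.0, atol=1e-9)

    def test_matches_brute_force_on_composition_fixture(self):
        # one highly expressed sample-specific gene distorts proportions
        a = np.array([100, 120, 80, 90, 110, 95, 105, 10_000])
        b = np.array([100, 118, 82, 95, 108, 92, 100, 5])
        counts = pd.DataFrame({"a": a, "b": b})
        factors = normalize.tmm_factors(counts, ref_sample="b")
        raw = brute_force_tmm(a, b)
        expected = np.array([raw, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(factors.to_numpy(), expected, rtol=1e-10)

    def test_invariant_to_scaling_one_sample(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, size=(200, 4)), columns=list("abcd"))
        f1 = normalize.tmm_factors(counts, ref_sample="a")
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 7  # integer scaling, no rounding error
        f2 = normalize.tmm_factors(scaled, ref_sample="a")
        # proportions are unchanged; only the depth-dependent precision
        # weights move, so agreement is close but not exact
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=0.01)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(300, 5)))
        f = normalize.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-6)
        assert (f > 0).all()

    def test_disjoint_support_warns_and_defaults(self, caplog):
        counts = pd.DataFrame({"a": [5, 5, 0, 0], "b": [0, 0, 5, 5]})
        with caplog.at_level("WARNING"):
            f = normalize.tmm_factors(counts, ref_sample="a")
        assert np.allclose(f, 1.0)


class TestTransforms:
    def test_forced_zero_count_value(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        lib = pd.Series({"s": 1e6 - 1})
        out = normalize.log_cpm(counts, lib, prior_count=0.5)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5), abs=1e-12)

    def test_ratio_invariance_without_prior(self):
        counts = pd.DataFrame({"s": [100]}, index=["g"])
        a = normalize.log_cpm(counts, pd.Series({"s": 1e6 - 1}), prior_count=0.0)
        b = normalize.log_cpm(2 * counts, pd.Series({"s": 2e6 - 1}), prior_count=0.0)
        assert a.iloc[0, 0] == pytest.approx(b.iloc[0, 0], abs=1e-12)

    def test_log_cpm_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.poisson(50, size=(20, 4)))
        lib = pd.Series(rng.uniform(1e5, 1e6, 4), index=counts.columns)
        out = normalize.log_cpm(counts, lib, prior_count=0.5)
        direct = np.log2((counts.to_numpy() + 0.5) / (lib.to_numpy() + 1) * 1e6)
        assert np.abs(out.to_numpy() - direct).max() < 1e-12

    def test_rpkm_forced_values(self):
        counts = pd.DataFrame({"s": [1000]}, index=["g"])
        lib = pd.Series({"s": 1e6})
        lengths = pd.Series({"g": 2000.0})
        lin = normalize.rpkm(counts, lib, lengths, prior_count=0, log=False)
        assert lin.iloc[0, 0] == pytest.approx(500.0, abs=1e-12)
        logged = normalize.rpkm(counts, lib, lengths, prior_count=0, log=True)
        assert logged.iloc[0, 0] == pytest.approx(np.log2(500.0), abs=1e-12)
        halved = normalize.rpkm(counts, lib, 2 * lengths, prior_count=0, log=False)
        assert halved.iloc[0, 0] == pytest.approx(250.0, abs=1e-12)

    def test_rpkm_missing_length_is_missing(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["g1", "g2"])
        out = normalize.rpkm(counts, pd.Series({"s": 1e6}), pd.Series({"g1": 1000.0}))
        assert np.isfinite(out.loc["g1", "s"])
        assert np.isnan(out.loc["g2", "s"])


def cellmeans_design(n_per=3):
    times = ["0"] * n_per + ["0.5h"] * n_per + ["3h"] * n_per
    idx = [f"s{i}" for i in range(3 * n_per)]
    return pd.DataFrame(
        {t: [1.0 if x == t else 0.0 for x in times] for t in ("0", "0.5h", "3h")},
        index=idx,
    )


class TestVoomWeights:
    def test_homoscedastic_data_gives_flat_weights(self):
        rng = np.random.default_rng(21)
        X = cellmeans_design()
        means = rng.uniform(2, 12, size=300)
        Y = pd.DataFrame(
            means[:, None] + rng.normal(0, 0.5, size=(300, 9)), columns=X.index
        )
        w = normalize.voom_weights(Y, X)
        flat = w.weights.to_numpy()
        assert flat.std() / flat.mean() < 0.15

    def test_nb_like_variance_gives_increasing_weights(self):
        cfg = SimulationConfig(n_genes=800, effect_size=0.0, dispersion=0.2, seed=13)
        exp, _ = simulate_counts(cfg)
        exp = normalize.filter_low_counts(exp)
        norm = normalize.normalize_experiment(exp)
        X = cellmeans_design()
        X.index = exp.sample_ids
        w = normalize.voom_weights(norm.log_cpm, X, lib_sizes=norm.effective_lib_sizes)
        mean_lc = norm.log_cpm.mean(axis=1)
        rho = spearmanr(mean_lc, w.weights.mean(axis=1)).statistic
        assert rho > 0.5

    def test_smoother_locality(self):
        rng = np.random.default_rng(5)
        X = cellmeans_design()
        means = np.linspace(0, 12, 400)
        Y = pd.DataFrame(
            means[:, None] + rng.normal(0, 0.4, size=(400, 9)), columns=X.index
        )
        w0 = normalize.voom_weights(Y, X)
        Y2 = Y.copy()
        Y2.iloc[0, 0] += 0.5  # perturb one observation at the low end
        w1 = normalize.voom_weights(Y2, X)
        far = means > 9
        delta = np.abs(w1.weights.to_numpy()[far] - w0.weights.to_numpy()[far])
        assert delta.max() < 1e-6

    def test_degenerate_zero_variance_rejected(self):
        X = cellmeans_design()
        Y = pd.DataFrame(np.ones((10, 9)), columns=X.index)
        with pytest.raises(ValueError, match="zero residual variance"):
            normalize.voom_weights(Y, X)
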