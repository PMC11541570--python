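import numpy as np
import pandas as pd
import pytest

from intronapa import survival as surv
from intronapa import synthetic as syn


def _clinical(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return surv.ClinicalTable(
        pd.DataFrame({"time": times, "event": events}, index=samples)
    )


class TestVarianceFilter:
    def test_constant_feature_removed(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [0.1, 0.5, 0.9]],
                         index=["const", "varies"])
        assert surv.variance_filter(m, 1e-6) == ["varies"]

    def test_tr_threshold_boundary(self):
        x = np.array([0.0, 0.2, 0.4])  # sample variance 0.04
        m = pd.DataFrame([x], index=["g"])
        assert surv.variance_filter(m, 0.01) == ["g"]
        assert surv.variance_filter(m, 0.05) == []

    def test_matches_brute_force_variance(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(30, 12)),
                         index=[f"f{i}" for i in range(30)])
        thr = 0.9
        expected = [
            f for f in m.index
            if np.sum((m.loc[f] - m.loc[f].mean()) ** 2) / 11 >= thr
        ]
        assert surv.variance_filter(m, thr) == expected


class TestLogrankScreen:
    def test_identical_groups_not_selected(self):
        times = list(range(1, 21))
        clin = _clinical(times, [1] * 20)
        # feature dichotomizes into two groups with identical survival
        x = [0.0, 1.0] * 10
        feats = pd.DataFrame([x], index=["f"], columns=clin.frame.index)
        # shuffle so high/low groups have interleaved identical times
        assert surv.logrank_screen(feats, clin, alpha=0.05) == []

    def test_zero_event_group_skipped(self):
        clin = _clinical([1, 2, 3, 4], [0, 0, 1, 1])
        feats = pd.DataFrame([[0.0, 0.2, 0.8, 1.0]], index=["f"],
                             columns=clin.frame.index)
        # low group (first two) has zero events
        assert surv.logrank_screen(feats, clin, alpha=0.99) == []

    def test_planted_hazard_detected(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        cfg = syn.SyntheticConfig(seed=3, censoring_rate=0.3)
        X = pd.DataFrame([x], index=["f"], columns=[f"s{i}" for i in range(n)])
        clin = syn.generate_survival(cfg, X, pd.Series({"f": np.log(3.0)}))
        assert surv.logrank_screen(X, clin, alpha=0.05) == ["f"]

    def test_leakage_guard(self):
        """Screening uses only training samples: permuting test-sample
        clinical rows never changes the selected set."""
        rng = np.random.default_rng(4)
        n = 100
        samples = [f"s{i}" for i in range(n)]
        feats = pd.DataFrame(rng.normal(size=(10, n)),
                             index=[f"f{i}" for i in range(10)],
                             columns=samples)
        cfg = syn.SyntheticConfig(seed=5, censoring_rate=0.2)
        beta = pd.Series(0.0, index=feats.index)
        beta["f0"] = 1.0
        clin = syn.generate_survival(cfg, feats, beta)
        train, test = surv.train_test_split_samples(samples, seed=9)
        base = surv.logrank_screen(feats, clin, 0.05, train)
        shuffled = clin.frame.copy()
        shuffled.loc[test, ["time", "event"]] = (
            shuffled.loc[rng.permutation(test), ["time", "event"]].to_numpy()
        )
        again = surv.logrank_screen(
            feats, surv.ClinicalTable(shuffled), 0.05, train
        )
        assert base == again


class TestCoxElasticNet:
    def test_pure_noise_with_heavy_l1_shrinks_to_zero(self):
        rng = np.random.default_rng(11)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 8)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"f{i}" for i in range(8)])
        clin = _clinical(rng.exponential(10, n), [1] * n,
                         samples=list(X.index))
        model = surv.fit_cox_elastic_net(X, clin, alpha=5.0, l1_ratio=1.0)
        assert (model.beta == 0).all()

    def test_duplicated_covariates_get_near_equal_weights(self):
        """Ridge-dominant elastic net spreads weight across duplicates."""
        rng = np.random.default_rng(13)
        n = 300
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": x.copy()},
                         index=[f"s{i}" for i in range(n)])
        cfg = syn.SyntheticConfig(seed=17, censoring_rate=0.2)
        clin = syn.generate_survival(
            cfg, X.T, pd.Series({"a": 0.5, "b": 0.5})
        )
        model = surv.fit_cox_elastic_net(X, clin, alpha=0.1, l1_ratio=0.01)
        assert model.beta["a"] == pytest.approx(model.beta["b"], rel=0.05)

    def test_recovers_planted_coefficient_with_light_penalty(self):
        rng = np.random.default_rng(19)
        n = 500
        x = rng.normal(size=n)
        X = pd.DataFrame({"f": x}, index=[f"s{i}" for i in range(n)])
        cfg = syn.SyntheticConfig(seed=23, censoring_rate=0.3)
        clin = syn.generate_survival(cfg, X.T, pd.Series({"f": 0.8}))
        model = surv.fit_cox_elastic_net(X, clin, alpha=1e-4)
        assert model.beta["f"] == pytest.approx(0.8, rel=0.15)


class TestRiskGroups:
    def test_pi_linear_arithmetic(self):
        model = surv.RiskModel(["a", "b"], pd.Series({"a": 1.0, "b": 2.0}))
        X = pd.DataFrame({"a": [0.5], "b": [0.25]}, index=["s0"])
        assert model.compute_pi(X)["s0"] == pytest.approx(1.0)

    def test_pi_shift_invariance(self):
        """Adding a constant to a covariate shifts PIs equally and leaves
        risk-group labels unchanged."""
        rng = np.random.default_rng(29)
        X = pd.DataFrame(rng.normal(size=(20, 2)),
                         index=[f"s{i}" for i in range(20)],
                         columns=["a", "b"])
        model = surv.RiskModel(["a", "b"], pd.Series({"a": 0.7, "b": -0.3}))
        clin = _clinical(rng.exponential(5, 20), [1] * 20, list(X.index))
        pi1 = model.compute_pi(X)
        labels1, _, _ = surv.risk_groups(pi1, clin)
        X2 = X.copy()
        X2["a"] += 10.0
        pi2 = model.compute_pi(X2)
        assert np.allclose(pi2 - pi1, 7.0)
        labels2, _, _ = surv.risk_groups(pi2, clin)
        assert (labels1 == labels2).all()

    def test_even_split(self):
        pi = pd.Series(np.arange(10, dtype=float),
                       index=[f"s{i}" for i in range(10)])
        clin = _clinical(list(range(1, 11)), [1] * 10)
        labels, _, _ = surv.risk_groups(pi, clin)
        assert (labels == "low").sum() == 5
        assert (labels == "high").sum() == 5

    def test_odd_n_median_sample_goes_low(self):
        pi = pd.Series(np.arange(11, dtype=float),
                       index=[f"s{i}" for i in range(11)])
        clin = _clinical(list(range(1, 12)), [1] * 11)
        labels, _, _ = surv.risk_groups(pi, clin)
        assert (labels == "low").sum() == 6
        assert labels["s5"] == "low"

    def test_km_reduces_to_empirical_survival_without_censoring(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        pi = pd.Series([0, 0, 0, 1, 1, 1.0],
                       index=[f"s{i}" for i in range(6)])
        clin = _clinical(times, [1] * 6)
        _, fits, _ = surv.risk_groups(pi, clin)
        km = fits["low"].survival_function_
        # low group has times 1,2,3 -> S(t) steps 2/3, 1/3, 0
        assert km.loc[1.0].iloc[0] == pytest.approx(2 / 3)
        assert km.loc[2.0].iloc[0] == pytest.approx(1 / 3)
        assert km.loc[3.0].iloc[0] == pytest.approx(0.0)

    def test_high_risk_curve_below_low_risk_in_expectation(self):
        """When PI truly drives hazard, the high-risk KM curve sits below
        the low-risk curve (averaged over replicates)."""
        deficits = []
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            n = 80
            x = rng.normal(size=n)
            X = pd.DataFrame({"f": x}, index=[f"s{i}" for i in range(n)])
            cfg = syn.SyntheticConfig(seed=rep, censoring_rate=0.2)
            clin = syn.generate_survival(cfg, X.T, pd.Series({"f": 1.0}),
                                         seed_offset=rep)
            pi = pd.Series(x, index=X.index)
            _, fits, _ = surv.risk_groups(pi, clin)
            grid = np.linspace(0.5, 10, 12)
            lo = fits["low"].survival_function_at_times(grid).to_numpy()
            hi = fits["high"].survival_function_at_times(grid).to_numpy()
            deficits.append((lo - hi).mean())
        assert np.mean(deficits) > 0.1


class TestIntegrationAndSelection:
    def test_block_concatenation_with_namespaces(self):
        rng = np.random.default_rng(31)
        samples = [f"s{i}" for i in range(10)]
        ge = pd.DataFrame(rng.normal(scale=3, size=(5, 10)),
                          index=[f"g{i}" for i in range(5)], columns=samples)
        tr = pd.DataFrame(rng.uniform(0, 1, size=(4, 10)),
                          index=[f"g{i}" for i in range(4)], columns=samples)
        combined = surv.integrate_covariates(ge, tr)
        assert all(f.startswith(("GE:", "TR:")) for f in combined.index)
        # overlapping raw gene names must stay distinct
        assert len(combined.index) == len(set(combined.index))

    def test_sample_mismatch_lists_difference(self):
        ge = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        tr = pd.DataFrame([[0.1, 0.2]], index=["g"], columns=["s1", "s3"])
        with pytest.raises(ValueError, match="s3"):
            surv.integrate_covariates(ge, tr)

    def test_ttest_top_k_prefers_separated_features(self):
        rng = np.random.default_rng(37)
        samples = [f"s{i}" for i in range(40)]
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=samples)
        flat = rng.normal(size=40)
        sep = np.r_[rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
        feats = pd.DataFrame([flat, sep], index=["flat", "sep"],
                             columns=samples)
        assert surv.ttest_top_k(feats, labels, k=1) == ["sep"]

    def test_ttest_top_k_edge_cases(self):
        samples = ["s1", "s2", "s3", "s4"]
        labels = pd.Series(["a", "a", "b", "b"], index=samples)
        feats = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f"],
                             columns=samples)
        assert surv.ttest_top_k(feats, labels, k=0) == []
        assert surv.ttest_top_k(feats, labels, k=10) == ["f"]

    def test_planted_discriminative_features_recalled(self):
        rng = np.random.default_rng(41)
        n, p, k = 100, 300, 10
        samples = [f"s{i}" for i in range(n)]
        labels = pd.Series(["a"] * 50 + ["b"] * 50, index=samples)
        recalls = []
        for _ in range(20):
            X = rng.normal(size=(p, n))
            X[:k, 50:] += 1.0  # 1-SD shift in the planted features
            feats = pd.DataFrame(X, index=[f"f{i}" for i in range(p)],
                                 columns=samples)
            chosen = surv.ttest_top_k(feats, labels, k=k)
            recalls.append(
                len(set(chosen) & {f"f{i}" for i in range(k)}) / k
            )
        assert np.mean(recalls) >= 0.9


def test_prognostic_pipeline_end_to_end():
    ge, tr, beta = syn.generate_feature_blocks(seed=3, n_samples=300)
    cfg = syn.SyntheticConfig(seed=3, censoring_rate=0.3)
    allX = pd.concat([ge, tr])
    clin = syn.generate_survival(cfg, allX, beta)
    model = surv.prognostic_pipeline(allX, clin, seed=3)
    assert model is not None
    assert model.logrank_p < 0.05
    assert set(model.risk_group.unique()) == {"high", "low"}
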