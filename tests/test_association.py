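import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microtopics as mt
from microtopics.association import estimate_null_fwer

from conftest import make_counts


def two_level_theta(mean_a, mean_b, n_per=5):
    """Theta where every level-A sample has row mean_a and level-B mean_b."""
    theta = np.array([mean_a] * n_per + [mean_b] * n_per, dtype=float)
    labels = ["A"] * n_per + ["B"] * n_per
    return theta, labels


class TestTopicWeighting:
    def test_symmetric_topic_sits_at_zero(self):
        theta, labels = two_level_theta([0.5, 0.5], [0.5, 0.5])
        tw = mt.topic_weighting(theta, labels)
        np.testing.assert_allclose(tw["coordinate"], 0.0)
        assert (tw["strength"] == "none").all()

    def test_four_to_one_share_gives_coordinate_three_quarters(self):
        theta, labels = two_level_theta([0.2, 0.8], [0.8, 0.2])
        tw = mt.topic_weighting(theta, labels)
        # topic 1 has w_B... topic 0: w_A=0.2/... mean share 4:1 toward B
        assert tw.loc[0, "coordinate"] == pytest.approx(0.75)   # toward B
        assert tw.loc[1, "coordinate"] == pytest.approx(-0.75)  # toward A

    def test_boundary_weighting_hits_plot_edge(self):
        assert mt.plot_coordinate(0.0, 1.0) == pytest.approx(1.0)
        assert mt.plot_coordinate(1.0, 0.0) == pytest.approx(-1.0)

    def test_per_level_share_x_sums_to_one(self):
        rng = np.random.default_rng(3)
        theta = rng.dirichlet(np.ones(6), size=20)
        labels = ["A"] * 11 + ["B"] * 9
        tw = mt.topic_weighting(theta, labels)
        assert tw["x_A"].sum() == pytest.approx(1.0, abs=1e-9)
        assert tw["x_B"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_coordinate_formula_direct_evaluation(self):
        # w2 = 0.8 (4:1 share) -> 2 - 1/0.8 = 0.75
        assert mt.plot_coordinate(0.2, 0.8) == pytest.approx(2 - 1 / 0.8)

    def test_needs_two_levels(self):
        theta = np.full((4, 2), 0.5)
        with pytest.raises(ValueError, match="2 levels"):
            mt.topic_weighting(theta, ["A", "A", "B", "C"])


class TestClassifyAssociation:
    def test_exact_four_fold_ratio_is_strong(self):
        theta, labels = two_level_theta([0.8, 0.2], [0.2, 0.8])
        out = mt.classify_association(theta, labels, "A")
        assert out.loc[0, "strength"] == "strong"
        assert out.loc[1, "strength"] == "none"

    def test_two_fold_ratio_is_moderate(self):
        theta, labels = two_level_theta([0.67, 0.33], [0.33, 0.67])
        out = mt.classify_association(theta, labels, "A")
        assert out.loc[0, "strength"] == "moderate"

    def test_min_over_alternatives_rule(self):
        # focal ratio 5 against one alternative but only 1.5 against the other
        theta = np.array([[0.5, 0.5]] * 2 + [[0.1, 0.9]] * 2 + [[1 / 3, 2 / 3]] * 2)
        labels = ["A", "A", "B", "B", "C", "C"]
        out = mt.classify_association(theta, labels, "A")
        assert out.loc[0, "min_ratio"] == pytest.approx(1.5)
        assert out.loc[0, "strength"] == "none"

    def test_zero_alternative_mean_is_degenerate_strong(self):
        theta, labels = two_level_theta([1.0, 0.0], [0.0, 1.0])
        out = mt.classify_association(theta, labels, "A")
        assert out.loc[0, "strength"] == "strong"
        assert bool(out.loc[0, "degenerate"])

    def test_unknown_focal_level_rejected(self):
        theta, labels = two_level_theta([0.5, 0.5], [0.5, 0.5])
        with pytest.raises(ValueError, match="focal level"):
            mt.classify_association(theta, labels, "Z")

    def test_threshold_equivalence_with_plot_coordinate(self):
        """Strength boundaries coincide with |coordinate| = 0.5 and 0.75
        for any two-level theta (algebraic identity of the w/ratio map)."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            theta = rng.dirichlet(np.full(4, 0.4), size=12)
            labels = ["A"] * 6 + ["B"] * 6
            tw = mt.topic_weighting(theta, labels)
            for _, row in tw.iterrows():
                c = abs(row["coordinate"])
                if row["strength"] == "strong":
                    assert c >= 0.75 - 1e-12
                elif row["strength"] == "moderate":
                    assert 0.5 - 1e-12 <= c < 0.75 + 1e-12
                else:
                    assert c < 0.5 + 1e-12


class TestRelativeAmplification:
    def test_phi_equal_to_corpus_frequency_gives_unit_lift(self):
        corpus = make_counts([[2, 2], [3, 3]])
        from conftest import make_model
        model = make_model(phi=[[0.5, 0.5]])
        amp = mt.relative_amplification(model, corpus)
        np.testing.assert_allclose(amp["lift"], 1.0)
        np.testing.assert_allclose(amp["amplification"], 0.5)

    def test_arithmetic_oracle(self):
        corpus = make_counts([[5, 5]])
        from conftest import make_model
        model = make_model(phi=[[0.9, 0.1]])
        amp = mt.relative_amplification(model, corpus)
        np.testing.assert_allclose(amp["lift"], [1.8, 0.2])
        np.testing.assert_allclose(amp["amplification"], [0.9, 0.1])

    def test_per_topic_normalized_sum_is_one(self, fitted_model, planted_dataset):
        amp = mt.relative_amplification(fitted_model, planted_dataset.counts)
        sums = amp.groupby("topic")["amplification"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_zero_frequency_taxon_rejected(self):
        corpus = make_counts([[5, 0]])
        from conftest import make_model
        model = make_model(phi=[[0.5, 0.5]])
        with pytest.raises(ValueError, match="zero-frequency"):
            mt.relative_amplification(model, corpus)


def holm_oracle(p_values):
    """Step-down Holm adjustment written independently for testing."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestTraitTests:
    def frame(self, arr, cols):
        idx = [f"S{i}" for i in range(len(arr))]
        return pd.DataFrame(arr, index=idx, columns=cols)

    def test_monotone_pair_has_rho_one(self):
        vals = self.frame([[0.1], [0.2], [0.3], [0.4]], ["t0"])
        traits = self.frame([[1.0], [2.0], [5.0], [9.0]], ["h"])
        out = mt.trait_tests(vals, traits)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_holm_adjustment_matches_stepdown_oracle(self):
        rng = np.random.default_rng(2)
        vals = self.frame(rng.normal(size=(15, 3)), ["a", "b", "c"])
        traits = self.frame(rng.normal(size=(15, 2)), ["x", "y"])
        traits["x"] += 2.0 * vals["a"]  # one real association
        out = mt.trait_tests(vals, traits)
        np.testing.assert_allclose(
            out["p_holm"], holm_oracle(out["p_raw"].to_numpy()), atol=1e-12
        )

    def test_stepdown_rejects_both_in_textbook_case(self):
        # family of 2 with raw p 0.01 and 0.04: 0.01 <= 0.025 then 0.04 <= 0.05
        adj = holm_oracle(np.array([0.01, 0.04]))
        assert (adj <= 0.05).all()
        np.testing.assert_allclose(adj, [0.02, 0.04])

    def test_constant_vector_recorded_with_reason(self):
        vals = self.frame([[0.5], [0.5], [0.5], [0.5]], ["t0"])
        traits = self.frame([[1.0], [2.0], [3.0], [4.0]], ["h"])
        out = mt.trait_tests(vals, traits)
        assert out.loc[0, "reason"] == "constant vector"
        assert np.isnan(out.loc[0, "rho"]) and not out.loc[0, "significant"]

    def test_missing_values_dropped_pairwise(self):
        vals = self.frame([[0.1], [0.2], [0.3], [0.4], [0.5]], ["t0"])
        traits = self.frame([[1.0], [np.nan], [3.0], [4.0], [5.0]], ["h"])
        out = mt.trait_tests(vals, traits)
        assert out.loc[0, "n"] == 4
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_too_few_pairs_excluded(self):
        vals = self.frame([[0.1], [0.2], [0.3]], ["t0"])
        traits = self.frame([[1.0], [np.nan], [np.nan]], ["h"])
        out = mt.trait_tests(vals, traits)
        assert "fewer than" in out.loc[0, "reason"]

    def test_holm_rejections_superset_of_bonferroni(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        for rep in range(10):
            vals = self.frame(rng.normal(size=(20, 4)), list("abcd"))
            traits = self.frame(rng.normal(size=(20, 3)), list("xyz"))
            traits["x"] += rng.normal(1.5) * vals["a"]
            out = mt.trait_tests(vals, traits)
            bonf = multipletests(out["p_raw"], alpha=0.05,
                                 method="bonferroni")[0]
            holm = out["significant"].to_numpy()
            assert (holm | ~bonf).all()  # bonferroni-rejected => holm-rejected
            # and every Holm rejection would also reject unadjusted
            assert (out.loc[holm, "p_raw"] <= 0.05).all()


class TestPerTaxonCorrelations:
    def test_reduces_to_trait_tests_on_relative_abundance(self):
        rng = np.random.default_rng(1)
        counts = make_counts(rng.integers(1, 50, size=(12, 3)))
        traits = pd.DataFrame(
            rng.normal(size=(12, 2)), index=counts.sample_ids, columns=["x", "y"]
        )
        direct = mt.per_taxon_correlations(counts, traits)
        rel = counts.data.div(counts.data.sum(axis=1), axis=0)
        via_units = mt.trait_tests(rel, traits)
        np.testing.assert_allclose(direct["rho"], via_units["rho"])

    def test_taxon_proportional_to_trait(self):
        counts = make_counts([[1, 9], [2, 8], [5, 5], [9, 1]])
        traits = pd.DataFrame({"h": [1.0, 2.0, 3.0, 4.0]},
                              index=counts.sample_ids)
        out = mt.per_taxon_correlations(counts, traits)
        assert out.set_index("unit").loc["T0", "rho"] == pytest.approx(1.0)

    def test_absent_taxon_excluded_with_reason(self):
        counts = make_counts([[3, 0], [4, 0], [2, 0], [6, 0]])
        # column T1 is zero everywhere, T0 becomes constant rel abundance
        traits = pd.DataFrame({"h": [1.0, 2.0, 3.0, 4.0]},
                              index=counts.sample_ids)
        out = mt.per_taxon_correlations(counts, traits)
        row = out.set_index("unit").loc["T1"]
        assert row["reason"] == "taxon absent from every sample"


class TestNullFwer:
    def test_small_null_study_controls_fwer(self):
        result = estimate_null_fwer(n_replicates=60, n_samples=40,
                                    n_topics=3, n_traits=3, seed=4)
        assert result["fwer"] <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)
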