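"""Discriminant engine: hand-computed scatter, closed-form single-variable
canonical correlation, sklearn cross-check, brute-force LOO oracle."""

import numpy as np
import pandas as pd
import pytest

from codlipids.discriminant import (
    SingularMatrixError,
    classify,
    classify_batch,
    fit_cda,
    loo_crossvalidate,
    resubstitution,
    scatter_matrices,
    stepwise_select,
    wilks_lambda,
)
from codlipids.profiles import profiles_to_frame
from codlipids.simulate import SimulationConfig, simulate_cohort

TOY_X = np.array([[1.0, 2.0], [2.0, 4.0], [5.0, 1.0], [6.0, 4.0]])
TOY_LABELS = np.array(["a", "a", "b", "b"])


class TestScatterMatrices:
    def test_hand_computation(self):
        T, W, B = scatter_matrices(TOY_X, TOY_LABELS)
        # group means a=(1.5,3), b=(5.5,2.5); overall (3.5,2.75)
        np.testing.assert_allclose(W, [[1.0, 2.5], [2.5, 6.5]])
        np.testing.assert_allclose(T, [[17.0, 0.5], [0.5, 6.75]])
        np.testing.assert_allclose(B, T - W)

    def test_decomposition_exact(self, rng):
        X = rng.normal(size=(30, 4))
        labels = np.repeat(["a", "b", "c"], 10)
        T, W, B = scatter_matrices(X, labels)
        np.testing.assert_allclose(T, W + B, atol=1e-12)
        eig = np.linalg.eigvalsh((B + B.T) / 2)
        assert eig.min() > -1e-10  # B is PSD

    def test_single_group_has_zero_between(self, rng):
        X = rng.normal(size=(6, 3))
        T, W, B = scatter_matrices(X, np.array(["a"] * 6))
        np.testing.assert_allclose(B, np.zeros((3, 3)), atol=1e-10)

    def test_duplicated_column_raises_named_singularity(self, rng):
        X = rng.normal(size=(12, 2))
        X = np.column_stack([X, X[:, 1]])
        labels = np.repeat(["a", "b"], 6)
        with pytest.raises(SingularMatrixError, match="x[12]"):
            scatter_matrices(X, labels, variables=["x0", "x1", "x2"])

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            scatter_matrices(TOY_X, np.array(["a", "a", "a", "b"]))


class TestFitCda:
    def test_single_variable_matches_point_biserial(self):
        """With one variable and two groups the canonical correlation is the
        Pearson correlation with the group indicator (closed form)."""
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array(["a", "a", "b", "b"])
        model = fit_cda(x, labels)
        expected_rho = abs(np.corrcoef(x[:, 0], [0, 0, 1, 1])[0, 1])
        assert model.n_roots == 1
        assert model.canonical_correlations[0] == pytest.approx(expected_rho)
        # B/W = 100/1 for this toy
        assert model.eigenvalues[0] == pytest.approx(100.0)

    def test_null_groups_have_tiny_eigenvalues(self, rng):
        X = rng.normal(size=(60, 3))
        labels = np.repeat(["a", "b", "c"], 20)
        model = fit_cda(X, labels)
        assert model.n_roots == 2
        assert model.eigenvalues.max() < 0.5

    def test_rho_eigenvalue_relation_and_ordering(self, summaries, table3):
        coef, _ = table3
        profiles, _ = simulate_cohort(
            SimulationConfig(groups=summaries, n_per_group=15, seed=3)
        )
        frame = profiles_to_frame(profiles)
        model = fit_cda(frame[coef.index], frame["origin"].to_numpy())
        lam = model.eigenvalues
        assert np.all(np.diff(lam) <= 0) and np.all(lam >= 0)
        np.testing.assert_allclose(
            model.canonical_correlations, np.sqrt(lam / (1 + lam))
        )
        np.testing.assert_allclose(
            model.cumulative_proportion, np.cumsum(lam) / lam.sum()
        )
        assert model.cumulative_proportion[-1] == pytest.approx(1.0)

    def test_three_groups_give_exactly_two_roots(self, summaries, table3):
        coef, _ = table3
        profiles, _ = simulate_cohort(
            SimulationConfig(groups=summaries, n_per_group=15, seed=1)
        )
        frame = profiles_to_frame(profiles)
        model = fit_cda(frame[coef.index], frame["origin"].to_numpy())
        assert model.n_roots == 2
        _, W, B = scatter_matrices(frame[coef.index], frame["origin"].to_numpy())
        assert model.eigenvalues.sum() == pytest.approx(np.trace(np.linalg.solve(W, B)))

    def test_variates_have_unit_pooled_within_variance(self, rng):
        X = rng.normal(size=(30, 4)) + np.repeat([[0], [2], [5]], 10, axis=0)
        labels = np.repeat(["a", "b", "c"], 10)
        model = fit_cda(X, labels)
        A = model.raw_coefficients.to_numpy()
        _, W, _ = scatter_matrices(X, labels)
        np.testing.assert_allclose(A.T @ (W / (30 - 3)) @ A, np.eye(2), atol=1e-8)

    def test_canonical_correlations_affine_invariant(self, rng):
        X = rng.normal(size=(36, 5)) + np.repeat([[0], [1], [3]], 12, axis=0)
        labels = np.repeat(["a", "b", "c"], 12)
        base = fit_cda(X, labels)
        scales = rng.uniform(0.1, 10.0, size=5)
        shifts = rng.normal(scale=50.0, size=5)
        rescaled = fit_cda(X * scales + shifts, labels)
        np.testing.assert_allclose(
            base.canonical_correlations, rescaled.canonical_correlations, atol=1e-9
        )

    def test_sign_convention(self, summaries, table3):
        coef, _ = table3
        profiles, _ = simulate_cohort(
            SimulationConfig(groups=summaries, n_per_group=15, seed=5)
        )
        frame = profiles_to_frame(profiles)
        model = fit_cda(frame[coef.index], frame["origin"].to_numpy())
        std = model.standardized_coefficients.to_numpy()
        for r in range(std.shape[1]):
            assert std[np.argmax(np.abs(std[:, r])), r] > 0

    def test_too_many_variables_rejected(self, rng):
        X = rng.normal(size=(8, 7))
        labels = np.repeat(["a", "b"], 4)
        with pytest.raises(ValueError, match="p <= n - g"):
            fit_cda(X, labels)


class TestClassify:
    def _model(self, rng):
        X = np.vstack([
            rng.normal([0.0, 0.0], 1.0, size=(10, 2)),
            rng.normal([6.0, 0.0], 1.0, size=(10, 2)),
        ])
        labels = np.repeat(["a", "b"], 10)
        return fit_cda(X, labels), X, labels

    def test_group_mean_classifies_to_its_group(self, rng):
        model, _, _ = self._model(rng)
        for grp in model.groups:
            x = model.group_means.loc[grp]
            winner, post = classify(model, x.to_dict())
            assert winner == grp
            assert post[grp] > 1.0 / len(model.groups)
            assert sum(post.values()) == pytest.approx(1.0)

    def test_equidistant_point_has_equal_posteriors(self, rng):
        model, _, _ = self._model(rng)
        mid = model.group_means.mean(axis=0)
        _, post = classify(model, mid.to_dict())
        assert post["a"] == pytest.approx(post["b"], abs=1e-9)

    def test_boundary_matches_hand_fisher_rule(self, rng):
        """Predictions agree with w = Σ⁻¹(μa − μb) thresholded at the
        midpoint, the classical two-group linear rule."""
        model, X, labels = self._model(rng)
        mu = model.group_means.to_numpy()
        sigma_inv = np.linalg.inv(model.pooled_within_cov.to_numpy())
        w = sigma_inv @ (mu[0] - mu[1])
        threshold = w @ (mu[0] + mu[1]) / 2.0
        fisher = np.where(X @ w > threshold, "a", "b")
        assert classify_batch(model, X) == fisher.tolist()

    def test_missing_variable_named(self, rng):
        model, _, _ = self._model(rng)
        with pytest.raises(KeyError, match="x1"):
            classify(model, {"x0": 0.0})

    def test_agrees_with_sklearn_lda(self, summaries, table3):
        """Independent oracle: scikit-learn's pooled-covariance LDA assigns
        the same class to every fish of a synthetic cohort."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        coef, _ = table3
        profiles, _ = simulate_cohort(
            SimulationConfig(groups=summaries, n_per_group=15, seed=8)
        )
        frame = profiles_to_frame(profiles)
        X = frame[coef.index].to_numpy()
        y = frame["origin"].to_numpy()
        model = fit_cda(frame[coef.index], y)
        lda = LinearDiscriminantAnalysis(priors=np.full(3, 1 / 3)).fit(X, y)
        assert classify_batch(model, X) == lda.predict(X).tolist()


class TestStepwise:
    def test_perfect_separator_enters_first(self, rng):
        n = 30
        labels = np.repeat(["a", "b", "c"], 10)
        X = rng.normal(size=(n, 5))
        X[:, 2] += np.repeat([0.0, 20.0, 40.0], 10)  # dominant variable
        names = [f"v{j}" for j in range(5)]
        selected = stepwise_select(pd.DataFrame(X, columns=names), labels)
        assert selected[0] == "v2"

    def test_strong_discriminators_recur_across_cohorts(self, summaries):
        """Over 50 fixed-seed cohorts (all 25 candidates), EPA is selected
        nearly always; C14:0, C16:0 and C20:1 cis-13 — the acids whose
        group means differ most relative to their SDs — enter in most."""
        from collections import Counter

        freq: Counter = Counter()
        for seed in range(50):
            profiles, _ = simulate_cohort(
                SimulationConfig(groups=summaries, n_per_group=15, seed=seed)
            )
            frame = profiles_to_frame(profiles)
            freq.update(
                stepwise_select(
                    frame.drop(columns=["sample_id", "origin"]),
                    frame["origin"].to_numpy(),
                )
            )
        assert freq["C20:5 n-3"] >= 45
        for fa in ("C14:0", "C16:0", "C20:1 cis-13"):
            assert freq[fa] >= 25

    def test_wilks_lambda_empty_set_is_one(self):
        assert wilks_lambda(np.empty((4, 0)), TOY_LABELS) == 1.0


class TestLeaveOneOut:
    def test_matches_bruteforce_refit_oracle(self, rng):
        """Explicit per-fold refit written from scratch reproduces the
        confusion matrix on a 12-sample toy."""
        X = np.vstack([
            rng.normal([0, 0], 1.5, size=(4, 2)),
            rng.normal([3, 0], 1.5, size=(4, 2)),
            rng.normal([0, 3], 1.5, size=(4, 2)),
        ])
        labels = np.repeat(["a", "b", "c"], 4)
        cm = loo_crossvalidate(X, labels)

        groups = ["a", "b", "c"]
        counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
        for i in range(12):
            keep = np.arange(12) != i
            Xt, yt = X[keep], labels[keep]
            means = {g: Xt[yt == g].mean(axis=0) for g in groups}
            pooled = sum(
                (Xt[yt == g] - means[g]).T @ (Xt[yt == g] - means[g]) for g in groups
            ) / (11 - 3)
            inv = np.linalg.inv(pooled)
            scores = {
                g: X[i] @ inv @ means[g] - 0.5 * means[g] @ inv @ means[g]
                for g in groups
            }
            pred = max(groups, key=lambda g: scores[g])
            counts.loc[labels[i], pred] += 1
        pd.testing.assert_frame_equal(cm.counts, counts)

    def test_null_cohort_accuracy_near_chance(self, rng):
        X = rng.normal(size=(60, 3))
        labels = np.repeat(["a", "b", "c"], 20)
        cm = loo_crossvalidate(X, labels)
        assert cm.accuracy < 60.0  # chance is 33%

    def test_loo_not_better_than_resubstitution_on_null(self, rng):
        """Averaged over 50 null cohorts, honest (LOO) accuracy does not
        exceed the optimistic resubstitution accuracy."""
        loo_acc, resub_acc = [], []
        for _ in range(50):
            X = rng.normal(size=(24, 3))
            labels = np.repeat(["a", "b", "c"], 8)
            loo_acc.append(loo_crossvalidate(X, labels).accuracy)
            resub_acc.append(resubstitution(X, labels).accuracy)
        assert np.mean(loo_acc) <= np.mean(resub_acc)

    def test_row_sums_and_accuracy_definition(self, summaries, table3):
        coef, _ = table3
        profiles, _ = simulate_cohort(
            SimulationConfig(groups=summaries, n_per_group=15, seed=4)
        )
        frame = profiles_to_frame(profiles)
        cm = loo_crossvalidate(frame[coef.index], frame["origin"].to_numpy())
        assert cm.counts.sum(axis=1).tolist() == [15, 15, 15]
        assert cm.accuracy == pytest.approx(
            100.0 * np.trace(cm.counts.to_numpy()) / 45.0
        )

    def test_groups_smaller_than_three_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match=">= 3"):
            loo_crossvalidate(X, np.array(["a", "a", "b", "b"]))


def test_model_json_roundtrip(tmp_path, summaries, table3):
    import json

    coef, _ = table3
    profiles, _ = simulate_cohort(
        SimulationConfig(groups=summaries, n_per_group=15, seed=6)
    )
    frame = profiles_to_frame(profiles)
    model = fit_cda(frame[coef.index], frame["origin"].to_numpy())
    path = tmp_path / "model.json"
    model.save_json(path)
    payload = json.loads(path.read_text())
    assert payload["variables"] == list(coef.index)
    assert len(payload["eigenvalues"]) == 2
    np.testing.assert_allclose(payload["eigenvalues"], model.eigenvalues)
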