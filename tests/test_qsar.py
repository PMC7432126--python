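"""PLS fit and validation-battery tests with independent oracles."""

import numpy as np
import pytest

from paedeg.qsar import (QsarModel, external_r2pred, field_contributions,
                         fit_statistics, loo_q2, pls_fit, predict, y_scramble)


def orthonormal_design(n, p, seed=0):
    """Orthonormal columns that are also mean-centered (orthogonal to 1)."""
    rng = np.random.default_rng(seed)
    M = np.hstack([np.ones((n, 1)), rng.normal(size=(n, p))])
    Q, _ = np.linalg.qr(M)
    return Q[:, 1:p + 1]


class TestPlsFit:
    def test_exact_linear_single_component(self):
        # orthogonal columns: one latent variable suffices for y = 2 x7 + 1
        X = orthonormal_design(20, 10)
        y = 2.0 * X[:, 7] + 1.0
        model = pls_fit(X, y, n_components=1)
        r = y - predict(model, X)
        assert (r ** 2).sum() == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_response_gives_null_coefficients(self):
        X = orthonormal_design(20, 5, seed=1)
        rng = np.random.default_rng(1)
        v = rng.normal(size=20)
        v -= v.mean()                    # centered ...
        y = v - X @ (X.T @ v)            # ... and orthogonal to every column
        model = pls_fit(X, y, n_components=3)
        assert np.abs(model.coef).max() < 1e-10

    def test_full_components_match_least_squares_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = pls_fit(X, y, n_components=5)
        Xc = X - X.mean(0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        assert model.coef == pytest.approx(beta, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        X = np.random.default_rng(3).normal(size=(10, 4))
        with pytest.raises(ValueError, match="variance"):
            pls_fit(X, np.ones(10), 2)
        with pytest.raises(ValueError, match="n_components"):
            pls_fit(X, X[:, 0], 10)

    def test_duplicated_column_pair_leaves_predictions_stable(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=25)
        # with enough components the fit converges to the projection onto
        # the (unchanged) column space, so the duplicate cannot matter
        X_dup = np.hstack([X, X[:, [2]]])
        p1 = predict(pls_fit(X, y, 6), X)
        p2 = predict(pls_fit(X_dup, y, 6), X_dup)
        assert p2 == pytest.approx(p1, abs=1e-6)


class TestLooQ2:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5)
        res = loo_q2(X, y, max_components=5)
        assert res.q2 > 0.999

    def test_pure_noise_has_no_predictivity(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        res = loo_q2(X, y, max_components=5)
        assert res.q2 < 0.2

    def test_press_matches_manual_fold_oracle(self):
        # n=5, full-rank, full components: each fold is an exact OLS problem
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        res = loo_q2(X, y, max_components=2)
        press = 0.0
        for i in range(5):
            mask = np.arange(5) != i
            Xtr, ytr = X[mask], y[mask]
            Xc = Xtr - Xtr.mean(0)
            beta, *_ = np.linalg.lstsq(Xc, ytr - ytr.mean(), rcond=None)
            pred = (X[i] - Xtr.mean(0)) @ beta + ytr.mean()
            press += (y[i] - pred) ** 2
        assert res.q2_by_ncomp[2] == pytest.approx(
            1 - press / ((y - y.mean()) ** 2).sum(), abs=1e-8)

    def test_component_cap_warns_and_clips(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        with pytest.warns(UserWarning, match="clipped"):
            res = loo_q2(X, y, max_components=8)
        assert max(res.q2_by_ncomp) == 3  # n - 2

    def test_q2_never_beats_r2(self):
        rng = np.random.default_rng(9)
        for sigma in (0.0, 0.5, 1.0):
            X = rng.normal(size=(20, 4))
            y = X @ rng.normal(size=4) + sigma * rng.normal(size=20)
            res = loo_q2(X, y, max_components=4)
            model = pls_fit(X, y, res.n_opt)
            stats = fit_statistics(model, X, y)
            assert res.q2 <= stats.r2 + 1e-12

    def test_q2_decreases_with_noise(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 5))
        beta = rng.normal(size=5)
        q2s = []
        for sigma in (0.0, 0.5, 1.0):
            y = X @ beta + sigma * rng.normal(size=30)
            q2s.append(loo_q2(X, y, max_components=5).q2)
        assert q2s[0] > q2s[1] > q2s[2]


class TestFitStatistics:
    def test_perfect_fit(self):
        X = orthonormal_design(12, 3, seed=11)
        y = X @ np.array([1.0, -2.0, 0.5])
        model = pls_fit(X, y, 3)
        stats = fit_statistics(model, X, y)
        assert stats.r2 == pytest.approx(1.0, abs=1e-12)
        assert stats.see == pytest.approx(0.0, abs=1e-8)
        assert stats.f == np.inf

    def test_training_geometry_degrees_of_freedom(self):
        # 13 training compounds with 8 components leave 4 residual dof
        rng = np.random.default_rng(12)
        X = rng.normal(size=(13, 20))
        y = rng.normal(size=13)
        model = pls_fit(X, y, 8)
        stats = fit_statistics(model, X, y)
        resid = y - predict(model, X)
        assert stats.see == pytest.approx(np.sqrt((resid ** 2).sum() / 4))

    def test_r2_matches_residual_oracle(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=15)
        model = pls_fit(X, y, 2)
        stats = fit_statistics(model, X, y)
        ss_res = ((y - predict(model, X)) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert stats.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_undefined_when_no_residual_dof(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        model = pls_fit(X, y, 4)
        with pytest.raises(ValueError, match="undefined"):
            fit_statistics(model, X, y)


class TestExternalR2pred:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        model = pls_fit(X, y, 3)
        Xt = rng.normal(size=(4, 3))
        yt = predict(model, Xt)
        assert external_r2pred(model, Xt, yt, y.mean()) == pytest.approx(1.0)

    def test_mean_predictions_score_zero(self):
        model = QsarModel(n_components=1, x_mean=np.zeros(2), y_mean=0.5,
                          x_sd=np.ones(2), coef=np.zeros(2))
        Xt = np.random.default_rng(16).normal(size=(5, 2))
        yt = np.array([0.1, 0.9, 0.4, 0.6, 0.2])
        assert external_r2pred(model, Xt, yt, 0.5) == pytest.approx(0.0)

    def test_hand_arithmetic_three_compounds(self):
        model = QsarModel(n_components=1, x_mean=np.zeros(1), y_mean=0.0,
                          x_sd=np.ones(1), coef=np.array([1.0]))
        Xt = np.array([[1.0], [2.0], [3.0]])   # predictions 1, 2, 3
        yt = np.array([1.5, 2.0, 2.5])
        sd = (1.5 - 2.0) ** 2 + (2.0 - 2.0) ** 2 + (2.5 - 2.0) ** 2  # 0.5
        press = 0.25 + 0.0 + 0.25
        expected = (sd - press) / sd
        assert external_r2pred(model, Xt, yt, 2.0) == pytest.approx(expected)

    def test_degenerate_test_set(self):
        model = QsarModel(n_components=1, x_mean=np.zeros(1), y_mean=0.0,
                          x_sd=np.ones(1), coef=np.array([1.0]))
        with pytest.raises(ValueError, match="undefined"):
            external_r2pred(model, np.ones((2, 1)), np.array([1.0, 1.0]), 1.0)


@pytest.fixture(scope="module")
def informative():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(16, 4))
    y = X @ rng.normal(size=4) + 0.1 * rng.normal(size=16)
    return X, y


class TestYScramble:
    def test_identity_level_reproduces_unscrambled_q2(self, informative):
        X, y = informative
        res = y_scramble(X, y, n_perm=10, levels=(0.0, 1.0), seed=1,
                         max_components=3)
        assert res.q2_scrambled[:10] == pytest.approx(
            np.full(10, res.q2_unscrambled))

    def test_seed_determinism(self, informative):
        X, y = informative
        a = y_scramble(X, y, n_perm=10, levels=(0.5, 1.0), seed=42,
                       max_components=3)
        b = y_scramble(X, y, n_perm=10, levels=(0.5, 1.0), seed=42,
                       max_components=3)
        assert (a.Q2, a.cSDEP, a.dq2_dr2yy) == (b.Q2, b.cSDEP, b.dq2_dr2yy)

    def test_scrambling_destroys_predictivity(self, informative):
        X, y = informative
        res = y_scramble(X, y, n_perm=10, levels=(1.0,), seed=2,
                         max_components=3)
        assert res.q2_unscrambled - res.q2_scrambled.mean() > 0.3

    def test_minimum_permutations_enforced(self, informative):
        X, y = informative
        with pytest.raises(ValueError, match="n_perm"):
            y_scramble(X, y, n_perm=5)


class TestFieldContributions:
    def _model(self, coef, x_sd, cmap):
        return QsarModel(n_components=1, x_mean=np.zeros(len(coef)),
                         y_mean=0.0, x_sd=np.asarray(x_sd, float),
                         coef=np.asarray(coef, float), column_map=cmap)

    def test_single_block_takes_all(self):
        cmap = [("steric", 0), ("steric", 1), ("electrostatic", 0)]
        model = self._model([0.5, -0.3, 0.0], [1.0, 1.0, 2.0], cmap)
        contrib = field_contributions(model)
        assert contrib["steric"] == pytest.approx(1.0)
        assert contrib["electrostatic"] == pytest.approx(0.0)

    def test_symmetric_blocks_split_evenly(self):
        cmap = [("steric", 0), ("hydrophobic", 0)]
        model = self._model([0.4, -0.4], [1.0, 1.0], cmap)
        contrib = field_contributions(model)
        assert contrib["steric"] == pytest.approx(0.5)
        assert contrib["hydrophobic"] == pytest.approx(0.5)

    def test_matches_accumulation_oracle(self):
        rng = np.random.default_rng(18)
        probes = ("steric", "electrostatic", "hydrophobic", "donor",
                  "acceptor")
        cmap = [(p, j) for p in probes for j in range(4)]
        coef = rng.normal(size=20)
        sd = rng.uniform(0.5, 2.0, 20)
        contrib = field_contributions(self._model(coef, sd, cmap))
        expected = {p: 0.0 for p in probes}
        for (p, _), c, s in zip(cmap, coef, sd):
            expected[p] += abs(c) * s
        total = sum(expected.values())
        for p in probes:
            assert contrib[p] == pytest.approx(expected[p] / total)
        assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-10)
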