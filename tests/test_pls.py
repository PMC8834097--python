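import numpy as np
import pytest

import cytosig as cs
from cytosig.panel import PanelError
from cytosig.pls import PLSError, fit_pls, rotate_to_lv1
from cytosig.preprocess import ZScaledMatrix

from conftest import make_panel


def _zmat(X):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    return ZScaledMatrix(X, np.zeros(p), np.ones(p),
                         [f"A{j}" for j in range(p)], [f"S{i}" for i in range(n)])


def _standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def random_problem(seed, n=10, p=5):
    rng = np.random.default_rng(seed)
    X = _standardize(rng.standard_normal((n, p)))
    y = np.where(rng.random(n) > 0.5, 1.0, -1.0)
    if abs(y.sum()) == n:  # ensure two classes
        y[0] = -y[0]
    return X, y


class TestEncodeGroups:
    def test_case_positive(self):
        y = cs.encode_groups(["CTRL", "MLIV", "MLIV"], case_label="MLIV")
        np.testing.assert_array_equal(y, [-1.0, 1.0, 1.0])

    @pytest.mark.parametrize("labels", [["CTRL"] * 3, ["A", "B", "C"]])
    def test_wrong_group_count_error(self, labels):
        with pytest.raises(PLSError):
            cs.encode_groups(labels, case_label=labels[0])

    def test_unknown_case_error(self):
        with pytest.raises(PLSError, match="case"):
            cs.encode_groups(["A", "B"], case_label="C")


class TestNipals:
    def test_single_predictor_perfect_correlation(self):
        rng = np.random.default_rng(0)
        y = np.where(rng.random(12) > 0.5, 1.0, -1.0)
        X = _standardize(y.reshape(-1, 1).copy())
        model = fit_pls(_zmat(X), y, n_components=1)
        r = np.corrcoef(model.scores_raw[:, 0], y)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_component1_weights_closed_form(self, seed):
        X, y = random_problem(seed)
        model = fit_pls(_zmat(X), y)
        expected = X.T @ (y - y.mean())
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(model.weights[:, 0], expected, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(seed)
        model = fit_pls(_zmat(X), y)
        ref = sklearn.PLSRegression(n_components=2, scale=False).fit(X, y)
        for k in range(2):
            s = np.sign(model.weights[:, k] @ ref.x_weights_[:, k]) or 1.0
            np.testing.assert_allclose(model.weights[:, k], s * ref.x_weights_[:, k], atol=1e-6)
            np.testing.assert_allclose(model.scores_raw[:, k], s * ref.x_scores_[:, k], atol=1e-6)

    def test_raw_scores_orthogonal_and_w1_unit(self):
        X, y = random_problem(3)
        model = fit_pls(_zmat(X), y)
        T = model.scores_raw
        assert abs(T[:, 0] @ T[:, 1]) < 1e-8
        assert np.linalg.norm(model.weights[:, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_zero_cross_covariance_error(self):
        X = _standardize(np.array([[1.0, -1.0], [0.0, 0.0], [-1.0, 1.0], [0.0, 0.0]]))
        y = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal to both columns
        with pytest.raises(PLSError, match="predictive"):
            fit_pls(_zmat(X), y)

    def test_too_many_components_error(self):
        X, y = random_problem(1, n=4, p=2)
        with pytest.raises(PLSError, match="n_components"):
            fit_pls(_zmat(X), y, n_components=4)


def _toy_model(T):
    """A hand-built 2-component model with prescribed raw scores."""
    T = np.asarray(T, dtype=float)
    p = 2
    return cs.PLSModel(
        analyte_names=["A1", "A2"], n_components=2,
        weights=np.eye(p), x_loadings=np.eye(p), y_loadings=np.array([1.0, 0.0]),
        x_rotations=np.eye(p), scores_raw=T,
        x_mean=np.zeros(p), x_sd=np.ones(p), y_mean=0.0,
        y_encoding={"CASE": 1.0, "CTRL": -1.0}, case_label="CASE",
        sample_ids=[f"S{i}" for i in range(T.shape[0])],
    )


class TestRotation:
    def test_identity_when_separation_on_lv1(self):
        T = np.array([[2.0, 0.1], [2.2, -0.1], [-2.0, 0.1], [-2.2, -0.1]])
        model = _toy_model(T)
        rot = rotate_to_lv1(model, groups=["CASE", "CASE", "CTRL", "CTRL"])
        np.testing.assert_allclose(rot.rotation, np.eye(2), atol=1e-10)

    def test_90deg_moves_separation_to_lv1(self):
        T = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, -2.0], [0.0, -2.0]])
        model = _toy_model(T)
        rot = rotate_to_lv1(model, groups=["CASE", "CASE", "CTRL", "CTRL"])
        S = rot.scores
        case_mean = S[:2].mean(axis=0)
        ctrl_mean = S[2:].mean(axis=0)
        assert case_mean[0] - ctrl_mean[0] == pytest.approx(4.0)
        assert case_mean[1] - ctrl_mean[1] == pytest.approx(0.0, abs=1e-10)

    def test_reconstruction_invariant(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        raw = model.scores_raw @ model.weights.T
        rot = model.scores @ model.lv_weights.T
        assert np.abs(raw - rot).max() < 1e-10

    def test_rotation_orthogonal(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        np.testing.assert_allclose(model.rotation.T @ model.rotation, np.eye(2), atol=1e-10)

    def test_case_positive_on_lv1(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        case = human_panel.groups() == "MLIV"
        assert model.scores[case, 0].mean() > model.scores[~case, 0].mean()

    def test_degenerate_rotation_error(self):
        T = np.zeros((4, 2))
        with pytest.raises(PLSError, match="degenerate"):
            rotate_to_lv1(_toy_model(T), groups=["CASE", "CASE", "CTRL", "CTRL"])


class TestModelInvariances:
    def test_label_flip_negates_lv1(self, human_panel):
        m_case = cs.fit_panel(human_panel, "group", case_label="MLIV")
        flipped = human_panel.copy()
        m_ctrl = cs.fit_panel(flipped, "group", case_label="CTRL")
        np.testing.assert_allclose(m_ctrl.scores[:, 0], -m_case.scores[:, 0], atol=1e-8)
        np.testing.assert_allclose(m_ctrl.lv_weights[:, 0], -m_case.lv_weights[:, 0], atol=1e-8)

    def test_column_scale_invariance(self, human_panel):
        scaled = human_panel.copy()
        scaled.concentrations.iloc[:, 3] *= 37.5
        m1 = cs.fit_panel(human_panel, "group", case_label="MLIV")
        m2 = cs.fit_panel(scaled, "group", case_label="MLIV")
        np.testing.assert_allclose(m2.scores, m1.scores, atol=1e-10)
        np.testing.assert_allclose(m2.lv_weights, m1.lv_weights, atol=1e-10)


class TestProject:
    def test_training_panel_reproduces_scores(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        np.testing.assert_allclose(cs.project(model, human_panel), model.scores, atol=1e-10)

    def test_sample_at_column_means_scores_zero(self):
        # last sample is exactly the column mean → z row of zeros → (0, 0)
        rng = np.random.default_rng(0)
        base = 10.0 + rng.random((3, 3))
        values = np.vstack([base, base.mean(axis=0)])
        panel = make_panel(values, ["X", "Y", "X", "Y"])
        model = cs.fit_panel(panel, "group", case_label="X")
        scores = cs.project(model, panel)
        np.testing.assert_allclose(scores[3], [0.0, 0.0], atol=1e-10)

    def test_missing_analyte_error_names_it(self, human_panel):
        model = cs.fit_panel(human_panel, "group", case_label="MLIV")
        smaller = human_panel.subset_analytes(human_panel.analyte_names[1:])
        with pytest.raises(PanelError, match=human_panel.analyte_names[0]):
            cs.project(model, smaller)

    def test_single_analyte_model_weight_unit(self, human_panel):
        sub = human_panel.subset_analytes(human_panel.analyte_names[:1])
        model = cs.fit_panel(sub, "group", case_label="MLIV")
        assert abs(model.lv1_loadings[0]) == pytest.approx(1.0, abs=1e-10)
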