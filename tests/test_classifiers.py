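"""k-NN, dummy coding, kernels and the PUK-kernel SVM."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from rainbowspec.classifiers import (
    KNNClassifier,
    SVMClassifier,
    decode,
    dummy_code,
    gaussian_kernel,
    make_classifier,
    puk_kernel,
)
from rainbowspec.errors import (
    DegenerateInputError,
    InvalidParameterError,
    UnsupportedConfigurationError,
)


class TestDummyCode:
    def test_two_classes(self):
        Y, order = dummy_code(["a", "b", "a"])
        assert order == ["a", "b"]
        np.testing.assert_array_equal(Y, [[1, 0], [0, 1], [1, 0]])

    def test_three_classes_three_columns(self):
        Y, order = dummy_code(["z", "a", "m", "z"])
        assert Y.shape == (4, 3)
        assert order == ["a", "m", "z"]
        np.testing.assert_array_equal(Y.sum(axis=1), 1)

    def test_round_trip(self, rng):
        labels = rng.choice(["x", "y", "z"], 30)
        Y, order = dummy_code(labels)
        assert decode(Y, order).tolist() == labels.tolist()

    def test_single_class(self):
        with pytest.raises(DegenerateInputError):
            dummy_code(["a", "a"])

    def test_tie_breaks_to_first_class(self):
        assert decode(np.array([[0.5, 0.5]]), ["a", "b"])[0] == "a"


class TestKNN:
    def test_query_equals_training_sample(self, binary_toy):
        X, y = binary_toy
        clf = KNNClassifier(k=1).fit(X, y)
        assert clf.predict(X[3][None])[0] == y[3]

    def test_nearest_of_two_classes(self):
        X = np.array([[1.0], [-2.0]])
        y = np.array(["near", "far"], dtype=object)
        assert KNNClassifier(k=1).fit(X, y).predict([[0.0]])[0] == "near"

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.choice(["a", "b", "c"], 20)
        while len(set(y)) < 2:
            y = rng.choice(["a", "b", "c"], 20)
        Q = rng.normal(size=(8, 4))
        clf = KNNClassifier(k=5).fit(X, y)
        got = clf.predict(Q)
        order_cls = sorted(set(y))
        for qi, q in enumerate(Q):
            d = [(np.linalg.norm(q - X[i]), i) for i in range(20)]
            nearest = [i for _, i in sorted(d)[:5]]
            counts = {c: sum(y[i] == c for i in nearest) for c in order_cls}
            best = max(counts.values())
            winner = next(c for c in order_cls if counts[c] == best)
            assert got[qi] == winner

    def test_k_exceeds_n(self):
        with pytest.raises(InvalidParameterError):
            KNNClassifier(k=5).fit(np.zeros((3, 2)), ["a", "b", "a"])

    def test_invalid_k(self):
        with pytest.raises(InvalidParameterError):
            KNNClassifier(k=0)


class TestGaussianKernel:
    def test_unit_diagonal(self, rng):
        A = rng.normal(size=(6, 3))
        K = gaussian_kernel(A, A, sigma=2.0)
        np.testing.assert_allclose(np.diag(K), 1.0)
        np.testing.assert_allclose(K, K.T)
        assert np.all(K > 0) and np.all(K <= 1)

    def test_hand_value(self):
        K = gaussian_kernel([[0.0, 0.0]], [[3.0, 4.0]], sigma=5.0)
        assert K[0, 0] == pytest.approx(np.exp(-0.5))

    def test_large_sigma_limit(self, rng):
        A = rng.normal(size=(4, 3))
        np.testing.assert_allclose(gaussian_kernel(A, A, sigma=1e8), 1.0, atol=1e-10)

    def test_invalid_sigma(self):
        with pytest.raises(InvalidParameterError):
            gaussian_kernel(np.zeros((2, 2)), np.zeros((2, 2)), sigma=0.0)

    def test_scale_invariance(self, rng):
        A = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            gaussian_kernel(A, A, sigma=1.5),
            gaussian_kernel(2 * A, 2 * A, sigma=3.0),
            atol=1e-12,
        )


class TestPukKernel:
    def test_self_similarity_is_one(self, rng):
        A = rng.normal(size=(5, 3))
        np.testing.assert_allclose(np.diag(puk_kernel(A, A)), 1.0)

    def test_monotone_decreasing_in_distance(self):
        x = np.zeros((1, 2))
        near = puk_kernel(x, [[0.5, 0.0]])[0, 0]
        far = puk_kernel(x, [[3.0, 0.0]])[0, 0]
        assert 1 > near > far > 0

    def test_closed_form(self):
        # omega=1: k = 1 / (1 + (2 d)^2) since sqrt(2^1 - 1) = 1, sigma = 1
        d = 0.7
        k = puk_kernel([[0.0]], [[d]], sigma=1.0, omega=1.0)[0, 0]
        assert k == pytest.approx(1.0 / (1.0 + (2 * d) ** 2))

    def test_invalid_params(self):
        with pytest.raises(InvalidParameterError):
            puk_kernel(np.zeros((1, 1)), np.zeros((1, 1)), sigma=-1)
        with pytest.raises(InvalidParameterError):
            puk_kernel(np.zeros((1, 1)), np.zeros((1, 1)), omega=0)


def svm_dual_oracle(X, y_signed, C, kernel):
    """Solve the soft-margin dual with a generic QP solver (SLSQP)."""
    n = len(y_signed)
    K = kernel(X, X)
    Q = np.outer(y_signed, y_signed) * K

    def objective(alpha):
        return 0.5 * alpha @ Q @ alpha - alpha.sum()

    res = minimize(
        objective,
        np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y_signed}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return res.x


class TestSVM:
    def test_puk_self_similarity(self):
        clf = SVMClassifier()
        x = np.ones((1, 4))
        assert clf._gram(x, x)[0, 0] == pytest.approx(1.0)

    def test_separable_toy_perfect_training(self, binary_toy):
        X, y = binary_toy
        clf = SVMClassifier(C=100.0, sigma=5.0).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_dual_matches_qp_oracle(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        C = 10.0
        clf = SVMClassifier(C=C, sigma=2.0).fit(X, y)
        y_signed = np.array([-1.0, -1.0, 1.0, 1.0])
        alpha = svm_dual_oracle(X, y_signed, C, lambda A, B: puk_kernel(A, B, sigma=2.0))
        sv_oracle = set(np.flatnonzero(alpha > 1e-6))
        assert set(clf._svc.support_.tolist()) == sv_oracle
        dual = np.zeros(4)
        dual[clf._svc.support_] = clf._svc.dual_coef_[0]
        # libsvm solves to ~1e-3 by default; the QP oracle is tighter
        np.testing.assert_allclose(dual, alpha * y_signed, atol=5e-3)

    def test_non_binary_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(UnsupportedConfigurationError):
            SVMClassifier().fit(X, ["a", "b", "c"])

    def test_invalid_C(self):
        with pytest.raises(InvalidParameterError):
            SVMClassifier(C=0)


class TestFactory:
    @pytest.mark.parametrize(
        "name,params",
        [
            ("knn", {"k": 3}),
            ("svm", {"C": 2.0, "sigma": 5.0}),
            ("plsda", {"n_lv": 2}),
            ("kplsda", {"n_lv": 2, "sigma": 10.0}),
            ("lwplsc", {"n_lv": 2, "phi": 5.0}),
        ],
    )
    def test_predictions_stay_in_training_label_set(self, name, params, binary_toy, rng):
        X, y = binary_toy
        clf = make_classifier(name, params).fit(X, y)
        Q = rng.normal(size=(10, X.shape[1]))
        assert set(clf.predict(Q).tolist()) <= set(y.tolist())

    def test_determinism(self, binary_toy, rng):
        X, y = binary_toy
        Q = rng.normal(size=(5, X.shape[1]))
        for name, params in [("knn", {"k": 3}), ("plsda", {"n_lv": 2}),
                             ("kplsda", {"n_lv": 2, "sigma": 10.0}),
                             ("lwplsc", {"n_lv": 2, "phi": 5.0})]:
            a = make_classifier(name, params).fit(X, y).predict(Q)
            b = make_classifier(name, params).fit(X, y).predict(Q)
            assert a.tolist() == b.tolist()

    def test_unknown_algorithm(self):
        with pytest.raises(KeyError):
            make_classifier("forest")
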