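"""Scikit-learn estimators wrapping the swap-test classification pipeline.

:class:`SwapTestClassifier` runs the full quantum route per test sample:
amplitude-encode the test, form the data-encoded joint state with both
class vectors entangled to the class-index qubit, apply the n-qubit swap
test on the statevector simulator, and read the class off the (s, m)
measurement statistics (exact marginals, or a seeded multinomial shot
sample).  :class:`InnerProductClassifier` is its classical twin, scoring
with the exact integer match counts; in exact mode the two agree on
every input, which is the package's central cross-check.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import features as fs
from .circuits import QubitRoleMap, joint_initial_state, swap_test
from .circuits import QuantumCircuit
from .features import (
    SIP,
    AMBIGUOUS,
    MetricConfig,
    BinarySample,
    ValidityError,
)
from .simulator import (
    exact_result,
    inner_product_from_rho,
    mpr,
    run,
    sample as sample_counts,
)


def _validate_binary(X, n_features: int | None = None) -> np.ndarray:
    X = check_array(X, dtype=np.int64)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("X must contain only 0/1 CNV presence calls")
    if n_features is not None and X.shape[1] != n_features:
        raise fs.DimensionError(
            f"X has {X.shape[1]} features; the classifier was fitted with {n_features}"
        )
    return X


class _ClassVectorFitMixin:
    """Shared fit-time bookkeeping: class vectors from a labelled matrix."""

    def _fit_class_data(self, X, y):
        X, y = check_X_y(X, y, dtype=np.int64)
        X = _validate_binary(X)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValidityError(
                f"exactly two classes are required, got {self.classes_.tolist()}"
            )
        counts = [int((y == c).sum()) for c in self.classes_]
        if counts[0] != counts[1]:
            raise ValidityError(
                "equal numbers of training samples per class are required "
                f"(got {counts}); the metric-equivalence guarantees fix W across classes"
            )
        self.n_features_in_ = X.shape[1]
        self.class_samples_ = tuple(
            tuple(
                BinarySample(f"train_{k}_{i}", row, label=k)
                for i, row in enumerate(X[y == c])
            )
            for k, c in enumerate(self.classes_)
        )
        return X, y


class SwapTestClassifier(_ClassVectorFitMixin, ClassifierMixin, BaseEstimator):
    """Binary CNV classifier executed as a simulated swap-test circuit.

    Parameters
    ----------
    metric : {"sip", "aip"}
        Encoding of CNV presence/absence: symmetric (+1/-1 coefficients,
        Hamming-equivalent) or active (1/0 coefficients, dot-product).
    sign_mode : {"matches_dominant", "mismatches_dominant"}
        Only |inner product| is measurable under SIP; the caller declares
        which regime the data is in.  Ignored for AIP.
    shots : int or None
        ``None`` classifies from exact measurement probabilities;
        otherwise each prediction samples this many shots.
    random_state : int or None
        Seed for shot sampling.
    norm_ratio_warn : float
        Warn at fit time when the class raw-normalization ratio deviates
        from 1 by more than this.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels, index 0 and 1 in the circuit's class-index qubit.
    class_vectors_ : tuple of ClassVector
        Pre-summed, normalized training states per class.
    n_qubits_ : int
        Size of the simulated register (2n + 2).
    eta_ratio_ : float
        Raw-normalization ratio eta_1 / eta_0 of the fitted classes.
    """

    def __init__(
        self,
        metric: str = SIP,
        sign_mode: str = "matches_dominant",
        shots: int | None = None,
        random_state: int | None = None,
        norm_ratio_warn: float = 0.1,
    ):
        self.metric = metric
        self.sign_mode = sign_mode
        self.shots = shots
        self.random_state = random_state
        self.norm_ratio_warn = norm_ratio_warn

    def _config(self) -> MetricConfig:
        return MetricConfig(
            metric=self.metric,
            sign_mode=self.sign_mode,
            shots=self.shots,
            seed=self.random_state or 0,
            norm_ratio_warn=self.norm_ratio_warn,
        )

    def fit(self, X, y):
        config = self._config()  # validates metric/sign_mode/shots eagerly
        X, y = self._fit_class_data(X, y)
        self.class_vectors_ = tuple(
            fs.build_class_vector(samples, k, metric=self.metric)
            for k, samples in enumerate(self.class_samples_)
        )
        report = fs.scaling_factor_check(
            self.class_vectors_[0], self.class_vectors_[1], tol=config.norm_ratio_warn
        )
        self.eta_ratio_ = report.ratio
        if report.flagged:
            warnings.warn(
                f"class raw-normalization ratio {report.ratio:.3f} deviates from 1 "
                "by more than the configured tolerance; inner-product ranking may "
                "not reflect the unnormalized scores",
                UserWarning,
                stacklevel=2,
            )
        self.n_qubits_ = 2 * self.class_vectors_[0].n_qubits + 2
        return self

    def _measure_sample(self, bits: np.ndarray, seed: int | None):
        """Run the swap-test circuit for one test sample."""
        test = fs.sample_to_amplitudes(
            BinarySample("test", bits), metric=self.metric
        )
        cv0, cv1 = self.class_vectors_
        n = cv0.n_qubits
        roles = QubitRoleMap.default(n)
        psi0 = joint_initial_state(
            (cv0.amplitudes, cv1.amplitudes), test.amplitudes, roles
        )
        circ = QuantumCircuit(
            num_qubits=roles.num_qubits, measured_qubits=(roles.s, roles.m)
        )
        circ.extend(swap_test(list(zip(roles.d, roles.t)), roles.s))
        state = run(circ, initial_state=psi0)
        if self.shots is None:
            return exact_result(state, roles)
        return sample_counts(state, roles, shots=self.shots, seed=seed)

    def measure(self, X):
        """Per-sample measurement diagnostics.

        Returns a list of dicts with ``rho_10``, ``rho_11``, ``mpr``,
        recovered ``|A_0|``/``|A_1|``, classifiability ``F`` and the
        ``prediction`` (a fitted class label, or :data:`fs.AMBIGUOUS`).
        """
        check_is_fitted(self, "class_vectors_")
        X = _validate_binary(X, self.n_features_in_)
        config = self._config()
        seeds = self._shot_seeds(X.shape[0])
        out = []
        for i, row in enumerate(X):
            result = self._measure_sample(row, seeds[i])
            a0 = inner_product_from_rho(result.rho_10, M=2, tol=1.0)
            a1 = inner_product_from_rho(result.rho_11, M=2, tol=1.0)
            verdict = fs.classify(a0, a1, config)
            out.append(
                {
                    "rho_10": result.rho_10,
                    "rho_11": result.rho_11,
                    "mpr": mpr(result),
                    "A0": a0,
                    "A1": a1,
                    "F": fs.classifiability(a0, a1),
                    "prediction": verdict
                    if verdict == AMBIGUOUS
                    else self.classes_[verdict],
                }
            )
        return out

    def _shot_seeds(self, n: int) -> list[int | None]:
        if self.shots is None:
            return [None] * n
        root = np.random.default_rng(self.random_state)
        return [int(s) for s in root.integers(0, 2**31 - 1, size=n)]

    def decision_function(self, X):
        """Signed margin: positive favors ``classes_[1]``.

        Computed from the recovered |A_k| and the declared sign regime;
        magnitude equals the classifiability F of the sample.
        """
        check_is_fitted(self, "class_vectors_")
        X = _validate_binary(X, self.n_features_in_)
        config = self._config()
        seeds = self._shot_seeds(X.shape[0])
        margins = np.empty(X.shape[0])
        flip = -1.0 if (self.metric == SIP and self.sign_mode == "mismatches_dominant") else 1.0
        for i, row in enumerate(X):
            result = self._measure_sample(row, seeds[i])
            a0 = inner_product_from_rho(result.rho_10, M=2, tol=1.0)
            a1 = inner_product_from_rho(result.rho_11, M=2, tol=1.0)
            margins[i] = flip * (a1 - a0)
        return margins

    def predict(self, X):
        margins = self.decision_function(X)
        # exact ties fall to the first class; measure() reports them as ambiguous
        return self.classes_[(margins > 0).astype(int)]


class InnerProductClassifier(_ClassVectorFitMixin, ClassifierMixin, BaseEstimator):
    """Classical counterpart of the swap-test classifier.

    Computes the normalized inner products A_k = <t|d^k> by a direct dot
    product in feature space — no statevector, no swap test — and applies
    the same decision rule.  In exact mode it agrees with
    :class:`SwapTestClassifier` on every input.  The underlying integer
    match scores (sigma / sigma_11) are exposed via
    :meth:`integer_scores`.
    """

    def __init__(self, metric: str = SIP, sign_mode: str = "matches_dominant"):
        self.metric = metric
        self.sign_mode = sign_mode

    def fit(self, X, y):
        MetricConfig(metric=self.metric, sign_mode=self.sign_mode)
        self._fit_class_data(X, y)
        self.class_vectors_ = tuple(
            fs.build_class_vector(samples, k, metric=self.metric)
            for k, samples in enumerate(self.class_samples_)
        )
        return self

    def inner_products(self, X) -> np.ndarray:
        """(n_samples, 2) array of signed inner products A_0, A_1."""
        check_is_fitted(self, "class_vectors_")
        X = _validate_binary(X, self.n_features_in_)
        out = np.empty((X.shape[0], 2))
        for i, row in enumerate(X):
            test = fs.sample_to_amplitudes(BinarySample("test", row), metric=self.metric)
            out[i] = [fs.feature_inner_product(test, cv) for cv in self.class_vectors_]
        return out

    def integer_scores(self, X) -> np.ndarray:
        """(n_samples, 2) array of exact integer scores sigma / sigma_11."""
        check_is_fitted(self, "class_samples_")
        X = _validate_binary(X, self.n_features_in_)
        score = fs.sip_score if self.metric == SIP else fs.aip_score
        return np.array(
            [[score(row, cls) for cls in self.class_samples_] for row in X]
        )

    def decision_function(self, X):
        a = np.abs(self.inner_products(X))
        flip = -1.0 if (self.metric == SIP and self.sign_mode == "mismatches_dominant") else 1.0
        return flip * (a[:, 1] - a[:, 0])

    def predict(self, X):
        margins = self.decision_function(X)
        return self.classes_[(margins > 0).astype(int)]
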