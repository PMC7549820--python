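"""Sparse optimal classifiers via double-greedy cost minimisation.

The classifier input is x = Omega . b(z): a few rows of sparse linear
combinations of dictionary entries. The weight matrix Omega is grown
greedily — outer loop over input dimensions, inner loop over support
components — with each candidate support's weights tuned by an
evolutionary strategy (CMA-ES) against a confidence-weighted,
class-balanced misclassification cost evaluated through randomized
stratified cross-validation of an LDA base classifier.

Cost conventions (binary labels in {-1, +1}): a perfectly confident,
all-correct classifier scores -2; an all-wrong one scores 1 + alpha,
where alpha >= 1 penalises false positives (a risky compound called
safe is the expensive error). The k-class extension scores -k at best
and sum(alpha_j) at worst. A regularization term beta * sum_k
(1 - ||omega_k||^2)^2 pins the row norms near 1, breaking the scaling
invariance of linear classification (the penalty's printed linear form
is retained as ``penalty_mode='as_printed'``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .optimize import cma_es, coordinate_search
from .validation import randomized_kfold

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- cost terms

@dataclass(frozen=True)
class CostParams:
    """Cost-function parameters.

    alpha: false-positive penalty (binary, >= 1). alphas: per-class
    penalty weights (multiclass, all > 0; equal weights = 1 when None).
    beta: regularization strength. penalty_mode: 'squared' (default,
    bounded below) or 'as_printed' (linear in the norm deficit).
    """

    alpha: float = 2.0
    alphas: tuple | None = None
    beta: float = 0.1
    penalty_mode: str = "squared"

    def __post_init__(self):
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.alphas is not None and any(a <= 0 for a in self.alphas):
            raise ValueError("all alphas must be positive")
        if self.penalty_mode not in ("squared", "as_printed"):
            raise ValueError(f"bad penalty mode {self.penalty_mode!r}")


@dataclass
class ClassifierOutput:
    """Predictions with the classifier's confidence for each of them."""

    predicted: np.ndarray
    confidence: np.ndarray        # posterior of the predicted label
    classes: np.ndarray

    def __post_init__(self):
        k = self.classes.size
        if np.any(self.confidence < 1.0 / k - 1e-9):
            raise ValueError("confidence below 1/n_classes")


def cost_binary(labels, output: ClassifierOutput, alpha: float = 2.0) -> float:
    """Confidence-weighted class-balanced binary cost in [-2, 1 + alpha].

    Labels in {-1, +1}; the positive class is the risk/blocker class
    and alpha >= 1 penalises predicting -1 for a true +1.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    l = np.asarray(labels)
    lh = np.asarray(output.predicted)
    p = np.asarray(output.confidence, dtype=float)
    if not set(np.unique(l)) <= {-1, 1}:
        raise ValueError("binary labels must be in {-1, +1}")
    ns = l.size
    n1 = int(np.sum(l == 1))
    nm1 = ns - n1
    if n1 == 0 or nm1 == 0:
        raise ValueError("both classes must be present")
    term = np.zeros(ns)
    term += (ns / n1) * ((lh == 1) & (l == 1))
    term += (ns / nm1) * ((lh == -1) & (l == -1))
    term -= alpha * (ns / n1) * ((lh == -1) & (l == 1))
    term -= (ns / nm1) * ((lh == 1) & (l == -1))
    return float(-np.sum(p * term) / ns)


def cost_multiclass(labels, output: ClassifierOutput,
                    alphas=None) -> float:
    """k-class extension of the cost, in [-k, sum(alpha_j)]."""
    l = np.asarray(labels)
    lh = np.asarray(output.predicted)
    p = np.asarray(output.confidence, dtype=float)
    classes = np.asarray(output.classes)
    k = classes.size
    if alphas is None:
        alphas = np.ones(k)
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size != k:
        raise ValueError("need one alpha per class")
    ns = l.size
    total = 0.0
    for j, cj in enumerate(classes):
        nj = int(np.sum(l == cj))
        if nj == 0:
            raise ValueError(f"class {cj} absent")
        correct = (l == cj) & (lh == cj)
        wrong = (l == cj) & (lh != cj)
        total += (ns / nj) * np.sum(p[correct])
        total -= (ns / nj) * alphas[j] * np.sum(p[wrong])
    return float(-total / ns)


def regularization_penalty(omega, beta: float,
                           mode: str = "squared") -> float:
    """Row-norm penalty breaking the scaling invariance of Omega."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    deficit = 1.0 - np.sum(omega ** 2, axis=1)
    if mode == "as_printed":
        return float(beta * np.sum(deficit))
    if mode == "squared":
        return float(beta * np.sum(deficit ** 2))
    raise ValueError(f"bad penalty mode {mode!r}")


# ----------------------------------------------------------- LDA wrapper

def lda_classify(M_train, l_train, M_eval) -> ClassifierOutput:
    """Shared-covariance linear discriminant prediction with confidences.

    A singular pooled covariance falls back to a ridge-stabilised
    (shrinkage lsqr) fit with a logged warning rather than crashing.
    """
    M_train = np.atleast_2d(np.asarray(M_train, dtype=float))
    M_eval = np.atleast_2d(np.asarray(M_eval, dtype=float))
    if M_train.shape[0] == 1:
        M_train = M_train.T
    if M_eval.shape[0] == 1 and M_train.shape[1] == 1:
        M_eval = M_eval.T
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", UserWarning)
            clf = LinearDiscriminantAnalysis()
            clf.fit(M_train, l_train)
    except (np.linalg.LinAlgError, UserWarning, FloatingPointError,
            IndexError, ValueError, ArithmeticError):
        logger.warning("singular pooled covariance; ridge-stabilised LDA fit")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.1)
        clf.fit(M_train, l_train)
    proba = clf.predict_proba(M_eval)
    idx = np.argmax(proba, axis=1)
    return ClassifierOutput(predicted=clf.classes_[idx],
                            confidence=proba[np.arange(len(idx)), idx],
                            classes=clf.classes_)


# ------------------------------------------------------- weight evaluation

@dataclass(frozen=True)
class CvConfig:
    """Cross-validation used to score candidate weight matrices."""

    n_fold: int = 2
    n_kfold: int = 10      # raise to ~500 for final reporting
    seed: int = 0


def classifier_input(features, omega) -> np.ndarray:
    """Input matrix M = F_s . Omega^T (restricted to active rows)."""
    F = features.values if hasattr(features, "values") else np.asarray(features)
    F = np.asarray(F, dtype=float)
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    if F.shape[1] != omega.shape[1]:
        raise ValueError(
            f"feature count {F.shape[1]} != weight columns {omega.shape[1]}")
    return F @ omega.T


def evaluate_weights(features, labels, omega, cost_params: CostParams,
                     cv: CvConfig | None = None):
    """Cross-validated cost of a weight matrix.

    Returns (s_ns, s_reg, ClassifierOutput) where the predictions come
    from the averaged cross-validated probabilities.
    """
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    if not np.any(omega != 0):
        raise ValueError("omega has no nonzero entry")
    cv = cv or CvConfig()
    M = classifier_input(features, omega)
    res = randomized_kfold(M, labels, cv.n_fold, cv.n_kfold, seed=cv.seed)
    out = ClassifierOutput(res.predicted, res.confidence, res.classes)
    if res.classes.size == 2 and set(res.classes) == {-1, 1}:
        s = cost_binary(labels, out, cost_params.alpha)
    else:
        s = cost_multiclass(labels, out, cost_params.alphas)
    s_reg = s + regularization_penalty(omega, cost_params.beta,
                                       cost_params.penalty_mode)
    return s, s_reg, out


def stop_check(cost_history, tol: float) -> bool:
    """Continue while the relative cost change stays >= tol.

    The first recorded cost always continues; a zero previous cost
    falls back to the absolute change.
    """
    hist = list(cost_history)
    if len(hist) < 2:
        return True
    s_old, s_new = hist[-2], hist[-1]
    denom = abs(s_old)
    change = abs(s_new - s_old)
    if denom == 0:
        return change >= tol
    return change / denom >= tol


# ------------------------------------------------------------ greedy search

@dataclass
class GreedyStep:
    dimension: int
    component: int
    entry: int
    weights: np.ndarray
    cost: float
    cost_reg: float


@dataclass
class GreedyTrace:
    steps: list = field(default_factory=list)
    stop_reasons: list = field(default_factory=list)

    def costs(self, dimension: int | None = None) -> list:
        return [s.cost_reg for s in self.steps
                if dimension is None or s.dimension == dimension]


class GreedySparseLDA(BaseEstimator, ClassifierMixin):
    """Greedy sparse-input LDA classifier (scikit-learn estimator).

    fit() grows a sparse weight matrix ``omega_`` by double-greedy
    search: outer loop over input dimensions (up to ``d_max``), inner
    loop over support components per dimension (up to ``n_comp_max``);
    every candidate entry's weights are tuned by CMA-ES against the
    cross-validated confidence-weighted cost; growth stops when the
    relative cost change drops below ``tol`` (5% by default).

    Parameters
    ----------
    alpha, alphas, beta, penalty_mode : cost parameters (see CostParams).
    d_max, n_comp_max : search budget per direction.
    tol : relative cost-variation stop criterion.
    optimizer : 'cmaes' or 'coordinate' (deterministic fallback).
    max_evals, sigma0, weight_bound : inner-optimizer budget and box.
    cv_n_fold, cv_n_kfold : cross-validation inside the search loop.
    random_state : master seed for CMA-ES and fold shuffling.

    Attributes
    ----------
    omega_ : (d, n_features) sparse weight matrix.
    trace_ : GreedyTrace with per-step costs and stop reasons.
    selected_ : list of per-dimension support index lists.
    lda_ : final LDA refit on the training inputs.
    classes_ : class labels.
    feature_names_in_ : column names when fitted on a DataFrame.
    """

    def __init__(self, alpha: float = 2.0, alphas=None, beta: float = 0.1,
                 penalty_mode: str = "squared", d_max: int = 2,
                 n_comp_max: int = 3, tol: float = 0.05,
                 optimizer: str = "cmaes", max_evals: int = 200,
                 sigma0: float = 0.3, weight_bound: float = 5.0,
                 cv_n_fold: int = 2, cv_n_kfold: int = 10,
                 random_state: int = 0):
        self.alpha = alpha
        self.alphas = alphas
        self.beta = beta
        self.penalty_mode = penalty_mode
        self.d_max = d_max
        self.n_comp_max = n_comp_max
        self.tol = tol
        self.optimizer = optimizer
        self.max_evals = max_evals
        self.sigma0 = sigma0
        self.weight_bound = weight_bound
        self.cv_n_fold = cv_n_fold
        self.cv_n_kfold = cv_n_kfold
        self.random_state = random_state

    # -- internals -------------------------------------------------------

    def _cost_params(self) -> CostParams:
        return CostParams(alpha=self.alpha, alphas=self.alphas,
                          beta=self.beta, penalty_mode=self.penalty_mode)

    def _score_omega(self, F, y, omega, seed) -> float:
        _, s_reg, _ = evaluate_weights(
            F, y, omega, self._cost_params(),
            CvConfig(self.cv_n_fold, self.cv_n_kfold, seed))
        return s_reg

    def _optimize_support(self, F, y, fixed_rows, support, w0, seed):
        """Tune the weights on ``support`` for the current dimension."""
        d_fixed = len(fixed_rows)
        nb = F.shape[1]

        def build(w):
            omega = np.zeros((d_fixed + 1, nb))
            for r, row in enumerate(fixed_rows):
                omega[r] = row
            omega[d_fixed, support] = w
            return omega

        def objective(w):
            return self._score_omega(F, y, build(w), seed)

        if self.optimizer == "cmaes":
            res = cma_es(objective, w0, sigma0=self.sigma0,
                         bounds=(-self.weight_bound, self.weight_bound),
                         max_evals=self.max_evals, rng=seed)
        elif self.optimizer == "coordinate":
            res = coordinate_search(objective, w0,
                                    bounds=(-self.weight_bound,
                                            self.weight_bound),
                                    max_evals=self.max_evals)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        return res.x, res.fun

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            F = X.to_numpy(dtype=float)
        else:
            F = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if F.ndim != 2 or F.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if F.shape[1] < 2:
            raise ValueError("need at least two dictionary entries")
        if not np.isfinite(F).all():
            raise ValueError("X contains non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        self.classes_ = classes

        nb = F.shape[1]
        rng = np.random.default_rng(self.random_state)
        trace = GreedyTrace()
        fixed_rows: list[np.ndarray] = []
        dim_costs: list[float] = []

        for dim in range(self.d_max):
            v_pos = list(range(nb))
            p_save: list[int] = []
            w_save = np.zeros(0)
            comp_costs: list[float] = []
            for comp in range(self.n_comp_max):
                best = None
                for pos in v_pos:
                    support = p_save + [pos]
                    w0 = np.append(w_save, 1.0)
                    seed = int(rng.integers(0, 2 ** 31 - 1))
                    w_opt, cost = self._optimize_support(
                        F, y, fixed_rows, support, w0, seed)
                    if best is None or cost < best[2] - 1e-15:
                        best = (pos, w_opt, cost)
                pos, w_opt, cost = best
                if comp_costs and (cost >= comp_costs[-1]
                                   or not stop_check(comp_costs + [cost],
                                                     self.tol)):
                    # candidate entry adds less than the tolerated
                    # variation (or worsens the cost): reject and stop
                    trace.stop_reasons.append(
                        f"dimension {dim}: component change < tol "
                        f"after {comp} components")
                    break
                p_save.append(pos)
                w_save = w_opt
                v_pos.remove(pos)
                s_plain, s_reg, _ = evaluate_weights(
                    F, y, self._build_row(fixed_rows, p_save, w_save, nb),
                    self._cost_params(),
                    CvConfig(self.cv_n_fold, self.cv_n_kfold,
                             self.random_state))
                trace.steps.append(GreedyStep(dim, comp, pos, w_save.copy(),
                                              s_plain, cost))
                comp_costs.append(cost)
                if not v_pos:
                    break
            row = np.zeros(nb)
            row[p_save] = w_save
            if dim_costs and not stop_check(dim_costs + [comp_costs[-1]],
                                            self.tol):
                # the whole extra dimension failed to move the cost
                trace.stop_reasons.append(
                    f"dimension change < tol: stopped at {dim} dimensions")
                break
            fixed_rows.append(row)
            dim_costs.append(comp_costs[-1])

        self.omega_ = np.vstack(fixed_rows)
        self.selected_ = [list(np.nonzero(r)[0]) for r in fixed_rows]
        self.trace_ = trace
        M = classifier_input(F, self.omega_)
        self.lda_ = LinearDiscriminantAnalysis().fit(M, y)
        self.n_features_in_ = nb
        return self

    def _build_row(self, fixed_rows, support, w, nb):
        omega = np.zeros((len(fixed_rows) + 1, nb))
        for r, row in enumerate(fixed_rows):
            omega[r] = row
        omega[len(fixed_rows), support] = w
        return omega

    def decision_input(self, X) -> np.ndarray:
        check_is_fitted(self, "omega_")
        F = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        return classifier_input(F, self.omega_)

    def predict(self, X):
        return self.lda_.predict(self.decision_input(X))

    def predict_proba(self, X):
        return self.lda_.predict_proba(self.decision_input(X))

    def selected_entry_names(self) -> list[list[str]]:
        check_is_fitted(self, "omega_")
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = np.array([f"b{j}" for j in range(self.omega_.shape[1])],
                             dtype=object)
        return [[str(names[j]) for j in row] for row in self.selected_]

    def report(self) -> str:
        """Human-readable summary of the selected sparse input space."""
        check_is_fitted(self, "omega_")
        lines = ["greedy sparse LDA classifier"]
        for d, sel in enumerate(self.selected_):
            terms = ", ".join(
                f"{self.omega_[d, j]:+.3f}*{name}"
                for j, name in zip(sel, self.selected_entry_names()[d]))
            lines.append(f"  x{d + 1} = {terms}")
        for s in self.trace_.stop_reasons:
            lines.append(f"  stop: {s}")
        return "\n".join(lines)


def greedy_optimize(features, labels, cost_params: CostParams | None = None,
                    d_max: int = 2, n_comp_max: int = 3, tol: float = 0.05,
                    optimizer: str = "cmaes", max_evals: int = 200,
                    cv: CvConfig | None = None, seed: int = 0):
    """Functional wrapper over GreedySparseLDA; returns (omega, trace)."""
    cp = cost_params or CostParams()
    cv = cv or CvConfig()
    est = GreedySparseLDA(
        alpha=cp.alpha, alphas=cp.alphas, beta=cp.beta,
        penalty_mode=cp.penalty_mode, d_max=d_max, n_comp_max=n_comp_max,
        tol=tol, optimizer=optimizer, max_evals=max_evals,
        cv_n_fold=cv.n_fold, cv_n_kfold=cv.n_kfold, random_state=seed)
    est.fit(features, labels)
    return est.omega_, est.trace_
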