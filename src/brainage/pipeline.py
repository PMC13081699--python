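"""Permutation-ensemble brain-age regression: PCA + linear SVR.

The estimator repeats, over many permutations, a group-stratified 2:1
train/test split, 5-fold cross-validation inside the training set, a
final fit on the full training set (PCA retaining 95% of variance, then
epsilon-insensitive linear SVR with epsilon = 0.1 years), and hold-out
prediction. Raw predictions are rescaled to the cohort's age scale
(z-scored, multiplied by the age SD, shifted to the age mean), then
averaged per participant over the permutations in which that
participant was held out. Ensemble stability is summarized by the
coefficient of variation of per-permutation test MAEs; cross-validation
significance comes from a label-shuffling null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array


@dataclass
class SplitPlan:
    """One stratified 2:1 train/test split."""

    permutation: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


@dataclass
class PermutationModel:
    """One ensemble member: split, PCA basis, SVR weights, errors."""

    split: SplitPlan
    pca_mean: np.ndarray                  # (M,)
    pca_components: np.ndarray            # (k, M)
    explained_variance_ratio: np.ndarray  # (k,)
    n_components_retained: int
    svr_weights: np.ndarray               # (k,) in component space
    svr_intercept: float
    cv_fold_maes: np.ndarray = field(default_factory=lambda: np.empty(0))
    test_raw_predictions: np.ndarray = field(default_factory=lambda: np.empty(0))
    # affine raw -> age-scale mapping learned from this permutation's
    # prediction set (mu, sd); degenerate sd stored as 0
    rescale_mu: float = 0.0
    rescale_sd: float = 1.0


def stratified_split(groups, seed, permutation: int = 0) -> SplitPlan:
    """Group-stratified 2:1 split: per group, floor(n_g/3) to test.

    The per-group convention reproduces a 496/246 split for group sizes
    (193, 338, 211). Groups with fewer than 3 members contribute no test
    rows (warned).
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for g in pd_unique_stable(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 3:
            warnings.warn(f"group {g!r} has n={idx.size} < 3; test count is 0")
        idx = rng.permutation(idx)
        n_test = idx.size // 3
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    try:
        seed_int = int(seed)  # SeedSequence and other generator seeds -> -1
    except (TypeError, ValueError):
        seed_int = -1
    return SplitPlan(
        permutation=permutation,
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)) if test else np.empty(0, int),
        seed=seed_int,
    )


def pd_unique_stable(values: np.ndarray) -> np.ndarray:
    """Unique values in first-appearance order."""
    _, first = np.unique(values, return_index=True)
    return values[np.sort(first)]


def fit_permutation(X_train: np.ndarray, y_train: np.ndarray,
                    variance_retained: float = 0.95, epsilon: float = 0.1,
                    C: float = 1.0, split: SplitPlan | None = None) -> PermutationModel:
    """Fit PCA (minimal components reaching >= ``variance_retained``
    cumulative explained variance) then a linear epsilon-insensitive SVR
    on the component scores. Deterministic given the data."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training participants")
    if not np.all(np.isfinite(X_train)):
        raise ValueError("features must be finite")
    if np.allclose(X_train.var(axis=0), 0.0):
        raise ValueError("degenerate features: no variance in the training set")

    pca = PCA(svd_solver="full").fit(X_train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_retained - 1e-12, side="left")) + 1
    k = min(k, len(cum))
    components = pca.components_[:k]
    Z = (X_train - pca.mean_) @ components.T
    svr = SVR(kernel="linear", C=C, epsilon=epsilon).fit(Z, y_train)
    return PermutationModel(
        split=split if split is not None else SplitPlan(0, np.arange(len(y_train)), np.empty(0, int), 0),
        pca_mean=pca.mean_,
        pca_components=components,
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        n_components_retained=k,
        svr_weights=np.asarray(svr.coef_).ravel(),
        svr_intercept=float(np.asarray(svr.intercept_).ravel()[0]),
    )


def predict_raw(model: PermutationModel, X: np.ndarray) -> np.ndarray:
    """Raw ensemble-member predictions: project, weight, shift."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.pca_mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the trained "
            f"edge order ({model.pca_mean.shape[0]})"
        )
    Z = (X - model.pca_mean) @ model.pca_components.T
    return Z @ model.svr_weights + model.svr_intercept


def rescale_predictions(raw: np.ndarray, age_mean: float, age_sd: float) -> np.ndarray:
    """Standardize raw predictions to the cohort's age scale.

    z-score the raw predictions (their own mean/SD), multiply by the
    sample age SD, add the sample mean age. A constant raw vector maps
    to the mean age.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 predictions to rescale")
    sd = raw.std()
    if sd == 0:
        return np.full_like(raw, float(age_mean))
    return (raw - raw.mean()) / sd * float(age_sd) + float(age_mean)


def _cv_fold_maes(X, y, groups, train_idx, k_folds, variance_retained,
                  epsilon, C, rng) -> np.ndarray:
    """Group-stratified k-fold CV inside the training set; raw-prediction MAEs."""
    strat = np.asarray(groups)[train_idx]
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    maes = []
    for fit_rel, val_rel in skf.split(np.zeros(train_idx.size), strat):
        fit_idx, val_idx = train_idx[fit_rel], train_idx[val_rel]
        m = fit_permutation(X[fit_idx], y[fit_idx], variance_retained, epsilon, C)
        pred = predict_raw(m, X[val_idx])
        maes.append(float(np.mean(np.abs(pred - y[val_idx]))))
    return np.asarray(maes)


class BrainAgeEnsemble(BaseEstimator, RegressorMixin):
    """Permutation ensemble of PCA + linear SVR brain-age models.

    Parameters
    ----------
    n_permutations : int
        Number of stratified train/test permutations (1000 at study scale).
    k_folds : int
        Cross-validation folds inside each training set.
    variance_retained : float
        Minimum cumulative explained variance of the retained components.
    epsilon : float
        SVR epsilon-insensitive tube half-width, in years.
    C : float
        SVR regularization constant.
    rescale_scope : {"per_permutation", "pooled"}
        Whether raw test predictions are standardized within each
        permutation's prediction set or over the pool of all permutations.
    random_state : int or None
        Base seed; one child seed is spawned per permutation
        (``SeedSequence(random_state).spawn``), so individual
        permutations are independently reproducible.

    Fitted attributes (trailing underscore) include the ensemble members
    (``models_``), per-permutation test MAEs, summary errors, the
    stability coefficient of variation, and per-subject averaged
    held-out predictions.
    """

    def __init__(self, n_permutations: int = 1000, k_folds: int = 5,
                 variance_retained: float = 0.95, epsilon: float = 0.1,
                 C: float = 1.0, rescale_scope: str = "per_permutation",
                 random_state: int | None = None):
        self.n_permutations = n_permutations
        self.k_folds = k_folds
        self.variance_retained = variance_retained
        self.epsilon = epsilon
        self.C = C
        self.rescale_scope = rescale_scope
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        """Run the full permutation ensemble.

        ``groups`` are the stratification labels (reading groups); they
        never enter model fitting, only the splits.
        """
        X, y = check_X_y(X, y, y_numeric=True)
        if self.rescale_scope not in ("per_permutation", "pooled"):
            raise ValueError(f"unknown rescale_scope {self.rescale_scope!r}")
        n = len(y)
        groups = np.asarray(["all"] * n) if groups is None else np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups length mismatch")
        self.age_mean_ = float(np.mean(y))
        self.age_sd_ = float(np.std(y))

        base = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        children = base.spawn(self.n_permutations)
        self.models_ = []
        for p, child in enumerate(children):
            rng = np.random.default_rng(child)
            plan = stratified_split(groups, child.spawn(1)[0], permutation=p)
            try:
                cv = _cv_fold_maes(X, y, groups, plan.train_idx, self.k_folds,
                                   self.variance_retained, self.epsilon, self.C, rng)
                model = fit_permutation(X[plan.train_idx], y[plan.train_idx],
                                        self.variance_retained, self.epsilon,
                                        self.C, split=plan)
            except Exception as err:  # noqa: BLE001 - tag with permutation index
                raise RuntimeError(f"permutation {p} failed: {err}") from err
            model.cv_fold_maes = cv
            model.test_raw_predictions = predict_raw(model, X[plan.test_idx])
            self.models_.append(model)

        self._finalize(y, n)
        return self

    def _finalize(self, y: np.ndarray, n: int) -> None:
        if self.rescale_scope == "pooled":
            pool = np.concatenate([m.test_raw_predictions for m in self.models_])
            mu, sd = float(pool.mean()), float(pool.std())
            for m in self.models_:
                m.rescale_mu, m.rescale_sd = mu, sd

        pred_sum = np.zeros(n)
        abs_err_sum = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        perm_maes = []
        for m in self.models_:
            raw = m.test_raw_predictions
            if self.rescale_scope == "per_permutation":
                m.rescale_mu = float(raw.mean())
                m.rescale_sd = float(raw.std())
            rescaled = self._apply_rescale(raw, m)
            err = np.abs(rescaled - y[m.split.test_idx])
            perm_maes.append(float(err.mean()))
            pred_sum[m.split.test_idx] += rescaled
            abs_err_sum[m.split.test_idx] += err
            counts[m.split.test_idx] += 1

        self.permutation_test_maes_ = np.asarray(perm_maes)
        self.test_mae_ = float(self.permutation_test_maes_.mean())
        self.cv_mae_ = float(np.mean([m.cv_fold_maes.mean() for m in self.models_]))
        mean_mae = self.permutation_test_maes_.mean()
        self.cov_pct_ = float(100.0 * self.permutation_test_maes_.std() / mean_mae) \
            if mean_mae != 0 else 0.0
        self.subject_test_counts_ = counts
        with np.errstate(invalid="ignore"):
            self.subject_prediction_ = np.where(counts > 0, pred_sum / counts, np.nan)
            self.subject_mae_ = np.where(counts > 0, abs_err_sum / counts, np.nan)
        self.n_components_ = np.asarray(
            [m.n_components_retained for m in self.models_]
        )
        self.n_features_in_ = self.models_[0].pca_mean.shape[0]

    def _apply_rescale(self, raw: np.ndarray, m: PermutationModel) -> np.ndarray:
        if m.rescale_sd == 0:
            return np.full_like(raw, self.age_mean_)
        return (raw - m.rescale_mu) / m.rescale_sd * self.age_sd_ + self.age_mean_

    def predict(self, X):
        """Ensemble-mean prediction on the age scale.

        Each member's raw output passes through the affine raw-to-age
        mapping learned from its own held-out prediction set at fit
        time; the member predictions are then averaged.
        """
        check_is_fitted(self, "models_")
        X = check_array(X)
        preds = [self._apply_rescale(predict_raw(m, X), m) for m in self.models_]
        return np.mean(preds, axis=0)

    def summary(self) -> dict:
        check_is_fitted(self, "models_")
        return {
            "n_permutations": self.n_permutations,
            "test_mae": self.test_mae_,
            "cv_mae": self.cv_mae_,
            "cov_pct": self.cov_pct_,
            "mean_components_retained": float(self.n_components_.mean()),
        }

    def cv_significance(self, X, y, groups=None, n_null: int = 1000,
                        random_state: int | None = None) -> dict:
        """Label-shuffling null for cross-validation accuracy.

        Each null iteration draws a fresh stratified split, shuffles the
        training ages, runs the same k-fold CV, and records its mean
        fold MAE. ``p = (1 + #{null <= observed}) / (1 + n_null)``
        (add-one estimator, never exactly zero).
        """
        check_is_fitted(self, "cv_mae_")
        X, y = check_X_y(X, y, y_numeric=True)
        groups = np.asarray(["all"] * len(y)) if groups is None else np.asarray(groups)
        seed = random_state if random_state is not None else (
            self.random_state if self.random_state is not None else 0
        )
        base = np.random.SeedSequence([int(seed), 0x5eed])
        null_maes = np.empty(n_null)
        for i, child in enumerate(base.spawn(n_null)):
            rng = np.random.default_rng(child)
            plan = stratified_split(groups, child.spawn(1)[0], permutation=i)
            y_null = y.copy()
            y_null[plan.train_idx] = rng.permutation(y_null[plan.train_idx])
            cv = _cv_fold_maes(X, y_null, groups, plan.train_idx, self.k_folds,
                               self.variance_retained, self.epsilon, self.C, rng)
            null_maes[i] = cv.mean()
        p = (1 + int(np.sum(null_maes <= self.cv_mae_))) / (1 + n_null)
        return {"observed_cv_mae": self.cv_mae_, "null_maes": null_maes, "p": p}


def run_ensemble(X, y, groups=None, n_permutations: int = 1000, k_folds: int = 5,
                 base_seed: int | None = None, **kwargs) -> BrainAgeEnsemble:
    """Thin functional wrapper: fit a :class:`BrainAgeEnsemble` and return it."""
    est = BrainAgeEnsemble(n_permutations=n_permutations, k_folds=k_folds,
                           random_state=base_seed, **kwargs)
    return est.fit(X, y, groups=groups)


def compare_models(subject_mae_a, subject_mae_b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired subject-level MAEs.

    Also reports Cohen's d of the paired differences. All-zero
    differences yield the degenerate (W=0, p=1, d=0).
    """
    a = np.asarray(subject_mae_a, dtype=float)
    b = np.asarray(subject_mae_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return {"W": 0.0, "p": 1.0, "cohens_d": 0.0}
    res = stats.wilcoxon(a, b, alternative="two-sided")
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else float(np.sign(diff.mean()) * np.inf)
    return {"W": float(res.statistic), "p": float(res.pvalue), "cohens_d": d}


def no_signal_mae(ages_test, age_mean: float | None = None) -> float:
    """MAE of the degenerate constant predictor (everyone gets the mean age).

    This is the rescaling rule's output when features carry no age
    information, so it serves as the no-signal reference error.
    """
    ages_test = np.asarray(ages_test, dtype=float)
    mu = float(np.mean(ages_test)) if age_mean is None else float(age_mean)
    return float(np.mean(np.abs(ages_test - mu)))
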