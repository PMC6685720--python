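"""Leave-one-out nu-SVR linking hit fingerprints to hemispheric asymmetry.

The question this module answers: does the spatial pattern of head impacts
(a player's normalized 648-bin fingerprint) carry information about which
hemisphere loses more white-matter integrity (the laterality index of the
FA change)? The machinery is

1. leave-one-out cross-validated nu-SVR with a linear kernel: for each of
   the n players, train on the other n - 1 and predict the held-out
   laterality;
2. the squared Pearson correlation r^2 between out-of-fold predictions and
   observed laterality as the summary statistic;
3. a label-permutation null for that r^2 (the add-one estimator, so the
   smallest attainable p with R shuffles is 1/(R+1));
4. a per-bin relevance map: the fold-specific primal weight at each bin,
   correlated across folds with the held-out laterality, squared, and
   Bonferroni-thresholded across the 648 bins.

Because the kernel is linear, the Gram matrix X X^T is computed once and
every fold (and every permutation, since shuffling labels leaves the Gram
unchanged) reuses its submatrices; primal weights are recovered from the
libsvm dual coefficients as w = alpha^T X_sv.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import NuSVR
from sklearn.utils.validation import check_is_fitted


def prediction_r2(predicted, observed) -> float:
    """Squared Pearson correlation between predictions and observations.

    Returns NaN (flagged) when either vector has zero variance; callers
    that rank r^2 values against a null treat NaN as 0 (no linear relation
    is demonstrable from a constant vector).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ValueError("prediction_r2 needs equal-length vectors, n >= 3")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("prediction_r2 requires finite inputs")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        return float("nan")
    r = np.corrcoef(p, o)[0, 1]
    return float(r * r)


def critical_r_squared(alpha: float, df: int) -> float:
    """Critical r^2 for a two-tailed correlation test at level ``alpha``.

    Inverts the t-r relation: with t* the two-tailed critical value of
    Student's t at ``df`` degrees of freedom, r^2* = t*^2 / (t*^2 + df).
    At alpha = 0.01 and df = 37 this is 0.166 (0.17 to two decimals).
    """
    if not 0 < alpha < 1 or df < 1:
        raise ValueError("need 0 < alpha < 1 and df >= 1")
    t = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(t * t / (t * t + df))


def bonferroni_alpha(alpha: float = 0.05, n_bins: int = 648) -> float:
    """Per-bin significance level after Bonferroni correction over the map."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return alpha / n_bins


def feature_relevance(fold_weights, y, alpha: float = 0.05):
    """Per-bin relevance of the fingerprint to laterality.

    For each bin j, correlate across folds the fold-specific primal weight
    at j with the laterality of the fold's held-out participant; relevance
    is the squared correlation. Significance is Bonferroni-corrected across
    bins (two-tailed p < alpha / n_bins). A zero-variance weight column has
    relevance 0 and is never significant.

    Returns (relevance, pvalues, mask): three length-n_bins arrays.
    """
    W = np.asarray(fold_weights, dtype=float)
    y = np.asarray(y, dtype=float)
    if W.ndim != 2 or W.shape[0] != y.size:
        raise ValueError("fold_weights must be (n_folds, n_bins) matching y")
    n, n_bins = W.shape
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    Wc = W - W.mean(axis=0)
    sw = np.sqrt((Wc ** 2).sum(axis=0))
    ok = (sw > 0) & (sy > 0)
    r = np.zeros(n_bins)
    r[ok] = (Wc[:, ok] * yc[:, None]).sum(axis=0) / (sw[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    relevance = r * r
    pvalues = np.ones(n_bins)
    with np.errstate(divide="ignore"):
        t = np.abs(r[ok]) * np.sqrt((n - 2) / np.maximum(1.0 - r[ok] ** 2, 1e-300))
    pvalues[ok] = 2.0 * sps.t.sf(t, n - 2)
    mask = pvalues < bonferroni_alpha(alpha, n_bins)
    mask &= relevance > 0
    return relevance, pvalues, mask


def _loo_predictions(K: np.ndarray, y: np.ndarray, nu: float, C: float,
                     X: np.ndarray | None = None, tol: float = 1e-3):
    """Leave-one-out predictions from a precomputed linear Gram matrix.

    Two scale invariances are enforced per fold, both from training
    statistics only (nothing leaks from the held-out row): the target is
    z-scored, and the Gram matrix is normalized to unit mean diagonal.
    Fingerprint rows have squared norms far below 1 (they are probability
    vectors), and without the kernel normalization the libsvm bound on dual
    coefficients caps the achievable prediction range well below the
    standardized targets, crippling the regression at any reasonable C.
    Predictions and weights are mapped back to original target units.

    Returns (predictions, fold_weights, sv_counts); fold weights are only
    materialized when the raw feature matrix ``X`` is supplied -- they are
    not needed for permutation nulls.
    """
    n = K.shape[0]
    diag = np.diag(K)
    preds = np.empty(n)
    weights = np.empty((n, X.shape[1])) if X is not None else None
    sv_counts = np.empty(n, dtype=int)
    model = NuSVR(kernel="precomputed", nu=nu, C=C, tol=tol)
    idx = np.arange(n)
    for i in range(n):
        tr = idx[idx != i]
        mu, sd = y[tr].mean(), y[tr].std()
        scale = diag[tr].mean()
        if sd == 0 or scale == 0:
            preds[i] = mu
            sv_counts[i] = 0
            if X is not None:
                weights[i] = 0.0
            continue
        model.fit(K[np.ix_(tr, tr)] / scale, (y[tr] - mu) / sd)
        preds[i] = model.predict(K[np.ix_([i], tr)] / scale)[0] * sd + mu
        sv_counts[i] = model.support_.size
        if X is not None:
            weights[i] = sd / scale * (model.dual_coef_[0] @ X[tr[model.support_]])
    return preds, weights, sv_counts


def _loo_fold_cache(K: np.ndarray):
    """Per-fold training Grams, test rows and kernel scales, built once.

    The linear Gram matrix does not depend on the labels, so the fold
    submatrices can be shared across all label permutations.
    """
    n = K.shape[0]
    diag = np.diag(K)
    idx = np.arange(n)
    cache = []
    for i in range(n):
        tr = idx[idx != i]
        scale = diag[tr].mean()
        cache.append((tr, K[np.ix_(tr, tr)] / scale, K[np.ix_([i], tr)] / scale))
    return cache


def _loo_r2_cached(cache, y: np.ndarray, nu: float, C: float, tol: float) -> float:
    """Cross-validated r^2 for one label vector using cached fold Grams."""
    n = len(cache)
    preds = np.empty(n)
    model = NuSVR(kernel="precomputed", nu=nu, C=C, tol=tol)
    for i, (tr, Ktr, Kte) in enumerate(cache):
        mu, sd = y[tr].mean(), y[tr].std()
        if sd == 0:
            preds[i] = mu
            continue
        model.fit(Ktr, (y[tr] - mu) / sd)
        preds[i] = model.predict(Kte)[0] * sd + mu
    r2 = prediction_r2(preds, y)
    return r2 if np.isfinite(r2) else 0.0


@dataclass
class PermutationResult:
    """Label-permutation null for the cross-validated r^2."""

    null_r2: np.ndarray
    observed_r2: float
    pvalue: float
    n_permutations: int
    early_stopped: bool = False


class LateralitySVR(RegressorMixin, BaseEstimator):
    """Linear nu-SVR from hit fingerprints to the laterality index.

    ``fit`` runs the full leave-one-out procedure (n folds for n players)
    and additionally fits the all-data model used by ``predict``.

    Parameters
    ----------
    nu : float in (0, 1]
        Lower bound on the fraction of support vectors. The default targets
        roughly 20 support vectors out of 37 training rows per fold.
    C : float
        Regularization strength of the nu-SVR.
    alpha : float
        Nominal significance level for the Bonferroni-thresholded
        relevance map.
    tol : float
        libsvm stopping tolerance.

    Attributes (after ``fit``)
    --------------------------
    oof_prediction_ : (n,) out-of-fold predicted laterality
    r_squared_ : squared correlation of predictions with observations
    fold_weights_ : (n, n_bins) primal weight vector of each fold
    sv_counts_ : (n,) realized support-vector count per fold
    relevance_, relevance_pvalues_, significant_bins_ : the relevance map
    coef_, intercept_ : all-data model used by ``predict``
    """

    def __init__(self, nu: float = 20.0 / 37.0, C: float = 10.0,
                 alpha: float = 0.05, tol: float = 1e-3):
        self.nu = nu
        self.C = C
        self.alpha = alpha
        self.tol = tol

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D fingerprint matrix")
        keep = np.isfinite(y)
        if not keep.all():
            import warnings

            warnings.warn(f"excluding {int((~keep).sum())} rows with undefined "
                          "laterality", stacklevel=3)
            X, y = X[keep], y[keep]
        if X.shape[0] < 5:
            raise ValueError("need at least 5 players with defined laterality")
        if not np.all(np.isfinite(X)):
            raise ValueError("fingerprints must be finite")
        row_sums = X.sum(axis=1)
        bad = ~(np.isclose(row_sums, 1.0, atol=1e-6) | (row_sums == 0))
        if bad.any():
            raise ValueError(f"{int(bad.sum())} fingerprint rows neither sum to 1 "
                             "nor are flagged all-zero")
        return X, y

    def fit(self, X, y):
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")
        X, y = self._validate(X, y)
        n, d = X.shape
        K = X @ X.T
        preds, weights, sv_counts = _loo_predictions(K, y, self.nu, self.C, X,
                                                     self.tol)
        self.n_features_in_ = d
        self.oof_prediction_ = preds
        self.fold_weights_ = weights
        self.sv_counts_ = sv_counts
        self.r_squared_ = prediction_r2(preds, y)
        self.relevance_, self.relevance_pvalues_, self.significant_bins_ = (
            feature_relevance(weights, y, self.alpha)
        )
        full = NuSVR(kernel="precomputed", nu=self.nu, C=self.C, tol=self.tol)
        mu, sd = y.mean(), y.std()
        scale = np.diag(K).mean()
        if sd == 0 or scale == 0:
            self.coef_ = np.zeros(d)
            self.intercept_ = float(mu)
        else:
            full.fit(K / scale, (y - mu) / sd)
            self.coef_ = sd / scale * (full.dual_coef_[0] @ X[full.support_])
            self.intercept_ = float(sd * full.intercept_[0] + mu)
        self._y_fit = y
        self._K_fit = K
        self._X_fit = X
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def permutation_test(self, n_permutations: int = 1000,
                         random_state=None, max_fits: int = 20_000_000,
                         early_stop_alpha: float | None = None) -> PermutationResult:
        """Label-permutation null for the leave-one-out r^2.

        Shuffles the laterality labels against the fingerprint rows
        ``n_permutations`` times, reruns the full leave-one-out procedure on
        each shuffle (the linear Gram matrix is label-free and reused), and
        reports the add-one p-value ``(1 + #{null >= observed}) / (1 + R)``,
        which can never be 0. A null replicate with a constant prediction
        vector scores r^2 = 0.

        ``early_stop_alpha`` enables an exact sequential shortcut for
        calibration studies that only need the reject/accept decision at
        that level: permutation order is exchangeable, so once the running
        exceedance count guarantees p > alpha the remaining shuffles cannot
        change the decision and the loop stops (the returned p is then an
        upper-bounded partial estimate, flagged by ``early_stopped``).
        """
        check_is_fitted(self, "r_squared_")
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        n = self._y_fit.size
        if n_permutations * n > max_fits:
            raise ValueError(
                f"{n_permutations} permutations x {n} folds = "
                f"{n_permutations * n} SVR fits exceeds the budget of "
                f"{max_fits}; reduce n_permutations or raise max_fits"
            )
        rng = np.random.default_rng(random_state)
        observed = self.r_squared_
        if not np.isfinite(observed):
            observed = 0.0
        stop_at = None
        if early_stop_alpha is not None:
            # p > alpha is certain once exceedances reach this count
            stop_at = int(np.floor(early_stop_alpha * (n_permutations + 1)))
        import sklearn

        cache = _loo_fold_cache(self._K_fit)
        null = []
        exceed = 0
        with sklearn.config_context(assume_finite=True):
            for _ in range(n_permutations):
                yp = rng.permutation(self._y_fit)
                r2 = _loo_r2_cached(cache, yp, self.nu, self.C, self.tol)
                null.append(r2)
                if r2 >= observed:
                    exceed += 1
                    if stop_at is not None and exceed >= stop_at:
                        break
        null = np.asarray(null)
        p = (1 + exceed) / (1 + n_permutations)
        return PermutationResult(null, self.r_squared_, float(p), n_permutations,
                                 early_stopped=null.size < n_permutations)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def loocv_svr_predict(X, y, nu: float = 20.0 / 37.0, C: float = 10.0):
    """Out-of-fold nu-SVR predictions and per-fold primal weights."""
    est = LateralitySVR(nu=nu, C=C).fit(X, y)
    return est.oof_prediction_, est.fold_weights_


def permutation_null(X, y, n_permutations: int = 1000, nu: float = 20.0 / 37.0,
                     C: float = 10.0, random_state=None) -> PermutationResult:
    """Fit the leave-one-out SVR and compute its permutation null."""
    est = LateralitySVR(nu=nu, C=C).fit(X, y)
    return est.permutation_test(n_permutations, random_state=random_state)
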