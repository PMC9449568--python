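"""A compact multivariate adaptive regression splines (MARS) classifier.

Forward pass: starting from the intercept-only model, repeatedly add the
reflected hinge pair max(0, x_j - t) / max(0, t - x_j) whose best member is
most correlated with the current least-squares residual, with candidate
knots at empirical quantiles of each feature. Backward pass: prune basis
terms by generalised cross-validation (GCV) with the conventional penalty of
3 effective parameters per knot. The surviving hinge basis is then fed to a
logistic regression for calibrated class probabilities.

Additive main-effects only (no interaction products): at species-
distribution scale the additive model is the workhorse configuration, and it
keeps the forward pass O(terms x candidates) with vectorised scoring.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = ["MARSClassifier"]


def _hinge(x: np.ndarray, knot: float, direction: int) -> np.ndarray:
    return np.maximum(0.0, direction * (x - knot))


class MARSClassifier(ClassifierMixin, BaseEstimator):
    """Piecewise-linear adaptive basis classifier.

    Parameters
    ----------
    max_terms:
        Maximum number of hinge basis functions (excluding the intercept)
        added in the forward pass; the backward pass may keep fewer.
    n_knot_candidates:
        Number of interior quantile knots tried per feature and step.
    penalty:
        GCV cost per knot (smoothing parameter d in the MARS literature).
    min_rss_decrease:
        Forward pass stops when the relative RSS improvement of the best
        candidate falls below this.
    """

    def __init__(
        self,
        max_terms: int = 12,
        n_knot_candidates: int = 15,
        penalty: float = 3.0,
        min_rss_decrease: float = 1e-4,
    ):
        self.max_terms = max_terms
        self.n_knot_candidates = n_knot_candidates
        self.penalty = penalty
        self.min_rss_decrease = min_rss_decrease

    # -- internals ----------------------------------------------------------

    def _design(self, X: np.ndarray, terms) -> np.ndarray:
        cols = [np.ones(X.shape[0])]
        cols.extend(_hinge(X[:, j], t, s) for j, t, s in terms)
        return np.column_stack(cols)

    @staticmethod
    def _rss(B: np.ndarray, y: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        r = y - B @ coef
        return float(r @ r)

    def _gcv(self, rss: float, n: int, n_terms: int) -> float:
        c = (n_terms + 1) + self.penalty * n_terms / 2.0
        if c >= n:
            return np.inf
        return (rss / n) / (1.0 - c / n) ** 2

    def _forward(self, X: np.ndarray, y: np.ndarray):
        n, p = X.shape
        qs = np.linspace(0.05, 0.95, self.n_knot_candidates)
        candidates: list[tuple[int, float, int]] = []
        for j in range(p):
            knots = np.unique(np.quantile(X[:, j], qs))
            candidates.extend((j, float(t), s) for t in knots for s in (1, -1))
        if not candidates:
            return []
        C = np.column_stack([_hinge(X[:, j], t, s) for j, t, s in candidates])
        Cc = C - C.mean(axis=0)
        norms = np.linalg.norm(Cc, axis=0)
        usable = norms > 1e-12

        terms: list[tuple[int, float, int]] = []
        B = np.ones((n, 1))
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        rss = float(resid @ resid)
        taken = np.zeros(len(candidates), dtype=bool)
        while len(terms) < self.max_terms and rss > 0:
            score = np.abs(Cc.T @ resid)
            score[~usable | taken] = -np.inf
            with np.errstate(invalid="ignore"):
                score = np.where(np.isfinite(score), score / np.where(norms > 0, norms, 1.0), -np.inf)
            best = int(np.argmax(score))
            if not np.isfinite(score[best]):
                break
            j, t, _ = candidates[best]
            # add the reflected pair for the winning (feature, knot)
            new_terms = [(j, t, 1), (j, t, -1)]
            for k, cand in enumerate(candidates):
                if cand[0] == j and cand[1] == t:
                    taken[k] = True
            trial = terms + [nt for nt in new_terms if nt not in terms]
            B_trial = self._design(X, trial)
            rss_trial = self._rss(B_trial, y)
            if rss - rss_trial < self.min_rss_decrease * max(rss, 1e-12):
                break
            terms = trial
            coef, *_ = np.linalg.lstsq(B_trial, y, rcond=None)
            resid = y - B_trial @ coef
            rss = rss_trial
        return terms

    def _prune(self, X: np.ndarray, y: np.ndarray, terms):
        n = X.shape[0]
        best_terms = list(terms)
        best_gcv = self._gcv(self._rss(self._design(X, best_terms), y), n, len(best_terms))
        current = list(terms)
        while current:
            trials = []
            for i in range(len(current)):
                sub = current[:i] + current[i + 1 :]
                g = self._gcv(self._rss(self._design(X, sub), y), n, len(sub))
                trials.append((g, sub))
            g, sub = min(trials, key=lambda t: t[0])
            current = sub
            if g <= best_gcv:
                best_gcv, best_terms = g, list(sub)
        return best_terms

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("MARSClassifier requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        terms = self._forward(X, y01)
        self.terms_ = self._prune(X, y01, terms)
        B = self._design(X, self.terms_)[:, 1:]  # logistic adds its own intercept
        if B.shape[1] == 0:
            B = np.zeros((X.shape[0], 1))
        self._logit = LogisticRegression(C=1e4, max_iter=2000)
        self._logit.fit(B, y01)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "terms_")
        X = np.asarray(X, dtype=float)
        B = self._design(X, self.terms_)[:, 1:]
        if B.shape[1] == 0:
            B = np.zeros((X.shape[0], 1))
        return self._logit.predict_proba(B)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]
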