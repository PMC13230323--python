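"""Linear genomic-prediction engines behind one pluggable predictor interface.

All predictors consume a samples x features matrix (SNP dosages, haplotype
allele counts or PC scores) and a per-line phenotype vector, and emit genomic
estimated breeding values (GEBVs).  RR-BLUP treats marker effects as i.i.d.
normal random effects with the shrinkage ratio lambda = sigma_e2/sigma_u2
estimated by REML profiled over the eigenvalues of the marker kernel; GBLUP
is the equivalent kinship-space formulation with the VanRaden genomic
relationship matrix, and predicts new samples through cross-kinship.  An
elastic net (inner-CV penalty choice), a Gibbs-sampled Bayesian ridge, and a
non-negative-least-squares stacking ensemble round out the set.  Custom
predictors plug in by subclassing :class:`GSModel` and registering a factory
with :func:`register_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .markerrep import MarkerSet


class PredictError(ValueError):
    pass


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, MarkerSet):
        return np.asarray(X.values, dtype=float), list(X.feature_names)
    X = np.asarray(X, dtype=float)
    return X, [f"f{j}" for j in range(X.shape[1])]


def _check_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if np.std(y) == 0:
        raise PredictError("phenotype vector has zero variance")
    if not np.isfinite(y).all():
        raise PredictError("non-finite phenotype values")
    return y


@dataclass
class PredictionResult:
    gebv: np.ndarray
    model_kind: str
    provenance: dict = field(default_factory=dict)


class GSModel:
    """fit/predict/provenance interface every predictor implements."""

    kind = "base"

    def fit(self, X, y) -> "GSModel":  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, X) -> PredictionResult:  # pragma: no cover - interface
        raise NotImplementedError

    # shared feature-identity enforcement
    def _check_features(self, names: list[str]) -> None:
        if names != self.feature_names:
            missing = sorted(set(self.feature_names) - set(names))[:5]
            extra = sorted(set(names) - set(self.feature_names))[:5]
            raise PredictError(
                "feature mismatch between fit and predict; "
                f"missing={missing} extra={extra}"
            )


# ---------------------------------------------------------------------------
# RR-BLUP / GBLUP via eigen-profiled REML
# ---------------------------------------------------------------------------

def _profile_reml_lambda(
    y: np.ndarray, eigvals: np.ndarray, Uty: np.ndarray, Ut1: np.ndarray
) -> float:
    """REML estimate of lambda = sigma_e2/sigma_u2 for y = 1*mu + g,
    g ~ N(0, sigma_u2 * K), via the eigendecomposition K = U diag(d) U'."""
    n = len(y)

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = eigvals + lam
        h_inv_y = Uty / w
        h_inv_1 = Ut1 / w
        denom = Ut1 @ h_inv_1
        mu = (Ut1 @ h_inv_y) / denom
        resid = Uty - mu * Ut1
        quad = resid @ (resid / w)
        s2 = quad / (n - 1)
        return 0.5 * ((n - 1) * np.log(s2) + np.log(w).sum() + np.log(denom))

    res = minimize_scalar(
        neg_reml, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


class RRBLUP(GSModel):
    """Ridge-regression BLUP: y = 1*mu + Z u + e, u ~ N(0, sigma_u2 I)."""

    kind = "rrblup"

    def __init__(self, lambda_: float | None = None):
        self.lambda_ = lambda_

    def fit(self, X, y) -> "RRBLUP":
        Z, names = _as_matrix(X)
        y = _check_y(y)
        if len(y) != Z.shape[0]:
            raise PredictError("X/y length mismatch")
        self.feature_names = names
        self.means_ = Z.mean(axis=0)
        Zc = Z - self.means_
        K = Zc @ Zc.T
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        Uty, Ut1 = U.T @ y, U.T @ np.ones(len(y))
        lam = (
            self.lambda_
            if self.lambda_ is not None
            else _profile_reml_lambda(y, d, Uty, Ut1)
        )
        w = d + lam
        h_inv_1 = U @ (Ut1 / w)
        h_inv_y = U @ (Uty / w)
        self.mu_ = float(np.ones(len(y)) @ h_inv_y / (np.ones(len(y)) @ h_inv_1))
        alpha = U @ ((Uty - self.mu_ * Ut1) / w)
        self.u_ = Zc.T @ alpha
        self.lambda_fit_ = lam
        sigma_u2 = float(
            ((Uty - self.mu_ * Ut1) @ ((Uty - self.mu_ * Ut1) / w)) / (len(y) - 1)
        )
        self.sigma_u2_ = sigma_u2
        self.sigma_e2_ = lam * sigma_u2
        self.train_gebv_ = self.mu_ + Zc @ self.u_
        return self

    def predict(self, X) -> PredictionResult:
        Z, names = _as_matrix(X)
        self._check_features(names)
        gebv = self.mu_ + (Z - self.means_) @ self.u_
        return PredictionResult(
            gebv=gebv,
            model_kind=self.kind,
            provenance={"lambda": self.lambda_fit_, "n_features": len(names)},
        )


class GBLUP(GSModel):
    """Kinship-space BLUP with the VanRaden genomic relationship matrix
    G = W W' / (2 * sum p_k (1 - p_k)), W = dosage centered by 2 p_k."""

    kind = "gblup"

    def __init__(self, jitter: float = 1e-6):
        self.jitter = jitter

    def fit(self, X, y) -> "GBLUP":
        Z, names = _as_matrix(X)
        y = _check_y(y)
        self.feature_names = names
        p = Z.mean(axis=0) / 2.0
        self.means_ = 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise PredictError("all features monomorphic; G undefined")
        self.scale_ = denom
        W = Z - self.means_
        G = W @ W.T / denom + self.jitter * np.eye(len(y))
        self.G_ = G
        d, U = np.linalg.eigh(G)
        d = np.clip(d, 0.0, None)
        Uty, Ut1 = U.T @ y, U.T @ np.ones(len(y))
        lam = _profile_reml_lambda(y, d, Uty, Ut1)
        w = d + lam
        h_inv_1 = U @ (Ut1 / w)
        h_inv_y = U @ (Uty / w)
        self.mu_ = float(np.ones(len(y)) @ h_inv_y / (np.ones(len(y)) @ h_inv_1))
        self.alpha_ = U @ ((Uty - self.mu_ * Ut1) / w)  # (G + lam I)^-1 (y - mu)
        self.u_ = W.T @ self.alpha_ / denom  # implied marker effects
        self.lambda_fit_ = lam
        self.train_gebv_ = self.mu_ + G @ self.alpha_ - self.jitter * self.alpha_
        return self

    def predict(self, X) -> PredictionResult:
        Z, names = _as_matrix(X)
        self._check_features(names)
        # cross-kinship path: G_new,train @ alpha == centered(X) @ u
        gebv = self.mu_ + (Z - self.means_) @ self.u_
        return PredictionResult(
            gebv=gebv,
            model_kind=self.kind,
            provenance={"lambda": self.lambda_fit_, "n_features": len(names)},
        )


# ---------------------------------------------------------------------------
# Regularized regression (elastic net)
# ---------------------------------------------------------------------------

class RegularizedRegression(GSModel):
    """Elastic net with the penalty chosen by inner k-fold CV (MSE).

    ``alpha`` mixes L1/L2 (sklearn's l1_ratio).  alpha = 0 is solved by
    closed-form ridge on the standardized features, since coordinate descent
    does not support a pure L2 penalty.  Coefficients are reported on the
    original feature scale.
    """

    kind = "elasticnet"

    def __init__(
        self,
        alpha: float = 0.5,
        lambda_grid: np.ndarray | None = None,
        inner_folds: int = 5,
        seed: int = 0,
    ):
        if not 0.0 <= alpha <= 1.0:
            raise PredictError("alpha must be in [0, 1]")
        self.alpha = alpha
        self.lambda_grid = (
            np.logspace(-4, 2, 25) if lambda_grid is None else np.asarray(lambda_grid)
        )
        self.inner_folds = inner_folds
        self.seed = seed

    def _solve(self, Xs, y, lam):
        n = len(y)
        if self.alpha == 0.0:
            p = Xs.shape[1]
            A = Xs.T @ Xs / n + lam * np.eye(p)
            coef = np.linalg.solve(A, Xs.T @ (y - y.mean()) / n)
            return coef, float(y.mean())
        model = ElasticNet(
            alpha=lam, l1_ratio=self.alpha, fit_intercept=True, max_iter=50000
        )
        model.fit(Xs, y)
        return model.coef_, float(model.intercept_)

    def fit(self, X, y) -> "RegularizedRegression":
        Z, names = _as_matrix(X)
        y = _check_y(y)
        self.feature_names = names
        self.means_ = Z.mean(axis=0)
        sd = Z.std(axis=0)
        self.scales_ = np.where(sd > 0, sd, 1.0)
        Xs = (Z - self.means_) / self.scales_
        kf = KFold(self.inner_folds, shuffle=True, random_state=self.seed)
        mse = np.zeros(len(self.lambda_grid))
        for tr, te in kf.split(Xs):
            for k, lam in enumerate(self.lambda_grid):
                coef, b0 = self._solve(Xs[tr], y[tr], lam)
                pred = b0 + Xs[te] @ coef
                mse[k] += np.mean((y[te] - pred) ** 2)
        self.lambda_fit_ = float(self.lambda_grid[int(np.argmin(mse))])
        coef, b0 = self._solve(Xs, y, self.lambda_fit_)
        self.u_ = coef / self.scales_  # original scale
        self.mu_ = b0 - float(self.means_ @ self.u_)
        return self

    def predict(self, X) -> PredictionResult:
        Z, names = _as_matrix(X)
        self._check_features(names)
        gebv = self.mu_ + Z @ self.u_
        return PredictionResult(
            gebv=gebv,
            model_kind=self.kind,
            provenance={"alpha": self.alpha, "lambda": self.lambda_fit_},
        )


# ---------------------------------------------------------------------------
# Bayesian ridge regression (Gibbs)
# ---------------------------------------------------------------------------

class BayesianRidge(GSModel):
    """Gibbs-sampled Bayesian ridge: conjugate normal / scaled-inverse-chi2
    updates for (mu, u, sigma_u2, sigma_e2); posterior-mean effects."""

    kind = "brr"

    def __init__(
        self,
        iters: int = 2000,
        burn_in: int = 500,
        seed: int = 0,
        df0: float = 4.0,
        fix_variances: tuple[float, float] | None = None,
    ):
        if burn_in >= iters:
            raise PredictError("burn_in must be < iters")
        self.iters = iters
        self.burn_in = burn_in
        self.seed = seed
        self.df0 = df0
        self.fix_variances = fix_variances

    def fit(self, X, y) -> "BayesianRidge":
        rng = np.random.default_rng(self.seed)
        Z, names = _as_matrix(X)
        y = _check_y(y)
        self.feature_names = names
        self.means_ = Z.mean(axis=0)
        Xc = Z - self.means_
        n, p = Xc.shape
        xx = np.einsum("ij,ij->j", Xc, Xc)
        vy = float(np.var(y))
        # scale hyperparameters so prior modes sit at a 50/50 variance split
        S_e = vy * 0.5 * (self.df0 + 2.0)
        msx = float(xx.sum() / n) or 1.0
        S_u = vy * 0.5 / msx * (self.df0 + 2.0)

        if self.fix_variances is not None:
            su2, se2 = self.fix_variances
        else:
            su2, se2 = vy * 0.5 / msx, vy * 0.5
        mu = float(y.mean())
        u = np.zeros(p)
        resid = y - mu  # residual with current u (=0)
        mu_sum = 0.0
        u_sum = np.zeros(p)
        su2_draws, se2_draws = [], []
        kept = 0
        for it in range(self.iters):
            # mu
            mu_new = rng.normal((resid + mu).mean(), np.sqrt(se2 / n))
            resid += mu - mu_new
            mu = mu_new
            # marker effects, single-site
            lam = se2 / su2
            for k in range(p):
                xk = Xc[:, k]
                if xx[k] == 0:
                    continue
                rk = resid @ xk + xx[k] * u[k]
                ck = xx[k] + lam
                mean_k = rk / ck
                u_new = rng.normal(mean_k, np.sqrt(se2 / ck))
                resid += xk * (u[k] - u_new)
                u[k] = u_new
            if self.fix_variances is None:
                su2 = float((u @ u + S_u) / rng.chisquare(self.df0 + p))
                se2 = float((resid @ resid + S_e) / rng.chisquare(self.df0 + n))
            if it >= self.burn_in:
                kept += 1
                mu_sum += mu
                u_sum += u
                su2_draws.append(su2)
                se2_draws.append(se2)
        self.mu_ = mu_sum / kept
        self.u_ = u_sum / kept
        self.sigma_u2_ = float(np.mean(su2_draws))
        self.sigma_e2_ = float(np.mean(se2_draws))
        return self

    def predict(self, X) -> PredictionResult:
        Z, names = _as_matrix(X)
        self._check_features(names)
        gebv = self.mu_ + (Z - self.means_) @ self.u_
        return PredictionResult(
            gebv=gebv,
            model_kind=self.kind,
            provenance={"iters": self.iters, "burn_in": self.burn_in, "seed": self.seed},
        )


# ---------------------------------------------------------------------------
# Stacking ensemble
# ---------------------------------------------------------------------------

class StackingEnsemble(GSModel):
    """Out-of-fold base predictions feed a non-negative least squares
    meta-learner with intercept; the final prediction combines full-data
    base model predictions with the NNLS weights."""

    kind = "stack"

    def __init__(self, base_factories=None, k: int = 5, seed: int = 0):
        self.base_factories = base_factories or [
            lambda: RRBLUP(),
            lambda: RegularizedRegression(alpha=0.5),
            lambda: BayesianRidge(iters=600, burn_in=200),
        ]
        self.k = k
        self.seed = seed

    def fit(self, X, y) -> "StackingEnsemble":
        Z, names = _as_matrix(X)
        y = _check_y(y)
        self.feature_names = names
        n = len(y)
        m = len(self.base_factories)
        oof = np.zeros((n, m))
        kf = KFold(self.k, shuffle=True, random_state=self.seed)
        for tr, te in kf.split(Z):
            for b, factory in enumerate(self.base_factories):
                fit = factory().fit(Z[tr], y[tr])
                oof[te, b] = fit.predict(Z[te]).gebv
        Pc = oof - oof.mean(axis=0)
        yc = y - y.mean()
        w, _ = nnls(Pc, yc)
        self.weights_ = w
        self.base_fits_ = [f().fit(Z, y) for f in self.base_factories]
        self.intercept_ = float(y.mean() - w @ oof.mean(axis=0))
        self.oof_mse_ = np.mean((oof - y[:, None]) ** 2, axis=0)
        return self

    def predict(self, X) -> PredictionResult:
        Z, names = _as_matrix(X)
        self._check_features(names)
        preds = np.column_stack([f.predict(Z).gebv for f in self.base_fits_])
        gebv = self.intercept_ + preds @ self.weights_
        return PredictionResult(
            gebv=gebv,
            model_kind=self.kind,
            provenance={"weights": self.weights_.tolist()},
        )


# ---------------------------------------------------------------------------
# Registry / convenience
# ---------------------------------------------------------------------------

_REGISTRY = {
    "rrblup": RRBLUP,
    "gblup": GBLUP,
    "elasticnet": RegularizedRegression,
    "brr": BayesianRidge,
    "stack": StackingEnsemble,
}


def register_model(name: str, factory) -> None:
    """Register a custom predictor factory (e.g. an ML/DL wrapper)."""
    _REGISTRY[name] = factory


def make_model(spec, **kwargs) -> GSModel:
    if isinstance(spec, GSModel):
        return spec
    if callable(spec) and not isinstance(spec, str):
        return spec()
    if spec not in _REGISTRY:
        raise PredictError(f"unknown model {spec!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[spec](**kwargs)


def fit_rrblup(X, y, **kw) -> RRBLUP:
    return RRBLUP(**kw).fit(X, y)


def fit_gblup(X, y, **kw) -> GBLUP:
    return GBLUP(**kw).fit(X, y)


def fit_regularized(X, y, **kw) -> RegularizedRegression:
    return RegularizedRegression(**kw).fit(X, y)


def fit_bayes_rr(X, y, **kw) -> BayesianRidge:
    return BayesianRidge(**kw).fit(X, y)


def stack_ensemble(X, y, base_factories=None, **kw) -> StackingEnsemble:
    return StackingEnsemble(base_factories=base_factories, **kw).fit(X, y)


def predict_new(fit: GSModel, X_new) -> PredictionResult:
    """Predict new samples; feature identity is enforced by name."""
    return fit.predict(X_new)
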