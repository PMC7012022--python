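"""Newton/IRLS logistic regression core.

All case-control fits in this package (score derivation, adjusted odds
ratios, leave-one-out refits, bootstrap refits) go through :func:`logistic_fit`.
The fit maximizes the binomial log-likelihood by damped Newton iterations on
internally standardized covariates, stops when the relative log-likelihood
change falls below ``tol_ll`` and the (standardized-scale) gradient infinity
norm falls below ``tol_grad``, and raises :class:`SeparationError` when the
coefficient norm diverges — the signature of complete or quasi-complete
separation, for which the MLE does not exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["LogisticResult", "SeparationError", "ConvergenceError", "logistic_fit"]


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer (data separation)."""


class ConvergenceError(RuntimeError):
    """Raised when Newton iterations exhaust ``max_iter`` without converging."""


@dataclass
class LogisticResult:
    """Maximum-likelihood fit of a binary logistic model.

    ``params`` is ordered (intercept, *covariates*) on the raw covariate
    scale; ``cov_params`` is the inverse observed information on the same
    scale, so Wald SEs are ``sqrt(diag(cov_params))``.
    """

    names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    grad_norm: float
    nobs: int
    llf_path: list[float] = field(default_factory=list, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.params[0] + X @ self.params[1:]


def _as_matrix(X, names):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def logistic_fit(
    X,
    y,
    *,
    names=None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol_ll: float = 1e-10,
    tol_grad: float = 1e-8,
    sep_norm: float = 1e4,
) -> LogisticResult:
    """Fit ``P(y=1|x) = expit(b0 + x @ b)`` by damped Newton iterations.

    Parameters
    ----------
    X : (n, p) array
        Covariates WITHOUT an intercept column (one is added internally).
    y : (n,) array of {0, 1}
    start : optional raw-scale starting values (intercept first), e.g. a
        previous fit's ``params`` for warm-started leave-one-out loops.
    sep_norm : coefficient-norm threshold (standardized scale) beyond which
        the fit is declared separated.

    Raises
    ------
    SeparationError
        If the standardized coefficient norm exceeds ``sep_norm`` while the
        likelihood keeps improving, or the Hessian collapses with perfectly
        classified observations. The message names the diverging direction.
    ConvergenceError
        If ``max_iter`` is reached without meeting both tolerances.
    """
    X, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("y must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("both outcome classes must be present")

    # standardize for numerical stability; constant columns are left alone
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = np.column_stack([np.ones(n), (X - mu) / sd])

    if start is not None:
        start = np.asarray(start, dtype=float)
        b = np.empty(p + 1)
        b[1:] = start[1:] * sd
        b[0] = start[0] + start[1:] @ mu
    else:
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        b = np.zeros(p + 1)
        b[0] = np.log(pbar / (1 - pbar))

    def loglik(beta):
        eta = Z @ beta
        # log(1 + exp(eta)) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(b)
    ll_path = [ll]
    converged = False
    grad_inf = np.inf
    it = 0
    polish = 0
    for it in range(1, max_iter + 1):
        eta = Z @ b
        pr = expit(eta)
        g = Z.T @ (y - pr)
        w = pr * (1.0 - pr)
        H = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped Newton: halve until the log-likelihood does not decrease
        # (tolerance relative to |ll|: the evaluation itself carries
        # floating-point noise of that order on large cohorts)
        t = 1.0
        for _ in range(40):
            cand = b + t * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-11 * (abs(ll) + 1.0):
                break
            t /= 2.0
        b = b + t * step
        d_ll = ll_new - ll
        ll = ll_new
        ll_path.append(ll)
        grad_inf = float(np.max(np.abs(Z.T @ (y - expit(Z @ b)))))

        bnorm = float(np.linalg.norm(b[1:]))
        if ll > -1e-6:
            direction = b[1:] / max(bnorm, 1e-300)
            worst = int(np.argmax(np.abs(direction)))
            raise SeparationError(
                "perfect separation: the likelihood approaches 1 along direction "
                f"{np.round(direction, 3).tolist()} (dominated by '{names[worst]}')"
            )
        if bnorm > sep_norm:
            direction = b[1:] / max(bnorm, 1e-300)
            worst = int(np.argmax(np.abs(direction)))
            raise SeparationError(
                "perfect or quasi-complete separation: coefficient norm "
                f"diverged along direction {np.round(direction, 3).tolist()} "
                f"(dominated by '{names[worst]}')"
            )
        if abs(d_ll) < tol_ll * (abs(ll) + 1.0) and grad_inf < tol_grad:
            # one extra Newton step after the tolerances are met: quadratic
            # convergence squares the residual error, so leave-one-out score
            # comparisons agree with independent optimizers well below 1e-10
            polish += 1
            if polish >= 2:
                converged = True
                break

    if not converged:
        # distinguish separation (ll -> 0 with diverging norm) from slow fits
        if ll > -1e-6 * n:
            raise SeparationError(
                "perfect separation: log-likelihood approached 0 "
                f"(llf={ll:.3e}) without a finite maximizer"
            )
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(|grad|_inf={grad_inf:.2e}, llf={ll:.6f})"
        )

    eta = Z @ b
    pr = expit(eta)
    w = np.clip(pr * (1.0 - pr), 1e-300, None)
    H = (Z * w[:, None]).T @ Z
    try:
        cov_z = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix at optimum: {exc}")

    # back-transform: beta_raw_j = beta_z_j / sd_j ; b0_raw = b0 - sum beta_z_j mu_j / sd_j
    T = np.eye(p + 1)
    T[0, 1:] = -mu / sd
    T[1:, 1:] = np.diag(1.0 / sd)
    params = T @ b
    cov = T @ cov_z @ T.T

    return LogisticResult(
        names=["intercept"] + names,
        params=params,
        cov_params=cov,
        llf=ll,
        converged=True,
        n_iter=it,
        grad_norm=grad_inf,
        nobs=n,
        llf_path=ll_path,
    )
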