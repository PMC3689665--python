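"""Phylogenetic signal and phylogenetic generalized least squares.

Blomberg's K with a tip-shuffling permutation test, and PGLS with
Pagel's lambda estimated by bounded maximum likelihood on [0, 1].

K is the ratio of the observed MSE0/MSE to its Brownian expectation:

    a_hat  = (1' C^-1 y) / (1' C^-1 1)
    MSE0   = (y - a_hat 1)'        (y - a_hat 1) / (n - 1)
    MSE    = (y - a_hat 1)' C^-1   (y - a_hat 1) / (n - 1)
    E[MSE0/MSE] = [tr(C) - n / sum(C^-1)] / (n - 1)

K = 1 under Brownian motion on the supplied tree, K -> 0 when trait
values are independent of phylogeny.

PGLS uses V(lambda) = C with off-diagonal entries scaled by lambda,
ML residual variance sigma2 = RSS_V / n, and t-tests on coefficients
with the small-sample correction n/(n - q) applied to the SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .tree import PhyloCovariance

__all__ = [
    "ZeroVarianceTraitError",
    "SingularCovarianceError",
    "CollinearityError",
    "KResult",
    "PGLSFit",
    "blomberg_k",
    "k_signal_test",
    "pgls_fit",
    "lambda_profile",
]

_CONDITION_LIMIT = 1e10


class ZeroVarianceTraitError(ValueError):
    """Trait is constant across tips; K is undefined."""


class SingularCovarianceError(ValueError):
    """Phylogenetic covariance is numerically singular (e.g. duplicate
    tips joined by zero-length branches); jitter or prune them."""


class CollinearityError(ValueError):
    """Design matrix is rank-deficient in the V-metric."""


@dataclass
class KResult:
    k_value: float
    observed_ratio: float
    expected_ratio: float
    p_permutation: float | None = None
    n_perm: int = 0
    seed: int | None = None


@dataclass
class PGLSFit:
    response_name: str
    predictor_names: list[str]
    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lambda_: float
    lambda_method: str
    log_likelihood: float
    r_squared_multiple: float
    r_squared_adjusted: float
    n_species: int
    model_f: float = np.nan
    model_p: float = np.nan
    sigma2: float = np.nan
    residuals: np.ndarray = field(default=None, repr=False)

    @property
    def coef_names(self) -> list[str]:
        return ["(Intercept)"] + list(self.predictor_names)


def _align_trait(vcv: PhyloCovariance, trait) -> np.ndarray:
    if isinstance(trait, dict):
        missing = [lab for lab in vcv.labels if lab not in trait]
        if missing:
            raise KeyError(f"trait missing for species: {missing}")
        y = np.array([float(trait[lab]) for lab in vcv.labels])
    else:
        y = np.asarray(trait, dtype=float)
        if y.shape != (len(vcv.labels),):
            raise ValueError("trait vector length does not match covariance")
    return y


def _inverse(C: np.ndarray) -> np.ndarray:
    try:
        cho = linalg.cho_factor(C, check_finite=False)
    except linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "covariance matrix is singular; jitter or prune zero-length "
            "duplicate tips"
        ) from exc
    if np.linalg.cond(C) > 1e14:
        raise SingularCovarianceError(
            "covariance matrix is numerically singular (condition number "
            "> 1e14); jitter or prune zero-length duplicate tips"
        )
    return linalg.cho_solve(cho, np.eye(C.shape[0]), check_finite=False)


def _k_mse_parts(Cinv: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = y.size
    ones = np.ones(n)
    w = Cinv @ ones
    a_hat = float(w @ y) / float(ones @ w)
    resid = y - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ Cinv @ resid) / (n - 1)
    return mse0, mse


def blomberg_k(vcv: PhyloCovariance, trait) -> KResult:
    """Blomberg's K for one continuous trait (no significance test)."""
    y = _align_trait(vcv, trait)
    n = y.size
    if n < 3:
        raise ValueError("Blomberg's K needs at least 3 species")
    if np.ptp(y) == 0:
        raise ZeroVarianceTraitError("zero-variance trait: K is undefined")
    C = vcv.values
    Cinv = _inverse(C)
    mse0, mse = _k_mse_parts(Cinv, y)
    if mse <= 0:
        raise ZeroVarianceTraitError("zero-variance trait: K is undefined")
    observed = mse0 / mse
    expected = (np.trace(C) - n / Cinv.sum()) / (n - 1)
    return KResult(
        k_value=observed / expected,
        observed_ratio=observed,
        expected_ratio=float(expected),
    )


def k_signal_test(
    vcv: PhyloCovariance,
    trait,
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Blomberg's K with a permutation test.

    Trait values are shuffled across tips; significance is the rank of
    the observed phylogenetically corrected MSE among permuted MSEs
    (smaller MSE = stronger signal):
    ``p = (1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = blomberg_k(vcv, trait)
    y = _align_trait(vcv, trait)
    n = y.size
    Cinv = _inverse(vcv.values)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    ones = np.ones(n)
    w = Cinv @ ones
    denom = float(ones @ w)
    a_hats = perms @ w / denom
    resid = perms - a_hats[:, None]
    mses = np.einsum("ij,jk,ik->i", resid, Cinv, resid) / (n - 1)
    _, mse_obs = _k_mse_parts(Cinv, y)
    p = (1 + int(np.count_nonzero(mses <= mse_obs))) / (n_perm + 1)
    res.p_permutation = p
    res.n_perm = n_perm
    res.seed = seed
    return res


# ---------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------


def _lambda_vcv(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_core(V: np.ndarray, y: np.ndarray, X: np.ndarray):
    """GLS via the Cholesky whitening transform; returns beta, RSS in the
    V-metric, log|V| and the whitened design for SE computation."""
    try:
        L = linalg.cholesky(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise SingularCovarianceError("V(lambda) is not positive definite") from exc
    Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
    xtx = Xw.T @ Xw
    if np.linalg.cond(xtx) > _CONDITION_LIMIT:
        raise CollinearityError(
            "predictors are collinear in the V-metric (condition number "
            f"of X'V^-1X exceeds {_CONDITION_LIMIT:g})"
        )
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet, xtx, resid_w


def _loglik(V: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    _, rss, logdet, _, _ = _gls_core(V, y, X)
    sigma2 = rss / n
    if sigma2 <= 0:
        return np.inf  # perfect fit; likelihood unbounded
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pgls_fit(
    vcv: PhyloCovariance,
    y,
    X,
    lambda_spec: str | float = "ML",
    response_name: str = "y",
    predictor_names: list[str] | None = None,
) -> PGLSFit:
    """Fit a PGLS regression with intercept.

    ``X`` is an (n, p) array of predictor columns (no intercept column;
    one is prepended). ``lambda_spec`` is ``"ML"`` for bounded maximum
    likelihood on [0, 1], or a fixed value in [0, 1]. R-squared values
    are computed against the intercept-only GLS model in the same
    V(lambda) metric.
    """
    y = _align_trait(vcv, y) if isinstance(y, dict) else np.asarray(y, float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("response / predictor length mismatch")
    q = p + 1
    if n <= q:
        raise ValueError(f"need n > {q} species for {p} predictors, got {n}")
    if predictor_names is None:
        predictor_names = [f"x{i + 1}" for i in range(p)]
    Xd = np.column_stack([np.ones(n), X])
    C = vcv.values

    if lambda_spec == "ML":
        def neg_ll(lam: float) -> float:
            return -_loglik(_lambda_vcv(C, lam), y, Xd)

        opt = optimize.minimize_scalar(
            neg_ll, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        # the optimum may sit at a boundary the bounded optimizer cannot
        # quite reach; compare against the endpoints explicitly
        cand = [(neg_ll(0.0), 0.0), (neg_ll(1.0), 1.0), (opt.fun, float(opt.x))]
        _, lam = min(cand, key=lambda t: t[0])
        method = "ML"
    else:
        lam = float(lambda_spec)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        method = "fixed"

    V = _lambda_vcv(C, lam)
    beta, rss, logdet, xtx, resid_w = _gls_core(V, y, Xd)
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n) if sigma2 > 0 else np.inf

    xtx_inv = np.linalg.inv(xtx)
    se = np.sqrt(np.diag(sigma2 * n / (n - q) * xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = beta / se
    p_vals = 2 * stats.t.sf(np.abs(t_vals), df=n - q)

    # null (intercept-only) model in the same V-metric
    _, rss0, _, _, _ = _gls_core(V, y, np.ones((n, 1)))
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q)
    if p >= 1 and rss > 0:
        f_stat = ((rss0 - rss) / p) / (rss / (n - q))
        model_p = float(stats.f.sf(f_stat, p, n - q))
    else:
        f_stat, model_p = np.inf, 0.0

    return PGLSFit(
        response_name=response_name,
        predictor_names=list(predictor_names),
        coefficients=beta,
        standard_errors=se,
        t_values=t_vals,
        p_values=p_vals,
        lambda_=lam,
        lambda_method=method,
        log_likelihood=float(ll),
        r_squared_multiple=float(r2),
        r_squared_adjusted=float(r2_adj),
        n_species=n,
        model_f=float(f_stat),
        model_p=model_p,
        sigma2=float(sigma2),
        residuals=resid_w,
    )


def lambda_profile(vcv: PhyloCovariance, y, X, grid=None) -> list[tuple[float, float]]:
    """Profile log-likelihood of lambda over a grid on [0, 1]."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    y = _align_trait(vcv, y) if isinstance(y, dict) else np.asarray(y, float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xd = np.column_stack([np.ones(len(y)), X])
    C = vcv.values
    return [(float(lam), _loglik(_lambda_vcv(C, lam), y, Xd)) for lam in grid]
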