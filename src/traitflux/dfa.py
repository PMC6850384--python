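"""Dynamic Factor Analysis: common latent trends in multivariate series.

The model decomposes n observed time series (here: anomaly-standardised
CWM trait series) into m << n shared latent random-walk trends:

    x_t = x_{t-1} + w_t,   w_t ~ N(0, I_m)
    y_t = Z x_t + v_t,     v_t ~ N(0, R)

with the upper-right triangle of the n x m loading matrix Z fixed at
zero for identifiability, the state-noise covariance fixed at the
identity, and a fixed diffuse-ish prior x_1 ~ N(0, kappa*I).  Three
observation-covariance structures are supported: "diagonal-equal"
(R = sigma^2 I), "diagonal-unequal" (R diagonal), and "equal-varcov"
(equal variances, equal off-diagonal covariances).

Estimation is by EM: the E-step runs a Kalman filter/smoother (exact
likelihood; years where the whole observation vector is missing skip the
measurement update), the M-step solves the constrained generalised
least-squares problem for Z and the structure-restricted closed form for
R.  The log-likelihood is non-decreasing across iterations.  Model
selection across numbers of trends and R structures is by AIC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

try:  # optional JIT of the smoother hot loop; pure-numpy fallback below
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = [
    "DFAModel",
    "DFAFit",
    "fit_dfa",
    "select_dfa",
    "rotate_and_orient",
    "subspace_canonical_correlations",
    "R_STRUCTURES",
]

R_STRUCTURES = ("diagonal-equal", "diagonal-unequal", "equal-varcov")

_PRIOR_VAR = 5.0       # variance of the x_1 prior (diffuse-ish, fixed)
_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class DFAModel:
    """Model shape: number of latent trends and observation-covariance structure."""

    m: int = 1
    r_structure: str = "diagonal-equal"

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("number of trends m must be >= 1")
        if self.r_structure not in R_STRUCTURES:
            raise ValueError(f"r_structure must be one of {R_STRUCTURES}")


@dataclass
class DFAFit:
    """Fitted DFA: loadings, smoothed trends and fit diagnostics."""

    model: DFAModel
    Z: np.ndarray                 # n x m loadings
    trends: np.ndarray            # m x T smoothed latent trends
    trend_cov: np.ndarray         # T x m x m smoothed state covariances
    R: np.ndarray                 # n x n observation covariance
    log_lik: float
    n_params: int
    converged: bool
    iterations: int
    log_lik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_lik

    def fitted_values(self) -> np.ndarray:
        """Model-implied series Z @ trends (n x T)."""
        return self.Z @ self.trends


def _observed_pattern(Y: np.ndarray) -> np.ndarray:
    """Per-timepoint flag: fully observed. Partial missingness is rejected."""
    nan = np.isnan(Y)
    col_any = nan.any(axis=0)
    col_all = nan.all(axis=0)
    if np.any(col_any & ~col_all):
        raise ValueError(
            "partially missing observation vectors are not supported: "
            "a year must be fully observed or fully missing"
        )
    return ~col_any


@njit(cache=False)
def _smoother_core(Yt, Z, Zt, R, obs, prior_var):  # pragma: no cover — exercised via wrapper
    T, n = Yt.shape
    m = Z.shape[1]
    eye_m = np.eye(m)
    xp = np.zeros((T, m))
    Pp = np.zeros((T, m, m))
    xf = np.zeros((T, m))
    Pf = np.zeros((T, m, m))
    ll = 0.0
    x_pred = np.zeros(m)
    P_pred = (prior_var + 1.0) * eye_m  # x_1 = x_0 + w_1, x_0 ~ N(0, kappa I)
    log2pi = np.log(2.0 * np.pi)
    for t in range(T):
        xp[t] = x_pred
        Pp[t] = P_pred
        if obs[t]:
            y = Yt[t]
            PZt = P_pred @ Zt                 # m x n
            S = Z @ PZt + R
            S = 0.5 * (S + S.T)
            L = np.linalg.cholesky(S)
            innov = y - Z @ x_pred
            alpha = np.linalg.solve(S, innov)
            logdet = 0.0
            for i in range(n):
                logdet += np.log(L[i, i])
            ll += -0.5 * (n * log2pi + 2.0 * logdet + innov @ alpha)
            K = np.linalg.solve(S, PZt.T).T   # m x n: Pp Z' S^-1
            xf[t] = x_pred + K @ innov
            Pf_t = (eye_m - K @ Z) @ P_pred
            Pf[t] = 0.5 * (Pf_t + Pf_t.T)
        else:
            xf[t] = x_pred
            Pf[t] = P_pred
        x_pred = xf[t]
        P_pred = Pf[t] + eye_m
    xs = np.zeros((T, m))
    Vs = np.zeros((T, m, m))
    xs[T - 1] = xf[T - 1]
    Vs[T - 1] = Pf[T - 1]
    for t in range(T - 2, -1, -1):
        J = np.linalg.solve(Pp[t + 1].T, Pf[t].T).T   # J = Pf_t @ Pp_{t+1}^{-1}
        xs[t] = xf[t] + J @ (xs[t + 1] - xp[t + 1])
        V = Pf[t] + J @ (Vs[t + 1] - Pp[t + 1]) @ J.T
        Vs[t] = 0.5 * (V + V.T)
    return xs, Vs, ll


def _kalman_smoother(Y, Z, R, obs):
    """RTS smoother for the random-walk DFA model; returns moments and logLik.

    Missing timepoints contribute no measurement update and no likelihood
    term.  Returns smoothed means xs (m x T), covariances Vs (T x m x m)
    and the exact log-likelihood of the observed data.
    """
    Yt = np.ascontiguousarray(np.nan_to_num(Y, nan=0.0).T)
    Z = np.ascontiguousarray(Z)
    xs, Vs, ll = _smoother_core(
        Yt, Z, np.ascontiguousarray(Z.T), np.ascontiguousarray(R),
        np.ascontiguousarray(obs), _PRIOR_VAR,
    )
    return xs.T, Vs, float(ll)


def _free_mask(n: int, m: int) -> np.ndarray:
    """Identifiability pattern: Z_ij free iff j <= i (upper-right fixed at 0)."""
    i = np.arange(n)[:, None]
    j = np.arange(m)[None, :]
    return j <= i


def _update_Z(S_xx, S_yx, R, mask):
    """Constrained M-step for Z: GLS over the free entries (column-major vec)."""
    n, m = S_yx.shape
    Rinv = np.linalg.inv(R)
    big = np.kron(S_xx, Rinv)
    rhs = (Rinv @ S_yx).flatten(order="F")
    free = mask.flatten(order="F")
    sol = np.linalg.solve(big[np.ix_(free, free)], rhs[free])
    z = np.zeros(n * m)
    z[free] = sol
    return z.reshape((n, m), order="F")


def _project_R(S_hat: np.ndarray, structure: str) -> np.ndarray:
    """Exact structured M-step for R from the expected residual outer product."""
    n = S_hat.shape[0]
    if structure == "diagonal-equal":
        sigma2 = max(np.trace(S_hat) / n, _VAR_FLOOR)
        return sigma2 * np.eye(n)
    if structure == "diagonal-unequal":
        return np.diag(np.maximum(np.diag(S_hat), _VAR_FLOOR))
    # equal-varcov: R = a I + b (J - I); MLE via the eigenbasis of J
    u = np.full(n, 1.0 / np.sqrt(n))
    s1 = max(float(u @ S_hat @ u), _VAR_FLOOR)           # eigenvalue a + (n-1) b
    s2 = max((np.trace(S_hat) - s1) / (n - 1), _VAR_FLOOR)  # eigenvalue a - b
    a = (s1 + (n - 1) * s2) / n
    b = (s1 - s2) / n
    return a * np.eye(n) + b * (np.ones((n, n)) - np.eye(n))


def _n_params(n: int, model: DFAModel) -> int:
    m = model.m
    z_free = n * m - m * (m - 1) // 2
    r_free = {"diagonal-equal": 1, "diagonal-unequal": n, "equal-varcov": 2}[model.r_structure]
    return z_free + r_free


def _init_Z(Y, obs, m, rng=None, jitter=0.0):
    """SVD-based initial loadings (principal directions of the observed data)."""
    Yo = Y[:, obs]
    Yc = Yo - Yo.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(Yc, full_matrices=False)
    k = min(m, len(s))
    Z0 = np.zeros((Y.shape[0], m))
    Z0[:, :k] = u[:, :k] * (s[:k] / np.sqrt(max(Yo.shape[1], 1)))[None, :]
    if m > k:
        Z0[:, k:] = 0.1
    if jitter and rng is not None:
        Z0 = Z0 + jitter * rng.standard_normal(Z0.shape)
    Z0[~_free_mask(*Z0.shape)] = 0.0
    # avoid an exactly singular all-zero column
    for j in range(m):
        if not np.any(Z0[:, j]):
            Z0[j:, j] = 0.1
    return Z0


def fit_dfa(
    Y,
    model: DFAModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
    seed: int | None = None,
    n_restarts: int = 3,
) -> DFAFit:
    """Fit the DFA model by EM with Kalman smoothing.

    Parameters
    ----------
    Y : array-like or DataFrame, shape (n_series, n_years)
        Anomaly-standardised series; NaN columns mark missing years.
    model : DFAModel
        Number of trends and R structure (default one trend, sigma^2 I).
    tol : float
        EM stops when the log-likelihood improves by less than ``tol``.
    max_iter : int
        Iteration cap per restart; exceeded caps set ``converged=False``.
    seed, n_restarts :
        The first start is a deterministic SVD-based initialisation;
        further restarts jitter it with the seeded generator.  The
        best-likelihood fit is returned.
    """
    model = model or DFAModel()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    n, T = Y.shape
    if T < 3 * model.m:
        raise ValueError(f"need at least {3 * model.m} years for m={model.m} trends")
    obs = _observed_pattern(Y)
    n_obs = int(obs.sum())
    if n_obs < 3:
        raise ValueError("need at least 3 observed years")
    Yo = np.nan_to_num(Y, nan=0.0)
    S_yy = (Yo[:, obs]) @ (Yo[:, obs]).T
    mask = _free_mask(n, model.m)
    rng = np.random.default_rng(seed)

    best = None
    for restart in range(max(1, n_restarts)):
        Z = _init_Z(Y, obs, model.m, rng=rng, jitter=0.0 if restart == 0 else 0.3)
        R = _project_R(np.diag(np.full(n, 0.5)), model.r_structure)
        ll_prev = -np.inf
        ll_path = []
        converged = False
        for it in range(1, max_iter + 1):
            xs, Vs, ll = _kalman_smoother(Y, Z, R, obs)
            ll_path.append(ll)
            if ll - ll_prev < tol and it > 1:
                converged = True
                break
            ll_prev = ll
            xo = xs[:, obs]                       # m x n_obs
            S_xx = xo @ xo.T + Vs[obs].sum(axis=0)
            S_yx = Yo[:, obs] @ xo.T
            Z = _update_Z(S_xx, S_yx, R, mask)
            S_hat = (S_yy - Z @ S_yx.T - S_yx @ Z.T + Z @ S_xx @ Z.T) / n_obs
            S_hat = (S_hat + S_hat.T) / 2.0
            R = _project_R(S_hat, model.r_structure)
        xs, Vs, ll = _kalman_smoother(Y, Z, R, obs)
        fit = DFAFit(
            model=model,
            Z=Z,
            trends=xs,
            trend_cov=Vs,
            R=R,
            log_lik=ll,
            n_params=_n_params(n, model),
            converged=converged,
            iterations=len(ll_path),
            log_lik_path=np.asarray(ll_path),
        )
        if best is None or fit.log_lik > best.log_lik:
            best = fit
    return best


def select_dfa(
    Y,
    m_candidates=(1, 2, 3),
    structures=R_STRUCTURES,
    tol: float = 1e-6,
    max_iter: int = 5000,
    seed: int | None = None,
    n_restarts: int = 3,
):
    """Fit all m x structure combinations; return (best AIC fit, AIC table).

    Ties are broken toward fewer trends, then the simpler structure (in
    the order diagonal-equal < diagonal-unequal < equal-varcov).
    """
    rows = []
    fits = {}
    errors = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(m_candidates) * len(structures))
    k = 0
    for m in m_candidates:
        for structure in structures:
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            try:
                fit = fit_dfa(
                    Y, DFAModel(m=m, r_structure=structure),
                    tol=tol, max_iter=max_iter, seed=sub_seed, n_restarts=n_restarts,
                )
            except Exception as exc:  # noqa: BLE001 — per-model diagnostics
                errors[(m, structure)] = str(exc)
                continue
            fits[(m, structure)] = fit
            rows.append(
                {"m": m, "r_structure": structure, "log_lik": fit.log_lik,
                 "n_params": fit.n_params, "AIC": fit.aic, "converged": fit.converged}
            )
    if not fits:
        raise RuntimeError(f"all DFA fits failed: {errors}")
    table = pd.DataFrame(rows).sort_values(["m", "r_structure"]).reset_index(drop=True)
    order = {s: i for i, s in enumerate(R_STRUCTURES)}
    best_key = min(fits, key=lambda key: (fits[key].aic, key[0], order[key[1]]))
    return fits[best_key], table


def rotate_and_orient(fit: DFAFit, rotate: bool = True) -> DFAFit:
    """Varimax-rotate loadings (m >= 2) and sign-orient each trend.

    The rotation is applied jointly to Z and the trends so the
    reconstruction Z @ trends is preserved; each trend is then flipped,
    if needed, so that the series with the largest |loading| loads
    positively.  For m = 1 only the sign orientation applies.
    """
    Z = fit.Z.copy()
    trends = fit.trends.copy()
    cov = fit.trend_cov.copy()
    m = Z.shape[1]
    if rotate and m >= 2:
        Z, rot = rotate_factors(Z, "varimax")
        trends = rot.T @ trends
        cov = np.einsum("ij,tjk,lk->til", rot.T, cov, rot.T)
    for j in range(m):
        i_star = int(np.argmax(np.abs(Z[:, j])))
        if Z[i_star, j] < 0:
            Z[:, j] = -Z[:, j]
            trends[j] = -trends[j]
    out = DFAFit(
        model=fit.model, Z=Z, trends=trends, trend_cov=cov, R=fit.R,
        log_lik=fit.log_lik, n_params=fit.n_params, converged=fit.converged,
        iterations=fit.iterations, log_lik_path=fit.log_lik_path,
    )
    return out


def subspace_canonical_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Canonical correlations between the column spaces of A and B.

    Used to compare estimated and true trend subspaces: values near 1
    mean the spaces coincide regardless of rotation or sign.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] < A.shape[1]:
        A = A.T
    if B.shape[0] < B.shape[1]:
        B = B.T
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.clip(sv, 0.0, 1.0)
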