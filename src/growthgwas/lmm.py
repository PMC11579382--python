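"""Linear mixed models for longitudinal log-BMI with spline mean curves.

The model for subject *i* observed at ages ``t_i`` is

    y_i = X_i beta + Z_i b_i + eps_i,
    b_i ~ MVN(0, G),   eps_i ~ MVN(0, sigma^2 C_i(phi)),

where ``X_i`` is a truncated-power spline design (plus optional categorical
covariates), ``Z_i`` a reduced spline/polynomial design for the subject
random effects, and ``C_i(phi)`` either the identity or a continuous AR(1)
correlation matrix with entries ``phi**|t_s - t_t|``.

Estimation maximises the marginal (or restricted) likelihood, which is a
sum of independent per-subject blocks because subjects are independent.
The optimisation is staged for robustness: a method-of-moments start (the
covariance of per-subject ridge-regularised OLS coefficients), an EM
iteration with closed-form updates — monotone in the marginal likelihood —
and a quasi-Newton polish on the log-Cholesky factor of ``G/sigma^2``
(guaranteeing a PSD ``G``) with ``beta`` and ``sigma^2`` profiled out
analytically.  A CAR(1) structure is handled by coordinate ascent:
residuals are whitened at the current ``phi``, EM runs on the whitened
data, and ``phi`` is re-optimised on the profiled likelihood.  Subjects
with equal visit counts are stacked so that each pass is a handful of
batched Cholesky factorisations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .splines import SplineSpec, design_matrix, random_is_reduction

__all__ = [
    "ModelSpec",
    "LMMFit",
    "FitDiagnostics",
    "car1_matrix",
    "fit_lmm",
    "blups",
    "diagnostics",
]

_PHI_MAX = 0.98  # CAR(1) upper limit; phi -> 1 makes V singular
_VAR_FLOOR = 1e-9  # scaled variance below this counts as a boundary


@dataclass(frozen=True)
class ModelSpec:
    """A candidate mixed model: fixed basis, random basis, correlation.

    ``random=None`` fits a fixed-effects-only (GLS/OLS) model; otherwise
    the random basis must be a reduction of the fixed basis.  ``covariates``
    names categorical columns (e.g. data source) entered as fixed-effect
    dummies, reference level = first sorted level.
    """

    fixed: SplineSpec
    random: SplineSpec | None = None
    correlation: str = "none"
    covariates: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.correlation not in ("none", "car1"):
            raise ValueError("correlation must be 'none' or 'car1'")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.random is not None and not random_is_reduction(self.fixed, self.random):
            raise ValueError(
                "random design must be a subset/reduction of the fixed design"
            )

    def label(self) -> str:
        rand = self.random.label() if self.random is not None else "none"
        return f"{self.fixed.label()}|{rand}|{self.correlation}"


@dataclass
class FitDiagnostics:
    aic: float
    bic: float
    rmse: float
    residual_sd: float
    icc: float
    r2_marginal: float
    r2_conditional: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class LMMFit:
    """Fitted mixed model: estimates, uncertainty and bookkeeping."""

    spec: ModelSpec
    beta: pd.Series
    beta_se: pd.Series
    G: pd.DataFrame
    sigma2: float
    phi: float | None
    loglik: float
    n_params: int
    converged: str  # "ok" | "warning" | "error"
    message: str
    n_subjects: int
    n_obs: int
    method: str
    loglik_trace: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.converged in ("ok", "warning")

    def fixed_coef(self) -> np.ndarray:
        """Spline coefficients only (covariate dummies excluded)."""
        return self.beta.values[: self.spec.fixed.n_columns]

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.spec.label(),
            "method": self.method,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "beta_se": {k: float(v) for k, v in self.beta_se.items()},
            "G": self.G.values.tolist() if self.G.size else [],
            "G_columns": list(self.G.columns),
            "sigma2": float(self.sigma2),
            "phi": None if self.phi is None else float(self.phi),
            "loglik": float(self.loglik),
            "n_params": self.n_params,
            "converged": self.converged,
            "message": self.message,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def car1_matrix(ages, phi: float) -> np.ndarray:
    """Continuous AR(1) correlation matrix: entry (s,t) = phi**|t_s - t_t|.

    ``phi`` must lie in [0, 1).  phi=0 gives the identity.
    """
    if not 0 <= phi < 1:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    t = np.asarray(ages, dtype=float)
    gaps = np.abs(t[:, None] - t[None, :])
    if phi == 0.0:
        return np.eye(len(t))
    return phi**gaps


# ---------------------------------------------------------------------------
# data grouped by visit count for batched linear algebra


class _BlockData:
    """Per-subject designs stacked into groups of equal visit count."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec, response: str):
        iid = table["iid"].to_numpy()
        order = np.argsort(iid, kind="stable")
        tbl = table.iloc[order]
        ages = tbl["age"].to_numpy(dtype=float)
        y = tbl[response].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")

        X = design_matrix(ages, spec.fixed)
        names = list(spec.fixed.column_names)
        for cov in spec.covariates:
            levels = sorted(pd.unique(tbl[cov].astype(str)))
            for lev in levels[1:]:
                X = np.column_stack([X, (tbl[cov].astype(str) == lev).astype(float)])
                names.append(f"{cov}[{lev}]")
        self.x_names = names
        q = spec.random.n_columns if spec.random is not None else 0
        Z = (
            design_matrix(ages, spec.random)
            if spec.random is not None
            else np.zeros((len(ages), 0))
        )
        self.z_names = spec.random.column_names if spec.random is not None else []

        # column scaling keeps the optimiser and normal equations conditioned
        self.x_scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
        self.z_scale = np.maximum(np.abs(Z).max(axis=0), 1e-12) if q else np.empty(0)
        Xs = X / self.x_scale
        Zs = Z / self.z_scale if q else Z

        ids, starts = np.unique(tbl["iid"].to_numpy(), return_index=True)
        bounds = np.r_[np.sort(starts), len(tbl)]
        counts = np.diff(bounds)
        self.subject_ids = ids
        self.n_subjects = len(ids)
        self.n_obs = len(tbl)
        self.p = Xs.shape[1]
        self.q = q

        self.groups = []
        for n in np.unique(counts):
            sel = np.where(counts == n)[0]
            idx = np.concatenate(
                [np.arange(bounds[s], bounds[s + 1]) for s in sel]
            ).reshape(len(sel), n)
            self.groups.append(
                {
                    "subjects": sel,
                    "X": Xs[idx],  # (m, n, p)
                    "Z": Zs[idx],  # (m, n, q)
                    "y": y[idx],  # (m, n)
                    "gaps": np.abs(ages[idx][:, :, None] - ages[idx][:, None, :]),
                }
            )


def _whiten(groups, phi: float):
    """Pre-multiply each subject's (X, Z, y) by C(phi)^{-1/2}."""
    if phi == 0.0:
        return groups
    out = []
    for g in groups:
        C = phi ** g["gaps"]
        L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[-1]))
        Xw = np.linalg.solve(L, g["X"])
        Zw = np.linalg.solve(L, g["Z"]) if g["Z"].shape[-1] else g["Z"]
        yw = np.linalg.solve(L, g["y"][:, :, None])[:, :, 0]
        out.append({**g, "X": Xw, "Z": Zw, "y": yw})
    return out


def _cross_products(groups):
    """Per-subject sufficient statistics for the EM updates."""
    stats = []
    for g in groups:
        X, Z, y = g["X"], g["Z"], g["y"]
        stats.append(
            {
                "n": X.shape[1],
                "XtX": np.einsum("mni,mnj->mij", X, X),
                "XtZ": np.einsum("mni,mnq->miq", X, Z),
                "ZtZ": np.einsum("mnq,mnr->mqr", Z, Z),
                "Xty": np.einsum("mni,mn->mi", X, y),
                "Zty": np.einsum("mnq,mn->mq", Z, y),
                "yty": np.einsum("mn,mn->m", y, y),
            }
        )
    return stats


def _mom_start(groups, p, q):
    """Method-of-moments (G, sigma^2): covariance of per-subject ridge OLS."""
    XtX = sum(np.einsum("mni,mnj->ij", g["X"], g["X"]) for g in groups)
    Xty = sum(np.einsum("mni,mn->i", g["X"], g["y"]) for g in groups)
    beta = np.linalg.solve(XtX + 1e-10 * np.eye(p), Xty)
    bs, res = [], []
    for g in groups:
        X, Z, y = g["X"], g["Z"], g["y"]
        r = y - np.einsum("mnp,p->mn", X, beta)
        ZtZ = np.einsum("mnq,mnr->mqr", Z, Z) + 1e-4 * np.eye(q)
        Ztr = np.einsum("mnq,mn->mq", Z, r)
        b = np.linalg.solve(ZtZ, Ztr[:, :, None])[:, :, 0]
        bs.append(b)
        res.append((r - np.einsum("mnq,mq->mn", Z, b)).ravel())
    B = np.concatenate(bs, axis=0)
    resid = np.concatenate(res)
    sigma2 = max(float(np.mean(resid**2)), 1e-10)
    G = np.atleast_2d(np.cov(B.T)) if len(B) > q else np.eye(q)
    w, V = np.linalg.eigh((G + G.T) / 2)
    w = np.maximum(w, max(1e-6 * w.max(), 1e-10))
    return (V * w) @ V.T, sigma2, beta


def _em_loglik(stats, G, sigma2, beta):
    """Marginal -2 log-likelihood at (beta, G, sigma^2) on whitened data."""
    q = G.shape[0]
    sign, logdetG = np.linalg.slogdet(G)
    if sign <= 0:
        return np.inf
    Ginv = np.linalg.inv(G)
    neg2 = 0.0
    N = 0
    for s in stats:
        m = s["XtX"].shape[0]
        n = s["n"]
        N += m * n
        M = Ginv[None] + s["ZtZ"] / sigma2
        sign_m, logdetM = np.linalg.slogdet(M)
        if np.any(sign_m <= 0):
            return np.inf
        Ztr = s["Zty"] - np.einsum("miq,i->mq", s["XtZ"], beta)
        r0 = (
            s["yty"]
            - 2 * s["Xty"] @ beta
            + np.einsum("i,mij,j->m", beta, s["XtX"], beta)
        )
        Kz = np.linalg.solve(M, Ztr[:, :, None])[:, :, 0]
        quad = (r0 - np.einsum("mq,mq->m", Ztr, Kz) / sigma2) / sigma2
        neg2 += float(
            m * n * np.log(sigma2) + logdetM.sum() + m * logdetG + quad.sum()
        )
    return neg2 + N * np.log(2 * np.pi)


def _em(stats, G, sigma2, beta, maxiter=500, tol=1e-8):
    """ECME iterations; returns (G, sigma2, beta, trace, converged)."""
    q = G.shape[0]
    trace = [-0.5 * _em_loglik(stats, G, sigma2, beta)]
    n_subj = sum(s["XtX"].shape[0] for s in stats)
    N = sum(s["XtX"].shape[0] * s["n"] for s in stats)
    converged = False
    for _ in range(maxiter):
        Ginv = np.linalg.inv(G + _VAR_FLOOR * np.trace(G) / q * np.eye(q))
        # GLS update of beta at current (G, sigma2)
        p = len(beta)
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        Ks, Ztrs = [], []
        for s in stats:
            M = Ginv[None] + s["ZtZ"] / sigma2
            K = np.linalg.inv(M)
            Ks.append(K)
            XtVX += (
                np.einsum("mij->ij", s["XtX"])
                - np.einsum("miq,mqr,mjr->ij", s["XtZ"], K, s["XtZ"]) / sigma2
            ) / sigma2
            XtVy += (
                s["Xty"].sum(axis=0)
                - np.einsum("miq,mqr,mr->i", s["XtZ"], K, s["Zty"]) / sigma2
            ) / sigma2
        beta = np.linalg.solve(XtVX, XtVy)
        # E-step and M-step for G, sigma2
        G_acc = np.zeros((q, q))
        rss = 0.0
        for s, K in zip(stats, Ks):
            Ztr = s["Zty"] - np.einsum("miq,i->mq", s["XtZ"], beta)
            b = np.einsum("mqr,mr->mq", K, Ztr) / sigma2
            G_acc += np.einsum("mq,mr->qr", b, b) + K.sum(axis=0)
            r0 = (
                s["yty"]
                - 2 * s["Xty"] @ beta
                + np.einsum("i,mij,j->m", beta, s["XtX"], beta)
            )
            rb = r0 - 2 * np.einsum("mq,mq->m", Ztr, b) + np.einsum(
                "mq,mqr,mr->m", b, s["ZtZ"], b
            )
            rss += float(rb.sum() + np.einsum("mqr,mrq->", s["ZtZ"], K))
        G = (G_acc + G_acc.T) / (2 * n_subj)
        sigma2 = max(rss / N, 1e-12)
        trace.append(-0.5 * _em_loglik(stats, G, sigma2, beta))
        # relative tolerance: the attainable precision scales with |loglik|
        if abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(trace[-1])):
            converged = True
            break
    return G, sigma2, beta, trace, converged


# ---------------------------------------------------------------------------
# profiled likelihood on (log-Cholesky of G/sigma^2, logit phi)


def _theta_to_chol(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    pos = 0
    for j in range(q):
        L[j, j] = np.exp(np.clip(theta[pos], -40, 40))
        pos += 1
        L[j, :j] = theta[pos : pos + j]
        pos += j
    return L


def _chol_to_theta(A: np.ndarray) -> np.ndarray:
    q = A.shape[0]
    w, V = np.linalg.eigh((A + A.T) / 2)
    w = np.maximum(w, max(w.max(), 1e-300) * 1e-12)
    L = np.linalg.cholesky((V * w) @ V.T + 1e-300 * np.eye(q))
    theta = []
    for j in range(q):
        theta.append(np.log(max(L[j, j], 1e-150)))
        theta.extend(L[j, :j])
    return np.array(theta)


def _profiled_neg2ll(theta, data: _BlockData, car1: bool, reml: bool):
    """-2 profile log-likelihood; beta and sigma^2 concentrated out."""
    q, p = data.q, data.p
    A = None
    if q:
        L = _theta_to_chol(theta[: q * (q + 1) // 2], q)
        A = L @ L.T  # G / sigma^2, on the scaled-Z coordinates
    phi = float(expit(theta[-1])) if car1 else 0.0

    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    ytWy = 0.0
    logdet = 0.0
    for g in data.groups:
        X, Z, y = g["X"], g["Z"], g["y"]
        m, n, _ = X.shape
        if car1:
            C = phi ** g["gaps"]
        else:
            C = np.broadcast_to(np.eye(n), (m, n, n))
        if q:
            V = C + np.einsum("mnq,qr,mkr->mnk", Z, A, Z, optimize=True)
        else:
            V = np.array(C, copy=True)
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdet += 2.0 * np.log(np.einsum("mii->mi", Lc)).sum()
        rhs = np.concatenate([X, y[:, :, None]], axis=2)
        sol = np.linalg.solve(V, rhs)  # V^{-1}[X | y]
        XtWX += np.einsum("mnp,mnr->pr", X, sol[:, :, :p])
        XtWy += np.einsum("mnp,mn->p", X, sol[:, :, p])
        ytWy += np.einsum("mn,mn->", y, sol[:, :, p])

    N = data.n_obs
    try:
        cho = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - beta @ XtWy
    if rss <= 0 or not np.isfinite(rss):
        return np.inf, None
    if reml:
        df = N - p
        sigma2 = rss / df
        logdet_xwx = 2.0 * np.log(np.diag(cho)).sum()
        neg2 = df * np.log(2 * np.pi * sigma2) + logdet + logdet_xwx + df
    else:
        sigma2 = rss / N
        neg2 = N * np.log(2 * np.pi * sigma2) + logdet + N
    return neg2, (beta, sigma2, phi, A, XtWX)


def _profiled_stable(theta, data: _BlockData, car1: bool, reml: bool):
    """Like :func:`_profiled_neg2ll` but via whitened least squares.

    Stacks C^{-1/2}-whitened rows and solves by QR/lstsq instead of the
    normal equations, so the reported beta, sigma^2 and standard errors do
    not pay the squared condition number of the spline design.  Used once
    at the optimum; the fast accumulation path drives the optimiser.
    """
    q, p = data.q, data.p
    A = None
    if q:
        L = _theta_to_chol(theta[: q * (q + 1) // 2], q)
        A = L @ L.T
    phi = float(expit(theta[-1])) if car1 else 0.0

    wx_parts, wy_parts = [], []
    logdet = 0.0
    for g in data.groups:
        X, Z, y = g["X"], g["Z"], g["y"]
        m, n, _ = X.shape
        if car1:
            C = phi ** g["gaps"]
        else:
            C = np.broadcast_to(np.eye(n), (m, n, n))
        if q:
            V = C + np.einsum("mnq,qr,mkr->mnk", Z, A, Z, optimize=True)
        else:
            V = np.array(C, copy=True)
        try:
            Lc = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdet += 2.0 * np.log(np.einsum("mii->mi", Lc)).sum()
        Wx = np.linalg.solve(Lc, X)  # C^{-1/2} X, batched
        Wy = np.linalg.solve(Lc, y[:, :, None])[:, :, 0]
        wx_parts.append(Wx.reshape(-1, p))
        wy_parts.append(Wy.reshape(-1))
    Wx = np.concatenate(wx_parts)
    Wy = np.concatenate(wy_parts)
    beta, *_ = np.linalg.lstsq(Wx, Wy, rcond=None)
    resid = Wy - Wx @ beta
    rss = float(resid @ resid)
    if rss <= 0 or not np.isfinite(rss):
        return np.inf, None
    XtWX = Wx.T @ Wx
    N = data.n_obs
    if reml:
        df = N - p
        sigma2 = rss / df
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf, None
        neg2 = df * np.log(2 * np.pi * sigma2) + logdet + logdet_xwx + df
    else:
        sigma2 = rss / N
        neg2 = N * np.log(2 * np.pi * sigma2) + logdet + N
    return neg2, (beta, sigma2, phi, A, XtWX)


def fit_lmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    method: str = "ML",
    response: str = "log_bmi",
    maxiter: int = 500,
) -> LMMFit:
    """Fit the mixed model by (restricted) maximum likelihood.

    ``table`` needs columns ``iid``, ``age``, the response, and any
    covariates named by the spec.  Failures never raise: the returned fit
    carries ``converged`` in {ok, warning, error} with a message, so grid
    runners can score every candidate.  ML is the default so that AIC/BIC
    remain comparable across fixed-effect structures; pass
    ``method="REML"`` for variance components unbiased under the chosen
    fixed structure.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method == "REML"
    car1 = spec.correlation == "car1"
    try:
        data = _BlockData(table, spec, response)
    except Exception as exc:
        return _failed_fit(spec, method, f"design construction failed: {exc}")

    warnings: list[str] = []
    ages = table["age"].to_numpy(dtype=float)
    for k in spec.fixed.knots:
        if not (ages.min() < k < ages.max()):
            warnings.append(f"knot {k:g} outside observed age range")

    q = data.q
    n_params = data.p + q * (q + 1) // 2 + 1 + (1 if car1 else 0)

    if maxiter <= 0:
        fit = _failed_fit(spec, method, "no optimizer iterations performed")
        fit.converged = "warning"
        return fit

    if q == 0:
        # GLS/OLS: only phi (if any) needs optimising
        if not car1:
            neg2, extra = _profiled_stable(np.empty(0), data, False, reml)
            if extra is None:
                return _failed_fit(spec, method, "OLS solve failed")
            return _assemble(spec, method, data, extra, neg2, n_params, "ok",
                             "; ".join(warnings), [])
        res = optimize.minimize_scalar(
            lambda z: _profiled_neg2ll(np.array([z]), data, True, reml)[0],
            bounds=(logit(1e-4), logit(_PHI_MAX)),
            method="bounded",
        )
        neg2, extra = _profiled_stable(np.array([res.x]), data, True, reml)
        if extra is None:
            return _failed_fit(spec, method, "GLS solve failed")
        return _assemble(spec, method, data, extra, neg2, n_params, "ok",
                         "; ".join(warnings), [])

    try:
        fitted = _optimise(data, car1, reml, maxiter, warnings)
    except Exception as exc:
        return _failed_fit(spec, method, f"optimization failed: {exc}")
    if fitted is None:
        return _failed_fit(spec, method, "likelihood could not be evaluated")
    theta, trace, status = fitted

    neg2, extra = _profiled_stable(theta, data, car1, reml)
    if extra is None or not np.isfinite(neg2):
        return _failed_fit(spec, method, "likelihood undefined at optimum")
    _, _, phi, A, XtWX = extra
    if np.any(np.diag(A) < _VAR_FLOOR):
        status = "warning"
        warnings.append("variance component at zero boundary")
    if car1 and phi > _PHI_MAX - 1e-3:
        status = "warning"
        warnings.append("phi at upper boundary")
    if np.linalg.cond(XtWX) > 1e10:
        status = "warning"
        warnings.append("near-singular fixed-effect information")
    return _assemble(
        spec, method, data, extra, neg2, n_params, status, "; ".join(warnings), trace
    )


def _optimise(data, car1, reml, maxiter, warnings):
    """MoM start -> (phi-whitened) EM -> quasi-Newton polish."""
    q = data.q
    stats0 = _cross_products(data.groups)
    G, sigma2, beta = _mom_start(data.groups, data.p, q)
    status = "ok"
    trace: list[float] = []
    phi = 0.2 if car1 else 0.0

    if not car1:
        G, sigma2, beta, trace, conv = _em(stats0, G, sigma2, beta, maxiter=maxiter)
        if not conv:
            status = "warning"
            warnings.append("EM iteration cap reached")
    else:
        prev = np.inf
        for outer in range(12):
            stats = _cross_products(_whiten(data.groups, phi))
            G, sigma2, beta, tr, conv = _em(
                stats, G, sigma2, beta, maxiter=min(120, maxiter)
            )
            trace.extend(tr)
            theta_A = _chol_to_theta(G / sigma2)
            res = optimize.minimize_scalar(
                lambda z: _profiled_neg2ll(np.r_[theta_A, z], data, True, False)[0],
                bounds=(logit(1e-4), logit(_PHI_MAX)),
                method="bounded",
                options={"xatol": 1e-4},
            )
            phi = float(expit(res.x))
            cur = float(res.fun)
            trace.append(-0.5 * cur)
            if abs(prev - cur) < 1e-4:
                break
            prev = cur
        else:
            status = "warning"
            warnings.append("CAR(1) coordinate ascent cap reached")

    theta = _chol_to_theta(G / sigma2)
    if car1:
        theta = np.r_[theta, logit(np.clip(phi, 1e-4, _PHI_MAX))]

    def objective(th):
        val, _ = _profiled_neg2ll(th, data, car1, reml)
        return val if np.isfinite(val) else 1e12

    base = objective(theta)
    if not np.isfinite(base) or base >= 1e12:
        return None
    # two polish passes: a coarse finite-difference step first (robust far
    # from the optimum), then a fine step for the last digits
    best = base
    for rel_step in (1e-5, 1e-7):
        try:
            res = optimize.minimize(
                objective,
                theta,
                method="L-BFGS-B",
                options={
                    "maxiter": 200,
                    "maxfun": 5000,
                    "finite_diff_rel_step": rel_step,
                },
            )
        except Exception:
            break  # polish is best-effort; EM solution stands
        if np.isfinite(res.fun) and res.fun < best - 1e-12:
            theta = res.x
            best = float(res.fun)
            trace.append(-0.5 * best)
    if len(theta) == 1:  # scalar problems allow an essentially exact solve
        try:
            res = optimize.minimize_scalar(
                lambda z: objective(np.array([z])),
                bracket=(theta[0] - 0.5, theta[0], theta[0] + 0.5),
                method="brent",
                options={"xtol": 1e-12},
            )
            if np.isfinite(res.fun) and res.fun <= best:
                theta = np.array([res.x])
                best = float(res.fun)
                trace.append(-0.5 * best)
        except ValueError:
            pass
    return theta, trace, status


def _failed_fit(spec, method, message) -> LMMFit:
    q = spec.random.n_columns if spec.random is not None else 0
    return LMMFit(
        spec=spec,
        beta=pd.Series(dtype=float),
        beta_se=pd.Series(dtype=float),
        G=pd.DataFrame(np.zeros((q, q))),
        sigma2=np.nan,
        phi=None,
        loglik=np.nan,
        n_params=0,
        converged="error",
        message=message,
        n_subjects=0,
        n_obs=0,
        method=method,
    )


def _assemble(spec, method, data, extra, neg2, n_params, status, message, trace) -> LMMFit:
    beta_s, sigma2, phi, A, XtWX = extra
    beta = beta_s / data.x_scale
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    beta_se = np.sqrt(np.diag(cov_beta)) / data.x_scale
    if data.q:
        G = sigma2 * (A / np.outer(data.z_scale, data.z_scale))
    else:
        G = np.zeros((0, 0))
    return LMMFit(
        spec=spec,
        beta=pd.Series(beta, index=data.x_names),
        beta_se=pd.Series(beta_se, index=data.x_names),
        G=pd.DataFrame(G, index=data.z_names, columns=data.z_names),
        sigma2=float(sigma2),
        phi=float(phi) if spec.correlation == "car1" else None,
        loglik=-0.5 * float(neg2),
        n_params=n_params,
        converged=status,
        message=message,
        n_subjects=data.n_subjects,
        n_obs=data.n_obs,
        method=method,
        loglik_trace=[float(t) for t in trace],
    )


def blups(fit: LMMFit, table: pd.DataFrame, response: str = "log_bmi") -> pd.DataFrame:
    """Best linear unbiased predictors of the subject random effects.

    b_i = G Z_i' V_i^{-1} (y_i - X_i beta) with V_i = Z_i G Z_i' +
    sigma^2 C_i(phi); shrinks toward zero for sparsely observed subjects.
    Returns one row per subject indexed by ``iid``.
    """
    if not fit.ok:
        raise ValueError(f"cannot compute BLUPs from a fit with status {fit.converged}")
    data = _BlockData(table, fit.spec, response)
    q = data.q
    out = np.zeros((data.n_subjects, q))
    if q == 0:
        return pd.DataFrame(out, index=pd.Index(data.subject_ids, name="iid"))
    G = fit.G.values
    Gs = G * np.outer(data.z_scale, data.z_scale)  # G on scaled-Z coordinates
    beta_s = fit.beta.values * data.x_scale
    phi = fit.phi if fit.phi is not None else 0.0
    for g in data.groups:
        X, Z, y = g["X"], g["Z"], g["y"]
        m, n, _ = X.shape
        C = phi ** g["gaps"] if phi else np.broadcast_to(np.eye(n), (m, n, n))
        V = fit.sigma2 * C + np.einsum("mnq,qr,mkr->mnk", Z, Gs, Z, optimize=True)
        r = y - X @ beta_s
        Vinv_r = np.linalg.solve(V, r[:, :, None])[:, :, 0]
        b_scaled = np.einsum("qr,mnr,mn->mq", Gs, Z, Vinv_r, optimize=True)
        out[g["subjects"]] = b_scaled / data.z_scale
    return pd.DataFrame(
        out, index=pd.Index(data.subject_ids, name="iid"), columns=data.z_names
    )


def diagnostics(
    fit: LMMFit, table: pd.DataFrame, response: str = "log_bmi"
) -> FitDiagnostics:
    """Model-quality summaries: AIC/BIC, conditional RMSE, ICC, R-squared.

    R-squared follows the variance-partition convention for mixed models:
    marginal = fixed-curve variance over total; conditional adds the
    trace-averaged random-effect variance to the numerator.  ICC uses the
    intercept variance only (the age-zero formula), a deliberate
    single-number simplification when slopes are random.
    """
    if not fit.ok:
        raise ValueError(f"cannot compute diagnostics for status {fit.converged}")
    aic = -2.0 * fit.loglik + 2 * fit.n_params
    bic = -2.0 * fit.loglik + np.log(fit.n_obs) * fit.n_params

    data = _BlockData(table, fit.spec, response)
    b = blups(fit, table, response=response)
    fixed_parts = []
    resid_parts = []
    rand_var_parts = []
    for g in data.groups:
        X, Z, y = g["X"], g["Z"], g["y"]
        xb = X @ (fit.beta.values * data.x_scale)
        fitted = xb
        if data.q:
            bs = b.values[g["subjects"]] * data.z_scale
            fitted = xb + np.einsum("mnq,mq->mn", Z, bs)
            Gs = fit.G.values * np.outer(data.z_scale, data.z_scale)
            rand_var_parts.append(np.einsum("mnq,qr,mnr->mn", Z, Gs, Z).ravel())
        fixed_parts.append(xb.ravel())
        resid_parts.append((y - fitted).ravel())
    xb_all = np.concatenate(fixed_parts)
    resid = np.concatenate(resid_parts)
    var_fixed = float(np.var(xb_all))
    var_rand = float(np.mean(np.concatenate(rand_var_parts))) if rand_var_parts else 0.0
    total = var_fixed + var_rand + fit.sigma2
    g00 = float(fit.G.values[0, 0]) if data.q else 0.0
    return FitDiagnostics(
        aic=float(aic),
        bic=float(bic),
        rmse=float(np.sqrt(np.mean(resid**2))),
        residual_sd=float(np.sqrt(fit.sigma2)),
        icc=g00 / (g00 + fit.sigma2),
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_rand) / total,
    )
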