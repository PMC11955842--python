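"""Internal REML machinery for Gaussian linear mixed models.

Two fitters cover the package's needs:

* :func:`spectral_reml_two` — the classic two-variance-component model
  ``y = X b + g + e`` with ``cov(g) = s2_g * H`` for an arbitrary PSD matrix
  ``H`` (typically ``Z K Z'`` for a GRM K). The REML criterion is profiled
  down to the single ratio ``delta = s2_e / s2_g`` after one eigendecomposition
  of H, then optimized in log space (the EMMA trick).

* :func:`ai_reml` — arbitrary variance-component models
  ``V = sum_k s2_k Z_k K_k Z_k' + s2_e I`` fitted by average-information
  REML with step-halving, so the recorded restricted log-likelihood trace is
  non-decreasing. Component variances are kept above a small floor rather
  than allowed to go negative.

Standard errors of variance components come from the inverse
average-information matrix at convergence; both fitters report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize


@dataclass
class VarianceComponents:
    """Named REML variance-component estimates with uncertainty and fit trace."""

    variances: dict[str, float]
    loglik: float
    se: dict[str, float] = field(default_factory=dict)
    trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_records: int = 0

    def heritability(self, genetic: str = "polygenic", residual: str = "residual") -> float:
        g = self.variances[genetic]
        e = self.variances[residual]
        return g / (g + e) if (g + e) > 0 else float("nan")


def _reml_loglik_from_rotated(delta: float, s: np.ndarray, ystar: np.ndarray,
                              xstar: np.ndarray) -> tuple[float, float]:
    """Profiled restricted log-likelihood for V = s2_g (H + delta I).

    Returns (loglik, s2_g_hat). ``s`` are eigenvalues of H; ystar/xstar are
    rotated into H's eigenbasis.
    """
    n, p = xstar.shape
    w = s + delta
    xtwx = xstar.T @ (xstar / w[:, None])
    xtwy = xstar.T @ (ystar / w)
    beta = linalg.solve(xtwx, xtwy, assume_a="pos")
    resid = ystar - xstar @ beta
    quad = float((resid**2 / w).sum())
    s2g = quad / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * s2g)
        + np.log(w).sum()
        + logdet_xtwx
        + (n - p)
    )
    return float(ll), float(s2g)


def spectral_reml_two(y: np.ndarray, X: np.ndarray, H: np.ndarray,
                      *, genetic: str = "polygenic", residual: str = "residual",
                      ridge: float = 0.0) -> VarianceComponents:
    """REML for ``y = Xb + g + e`` with ``cov(g) = s2_g H``, via eigenrotation."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows must match y")
    if ridge:
        H = H + ridge * np.eye(n)
    s, U = linalg.eigh(H)
    s = np.clip(s, 0.0, None)
    ystar = U.T @ y
    xstar = U.T @ X

    def neg(log_delta: float) -> float:
        ll, _ = _reml_loglik_from_rotated(10.0**log_delta, s, ystar, xstar)
        return -ll

    res = optimize.minimize_scalar(neg, bounds=(-8.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    delta = 10.0**res.x
    ll, s2g = _reml_loglik_from_rotated(delta, s, ystar, xstar)
    s2e = s2g * delta
    # boundary handling: deltas at the box edge mean one component ~ 0
    variances = {genetic: s2g, residual: s2e}

    # numerical observed information on (s2g, s2e) for SEs
    def ll_of(v):
        return _full_ll(max(v[0], 1e-12), max(v[1], 1e-12))

    def _full_ll(vg, ve):
        w = vg * s + ve
        xtwx = xstar.T @ (xstar / w[:, None])
        beta = linalg.solve(xtwx, xstar.T @ (ystar / w), assume_a="pos")
        resid = ystar - xstar @ beta
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        return float(-0.5 * (np.log(w).sum() + logdet_xtwx
                             + (resid**2 / w).sum()
                             + (n - X.shape[1]) * np.log(2 * np.pi)))

    se = _numeric_se(ll_of, np.array([s2g, s2e]))
    return VarianceComponents(
        variances=variances, loglik=ll, n_records=n,
        se={genetic: se[0], residual: se[1]}, trace=[ll],
    )


def _numeric_se(f, theta: np.ndarray) -> np.ndarray:
    """SEs from a central-difference Hessian of a log-likelihood."""
    k = theta.size
    h = np.maximum(1e-4 * np.abs(theta), 1e-6)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


# ---------------------------------------------------------------------------
# general multi-component AI-REML
# ---------------------------------------------------------------------------

@dataclass
class RandomEffect:
    """One variance component: cov contribution s2 * Z K Z' (K=None -> identity)."""

    name: str
    Z: np.ndarray
    K: np.ndarray | None = None

    def apply(self, M: np.ndarray) -> np.ndarray:
        """Compute (Z K Z') @ M without forming the n x n matrix."""
        t = self.Z.T @ M
        if self.K is not None:
            t = self.K @ t
        return self.Z @ t

    def full(self, n: int) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


def ai_reml(y: np.ndarray, X: np.ndarray, effects: list[RandomEffect],
            *, max_iter: int = 200, tol: float = 1e-6,
            residual_name: str = "residual") -> VarianceComponents:
    """Average-information REML with a monotone (accept-only) likelihood trace.

    Fits ``V = sum_k s2_k Z_k K_k Z_k' + s2_e I``. Starts from an equal split
    of the phenotypic variance, takes AI steps with step-halving whenever the
    restricted log-likelihood would decrease, and floors variances at
    ``1e-8 * var(y)``. Raises on non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("zero-variance response")
    names = [e.name for e in effects] + [residual_name]
    k = len(names)
    Vk_full = [e.full(n) for e in effects] + [np.eye(n)]
    theta = np.full(k, vary / k)
    floor = 1e-8 * vary

    def criterion(th: np.ndarray):
        V = sum(t * Vf for t, Vf in zip(th, Vk_full))
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return None
        Vinv = linalg.cho_solve((c, low), np.eye(n))
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        XtViX = X.T @ Vinv @ X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        XtViX_inv = np.linalg.inv(XtViX)
        Viy = Vinv @ y
        ViX = Vinv @ X
        Py = Viy - ViX @ (XtViX_inv @ (X.T @ Viy))
        yPy = float(y @ Py)
        ll = -0.5 * (logdet_v + logdet_x + yPy + (n - X.shape[1]) * np.log(2 * np.pi))
        return ll, Vinv, ViX, XtViX_inv, Py

    state = criterion(theta)
    if state is None:
        raise RuntimeError("initial covariance not positive definite")
    ll = state[0]
    trace = [ll]
    converged = False
    AI = np.eye(k)
    for _ in range(max_iter):
        ll, Vinv, ViX, XtViX_inv, Py = state
        # gradient: dl/ds2_k = -0.5 [tr(P Vk) - y' P Vk P y], with
        # tr(P Vk) = tr(Vinv Vk) - tr(XtViX_inv X'Vinv Vk Vinv X) and
        # y' P Vk P y = (Py)' Vk (Py)
        grad = np.empty(k)
        PVky = []
        for i, Vf in enumerate(Vk_full):
            w = Vf @ Py
            PVky.append(w)
            grad[i] = -0.5 * (
                float(np.einsum("ij,ji->", Vinv, Vf))
                - float(np.einsum("ij,ji->", XtViX_inv, ViX.T @ Vf @ ViX))
                - float(Py @ w)
            )
        AI = np.empty((k, k))
        Pw = [_apply_P(w, Vinv, ViX, XtViX_inv, X) for w in PVky]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(PVky[i] @ Pw[j])
        if np.linalg.norm(grad) < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            step = grad / max(np.diag(AI).max(), 1.0)
        improved = False
        for _half in range(30):
            cand = np.maximum(theta + step, floor)
            new_state = criterion(cand)
            if new_state is not None and new_state[0] >= ll - 1e-12:
                improved = new_state[0] > ll + tol * 1e-3
                theta = cand
                state = new_state
                trace.append(new_state[0])
                break
            step *= 0.5
        else:
            converged = True  # cannot improve further; treat as converged
            break
        if not improved:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"AI-REML failed to converge; trace={trace[-5:]}")
    ll = state[0]
    try:
        cov = np.linalg.inv(AI)
        d = np.diag(cov)
        se = dict(zip(names, np.sqrt(np.where(d > 0, d, np.nan))))
    except np.linalg.LinAlgError:
        se = {nm: float("nan") for nm in names}
    return VarianceComponents(
        variances=dict(zip(names, theta.tolist())), loglik=float(ll),
        se=se, trace=trace, converged=True, n_records=n,
    )


def _apply_P(v: np.ndarray, Vinv: np.ndarray, ViX: np.ndarray,
             XtViX_inv: np.ndarray, X: np.ndarray) -> np.ndarray:
    return Vinv @ v - ViX @ (XtViX_inv @ (X.T @ (Vinv @ v)))


def assemble_covariance(effects: list[RandomEffect], variances: dict[str, float],
                        n: int, residual_name: str = "residual") -> np.ndarray:
    """Build the fitted n x n phenotypic covariance from components."""
    V = variances[residual_name] * np.eye(n)
    for e in effects:
        V += variances[e.name] * e.full(n)
    return V
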