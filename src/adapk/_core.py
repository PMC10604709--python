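"""Internal vectorized likelihood machinery.

Everything here operates on padded per-cohort arrays so that inner
(empirical-Bayes) Newton solves and outer marginal-likelihood evaluations are
batched across subjects with plain numpy.  The dose/observation time tensors
and the absorption exponentials are precomputed per cohort (the absorption
constant is fixed in every fit this package runs), and the gradient of the
joint individual log-likelihood with respect to the random effects is
analytic; only the 2x2 curvature uses finite differences of that gradient.
Public modules wrap these routines with the domain-level API; nothing in here
is part of the package surface.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import _kernels
from .structural import KA_KE_SWITCH

_LOG_2PI = math.log(2.0 * math.pi)

# numerical knobs: inner Newton gradient tolerance, FD steps, Hessian floor
EBE_GTOL = 1e-8
EBE_SOFT_GTOL = 1e-5
HESS_FLOOR = 1e-10
_SD_FLOOR = 1e-12


class CohortArrays:
    """Padded array view of a cohort for batched likelihood work.

    Padding convention: dose slots beyond a subject's history carry amount 0
    (zero contribution); observation slots beyond a subject's count are masked
    out of every sum.  ``lik_mask`` additionally excludes held-out
    observations when ``use_held_out=False``.
    """

    def __init__(self, cohort, use_held_out: bool = True):
        subjects = list(cohort)
        self.ids = [s.id for s in subjects]
        self.n = len(subjects)
        m = max((s.n_obs for s in subjects), default=0)
        d = max((len(s.doses) for s in subjects), default=0)
        self.t = np.zeros((self.n, m))
        self.y = np.zeros((self.n, m))
        self.obs_mask = np.zeros((self.n, m), dtype=bool)
        self.held_mask = np.zeros((self.n, m), dtype=bool)
        self.dose_t = np.zeros((self.n, d))
        self.dose_a = np.zeros((self.n, d))
        self.alb = np.empty(self.n)
        self.aaa = np.empty(self.n)
        self.extra: dict[str, np.ndarray] = {}

        extra_keys = sorted({k for s in subjects for k in s.covariates})
        for k in extra_keys:
            self.extra[k] = np.empty(self.n)

        for i, s in enumerate(subjects):
            if s.albumin is None or s.aaa is None:
                raise ValueError(f"subject {s.id}: covariates missing; impute first")
            self.alb[i] = s.albumin
            self.aaa[i] = s.aaa
            for k in extra_keys:
                if k not in s.covariates:
                    raise ValueError(f"subject {s.id}: missing covariate {k!r}")
                self.extra[k][i] = s.covariates[k]
            for j, o in enumerate(s.observations):
                self.t[i, j] = o.time
                self.y[i, j] = o.concentration
                self.obs_mask[i, j] = True
                self.held_mask[i, j] = o.held_out
            for j, dose in enumerate(s.doses):
                self.dose_t[i, j] = dose.time
                self.dose_a[i, j] = dose.amount

        if use_held_out:
            self.lik_mask = self.obs_mask.copy()
        else:
            self.lik_mask = self.obs_mask & ~self.held_mask
        self.n_lik_obs = int(self.lik_mask.sum())
        self._ka: float | None = None

    def _prep(self, ka: float) -> None:
        """Cache the ka-dependent dose tensors (ka is fixed within a fit)."""
        if self._ka == ka:
            return
        tau = self.t[:, :, None] - self.dose_t[:, None, :]  # (n, m, d)
        active = (tau >= 0) & (self.dose_a[:, None, :] > 0)
        self._tau = np.ascontiguousarray(np.where(active, tau, 0.0))
        self._amt = np.ascontiguousarray(np.where(active, self.dose_a[:, None, :], 0.0))
        self._e_ka = np.exp(-ka * self._tau)
        self._lik_u8 = np.ascontiguousarray(self.lik_mask.astype(np.uint8))
        self._ka = ka

    def conc(self, cl: np.ndarray, v: np.ndarray, ka: float, grad: bool = False):
        """Concentrations (n, m) at the observation times; optionally the
        derivatives with respect to the log-scale random effects.

        ``grad=True`` additionally returns ``df/d(eta_cl)`` and
        ``df/d(eta_v)`` where ``cl = cl_typ*exp(eta_cl)``,
        ``v = v_pop*exp(eta_v)``.
        """
        self._prep(ka)
        tau, amt, e_ka = self._tau, self._amt, self._e_ka
        ke = cl / v
        delta = ka - ke[:, None, None]
        near = np.abs(delta) < KA_KE_SWITCH * ka
        safe = np.where(near, ka, delta)
        with np.errstate(over="ignore", invalid="ignore"):
            em1 = np.expm1(safe * tau)
            u = np.where(near, ka * tau * e_ka, (ka / safe) * e_ka * em1)
            f = np.einsum("nmd,nmd->nm", u, amt) / v[:, None]
            if not grad:
                return f
            # du/dke = ka*(h/delta^2 - tau*e^{-ke tau}/delta), h = e_ka*em1
            dudke = ka * (e_ka * em1 / safe**2 - tau * e_ka * (em1 + 1.0) / safe)
            dudke = np.where(near, -0.5 * ka * tau**2 * e_ka, dudke)
            s = np.einsum("nmd,nmd->nm", dudke, amt) / v[:, None]
        ke_col = ke[:, None]
        df_dcl = ke_col * s  # d f / d eta_cl
        df_dv = -f - ke_col * s  # d f / d eta_v
        return f, df_dcl, df_dv


def typical_cl(pop, arr: CohortArrays, extra_effects=()) -> np.ndarray:
    """Covariate-adjusted typical clearance per subject, shape (n,)."""
    cl = (
        pop.cl_pop
        * (1.0 + arr.aaa * pop.cov_aaa)
        * (arr.alb / pop.m_alb) ** pop.cov_alb
    )
    for eff in extra_effects:
        x = arr.extra[eff.covariate]
        if eff.form == "power":
            center = eff.center if eff.center is not None else 1.0
            cl = cl * (x / center) ** eff.value
        elif eff.form == "proportional":
            cl = cl * (1.0 + eff.value * x)
        else:  # pragma: no cover - validated upstream
            raise ValueError(f"unknown covariate form {eff.form!r}")
    return cl


def _individual_cl_v(pop, arr, eta, extra_effects):
    with np.errstate(over="ignore"):
        cl = typical_cl(pop, arr, extra_effects) * np.exp(eta[:, 0])
        v = pop.v_pop * np.exp(eta[:, 1])
    return cl, v


def predict(arr: CohortArrays, pop, eta: np.ndarray, times=None, extra_effects=()):
    """Individual predictions at ``times`` (default: the observation times)."""
    cl, v = _individual_cl_v(pop, arr, eta, extra_effects)
    if times is None:
        return arr.conc(cl, v, pop.ka_pop)
    from .structural import profile

    return profile(cl, v, pop.ka_pop, arr.dose_t, arr.dose_a, times)


def neg_loglik(arr: CohortArrays, pop, eta: np.ndarray, extra_effects=()) -> np.ndarray:
    """Per-subject negative joint log-likelihood, shape (n,).

    Data term: Gaussian with SD ``err_add + err_prop * f`` over the
    likelihood-visible observations, plus the eta prior under
    N(0, diag(omega^2)).  The residual SD is floored at 1e-12 so extreme
    trial etas produce a huge finite penalty instead of an error.
    """
    return _nll(arr, pop, eta, extra_effects, grad=False)


def nll_grad(arr: CohortArrays, pop, eta: np.ndarray, extra_effects=()):
    """Negative joint log-likelihood, analytic eta-gradient and the
    expected-information (Gauss-Newton) 2x2 curvature.

    The curvature is ``sum_j (1 + 2 b^2) (df_j)(df_j)^T / sd_j^2 + Omega^{-1}``
    -- the expected negative Hessian of the joint log-density for a Gaussian
    observation whose mean and SD both depend on eta through ``f`` (``sd' =
    b f'``).  It is positive definite by construction (at least the eta-prior
    precision), which keeps Newton steps and the Laplace log-determinant
    stable even where the observed Hessian loses rank.
    """
    return _nll(arr, pop, eta, extra_effects, grad=True)


def _nll(arr, pop, eta, extra_effects, grad):
    cl, v = _individual_cl_v(pop, arr, eta, extra_effects)
    if _kernels.HAVE_NUMBA:
        arr._prep(pop.ka_pop)
        out, g, H = _kernels.nll_kernel(
            arr._tau, arr._amt, arr._e_ka, arr.y, arr._lik_u8,
            cl, v, pop.ka_pop, pop.err_add, pop.err_prop,
            np.ascontiguousarray(eta), pop.omega_cl, pop.omega_v,
            1 if grad else 0,
        )
        return (out, g, H) if grad else out
    mask = arr.lik_mask
    if grad:
        f, df1, df2 = arr.conc(cl, v, pop.ka_pop, grad=True)
    else:
        f = arr.conc(cl, v, pop.ka_pop)
    sd = np.where(mask, np.maximum(pop.err_add + pop.err_prop * f, _SD_FLOOR), 1.0)
    z = np.where(mask, (arr.y - f) / sd, 0.0)
    with np.errstate(invalid="ignore"):
        data = np.sum(np.where(mask, 0.5 * _LOG_2PI + np.log(sd) + 0.5 * z * z, 0.0), axis=1)
    w_cl, w_v = pop.omega_cl, pop.omega_v
    prior = (
        _LOG_2PI
        + math.log(w_cl)
        + math.log(w_v)
        + 0.5 * (eta[:, 0] / w_cl) ** 2
        + 0.5 * (eta[:, 1] / w_v) ** 2
    )
    out = data + prior
    out = np.where(np.isfinite(out), out, 1e300)
    if not grad:
        return out
    # d nll / d f per observation: b/sd - z(1 + z b)/sd
    b = pop.err_prop
    w = np.where(mask, (b - z * (1.0 + z * b)) / sd, 0.0)
    g = np.empty_like(eta)
    g[:, 0] = np.sum(w * df1, axis=1) + eta[:, 0] / w_cl**2
    g[:, 1] = np.sum(w * df2, axis=1) + eta[:, 1] / w_v**2
    g = np.where(np.isfinite(g), g, 0.0)
    # expected information (Gauss-Newton) curvature
    w2 = np.where(mask, (1.0 + 2.0 * b * b) / (sd * sd), 0.0)
    H = np.empty((eta.shape[0], 2, 2))
    H[:, 0, 0] = np.sum(w2 * df1 * df1, axis=1) + 1.0 / w_cl**2
    H[:, 1, 1] = np.sum(w2 * df2 * df2, axis=1) + 1.0 / w_v**2
    H[:, 0, 1] = H[:, 1, 0] = np.sum(w2 * df1 * df2, axis=1)
    H = np.where(np.isfinite(H), H, 0.0)
    return out, g, H


def _observed_hessian(grad_fun, eta, g0, h=1e-6):
    """Batched 2x2 observed Hessian by forward differences of the gradient."""
    n = eta.shape[0]
    H = np.empty((n, 2, 2))
    for k in range(2):
        hk = h * np.maximum(1.0, np.abs(eta[:, k]))
        ep = eta.copy()
        ep[:, k] += hk
        _, gp, _ = grad_fun(ep)
        H[:, k, :] = (gp - g0) / hk[:, None]
    return 0.5 * (H + H.transpose(0, 2, 1))


def _eig2x2(H):
    """Eigenvalues of symmetric 2x2 batch, shape (n, 2) ascending."""
    tr = H[:, 0, 0] + H[:, 1, 1]
    det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
    disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    return np.stack([tr / 2 - disc, tr / 2 + disc], axis=1)


def _solve2x2(H, b):
    """Solve H @ s = b for batched 2x2 H after PD regularization."""
    eig = _eig2x2(H)
    floor = np.maximum(1e-6 * np.abs(eig[:, 1]), 1e-8)
    shift = np.maximum(floor - eig[:, 0], 0.0)
    a = H[:, 0, 0] + shift
    c = H[:, 1, 1] + shift
    bb = H[:, 0, 1]
    det = a * c - bb * bb
    s = np.empty_like(b)
    s[:, 0] = (c * b[:, 0] - bb * b[:, 1]) / det
    s[:, 1] = (a * b[:, 1] - bb * b[:, 0]) / det
    return s


# deterministic restart grid (in units of omega) for stubborn subjects
_RESTARTS = [(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0),
             (1.0, 1.0), (-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0)]


def solve_ebes(
    arr: CohortArrays,
    pop,
    eta0: np.ndarray | None = None,
    extra_effects=(),
    gtol: float = EBE_GTOL,
    max_iter: int = 60,
):
    """Batched damped-Newton maximization of the joint individual likelihood.

    Returns ``(eta, nll, grad, hess, converged)`` where ``hess`` is the
    expected-information (Gauss-Newton) curvature at the mode -- the Laplace
    curvature in the FOCE convention -- and ``converged`` is a per-subject
    bool (analytic gradient inf-norm below ``gtol``, or Newton decrement at
    floating-point resolution, after the deterministic restart grid).
    """

    if _kernels.HAVE_NUMBA:
        arr._prep(pop.ka_pop)
        cl_typ = np.ascontiguousarray(typical_cl(pop, arr, extra_effects))
        start = (
            np.zeros((arr.n, 2))
            if eta0 is None
            else np.ascontiguousarray(np.asarray(eta0, dtype=float))
        )
        eta, f, g, H, done8 = _kernels.ebe_solve_kernel(
            arr._tau, arr._amt, arr._e_ka, arr.y, arr._lik_u8,
            cl_typ, pop.v_pop, pop.ka_pop, pop.err_add, pop.err_prop,
            pop.omega_cl, pop.omega_v, start, gtol, max_iter,
        )
        return eta, f, g, H, done8.astype(bool)

    def fval(e):
        return _nll(arr, pop, e, extra_effects, grad=False)

    def fgrad(e):
        return _nll(arr, pop, e, extra_effects, grad=True)

    def decrement(g, H):
        # Newton decrement^2: ~2x the distance to the optimum in nll units
        return np.einsum("ij,ij->i", g, _solve2x2(H, g))

    def run(eta_start):
        eta = eta_start.copy()
        stalled = np.zeros(arr.n, dtype=bool)
        f, g, H = fgrad(eta)
        for it in range(max_iter):
            # stop per subject on gradient norm, or on the Newton decrement
            # where floating point cannot resolve the gradient tolerance
            # (e.g. omega -> 0 collapse)
            active = (
                (np.max(np.abs(g), axis=1) >= gtol)
                & (decrement(g, H) >= 1e-10 * (1.0 + np.abs(f)))
                & ~stalled
            )
            if not active.any():
                break
            H_step = H
            if it >= 15:
                # stragglers where the expected information is a poor local
                # curvature model: switch to observed-Hessian steps
                # (quadratic convergence; _solve2x2 regularizes indefiniteness)
                H_step = _observed_hessian(fgrad, eta, g)
            step = _solve2x2(H_step, -g)
            # trust-region style cap: etas live within a few omegas of zero
            norm = np.linalg.norm(step, axis=1)
            step *= np.where(norm > 5.0, 5.0 / np.maximum(norm, 1e-300), 1.0)[:, None]
            descent = np.einsum("ij,ij->i", g, step)
            alpha = np.where(active, 1.0, 0.0)
            improved = ~active
            for _ in range(30):
                trial = eta + alpha[:, None] * step
                ft = fval(trial)
                ok = active & ~improved & (ft <= f + 1e-4 * alpha * descent)
                eta = np.where(ok[:, None], trial, eta)
                improved |= ok
                alpha = np.where(improved, alpha, alpha / 2)
                if improved.all():
                    break
            # a subject whose line search cannot improve sits at its
            # numerical optimum; freeze it rather than spin
            stalled |= active & ~improved
            f, g, H = fgrad(eta)
        return eta, f, g, H

    def is_done(f, g, H):
        gnorm = np.max(np.abs(g), axis=1)
        return (gnorm < max(gtol, EBE_SOFT_GTOL)) | (
            decrement(g, H) < 1e-10 * (1.0 + np.abs(f))
        )

    eta = np.zeros((arr.n, 2)) if eta0 is None else np.asarray(eta0, dtype=float).copy()
    eta, f, g, H = run(eta)
    done = is_done(f, g, H)

    if not done.all():
        scale = np.array([pop.omega_cl, pop.omega_v])
        for r in _RESTARTS:
            if done.all():
                break
            eta_try = eta.copy()
            eta_try[~done] = np.asarray(r) * scale
            eta2, f2, g2, H2 = run(eta_try)
            better = ~done & (f2 < f)
            eta = np.where(better[:, None], eta2, eta)
            f = np.where(better, f2, f)
            g = np.where(better[:, None], g2, g)
            H = np.where(better[:, None, None], H2, H)
            done = is_done(f, g, H)

    return eta, f, g, H, done


# Gauss-Hermite nodes per dimension for the marginal-likelihood integral;
# 1 reproduces the pure Laplace approximation
N_QUAD = 5


def laplace_terms(arr: CohortArrays, pop, eta0=None, extra_effects=(), n_quad=None):
    """Per-subject -2 log marginal likelihood contributions.

    Laplace-type approximation refined by adaptive Gauss-Hermite quadrature:
    the integral over each subject's random effects is evaluated on an
    ``n_quad x n_quad`` Hermite grid centered at the joint mode and scaled by
    the expected-information curvature.  ``n_quad=1`` is exactly the Laplace
    approximation (OFV_i = 2 nll_i + log det H_i - 2 log 2 pi); the default
    grid integrates the skewness of the individual posteriors that plain
    Laplace misses under large IIV with a proportional error model.
    """
    n_quad = N_QUAD if n_quad is None else int(n_quad)
    eta, f, g, H, conv = solve_ebes(arr, pop, eta0, extra_effects)
    eig = _eig2x2(H)
    if np.any(eig[:, 0] <= HESS_FLOOR):
        warnings.warn(
            "non-positive-definite individual curvature regularized in Laplace term",
            RuntimeWarning,
            stacklevel=2,
        )
        shift = np.maximum(HESS_FLOOR - eig[:, 0], 0.0)
        H = H + shift[:, None, None] * np.eye(2)

    z, w = np.polynomial.hermite.hermgauss(n_quad)
    if _kernels.HAVE_NUMBA:
        arr._prep(pop.ka_pop)
        cl_typ = np.ascontiguousarray(typical_cl(pop, arr, extra_effects))
        ofv_i = _kernels.agq_kernel(
            arr._tau, arr._amt, arr._e_ka, arr.y, arr._lik_u8,
            cl_typ, pop.v_pop, pop.ka_pop, pop.err_add, pop.err_prop,
            pop.omega_cl, pop.omega_v, eta, H,
            np.ascontiguousarray(z), np.ascontiguousarray(w),
        )
        return ofv_i, eta, conv

    # numpy fallback: batched evaluation over the Hermite grid
    det = np.maximum(H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2, 1e-300)
    s00 = np.maximum(H[:, 1, 1] / det, 1e-300)
    s01 = -H[:, 0, 1] / det
    s11 = H[:, 0, 0] / det
    l00 = np.sqrt(s00)
    l10 = s01 / l00
    l11 = np.sqrt(np.maximum(s11 - l10**2, 1e-300))
    vals = np.empty((n_quad * n_quad, arr.n))
    logw = np.empty(n_quad * n_quad)
    idx = 0
    for j in range(n_quad):
        for k in range(n_quad):
            z0, z1 = z[j], z[k]
            e = np.empty_like(eta)
            e[:, 0] = eta[:, 0] + math.sqrt(2.0) * l00 * z0
            e[:, 1] = eta[:, 1] + math.sqrt(2.0) * (l10 * z0 + l11 * z1)
            nll = _nll(arr, pop, e, extra_effects, grad=False)
            vals[idx] = -nll + z0 * z0 + z1 * z1
            logw[idx] = math.log(w[j] * w[k])
            idx += 1
    s = vals + logw[:, None]
    m = s.max(axis=0)
    acc = np.exp(s - m).sum(axis=0)
    ofv_i = -2.0 * (m + np.log(acc) + np.log(2.0 * l00 * l11))
    ofv_i = np.where(np.isfinite(ofv_i), ofv_i, 1e300)
    return ofv_i, eta, conv
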