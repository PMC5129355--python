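"""Penalized IWLS estimation with REML variance components.

Both response models share one engine:

* binary logit  ``P(y = 1) = F(gamma0 + w)``  (y = 1 is the detrimental,
  low-weight outcome);
* cumulative (proportional-odds) logit  ``P(y <= j) = F(theta_j - w)``
  for ordered categories ``1..K``.

``w`` is the structured additive predictor: effect-coded fixed effects,
centered P-spline smooths and centered structured/unstructured region
effects.  Every penalized term is rewritten in mixed-model form (penalty
null space -> unpenalized columns, whitened range space -> an i.i.d.
random-effect block), so each smoothing parameter becomes a variance
component ``tau2`` estimated by an EM-type REML update on the working
model.  A positive coefficient therefore always moves probability mass
toward *higher* outcome categories in the cumulative model, and raises
``P(y = 1)`` in the binary model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .design import DesignBlocks, ModelSpec, build_design
from .exceptions import DataError, NumericsError
from .summaries import information_criteria
from .synthetic import OrdinalDataset

__all__ = [
    "FitOptions",
    "FitResult",
    "MixedParts",
    "TermEffect",
    "effective_df",
    "fit_binary",
    "fit_cumulative",
    "reml_step",
    "reparameterize",
]


# ---------------------------------------------------------------------------
# mixed-model reparameterization
# ---------------------------------------------------------------------------


@dataclass
class MixedParts:
    """Spectral split of a penalized term into unpenalized + whitened parts.

    ``X_unpen`` spans the penalty null space, ``Z_pen`` carries an exact
    identity penalty.  ``T_unpen`` / ``T_pen`` map block coefficients back
    to the term's original coefficient scale:
    ``c = T_unpen @ a + T_pen @ b``.
    """

    X_unpen: np.ndarray
    Z_pen: np.ndarray
    T_unpen: np.ndarray
    T_pen: np.ndarray


def reparameterize(basis: np.ndarray, penalty: np.ndarray) -> MixedParts:
    """Split ``basis`` according to the eigenstructure of ``penalty``.

    With ``K = Gamma Lambda Gamma'``, the unpenalized block is
    ``basis @ Gamma_0`` (null space) and the penalized block
    ``basis @ Gamma_+ @ Lambda_+^{-1/2}`` whose implied penalty is the
    identity.  Raises :class:`NumericsError` if ``penalty`` is numerically
    indefinite.
    """
    penalty = np.asarray(penalty, dtype=float)
    lam, gamma = np.linalg.eigh((penalty + penalty.T) / 2.0)
    scale = max(lam.max(), 1.0)
    if lam.min() < -1e-8 * scale:
        raise NumericsError(
            f"penalty indefinite: smallest eigenvalue {lam.min():.3e}"
        )
    null = lam < 1e-9 * scale
    T_unpen = gamma[:, null]
    T_pen = gamma[:, ~null] / np.sqrt(lam[~null])
    return MixedParts(
        X_unpen=basis @ T_unpen,
        Z_pen=basis @ T_pen,
        T_unpen=T_unpen,
        T_pen=T_pen,
    )


# ---------------------------------------------------------------------------
# internal fit state
# ---------------------------------------------------------------------------


@dataclass
class _PenBlock:
    name: str
    sl: slice          # slice into psi (working parameter vector)
    q: int


@dataclass
class _TermMap:
    """Bookkeeping from working parameters back to a term's coefficients."""

    name: str
    kind: str                  # 'pspline' | 'mrf' | 'iid'
    idx: np.ndarray            # psi indices (unpen cols then pen cols)
    transform: np.ndarray      # (q_orig, len(idx))
    meta: dict


@dataclass
class FitOptions:
    """Convergence and robustness knobs (defaults are the documented ones)."""

    max_outer: int = 200
    max_inner: int = 100
    tol_outer: float = 1e-6
    tol_inner: float = 1e-8
    tau2_floor: float = 1e-8
    tau2_collapse: float = 1e-5
    tau2_ceiling: float = 1e8
    tau2_init: float = 0.1
    ridge_fallback: float = 1e-4
    separation_bound: float = 30.0  # on the linear-predictor scale


class _FitState:
    """Everything the IWLS/REML loops need; kept on the FitResult for
    oracle-style tests (``effective_df``, ``reml_step``)."""

    def __init__(self, kind, y, K, X, n_free, blocks, tau2, options, log):
        self.kind = kind
        self.y = y
        self.K = K
        self.X = X                      # (n, p) design for the beta part
        self.n_free = n_free            # leading threshold parameters (zeta)
        self.blocks = blocks            # list[_PenBlock]
        self.tau2 = dict(tau2)
        self.options = options
        self.log = log
        self.n_obs = len(y)
        self.n_params = n_free + X.shape[1]
        self.psi = np.zeros(self.n_params)
        self.ridge = 0.0                # separation fallback on unpen coefs
        self.converged = False
        self.n_outer = 0
        self.iterations = []
        if kind == "cumulative":
            # start thresholds at the empirical cumulative logits
            freq = np.bincount(y, minlength=K + 1)[1:] / self.n_obs
            cum = np.clip(np.cumsum(freq)[: K - 1], 1e-6, 1 - 1e-6)
            theta0 = np.log(cum / (1 - cum))
            theta0 = np.maximum.accumulate(theta0)
            theta0 += np.arange(K - 1) * 1e-6  # strictness guard
            self.psi[: K - 1] = _theta_to_zeta(theta0)

    # -- penalty ------------------------------------------------------------

    def penalty_diag(self) -> np.ndarray:
        d = np.zeros(self.n_params)
        for b in self.blocks:
            d[b.sl] = 1.0 / self.tau2[b.name]
        if self.ridge > 0:
            unpen = np.ones(self.n_params, dtype=bool)
            unpen[: self.n_free] = False  # thresholds stay unpenalized
            for b in self.blocks:
                unpen[b.sl] = False
            d[unpen] += self.ridge
        return d

    # -- likelihood ---------------------------------------------------------

    def loglik(self, psi=None) -> float:
        psi = self.psi if psi is None else psi
        if self.kind == "binary":
            eta = self.X @ psi
            return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        theta = _zeta_to_theta(psi[: self.K - 1])
        w = self.X @ psi[self.K - 1:]
        p = _cum_category_probs(theta, w)
        return float(np.sum(np.log(np.maximum(p[np.arange(self.n_obs),
                                                self.y - 1], 1e-300))))

    def penalized_loglik(self, psi=None) -> float:
        psi = self.psi if psi is None else psi
        d = self.penalty_diag()
        return self.loglik(psi) - 0.5 * float(psi @ (d * psi))

    def score_info(self, psi=None):
        """Gradient and expected information in the working parameterization."""
        psi = self.psi if psi is None else psi
        if self.kind == "binary":
            eta = self.X @ psi
            mu = expit(eta)
            wgt = np.maximum(mu * (1.0 - mu), 1e-12)
            grad = self.X.T @ (self.y - mu)
            info = self.X.T @ (self.X * wgt[:, None])
            return grad, info
        q = self.K - 1
        zeta = psi[:q]
        theta = _zeta_to_theta(zeta)
        w = self.X @ psi[q:]
        g_t, g_b, F_tt, F_tb, F_bb = _cum_score_info(theta, w, self.X,
                                                     self.y, self.K)
        J = _zeta_jacobian(zeta)
        grad = np.concatenate([J.T @ g_t, g_b])
        info = np.empty((self.n_params, self.n_params))
        info[:q, :q] = J.T @ F_tt @ J
        info[:q, q:] = J.T @ F_tb
        info[q:, :q] = info[:q, q:].T
        info[q:, q:] = F_bb
        return grad, info


# -- cumulative-model internals ---------------------------------------------


def _zeta_to_theta(zeta):
    """theta_1 = zeta_1; theta_j = theta_{j-1} + exp(zeta_j): ordering is
    structural, never enforced by projection."""
    theta = np.empty_like(zeta)
    theta[0] = zeta[0]
    if zeta.size > 1:
        theta[1:] = zeta[0] + np.cumsum(np.exp(zeta[1:]))
    return theta


def _theta_to_zeta(theta):
    zeta = np.empty_like(theta)
    zeta[0] = theta[0]
    if theta.size > 1:
        zeta[1:] = np.log(np.diff(theta))
    return zeta


def _zeta_jacobian(zeta):
    q = zeta.size
    J = np.zeros((q, q))
    J[:, 0] = 1.0
    for m in range(1, q):
        J[m:, m] = math.exp(zeta[m])
    return J


def _cum_category_probs(theta, w):
    cum = expit(theta[None, :] - w[:, None])
    full = np.concatenate([np.zeros((w.size, 1)), cum, np.ones((w.size, 1))],
                          axis=1)
    return np.diff(full, axis=1)


def _cum_score_info(theta, w, X, y, K):
    """Multicategorical score and expected Fisher information.

    Works on the (K-1)-dimensional indicator response per observation with
    the multinomial weight matrix; all quantities are exact expectations,
    not observed curvature.
    """
    n, q = w.size, K - 1
    G = expit(theta[None, :] - w[:, None])           # (n, q) cumulative probs
    f = G * (1.0 - G)                                # logistic densities
    p = _cum_category_probs(theta, w)                # (n, K)
    mu = np.maximum(p[:, :q], 1e-12)
    pK = np.maximum(p[:, q], 1e-12)

    d = np.zeros((n, q))
    low = y <= q
    d[np.arange(n)[low], y[low] - 1] = 1.0

    r = d - mu
    t = r / mu + (r.sum(axis=1) / pK)[:, None]       # Sigma^{-1} r
    t_pad = np.concatenate([t, np.zeros((n, 1))], axis=1)
    s = f * (t_pad[:, :q] - t_pad[:, 1:])            # D' Sigma^{-1} r

    # D_i: row j has f_j at col j, -f_{j-1} at col j-1
    D = np.zeros((n, q, q))
    ar = np.arange(q)
    D[:, ar, ar] = f
    if q > 1:
        D[:, ar[1:], ar[:-1]] = -f[:, :-1]
    Sinv = np.zeros((n, q, q))
    Sinv[:, ar, ar] = 1.0 / mu
    Sinv += (1.0 / pK)[:, None, None]
    W = np.einsum("nji,njk,nkl->nil", D, Sinv, D, optimize=True)

    grad_theta = s.sum(axis=0)
    grad_beta = -X.T @ s.sum(axis=1)
    F_tt = W.sum(axis=0)
    Wrow = W.sum(axis=2)                             # (n, q) = W_i 1
    F_tb = -(Wrow.T @ X)
    wtot = W.sum(axis=(1, 2))
    F_bb = X.T @ (X * wtot[:, None])
    return grad_theta, grad_beta, F_tt, F_tb, F_bb


# ---------------------------------------------------------------------------
# solver loops
# ---------------------------------------------------------------------------


def _solve_spd(A, b):
    try:
        return cho_solve(cho_factor(A), b)
    except Exception:
        jitter = 1e-10 * max(np.trace(A) / A.shape[0], 1.0)
        for _ in range(12):
            try:
                return cho_solve(cho_factor(A + jitter * np.eye(A.shape[0])), b)
            except Exception:
                jitter *= 10.0
    raise NumericsError("penalized information matrix is not positive definite")


def _inner_iwls(state: _FitState) -> int:
    """Fisher scoring with step-halving; penalized log-lik never decreases."""
    opt = state.options
    pll = state.penalized_loglik()
    for it in range(opt.max_inner):
        grad, info = state.score_info()
        d = state.penalty_diag()
        step = _solve_spd(info + np.diag(d), grad - d * state.psi)
        lam, accepted = 1.0, False
        for _ in range(40):
            trial = state.psi + lam * step
            pll_trial = state.penalized_loglik(trial)
            if np.isfinite(pll_trial) and pll_trial >= pll - 1e-10 * (1 + abs(pll)):
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            break
        move = float(np.max(np.abs(lam * step)))
        state.psi = trial
        pll = pll_trial
        if move < opt.tol_inner * (1.0 + float(np.max(np.abs(state.psi)))):
            return it + 1
    return opt.max_inner


def reml_step(state: _FitState) -> dict:
    """One EM-type REML update of every variance component.

    ``tau2_k <- b_k' b_k / (q_k - tr(C_kk) / tau2_k)`` with ``C`` the
    inverse penalized information of the working model at the current IWLS
    solution.  Values collapsing below the floor are clamped (the term then
    contributes its null space only) and a notice is logged.
    """
    _, info = state.score_info()
    C = np.linalg.inv(info + np.diag(state.penalty_diag()))
    opt = state.options
    new = {}
    for blk in state.blocks:
        b = state.psi[blk.sl]
        denom = blk.q - np.trace(C[blk.sl, blk.sl]) / state.tau2[blk.name]
        denom = max(denom, 1e-8)
        tau = float(b @ b) / denom
        if tau < opt.tau2_collapse:
            # geometric decay toward zero: snap to the floor instead of
            # spending dozens of outer iterations on a vanishing component
            if tau > opt.tau2_floor:
                state.log.append(
                    f"variance of {blk.name!r} collapsed below "
                    f"{opt.tau2_collapse:g}; clamped at floor "
                    f"{opt.tau2_floor:g} (effect is null-space only)"
                )
            tau = opt.tau2_floor
        new[blk.name] = min(tau, opt.tau2_ceiling)
    return new


def effective_df(state: _FitState) -> float:
    """Trace of the influence matrix ``(F + P)^{-1} F`` at convergence."""
    _, info = state.score_info()
    C = np.linalg.inv(info + np.diag(state.penalty_diag()))
    return float(np.trace(C @ info))


def _accelerate(history, tau, floor, ceiling):
    """Aitken extrapolation of slowly contracting log-variance sequences.

    The EM-type update converges geometrically, which is painfully slow on
    the ridge where a structured and an unstructured spatial variance trade
    off; two consecutive same-sign steps with a stable ratio are
    extrapolated to their geometric limit.
    """
    if len(history) < 3:
        return tau, False
    h2, h1, h0 = history[-3], history[-2], history[-1]
    jumped = False
    out = dict(tau)
    for k in tau:
        d0, d1 = h1[k] - h2[k], h0[k] - h1[k]
        if abs(d0) < 1e-12 or d0 * d1 <= 0:
            continue
        r = d1 / d0
        if 0.2 < r < 0.995:
            extra = max(min(d1 * r / (1.0 - r), 10.0), -10.0)
            out[k] = float(np.clip(math.exp(h0[k] + extra), floor, ceiling))
            jumped = True
    return out, jumped


def _outer_loop(state: _FitState, reml: bool):
    opt = state.options
    history = []
    for outer in range(opt.max_outer):
        psi_old = state.psi.copy()
        tau_old = dict(state.tau2)
        n_inner = _inner_iwls(state)
        state.n_outer = outer + 1
        state.iterations.append({
            "outer": outer + 1, "inner": n_inner,
            "penalized_loglik": state.penalized_loglik(),
            "tau2": dict(state.tau2),
        })
        if not (reml and state.blocks):
            state.converged = n_inner < opt.max_inner
            break
        new_tau = reml_step(state)
        dtau = max(
            abs(math.log(new_tau[k]) - math.log(tau_old[k]))
            for k in new_tau
        ) if new_tau else 0.0
        history.append({k: math.log(v) for k, v in new_tau.items()})
        new_tau, jumped = _accelerate(history, new_tau,
                                      opt.tau2_floor, opt.tau2_ceiling)
        if jumped:
            history.clear()
        state.tau2 = new_tau
        dpsi = float(np.max(np.abs(state.psi - psi_old))) / (
            1.0 + float(np.max(np.abs(state.psi))))
        if outer > 0 and not jumped and dpsi < opt.tol_outer \
                and dtau < opt.tol_outer:
            state.converged = True
            break
    # separation / divergence fallback: refit once with a small ridge.
    # Detection is on the predictor scale: |eta| beyond the bound means the
    # fitted probabilities have saturated (coefficient norms are meaningless
    # for whitened / null-space columns).
    if state.kind == "binary":
        eta_max = float(np.max(np.abs(state.X @ state.psi), initial=0.0))
    else:
        eta_max = float(np.max(np.abs(state.X @ state.psi[state.n_free:]),
                               initial=0.0))
    if eta_max > opt.separation_bound and state.ridge == 0.0:
        state.log.append(
            "coefficients diverging (possible complete separation); "
            f"refitting with ridge {opt.ridge_fallback:g} on unpenalized terms"
        )
        state.ridge = opt.ridge_fallback
        _inner_iwls(state)
    if not state.converged:
        state.log.append("outer loop reached iteration limit without convergence")


# ---------------------------------------------------------------------------
# public results
# ---------------------------------------------------------------------------


@dataclass
class TermEffect:
    """A penalized term on its original coefficient scale.

    ``coef``/``cov`` are the spline coefficients (pspline) or per-region
    effects (mrf/iid).  ``idx``/``transform`` allow joint operations across
    terms using the fit's full covariance.
    """

    name: str
    kind: str
    coef: np.ndarray
    cov: np.ndarray
    idx: np.ndarray
    transform: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class FitResult:
    """Estimates, uncertainties and fit criteria of one model.

    Intervals derived from ``cov`` are empirical-Bayes Wald intervals from
    the penalized information matrix ("95% intervals" throughout).
    """

    kind: str
    n_obs: int
    n_categories: int
    thresholds: Optional[np.ndarray]
    thresholds_cov: Optional[np.ndarray]
    coefficients: dict
    x_names: list
    beta: np.ndarray
    cov: np.ndarray
    terms: dict
    variance_components: dict
    minus2ll: float
    edf: float
    edf_by_term: dict
    aic: float
    bic: float
    gcv: float
    converged: bool
    n_outer: int
    iterations: list
    log: list
    state: _FitState

    @property
    def intercept(self):
        if "(intercept)" in self.x_names:
            return float(self.beta[self.x_names.index("(intercept)")])
        return None

    def fixed_table(self, level: float = 0.95):
        """Per-level estimates and Wald interval bounds, as plain records."""
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        rows = []
        if self.intercept is not None:
            i = self.x_names.index("(intercept)")
            off = 0 if self.thresholds is None else len(self.thresholds)
            se = math.sqrt(self.cov[off + i, off + i])
            rows.append(("(intercept)", "", self.intercept,
                         self.intercept - z * se, self.intercept + z * se))
        if self.thresholds is not None:
            for j, th in enumerate(self.thresholds):
                se = math.sqrt(self.thresholds_cov[j, j])
                rows.append((f"theta{j + 1}", "", float(th),
                             float(th) - z * se, float(th) + z * se))
        for name, (levels, est, cov) in self.coefficients.items():
            for k, lev in enumerate(levels):
                se = math.sqrt(cov[k, k])
                rows.append((name, lev, float(est[k]),
                             float(est[k]) - z * se, float(est[k]) + z * se))
        return rows


# ---------------------------------------------------------------------------
# fitting entry points
# ---------------------------------------------------------------------------


def _assemble(dataset, spec, *, intercept, options, tau2_arg):
    design = build_design(dataset, spec, intercept=intercept)
    X_parts = [design.X]
    x_names = list(design.x_names)
    col = design.X.shape[1]
    term_unpen = {}
    parts = []
    for blk in design.blocks:
        mp = reparameterize(blk.basis, blk.penalty)
        q0 = mp.X_unpen.shape[1]
        if q0:
            X_parts.append(mp.X_unpen)
            x_names.extend(f"{blk.name}:null{k}" for k in range(q0))
            term_unpen[blk.name] = (col, q0)
            col += q0
        parts.append((blk, mp))
    pen_blocks = []
    Z_parts = []
    tau2 = {}
    for blk, mp in parts:
        q1 = mp.Z_pen.shape[1]
        Z_parts.append(mp.Z_pen)
        pen_blocks.append((blk, mp, col, q1))
        if isinstance(tau2_arg, dict) and blk.name in tau2_arg:
            tau2[blk.name] = float(tau2_arg[blk.name])
        elif np.isscalar(tau2_arg) and tau2_arg is not None:
            tau2[blk.name] = float(tau2_arg)
        else:
            tau2[blk.name] = options.tau2_init
        col += q1
    X = np.concatenate(X_parts + Z_parts, axis=1) if (X_parts or Z_parts) \
        else np.zeros((dataset.n_obs, 0))
    return design, X, x_names, term_unpen, pen_blocks, tau2


def _finalize(state, design, term_unpen, pen_blocks, n_free, x_names):
    """Transform to reporting scale and package a FitResult."""
    grad, info = state.score_info()
    C = np.linalg.inv(info + np.diag(state.penalty_diag()))
    df = float(np.trace(C @ info))
    H = C @ info
    psi = state.psi.copy()
    if state.kind == "cumulative":
        q = state.K - 1
        theta = _zeta_to_theta(psi[:q])
        J = _zeta_jacobian(psi[:q])
        T = np.eye(state.n_params)
        T[:q, :q] = J
        C_rep = T @ C @ T.T
        psi_rep = psi.copy()
        psi_rep[:q] = theta
        thresholds, th_cov = theta, C_rep[:q, :q]
    else:
        q = 0
        C_rep, psi_rep = C, psi
        thresholds, th_cov = None, None

    coefficients = {}
    for name, (sl, levels) in design.fixed_slices.items():
        g_sl = slice(q + sl.start, q + sl.stop)
        coefficients[name] = (levels, psi_rep[g_sl].copy(),
                              C_rep[g_sl, g_sl].copy())

    terms = {}
    edf_by_term = {}
    for blk, mp, start, q1 in pen_blocks:
        idx = []
        maps = []
        if blk.name in term_unpen:
            c0, q0 = term_unpen[blk.name]
            idx.extend(range(q + c0, q + c0 + q0))
            maps.append(mp.T_unpen)
        idx.extend(range(q + start, q + start + q1))
        maps.append(mp.T_pen)
        idx = np.asarray(idx, dtype=int)
        M = blk.coef_transform @ np.concatenate(maps, axis=1)
        coef = M @ psi_rep[idx]
        cov = M @ C_rep[np.ix_(idx, idx)] @ M.T
        terms[blk.name] = TermEffect(
            name=blk.name, kind=blk.kind, coef=coef, cov=cov,
            idx=idx, transform=M, meta=dict(blk.meta),
        )
        pen_sl = slice(q + start, q + start + q1)
        edf = float(np.trace(H[pen_sl, pen_sl]))
        if blk.name in term_unpen:
            c0, q0 = term_unpen[blk.name]
            edf += float(np.trace(H[q + c0: q + c0 + q0, q + c0: q + c0 + q0]))
        edf_by_term[blk.name] = edf

    m2ll = -2.0 * state.loglik()
    aic, bic, gcv = information_criteria(m2ll, df, state.n_obs)
    return FitResult(
        kind=state.kind, n_obs=state.n_obs, n_categories=state.K,
        thresholds=thresholds, thresholds_cov=th_cov,
        coefficients=coefficients, x_names=x_names,
        beta=psi_rep[q:].copy(), cov=C_rep, terms=terms,
        variance_components=dict(state.tau2),
        minus2ll=m2ll, edf=df, edf_by_term=edf_by_term,
        aic=aic, bic=bic, gcv=gcv,
        converged=state.converged, n_outer=state.n_outer,
        iterations=state.iterations, log=state.log, state=state,
    )


def fit_binary(dataset: OrdinalDataset, spec: ModelSpec, *,
               reml: bool = True, tau2=None,
               options: FitOptions = None) -> FitResult:
    """Fit the penalized binary-logit model ``P(y=1) = F(gamma0 + w)``.

    ``tau2`` may fix variance components (scalar or per-term dict); with
    ``reml=True`` (default) they are estimated, any given values serving as
    initial values.
    """
    options = options or FitOptions()
    y = np.asarray(dataset.y, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise DataError("binary model requires y in {0, 1}")
    design, X, x_names, term_unpen, pen_blocks, tau2_map = _assemble(
        dataset, spec, intercept=True, options=options, tau2_arg=tau2)
    log = []
    blocks = [_PenBlock(blk.name, slice(start, start + q1), q1)
              for blk, _, start, q1 in pen_blocks]
    state = _FitState("binary", y, 2, X, 0, blocks, tau2_map, options, log)
    _outer_loop(state, reml)
    return _finalize(state, design, term_unpen, pen_blocks, 0, x_names)


def fit_cumulative(dataset: OrdinalDataset, spec: ModelSpec, *,
                   n_categories: int = None, reml: bool = True, tau2=None,
                   options: FitOptions = None) -> FitResult:
    """Fit the penalized cumulative-logit model ``P(y<=j) = F(theta_j - w)``.

    ``y`` must take values ``1..K`` with every category observed at least
    once.  ``K = 2`` delegates to :func:`fit_binary` on the high-category
    indicator and converts the intercept back to a threshold
    (``theta_1 = -gamma0``).
    """
    options = options or FitOptions()
    y = np.asarray(dataset.y, dtype=int)
    K = int(n_categories) if n_categories else int(y.max())
    if y.min() < 1 or y.max() > K:
        raise DataError(f"y must lie in 1..{K}")
    counts = np.bincount(y, minlength=K + 1)[1:]
    empty = [j + 1 for j, c in enumerate(counts) if c == 0]
    if empty:
        raise DataError(f"empty outcome category: {empty}")
    if K == 2:
        ds_bin = OrdinalDataset(
            y=(y == 2).astype(int), x_cont=dataset.x_cont,
            v_cat=dataset.v_cat, region=dataset.region)
        res = fit_binary(ds_bin, spec, reml=reml, tau2=tau2, options=options)
        i = res.x_names.index("(intercept)")
        res.kind = "cumulative"
        res.thresholds = np.array([-res.beta[i]])
        res.thresholds_cov = res.cov[i: i + 1, i: i + 1].copy()
        res.log.append("K=2: delegated to binary fit; theta1 = -intercept")
        return res

    design, X, x_names, term_unpen, pen_blocks, tau2_map = _assemble(
        dataset, spec, intercept=False, options=options, tau2_arg=tau2)
    log = []
    n_free = K - 1
    blocks = [_PenBlock(blk.name,
                        slice(n_free + start, n_free + start + q1), q1)
              for blk, _, start, q1 in pen_blocks]
    # _assemble indexes columns of X only; shift block slices past zeta
    state = _FitState("cumulative", y, K, X, n_free, blocks, tau2_map,
                      options, log)
    _outer_loop(state, reml)
    return _finalize(state, design, term_unpen, pen_blocks, n_free, x_names)
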