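"""EM algorithm for the latent-state deconvolution model.

Model (per platform): for sample i and region r,

    Y_ir = sum_k pi_ik [ (1 - Z_rk) delta_0r + Z_rk delta_1r ] + eps_ir

with delta_0 ~ N(alpha0 1, sigma0^2 I), delta_1 ~ N(alpha1 1,
sigma1^2 I) shared across samples (they encode the platform's
rendering of the two latent states region by region), and
eps ~ N(0, tau^2 I).  Writing W0_ri = sum_k pi_ik (1 - Z_rk) and
W1_ri = sum_k pi_ik Z_rk (so W0 + W1 = 1 on the simplex), the
stacked observed vector and each delta are jointly Gaussian; the
covariance couples samples only *within* a region, so the E-step
conditional moments of delta_0r, delta_1r given the full data reduce
to independent per-region computations over the observed samples of
that region.  Each region's N x N covariance block

    C_r = tau^2 I + sigma0^2 w0 w0' + sigma1^2 w1 w1'

is rank-2 structured; its inverse and determinant are evaluated with
the Woodbury identity / matrix determinant lemma in O(N) per region.

The M-step maximises the expected complete-data log-likelihood:
closed-form updates alpha = T/R, sigma^2 = T'/R - alpha^2 from the
posterior moment sums, a simplex-constrained QP update of pi against
the posterior-mean design X = (1-Z) E[delta_0|Y] + Z E[delta_1|Y],
and the residual update of tau^2.  Because the pi update plugs in
posterior means and drops the posterior covariance terms, the observed
log-likelihood is not guaranteed to be monotone; decreases beyond
1e-6 are logged as warnings rather than treated as errors.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .composition import CompositionEstimate, ModelParams, estimate_pi_given_X, init_params
from .datamodel import RegionMethylationMatrix, RegionStateMatrix

__all__ = [
    "ConditionalMoments",
    "SufficientStats",
    "FitResult",
    "region_weights",
    "e_step",
    "m_step",
    "observed_loglik",
    "fit_model",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


@dataclass
class ConditionalMoments:
    """Posterior means/variances of the state effects given the data."""

    mean_delta0: np.ndarray
    mean_delta1: np.ndarray
    var_delta0: np.ndarray
    var_delta1: np.ndarray


@dataclass
class SufficientStats:
    """Expected complete-data sufficient statistics.

    T1 = sum_r E[delta_0r | Y],  T3 = sum_r E[delta_0r^2 | Y],
    T2, T4 analogous for delta_1; T5 is the plug-in residual sum of
    squares at the posterior means (informational).
    """

    T1: float
    T2: float
    T3: float
    T4: float
    T5: float


@dataclass
class FitResult:
    pi: CompositionEstimate
    theta: ModelParams
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    theta_trace: list[dict[str, float]] = field(default_factory=list)


def _pi_array(pi) -> np.ndarray:
    if isinstance(pi, CompositionEstimate):
        return pi.pi
    return np.asarray(pi, dtype=float)


def region_weights(pi, Z: RegionStateMatrix) -> tuple[np.ndarray, np.ndarray]:
    """State weights W0_ri = sum_k pi_ik (1-Z_rk), W1_ri = sum_k pi_ik Z_rk.

    Both are R x N; on the simplex W0 + W1 = 1 exactly.
    """
    P = _pi_array(pi)
    Zm = Z.Z.astype(float)
    if P.shape[1] != Zm.shape[1]:
        raise ValidationError(
            f"pi has {P.shape[1]} cell types but Z has {Zm.shape[1]}"
        )
    W0 = (1.0 - Zm) @ P.T
    W1 = Zm @ P.T
    return W0, W1


def _block_terms(Y, Z, theta, pi):
    """Shared per-region quantities for the E-step and the likelihood.

    Everything is vectorised over regions; missing entries are excluded
    from the per-region blocks by zero-masking.
    """
    Zm = Z.Z.astype(float)
    Ym = Y.Y
    P = _pi_array(pi)
    obs = ~np.isnan(Ym)
    X = (1.0 - Zm) * theta.alpha0 + Zm * theta.alpha1  # R x K
    E = np.where(obs, Ym - X @ P.T, 0.0)
    W0 = np.where(obs, (1.0 - Zm) @ P.T, 0.0)
    W1 = np.where(obs, Zm @ P.T, 0.0)
    s0, s1, t2 = theta.sigma0_sq, theta.sigma1_sq, theta.tau_sq
    G00 = (W0 * W0).sum(axis=1)
    G01 = (W0 * W1).sum(axis=1)
    G11 = (W1 * W1).sum(axis=1)
    t0 = (W0 * E).sum(axis=1)
    t1 = (W1 * E).sum(axis=1)
    # M = tau^2 I2 + V'V with V = [sqrt(s0) w0, sqrt(s1) w1]
    A = t2 + s0 * G00
    B = np.sqrt(s0 * s1) * G01
    C = t2 + s1 * G11
    det = A * C - B * B
    return {
        "obs": obs, "E": E, "W0": W0, "W1": W1,
        "G00": G00, "G01": G01, "G11": G11, "t0": t0, "t1": t1,
        "A": A, "B": B, "C": C, "det": det,
        "s0": s0, "s1": s1, "t2": t2,
    }


def _minv_quad(u0, u1, v0, v1, A, B, C, det):
    """u' M^{-1} v for per-region 2-vectors u, v and 2x2 M=[[A,B],[B,C]]."""
    return (u0 * (C * v0 - B * v1) + u1 * (-B * v0 + A * v1)) / det


def e_step(
    Y: RegionMethylationMatrix,
    Z: RegionStateMatrix,
    theta: ModelParams,
    pi,
) -> tuple[ConditionalMoments, SufficientStats]:
    """Per-region conditional moments of delta_0, delta_1 given Y.

    For region r with observed residual vector e and weight rows w0, w1:

        E[delta_0r | Y]  = alpha0 + sigma0^2 w0' C_r^{-1} e
        Var[delta_0r | Y] = sigma0^2 - sigma0^4 w0' C_r^{-1} w0

    and symmetrically for delta_1.  Regions with no observed sample
    fall back to the prior moments.
    """
    T = _block_terms(Y, Z, theta, pi)
    s0, s1, t2 = T["s0"], T["s1"], T["t2"]
    r0, r1 = np.sqrt(s0), np.sqrt(s1)
    A, B, C, det = T["A"], T["B"], T["C"], T["det"]
    G00, G01, G11, t0, t1 = T["G00"], T["G01"], T["G11"], T["t0"], T["t1"]
    # V' e = (r0 t0, r1 t1); w0'V = (r0 G00, r1 G01); w1'V = (r0 G01, r1 G11)
    w0Ce = (t0 - _minv_quad(r0 * G00, r1 * G01, r0 * t0, r1 * t1, A, B, C, det)) / t2
    w1Ce = (t1 - _minv_quad(r0 * G01, r1 * G11, r0 * t0, r1 * t1, A, B, C, det)) / t2
    w0Cw0 = (G00 - _minv_quad(r0 * G00, r1 * G01, r0 * G00, r1 * G01, A, B, C, det)) / t2
    w1Cw1 = (G11 - _minv_quad(r0 * G01, r1 * G11, r0 * G01, r1 * G11, A, B, C, det)) / t2
    mean0 = theta.alpha0 + s0 * w0Ce
    mean1 = theta.alpha1 + s1 * w1Ce
    var0 = s0 - s0 ** 2 * w0Cw0
    var1 = s1 - s1 ** 2 * w1Cw1
    var0 = np.clip(var0, 0.0, None)
    var1 = np.clip(var1, 0.0, None)
    if not (np.isfinite(mean0).all() and np.isfinite(mean1).all()):
        bad = int(np.flatnonzero(~np.isfinite(mean0 + mean1))[0])
        raise ValidationError(f"non-finite posterior moments at region index {bad}")
    moments = ConditionalMoments(
        mean_delta0=mean0, mean_delta1=mean1, var_delta0=var0, var_delta1=var1
    )
    # plug-in residual sum at the posterior means (informational T5)
    Zm = Z.Z.astype(float)
    Xpost = (1.0 - Zm) * mean0[:, None] + Zm * mean1[:, None]
    resid = np.where(T["obs"], Y.Y - Xpost @ _pi_array(pi).T, 0.0)
    stats = SufficientStats(
        T1=float(mean0.sum()),
        T2=float(mean1.sum()),
        T3=float((mean0 ** 2 + var0).sum()),
        T4=float((mean1 ** 2 + var1).sum()),
        T5=float((resid ** 2).sum()),
    )
    return moments, stats


def m_step(
    stats: SufficientStats,
    moments: ConditionalMoments,
    Y: RegionMethylationMatrix,
    Z: RegionStateMatrix,
) -> tuple[ModelParams, CompositionEstimate]:
    """Closed-form theta update and QP update of pi.

    alpha = T/R and sigma^2 = T'/R - alpha^2 (floored at 1e-12 to keep
    the covariance blocks positive definite); pi is re-estimated by
    simplex-constrained least squares against the posterior-mean design
    X = (1-Z) E[delta_0|Y] + Z E[delta_1|Y]; tau^2 is the mean squared
    residual of that fit over observed entries.
    """
    R = Z.n_regions
    alpha0 = stats.T1 / R
    alpha1 = stats.T2 / R
    sigma0_sq = stats.T3 / R - alpha0 ** 2
    sigma1_sq = stats.T4 / R - alpha1 ** 2
    if sigma0_sq < _VAR_FLOOR or sigma1_sq < _VAR_FLOOR:
        logger.debug("state variance floored at %g", _VAR_FLOOR)
    sigma0_sq = max(sigma0_sq, _VAR_FLOOR)
    sigma1_sq = max(sigma1_sq, _VAR_FLOOR)
    Zm = Z.Z.astype(float)
    X_t = (1.0 - Zm) * moments.mean_delta0[:, None] + Zm * moments.mean_delta1[:, None]
    pi = estimate_pi_given_X(Y, X_t, sum_to_one=True, cell_types=Z.cell_types)
    obs = ~np.isnan(Y.Y)
    resid = np.where(obs, Y.Y - X_t @ pi.pi.T, 0.0)
    tau_sq = float((resid ** 2).sum() / obs.sum())
    if tau_sq < _VAR_FLOOR:
        warnings.warn(
            "tau^2 update hit the 1e-12 floor (data are essentially noiseless)",
            UserWarning,
            stacklevel=2,
        )
        tau_sq = _VAR_FLOOR
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # soft alpha ordering check
        theta = ModelParams(
            alpha0=alpha0,
            alpha1=alpha1,
            sigma0_sq=sigma0_sq,
            sigma1_sq=sigma1_sq,
            tau_sq=tau_sq,
        )
    return theta, pi


def observed_loglik(
    Y: RegionMethylationMatrix,
    Z: RegionStateMatrix,
    theta: ModelParams,
    pi,
) -> float:
    """Marginal Gaussian log-likelihood of the observed data.

    The density factorises over regions; each region contributes a
    multivariate normal over its observed samples with mean (X pi)_r
    and covariance C_r, evaluated with the Woodbury identity and the
    matrix determinant lemma.  All-missing regions contribute zero.
    """
    T = _block_terms(Y, Z, theta, pi)
    A, B, C, det = T["A"], T["B"], T["C"], T["det"]
    t2 = T["t2"]
    r0, r1 = np.sqrt(T["s0"]), np.sqrt(T["s1"])
    n_r = T["obs"].sum(axis=1)
    S2 = (T["E"] ** 2).sum(axis=1)
    v0, v1 = r0 * T["t0"], r1 * T["t1"]
    quad = (S2 - _minv_quad(v0, v1, v0, v1, A, B, C, det)) / t2
    # det(C_r) = tau^(2 n_r) * det(M_r) / tau^4
    logdet = n_r * np.log(t2) + np.log(det) - 2.0 * np.log(t2)
    ll = -0.5 * (n_r * np.log(2.0 * np.pi) + logdet + quad)
    ll = np.where(n_r > 0, ll, 0.0)
    if not np.isfinite(ll).all():
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise ValidationError(f"non-finite log-likelihood at region index {bad}")
    return float(ll.sum())


def _theta_rel_change(old: ModelParams, new: ModelParams) -> float:
    changes = []
    for key, ov in old.as_dict().items():
        nv = new.as_dict()[key]
        changes.append(abs(nv - ov) / max(abs(ov), 1e-8))
    return max(changes)


def fit_model(
    Y: RegionMethylationMatrix,
    Z: RegionStateMatrix,
    max_iter: int = 100,
    tol: float = 1e-4,
    init_override: tuple[ModelParams, CompositionEstimate] | None = None,
    min_nonmissing_fraction: float = 0.8,
) -> FitResult:
    """Fit the latent-state model by EM.

    Alternates :func:`e_step` and :func:`m_step` from the method-of-
    moments initialisation until the maximum relative change in theta
    and the maximum absolute change in pi both fall below ``tol``, or
    ``max_iter`` is reached (returned with ``converged=False``, not an
    exception).  The fit is deterministic: there is no randomness
    anywhere in the algorithm.
    """
    if Z.n_regions != Y.n_regions:
        raise ValidationError(
            f"Y has {Y.n_regions} regions but Z has {Z.n_regions}"
        )
    if Y.n_regions <= Z.n_cell_types:
        raise ValidationError(
            f"need more regions (R={Y.n_regions}) than cell types "
            f"(K={Z.n_cell_types})"
        )
    obs_frac = (~np.isnan(Y.Y)).mean(axis=0)
    low = obs_frac < min_nonmissing_fraction
    if low.any():
        names = [Y.sample_ids[i] for i in np.flatnonzero(low)]
        warnings.warn(
            f"sample(s) {names[:10]} have fewer than "
            f"{min_nonmissing_fraction:.0%} non-missing regions; estimates "
            "may be unstable",
            UserWarning,
            stacklevel=2,
        )
    theta, pi = init_override if init_override is not None else init_params(Y, Z)
    loglik_trace: list[float] = []
    theta_trace: list[dict[str, float]] = [theta.as_dict()]
    converged = False
    decreased = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        moments, stats = e_step(Y, Z, theta, pi)
        theta_new, pi_new = m_step(stats, moments, Y, Z)
        ll = observed_loglik(Y, Z, theta_new, pi_new)
        if loglik_trace and ll < loglik_trace[-1] - 1e-6:
            if not decreased:
                logger.warning(
                    "observed log-likelihood decreased at iteration %d "
                    "(%.6f -> %.6f); the pi update ignores posterior "
                    "covariances, so strict monotonicity is not guaranteed",
                    it, loglik_trace[-1], ll,
                )
            decreased = True
        loglik_trace.append(ll)
        theta_trace.append(theta_new.as_dict())
        d_theta = _theta_rel_change(theta, theta_new)
        d_pi = float(np.abs(pi_new.pi - pi.pi).max(initial=0.0))
        theta, pi = theta_new, pi_new
        logger.debug(
            "iter %d: ll=%.4f d_theta=%.3e d_pi=%.3e", it, ll, d_theta, d_pi
        )
        if d_theta < tol and d_pi < tol:
            converged = True
            break
    return FitResult(
        pi=pi,
        theta=theta,
        loglik_trace=loglik_trace,
        n_iter=n_iter,
        converged=converged,
        theta_trace=theta_trace,
    )
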