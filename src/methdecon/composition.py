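"""Cell-composition estimation: constrained least squares, the
reference-based baseline, and EM initialisation.

Two estimators live here:

* :func:`houseman_estimate` — the classical reference-based approach:
  regress each sample's CpG-level methylation on a measured cell-type
  reference profile under non-negativity (by default *without* the
  sum-to-one constraint, so unaccounted cell types can absorb mass).
* :func:`init_params` — step t=0 of the latent-state model: method-of-
  moments estimates of (alpha0, alpha1, sigma0^2, sigma1^2) from
  regions that are unmethylated (R0) or methylated (R1) in every cell
  type, followed by a simplex-constrained projection for pi and a
  residual-variance estimate for tau^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .datamodel import (
    CellTypeReferenceProfile,
    CpGMeasurementTable,
    RegionMethylationMatrix,
    RegionStateMatrix,
)
from .qp import SimplexQPProblem, solve_simplex_qp

__all__ = [
    "ModelParams",
    "CompositionEstimate",
    "estimate_pi_given_X",
    "houseman_estimate",
    "init_params",
]

_VAR_FLOOR = 1e-12


@dataclass
class ModelParams:
    """Parameters theta = (alpha0, alpha1, sigma0^2, sigma1^2, tau^2).

    alpha0/alpha1 are the mean methylation levels of the unmethylated and
    methylated latent states on the platform at hand; sigma0^2/sigma1^2
    the region-to-region variances of the corresponding random effects;
    tau^2 the measurement-error variance.
    """

    alpha0: float
    alpha1: float
    sigma0_sq: float
    sigma1_sq: float
    tau_sq: float

    def __post_init__(self) -> None:
        if self.sigma0_sq < 0 or self.sigma1_sq < 0:
            raise ValidationError("state variances must be non-negative")
        if self.tau_sq <= 0:
            raise ValidationError("tau_sq must be positive")
        if not (0.0 <= self.alpha0 <= self.alpha1 <= 1.0):
            warnings.warn(
                f"expected 0 <= alpha0 <= alpha1 <= 1, got "
                f"alpha0={self.alpha0:.4g}, alpha1={self.alpha1:.4g}",
                UserWarning,
                stacklevel=2,
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "sigma0_sq": self.sigma0_sq,
            "sigma1_sq": self.sigma1_sq,
            "tau_sq": self.tau_sq,
        }


@dataclass
class CompositionEstimate:
    """Estimated cell-type proportions pi (N samples x K cell types)."""

    sample_ids: list[str]
    cell_types: list[str]
    pi: np.ndarray
    sum_constrained: bool = True

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        N, K = len(self.sample_ids), len(self.cell_types)
        if self.pi.shape != (N, K):
            raise ValidationError(
                f"pi has shape {self.pi.shape}, expected ({N}, {K})"
            )
        if self.pi.min(initial=0.0) < -1e-10:
            raise ValidationError("pi entries must be >= -1e-10")
        if self.sum_constrained:
            dev = np.abs(self.pi.sum(axis=1) - 1.0).max(initial=0.0)
            if dev > 1e-8:
                raise ValidationError(
                    f"pi rows must sum to 1 within 1e-8 (max deviation {dev:.3e})"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pi, index=self.sample_ids, columns=self.cell_types)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def _as_matrix(Y) -> tuple[np.ndarray, list[str]]:
    if isinstance(Y, RegionMethylationMatrix):
        return Y.Y, list(Y.sample_ids)
    Y = np.asarray(Y, dtype=float)
    return Y, [f"sample{i}" for i in range(Y.shape[1])]


def _pi_rows(Y: np.ndarray, X: np.ndarray, sum_to_one: bool) -> np.ndarray:
    """Per-sample constrained least squares of Y[:, i] on X (NaN-aware)."""
    R, K = X.shape
    N = Y.shape[1]
    pi = np.zeros((N, K))
    obs_all = ~np.isnan(Y)
    complete = bool(obs_all.all())
    if complete:
        Q_full = X.T @ X
    for i in range(N):
        obs = obs_all[:, i]
        if obs.sum() < K:
            raise ValidationError(
                f"sample index {i}: only {int(obs.sum())} non-missing regions, "
                f"need at least K={K}"
            )
        Xi = X if complete else X[obs]
        if np.linalg.matrix_rank(Xi) < K:
            raise ValidationError(
                f"sample index {i}: design is rank deficient on its "
                "non-missing regions"
            )
        Q = Q_full if complete else Xi.T @ Xi
        a = -Xi.T @ Y[obs, i]
        pi[i] = solve_simplex_qp(
            SimplexQPProblem(
                Q=Q, a=a, equality_sum_constraint=sum_to_one, lower_bound_zero=True
            )
        )
    return pi


def estimate_pi_given_X(
    Y,
    X: np.ndarray,
    sum_to_one: bool = True,
    cell_types: list[str] | None = None,
) -> CompositionEstimate:
    """Constrained least-squares proportions given a known design X.

    Each sample i solves ``min ||X pi - Y_i||^2`` over its non-missing
    rows subject to ``pi >= 0`` and optionally ``sum(pi) = 1``, via the
    QP with ``Q = X'X`` and ``a = -X'Y_i``.
    """
    Ym, sample_ids = _as_matrix(Y)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != Ym.shape[0]:
        raise ValidationError(
            f"X has {X.shape[0]} rows but Y has {Ym.shape[0]} regions"
        )
    K = X.shape[1]
    pi = _pi_rows(Ym, X, sum_to_one)
    names = cell_types if cell_types is not None else [f"ct{k}" for k in range(K)]
    return CompositionEstimate(
        sample_ids=sample_ids,
        cell_types=list(names),
        pi=pi,
        sum_constrained=sum_to_one,
    )


def houseman_estimate(
    samples: list[CpGMeasurementTable],
    reference: CellTypeReferenceProfile,
    sum_to_one: bool = False,
) -> tuple[CompositionEstimate, pd.Series]:
    """Reference-based composition estimate from CpG-level data.

    For each sample, the measured CpGs are intersected with the
    reference profile's CpGs (by id); the sample's methylation levels
    are then regressed on the reference design under ``pi >= 0``.  By
    default the proportions are *not* rescaled to sum to one, leaving
    room for unaccounted cell types.

    Returns the estimate and a per-sample Series of the number of
    reference CpGs actually used; a sample whose intersection is
    smaller than K is an error — on a new platform many reference CpGs
    may simply not be measured.
    """
    K = len(reference.cell_types)
    ref_index = {cid: j for j, cid in enumerate(reference.cpg_ids)}
    pi = np.zeros((len(samples), K))
    n_used = []
    for i, s in enumerate(samples):
        ids = s.data["cpg_id"].astype(str).to_numpy()
        levels = s.levels()
        rows, y = [], []
        for cid, lev in zip(ids, levels):
            j = ref_index.get(cid)
            if j is not None and not np.isnan(lev):
                rows.append(j)
                y.append(lev)
        if len(rows) < K:
            raise ValidationError(
                f"sample {s.sample_id}: only {len(rows)} of "
                f"{len(reference.cpg_ids)} reference CpGs measured, "
                f"need at least K={K}"
            )
        Xi = reference.X[rows]
        y = np.asarray(y)
        pi[i] = solve_simplex_qp(
            SimplexQPProblem(
                Q=Xi.T @ Xi,
                a=-Xi.T @ y,
                equality_sum_constraint=sum_to_one,
                lower_bound_zero=True,
            )
        )
        n_used.append(len(rows))
    est = CompositionEstimate(
        sample_ids=[s.sample_id for s in samples],
        cell_types=list(reference.cell_types),
        pi=pi,
        sum_constrained=sum_to_one,
    )
    return est, pd.Series(n_used, index=est.sample_ids, name="n_cpgs_used")


def _extreme_rows(Z: np.ndarray, low: bool, min_rows: int) -> np.ndarray:
    """Indices of all-zero (low) / all-one rows, padding with the rows
    closest to that extreme if fewer than ``min_rows`` exist."""
    K = Z.shape[1]
    row_sum = Z.sum(axis=1)
    target = 0 if low else K
    exact = np.flatnonzero(row_sum == target)
    if exact.size >= min_rows:
        return exact
    side = "unmethylated" if low else "methylated"
    values = np.sort(np.unique(row_sum)) if low else np.sort(np.unique(row_sum))[::-1]
    chosen: list[int] = []
    for v in values:
        chosen.extend(np.flatnonzero(row_sum == v).tolist())
        if len(chosen) >= min_rows:
            break
    if len(chosen) < min_rows:
        raise ValidationError(
            f"cannot find {min_rows} rows for the all-{side} pseudo set"
        )
    warnings.warn(
        f"Z has only {exact.size} all-{side} row(s); falling back to "
        f"{len(chosen)} rows closest to that extreme for initialisation",
        UserWarning,
        stacklevel=3,
    )
    return np.asarray(chosen)


def init_params(
    Y: RegionMethylationMatrix,
    Z: RegionStateMatrix,
    min_extreme_rows: int = 2,
) -> tuple[ModelParams, CompositionEstimate]:
    """Method-of-moments initialisation (step t=0).

    Over regions unmethylated in every cell type (the R0 set),
    E(Y_ir) = alpha0 and Var(Y_ir) <= sigma0^2 + tau^2, so with small
    measurement error the per-sample mean and variance over R0 estimate
    alpha0 and sigma0^2 (a slight over-estimate, by up to tau^2);
    symmetrically for R1.  pi^(0) comes from the simplex-constrained
    projection on X^(0) = (1-Z) alpha0 + Z alpha1, and tau^2(0) is the
    mean squared residual.
    """
    Zm = Z.Z.astype(float)
    Ym = Y.Y
    r0 = _extreme_rows(Z.Z, low=True, min_rows=min_extreme_rows)
    r1 = _extreme_rows(Z.Z, low=False, min_rows=min_extreme_rows)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        alpha0 = float(np.nanmean(np.nanmean(Ym[r0], axis=0)))
        alpha1 = float(np.nanmean(np.nanmean(Ym[r1], axis=0)))
        sigma0_sq = float(np.nanmean(np.nanvar(Ym[r0], axis=0, ddof=1)))
        sigma1_sq = float(np.nanmean(np.nanvar(Ym[r1], axis=0, ddof=1)))
    for name, v in (
        ("alpha0", alpha0),
        ("alpha1", alpha1),
        ("sigma0_sq", sigma0_sq),
        ("sigma1_sq", sigma1_sq),
    ):
        if not np.isfinite(v):
            raise ValidationError(
                f"initialisation failed: {name} is not finite (too much "
                "missing data in the extreme region sets)"
            )
    sigma0_sq = max(sigma0_sq, 0.0)
    sigma1_sq = max(sigma1_sq, 0.0)

    X0 = (1.0 - Zm) * alpha0 + Zm * alpha1
    pi0 = estimate_pi_given_X(Y, X0, sum_to_one=True, cell_types=Z.cell_types)
    resid = Ym - X0 @ pi0.pi.T
    obs = ~np.isnan(Ym)
    tau_sq = float(np.mean(resid[obs] ** 2))
    tau_sq = max(tau_sq, _VAR_FLOOR)
    theta = ModelParams(
        alpha0=alpha0,
        alpha1=alpha1,
        sigma0_sq=sigma0_sq,
        sigma1_sq=sigma1_sq,
        tau_sq=tau_sq,
    )
    return theta, pi0
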