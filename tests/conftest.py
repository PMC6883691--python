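"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own computational
shortcuts: the E-step oracle materialises the full joint normal of the
stacked observed data and the state effects and applies the textbook
conditional-normal formula; the QP oracle evaluates the objective on
an exhaustive simplex grid.
"""
from __future__ import annotations

import numpy as np
import pytest

from methdecon.composition import ModelParams
from methdecon.datamodel import GenomicRegion, RegionMethylationMatrix, RegionStateMatrix


def make_region_state(Zm, cell_types=None) -> RegionStateMatrix:
    """Wrap a plain 0/1 array into a RegionStateMatrix with dummy coords."""
    Zm = np.asarray(Zm)
    R, K = Zm.shape
    cell_types = cell_types or [f"ct{k}" for k in range(K)]
    regions = [
        GenomicRegion("chr1", 1000 * r, 1000 * r + 500, f"r{r:03d}")
        for r in range(R)
    ]
    return RegionStateMatrix(regions=regions, cell_types=cell_types, Z=Zm)


def make_region_matrix(Y, regions=None) -> RegionMethylationMatrix:
    Y = np.asarray(Y, dtype=float)
    R, N = Y.shape
    if regions is None:
        regions = [
            GenomicRegion("chr1", 1000 * r, 1000 * r + 500, f"r{r:03d}")
            for r in range(R)
        ]
    return RegionMethylationMatrix(
        regions=list(regions), sample_ids=[f"s{i:03d}" for i in range(N)], Y=Y
    )


def dense_conditional_oracle(Y, Zm, theta: ModelParams, P):
    """Condition the state effects on the observed data the long way.

    Builds the full (n_obs + R) joint normal for (Y, delta_l), l = 0, 1,
    with the model covariances (within-region coupling across samples,
    zero across regions), inverts it densely, and returns the posterior
    means/variances plus the marginal log-likelihood of the observed
    vector.  Quadratic in the problem size: only for tiny instances.
    """
    Y = np.asarray(Y, dtype=float)
    Zm = np.asarray(Zm, dtype=float)
    P = np.asarray(P, dtype=float)
    R, N = Y.shape
    obs = ~np.isnan(Y)
    W = [ (1.0 - Zm) @ P.T, Zm @ P.T ]
    X = (1.0 - Zm) * theta.alpha0 + Zm * theta.alpha1
    mu_Y = X @ P.T
    idx = [(r, i) for r in range(R) for i in range(N) if obs[r, i]]
    n = len(idx)
    sig = [theta.sigma0_sq, theta.sigma1_sq]
    S11 = np.zeros((n, n))
    for a, (r, i) in enumerate(idx):
        for b, (r2, i2) in enumerate(idx):
            if r == r2:
                S11[a, b] = (
                    W[0][r, i] * W[0][r2, i2] * sig[0]
                    + W[1][r, i] * W[1][r2, i2] * sig[1]
                )
                if a == b:
                    S11[a, b] += theta.tau_sq
    yvec = np.array([Y[r, i] for (r, i) in idx])
    resid = yvec - np.array([mu_Y[r, i] for (r, i) in idx])
    S11inv = np.linalg.inv(S11)
    out = []
    for state, alpha in enumerate([theta.alpha0, theta.alpha1]):
        S12 = np.zeros((n, R))
        for a, (r, i) in enumerate(idx):
            S12[a, r] = W[state][r, i] * sig[state]
        mean = alpha + S12.T @ S11inv @ resid
        cov = sig[state] * np.eye(R) - S12.T @ S11inv @ S12
        out.append((mean, np.diag(cov).copy()))
    _, logdet = np.linalg.slogdet(S11)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + resid @ S11inv @ resid)
    return out[0], out[1], float(ll)


_GRID_CACHE: dict[tuple[int, float], np.ndarray] = {}


def simplex_grid(K: int = 3, step: float = 0.001) -> np.ndarray:
    """All points of the K-simplex at the given resolution (K <= 3)."""
    key = (K, step)
    if key not in _GRID_CACHE:
        m = int(round(1.0 / step))
        if K == 2:
            i = np.arange(m + 1)
            pts = np.column_stack([i, m - i]) / m
        elif K == 3:
            i, j = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
            keep = i + j <= m
            i, j = i[keep], j[keep]
            pts = np.column_stack([i, j, m - i - j]) / m
        else:
            raise ValueError("grid oracle only supports K <= 3")
        _GRID_CACHE[key] = pts
    return _GRID_CACHE[key]


def grid_qp_oracle(Q, a, step: float = 0.001) -> np.ndarray:
    """Exhaustive-search minimiser of 0.5 x'Qx + a'x on the simplex."""
    pts = simplex_grid(len(a), step)
    vals = 0.5 * np.einsum("ij,jk,ik->i", pts, Q, pts) + pts @ a
    return pts[int(np.argmin(vals))]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
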