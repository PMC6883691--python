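"""Synthetic data generation and the two-platform simulation study.

The generator mirrors the generative model the estimator assumes: for
each platform, state-level random effects delta0*, delta1* are drawn
once per region from N(alpha_l*, sigma_l*^2) and assembled into the
platform's cell-type profiles X* = (1-Z) delta0* + Z delta1*; mixture
samples are then Y_i = sum_k pi_ik X*_k + eps_i with Dirichlet
proportions and i.i.d. Gaussian noise.  The *same* pi and eps are
reused on every platform, so two platforms differ only through their
state effects — the technology bias the latent-state model is built
to absorb.

Default platform constants emulate the qualitative array-vs-sequencing
contrast (sequencing values sit closer to 0 and 1, the array
attenuates them): array-like alpha* = (0.15, 0.85), sequencing-like
alpha* = (0.05, 0.95), both with state variance 0.0025 and measurement
noise tau = 0.03.  Proportions are Dirichlet(2, ..., 2).  Everything
is reproducible bit-exactly from (config, seed); replicate s of a
study reuses seed + s.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .composition import CompositionEstimate, ModelParams, estimate_pi_given_X
from .datamodel import GenomicRegion, RegionMethylationMatrix, RegionStateMatrix
from .dmr import ReferenceSampleSet
from .em import fit_model

__all__ = [
    "PlatformParams",
    "ARRAY_PLATFORM",
    "SEQUENCING_PLATFORM",
    "WHOLE_BLOOD_CELL_TYPES",
    "SimulationConfig",
    "SimulatedDataset",
    "default_blood_z",
    "simulate_platform_profiles",
    "simulate_mixtures",
    "rmse_by_cell_type",
    "run_simulation_study",
    "StudyResult",
    "simulate_sorted_reference",
]

WHOLE_BLOOD_CELL_TYPES = ["Gran", "CD4T", "CD8T", "Bcell", "Mono", "NK"]


@dataclass(frozen=True)
class PlatformParams:
    """State means/variances of one platform's random effects."""

    name: str
    alpha0_star: float
    alpha1_star: float
    sigma0_sq_star: float
    sigma1_sq_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha0_star < self.alpha1_star <= 1.0:
            raise ValidationError(
                f"platform {self.name}: need 0 <= alpha0* < alpha1* <= 1, "
                f"got ({self.alpha0_star}, {self.alpha1_star})"
            )
        if self.sigma0_sq_star < 0 or self.sigma1_sq_star < 0:
            raise ValidationError(
                f"platform {self.name}: negative state variance"
            )


ARRAY_PLATFORM = PlatformParams("array", 0.15, 0.85, 0.0025, 0.0025)
SEQUENCING_PLATFORM = PlatformParams("sequencing", 0.05, 0.95, 0.0025, 0.0025)


def default_blood_z(
    n_regions: int = 210, cell_types: list[str] | None = None
) -> RegionStateMatrix:
    """Deterministic whole-blood-style latent-state layout.

    Contains blocks of all-unmethylated and all-methylated consensus
    rows (used by the moment initialisation), plus for each cell type a
    set of rows methylated only in that type and rows unmethylated only
    in that type.  Full column rank by construction.
    """
    cell_types = cell_types or list(WHOLE_BLOOD_CELL_TYPES)
    K = len(cell_types)
    if n_regions < 2 * K + 4:
        raise ValidationError(
            f"n_regions={n_regions} too small for K={K} (need >= {2 * K + 4})"
        )
    n_zero = max(2, round(0.06 * n_regions))
    n_one = n_zero
    remaining = n_regions - n_zero - n_one
    per_type = remaining // (2 * K)
    rows: list[np.ndarray] = []
    rows += [np.zeros(K, dtype=np.int8)] * n_zero
    rows += [np.ones(K, dtype=np.int8)] * n_one
    for k in range(K):
        e = np.zeros(K, dtype=np.int8)
        e[k] = 1
        rows += [e] * per_type
        rows += [(1 - e).astype(np.int8)] * per_type
    k = 0
    while len(rows) < n_regions:  # distribute the remainder
        e = np.zeros(K, dtype=np.int8)
        e[k % K] = 1
        rows.append(e)
        k += 1
    Z = np.vstack(rows[:n_regions])
    regions = [
        GenomicRegion("chr1", 1000 + 2000 * r, 1500 + 2000 * r, f"region{r:04d}")
        for r in range(n_regions)
    ]
    return RegionStateMatrix(regions=regions, cell_types=cell_types, Z=Z)


@dataclass
class SimulationConfig:
    """Study conditions for the two-platform simulation."""

    n_samples: int = 200
    Z: RegionStateMatrix | None = None
    pi_dirichlet_alpha: float | np.ndarray = 2.0
    tau: float = 0.03
    platforms: tuple[PlatformParams, ...] = (ARRAY_PLATFORM, SEQUENCING_PLATFORM)
    n_sims: int = 100
    seed: int = 0
    share_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_sims < 1:
            raise ValidationError("n_sims must be >= 1")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")
        if self.Z is None:
            self.Z = default_blood_z()
        alpha = np.atleast_1d(np.asarray(self.pi_dirichlet_alpha, dtype=float))
        if alpha.size == 1:
            alpha = np.full(self.Z.n_cell_types, float(alpha[0]))
        if alpha.size != self.Z.n_cell_types:
            raise ValidationError(
                f"pi_dirichlet_alpha has {alpha.size} entries for "
                f"K={self.Z.n_cell_types} cell types"
            )
        if (alpha <= 0).any():
            raise ValidationError("Dirichlet alpha must be positive")
        self.pi_dirichlet_alpha = alpha
        names = [p.name for p in self.platforms]
        if len(set(names)) != len(names):
            raise ValidationError("platform names must be unique")


@dataclass
class SimulatedDataset:
    """One replicate of the two-platform generative model."""

    Y: dict[str, RegionMethylationMatrix]
    X_star: dict[str, np.ndarray]
    pi_true: np.ndarray
    theta_true: dict[str, ModelParams]
    clip_fraction: dict[str, float]
    config: SimulationConfig
    seed: int


def simulate_platform_profiles(
    Z: RegionStateMatrix, platform: PlatformParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw one platform's R x K cell-type profile matrix X*.

    delta0*, delta1* are region-indexed (shared across cell types) and
    clipped to [0, 1] after the normal draw; X*_rk = (1-Z_rk) delta0*_r
    + Z_rk delta1*_r.
    """
    R = Z.n_regions
    delta0 = np.clip(
        rng.normal(platform.alpha0_star, np.sqrt(platform.sigma0_sq_star), R),
        0.0, 1.0,
    )
    delta1 = np.clip(
        rng.normal(platform.alpha1_star, np.sqrt(platform.sigma1_sq_star), R),
        0.0, 1.0,
    )
    Zm = Z.Z.astype(float)
    return (1.0 - Zm) * delta0[:, None] + Zm * delta1[:, None]


def simulate_mixtures(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedDataset:
    """Simulate one replicate: shared pi and noise, per-platform profiles.

    Y values are clipped to [0, 1]; the clipped fraction is recorded so
    callers can verify clipping is rare under the default constants.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    Z = config.Z
    R, K, N = Z.n_regions, Z.n_cell_types, config.n_samples
    pi = rng.dirichlet(config.pi_dirichlet_alpha, size=N)
    X_star = {p.name: simulate_platform_profiles(Z, p, rng) for p in config.platforms}
    eps_shared = rng.normal(0.0, config.tau, size=(R, N))
    Y: dict[str, RegionMethylationMatrix] = {}
    clip_fraction: dict[str, float] = {}
    theta_true: dict[str, ModelParams] = {}
    for p in config.platforms:
        eps = eps_shared if config.share_noise else rng.normal(0.0, config.tau, (R, N))
        raw = X_star[p.name] @ pi.T + eps
        clipped = np.clip(raw, 0.0, 1.0)
        clip_fraction[p.name] = float((raw != clipped).mean())
        Y[p.name] = RegionMethylationMatrix(
            regions=list(Z.regions),
            sample_ids=[f"s{i:03d}" for i in range(N)],
            Y=clipped,
        )
        theta_true[p.name] = ModelParams(
            alpha0=p.alpha0_star,
            alpha1=p.alpha1_star,
            sigma0_sq=p.sigma0_sq_star,
            sigma1_sq=p.sigma1_sq_star,
            tau_sq=max(config.tau ** 2, 1e-12),
        )
    return SimulatedDataset(
        Y=Y,
        X_star=X_star,
        pi_true=pi,
        theta_true=theta_true,
        clip_fraction=clip_fraction,
        config=config,
        seed=seed,
    )


def rmse_by_cell_type(pi_hat, pi_true) -> np.ndarray:
    """Cell-type-specific RMSE_k = sqrt(mean_i (pi_hat_ik - pi_ik)^2)."""
    if isinstance(pi_hat, CompositionEstimate):
        pi_hat = pi_hat.pi
    pi_hat = np.asarray(pi_hat, dtype=float)
    pi_true = np.asarray(pi_true, dtype=float)
    if pi_hat.shape != pi_true.shape:
        raise ValidationError(
            f"shape mismatch: {pi_hat.shape} vs {pi_true.shape}"
        )
    return np.sqrt(np.mean((pi_hat - pi_true) ** 2, axis=0))


VALID_METHODS = ("houseman", "latent")


@dataclass
class StudyResult:
    """Per-replicate mean-RMSE records and their summary."""

    records: pd.DataFrame  # columns: replicate, platform, method, mean_rmse
    summary: pd.DataFrame  # per (platform, method): median, iqr, n
    failures: list[dict] = field(default_factory=list)


def run_simulation_study(
    config: SimulationConfig,
    methods: tuple[str, ...] = VALID_METHODS,
    reference_platform: str | None = None,
    fit_kwargs: dict | None = None,
) -> StudyResult:
    """Monte Carlo comparison of the two estimators across platforms.

    Per replicate, fresh pi/delta*/eps are drawn and each method is run
    on every platform's Y.  The reference-based method always uses the
    *reference platform's* X* as its design (first platform by
    default), so on that platform it is matched and on the others it is
    cross-platform mismatched; the latent-state model never sees X*.
    The mean (over cell types) RMSE of each fit is recorded; replicates
    where an estimator fails are excluded from that method's summary
    and counted.
    """
    bad = [m for m in methods if m not in VALID_METHODS]
    if bad:
        raise ValidationError(f"unknown method(s) {bad}; valid: {VALID_METHODS}")
    fit_kwargs = fit_kwargs or {}
    ref_name = reference_platform or config.platforms[0].name
    if ref_name not in {p.name for p in config.platforms}:
        raise ValidationError(f"unknown reference platform '{ref_name}'")
    rows = []
    failures: list[dict] = []
    for s in range(config.n_sims):
        ds = simulate_mixtures(config, seed=config.seed + s)
        X_ref = ds.X_star[ref_name]
        for p in config.platforms:
            Ymat = ds.Y[p.name]
            for method in methods:
                try:
                    if method == "houseman":
                        est = estimate_pi_given_X(
                            Ymat, X_ref, sum_to_one=False,
                            cell_types=config.Z.cell_types,
                        )
                    else:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", UserWarning)
                            est = fit_model(Ymat, config.Z, **fit_kwargs).pi
                    mean_rmse = float(rmse_by_cell_type(est, ds.pi_true).mean())
                    rows.append(
                        {
                            "replicate": s,
                            "platform": p.name,
                            "method": method,
                            "mean_rmse": mean_rmse,
                        }
                    )
                except Exception as exc:  # record, exclude, keep going
                    failures.append(
                        {
                            "replicate": s,
                            "platform": p.name,
                            "method": method,
                            "error": str(exc),
                        }
                    )
    records = pd.DataFrame(
        rows, columns=["replicate", "platform", "method", "mean_rmse"]
    )
    if records.empty:
        summary = pd.DataFrame(
            columns=["platform", "method", "median", "iqr", "n"]
        )
    else:
        grouped = records.groupby(["platform", "method"])["mean_rmse"]
        summary = grouped.agg(
            median="median",
            iqr=lambda x: float(np.subtract(*np.percentile(x, [75, 25]))),
            n="count",
        ).reset_index()
    return StudyResult(records=records, summary=summary, failures=failures)


def simulate_sorted_reference(
    cell_types: list[str] | None = None,
    n_replicates: int = 6,
    blocks_per_type: int = 3,
    cpgs_per_block: int = 5,
    block_delta: float = 0.8,
    noise_sd: float = 0.05,
    n_background: int = 60,
    n_consensus: int = 3,
    seed: int = 0,
) -> tuple[ReferenceSampleSet, pd.DataFrame]:
    """Synthetic sorted-cell reference with planted DMR blocks.

    Emulates a sorted-cell experiment (default: six replicates of each
    of six leukocyte types).  For each cell type, ``blocks_per_type``
    CpG blocks are planted in each direction (methylated only in that
    type / unmethylated only in that type, difference ``block_delta``);
    consensus blocks methylated or unmethylated in *all* types and
    no-signal background CpGs fill the rest.  Gaussian noise of SD
    ``noise_sd`` is added and betas are clipped to [0, 1].

    Returns the reference set and a table of planted block truth
    (cell_type, direction, chrom, start, end, CpG index range).
    """
    cell_types = cell_types or list(WHOLE_BLOOD_CELL_TYPES)
    K = len(cell_types)
    rng = np.random.default_rng(seed)
    labels = [ct for ct in cell_types for _ in range(n_replicates)]
    M = len(labels)
    lo, hi = 0.5 - block_delta / 2, 0.5 + block_delta / 2

    blocks: list[dict] = []
    base_rows: list[np.ndarray] = []
    chroms: list[str] = []
    positions: list[int] = []
    pos = 1000
    gap_in, gap_between = 50, 5000

    def add_block(mean_by_type: np.ndarray, tag: dict | None) -> None:
        nonlocal pos
        first_idx = len(base_rows)
        for c in range(cpgs_per_block):
            row = np.repeat(mean_by_type, n_replicates)
            base_rows.append(row)
            chroms.append("chr1")
            positions.append(pos)
            pos += gap_in
        if tag is not None:
            tag = dict(tag)
            tag.update(
                {
                    "chrom": "chr1",
                    "start": positions[first_idx],
                    "end": positions[-1] + 1,
                    "cpg_first": first_idx,
                    "cpg_last": len(base_rows) - 1,
                }
            )
            blocks.append(tag)
        pos += gap_between

    for k, ct in enumerate(cell_types):
        for direction in (1, -1):
            for _ in range(blocks_per_type):
                means = np.full(K, lo if direction > 0 else hi)
                means[k] = hi if direction > 0 else lo
                add_block(means, {"cell_type": ct, "direction": direction})
    for _ in range(n_consensus):
        add_block(np.full(K, hi), None)
        add_block(np.full(K, lo), None)
    for _ in range(n_background):
        # background CpGs: isolated positions, no between-type signal
        row = np.full(K, hi if rng.uniform() < 0.5 else lo)
        base_rows.append(np.repeat(row, n_replicates))
        chroms.append("chr1")
        positions.append(pos)
        pos += gap_between

    base = np.vstack(base_rows)
    betas = np.clip(base + rng.normal(0.0, noise_sd, size=(len(base_rows), M)), 0.0, 1.0)
    ref = ReferenceSampleSet(
        betas=betas,
        labels=labels,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=int),
    )
    truth = pd.DataFrame(blocks)
    return ref, truth
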