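"""Differentially methylated region (DMR) search on sorted-cell data.

The latent-state matrix Z is built from sorted-cell reference samples
by a one-vs-rest search: for each cell type, the per-CpG two-group
mean difference (equivalently, the least-squares slope of a two-group
linear model) is computed, and maximal runs of consecutive CpGs with a
large same-sign effect and small inter-CpG gaps are called as
candidate regions.  Candidates from all (cell type, direction)
contrasts are ranked by (CpG count, mean absolute effect) and selected
greedily subject to pairwise non-overlap, so the chosen regions can be
treated as independent observations downstream.  Each region's latent
state Z_rk is then set by dichotomising the mean reference methylation
of cell type k in the region at a threshold (default 0.5).

The procedure is fully deterministic: identical inputs and criteria
give bit-identical output.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._exceptions import IdentifiabilityError, ValidationError
from .datamodel import GenomicRegion, RegionStateMatrix

__all__ = [
    "ReferenceSampleSet",
    "DMRCriteria",
    "CandidateRegion",
    "fit_per_cpg_contrast",
    "call_regions",
    "build_z_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSampleSet:
    """CpG-level betas for sorted-cell reference samples.

    ``betas`` is J CpGs x M samples; ``labels`` assigns each sample to
    one of K cell types (each type needs >= 2 replicates); positions
    must be sorted within each chromosome.
    """

    betas: np.ndarray
    labels: list[str]
    chroms: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=int)
        J, M = self.betas.shape
        if len(self.labels) != M:
            raise ValidationError(
                f"{len(self.labels)} labels for {M} sample columns"
            )
        if len(self.chroms) != J or len(self.positions) != J:
            raise ValidationError("chroms/positions length must match CpG count")
        if ((self.betas < -1e-9) | (self.betas > 1 + 1e-9)).any():
            raise ValidationError("reference betas must lie in [0, 1]")
        counts = pd.Series(self.labels).value_counts()
        thin = counts[counts < 2]
        if not thin.empty:
            raise ValidationError(
                f"cell type(s) with fewer than 2 replicates: {list(thin.index)}"
            )
        for chrom in pd.unique(self.chroms):
            p = self.positions[self.chroms == chrom]
            if not np.all(np.diff(p) > 0):
                raise ValidationError(
                    f"positions not strictly increasing on {chrom}"
                )

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(pd.Series(self.labels)))


@dataclass
class DMRCriteria:
    """Run-calling criteria for the one-vs-rest DMR search.

    ``effect_cutoff`` is the minimum absolute per-CpG mean difference;
    ``min_cpgs`` the CpG count above which a run counts as a proper
    multi-CpG region (smaller runs are kept only under the single-CpG
    rule); ``max_gap`` the maximum base-pair gap between consecutive
    CpGs of one region; ``include_single_cpgs`` forces sub-threshold
    runs to be kept, useful when too few regions are found.
    """

    effect_cutoff: float = 0.3
    min_cpgs: int = 2
    max_gap: int = 500
    max_regions_per_contrast: int = 20
    include_single_cpgs: bool = False
    state_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_cutoff < 1.0:
            raise ValidationError("effect_cutoff must be in (0, 1)")
        if self.max_gap <= 0:
            raise ValidationError("max_gap must be positive")
        if self.min_cpgs < 1:
            raise ValidationError("min_cpgs must be >= 1")


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    cpg_indices: np.ndarray
    direction: int  # +1: target hypermethylated vs rest; -1: hypomethylated
    mean_abs_effect: float
    cell_type: str = ""

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_indices)

    def overlaps(self, other: "CandidateRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def fit_per_cpg_contrast(
    ref: ReferenceSampleSet, target_cell_type: str
) -> pd.DataFrame:
    """Per-CpG one-vs-rest effect estimates for one cell type.

    The effect is the mean beta of the target cell type minus the mean
    of all other samples — identical to the least-squares slope of the
    two-group linear model with the rest group as baseline (sign
    flipped if the rest group is coded 1).  A pooled-variance t-like
    score accompanies each effect.
    """
    labels = np.asarray(ref.labels)
    in_target = labels == target_cell_type
    if not in_target.any():
        raise ValidationError(
            f"cell type '{target_cell_type}' not present in labels"
        )
    n1, n2 = int(in_target.sum()), int((~in_target).sum())
    if n2 == 0:
        raise ValidationError("no 'rest' samples to contrast against")
    tgt = ref.betas[:, in_target]
    rest = ref.betas[:, ~in_target]
    effect = tgt.mean(axis=1) - rest.mean(axis=1)
    v1 = tgt.var(axis=1, ddof=1)
    v2 = rest.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.sign(effect) * np.inf)
    tstat = np.where(effect == 0.0, 0.0, tstat)
    return pd.DataFrame({"effect": effect, "tstat": tstat})


def call_regions(
    effects: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    criteria: DMRCriteria,
) -> list[CandidateRegion]:
    """Call candidate regions as maximal same-sign runs of large effects.

    A run consists of consecutive CpGs on one chromosome with
    ``|effect| >= effect_cutoff``, identical effect sign, and inter-CpG
    gaps ``<= max_gap``.  Runs are ranked by (CpG count, mean absolute
    effect) descending.  Runs shorter than ``min_cpgs`` are kept only
    if ``include_single_cpgs`` is set or no longer run exists at all
    (regions with more than one CpG are prioritised whenever possible).
    Region bounds are ``[first CpG, last CpG + 1)``.
    """
    effects = np.asarray(effects, dtype=float)
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=int)
    strong = np.abs(effects) >= criteria.effect_cutoff
    candidates: list[CandidateRegion] = []
    run: list[int] = []

    def flush() -> None:
        if not run:
            return
        idx = np.asarray(run)
        candidates.append(
            CandidateRegion(
                chrom=str(chroms[idx[0]]),
                start=int(positions[idx[0]]),
                end=int(positions[idx[-1]]) + 1,
                cpg_indices=idx,
                direction=int(np.sign(effects[idx[0]])),
                mean_abs_effect=float(np.abs(effects[idx]).mean()),
            )
        )
        run.clear()

    for j in range(len(effects)):
        if not strong[j]:
            flush()
            continue
        if run:
            prev = run[-1]
            same = (
                chroms[j] == chroms[prev]
                and positions[j] - positions[prev] <= criteria.max_gap
                and np.sign(effects[j]) == np.sign(effects[prev])
            )
            if not same:
                flush()
        run.append(j)
    flush()

    multi = [c for c in candidates if c.n_cpgs >= max(criteria.min_cpgs, 2)]
    if not criteria.include_single_cpgs and multi:
        candidates = multi
    candidates.sort(
        key=lambda c: (-c.n_cpgs, -c.mean_abs_effect, c.chrom, c.start)
    )
    return candidates


def _region_state(
    ref: ReferenceSampleSet, cand: CandidateRegion, threshold: float
) -> np.ndarray:
    labels = np.asarray(ref.labels)
    block = ref.betas[cand.cpg_indices]
    return np.array(
        [
            1 if block[:, labels == ct].mean() > threshold else 0
            for ct in ref.cell_types
        ],
        dtype=np.int8,
    )


def build_z_matrix(
    ref: ReferenceSampleSet, criteria: DMRCriteria | None = None
) -> RegionStateMatrix:
    """Build the full-rank latent-state matrix Z from reference samples.

    Runs the one-vs-rest contrast for every cell type in both
    directions, pools all candidates, and greedily accepts the
    top-ranked non-overlapping ones (at most ``max_regions_per_contrast``
    per cell type and direction).  Latent states are assigned by
    dichotomising each cell type's mean reference beta per region at
    ``state_threshold``.
    """
    criteria = criteria or DMRCriteria()
    cell_types = ref.cell_types
    relaxed = replace(criteria, include_single_cpgs=True)
    pooled: list[CandidateRegion] = []
    for ct in cell_types:
        effects = fit_per_cpg_contrast(ref, ct)["effect"].to_numpy()
        cands = call_regions(effects, ref.chroms, ref.positions, relaxed)
        for direction in (1, -1):
            dir_cands = [c for c in cands if c.direction == direction]
            multi = [
                c for c in dir_cands if c.n_cpgs >= max(criteria.min_cpgs, 2)
            ]
            # prioritise proper multi-CpG regions; fall back to single-CpG
            # candidates only when a contrast has nothing better
            if multi and not criteria.include_single_cpgs:
                dir_cands = multi
            if not dir_cands:
                warnings.warn(
                    f"no candidate region for contrast ({ct}, "
                    f"{'hyper' if direction > 0 else 'hypo'})",
                    UserWarning,
                    stacklevel=2,
                )
            for c in dir_cands:
                c = CandidateRegion(
                    chrom=c.chrom,
                    start=c.start,
                    end=c.end,
                    cpg_indices=c.cpg_indices,
                    direction=c.direction,
                    mean_abs_effect=c.mean_abs_effect,
                    cell_type=ct,
                )
                pooled.append(c)
    if not pooled:
        raise ValidationError(
            "no differential signal found: no candidate regions for any "
            "contrast; relax effect_cutoff or set include_single_cpgs"
        )
    pooled.sort(
        key=lambda c: (
            -c.n_cpgs, -c.mean_abs_effect, c.chrom, c.start, c.cell_type, -c.direction
        )
    )
    accepted: list[CandidateRegion] = []
    per_contrast: dict[tuple[str, int], int] = {}
    for c in pooled:
        key = (c.cell_type, c.direction)
        if per_contrast.get(key, 0) >= criteria.max_regions_per_contrast:
            continue
        if any(c.overlaps(a) for a in accepted):
            continue
        accepted.append(c)
        per_contrast[key] = per_contrast.get(key, 0) + 1
    accepted.sort(key=lambda c: (c.chrom, c.start))
    regions = [
        GenomicRegion(
            chrom=c.chrom,
            start=c.start,
            end=c.end,
            region_id=f"dmr{i:04d}_{c.cell_type}_"
            f"{'hyper' if c.direction > 0 else 'hypo'}",
        )
        for i, c in enumerate(accepted)
    ]
    Zrows = np.vstack(
        [_region_state(ref, c, criteria.state_threshold) for c in accepted]
    )
    try:
        rsm = RegionStateMatrix(regions=regions, cell_types=cell_types, Z=Zrows)
    except IdentifiabilityError as exc:
        raise IdentifiabilityError(
            f"{exc} The DMR search did not separate all cell types; relax "
            "effect_cutoff / max_gap or enable include_single_cpgs."
        ) from exc
    logger.info(
        "built Z with R=%d regions over K=%d cell types (per-contrast: %s)",
        rsm.n_regions, rsm.n_cell_types,
        {f"{k[0]}{'+' if k[1] > 0 else '-'}": v for k, v in per_contrast.items()},
    )
    return rsm
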