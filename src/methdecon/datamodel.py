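"""Core domain containers for region-level methylation deconvolution.

The estimation machinery works on three objects:

* a :class:`RegionStateMatrix` holding R genomic regions and a binary
  R x K matrix ``Z`` that says, for each region and each of the K cell
  types, whether the region is methylated (1) or unmethylated (0) in
  that cell type.  ``Z`` is determined by biology, not by the assay, so
  it is shared across platforms;
* per-sample CpG-level measurements (:class:`CpGMeasurementTable`),
  either array-style beta values or bisulfite-sequencing counts;
* the region-by-sample matrix ``Y`` of observed methylation fractions
  (:class:`RegionMethylationMatrix`) obtained by summarising CpGs
  within each region.

All genomic coordinates are 0-based, half-open (BED convention).
Strand is ignored: CpG measurements are assumed pre-collapsed to one
strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import IdentifiabilityError, ValidationError

__all__ = [
    "GenomicRegion",
    "RegionStateMatrix",
    "CpGMeasurementTable",
    "RegionMethylationMatrix",
    "CellTypeReferenceProfile",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValidationError(
                f"region {self.region_id}: negative coordinate "
                f"({self.start}, {self.end})"
            )
        if not self.start < self.end:
            raise ValidationError(
                f"region {self.region_id}: start must be < end, got "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Half-open membership: ``start <= pos < end``."""
        return chrom == self.chrom and self.start <= pos < self.end


def _dependent_columns(Z: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns that do not increase the rank of the preceding ones."""
    dependent = []
    rank = 0
    kept: list[int] = []
    for j in range(Z.shape[1]):
        cand = Z[:, kept + [j]].astype(float)
        new_rank = np.linalg.matrix_rank(cand)
        if new_rank > rank:
            kept.append(j)
            rank = new_rank
        else:
            dependent.append(names[j])
    return dependent


@dataclass
class RegionStateMatrix:
    """R non-overlapping regions with a binary R x K latent-state matrix.

    ``Z[r, k] == 1`` iff region ``r`` is methylated in cell type ``k``.
    ``Z`` must have full column rank for the mixing proportions to be
    identifiable.
    """

    regions: list[GenomicRegion]
    cell_types: list[str]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z)
        R, K = len(self.regions), len(self.cell_types)
        if self.Z.shape != (R, K):
            raise ValidationError(
                f"Z has shape {self.Z.shape}, expected ({R}, {K})"
            )
        if len(set(self.cell_types)) != K:
            raise ValidationError("duplicate cell-type names")
        if not np.isin(self.Z, (0, 1)).all():
            raise ValidationError("Z entries must all be 0 or 1")
        self.Z = self.Z.astype(np.int8)
        self._check_non_overlapping()
        rank = np.linalg.matrix_rank(self.Z.astype(float))
        if rank < K:
            dep = _dependent_columns(self.Z, self.cell_types)
            raise IdentifiabilityError(
                f"Z is rank deficient (rank {rank} < K={K}); dependent "
                f"cell-type columns: {dep}. Proportions are not "
                "identifiable — add regions that separate these cell types."
            )

    def _check_non_overlapping(self) -> None:
        order = sorted(
            range(len(self.regions)),
            key=lambda i: (self.regions[i].chrom, self.regions[i].start),
        )
        for a, b in zip(order, order[1:]):
            ra, rb = self.regions[a], self.regions[b]
            if ra.chrom == rb.chrom and rb.start < ra.end:
                raise ValidationError(
                    f"regions overlap: {ra.region_id} and {rb.region_id}"
                )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "region_id": [r.region_id for r in self.regions],
            }
        )
        for j, ct in enumerate(self.cell_types):
            df[ct] = self.Z[:, j]
        return df


@dataclass
class CpGMeasurementTable:
    """CpG-level measurements for one sample.

    ``data`` is a DataFrame with columns ``cpg_id``, ``chrom``, ``pos``
    (0-based) plus either a ``beta`` column (array-style input) or
    integer ``meth`` / ``unmeth`` count columns (sequencing-style
    input).  Positions must be unique within the sample.
    """

    sample_id: str
    data: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        required = {"cpg_id", "chrom", "pos"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(
                f"sample {self.sample_id}: missing columns {sorted(missing)}"
            )
        has_beta = "beta" in self.data.columns
        has_counts = {"meth", "unmeth"} <= set(self.data.columns)
        if not (has_beta or has_counts):
            raise ValidationError(
                f"sample {self.sample_id}: need a 'beta' column or "
                "'meth'/'unmeth' count columns"
            )
        if self.data.duplicated(["chrom", "pos"]).any():
            raise ValidationError(
                f"sample {self.sample_id}: duplicate CpG positions"
            )
        if has_beta:
            beta = self.data["beta"].to_numpy(float)
            ok = np.isnan(beta) | ((beta >= 0.0) & (beta <= 1.0))
            if not ok.all():
                bad = beta[~ok][0]
                raise ValidationError(
                    f"sample {self.sample_id}: beta value {bad!r} outside [0, 1]"
                )
        if has_counts:
            for col in ("meth", "unmeth"):
                counts = self.data[col].to_numpy()
                if (counts < 0).any():
                    raise ValidationError(
                        f"sample {self.sample_id}: negative {col} count"
                    )
                if not np.issubdtype(counts.dtype, np.integer):
                    if not np.allclose(counts, np.round(counts)):
                        raise ValidationError(
                            f"sample {self.sample_id}: non-integer {col} count"
                        )
                    self.data[col] = counts.astype(np.int64)

    @property
    def kind(self) -> str:
        """``"sequencing"`` if count columns are present, else ``"array"``."""
        return (
            "sequencing"
            if {"meth", "unmeth"} <= set(self.data.columns)
            else "array"
        )

    def levels(self) -> np.ndarray:
        """Per-CpG methylation fraction; NaN where coverage is zero."""
        if self.kind == "array":
            return self.data["beta"].to_numpy(float)
        meth = self.data["meth"].to_numpy(float)
        total = meth + self.data["unmeth"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
        return lev


@dataclass
class RegionMethylationMatrix:
    """Region-by-sample methylation fractions Y (R x N); NaN = missing."""

    regions: list[GenomicRegion]
    sample_ids: list[str]
    Y: np.ndarray
    cpg_counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        R, N = len(self.regions), len(self.sample_ids)
        if self.Y.shape != (R, N):
            raise ValidationError(
                f"Y has shape {self.Y.shape}, expected ({R}, {N})"
            )
        obs = ~np.isnan(self.Y)
        vals = self.Y[obs]
        if vals.size and ((vals < -1e-9).any() or (vals > 1 + 1e-9).any()):
            raise ValidationError("non-missing Y entries must lie in [0, 1]")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.Y)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Y,
            index=[r.region_id for r in self.regions],
            columns=self.sample_ids,
        )


@dataclass
class CellTypeReferenceProfile:
    """CpG-level cell-type-specific methylation profiles X (J x K).

    This is the plug-in design of the classical reference-based
    estimator: column k is the measured methylation profile of sorted
    cells of type k on one particular platform.
    """

    cpg_ids: list[str]
    cell_types: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        J, K = len(self.cpg_ids), len(self.cell_types)
        if self.X.shape != (J, K):
            raise ValidationError(
                f"X has shape {self.X.shape}, expected ({J}, {K})"
            )
        if np.isnan(self.X).any():
            raise ValidationError("reference profile contains missing entries")
        if ((self.X < -1e-9) | (self.X > 1 + 1e-9)).any():
            raise ValidationError("reference profile entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.cpg_ids, columns=self.cell_types)
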