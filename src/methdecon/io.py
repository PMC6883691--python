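"""Readers, writers and CpG-to-region summarisation.

File formats
------------
* **Region BED** — tab-separated with a header line: ``chrom  start  end
  region_id  <cell type 1> ... <cell type K>`` where the cell-type
  columns hold the binary latent states.  Coordinates are 0-based,
  half-open.
* **Beta table** — tab-separated, header ``cpg_id  chrom  pos
  <sample 1> ... <sample N>`` with beta values in [0, 1].
* **Bismark coverage** — headerless, tab-separated: chromosome,
  start (1-based), end (1-based inclusive), methylation percentage,
  methylated count, unmethylated count.  Converted to 0-based
  positions on read.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .datamodel import (
    CellTypeReferenceProfile,
    CpGMeasurementTable,
    GenomicRegion,
    RegionMethylationMatrix,
    RegionStateMatrix,
)

__all__ = [
    "read_regions",
    "write_regions",
    "read_beta_table",
    "write_beta_table",
    "read_bismark_coverage",
    "write_bismark_coverage",
    "summarize_regions",
    "read_reference_profile",
    "write_reference_profile",
    "write_region_matrix",
    "load_packaged_regions",
]

_BED_FIXED = ["chrom", "start", "end", "region_id"]


def read_regions(path, state_columns: Sequence[str] | None = None) -> RegionStateMatrix:
    """Read a region BED file with binary cell-type state columns.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with header ``chrom start end region_id`` plus
        one binary column per cell type.
    state_columns : sequence of str, optional
        Names of the cell-type columns to use.  Defaults to every column
        after ``region_id``.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"cannot parse region file {path}: {exc}") from exc
    missing = [c for c in _BED_FIXED if c not in df.columns]
    if missing:
        raise ValidationError(
            f"region file {path}: missing columns {missing} "
            "(expected header: chrom start end region_id <cell types...>)"
        )
    if state_columns is None:
        state_columns = [c for c in df.columns if c not in _BED_FIXED]
    else:
        absent = [c for c in state_columns if c not in df.columns]
        if absent:
            raise ValidationError(
                f"region file {path}: state columns {absent} not present"
            )
    if not state_columns:
        raise ValidationError(f"region file {path}: no cell-type state columns")
    try:
        starts = df["start"].astype(int)
        ends = df["end"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"region file {path}: malformed coordinates ({exc})"
        ) from exc
    regions = [
        GenomicRegion(str(c), int(s), int(e), str(rid))
        for c, s, e, rid in zip(df["chrom"], starts, ends, df["region_id"])
    ]
    Z = df[list(state_columns)].to_numpy()
    return RegionStateMatrix(regions=regions, cell_types=list(state_columns), Z=Z)


def write_regions(rsm: RegionStateMatrix, path) -> None:
    rsm.to_frame().to_csv(path, sep="\t", index=False)


def read_beta_table(
    path, clamp: bool = False, tol: float = 1e-9, platform: str = "array"
) -> list[CpGMeasurementTable]:
    """Read a multi-sample beta table; returns one table per sample column."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    # round_trip parsing keeps write->read bit-exact for beta values
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in ("cpg_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValidationError(f"beta table {path}: missing column '{col}'")
    sample_cols = [c for c in df.columns if c not in ("cpg_id", "chrom", "pos")]
    if not sample_cols:
        raise ValidationError(f"beta table {path}: no sample columns")
    tables = []
    for col in sample_cols:
        beta = df[col].to_numpy(float)
        finite = ~np.isnan(beta)
        out_of_range = finite & ((beta < -tol) | (beta > 1 + tol))
        if out_of_range.any():
            if not clamp:
                bad = beta[out_of_range][0]
                raise ValidationError(
                    f"beta table {path}, sample {col}: beta value {bad} "
                    f"outside [0, 1] beyond tolerance {tol}"
                )
        beta = np.clip(beta, 0.0, 1.0)
        data = pd.DataFrame(
            {
                "cpg_id": df["cpg_id"].astype(str),
                "chrom": df["chrom"].astype(str),
                "pos": df["pos"].astype(int),
                "beta": beta,
            }
        )
        tables.append(
            CpGMeasurementTable(sample_id=str(col), data=data, platform=platform)
        )
    return tables


def write_beta_table(samples: Sequence[CpGMeasurementTable], path) -> None:
    """Write array-style samples (sharing the same CpGs) to one beta table."""
    if not samples:
        raise ValidationError("no samples to write")
    base = samples[0].data[["cpg_id", "chrom", "pos"]].reset_index(drop=True)
    out = base.copy()
    for s in samples:
        if s.kind != "array":
            raise ValidationError(
                f"sample {s.sample_id}: beta tables require array-style input"
            )
        d = s.data.reset_index(drop=True)
        if not (d["pos"].equals(base["pos"]) and d["chrom"].equals(base["chrom"])):
            raise ValidationError("samples do not share the same CpG set")
        out[s.sample_id] = d["beta"].to_numpy()
    # %.17g guarantees bit-exact float round-trips through the text format
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_bismark_coverage(
    path, sample_id: str | None = None, platform: str = "sequencing"
) -> CpGMeasurementTable:
    """Read one Bismark-coverage-style file as a sequencing sample.

    Input positions are 1-based inclusive and converted to the internal
    0-based convention.  CpGs with zero total coverage are kept; their
    methylation level is reported as missing.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
    )
    if df.shape[1] != 6:
        raise ValidationError(f"coverage file {path}: expected 6 columns")
    sample_id = sample_id or Path(str(path)).stem
    pos = df["start"].astype(int) - 1  # 1-based -> 0-based
    data = pd.DataFrame(
        {
            "cpg_id": df["chrom"].astype(str) + ":" + pos.astype(str),
            "chrom": df["chrom"].astype(str),
            "pos": pos,
            "meth": df["meth"].astype(int),
            "unmeth": df["unmeth"].astype(int),
        }
    )
    return CpGMeasurementTable(sample_id=sample_id, data=data, platform=platform)


def write_bismark_coverage(sample: CpGMeasurementTable, path) -> None:
    if sample.kind != "sequencing":
        raise ValidationError("coverage output requires count data")
    d = sample.data
    total = (d["meth"] + d["unmeth"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * d["meth"] / np.where(total > 0, total, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": d["chrom"],
            "start": d["pos"] + 1,  # back to 1-based
            "end": d["pos"] + 1,
            "pct": pct,
            "meth": d["meth"],
            "unmeth": d["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _assign_regions(
    table: CpGMeasurementTable, regions: list[GenomicRegion]
) -> np.ndarray:
    """Region index for each CpG (-1 if in no region); half-open overlap."""
    assignment = np.full(len(table.data), -1, dtype=int)
    by_chrom: dict[str, list[int]] = {}
    for idx, reg in enumerate(regions):
        by_chrom.setdefault(reg.chrom, []).append(idx)
    chroms = table.data["chrom"].to_numpy()
    pos = table.data["pos"].to_numpy(int)
    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: regions[i].start)
        starts = np.array([regions[i].start for i in idxs])
        ends = np.array([regions[i].end for i in idxs])
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        p = pos[sel]
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < ends[np.clip(j, 0, len(idxs) - 1)])
        assignment[sel[ok]] = np.array(idxs)[j[ok]]
    return assignment


def summarize_regions(
    samples: Sequence[CpGMeasurementTable],
    regions: RegionStateMatrix,
    weighting: str = "auto",
    sparse_region_fraction: float = 0.5,
    drop_sparse_regions: bool = False,
) -> RegionMethylationMatrix:
    """Summarise CpG-level measurements into the R x N matrix Y.

    For each sample and region, the region-level methylation level is
    the unweighted mean of per-CpG levels ("unweighted") or the pooled
    count ratio sum(meth)/sum(meth+unmeth) ("coverage", sequencing
    input only).  ``weighting="auto"`` picks unweighted for array
    samples and coverage for sequencing samples.  Regions with no
    covered CpG in a sample are missing (NaN); regions missing in more
    than ``sparse_region_fraction`` of samples trigger a warning and
    are dropped when ``drop_sparse_regions`` is set.

    The returned matrix carries a per-region, per-sample CpG-count
    report in its ``cpg_counts`` attribute.
    """
    if weighting not in ("auto", "unweighted", "coverage"):
        raise ValidationError(f"unknown weighting '{weighting}'")
    R = regions.n_regions
    N = len(samples)
    if N == 0:
        raise ValidationError("no samples given")
    Y = np.full((R, N), np.nan)
    counts = np.zeros((R, N), dtype=int)
    for i, s in enumerate(samples):
        mode = weighting
        if mode == "auto":
            mode = "coverage" if s.kind == "sequencing" else "unweighted"
        if mode == "coverage" and s.kind != "sequencing":
            raise ValidationError(
                f"sample {s.sample_id}: coverage weighting requires count data"
            )
        assignment = _assign_regions(s, regions.regions)
        in_region = assignment >= 0
        if not in_region.any():
            raise ValidationError(
                f"sample {s.sample_id} has no CpG overlapping any region"
            )
        idx = assignment[in_region]
        if mode == "coverage":
            meth = s.data["meth"].to_numpy(float)[in_region]
            unmeth = s.data["unmeth"].to_numpy(float)[in_region]
            m_sum = np.bincount(idx, weights=meth, minlength=R)
            t_sum = np.bincount(idx, weights=meth + unmeth, minlength=R)
            covered = np.bincount(idx, minlength=R) > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(t_sum > 0, m_sum / np.where(t_sum > 0, t_sum, 1), np.nan)
            Y[covered, i] = vals[covered]
            counts[:, i] = np.bincount(idx, minlength=R)
        else:
            lev = s.levels()[in_region]
            keep = ~np.isnan(lev)
            idx_k = idx[keep]
            sums = np.bincount(idx_k, weights=lev[keep], minlength=R)
            n = np.bincount(idx_k, minlength=R)
            covered = n > 0
            Y[covered, i] = sums[covered] / n[covered]
            counts[:, i] = n
    miss_frac = np.isnan(Y).mean(axis=1)
    sparse = miss_frac > sparse_region_fraction
    if sparse.any():
        names = [regions.regions[r].region_id for r in np.flatnonzero(sparse)]
        warnings.warn(
            f"{sparse.sum()} region(s) missing in more than "
            f"{sparse_region_fraction:.0%} of samples: {names[:10]}",
            UserWarning,
            stacklevel=2,
        )
    region_list = regions.regions
    if drop_sparse_regions and sparse.any():
        keep = ~sparse
        Y = Y[keep]
        counts = counts[keep]
        region_list = [r for r, k in zip(region_list, keep) if k]
    report = pd.DataFrame(
        counts,
        index=[r.region_id for r in region_list],
        columns=[s.sample_id for s in samples],
    )
    return RegionMethylationMatrix(
        regions=list(region_list),
        sample_ids=[s.sample_id for s in samples],
        Y=Y,
        cpg_counts=report,
    )


def read_reference_profile(path) -> CellTypeReferenceProfile:
    """Read a CpG x cell-type reference profile TSV (index = cpg_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellTypeReferenceProfile(
        cpg_ids=[str(i) for i in df.index],
        cell_types=[str(c) for c in df.columns],
        X=df.to_numpy(float),
    )


def write_reference_profile(ref: CellTypeReferenceProfile, path) -> None:
    ref.to_frame().to_csv(path, sep="\t", index_label="cpg_id")


def write_region_matrix(mat: RegionMethylationMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="region_id")


def load_packaged_regions() -> RegionStateMatrix:
    """Load the packaged synthetic whole-blood region fixture.

    The fixture was produced by running the package's own DMR search on
    a synthetic sorted-cell reference (six leukocyte types); it is a
    synthetic stand-in for an experimentally derived whole-blood region
    set, shipped so the pipeline can run end to end out of the box.
    """
    from importlib.resources import files

    path = files("methdecon").joinpath("data/synthetic_wholeblood_regions.bed")
    with path.open("r") as fh:
        return read_regions(fh)
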