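"""Reading, writing, validation and region aggregation of per-CpG methylation data.

Coordinate conventions
----------------------
All interval logic is 0-based half-open: an interval ``[start, end)``
contains position ``p`` iff ``start <= p < end``.  A CpG site is addressed
by the position of the C on the forward strand, with both strands of the CG
dinucleotide assumed pre-merged by the upstream quantifier.

The native on-disk methylome dialect is 6-column tab-separated text::

    chrom  start  end  ratio  coverage  meth_count

(start = CpG position, end = start + 2, covering the CG dinucleotide).
A plain 4-column bedGraph (``chrom start end ratio``) is also accepted, in
which case coverage information is absent and the minimum-coverage filter
cannot be applied (a warning is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of an in-memory methylome frame
METH_COLUMNS = ["chrom", "pos", "coverage", "meth_count", "ratio"]

#: canonical column order of an interval frame (BED-like, 0-based half-open)
INTERVAL_COLUMNS = ["chrom", "start", "end"]


@dataclass
class MethylationMatrix:
    """Features-by-samples beta-value matrix with group labels.

    Parameters
    ----------
    values
        DataFrame of beta values in [0, 1]; rows are features (sites or
        regions), columns are sample ids.  Missing values allowed (NaN).
    features
        DataFrame indexed like ``values`` with at least ``chrom`` and either
        ``pos`` (site-level) or ``start``/``end`` (region-level) columns.
    groups
        Series mapping sample id -> group label; must cover every column of
        ``values``.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.features.index):
            raise ValueError("values and features indexes differ")
        if self.groups is not None:
            missing = [s for s in self.values.columns if s not in self.groups.index]
            if missing:
                raise ValueError(f"samples without group label: {missing}")
            self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_of(self, group: str) -> list:
        if self.groups is None:
            raise ValueError("matrix has no group labels")
        return list(self.groups.index[self.groups == group])

    def group_means(self) -> pd.DataFrame:
        """Per-feature mean beta per group (NaN-aware)."""
        out = {}
        for g in pd.unique(self.groups):
            out[g] = self.values[self.samples_of(g)].mean(axis=1)
        return pd.DataFrame(out)

    def subset_features(self, mask_or_index) -> "MethylationMatrix":
        v = self.values.loc[mask_or_index]
        f = self.features.loc[v.index]
        return MethylationMatrix(v, f, self.groups)


def _finalize_methylome(df: pd.DataFrame, min_coverage: int, source: str) -> pd.DataFrame:
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if df["coverage"].notna().all():
        n0 = len(df)
        df = df[df["coverage"] >= min_coverage].reset_index(drop=True)
        logger.info("%s: dropped %d/%d sites with coverage < %d", source, n0 - len(df), n0, min_coverage)
    return df


def read_methylome(path, min_coverage: int = 4) -> pd.DataFrame:
    """Read a per-CpG methylation file into a sorted, coverage-filtered frame.

    Sites with ``coverage < min_coverage`` are dropped (default 4, matching
    the quantification floor used throughout the pipeline); the drop count
    is logged.  Returns a frame with columns ``chrom, pos, coverage,
    meth_count, ratio`` sorted by (chrom, pos).

    Raises
    ------
    ValueError
        On a malformed line (wrong column count, non-numeric field,
        meth_count > coverage), with the 1-based line number.
    """
    path = Path(path)
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if ncols is None:
                if len(parts) not in (4, 6):
                    raise ValueError(f"{path}:{lineno}: expected 4 or 6 columns, got {len(parts)}")
                ncols = len(parts)
            if len(parts) != ncols:
                raise ValueError(f"{path}:{lineno}: expected {ncols} columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                ratio = float(parts[3])
                if ncols == 6:
                    cov = int(parts[4])
                    meth = int(parts[5])
                else:
                    cov = meth = None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            if cov is not None:
                if meth > cov:
                    raise ValueError(f"{path}:{lineno}: meth_count {meth} > coverage {cov}")
                if cov < 0 or meth < 0:
                    raise ValueError(f"{path}:{lineno}: negative count")
            if not (np.isnan(ratio) or 0.0 <= ratio <= 1.0):
                raise ValueError(f"{path}:{lineno}: ratio {ratio} outside [0, 1]")
            rows.append((chrom, start, cov, meth, ratio))
    df = pd.DataFrame(rows, columns=METH_COLUMNS)
    if ncols == 4:
        logger.warning("%s: 4-column bedGraph without coverage; min_coverage filter not applied", path)
        df["coverage"] = np.nan
        df["meth_count"] = np.nan
        return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["coverage"] = df["coverage"].astype(np.int64)
    df["meth_count"] = df["meth_count"].astype(np.int64)
    return _finalize_methylome(df, min_coverage, str(path))


def write_methylome(records: pd.DataFrame, path) -> None:
    """Write the 6-column methylome dialect (lossless round-trip partner of
    :func:`read_methylome` at ``min_coverage=0``)."""
    df = records.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(np.int64),
            "end": df["pos"].astype(np.int64) + 2,
            "ratio": df["ratio"].map(lambda r: "nan" if pd.isna(r) else format(r, ".6g")),
            "coverage": df["coverage"].astype(np.int64),
            "meth_count": df["meth_count"].astype(np.int64),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def records_from_arrays(chrom, pos, coverage, meth_count) -> pd.DataFrame:
    """Assemble a methylome frame from parallel arrays; ratio is NaN where
    coverage is zero."""
    pos = np.asarray(pos, dtype=np.int64)
    coverage = np.asarray(coverage, dtype=np.int64)
    meth_count = np.asarray(meth_count, dtype=np.int64)
    if np.any(meth_count > coverage):
        raise ValueError("meth_count > coverage")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(coverage > 0, meth_count / np.maximum(coverage, 1), np.nan)
    if np.isscalar(chrom) or isinstance(chrom, str):
        chrom = np.repeat(chrom, len(pos))
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "coverage": coverage, "meth_count": meth_count, "ratio": ratio}
    )


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 interval file (0-based half-open)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: interval with start >= end at row {bad}")
    return df


def write_bed(intervals: pd.DataFrame, path, extra_cols: Iterable[str] = ()) -> None:
    cols = ["chrom", "start", "end"]
    for c in ("name", "score", "strand"):
        if c in intervals.columns:
            cols.append(c)
    cols += [c for c in extra_cols if c in intervals.columns and c not in cols]
    intervals.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def make_windows(chrom_sizes: Mapping[str, int], width: int = 2000) -> pd.DataFrame:
    """Tile each chromosome with nonoverlapping windows of ``width`` bp.

    The last window of each chromosome is truncated at the chromosome end,
    so the total count is sum(ceil(len / width)).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    frames = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def _region_means_one_sample(records: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Unweighted mean ratio per region for one sample; NaN where no CpG."""
    out = np.full(len(regions), np.nan)
    for chrom, sub in records.groupby("chrom", sort=False):
        sel = regions["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        ratio = sub["ratio"].to_numpy()[order]
        csum = np.concatenate([[0.0], np.nancumsum(ratio)])
        cnt = np.concatenate([[0], np.cumsum(~np.isnan(ratio))])
        lo = np.searchsorted(pos, regions.loc[sel, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, regions.loc[sel, "end"].to_numpy(), side="left")
        n = cnt[hi] - cnt[lo]
        with np.errstate(invalid="ignore"):
            means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        out[sel] = means
    return out


def map_to_regions(
    samples: Mapping[str, pd.DataFrame],
    regions: pd.DataFrame,
    groups: pd.Series | None = None,
    stat: str = "mean",
) -> MethylationMatrix:
    """Aggregate per-CpG ratios to per-region, per-sample means.

    For every region and sample the value is the unweighted mean of the
    ratios of CpGs whose position lies in ``[start, end)``.  Regions with no
    covered CpG for a sample are missing (NaN).  The result is invariant to
    the order of the input records.

    Parameters
    ----------
    samples
        Mapping sample id -> methylome frame (``chrom, pos, ..., ratio``).
    regions
        Interval frame; its index becomes the feature index of the matrix.
    groups
        Optional sample -> group labels carried on the matrix.
    stat
        Only ``"mean"`` is supported.
    """
    if stat != "mean":
        raise ValueError("only stat='mean' is supported")
    regions = regions.copy()
    values = {}
    for sid, rec in samples.items():
        values[sid] = _region_means_one_sample(rec, regions)
    vdf = pd.DataFrame(values, index=regions.index)
    return MethylationMatrix(vdf, regions, groups)


def drop_chromosome(data, chrom: str = "chrX"):
    """Remove every record/feature on the named chromosome.

    Accepts a methylome/interval DataFrame (any frame with a ``chrom``
    column) or a :class:`MethylationMatrix`; idempotent.
    """
    if isinstance(data, MethylationMatrix):
        keep = data.features["chrom"] != chrom
        return MethylationMatrix(
            data.values.loc[keep], data.features.loc[keep], data.groups
        )
    if "chrom" not in data.columns:
        raise ValueError("frame has no 'chrom' column")
    return data[data["chrom"] != chrom].reset_index(drop=True)
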