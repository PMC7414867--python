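"""Signal-quality and cross-platform similarity metrics on Log2-ratio data.

Two probe-level noise measures and two binned cross-platform measures:

* **dLRS** (derivative Log Ratio Spread): sample standard deviation of
  the Log2 differences between genomically adjacent probes, divided by
  sqrt(2) so that for white noise it estimates the per-probe sd.  A
  ``plain_sd`` flag computes the plain standard deviation of the Log2
  values instead, for the literal "sd of Log2 ratios" reading.
* **MAPD**: median absolute Log2 difference between adjacent probes.
* **Binned deviation / correlation**: both platforms' Log2 signals are
  reduced to a fixed 10 kb bin grid (median of the values mapping to each
  bin); the cross-platform deviation is the median absolute per-bin
  difference of *segmented* Log2, and the cross-platform correlation is
  the Spearman coefficient of the *unsegmented* (probe) Log2.

Adjacency never spans a chromosome boundary.  Missing bins are excluded
pairwise, never imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cn_io import ProbeTrack, SegmentProfile
from .genome_ref import BinGrid

__all__ = [
    "BinnedTrack",
    "dlrs",
    "mapd",
    "segment_log2",
    "bin_median",
    "binned_deviation",
    "binned_spearman",
]


@dataclass
class BinnedTrack:
    """Per-bin median Log2 values on a :class:`~hrdscar.genome_ref.BinGrid`.

    ``values`` has one entry per grid bin, NaN where no datum mapped.
    """

    grid: BinGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.total,):
            raise ValueError(
                f"expected {self.grid.total} bin values, got {self.values.shape}"
            )

    @property
    def covered(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _adjacent_diffs(track: ProbeTrack) -> np.ndarray:
    parts = [
        np.diff(grp["log2"].to_numpy(dtype=float))
        for _, grp in track.data.groupby("chrom", sort=False)
    ]
    parts = [p for p in parts if p.size]
    return np.concatenate(parts) if parts else np.empty(0)


def dlrs(track: ProbeTrack, plain_sd: bool = False) -> float:
    """Derivative Log Ratio Spread of a probe track.

    sd(adjacent within-chromosome Log2 differences, ddof=1) / sqrt(2);
    with ``plain_sd=True``, sd of the Log2 values themselves.
    """
    if len(track) < 3:
        raise ValueError(f"dLRS needs at least 3 probes, got {len(track)}")
    if plain_sd:
        return float(np.std(track.data["log2"].to_numpy(dtype=float), ddof=1))
    diffs = _adjacent_diffs(track)
    if diffs.size < 2:
        raise ValueError("dLRS needs at least 2 adjacent probe differences")
    return float(np.std(diffs, ddof=1) / math.sqrt(2.0))


def mapd(track: ProbeTrack) -> float:
    """Median absolute Log2 difference between adjacent probes."""
    if len(track) < 2:
        raise ValueError(f"MAPD needs at least 2 probes, got {len(track)}")
    diffs = _adjacent_diffs(track)
    if diffs.size == 0:
        raise ValueError("MAPD found no within-chromosome adjacent pairs")
    return float(np.median(np.abs(diffs)))


def segment_log2(profile: SegmentProfile) -> np.ndarray:
    """Per-segment Log2 ratio from copy state: log2(total / ploidy).

    A homozygous-deletion total of 0 is floored at 0.5 copies to keep the
    logarithm finite.
    """
    totals = np.array([max(s.total, 0.5) for s in profile.segments], dtype=float)
    return np.log2(totals / profile.ploidy)


def bin_median(
    source: ProbeTrack | SegmentProfile,
    grid: BinGrid,
    mode: str = "probe",
    log2_values: np.ndarray | None = None,
) -> BinnedTrack:
    """Reduce a probe track or a segmentation to per-bin median Log2.

    In ``probe`` mode each probe maps to the bin containing its position.
    In ``segmented`` mode each segment contributes its single Log2 value
    once per bin it overlaps (not length-weighted); segment Log2 values
    default to :func:`segment_log2` when not supplied.  Bin medians use
    the midpoint convention for ties.
    """
    if mode == "probe":
        if not isinstance(source, ProbeTrack):
            raise TypeError("probe mode needs a ProbeTrack")
        idx_parts, val_parts = [], []
        for chrom, grp in source.data.groupby("chrom", sort=False):
            if chrom not in grid.build.lengths:
                raise ValueError(f"chromosome {chrom} absent from bin grid")
            pos = grp["pos"].to_numpy()
            off = grid.offsets[chrom]
            idx_parts.append(off + (pos - 1) // grid.bin_size)
            val_parts.append(grp["log2"].to_numpy(dtype=float))
        idx = np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=int)
        vals = np.concatenate(val_parts) if val_parts else np.empty(0)
    elif mode == "segmented":
        if not isinstance(source, SegmentProfile):
            raise TypeError("segmented mode needs a SegmentProfile")
        seg_vals = (
            np.asarray(log2_values, dtype=float)
            if log2_values is not None
            else segment_log2(source)
        )
        if seg_vals.shape != (len(source.segments),):
            raise ValueError("one Log2 value per segment required")
        idx_list, val_list = [], []
        for seg, v in zip(source.segments, seg_vals):
            if seg.chrom not in grid.build.lengths:
                raise ValueError(f"chromosome {seg.chrom} absent from bin grid")
            first, last = grid.bin_span(seg.chrom, seg.start, seg.end)
            idx_list.append(np.arange(first, last + 1))
            val_list.append(np.full(last - first + 1, v))
        idx = np.concatenate(idx_list) if idx_list else np.empty(0, dtype=int)
        vals = np.concatenate(val_list) if val_list else np.empty(0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = np.full(grid.total, np.nan)
    if idx.size:
        med = pd.Series(vals).groupby(pd.Series(idx)).median()
        out[med.index.to_numpy()] = med.to_numpy()
    return BinnedTrack(grid=grid, values=out)


def _joint(a: BinnedTrack, b: BinnedTrack) -> tuple[np.ndarray, np.ndarray]:
    if a.grid != b.grid:
        raise ValueError("binned tracks are on different grids")
    both = a.covered & b.covered
    if not both.any():
        raise ValueError("no jointly covered bins")
    return a.values[both], b.values[both]


def binned_deviation(a: BinnedTrack, b: BinnedTrack) -> float:
    """Median absolute per-bin difference over jointly covered bins."""
    va, vb = _joint(a, b)
    return float(np.median(np.abs(va - vb)))


def binned_spearman(a: BinnedTrack, b: BinnedTrack) -> float:
    """Spearman correlation over jointly covered bins (NaN if degenerate)."""
    va, vb = _joint(a, b)
    if va.size < 3:
        raise ValueError(f"Spearman needs >= 3 jointly covered bins, got {va.size}")
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(va, vb)
    return float(rho)
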