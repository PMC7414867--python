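"""Readers, writers and validation for segment tables and probe-level tracks.

The scoring substrate is the output of allele-specific copy-number callers
(ASCAT for arrays, ascatNgs for WGS): per-segment major/minor allele copy
counts plus sample purity (aberrant cell fraction) and ploidy.  Three
tabular dialects are understood:

* ``generic`` - TSV, header ``sample chrom start end nMajor nMinor``
  (optional ``purity``/``ploidy`` columns);
* ``ascat`` - TSV, header ``sample chr startpos endpos nMajor nMinor``;
* ``ascatngs`` - the ``*.copynumber.caveman.csv`` layout: headerless CSV
  with columns id, chrom, start, end, normal total, normal minor,
  tumour total, tumour minor; major/minor counts are derived from the
  tumour columns.

Probe tracks are TSV with header ``chrom pos log2`` and an optional
``baf`` column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_ref import GenomeBuild, canonical_chrom, chrom_sort_key

log = logging.getLogger(__name__)


@dataclass(frozen=True, eq=True)
class Segment:
    """One allele-specific copy-number segment (1-based, closed interval)."""

    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise ValueError(
                f"allele copies must satisfy n_major >= n_minor >= 0, "
                f"got {self.n_major}+{self.n_minor}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.n_major, self.n_minor)

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor

    @property
    def is_ai(self) -> bool:
        """Allelic imbalance: unequal parental allele counts."""
        return self.n_major != self.n_minor

    def is_loh(self, allow_homdel: bool = False) -> bool:
        """Loss of heterozygosity: minor allele lost, other retained."""
        if allow_homdel:
            return self.n_minor == 0
        return self.n_minor == 0 and self.n_major >= 1


@dataclass
class SegmentProfile:
    """One sample's segmentation plus purity/ploidy metadata."""

    sample_id: str
    segments: list[Segment]
    purity: float = 1.0
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")
        self.segments = sorted(
            self.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start)
        )
        self._check_no_overlap()

    def _check_no_overlap(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(
                    f"{self.sample_id}: overlapping segments on chromosome "
                    f"{a.chrom}: [{a.start}, {a.end}] and [{b.start}, {b.end}]"
                )

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.chrom, []).append(s)
        return out

    def validate_against(self, build: GenomeBuild) -> None:
        for s in self.segments:
            build._check_interval(s.chrom, s.start, s.end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "nMajor": [s.n_major for s in self.segments],
                "nMinor": [s.n_minor for s in self.segments],
            }
        )


@dataclass
class ProbeTrack:
    """Ordered per-position Log2-ratio (and optional BAF) observations."""

    sample_id: str
    data: pd.DataFrame  # columns: chrom, pos, log2 [, baf]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "log2"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"probe track missing columns {sorted(missing)}")
        df = self.data.copy()
        df["chrom"] = df["chrom"].map(canonical_chrom)
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                bad = int(np.flatnonzero(np.diff(pos) <= 0)[0])
                raise ValueError(
                    f"{self.sample_id}: positions not strictly increasing on "
                    f"chromosome {chrom} near pos {pos[bad + 1]}"
                )
        if "baf" in df.columns:
            baf = df["baf"].to_numpy(dtype=float)
            ok = np.isnan(baf) | ((baf >= 0.0) & (baf <= 1.0))
            if not np.all(ok):
                raise ValueError(f"{self.sample_id}: BAF values outside [0, 1]")
        self.data = df.reset_index(drop=True)

    @property
    def has_baf(self) -> bool:
        return "baf" in self.data.columns

    def __len__(self) -> int:
        return len(self.data)


_DIALECTS = {
    "generic": {
        "sep": "\t",
        "header": 0,
        "cols": {
            "sample": "sample",
            "chrom": "chrom",
            "start": "start",
            "end": "end",
            "nMajor": "nMajor",
            "nMinor": "nMinor",
        },
    },
    "ascat": {
        "sep": "\t",
        "header": 0,
        "cols": {
            "sample": "sample",
            "chrom": "chr",
            "start": "startpos",
            "end": "endpos",
            "nMajor": "nMajor",
            "nMinor": "nMinor",
        },
    },
}

_ASCATNGS_COLS = [
    "id",
    "chrom",
    "start",
    "end",
    "normal_total",
    "normal_minor",
    "tumour_total",
    "tumour_minor",
]


def _coerce_copies(values: pd.Series, name: str, round_cn: bool) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"non-finite values in column {name}")
    if np.any(arr < 0):
        rows = np.flatnonzero(arr < 0) + 2  # 1-based incl. header
        raise ValueError(f"negative copy number in column {name}, file row(s) {rows.tolist()}")
    frac = arr != np.trunc(arr)
    if np.any(frac):
        if not round_cn:
            rows = np.flatnonzero(frac) + 2
            raise ValueError(
                f"non-integer copy numbers in column {name}, file row(s) "
                f"{rows.tolist()}; pass round_cn=True to round"
            )
        arr = np.sign(arr) * np.floor(np.abs(arr) + 0.5)  # half away from zero
    return arr.astype(int)


def _rows_to_profile(
    df: pd.DataFrame,
    sample_id: str,
    purity: float,
    ploidy: float,
    round_cn: bool,
) -> SegmentProfile:
    major = _coerce_copies(df["nMajor"], "nMajor", round_cn)
    minor = _coerce_copies(df["nMinor"], "nMinor", round_cn)
    swapped = minor > major
    if np.any(swapped):
        rows = (df.index[swapped] + 2).tolist()
        log.warning(
            "%s: nMinor > nMajor in file row(s) %s; swapping to canonical order",
            sample_id,
            rows,
        )
        major, minor = np.where(swapped, minor, major), np.where(swapped, major, minor)

    chroms = df["chrom"].map(canonical_chrom).tolist()
    starts = df["start"].astype(int).tolist()
    ends = df["end"].astype(int).tolist()

    # within-chromosome order must already be sorted and non-overlapping;
    # report file row numbers (1-based, counting the header line) otherwise
    last: dict[str, tuple[int, int, int]] = {}
    for i, (c, s, e) in enumerate(zip(chroms, starts, ends)):
        if s > e:
            raise ValueError(f"{sample_id}: start > end at file row {i + 2}")
        if c in last:
            prev_row, prev_start, prev_end = last[c]
            if s < prev_start:
                raise ValueError(
                    f"{sample_id}: unsorted segments on chromosome {c} "
                    f"(file rows {prev_row} and {i + 2})"
                )
            if s <= prev_end:
                raise ValueError(
                    f"{sample_id}: overlapping segments on chromosome {c} "
                    f"(file rows {prev_row} and {i + 2})"
                )
        last[c] = (i + 2, s, e)

    segments = [
        Segment(c, s, e, int(ma), int(mi))
        for c, s, e, ma, mi in zip(chroms, starts, ends, major, minor)
    ]
    return SegmentProfile(
        sample_id=sample_id, segments=segments, purity=purity, ploidy=ploidy
    )


def read_cohort(
    path: str | Path,
    dialect: str = "generic",
    purity: float | None = None,
    ploidy: float | None = None,
    round_cn: bool = False,
) -> list[SegmentProfile]:
    """Read every sample in a segment table; see :func:`read_segments`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "ascatngs":
        df = pd.read_csv(path, header=None)
        if df.shape[1] != len(_ASCATNGS_COLS):
            raise ValueError(
                f"{path}: expected {len(_ASCATNGS_COLS)} columns in ascatNgs "
                f"CSV, found {df.shape[1]}"
            )
        df.columns = _ASCATNGS_COLS
        df["sample"] = path.stem.split(".")[0]
        df["nMinor"] = df["tumour_minor"]
        df["nMajor"] = df["tumour_total"] - df["tumour_minor"]
    elif dialect in _DIALECTS:
        spec = _DIALECTS[dialect]
        df = pd.read_csv(path, sep=spec["sep"], header=spec["header"])
        missing = [c for c in spec["cols"].values() if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        df = df.rename(columns={v: k for k, v in spec["cols"].items()})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    profiles = []
    for sample_id, grp in df.groupby("sample", sort=False):
        grp = grp.reset_index(drop=True)
        p = purity if purity is not None else float(grp["purity"].iloc[0]) if "purity" in grp else 1.0
        pl = ploidy if ploidy is not None else float(grp["ploidy"].iloc[0]) if "ploidy" in grp else 2.0
        profiles.append(_rows_to_profile(grp, str(sample_id), p, pl, round_cn))
    if not profiles:
        raise ValueError(f"{path}: no segments found")
    return profiles


def read_segments(
    path: str | Path,
    dialect: str = "generic",
    purity: float | None = None,
    ploidy: float | None = None,
    round_cn: bool = False,
) -> SegmentProfile:
    """Read a single-sample segment table into a validated profile.

    Adjacent same-state rows are *not* merged here; normalisation is an
    explicit scoring step.  Rows with swapped allele order are
    canonicalised with a logged warning; negative or (by default)
    non-integer copy numbers, unsorted rows and overlapping rows are
    errors reported with file row numbers.
    """
    profiles = read_cohort(path, dialect, purity, ploidy, round_cn)
    if len(profiles) > 1:
        raise ValueError(
            f"{path}: {len(profiles)} samples found; use read_cohort() for "
            "multi-sample tables"
        )
    return profiles[0]


def read_probe_track(path: str | Path, sample_id: str | None = None) -> ProbeTrack:
    """Read a probe-level Log2 (and optional BAF) track from TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "log2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    keep = ["chrom", "pos", "log2"] + (["baf"] if "baf" in df.columns else [])
    df = df[keep]
    df["pos"] = df["pos"].astype(int)
    return ProbeTrack(sample_id=sample_id or path.stem, data=df)


def write_probe_track(track: ProbeTrack, path: str | Path) -> None:
    track.data.to_csv(path, sep="\t", index=False)


def write_segments(
    profiles: SegmentProfile | Iterable[SegmentProfile], path: str | Path
) -> None:
    """Write one or more profiles as a generic-dialect TSV."""
    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    frames = [p.to_frame() for p in profiles]
    if not frames:
        raise ValueError("no profiles to write")
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


_SCORE_COLUMNS = [
    "sample_id",
    "ntai",
    "hrd_loh",
    "lst",
    "hrd_score",
    "hr_status",
    "contrib_ntai_pct",
    "contrib_hrd_loh_pct",
    "contrib_lst_pct",
]


def _result_row(r) -> dict:
    d = r.to_dict()
    row = {k: d[k] for k in ("sample_id", "ntai", "hrd_loh", "lst", "hrd_score", "hr_status")}
    row["contrib_ntai_pct"] = d["contributions"]["ntai"]
    row["contrib_hrd_loh_pct"] = d["contributions"]["hrd_loh"]
    row["contrib_lst_pct"] = d["contributions"]["lst"]
    return row


def write_results(results, path: str | Path, format: str = "tsv") -> None:
    """Write scoring results and/or agreement reports.

    ``HRDResult`` collections become a deterministic-column TSV or a JSON
    list; objects exposing ``to_dict`` (agreement reports) are written as
    JSON.  Numeric fields keep full precision and survive a read round
    trip exactly.
    """
    if results is None:
        raise ValueError("no results to write")
    items = list(results) if isinstance(results, (list, tuple)) else [results]
    if not items:
        raise ValueError("no results to write")
    path = Path(path)

    if all(hasattr(r, "hrd_score") for r in items):
        rows = [_result_row(r) for r in items]
        if format == "tsv":
            pd.DataFrame(rows, columns=_SCORE_COLUMNS).to_csv(
                path, sep="\t", index=False
            )
        elif format == "json":
            path.write_text(json.dumps([r.to_dict() for r in items], indent=2))
        else:
            raise ValueError(f"unknown format {format!r}")
        return

    payload = [r.to_dict() if hasattr(r, "to_dict") else r for r in items]
    if len(payload) == 1:
        payload = payload[0]
    path.write_text(json.dumps(payload, indent=2))


def read_scores(path: str | Path):
    """Read a score table written by :func:`write_results` (TSV or JSON)."""
    from .hrd_scoring import HRDResult  # local import to avoid a cycle

    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path, sep="\t").to_dict("records")
    out = []
    for rec in records:
        contributions = rec.get("contributions") or {
            "ntai": rec["contrib_ntai_pct"],
            "hrd_loh": rec["contrib_hrd_loh_pct"],
            "lst": rec["contrib_lst_pct"],
        }
        out.append(
            HRDResult(
                sample_id=str(rec["sample_id"]),
                ntai=int(rec["ntai"]),
                hrd_loh=int(rec["hrd_loh"]),
                lst=int(rec["lst"]),
                hrd_score=int(rec["hrd_score"]),
                hr_status=str(rec["hr_status"]),
                contributions={k: float(v) for k, v in contributions.items()},
            )
        )
    return out
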