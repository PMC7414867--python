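"""Reference coordinate model: chromosome sizes, centromeres, arms and bin grids.

Genomic-scar scoring needs three pieces of positional context: how long
each chromosome is, where its centromere lies (telomeric allelic-imbalance
and per-arm LST logic both depend on it), and a fixed-width bin grid used
by the probe-level QC metrics.  Constants for the GRCh37 autosomes are
bundled with the package; custom builds load from plain TSV tables.

All coordinates throughout the package are 1-based, fully-closed
intervals, matching the ASCAT segment convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: canonical sort order for chromosome names
_CHROM_ORDER = {name: i for i, name in enumerate(AUTOSOMES + ("X", "Y", "MT"))}


def canonical_chrom(name: object) -> str:
    """Normalise a chromosome name: strip a leading 'chr', keep the rest."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "M":
        s = "MT"
    return s


def chrom_sort_key(name: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(name, len(_CHROM_ORDER)), name)


@dataclass(frozen=True, eq=True)
class GenomeBuild:
    """Chromosome lengths plus one centromere interval per chromosome.

    Parameters
    ----------
    name
        Text label, e.g. ``"GRCh37"``.
    lengths
        Mapping chromosome name -> length in bp, in canonical order.
    centromeres
        Mapping chromosome name -> (start, end) of the centromere,
        1-based closed, strictly inside the chromosome.
    """

    name: str
    lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome build has no chromosomes")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in self.lengths:
                raise ValueError(f"centromere for unknown chromosome {chrom}")
            length = self.lengths[chrom]
            if not (0 < cs < ce < length):
                raise ValueError(
                    f"chromosome {chrom}: centromere [{cs}, {ce}] not strictly "
                    f"inside chromosome of length {length}"
                )
        missing = set(self.lengths) - set(self.centromeres)
        if missing:
            raise ValueError(f"chromosomes without centromere: {sorted(missing)}")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def length(self, chrom: str) -> int:
        self._check(chrom)
        return self.lengths[chrom]

    def centromere(self, chrom: str) -> tuple[int, int]:
        self._check(chrom)
        return self.centromeres[chrom]

    def total_length(self) -> int:
        return sum(self.lengths.values())

    def _check(self, chrom: str) -> None:
        if chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {chrom!r} for build {self.name}")

    def _check_interval(self, chrom: str, start: int, end: int) -> None:
        self._check(chrom)
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
        if start < 1 or end > self.lengths[chrom]:
            raise ValueError(
                f"interval [{start}, {end}] out of bounds for chromosome "
                f"{chrom} (length {self.lengths[chrom]})"
            )


@dataclass(frozen=True, eq=True)
class BinGrid:
    """Fixed-width tiling of a genome build into consecutive bins.

    Each chromosome is cut into ``ceil(length / bin_size)`` bins; the last
    bin may be partial.  Bins carry global indices, chromosome by
    chromosome in build order.
    """

    build: GenomeBuild
    bin_size: int
    n_bins: dict[str, int] = field(init=False)
    offsets: dict[str, int] = field(init=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"non-positive bin size {self.bin_size}")
        n_bins: dict[str, int] = {}
        offsets: dict[str, int] = {}
        total = 0
        for chrom, length in self.build.lengths.items():
            offsets[chrom] = total
            n_bins[chrom] = math.ceil(length / self.bin_size)
            total += n_bins[chrom]
        object.__setattr__(self, "n_bins", n_bins)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "total", total)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a 1-based position."""
        self.build._check_interval(chrom, pos, pos)
        return self.offsets[chrom] + (pos - 1) // self.bin_size

    def bin_span(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global indices (first, last) of the bins overlapped by [start, end]."""
        self.build._check_interval(chrom, start, end)
        off = self.offsets[chrom]
        return off + (start - 1) // self.bin_size, off + (end - 1) // self.bin_size


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_build(
    name: str | Path = "GRCh37",
    centromeres: str | Path | None = None,
    autosomes_only: bool = True,
) -> GenomeBuild:
    """Load a genome build, either a bundled one or from TSV tables.

    Parameters
    ----------
    name
        Bundled build label (currently ``"GRCh37"``) or path to a lengths
        table with header ``chrom  length``.
    centromeres
        Path to a centromere table with header ``chrom  cen_start  cen_end``;
        required when loading from files, ignored for bundled builds.
    autosomes_only
        Restrict to chromosomes 1-22 (the default everywhere in this
        package; the scores are defined on autosomes).
    """
    if isinstance(name, str) and name.upper() == "GRCH37":
        data = resources.files("hrdscar") / "data"
        lengths_path = Path(str(data / "grch37_lengths.tsv"))
        cen_path = Path(str(data / "grch37_centromeres.tsv"))
        label = "GRCh37"
    else:
        lengths_path = Path(name)
        if not lengths_path.exists():
            raise ValueError(f"unknown build label or missing file: {name!r}")
        if centromeres is None:
            raise ValueError("a centromere table is required for custom builds")
        cen_path = Path(centromeres)
        label = lengths_path.stem

    ldf = _read_table(lengths_path, ["chrom", "length"])
    cdf = _read_table(cen_path, ["chrom", "cen_start", "cen_end"])

    lengths: dict[str, int] = {}
    for _, row in ldf.iterrows():
        chrom = canonical_chrom(row["chrom"])
        if chrom in lengths:
            raise ValueError(f"duplicate chromosome {chrom} in {lengths_path}")
        lengths[chrom] = int(row["length"])
    cens: dict[str, tuple[int, int]] = {}
    for _, row in cdf.iterrows():
        chrom = canonical_chrom(row["chrom"])
        cens[chrom] = (int(row["cen_start"]), int(row["cen_end"]))

    if autosomes_only:
        lengths = {c: l for c, l in lengths.items() if c in AUTOSOMES}
        cens = {c: v for c, v in cens.items() if c in lengths}
    lengths = dict(sorted(lengths.items(), key=lambda kv: chrom_sort_key(kv[0])))
    return GenomeBuild(name=label, lengths=lengths, centromeres=cens)


def make_bins(build: GenomeBuild, bin_size: int = 10_000) -> BinGrid:
    """Tile every chromosome of ``build`` into fixed ``bin_size`` bins."""
    return BinGrid(build=build, bin_size=bin_size)


def crosses_centromere(build: GenomeBuild, chrom: str, start: int, end: int) -> bool:
    """True iff [start, end] has bases on both sides of the centromere.

    An interval ending (or starting) inside the centromere interval does
    not cross it: crossing requires at least one position strictly below
    the centromere start and one strictly above its end.
    """
    build._check_interval(chrom, start, end)
    cs, ce = build.centromeres[chrom]
    return start < cs and end > ce


def arm_of(build: GenomeBuild, chrom: str, start: int, end: int) -> str:
    """Arm label of an interval: ``"p"``, ``"q"`` or ``"spanning"``.

    Positions inside the centromere belong to neither arm, so any overlap
    with the centromere interval yields ``"spanning"``.
    """
    build._check_interval(chrom, start, end)
    cs, ce = build.centromeres[chrom]
    if end < cs:
        return "p"
    if start > ce:
        return "q"
    return "spanning"
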