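"""Genomic-scar scoring: NtAI, HRD-LOH, LST, summed HRD score, HR status.

The HRD score is the sum of three counts of structural genomic scars
computed from an allele-specific copy-number segmentation:

* **NtAI** - segments in allelic imbalance (major != minor allele count)
  that extend to a telomere, do not cross the centromere and do not span
  the whole chromosome;
* **HRD-LOH** - loss-of-heterozygosity regions (minor allele count 0 with
  a retained major allele) longer than 15 Mb that do not span the whole
  chromosome; adjacent LOH segments merge into one region regardless of
  major allele count;
* **LST** - large-scale state transitions: after removing segments
  shorter than 3 Mb (per chromosome arm) and re-merging identical
  states, the number of adjacent segment pairs with different
  allele-specific states where both flanks are at least 10 Mb and the
  gap between them is at most 3 Mb.

Samples with summed score >= 42 are classified homologous-recombination
deficient, < 42 proficient.

Telomere-touching is a property of the segmented profile, not of raw
coordinates: the first (or last) segment of a chromosome counts as
reaching the telomere even when the segmentation does not extend to
literal base 1, because real caller output rarely does.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cn_io import Segment, SegmentProfile
from .genome_ref import GenomeBuild, crosses_centromere

HR_DEFICIENT = "deficient"
HR_PROFICIENT = "proficient"
COMPONENTS = ("ntai", "hrd_loh", "lst")


@dataclass(frozen=True)
class ScoringParams:
    """Length thresholds and the classification threshold, all in bp / counts.

    Defaults follow the component definitions the summed score was built
    on: LOH regions must exceed 15 Mb, LST flanks must reach 10 Mb with
    3 Mb smoothing and a 3 Mb maximum inter-flank gap, and the HR
    deficiency call uses the score-42 threshold.
    """

    loh_min_len: int = 15_000_000
    lst_min_flank: int = 10_000_000
    lst_smooth_len: int = 3_000_000
    lst_max_gap: int = 3_000_000
    ntai_min_len: int = 0
    hr_threshold: int = 42
    loh_allow_homdel: bool = False

    def __post_init__(self) -> None:
        for name in ("loh_min_len", "lst_min_flank", "lst_smooth_len", "lst_max_gap", "ntai_min_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hr_threshold <= 0:
            raise ValueError("hr_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown scoring parameters: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class HRDResult:
    """Component counts, summed score, HR status and % contributions."""

    sample_id: str
    ntai: int
    hrd_loh: int
    lst: int
    hrd_score: int
    hr_status: str
    contributions: dict[str, float]

    def __post_init__(self) -> None:
        if self.hrd_score != self.ntai + self.hrd_loh + self.lst:
            raise ValueError("hrd_score must equal ntai + hrd_loh + lst")
        if min(self.ntai, self.hrd_loh, self.lst) < 0:
            raise ValueError("component counts must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def classify_hr(score: int, threshold: int = 42) -> str:
    """HR status from the summed score: deficient iff score >= threshold."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    return HR_DEFICIENT if score >= threshold else HR_PROFICIENT


def _merge_zero_gap(segments: list[Segment]) -> list[Segment]:
    """Merge consecutive same-chromosome, same-state segments with gap 0."""
    out: list[Segment] = []
    for seg in segments:
        if (
            out
            and out[-1].chrom == seg.chrom
            and out[-1].state == seg.state
            and seg.start == out[-1].end + 1
        ):
            out[-1] = dataclasses.replace(out[-1], end=seg.end)
        else:
            out.append(seg)
    return out


def normalize_profile(profile: SegmentProfile, build: GenomeBuild) -> SegmentProfile:
    """Canonicalise a profile before scoring.

    Drops chromosomes absent from the build (sex chromosomes under the
    default autosome-only build), splits segments overlapping the
    centromere at the centromere boundaries (bases strictly inside the
    centromere belong to neither arm and are discarded), and merges
    adjacent segments with identical allele-specific state and zero gap.
    Idempotent; raises if a segment extends beyond its chromosome end.
    """
    kept: list[Segment] = []
    for seg in profile.segments:
        if seg.chrom not in build.lengths:
            continue
        build._check_interval(seg.chrom, seg.start, seg.end)
        cs, ce = build.centromeres[seg.chrom]
        if seg.end < cs or seg.start > ce:
            kept.append(seg)
            continue
        if seg.start < cs:
            kept.append(dataclasses.replace(seg, end=cs - 1))
        if seg.end > ce:
            kept.append(dataclasses.replace(seg, start=ce + 1))
        # a segment entirely inside the centromere is dropped
    merged = _merge_zero_gap(kept)
    return SegmentProfile(
        sample_id=profile.sample_id,
        segments=merged,
        purity=profile.purity,
        ploidy=profile.ploidy,
    )


def _bridge_centromere(
    segments: list[Segment], build: GenomeBuild
) -> list[Segment]:
    """Re-join same-state segments split only by the centromere.

    The chromosome-level components (NtAI, HRD-LOH) reason about whole
    chromosomes, so the centromere split performed by
    :func:`normalize_profile` is undone here: two same-state neighbours
    whose gap lies entirely within the centromere interval merge back
    into one segment spanning the gap.
    """
    out: list[Segment] = []
    for seg in segments:
        if out and out[-1].chrom == seg.chrom and out[-1].state == seg.state:
            gap_start, gap_end = out[-1].end + 1, seg.start - 1
            cs, ce = build.centromeres[seg.chrom]
            if gap_start > gap_end or (gap_start >= cs and gap_end <= ce):
                out[-1] = dataclasses.replace(out[-1], end=seg.end)
                continue
        out.append(seg)
    return out


def score_ntai(
    profile: SegmentProfile, build: GenomeBuild, params: ScoringParams = ScoringParams()
) -> int:
    """Count telomeric allelic-imbalance segments.

    Expects a normalized profile.  A segment counts when it (a) is the
    first or last segment of its chromosome, (b) is in allelic imbalance,
    (c) does not cross the centromere, (d) is not the chromosome's only
    segment (whole-chromosome imbalance is excluded), and (e) is at least
    ``ntai_min_len`` long.
    """
    count = 0
    for chrom, segs in profile.by_chrom().items():
        segs = _bridge_centromere(segs, build)
        if len(segs) < 2:
            continue  # single segment spans the whole profiled chromosome
        for seg in {0: segs[0], len(segs) - 1: segs[-1]}.values():
            if not seg.is_ai:
                continue
            if crosses_centromere(build, chrom, seg.start, seg.end):
                continue
            if seg.length < params.ntai_min_len:
                continue
            count += 1
    return count


def score_hrd_loh(
    profile: SegmentProfile, build: GenomeBuild, params: ScoringParams = ScoringParams()
) -> int:
    """Count LOH regions longer than ``loh_min_len`` (strictly).

    Expects a normalized profile.  Consecutive LOH-state segments with
    zero gap merge into one region regardless of major allele count;
    homozygous deletions (0+0) terminate a region by default.  A region
    spanning the chromosome's entire segmented extent does not count.
    """
    count = 0
    for segs in profile.by_chrom().values():
        segs = _bridge_centromere(segs, build)
        n = len(segs)
        i = 0
        while i < n:
            if not segs[i].is_loh(params.loh_allow_homdel):
                i += 1
                continue
            j = i
            while (
                j + 1 < n
                and segs[j + 1].is_loh(params.loh_allow_homdel)
                and segs[j + 1].start == segs[j].end + 1
            ):
                j += 1
            run_len = segs[j].end - segs[i].start + 1
            whole_chrom = i == 0 and j == n - 1
            if run_len > params.loh_min_len and not whole_chrom:
                count += 1
            i = j + 1
    return count


def _smooth_arm(segments: list[Segment], min_len: int) -> list[Segment]:
    """Iteratively drop segments shorter than ``min_len``.

    When a removal makes two identical-state segments adjacent in the
    list they merge into one segment spanning the removed region.
    Removals that enable such a merge (short noise segments interrupting
    one homogeneous stretch) are taken first, shortest first with a
    leftmost tie-break, so an interrupted flank is restored before any
    unmatched short segment is discarded; this makes the outcome
    deterministic and keeps single short interruptions from cascading
    into large coverage holes.  The loop runs until every remaining
    segment reaches ``min_len``.
    """
    segs = list(segments)
    while segs:
        short = [(s.length, k) for k, s in enumerate(segs) if s.length < min_len]
        if not short:
            break
        mergeable = [
            (length, k)
            for length, k in short
            if 0 < k < len(segs) - 1 and segs[k - 1].state == segs[k + 1].state
        ]
        _, k = min(mergeable) if mergeable else min(short)
        left = segs[k - 1] if k > 0 else None
        right = segs[k + 1] if k + 1 < len(segs) else None
        del segs[k]
        if left is not None and right is not None and left.state == right.state:
            segs[k - 1] = dataclasses.replace(left, end=right.end)
            del segs[k]
    return segs


def score_lst(
    profile: SegmentProfile, build: GenomeBuild, params: ScoringParams = ScoringParams()
) -> int:
    """Count large-scale state transitions, summed over chromosome arms.

    Expects a normalized profile (centromere-split, so every segment lies
    on one arm).  Per arm: smooth away sub-``lst_smooth_len`` segments,
    then count adjacent pairs with different allele-specific states where
    both flanks are >= ``lst_min_flank`` and the genomic gap between them
    is <= ``lst_max_gap``.
    """
    count = 0
    for chrom, segs in profile.by_chrom().items():
        cs, ce = build.centromeres[chrom]
        for arm_segs in ([s for s in segs if s.end < cs], [s for s in segs if s.start > ce]):
            smoothed = _smooth_arm(arm_segs, params.lst_smooth_len)
            for a, b in zip(smoothed, smoothed[1:]):
                if a.state == b.state:
                    continue
                if a.length < params.lst_min_flank or b.length < params.lst_min_flank:
                    continue
                if b.start - a.end - 1 > params.lst_max_gap:
                    continue
                count += 1
    return count


def _contributions(ntai: int, hrd_loh: int, lst: int) -> dict[str, float]:
    total = ntai + hrd_loh + lst
    if total == 0:
        return {c: 0.0 for c in COMPONENTS}
    return {
        "ntai": 100.0 * ntai / total,
        "hrd_loh": 100.0 * hrd_loh / total,
        "lst": 100.0 * lst / total,
    }


def score_hrd(
    profile: SegmentProfile,
    build: GenomeBuild,
    params: ScoringParams = ScoringParams(),
    normalize: bool = True,
) -> HRDResult:
    """Score one sample: the three components, their sum and HR status."""
    if normalize:
        profile = normalize_profile(profile, build)
    ntai = score_ntai(profile, build, params)
    loh = score_hrd_loh(profile, build, params)
    lst = score_lst(profile, build, params)
    total = ntai + loh + lst
    return HRDResult(
        sample_id=profile.sample_id,
        ntai=ntai,
        hrd_loh=loh,
        lst=lst,
        hrd_score=total,
        hr_status=classify_hr(total, params.hr_threshold),
        contributions=_contributions(ntai, loh, lst),
    )
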