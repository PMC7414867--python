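"""Synthetic tumour copy-number profiles with paired platform views.

The study design this package targets - the same tumours segmented on a
SNP array and on (possibly downsampled) WGS - uses controlled-access
patient data, so the generator builds an equivalent testbed with known
ground truth:

* a **true profile** starts from a diploid heterozygous (1+1) autosomal
  genome and receives three kinds of scar events with Poisson counts per
  archetype: interstitial LOH regions (1+0, 20-45 Mb), telomeric
  allelic-imbalance events (2+1 or 3+1, 5-30 Mb, confined to one arm),
  and interstitial large-scale state switches (14-28 Mb, flanked by
  >= 13 Mb of diploid sequence).  Placement keeps every event >= 13 Mb
  clear of arm boundaries and of other events, so each event's
  contribution to the three component counts is known exactly;
* a **platform view** perturbs the truth the way a real caller would:
  breakpoints jitter by a platform-specific sd, whole events drop out
  with a platform-specific probability, and spurious short (<= 3 Mb)
  segments with a one-copy major-allele gain appear as a Poisson process
  along the genome - the mechanism by which low-coverage sequencing
  inflates scar counts;
* a **probe track** samples the view on a regular grid with Gaussian
  Log2 and (symmetrised) BAF noise.

Lower nominal coverage never decreases the spurious-breakpoint rate or
the Log2 noise across the shipped presets.  All randomness derives from
one integer seed via stable per-(sample, platform) substreams, so every
output is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cn_io import ProbeTrack, Segment, SegmentProfile
from .genome_ref import GenomeBuild
from .hrd_scoring import HRDResult, ScoringParams, score_hrd

log = logging.getLogger(__name__)

_MB = 1_000_000


@dataclass(frozen=True)
class PlatformModel:
    """Noise model for one measurement platform.

    ``p_spurious_breakpoint`` is a rate per 100 Mb of genome;
    ``p_miss_event`` applies independently to each injected true event.
    """

    label: str
    breakpoint_jitter_sd: float = 0.0
    p_miss_event: float = 0.0
    p_spurious_breakpoint: float = 0.0
    probe_spacing: int = 1_600
    log2_noise_sd: float = 0.0
    baf_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_miss_event <= 1.0:
            raise ValueError("p_miss_event must be in [0, 1]")
        for name in ("breakpoint_jitter_sd", "p_spurious_breakpoint", "log2_noise_sd", "baf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")


#: shipped presets; the wgs* tiers satisfy the coverage-noise ordering
#: (lower coverage => spurious rate and Log2 noise non-decreasing)
PLATFORM_PRESETS: dict[str, PlatformModel] = {
    "array": PlatformModel(
        "array",
        breakpoint_jitter_sd=50_000,
        p_miss_event=0.02,
        p_spurious_breakpoint=0.05,
        probe_spacing=1_600,
        log2_noise_sd=0.20,
        baf_noise_sd=0.04,
    ),
    "wgs70x": PlatformModel(
        "wgs70x",
        breakpoint_jitter_sd=25_000,
        p_miss_event=0.0,
        p_spurious_breakpoint=0.05,
        probe_spacing=1_600,
        log2_noise_sd=0.12,
        baf_noise_sd=0.03,
    ),
    "wgs30x": PlatformModel(
        "wgs30x",
        breakpoint_jitter_sd=50_000,
        p_miss_event=0.0,
        p_spurious_breakpoint=0.3,
        probe_spacing=1_600,
        log2_noise_sd=0.18,
        baf_noise_sd=0.05,
    ),
    "wgs15x": PlatformModel(
        "wgs15x",
        breakpoint_jitter_sd=100_000,
        p_miss_event=0.0,
        p_spurious_breakpoint=1.0,
        probe_spacing=1_600,
        log2_noise_sd=0.25,
        baf_noise_sd=0.07,
    ),
    "wgs10x": PlatformModel(
        "wgs10x",
        breakpoint_jitter_sd=150_000,
        p_miss_event=0.0,
        p_spurious_breakpoint=2.0,
        probe_spacing=1_600,
        log2_noise_sd=0.32,
        baf_noise_sd=0.09,
    ),
}

ZERO_NOISE = PlatformModel("truth")

#: mean injected event counts per archetype; deficient profiles score
#: around 65 in expectation (>= 60), proficient around 11 (<= 20)
ARCHETYPES = {
    "hr_deficient": {"tai": 12.0, "loh": 8.0, "switch": 10.0},
    "hr_proficient": {"tai": 2.0, "loh": 1.0, "switch": 2.0},
}

_TAI_STATES = [(2, 1), (3, 1)]
_SWITCH_STATES = [(2, 2), (2, 1), (3, 1)]
_MIN_CLEARANCE = 13 * _MB  # flank / inter-event clearance in bp


@dataclass(frozen=True)
class TrueEvent:
    kind: str  # "tai" | "loh" | "switch"
    chrom: str
    arm: str  # "p" | "q"
    start: int
    end: int
    n_major: int
    n_minor: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated sample."""

    seed: int
    archetype: str
    events: list[TrueEvent]
    profile: SegmentProfile
    ntai_true: int = 0
    hrd_loh_true: int = 0
    lst_true: int = 0

    @property
    def hrd_true(self) -> int:
        return self.ntai_true + self.hrd_loh_true + self.lst_true


def _substream(seed: int, *parts: object) -> np.random.Generator:
    """Derive a reproducible RNG substream from the global seed."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            entropy.append(zlib.crc32(p.encode()))
        else:
            entropy.append(int(p) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _overlay(segments: list[Segment], ev: Segment) -> list[Segment]:
    """Replace the portion of a covering segmentation under ``ev``."""
    out: list[Segment] = []
    placed = False
    for s in segments:
        if s.chrom != ev.chrom or s.end < ev.start or s.start > ev.end:
            out.append(s)
            continue
        if s.start < ev.start:
            out.append(dataclasses.replace(s, end=ev.start - 1))
        if not placed:
            out.append(ev)
            placed = True
        if s.end > ev.end:
            out.append(dataclasses.replace(s, start=ev.end + 1))
    if not placed:
        out.append(ev)
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


def _arm_bounds(build: GenomeBuild, chrom: str, arm: str) -> tuple[int, int]:
    cs, ce = build.centromeres[chrom]
    if arm == "p":
        return 1, cs - 1
    return ce + 1, build.lengths[chrom]


def _clear_of_events(
    events: list[TrueEvent], chrom: str, start: int, end: int
) -> bool:
    for e in events:
        if e.chrom != chrom:
            continue
        if start - e.end <= _MIN_CLEARANCE and e.start - end <= _MIN_CLEARANCE:
            return False
    return True


def _pick_chrom_arm(build: GenomeBuild, rng: np.random.Generator) -> tuple[str, str]:
    chroms = list(build.lengths)
    weights = np.array([build.lengths[c] for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
    cs, ce = build.centromeres[chrom]
    p_len = cs - 1
    q_len = build.lengths[chrom] - ce
    arm = rng.choice(["p", "q"], p=np.array([p_len, q_len]) / (p_len + q_len))
    return chrom, str(arm)


def _place_interstitial(
    build: GenomeBuild,
    events: list[TrueEvent],
    rng: np.random.Generator,
    kind: str,
    length: int,
    state: tuple[int, int],
    attempts: int = 100,
) -> TrueEvent | None:
    for _ in range(attempts):
        chrom, arm = _pick_chrom_arm(build, rng)
        lo, hi = _arm_bounds(build, chrom, arm)
        start_lo = lo + _MIN_CLEARANCE
        start_hi = hi - _MIN_CLEARANCE - length + 1
        if start_hi < start_lo:
            continue
        start = int(rng.integers(start_lo, start_hi + 1))
        end = start + length - 1
        if not _clear_of_events(events, chrom, start, end):
            continue
        return TrueEvent(kind, chrom, arm, start, end, *state)
    return None


def _place_terminal(
    build: GenomeBuild,
    events: list[TrueEvent],
    rng: np.random.Generator,
    length: int,
    state: tuple[int, int],
    attempts: int = 100,
) -> TrueEvent | None:
    for _ in range(attempts):
        chrom, arm = _pick_chrom_arm(build, rng)
        lo, hi = _arm_bounds(build, chrom, arm)
        if hi - lo + 1 < length + _MIN_CLEARANCE:
            continue
        if arm == "p":
            start, end = 1, length
        else:
            start, end = build.lengths[chrom] - length + 1, build.lengths[chrom]
        if not _clear_of_events(events, chrom, start, end):
            continue
        return TrueEvent("tai", chrom, arm, start, end, *state)
    return None


def _profile_from_events(
    build: GenomeBuild, events: list[TrueEvent], sample_id: str
) -> SegmentProfile:
    segments: list[Segment] = [
        Segment(c, 1, length, 1, 1) for c, length in build.lengths.items()
    ]
    for e in sorted(events, key=lambda e: (e.chrom, e.start)):
        segments = _overlay(
            segments, Segment(e.chrom, e.start, e.end, e.n_major, e.n_minor)
        )
    return SegmentProfile(sample_id=sample_id, segments=segments)


def simulate_true_profile(
    build: GenomeBuild,
    archetype: str = "hr_deficient",
    rng_seed: int = 0,
    sample_id: str | None = None,
    event_means: dict[str, float] | None = None,
    params: ScoringParams = ScoringParams(),
) -> tuple[SegmentProfile, SyntheticTruth]:
    """Simulate one tumour genome with known injected scar counts.

    Placement guarantees >= 13 Mb clearance around every event and event
    lengths comfortably exceed the qualifying cutoffs (LOH 20-45 Mb vs
    the >15 Mb rule, switches 14-28 Mb vs the 10 Mb flank rule), so each
    LOH event contributes exactly one HRD-LOH region and two LSTs, each
    state switch two LSTs, and each telomeric AI event one NtAI plus one
    LST when the event itself reaches the 10 Mb flank size; sub-3 Mb
    view perturbations cannot flip a qualifying region.  An event
    that cannot be placed after 100 attempts is skipped (and logged), and
    the recorded truth counts shrink accordingly.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    means = event_means if event_means is not None else ARCHETYPES[archetype]
    rng = _substream(rng_seed, "truth")
    sample_id = sample_id or f"{archetype}_{rng_seed}"

    n_tai = int(rng.poisson(means["tai"]))
    n_loh = int(rng.poisson(means["loh"]))
    n_switch = int(rng.poisson(means["switch"]))

    events: list[TrueEvent] = []
    truth = SyntheticTruth(seed=rng_seed, archetype=archetype, events=events, profile=None)  # type: ignore[arg-type]

    for _ in range(n_loh):
        length = int(rng.uniform(20 * _MB, 45 * _MB))
        ev = _place_interstitial(build, events, rng, "loh", length, (1, 0))
        if ev is None:
            log.debug("%s: skipped an LOH event (no room)", sample_id)
            continue
        events.append(ev)
        truth.hrd_loh_true += 1
        truth.lst_true += 2
    for _ in range(n_tai):
        length = int(rng.uniform(5 * _MB, 30 * _MB))
        state = _TAI_STATES[int(rng.integers(len(_TAI_STATES)))]
        ev = _place_terminal(build, events, rng, length, state)
        if ev is None:
            log.debug("%s: skipped a telomeric AI event (no room)", sample_id)
            continue
        events.append(ev)
        truth.ntai_true += 1
        if length >= params.lst_min_flank:
            truth.lst_true += 1
    for _ in range(n_switch):
        length = int(rng.uniform(14 * _MB, 28 * _MB))
        state = _SWITCH_STATES[int(rng.integers(len(_SWITCH_STATES)))]
        ev = _place_interstitial(build, events, rng, "switch", length, state)
        if ev is None:
            log.debug("%s: skipped a state-switch event (no room)", sample_id)
            continue
        events.append(ev)
        truth.lst_true += 2

    profile = _profile_from_events(build, events, sample_id)
    truth.profile = profile
    return profile, truth


def render_platform_view(
    truth: SyntheticTruth,
    model: PlatformModel,
    rng_seed: int,
    build: GenomeBuild,
    sample_id: str | None = None,
) -> SegmentProfile:
    """Render one platform's view of a true profile.

    Event-level dropout, Gaussian breakpoint jitter (telomeric ends stay
    anchored; ordering is preserved by clamping), and spurious <= 3 Mb
    segments whose major allele count is one above the underlying state.
    A zero-noise model reproduces the truth exactly.
    """
    rng = _substream(rng_seed, "view", model.label)
    sample_id = sample_id or f"{truth.profile.sample_id}_{model.label}"

    surviving = [e for e in truth.events if rng.random() >= model.p_miss_event]

    jittered: list[TrueEvent] = []
    by_chrom: dict[str, list[TrueEvent]] = {}
    for e in sorted(surviving, key=lambda e: (e.chrom, e.start)):
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, evs in by_chrom.items():
        chrom_len = build.lengths[chrom]
        prev_end = -1  # so an anchored p-terminal event may keep start = 1
        for e in evs:
            start, end = e.start, e.end
            if not (e.kind == "tai" and e.arm == "p"):
                start = start + int(round(rng.normal(0.0, model.breakpoint_jitter_sd)))
            if not (e.kind == "tai" and e.arm == "q"):
                end = end + int(round(rng.normal(0.0, model.breakpoint_jitter_sd)))
            start = max(start, prev_end + 2, 1)
            end = min(max(end, start), chrom_len)
            start = min(start, end)
            jittered.append(dataclasses.replace(e, start=start, end=end))
            prev_end = end

    view = _profile_from_events(build, jittered, sample_id)

    n_spurious = int(rng.poisson(model.p_spurious_breakpoint * build.total_length() / 1e8))
    chroms = list(build.lengths)
    weights = np.array([build.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    segments = view.segments
    for _ in range(n_spurious):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        chrom_len = build.lengths[chrom]
        length = int(rng.uniform(0.5 * _MB, 3 * _MB))
        if length >= chrom_len:
            continue
        # a false boundary at a uniform position, with the perturbed state
        # extending <= 3 Mb to one side; clamped at the chromosome ends, so
        # a breakpoint near a telomere leaves a short terminal segment
        pos = int(rng.integers(1, chrom_len + 1))
        if rng.random() < 0.5:
            start, end = pos, min(pos + length - 1, chrom_len)
        else:
            start, end = max(pos - length + 1, 1), pos
        under = next(
            (s for s in segments if s.chrom == chrom and s.start <= pos <= s.end),
            None,
        )
        if under is None:
            continue
        spur = Segment(chrom, start, end, under.n_major + 1, under.n_minor)
        segments = _overlay(segments, spur)

    return SegmentProfile(sample_id=sample_id, segments=segments)


def render_probe_track(
    view: SegmentProfile,
    model: PlatformModel,
    rng_seed: int,
    build: GenomeBuild,
) -> ProbeTrack:
    """Sample a platform view on a regular probe grid with noise.

    Log2 = log2(total copies / 2) + N(0, log2_noise_sd) (total floored at
    0.5 copies); BAF is drawn around minor/total, randomly reflected
    about 0.5 (allele labels are arbitrary), with sd ``baf_noise_sd``,
    clamped to [0, 1].
    """
    rng = _substream(rng_seed, "probes", model.label)
    chrom_col, pos_col, log2_col, baf_col = [], [], [], []
    by_chrom = view.by_chrom()
    for chrom, segs in by_chrom.items():
        chrom_len = build.lengths[chrom]
        pos = np.arange(model.probe_spacing, chrom_len + 1, model.probe_spacing)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        seg_idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (seg_idx >= 0) & (pos <= ends[np.clip(seg_idx, 0, None)])
        pos = pos[inside]
        seg_idx = seg_idx[inside]
        totals = np.array([max(s.total, 0.5) for s in segs], dtype=float)
        minors = np.array([s.n_minor for s in segs], dtype=float)
        log2 = np.log2(totals[seg_idx] / 2.0)
        if model.log2_noise_sd > 0:
            log2 = log2 + rng.normal(0.0, model.log2_noise_sd, size=log2.size)
        with np.errstate(divide="ignore", invalid="ignore"):
            baf_mean = np.where(
                totals[seg_idx] > 0, minors[seg_idx] / totals[seg_idx], 0.5
            )
        flip = rng.random(baf_mean.size) < 0.5
        baf = np.where(flip, 1.0 - baf_mean, baf_mean)
        if model.baf_noise_sd > 0:
            baf = baf + rng.normal(0.0, model.baf_noise_sd, size=baf.size)
        baf = np.clip(baf, 0.0, 1.0)
        chrom_col.append(np.full(pos.size, chrom, dtype=object))
        pos_col.append(pos)
        log2_col.append(log2)
        baf_col.append(baf)
    data = pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_col),
            "pos": np.concatenate(pos_col).astype(int),
            "log2": np.concatenate(log2_col),
            "baf": np.concatenate(baf_col),
        }
    )
    return ProbeTrack(sample_id=view.sample_id, data=data)


@dataclass
class SampleRecord:
    sample_id: str
    truth: SyntheticTruth
    views: dict[str, SegmentProfile]
    scores: dict[str, HRDResult]
    truth_score: HRDResult


@dataclass
class CohortBundle:
    """A simulated paired cohort: one truth and several platform views
    per sample, all scored."""

    build: GenomeBuild
    seed: int
    models: dict[str, PlatformModel]
    samples: list[SampleRecord]

    def results(self, platform: str) -> list[HRDResult]:
        return [s.scores[platform] for s in self.samples]

    def scores_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for platform, r in s.scores.items():
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "platform": platform,
                        "archetype": s.truth.archetype,
                        "ntai": r.ntai,
                        "hrd_loh": r.hrd_loh,
                        "lst": r.lst,
                        "hrd_score": r.hrd_score,
                        "hr_status": r.hr_status,
                    }
                )
        return pd.DataFrame(rows)


def resolve_models(platforms) -> dict[str, PlatformModel]:
    models: dict[str, PlatformModel] = {}
    for p in platforms:
        if isinstance(p, PlatformModel):
            models[p.label] = p
        elif p in PLATFORM_PRESETS:
            models[p] = PLATFORM_PRESETS[p]
        else:
            raise ValueError(
                f"unknown platform {p!r}; presets: {sorted(PLATFORM_PRESETS)}"
            )
    return models


def simulate_cohort(
    build: GenomeBuild,
    n_samples: int,
    deficient_fraction: float,
    models,
    rng_seed: int = 0,
    params: ScoringParams = ScoringParams(),
) -> CohortBundle:
    """Simulate and score a paired cohort across two or more platforms."""
    if n_samples < 3:
        raise ValueError("cohort needs at least 3 samples")
    if not 0.0 <= deficient_fraction <= 1.0:
        raise ValueError("deficient_fraction must be in [0, 1]")
    model_map = resolve_models(models)
    if len(model_map) < 2:
        raise ValueError("need at least two platform models")

    n_def = int(round(n_samples * deficient_fraction))
    archetypes = ["hr_deficient"] * n_def + ["hr_proficient"] * (n_samples - n_def)
    _substream(rng_seed, "assignment").shuffle(archetypes)

    samples: list[SampleRecord] = []
    for i, archetype in enumerate(archetypes):
        sample_id = f"SYN{i + 1:03d}"
        sample_seed = (int(rng_seed) * 100_003 + i) & 0x7FFFFFFF
        profile, truth = simulate_true_profile(
            build, archetype, sample_seed, sample_id=sample_id, params=params
        )
        views = {
            label: render_platform_view(truth, m, sample_seed, build, f"{sample_id}_{label}")
            for label, m in model_map.items()
        }
        scores = {
            label: dataclasses.replace(
                score_hrd(v, build, params), sample_id=sample_id
            )
            for label, v in views.items()
        }
        samples.append(
            SampleRecord(
                sample_id=sample_id,
                truth=truth,
                views=views,
                scores=scores,
                truth_score=score_hrd(profile, build, params),
            )
        )
    return CohortBundle(build=build, seed=rng_seed, models=model_map, samples=samples)
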