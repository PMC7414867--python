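"""End-to-end synthetic-study orchestration.

``run_study`` mirrors the analysis order of a paired-platform comparison:
simulate (or load) a cohort, score every platform, compute probe-level QC
for a subset of samples, then build the agreement report between the
first two platforms.  Every output is a deterministic function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cn_io import write_results, write_segments
from .concordance import AgreementReport, build_agreement_report
from .genome_ref import GenomeBuild, load_build, make_bins
from .hrd_scoring import ScoringParams
from .qc_metrics import bin_median, binned_deviation, binned_spearman, dlrs, mapd
from .synth_data import CohortBundle, resolve_models, render_probe_track, simulate_cohort

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a synthetic paired-platform study run."""

    build: str = "GRCh37"
    n_samples: int = 67
    deficient_fraction: float = 0.5
    platforms: tuple[str, ...] = ("array", "wgs70x")
    seed: int = 0
    outdir: str | None = None
    scoring: ScoringParams = field(default_factory=ScoringParams)
    qc_samples: int = 3
    qc_bin_size: int = 10_000
    skip_failed: bool = False

    def __post_init__(self) -> None:
        if len(self.platforms) < 2:
            raise ValueError("need at least two platforms")


@dataclass
class StudyReport:
    config: RunConfig
    bundle: CohortBundle
    agreement: AgreementReport
    qc: pd.DataFrame
    failures: list[dict]

    def summary(self) -> str:
        a, b = self.config.platforms[:2]
        m = self.agreement.metrics["hrd_score"]
        lines = [
            f"samples: {self.agreement.n} ({a} vs {b}), seed {self.config.seed}",
            f"HRD score: Pearson r = {m.pearson_r:.3f}, R^2 = {m.r_squared:.3f}, "
            f"ICC(3,1) = {m.icc3:.3f}",
            f"Bland-Altman bias = {m.bland_altman.bias:.2f} "
            f"[{m.bland_altman.loa_low:.2f}, {m.bland_altman.loa_high:.2f}], "
            f"{100 * m.bland_altman.fraction_within:.2f}% within limits",
            f"HR classification: concordance = {self.agreement.concordance_pct:.2f}%, "
            f"Fleiss kappa = {self.agreement.fleiss_kappa:.3f} "
            f"(p = {self.agreement.kappa_p_value:.2e})",
            f"discordant samples: {len(self.agreement.discordant)}",
        ]
        if self.failures:
            lines.append(f"excluded after failures: {len(self.failures)}")
        return "\n".join(lines)


def run_study(config: RunConfig) -> StudyReport:
    """Simulate, score, QC and compare a paired synthetic cohort."""
    t0 = time.monotonic()
    build = load_build(config.build)
    log.info("simulating cohort: n=%d, platforms=%s", config.n_samples, config.platforms)
    bundle = simulate_cohort(
        build,
        config.n_samples,
        config.deficient_fraction,
        list(config.platforms),
        rng_seed=config.seed,
        params=config.scoring,
    )
    log.info("simulated and scored in %.1fs", time.monotonic() - t0)

    failures: list[dict] = []
    qc_rows = []
    grid = make_bins(build, config.qc_bin_size)
    a_label, b_label = config.platforms[:2]
    for rec in bundle.samples[: config.qc_samples]:
        try:
            track_a = render_probe_track(
                rec.views[a_label], bundle.models[a_label], rec.truth.seed, build
            )
            track_b = render_probe_track(
                rec.views[b_label], bundle.models[b_label], rec.truth.seed, build
            )
            seg_a = bin_median(rec.views[a_label], grid, mode="segmented")
            seg_b = bin_median(rec.views[b_label], grid, mode="segmented")
            probe_a = bin_median(track_a, grid, mode="probe")
            probe_b = bin_median(track_b, grid, mode="probe")
            qc_rows.append(
                {
                    "sample_id": rec.sample_id,
                    f"dlrs_{a_label}": dlrs(track_a),
                    f"dlrs_{b_label}": dlrs(track_b),
                    f"mapd_{a_label}": mapd(track_a),
                    f"mapd_{b_label}": mapd(track_b),
                    "segmented_log2_deviation": binned_deviation(seg_a, seg_b),
                    "log2_spearman": binned_spearman(probe_a, probe_b),
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-sample attribution
            if not config.skip_failed:
                raise StageError("qc", rec.sample_id, exc) from exc
            log.warning("qc failed for %s: %s; skipping", rec.sample_id, exc)
            failures.append({"stage": "qc", "sample_id": rec.sample_id, "error": str(exc)})
    qc = pd.DataFrame(qc_rows)

    agreement = build_agreement_report(
        bundle.results(a_label),
        bundle.results(b_label),
        threshold=config.scoring.hr_threshold,
    )
    report = StudyReport(
        config=config, bundle=bundle, agreement=agreement, qc=qc, failures=failures
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label in config.platforms:
            write_results(bundle.results(label), outdir / f"scores_{label}.tsv")
            write_segments(
                [rec.views[label] for rec in bundle.samples],
                outdir / f"segments_{label}.tsv",
            )
        (outdir / "report.json").write_text(agreement.to_json())
        agreement.flat_summary().to_csv(outdir / "report_summary.tsv", sep="\t", index=False)
        if not qc.empty:
            qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        manifest = {
            "seed": config.seed,
            "n_samples": config.n_samples,
            "platforms": list(config.platforms),
            "truth": [
                {
                    "sample_id": rec.sample_id,
                    "archetype": rec.truth.archetype,
                    "ntai_true": rec.truth.ntai_true,
                    "hrd_loh_true": rec.truth.hrd_loh_true,
                    "lst_true": rec.truth.lst_true,
                }
                for rec in bundle.samples
            ],
            "failures": failures,
        }
        (outdir / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "summary.txt").write_text(report.summary() + "\n")
    log.info("study complete in %.1fs", time.monotonic() - t0)
    return report
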