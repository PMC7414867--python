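"""Paired-cohort agreement analysis between two scoring platforms.

Given the same samples scored on two platforms (e.g. SNP array and WGS),
this module quantifies agreement the way method-comparison studies do:

* Pearson correlation and ordinary least-squares regression (the
  sequencing platform is the explanatory variable, the array the
  response);
* Bland-Altman analysis: mean bias and 95% limits of agreement of the
  paired differences (WGS - array by convention), with confidence
  intervals following the BlandAltmanLeh conventions
  (SE of a limit = sd * sqrt(3/n));
* intraclass correlation ICC(3,1): two-way mixed model, single measure,
  consistency form, (MS_rows - MS_err) / (MS_rows + (k-1) MS_err);
* Fleiss' kappa for the dichotomous HR classification (2 raters, 2
  categories), with the standard large-sample z-test p-value;
* classification concordance with a per-sample discordance listing;
* Wilcoxon / rank-sum comparison of component contributions and
  Kolmogorov-Smirnov comparison of score distributions.

No multiple-testing correction is applied anywhere; every p-value is
reported raw.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hrd_scoring import COMPONENTS, HRDResult, classify_hr, HR_DEFICIENT

METRICS = ("ntai", "hrd_loh", "lst", "hrd_score")


class RegressionResult(NamedTuple):
    r: float
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float


def pearson_with_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """Pearson r plus an OLS fit of y on x (x explanatory, y response)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        se_slope=float(fit.stderr),
        se_intercept=float(fit.intercept_stderr),
        r_squared=float(fit.rvalue) ** 2,
    )


@dataclass(frozen=True)
class BAReport:
    """Bland-Altman summary of paired differences d = x - y."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    fraction_within: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BAReport:
    """Limits-of-agreement analysis of paired measurements.

    Differences are ``x - y`` (callers pass WGS as ``x`` and array as
    ``y`` to match the reporting convention).  Limits are
    bias +/- 1.96 sd; the CI of the bias uses the t distribution with
    n-1 df, and the CI of each limit uses SE = sd * sqrt(3/n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"Bland-Altman needs at least 3 pairs, got {n}")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    t = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(3.0 / n)
    within = (d >= loa_low) & (d <= loa_high)
    return BAReport(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_low=(loa_low - t * se_loa, loa_low + t * se_loa),
        ci_loa_high=(loa_high - t * se_loa, loa_high + t * se_loa),
        fraction_within=float(np.mean(within)),
    )


def icc3(x: Sequence[float], y: Sequence[float]) -> float:
    """ICC(3,1): two-way mixed, single measure, consistency form.

    Subjects are rows, the two platforms are the (fixed) raters:
    (MS_rows - MS_err) / (MS_rows + (k - 1) MS_err) with k = 2.
    Consistency form: a fixed offset between raters does not lower it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def fleiss_kappa_binary(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> tuple[float, float]:
    """Fleiss' kappa for 2 raters x 2 categories, with large-sample p.

    Equivalent to Scott's pi for two raters.  The p-value is the
    two-sided normal test z = kappa / SE0 with the classic null standard
    error; (NaN, NaN) with a warning when only one category occurs
    anywhere (kappa undefined).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    cats = sorted(set(a) | set(b))
    if len(cats) == 1:
        warnings.warn("single category across all ratings: kappa undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    m = 2  # raters per subject
    counts = np.zeros((n, len(cats)))
    cat_idx = {c: i for i, c in enumerate(cats)}
    for i, (la, lb) in enumerate(zip(a, b)):
        counts[i, cat_idx[la]] += 1
        counts[i, cat_idx[lb]] += 1
    p_j = counts.sum(axis=0) / (n * m)
    p_i = (np.sum(counts**2, axis=1) - m) / (m * (m - 1))
    p_bar = float(np.mean(p_i))
    p_e = float(np.sum(p_j**2))
    if p_e == 1.0:
        warnings.warn("degenerate category distribution: kappa undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    kappa = (p_bar - p_e) / (1.0 - p_e)
    q_j = 1.0 - p_j
    s = float(np.sum(p_j * q_j))
    se0 = math.sqrt(2.0 / (n * m * (m - 1))) * math.sqrt(
        s**2 - float(np.sum(p_j * q_j * (q_j - p_j)))
    ) / s
    z = kappa / se0
    p_value = 2.0 * float(stats.norm.sf(abs(z)))
    return (float(kappa), p_value)


@dataclass(frozen=True)
class Discordance:
    sample_id: str
    score_a: int
    score_b: int
    direction: str  # "deficient_by_a_only" | "deficient_by_b_only"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def classification_concordance(
    scores_a: Sequence[int],
    scores_b: Sequence[int],
    threshold: int = 42,
    sample_ids: Sequence[str] | None = None,
) -> tuple[float, list[Discordance]]:
    """Percent agreement of HR status calls, plus the discordant samples."""
    sa = list(scores_a)
    sb = list(scores_b)
    if len(sa) != len(sb):
        raise ValueError("score sequences must have equal length")
    ids = list(sample_ids) if sample_ids is not None else [f"S{i+1:03d}" for i in range(len(sa))]
    discordant: list[Discordance] = []
    agree = 0
    for sid, a, b in zip(ids, sa, sb):
        status_a = classify_hr(a, threshold)
        status_b = classify_hr(b, threshold)
        if status_a == status_b:
            agree += 1
        else:
            direction = (
                "deficient_by_a_only" if status_a == HR_DEFICIENT else "deficient_by_b_only"
            )
            discordant.append(Discordance(sid, int(a), int(b), direction))
    pct = 100.0 * agree / len(sa) if sa else float("nan")
    return pct, discordant


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    n = values.size
    mean = float(np.mean(values))
    if n < 2:
        return mean, mean, mean
    sd = float(np.std(values, ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return mean, mean - half, mean + half


def _paired_test(da: np.ndarray, db: np.ndarray) -> float:
    diffs = da - db
    if np.allclose(diffs, 0.0):
        return 1.0
    informative = int(np.sum(diffs != 0))
    method = "exact" if informative < 5 else "auto"
    try:
        return float(stats.wilcoxon(da, db, method=method).pvalue)
    except ValueError:
        return float("nan")


def compare_contributions(
    results_a: Sequence[HRDResult],
    results_b: Sequence[HRDResult],
    grouping: str = "platform-paired",
    threshold: int = 42,
) -> pd.DataFrame:
    """Compare component contribution percentages.

    ``platform-paired``: Wilcoxon signed-rank per component between the
    paired platforms (exact null when fewer than 5 informative pairs).
    ``hr-status``: within platform a, rank-sum (Mann-Whitney) test of
    each component's contribution between HR-deficient and HR-proficient
    samples; the two groups are unpaired, so a signed-rank test does not
    apply.  Returns one row per component with the p-value and per-group
    mean contribution with a 95% t-interval.
    """
    rows = []
    if grouping == "platform-paired":
        if len(results_a) != len(results_b):
            raise ValueError("paired mode needs equal-length cohorts")
        for comp in COMPONENTS:
            ca = np.array([r.contributions[comp] for r in results_a])
            cb = np.array([r.contributions[comp] for r in results_b])
            mean_a, lo_a, hi_a = _mean_ci(ca)
            mean_b, lo_b, hi_b = _mean_ci(cb)
            rows.append(
                {
                    "component": comp,
                    "p_value": _paired_test(ca, cb),
                    "mean_a": mean_a,
                    "ci_low_a": lo_a,
                    "ci_high_a": hi_a,
                    "mean_b": mean_b,
                    "ci_low_b": lo_b,
                    "ci_high_b": hi_b,
                }
            )
    elif grouping == "hr-status":
        deficient = [r for r in results_a if r.hrd_score >= threshold]
        proficient = [r for r in results_a if r.hrd_score < threshold]
        if not deficient or not proficient:
            raise ValueError("hr-status mode needs both classes present")
        for comp in COMPONENTS:
            cd = np.array([r.contributions[comp] for r in deficient])
            cp = np.array([r.contributions[comp] for r in proficient])
            mean_d, lo_d, hi_d = _mean_ci(cd)
            mean_p, lo_p, hi_p = _mean_ci(cp)
            p = float(stats.mannwhitneyu(cd, cp, alternative="two-sided").pvalue)
            rows.append(
                {
                    "component": comp,
                    "p_value": p,
                    "mean_a": mean_d,
                    "ci_low_a": lo_d,
                    "ci_high_a": hi_d,
                    "mean_b": mean_p,
                    "ci_low_b": lo_p,
                    "ci_high_b": hi_p,
                }
            )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return pd.DataFrame(rows)


def ks_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov statistic and asymptotic p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("KS comparison needs at least 3 values per sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetricAgreement:
    metric: str
    n: int
    pearson_r: float
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    icc3: float
    ks_d: float
    ks_p: float
    bland_altman: BAReport

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bland_altman"] = self.bland_altman.to_dict()
        return d


@dataclass
class AgreementReport:
    """Full paired-platform concordance summary (platform b is the
    explanatory/sequencing side; differences are b - a)."""

    n: int
    threshold: int
    metrics: dict[str, MetricAgreement]
    fleiss_kappa: float
    kappa_p_value: float
    concordance_pct: float
    discordant: list[Discordance]
    contribution_tests: pd.DataFrame
    schema_version: str = "1.0"

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "n": self.n,
            "threshold": self.threshold,
            "metrics": {k: v.to_dict() for k, v in self.metrics.items()},
            "classification": {
                "fleiss_kappa": self.fleiss_kappa,
                "kappa_p_value": self.kappa_p_value,
                "concordance_pct": self.concordance_pct,
                "discordant": [d.to_dict() for d in self.discordant],
            },
            "contribution_tests": self.contribution_tests.to_dict("records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def flat_summary(self) -> pd.DataFrame:
        rows = []
        for name, m in self.metrics.items():
            rows.append(
                {
                    "metric": name,
                    "pearson_r": m.pearson_r,
                    "r_squared": m.r_squared,
                    "slope": m.slope,
                    "intercept": m.intercept,
                    "icc3": m.icc3,
                    "bias": m.bland_altman.bias,
                    "loa_low": m.bland_altman.loa_low,
                    "loa_high": m.bland_altman.loa_high,
                    "fraction_within": m.bland_altman.fraction_within,
                    "ks_d": m.ks_d,
                    "ks_p": m.ks_p,
                }
            )
        return pd.DataFrame(rows)


def build_agreement_report(
    results_a: Sequence[HRDResult],
    results_b: Sequence[HRDResult],
    threshold: int = 42,
) -> AgreementReport:
    """Assemble the full agreement battery for a paired cohort.

    ``results_a`` is the reference platform (array), ``results_b`` the
    comparison platform (WGS): regressions use b as x, and Bland-Altman
    differences are b - a.
    """
    if len(results_a) != len(results_b):
        raise ValueError("cohorts must be paired (equal length)")
    n = len(results_a)
    if n < 3:
        raise ValueError(f"agreement analysis needs at least 3 samples, got {n}")

    metrics: dict[str, MetricAgreement] = {}
    for metric in METRICS:
        va = np.array([getattr(r, metric) for r in results_a], dtype=float)
        vb = np.array([getattr(r, metric) for r in results_b], dtype=float)
        reg = pearson_with_regression(vb, va)
        ba = bland_altman(vb, va)
        d, p = ks_compare(va, vb)
        metrics[metric] = MetricAgreement(
            metric=metric,
            n=n,
            pearson_r=reg.r,
            slope=reg.slope,
            intercept=reg.intercept,
            se_slope=reg.se_slope,
            se_intercept=reg.se_intercept,
            r_squared=reg.r_squared,
            icc3=icc3(va, vb),
            ks_d=d,
            ks_p=p,
            bland_altman=ba,
        )

    ids = [r.sample_id for r in results_a]
    sa = [r.hrd_score for r in results_a]
    sb = [r.hrd_score for r in results_b]
    concordance_pct, discordant = classification_concordance(
        sa, sb, threshold, sample_ids=ids
    )
    la = [classify_hr(s, threshold) for s in sa]
    lb = [classify_hr(s, threshold) for s in sb]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappa, kappa_p = fleiss_kappa_binary(la, lb)
    contrib = compare_contributions(results_a, results_b, "platform-paired")
    return AgreementReport(
        n=n,
        threshold=threshold,
        metrics=metrics,
        fleiss_kappa=kappa,
        kappa_p_value=kappa_p,
        concordance_pct=concordance_pct,
        discordant=discordant,
        contribution_tests=contrib,
    )
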