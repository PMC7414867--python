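"""Independent brute-force oracles for the scoring and agreement statistics.

These re-derive every quantity directly from the stated rules with the
simplest possible code (plain loops over literal candidate enumerations),
sharing nothing with the package implementation, so that agreement
between the two is meaningful evidence of correctness.
"""

from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# scar-component oracles


def _clip(profile, build):
    """Autosome filter plus centromere clipping, no merging.

    Returns {chrom: [(start, end, maj, min), ...]} with centromere-interior
    bases removed (a spanning segment leaves one piece per arm).
    """
    per_chrom = {}
    for seg in profile.segments:
        if seg.chrom not in build.lengths:
            continue
        cs, ce = build.centromeres[seg.chrom]
        pieces = []
        if seg.start < cs:
            pieces.append((seg.start, min(seg.end, cs - 1)))
        if seg.end > ce:
            pieces.append((max(seg.start, ce + 1), seg.end))
        for s, e in pieces:
            per_chrom.setdefault(seg.chrom, []).append((s, e, seg.n_major, seg.n_minor))
    return per_chrom


def _clip_and_bridge(profile, build):
    """Literal rule set: clipping, then neighbouring pieces with identical
    state merge when their gap is zero or lies entirely inside the
    centromere (the chromosome-level view used by NtAI and HRD-LOH)."""
    per_chrom = _clip(profile, build)
    bridged = {}
    for chrom, rows in per_chrom.items():
        rows = sorted(rows)
        cs, ce = build.centromeres[chrom]
        out = [rows[0]]
        for s, e, ma, mi in rows[1:]:
            ps, pe, pma, pmi = out[-1]
            gap_lo, gap_hi = pe + 1, s - 1
            same_state = (ma, mi) == (pma, pmi)
            gap_ok = gap_lo > gap_hi or (gap_lo >= cs and gap_hi <= ce)
            if same_state and gap_ok:
                out[-1] = (ps, e, pma, pmi)
            else:
                out.append((s, e, ma, mi))
        bridged[chrom] = out
    return bridged


def oracle_ntai(profile, build, params):
    """Count telomeric AI segments by literally checking every segment."""
    count = 0
    for chrom, rows in _clip_and_bridge(profile, build).items():
        cs, ce = build.centromeres[chrom]
        for idx, (s, e, ma, mi) in enumerate(rows):
            terminal = idx == 0 or idx == len(rows) - 1
            only_segment = len(rows) == 1
            ai = ma != mi
            crosses = s < cs and e > ce
            long_enough = (e - s + 1) >= params.ntai_min_len
            if terminal and ai and not crosses and not only_segment and long_enough:
                count += 1
    return count


def oracle_hrd_loh(profile, build, params):
    """Count LOH regions by enumerating every maximal LOH run."""

    def is_loh(ma, mi):
        return mi == 0 and (params.loh_allow_homdel or ma >= 1)

    count = 0
    for rows in _clip_and_bridge(profile, build).values():
        runs = []
        current = None
        prev_end = None
        for idx, (s, e, ma, mi) in enumerate(rows):
            if is_loh(ma, mi) and current is not None and s == prev_end + 1:
                current[1] = e
                current[3] = idx
            elif is_loh(ma, mi):
                current = [s, e, idx, idx]
                runs.append(current)
            else:
                current = None
            prev_end = e
        for s, e, first, last in runs:
            if e - s + 1 > params.loh_min_len and not (first == 0 and last == len(rows) - 1):
                count += 1
    return count


def _oracle_smooth(rows, min_len):
    """Same stated smoothing rule, re-derived with index-free scans."""
    rows = list(rows)
    while True:
        short = [r for r in rows if r[1] - r[0] + 1 < min_len]
        if not short:
            return rows

        def enables_merge(r):
            k = rows.index(r)
            return (
                0 < k < len(rows) - 1
                and rows[k - 1][2:] == rows[k + 1][2:]
            )

        candidates = [r for r in short if enables_merge(r)] or short
        victim = min(candidates, key=lambda r: (r[1] - r[0] + 1, r[0]))
        k = rows.index(victim)
        left = rows[k - 1] if k > 0 else None
        right = rows[k + 1] if k + 1 < len(rows) else None
        rows = rows[:k] + rows[k + 1 :]
        if left is not None and right is not None and left[2:] == right[2:]:
            merged = (left[0], right[1], left[2], left[3])
            rows = rows[: k - 1] + [merged] + rows[k + 1 :]


def oracle_lst(profile, build, params):
    """Count LSTs by enumerating adjacent pairs on each smoothed arm.

    Works per arm on the clipped rows, with zero-gap same-state pieces
    merged first (they are one segment, and must enter the length-based
    smoothing as one).
    """

    def merge_zero_gap(rows):
        out = []
        for r in sorted(rows):
            if out and out[-1][2:] == r[2:] and r[0] == out[-1][1] + 1:
                out[-1] = (out[-1][0], r[1], *r[2:])
            else:
                out.append(r)
        return out

    count = 0
    for chrom, rows in _clip(profile, build).items():
        cs, ce = build.centromeres[chrom]
        for arm_rows in ([r for r in rows if r[1] < cs], [r for r in rows if r[0] > ce]):
            smoothed = _oracle_smooth(merge_zero_gap(arm_rows), params.lst_smooth_len)
            for (s1, e1, ma1, mi1), (s2, e2, ma2, mi2) in zip(smoothed, smoothed[1:]):
                if (ma1, mi1) == (ma2, mi2):
                    continue
                if (e1 - s1 + 1) < params.lst_min_flank or (e2 - s2 + 1) < params.lst_min_flank:
                    continue
                if s2 - e1 - 1 > params.lst_max_gap:
                    continue
                count += 1
    return count


# ---------------------------------------------------------------------------
# agreement-statistic oracles


def oracle_crosses_centromere(build, chrom, start, end):
    """Per-position membership test on a small chromosome."""
    cs, ce = build.centromeres[chrom]
    positions = set(range(start, end + 1))
    below = any(p < cs for p in positions)
    above = any(p > ce for p in positions)
    return below and above


def oracle_fleiss_from_table(a, b, c, d):
    """Fleiss kappa for 2 raters from the 2x2 agreement table.

    ``a`` both-category-1, ``b`` rater1-only, ``c`` rater2-only, ``d``
    both-category-2.  Direct evaluation of observed vs chance agreement.
    """
    n = a + b + c + d
    p1 = (2 * a + b + c) / (2 * n)
    p2 = 1.0 - p1
    p_obs = (a + d) / n  # for 2 raters P_i is 1 (agree) or 0 (disagree)
    p_exp = p1**2 + p2**2
    if p_exp == 1.0:
        return float("nan")
    return (p_obs - p_exp) / (1.0 - p_exp)


def oracle_icc3(x, y):
    """ICC(3,1) consistency via an explicit two-way ANOVA decomposition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = len(x), 2
    grand = (x.sum() + y.sum()) / (n * k)
    subj_means = (x + y) / 2
    rater_means = np.array([x.mean(), y.mean()])
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum() + ((y - grand) ** 2).sum()
    ms_subj = ss_subj / (n - 1)
    ms_err = (ss_tot - ss_subj - ss_rater) / ((n - 1) * (k - 1))
    return (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)


def oracle_signed_rank_exact_p(diffs):
    """Two-sided exact signed-rank p by enumerating all sign patterns.

    Zero differences are dropped (the standard reduction); ranks of
    |diffs| are midranks for ties.  Enumerates the full 2^n null.
    """
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    n = len(d)
    if n == 0:
        return 1.0
    order = np.abs(d)
    ranks = np.empty(n)
    srt = np.argsort(order)
    sorted_abs = order[srt]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[srt[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    p_low = np.mean(stats <= w_obs)
    p_high = np.mean(stats >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))
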