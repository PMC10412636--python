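"""One-way ANOVA and Duncan's multiple range test.

The post-hoc procedure follows Duncan's new multiple range test: group
means are sorted, and the difference between the extremes of any span
of p consecutive means is compared against the critical range

    R_p = q_{alpha_p, p, df} * sqrt(MSE / n_h),   alpha_p = 1 - (1-alpha)^(p-1)

where q is the studentized-range quantile (computed numerically, no
lookup tables), MSE the within-group mean square, and n_h the harmonic
mean of the group sizes (the standard extension to mildly unbalanced
designs).  Spans inside a range already declared homogeneous are never
tested — the usual protection rule — which makes the homogeneous sets
contiguous intervals of the sorted means; the letter display simply
labels the maximal intervals.  Treatment-vs-control significance (the
asterisks of publication figures) is read off the letter display: a
group sharing no letter with the control differs from it at alpha.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError


@dataclass
class GroupedMeasurements:
    """Replicate observations per group, with a designated control."""

    groups: dict[str, np.ndarray]
    control_label: str

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float)
                       for k, v in self.groups.items()}
        if self.control_label not in self.groups:
            raise ValidationError(
                f"control label {self.control_label!r} not among groups")
        for k, v in self.groups.items():
            if v.ndim != 1 or v.size < 2:
                raise ValidationError(f"group {k!r} needs >= 2 observations")


@dataclass
class SignificanceReport:
    F_stat: float
    p_value: float
    letters: dict[str, str]
    vs_control_significant: dict[str, bool]
    alpha: float
    means: dict[str, float] = field(default_factory=dict)
    critical_ranges: dict[int, float] = field(default_factory=dict)


def one_way_anova(data: GroupedMeasurements) -> tuple[float, float, int, int]:
    """Classical one-way ANOVA decomposition.

    Returns (F, p, df_between, df_within).  All-identical data yields
    F = 0, p = 1 rather than 0/0.
    """
    samples = list(data.groups.values())
    if len(samples) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    n_total = sum(s.size for s in samples)
    k = len(samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0, df_b, df_w
        return np.inf, 0.0, df_b, df_w
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p, df_b, df_w


@lru_cache(maxsize=512)
def _duncan_q(protection: float, p: int, df_w: int) -> float:
    # the studentized-range quantile is expensive to evaluate and depends
    # only on (protection level, span, df), so cache it across calls
    return float(sps.studentized_range.ppf(protection, p, df_w))


def _duncan_critical_ranges(n_means: int, df_w: int, mse: float,
                            n_h: float, alpha: float) -> dict[int, float]:
    out = {}
    for p in range(2, n_means + 1):
        protection = (1.0 - alpha) ** (p - 1)
        out[p] = _duncan_q(protection, p, df_w) * np.sqrt(mse / n_h)
    return out


def _homogeneous_intervals(means: np.ndarray,
                           ranges: dict[int, float]) -> list[tuple[int, int]]:
    """Maximal intervals of sorted means not separable by the range test."""
    found: set[tuple[int, int]] = set()

    def test(i: int, j: int):
        if (i, j) in found:
            return
        if i == j or means[j] - means[i] < ranges[j - i + 1]:
            found.add((i, j))
            return
        test(i, j - 1)
        test(i + 1, j)

    test(0, means.size - 1)
    maximal = [iv for iv in found
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                          for o in found)]
    maximal.sort()
    return maximal


def duncan_mrt(data: GroupedMeasurements, alpha: float = 0.05) -> SignificanceReport:
    """Duncan's multiple range test with a letter display and control flags."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    labels = list(data.groups)
    if len(labels) < 2:
        raise ValidationError("Duncan's test needs >= 2 groups")
    f, p, df_b, df_w = one_way_anova(data)
    sizes = np.array([data.groups[g].size for g in labels], dtype=float)
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.groups.values()) / df_w
    n_h = sizes.size / (1.0 / sizes).sum()
    means = np.array([data.groups[g].mean() for g in labels])
    order = np.argsort(means)
    sorted_labels = [labels[i] for i in order]
    sorted_means = means[order]

    if mse == 0.0:
        # no within-group variance: any mean difference is significant,
        # so homogeneous sets are runs of exactly equal means
        intervals, i = [], 0
        while i < sorted_means.size:
            j = i
            while j + 1 < sorted_means.size and sorted_means[j + 1] == sorted_means[i]:
                j += 1
            intervals.append((i, j))
            i = j + 1
        ranges = {}
    else:
        ranges = _duncan_critical_ranges(len(labels), df_w, mse, n_h, alpha)
        intervals = _homogeneous_intervals(sorted_means, ranges)

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for li, (i, j) in enumerate(intervals):
        ch = alphabet[li % len(alphabet)]
        for k in range(i, j + 1):
            letters[sorted_labels[k]] += ch

    ctrl = set(letters[data.control_label])
    vs_control = {lab: (lab != data.control_label
                        and not (set(letters[lab]) & ctrl))
                  for lab in labels}
    return SignificanceReport(F_stat=f, p_value=p, letters=letters,
                              vs_control_significant=vs_control, alpha=alpha,
                              means=dict(zip(labels, means)),
                              critical_ranges=ranges)


def means_table(data: GroupedMeasurements,
                report: SignificanceReport | None = None,
                decimals: int = 2) -> pd.DataFrame:
    """Publication-style annotated means table ("mean ± SD", letters, *)."""
    if report is None:
        report = duncan_mrt(data)
    rows = []
    for lab, vals in data.groups.items():
        rows.append({
            "group": lab,
            "mean_sd": f"{vals.mean():.{decimals}f} ± {vals.std(ddof=1):.{decimals}f}",
            "letters": report.letters[lab],
            "vs_control": "*" if report.vs_control_significant[lab] else "",
        })
    return pd.DataFrame(rows).set_index("group")
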