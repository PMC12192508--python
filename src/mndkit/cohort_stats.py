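"""Cohort-comparison statistics: group summaries, omnibus and pairwise
tests with Bonferroni control, variance comparisons, effect sizes, and
rank correlation.

Test selection (``mode="auto"``) uses one-way ANOVA when every group has
n >= 30 (central-limit shortcut) or when a Shapiro-Wilk test on the pooled
group-centered residuals does not reject normality at 0.05; otherwise the
Kruskal-Wallis test. Pairwise tests follow the same choice (Welch t vs
Mann-Whitney U), are two-sided, and are Bonferroni-adjusted over the family
of all unordered pairs. Alpha defaults to 0.05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError, ValidationError

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float  # NaN for n == 1 (n-1 denominator undefined)
    variance: float
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    test: str  # "t" or "mannwhitney"
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class EffectSize:
    group_a: str
    group_b: str
    cohens_d: float


@dataclass(frozen=True)
class VarianceResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p: float


@dataclass
class ComparisonReport:
    """Full output of one multi-group comparison."""

    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    summaries: list[GroupSummary] = field(default_factory=list)
    pairwise: list[PairwiseResult] = field(default_factory=list)
    effects: list[EffectSize] = field(default_factory=list)
    variance_tests: list[VarianceResult] = field(default_factory=list)
    alpha: float = ALPHA_DEFAULT

    def to_dict(self) -> dict:
        return {
            "omnibus": {
                "test": self.omnibus_test,
                "statistic": self.omnibus_statistic,
                "p": self.omnibus_p,
            },
            "alpha": self.alpha,
            "summaries": [vars(s) for s in self.summaries],
            "pairwise": [vars(p) for p in self.pairwise],
            "effects": [vars(e) for e in self.effects],
            "variance_tests": [vars(v) for v in self.variance_tests],
        }


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValidationError(f"group {label!r} is empty")
        out[str(label)] = arr
    return out


def summarize(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Exact sample statistics per group (sd uses the n-1 denominator)."""
    out = []
    for label, arr in _as_groups(groups).items():
        n = arr.size
        var = float(np.var(arr, ddof=1)) if n > 1 else float("nan")
        out.append(
            GroupSummary(
                label=label,
                n=n,
                mean=float(arr.mean()),
                sd=math.sqrt(var) if n > 1 else float("nan"),
                variance=var,
                median=float(np.median(arr)),
                min=float(arr.min()),
                max=float(arr.max()),
            )
        )
    return out


def _select_parametric(arrays: Sequence[np.ndarray]) -> bool:
    """auto rule: CLT shortcut at n >= 30, else Shapiro-Wilk on residuals."""
    if all(a.size >= 30 for a in arrays):
        return True
    residuals = np.concatenate([a - a.mean() for a in arrays])
    if residuals.size < 3 or np.ptp(residuals) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000
        _, p = stats.shapiro(residuals)
    return p > 0.05


def omnibus_test(
    groups: Mapping[str, Sequence[float]], mode: str = "auto"
) -> tuple[str, float, float]:
    """Omnibus comparison of >= 2 groups.

    Returns ``(test_name, statistic, p)`` with test_name "anova" or
    "kruskal". ``mode`` forces the choice; "auto" applies the selection
    rule in the module docstring.
    """
    arrays = list(_as_groups(groups).values())
    if len(arrays) < 2:
        raise ValidationError("omnibus test needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("omnibus test needs n >= 2 per group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise PipelineError("all values identical; omnibus statistic degenerate")
    if mode == "auto":
        mode = "anova" if _select_parametric(arrays) else "kruskal"
    if mode == "anova":
        stat, p = stats.f_oneway(*arrays)
        return "anova", float(stat), float(p)
    if mode == "kruskal":
        stat, p = stats.kruskal(*arrays)
        return "kruskal", float(stat), float(p)
    raise ValidationError(f"unknown mode {mode!r}")


def bonferroni(p_raw: float, family_size: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if family_size < 1:
        raise ValidationError("family_size must be >= 1")
    return min(1.0, p_raw * family_size)


def pairwise_tests(
    groups: Mapping[str, Sequence[float]],
    mode: str = "auto",
    family_size: int | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> list[PairwiseResult]:
    """Two-sided tests of every unordered pair with Bonferroni control.

    Welch's t-test in the parametric branch, Mann-Whitney U otherwise;
    "auto" reuses the omnibus selection rule on the full group family.
    ``family_size`` defaults to the number of testable pairs.
    """
    arrays = _as_groups(groups)
    if mode == "auto":
        testable = [a for a in arrays.values() if a.size >= 2]
        mode = "t" if testable and _select_parametric(testable) else "mannwhitney"
    if mode not in ("t", "mannwhitney"):
        raise ValidationError(f"unknown mode {mode!r}")

    pairs = list(itertools.combinations(arrays, 2))
    usable = [
        (a, b) for a, b in pairs if arrays[a].size >= 2 and arrays[b].size >= 2
    ]
    for a, b in set(pairs) - set(usable):
        warnings.warn(f"skipping pair ({a}, {b}): group with n < 2", stacklevel=2)
    m = family_size if family_size is not None else len(usable)
    out = []
    for a, b in usable:
        if mode == "t":
            stat, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
        else:
            stat, p = stats.mannwhitneyu(
                arrays[a], arrays[b], alternative="two-sided"
            )
        p_adj = bonferroni(float(p), m)
        out.append(
            PairwiseResult(a, b, mode, float(stat), float(p), p_adj, p_adj < alpha)
        )
    return out


def cohens_d(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    denominator: str = "rms",
) -> float:
    """Standardized mean difference (group a minus group b).

    ``denominator="rms"`` (default) uses sqrt((sd_a^2 + sd_b^2) / 2);
    ``"pooled"`` uses the (n-1)-weighted pooled standard deviation.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("standard deviations must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValidationError("cohens_d needs n >= 2 per group")
    if sd_a == 0 and sd_b == 0:
        raise PipelineError("both standard deviations are 0; d undefined")
    if denominator == "rms":
        denom = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    elif denominator == "pooled":
        denom = math.sqrt(
            ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        )
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    return (mean_a - mean_b) / denom


def variance_ratio(var_a: float, var_b: float) -> float:
    """Fold difference of two variances (a over b)."""
    if var_b == 0:
        raise PipelineError("zero variance in denominator")
    return var_a / var_b


def variance_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "f",
) -> tuple[float, float]:
    """Two-sided comparison of two sample variances.

    ``method="f"``: variance-ratio F-test with the larger variance in the
    numerator; ``method="levene"``: Brown-Forsythe/Levene test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("variance test needs n >= 2 per group")
    if method == "levene":
        stat, p = stats.levene(a, b)
        return float(stat), float(p)
    if method != "f":
        raise ValidationError(f"unknown variance test {method!r}")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        raise PipelineError("both variances are 0; F statistic undefined")
    if va >= vb:
        if vb == 0:
            raise PipelineError("zero variance in denominator")
        f, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = 2.0 * stats.f.sf(f, dfn, dfd)
    return float(f), float(min(1.0, p))


def rank_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("rank_correlation needs equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PipelineError("constant vector; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    mode: str = "auto",
    effect_denominator: str = "rms",
    variance_method: str = "f",
    alpha: float = ALPHA_DEFAULT,
    reference: str | None = None,
) -> ComparisonReport:
    """One-stop comparison: omnibus + pairwise + effect sizes + variances.

    Effect sizes and variance tests compare ``reference`` (default: the
    first group) against every other group, reference first in the
    difference.
    """
    arrays = _as_groups(groups)
    name, stat, p = omnibus_test(arrays, mode=mode)
    report = ComparisonReport(
        omnibus_test=name,
        omnibus_statistic=stat,
        omnibus_p=p,
        summaries=summarize(arrays),
        pairwise=pairwise_tests(arrays, mode=mode, alpha=alpha),
        alpha=alpha,
    )
    ref = reference if reference is not None else next(iter(arrays))
    if ref not in arrays:
        raise ValidationError(f"reference group {ref!r} not found")
    stats_by_label = {s.label: s for s in report.summaries}
    for other in arrays:
        if other == ref:
            continue
        sa, sb = stats_by_label[ref], stats_by_label[other]
        if sa.n >= 2 and sb.n >= 2 and not (sa.sd == 0 and sb.sd == 0):
            report.effects.append(
                EffectSize(
                    ref,
                    other,
                    cohens_d(
                        sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n,
                        denominator=effect_denominator,
                    ),
                )
            )
        try:
            vstat, vp = variance_test(
                arrays[ref], arrays[other], method=variance_method
            )
        except PipelineError:
            continue
        report.variance_tests.append(
            VarianceResult(ref, other, variance_method, vstat, vp)
        )
    return report


def report_to_frames(report: ComparisonReport) -> dict[str, pd.DataFrame]:
    """Tidy DataFrames for TSV export, one per report section."""
    return {
        "summary": pd.DataFrame([vars(s) for s in report.summaries]),
        "omnibus": pd.DataFrame(
            [
                {
                    "test": report.omnibus_test,
                    "statistic": report.omnibus_statistic,
                    "p": report.omnibus_p,
                    "alpha": report.alpha,
                }
            ]
        ),
        "pairwise": pd.DataFrame([vars(p) for p in report.pairwise]),
        "effects": pd.DataFrame([vars(e) for e in report.effects]),
        "variance": pd.DataFrame([vars(v) for v in report.variance_tests]),
    }
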