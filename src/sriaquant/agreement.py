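"""Frozen-vs-paraffin method agreement statistics.

Implements the agreement battery used to compare two measurements of the
same quantity on the same biopsies:

* Bland–Altman analysis with 95% limits of agreement and an OLS test of
  proportional bias (difference regressed on the pair mean);
* two-way consistency, average-measures intraclass correlation
  (ICC(C, k=2)) with its F-based confidence interval;
* quadratic-weighted Cohen's kappa for the ordinal IF grades;
* subgroup comparisons of the frozen-minus-paraffin differences with a
  Shapiro–Wilk normality gate choosing between the unpaired t-test and the
  Mann–Whitney U test;
* the "relevant difference" flags (>=10 percentage-point SRIA discrepancy,
  or any IF-grade discrepancy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import BiopsyPair

__all__ = [
    "BlandAltmanResult",
    "IccResult",
    "KappaResult",
    "SubgroupTestResult",
    "RelevantDifferenceFlags",
    "bland_altman",
    "icc_consistency_average",
    "icc_from_f",
    "weighted_kappa",
    "subgroup_difference",
    "relevant_difference_flags",
    "PairAgreement",
]

_Z_95 = 1.96  # used exactly, by convention, for limits of agreement and CIs


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, 95% limits of agreement and proportional-bias test."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_slope_beta: float
    bias_p: float
    n_pairs: int
    slope_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "mean_diff_pp": self.mean_diff,
            "sd_diff_pp": self.sd_diff,
            "loa_low_pp": self.loa_low,
            "loa_high_pp": self.loa_high,
            "bias_slope_beta": self.bias_slope_beta,
            "bias_p": self.bias_p,
            "n_pairs": self.n_pairs,
            "slope_defined": self.slope_defined,
        }


@dataclass(frozen=True)
class IccResult:
    """Two-way consistency, average-measures intraclass correlation."""

    icc: float
    f_value: float
    df1: int
    df2: int
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    model: str = "two-way consistency, average measures"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "f_value": self.f_value,
            "df1": self.df1,
            "df2": self.df2,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "model": self.model,
        }


@dataclass(frozen=True)
class KappaResult:
    """Quadratic-weighted Cohen's kappa over a K x K confusion table."""

    kappa: float
    confusion: np.ndarray
    n: int
    weight_scheme: str = "quadratic"
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "n": self.n,
            "weight_scheme": self.weight_scheme,
            "defined": self.defined,
            "confusion": np.asarray(self.confusion).tolist(),
        }


@dataclass(frozen=True)
class SubgroupTestResult:
    """Comparison of frozen-paraffin differences between two subgroups."""

    factor: str
    group_labels: tuple[str, str]
    group_means: tuple[float, float]
    group_sizes: tuple[int, int]
    test_used: Literal["t_test", "mann_whitney"]
    statistic: float
    p: float

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "group_labels": list(self.group_labels),
            "group_means": list(self.group_means),
            "group_sizes": list(self.group_sizes),
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p": self.p,
        }


@dataclass(frozen=True)
class RelevantDifferenceFlags:
    """Flags marking a clinically relevant frozen/paraffin discrepancy."""

    sria_flag: bool
    score_flag: Optional[bool]
    abs_difference_pp: float


def _as_float_array(x: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def bland_altman(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
) -> BlandAltmanResult:
    """Bland–Altman analysis of (frozen, paraffin) measurement pairs.

    Differences are frozen - paraffin; limits of agreement are
    mean +/- 1.96 x sample SD (n-1 denominator).  Proportional bias is the
    OLS slope of the difference on the pair mean, with a two-sided t-test
    p-value; a zero-variance pair mean leaves the slope undefined (flagged).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (frozen, paraffin) tuples")
    if arr.shape[0] < 3:
        raise ValueError("Bland–Altman analysis requires at least 3 pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs contain non-finite values")
    diff = arr[:, 0] - arr[:, 1]
    mean_pair = arr.mean(axis=1)
    n = arr.shape[0]
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa_low = mean_diff - _Z_95 * sd_diff
    loa_high = mean_diff + _Z_95 * sd_diff
    if np.ptp(mean_pair) == 0.0:
        return BlandAltmanResult(
            mean_diff, sd_diff, loa_low, loa_high,
            bias_slope_beta=float("nan"), bias_p=float("nan"),
            n_pairs=n, slope_defined=False,
        )
    res = stats.linregress(mean_pair, diff)
    # slope p-value is nan when the differences are exactly constant
    bias_p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return BlandAltmanResult(
        mean_diff, sd_diff, loa_low, loa_high,
        bias_slope_beta=float(res.slope), bias_p=bias_p, n_pairs=n,
    )


def icc_from_f(
    f_value: float, df1: int, df2: int, alpha: float = 0.05
) -> IccResult:
    """ICC(C, k) and its CI from a reported F statistic.

    Average-measures consistency identity: ICC = 1 - 1/F with
    F = MS_subjects / MS_error on (n-1, (n-1)(k-1)) degrees of freedom.  The
    confidence interval follows from the F quantiles:
    ci_low = 1 - F*_{1-alpha/2} / F, ci_high = 1 - 1 / (F · F*_{1-alpha/2}).
    """
    if f_value <= 0:
        raise ValueError("F must be positive")
    fq = stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    return IccResult(
        icc=1.0 - 1.0 / f_value,
        f_value=float(f_value),
        df1=int(df1),
        df2=int(df2),
        ci_low=1.0 - fq / f_value,
        ci_high=1.0 - 1.0 / (f_value * fq),
        alpha=alpha,
    )


def icc_consistency_average(
    x: Iterable[float], y: Iterable[float], alpha: float = 0.05
) -> IccResult:
    """Two-way consistency, average-measures ICC for two raters.

    A two-way ANOVA over n subjects x 2 raters decomposes the variance into
    subject, rater and residual mean squares; consistency ignores the rater
    (systematic-offset) component:

        ICC(C, k=2) = (MS_subjects - MS_error) / MS_subjects = 1 - 1/F

    with F = MS_subjects / MS_error on (n-1, n-1) degrees of freedom.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    data = np.column_stack([xa, ya])  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    df1, df2 = n - 1, (n - 1) * (k - 1)
    ms_subj = ss_subj / df1
    ms_err = ss_err / df2
    # residual indistinguishable from zero (perfect consistency up to float
    # rounding) => ICC 1 with a degenerate CI
    if ms_err <= 0.0 or ms_err < 1e-12 * max(ms_subj, 1.0):
        return IccResult(
            icc=1.0, f_value=float("inf"), df1=df1, df2=df2,
            ci_low=1.0, ci_high=1.0, alpha=alpha, degenerate=True,
        )
    f_value = ms_subj / ms_err
    result = icc_from_f(f_value, df1, df2, alpha=alpha)
    return result


def weighted_kappa(
    a: Iterable[int],
    b: Iterable[int],
    n_categories: Optional[int] = None,
    scheme: Literal["quadratic"] = "quadratic",
) -> KappaResult:
    """Quadratic-weighted Cohen's kappa for paired ordinal ratings.

    kappa = 1 - sum(w_ij O_ij) / sum(w_ij E_ij) with disagreement weights
    w_ij = ((i - j) / (K - 1))^2, O the observed joint proportions and E the
    outer product of the marginals.  When both raters use a single category
    the expected disagreement is zero and kappa is undefined (flagged).
    """
    if scheme != "quadratic":
        raise ValueError("only the quadratic weight scheme is supported")
    aa = np.asarray(list(a), dtype=int)
    bb = np.asarray(list(b), dtype=int)
    if aa.size != bb.size:
        raise ValueError("rating vectors must have equal length")
    if aa.size == 0:
        raise ValueError("empty rating vectors")
    if n_categories is None:
        n_categories = int(max(aa.max(), bb.max())) + 1
    K = int(n_categories)
    if K < 2:
        raise ValueError("need at least 2 categories")
    if aa.min() < 0 or bb.min() < 0 or aa.max() >= K or bb.max() >= K:
        raise ValueError(f"grades must lie in 0..{K - 1}")
    confusion = np.zeros((K, K), dtype=int)
    np.add.at(confusion, (aa, bb), 1)
    n = aa.size
    O = confusion / n
    marg_a = O.sum(axis=1)
    marg_b = O.sum(axis=0)
    E = np.outer(marg_a, marg_b)
    i, j = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    w = ((i - j) / (K - 1)) ** 2
    expected_disagreement = float((w * E).sum())
    if expected_disagreement == 0.0:
        return KappaResult(
            kappa=float("nan"), confusion=confusion, n=n, defined=False
        )
    kappa = 1.0 - float((w * O).sum()) / expected_disagreement
    return KappaResult(kappa=kappa, confusion=confusion, n=n)


def _normality_gate(values: np.ndarray, alpha: float = 0.05) -> bool:
    """True when Shapiro–Wilk does not reject normality at alpha.

    Groups below 8 observations fail the gate outright: Shapiro–Wilk has
    essentially no power there, so the nonparametric branch is used.
    """
    if values.size < 8 or np.ptp(values) == 0.0:
        return False
    return stats.shapiro(values).pvalue > alpha


def subgroup_difference(
    differences: Iterable[float],
    factor_values: Iterable,
    factor: str = "factor",
    normality_alpha: float = 0.05,
    exact_max_n: int = 12,
) -> SubgroupTestResult:
    """Compare frozen-paraffin differences between the two levels of a factor.

    Both groups must have >= 3 observations.  If both pass a Shapiro–Wilk
    normality gate (alpha = 0.05) an unpaired t-test is used; otherwise a
    Mann–Whitney U test, exact when the combined sample size is <= 12 and
    with the tie-corrected normal approximation otherwise.
    """
    diff = _as_float_array(differences, "differences")
    fac = np.asarray(list(factor_values))
    if fac.size != diff.size:
        raise ValueError("differences and factor_values must have equal length")
    levels = pd.unique(fac)
    if len(levels) != 2:
        raise ValueError(
            f"factor {factor!r} must have exactly 2 levels, found {len(levels)}"
        )
    g1 = diff[fac == levels[0]]
    g2 = diff[fac == levels[1]]
    for lv, g in zip(levels, (g1, g2)):
        if g.size == 0:
            raise ValueError(f"factor {factor!r}: empty subgroup for level {lv!r}")
        if g.size < 3:
            raise ValueError(
                f"factor {factor!r}: subgroup {lv!r} has fewer than 3 observations"
            )
    normal = _normality_gate(g1, normality_alpha) and _normality_gate(g2, normality_alpha)
    if normal:
        res = stats.ttest_ind(g1, g2)
        test_used, statistic, p = "t_test", float(res.statistic), float(res.pvalue)
    else:
        method = "exact" if (g1.size + g2.size) <= exact_max_n else "asymptotic"
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
        test_used, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    return SubgroupTestResult(
        factor=factor,
        group_labels=(str(levels[0]), str(levels[1])),
        group_means=(float(g1.mean()), float(g2.mean())),
        group_sizes=(int(g1.size), int(g2.size)),
        test_used=test_used,
        statistic=statistic,
        p=min(p, 1.0),
    )


def relevant_difference_flags(
    pair: BiopsyPair | tuple[float, float],
    grade_frozen: Optional[int] = None,
    grade_paraffin: Optional[int] = None,
    sria_threshold_pp: float = 10.0,
) -> RelevantDifferenceFlags:
    """Flag clinically relevant frozen/paraffin discrepancies.

    sria_flag: |frozen - paraffin| >= 10 percentage points of SRIA.
    score_flag: the two IF grades are present and unequal (None if absent).
    """
    if isinstance(pair, BiopsyPair):
        f, p = pair.frozen.fraction_pct, pair.paraffin.fraction_pct
        if grade_frozen is None:
            grade_frozen = pair.original_if_frozen
        if grade_paraffin is None:
            grade_paraffin = pair.original_if_paraffin
    else:
        f, p = float(pair[0]), float(pair[1])
    abs_diff = abs(f - p)
    score_flag = None
    if grade_frozen is not None and grade_paraffin is not None:
        score_flag = grade_frozen != grade_paraffin
    return RelevantDifferenceFlags(
        sria_flag=abs_diff >= sria_threshold_pp,
        score_flag=score_flag,
        abs_difference_pp=abs_diff,
    )


class PairAgreement:
    """Agreement analysis over a set of frozen/paraffin measurement pairs.

    Accepts either a list of :class:`BiopsyPair` (excluded pairs are
    dropped) or raw (frozen_pct, paraffin_pct) tuples with optional grade
    vectors, and exposes the full agreement battery plus a text summary.
    """

    def __init__(
        self,
        pairs: Sequence[BiopsyPair] | Sequence[tuple[float, float]],
        grades_frozen: Optional[Sequence[int]] = None,
        grades_paraffin: Optional[Sequence[int]] = None,
    ) -> None:
        if len(pairs) and isinstance(pairs[0], BiopsyPair):
            kept = [p for p in pairs if p.included]
            self.values = np.array(
                [(p.frozen.fraction_pct, p.paraffin.fraction_pct) for p in kept]
            )
            gf = [p.original_if_frozen for p in kept]
            gp = [p.original_if_paraffin for p in kept]
            if all(g is not None for g in gf) and all(g is not None for g in gp):
                grades_frozen = grades_frozen or gf
                grades_paraffin = grades_paraffin or gp
            self.pairs = kept
        else:
            self.values = np.asarray(pairs, dtype=float)
            self.pairs = None
        self.grades_frozen = grades_frozen
        self.grades_paraffin = grades_paraffin

    @property
    def n_pairs(self) -> int:
        return int(self.values.shape[0])

    def bland_altman(self) -> BlandAltmanResult:
        return bland_altman(self.values)

    def icc(self, alpha: float = 0.05) -> IccResult:
        return icc_consistency_average(
            self.values[:, 0], self.values[:, 1], alpha=alpha
        )

    def kappa(self) -> KappaResult:
        if self.grades_frozen is None or self.grades_paraffin is None:
            raise ValueError("grade vectors are required for kappa")
        return weighted_kappa(self.grades_frozen, self.grades_paraffin, n_categories=4)

    def flags(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_pairs):
            gf = self.grades_frozen[i] if self.grades_frozen is not None else None
            gp = self.grades_paraffin[i] if self.grades_paraffin is not None else None
            fl = relevant_difference_flags(
                (self.values[i, 0], self.values[i, 1]), gf, gp
            )
            rows.append(
                {
                    "frozen_pct": self.values[i, 0],
                    "paraffin_pct": self.values[i, 1],
                    "difference_pp": self.values[i, 0] - self.values[i, 1],
                    "sria_flag": fl.sria_flag,
                    "score_flag": fl.score_flag,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ba = self.bland_altman()
        icc = self.icc()
        lines = [
            "Frozen vs paraffin agreement",
            "=" * 40,
            f"pairs analysed          {self.n_pairs}",
            f"mean difference (pp)    {ba.mean_diff:8.2f}",
            f"SD of differences (pp)  {ba.sd_diff:8.2f}",
            f"95% limits of agreement [{ba.loa_low:.2f}, {ba.loa_high:.2f}]",
            f"proportional bias slope {ba.bias_slope_beta:8.3f} (p = {ba.bias_p:.3f})",
            f"ICC(C, k=2)             {icc.icc:8.3f} "
            f"(95% CI {icc.ci_low:.3f}-{icc.ci_high:.3f}, "
            f"F({icc.df1},{icc.df2}) = {icc.f_value:.3f})",
        ]
        if self.grades_frozen is not None and self.grades_paraffin is not None:
            kp = self.kappa()
            kval = f"{kp.kappa:8.3f}" if kp.defined else "  undefined"
            lines.append(f"quadratic-weighted kappa{kval}")
        return "\n".join(lines)
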