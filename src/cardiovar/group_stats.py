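"""Group-level statistics: summaries, assumption checks, ANOVA with
Dunnett's many-to-one comparisons, unpaired t-tests and the
figure-caption significance-mark conventions.

Dunnett's two-sided adjusted p-values are computed by deterministic
Gauss-Hermite x Gauss-Legendre quadrature over the exact multivariate-t
representation (conditioning on the control mean and the pooled scale),
which reduces *exactly* to the pooled two-sample t-test when only one
treatment group is present -- a property Monte-Carlo/QMC evaluations of
the multivariate-t CDF cannot guarantee to 1e-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Mapping, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats as sstats
from statsmodels.stats.diagnostic import lilliefors

from .core import ValidationError

_MARK_THRESHOLDS = ((1e-4, 4), (1e-3, 3), (1e-2, 2), (5e-2, 1))


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.sem < 0:
            raise ValidationError("sem must be >= 0")


@dataclass
class ComparisonResult:
    test: str                        # dunnett | t_unpaired | ks_normality | levene | anova
    groups: Tuple[str, ...]
    statistic: float
    p_value: float
    marks: str = ""
    flags: List[str] = field(default_factory=list)

    def __post_init__(self):
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def summarize(values: Sequence[float], group_label: str) -> GroupSummary:
    """Mean and SEM (sample SD over sqrt(n)); SEM = 0 with warning at n = 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    if arr.size == 1:
        warnings.warn("n = 1: SEM reported as 0", stacklevel=2)
        return GroupSummary(group_label, 1, float(arr[0]), 0.0)
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size))
    return GroupSummary(group_label, int(arr.size), float(np.mean(arr)), sem)


def significance_marks(p: float, context: str = "vs_control") -> str:
    """Caption convention: '*' marks vs control, '#' marks intergroup.

    One symbol per decade: p < 0.05 -> 1, < 0.01 -> 2, < 0.001 -> 3,
    < 0.0001 -> 4.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if context == "vs_control":
        char = "*"
    elif context == "intergroup":
        char = "#"
    else:
        raise ValidationError("context must be 'vs_control' or 'intergroup'")
    for threshold, count in _MARK_THRESHOLDS:
        if p < threshold:
            return char * count
    return ""


def unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = True,
    context: str = "intergroup",
) -> ComparisonResult:
    """Two-sided unpaired t-test (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2 for a t-test")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return ComparisonResult("t_unpaired", ("a", "b"), 0.0, 1.0,
                                    flags=["zero_variance"])
        return ComparisonResult("t_unpaired", ("a", "b"), float("inf"), 0.0,
                                marks=significance_marks(0.0, context),
                                flags=["zero_variance"])
    stat, p = sstats.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult("t_unpaired", ("a", "b"), float(stat), float(p),
                            marks=significance_marks(float(p), context))


def check_assumptions(groups: Mapping[str, Sequence[float]]) -> List[ComparisonResult]:
    """Per-group normality (Lilliefors-corrected KS) plus one Levene test.

    The KS test is against a normal with *estimated* mean/SD, so the
    Lilliefors correction is applied (flagged in the output).  Groups
    with n < 3 have their normality check skipped with a flag.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    results: List[ComparisonResult] = []
    usable: List[np.ndarray] = []
    labels: List[str] = []
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        labels.append(label)
        usable.append(arr)
        if arr.size < 4:
            results.append(ComparisonResult(
                "ks_normality", (label,), float("nan"), float("nan"),
                flags=["skipped_small_n"]))
            continue
        if np.std(arr, ddof=1) == 0.0:
            results.append(ComparisonResult(
                "ks_normality", (label,), float("nan"), float("nan"),
                flags=["skipped_zero_variance"]))
            continue
        stat, p = lilliefors(arr, dist="norm")
        results.append(ComparisonResult(
            "ks_normality", (label,), float(stat), float(p),
            flags=["lilliefors_correction"]))
    if all(arr.size >= 3 for arr in usable):
        if all(np.ptp(arr) == 0 for arr in usable):
            results.append(ComparisonResult("levene", tuple(labels), 0.0, 1.0,
                                            flags=["zero_variance"]))
        else:
            stat, p = sstats.levene(*usable, center="mean")
            results.append(ComparisonResult("levene", tuple(labels),
                                            float(stat), float(p)))
    else:
        results.append(ComparisonResult("levene", tuple(labels), float("nan"),
                                        float("nan"), flags=["skipped_small_n"]))
    return results


# --------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# --------------------------------------------------------------------------

def _dunnett_prob(
    q,
    df: int,
    n_treat: Sequence[int],
    n_control: int,
    n_hermite: int = 128,
    n_scale: int = 512,
) -> np.ndarray:
    """P(max_i |T_i| <= q) for Dunnett's two-sided statistic.

    T_i = (m_i - m_0) / (S * sqrt(1/n_i + 1/n_0)) with a pooled scale S
    on ``df`` degrees of freedom.  Conditioning on the control mean
    (z0 ~ N(0,1)) and the scale (s ~ chi_df / sqrt(df)) factorizes the
    joint probability into a product of normal CDF differences, which is
    integrated on a tensor Gauss-Hermite x Gauss-Legendre grid.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_hermite)
    z0 = np.sqrt(2.0) * gh_x                      # (nz,)
    wz = gh_w / np.sqrt(np.pi)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_scale)
    u = 0.5 * (gl_x + 1.0)                        # (ns,) in (0, 1)
    wu = 0.5 * gl_w
    s = sstats.chi.ppf(u, df) / np.sqrt(df)       # pooled-scale quantiles

    out = np.empty(q.size)
    chunk = 256
    z0g = z0[None, :, None]
    sg = s[None, None, :]
    for lo in range(0, q.size, chunk):
        qg = q[lo: lo + chunk, None, None]        # (nq, 1, 1)
        prod = np.ones((qg.shape[0], z0.size, s.size))
        for n_i in n_treat:
            w_i = np.sqrt(1.0 / n_i + 1.0 / n_control)
            c = np.sqrt(n_i / n_control) * z0g
            h = np.sqrt(n_i) * qg * sg * w_i
            prod *= special.ndtr(c + h) - special.ndtr(c - h)
        out[lo: lo + chunk] = np.einsum("qzs,z,s->q", prod, wz, wu)
    return np.clip(out, 0.0, 1.0)


def dunnett_adjusted_p(
    t_stats,
    df: int,
    n_treat: Sequence[int],
    n_control: int,
) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values for observed t statistics."""
    t = np.atleast_1d(np.asarray(t_stats, dtype=float))
    return 1.0 - _dunnett_prob(np.abs(t), df, n_treat, n_control)


def dunnett_critical_value(
    alpha: float, df: int, n_treat: Sequence[int], n_control: int
) -> float:
    """q such that P(max_i |T_i| > q) = alpha under the global null."""
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    fn = lambda q: _dunnett_prob(q, df, n_treat, n_control)[0] - (1.0 - alpha)
    return float(optimize.brentq(fn, 1e-6, 50.0, xtol=1e-10))


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control_label: str = "CTL",
) -> List[ComparisonResult]:
    """One-way ANOVA plus Dunnett comparisons of each treatment vs control."""
    if control_label not in groups:
        raise ValidationError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group {label!r} needs n >= 2")

    all_values = list(arrays.values())
    results: List[ComparisonResult] = []
    pooled_var = _pooled_variance(all_values)
    if pooled_var == 0.0:
        # degenerate: perfectly constant groups (noise-free synthetic runs);
        # convention mirrors unpaired_t -- p = 1 for equal means, 0 otherwise
        control_mean = float(np.mean(arrays[control_label]))
        all_equal = np.ptp([np.mean(a) for a in all_values]) == 0.0
        results.append(ComparisonResult(
            "anova", tuple(arrays), float("nan"), 1.0 if all_equal else 0.0,
            flags=["degenerate_zero_variance"]))
        for label in arrays:
            if label != control_label:
                equal = float(np.mean(arrays[label])) == control_mean
                results.append(ComparisonResult(
                    "dunnett", (label, control_label),
                    0.0 if equal else float("inf"), 1.0 if equal else 0.0,
                    marks="" if equal else significance_marks(0.0, "vs_control"),
                    flags=["degenerate_zero_variance"]))
        return results

    f_stat, f_p = sstats.f_oneway(*all_values)
    results.append(ComparisonResult("anova", tuple(arrays), float(f_stat), float(f_p)))

    control = arrays[control_label]
    treat_labels = [k for k in arrays if k != control_label]
    n_treat = [arrays[k].size for k in treat_labels]
    df = sum(a.size for a in all_values) - len(all_values)
    s = np.sqrt(pooled_var)
    t_obs = np.array([
        (np.mean(arrays[k]) - np.mean(control))
        / (s * np.sqrt(1.0 / arrays[k].size + 1.0 / control.size))
        for k in treat_labels
    ])
    p_adj = dunnett_adjusted_p(t_obs, df, n_treat, control.size)
    for label, t, p in zip(treat_labels, t_obs, p_adj):
        results.append(ComparisonResult(
            "dunnett", (label, control_label), float(t), float(p),
            marks=significance_marks(float(p), "vs_control")))
    return results


def _pooled_variance(arrays: Sequence[np.ndarray]) -> float:
    ss = sum(float(np.sum((a - np.mean(a)) ** 2)) for a in arrays)
    df = sum(a.size for a in arrays) - len(arrays)
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    return ss / df
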