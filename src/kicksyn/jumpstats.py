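"""Jump-height computation and the study's statistical layer.

Covers: flight-time jump height h = g t^2 / 8, best-of-three aggregation,
a priori power / sample-size for a within-subject repeated-measures ANOVA
(noncentral-F, G*Power within-factor convention), the two-way RM-ANOVA
sums-of-squares partition with partial eta squared, the Friedman test,
pairwise post hocs with Bonferroni/Holm correction, the Z-to-Cohen's-d
conversion, and the Shapiro-Wilk normality gate that routes each outcome to
the parametric or non-parametric branch.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import nan, sqrt

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GRAVITY", "JumpResult", "PowerSpec", "AnovaResult", "StatResult",
    "GateResult", "jump_height", "best_of_jumps", "rm_anova_power",
    "rm_anova_sample_size", "one_way_rm_anova", "two_way_rm_anova",
    "friedman_test", "posthoc_pairwise", "cohens_d_from_z", "shapiro_gate",
]

GRAVITY = 9.81  # m/s^2

#: partial-eta-squared descriptive labels (labeling only, never inference)
ETA_P_SQ_LABELS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))


@dataclass(frozen=True)
class JumpResult:
    flight_time_s: float
    height_cm: float
    gravity: float = GRAVITY


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the within-factor RM-ANOVA power computation."""

    effect_size_f: float
    alpha: float = 0.05
    power_target: float = 0.80
    n_measurements: int = 3
    correlation_rho: float = 0.5
    nonsphericity_epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must be in (0, 1)")
        if not 0 <= self.correlation_rho < 1:
            raise ValueError("correlation_rho must be in [0, 1)")
        if self.n_measurements < 2:
            raise ValueError("need at least two repeated measurements")
        if self.effect_size_f <= 0:
            raise ValueError("effect_size_f must be positive")
        if not 0 < self.nonsphericity_epsilon <= 1:
            raise ValueError("nonsphericity_epsilon must be in (0, 1]")


@dataclass(frozen=True)
class AnovaResult:
    effect_name: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_p_sq: float

    @property
    def effect_label(self) -> str:
        for cut, label in ETA_P_SQ_LABELS:
            if self.eta_p_sq >= cut:
                return label
        return "negligible"


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    correction: str                      # bonferroni | holm | none
    effect_size: float
    comparison: tuple[str, ...] = ()
    effect_size_name: str = "d"
    degenerate: bool = False
    df: float | None = None


@dataclass(frozen=True)
class GateResult:
    parametric: bool
    p_values: dict[str, float] = field(default_factory=dict)
    degenerate_cells: tuple[str, ...] = ()


def jump_height(flight_time_s, g: float = GRAVITY):
    """Vertical jump height in cm from flight time: h = g t^2 / 8."""
    t = np.asarray(flight_time_s, dtype=float)
    if (t < 0).any():
        raise ValueError("flight time must be non-negative")
    h = 100.0 * g * t ** 2 / 8.0
    return float(h) if np.isscalar(flight_time_s) or h.ndim == 0 else h


def best_of_jumps(heights) -> float:
    """Highest of the recorded jumps (the value carried to analysis)."""
    arr = np.asarray(heights, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one jump")
    return float(arr.max())


def rm_anova_power(spec: PowerSpec, n: int) -> float:
    """Power of the within-factor F test at sample size ``n``.

    Noncentral-F with numerator df (m-1)*eps, denominator df (n-1)(m-1)*eps
    and noncentrality lambda = n * f^2 * m * eps / (1 - rho).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    m, eps = spec.n_measurements, spec.nonsphericity_epsilon
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    lam = n * spec.effect_size_f ** 2 * m * eps / (1 - spec.correlation_rho)
    crit = stats.f.ppf(1 - spec.alpha, df1, df2)
    return float(1 - stats.ncf.cdf(crit, df1, df2, lam))


def rm_anova_sample_size(spec: PowerSpec, n_cap: int = 10000) -> int:
    """Smallest N whose within-factor power reaches the target."""
    powers = {}
    for n in range(2, n_cap + 1):
        p = rm_anova_power(spec, n)
        powers[n] = p
        if p >= spec.power_target:
            return n
    raise ValueError(
        f"target power {spec.power_target} unreachable below N={n_cap}; "
        f"power at cap: {powers[n_cap]:.4f}")


def _check_complete(data: np.ndarray, ndim: int) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"expected a {ndim}-D array, got {arr.ndim}-D")
    if np.isnan(arr).any():
        raise ValueError("design has missing cells; no imputation is done")
    if arr.shape[0] < 2:
        raise ValueError("need at least two subjects")
    return arr


def _f_result(name: str, ss_eff: float, ss_err: float, df1: int, df2: int,
              scale: float) -> AnovaResult:
    """F, p and partial eta squared from an effect/error SS pair.

    Sums of squares below 1e-12 of the total variation are treated as exact
    zeros so that identical-by-construction conditions report F = 0 rather
    than a ratio of rounding residue.
    """
    tiny = 1e-12 * (scale + 1.0)
    ss_eff = 0.0 if ss_eff <= tiny else ss_eff
    ss_err = 0.0 if ss_err <= tiny else ss_err
    ms_err = ss_err / df2
    if ms_err > 0:
        F = (ss_eff / df1) / ms_err
    else:
        F = 0.0 if ss_eff == 0 else np.inf
    p = float(stats.f.sf(F, df1, df2))
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaResult(name, float(F), df1, df2, p, float(eta))


def one_way_rm_anova(data, effect_name: str = "condition") -> AnovaResult:
    """Univariate RM-ANOVA for one within factor; data is subjects x levels."""
    y = _check_complete(data, 2)
    n, a = y.shape
    grand = y.mean()
    cond = y.mean(axis=0)
    subj = y.mean(axis=1)
    ss_eff = n * np.sum((cond - grand) ** 2)
    ss_err = np.sum((y - cond[None, :] - subj[:, None] + grand) ** 2)
    return _f_result(effect_name, ss_eff, ss_err, a - 1, (n - 1) * (a - 1),
                     scale=np.sum((y - grand) ** 2))


def two_way_rm_anova(data, factor_names: tuple[str, str] = ("protocol",
                                                            "time"),
                     ) -> list[AnovaResult]:
    """Fully within-subject two-way RM-ANOVA on a subjects x A x B array.

    Each effect is tested against its own subject-by-effect interaction
    (standard univariate partition); partial eta squared is
    SS_effect / (SS_effect + SS_error-of-that-effect).
    """
    y = _check_complete(data, 3)
    n, a, b = y.shape
    grand = y.mean()
    A = y.mean(axis=(0, 2))            # a
    B = y.mean(axis=(0, 1))            # b
    S = y.mean(axis=(1, 2))            # n
    AB = y.mean(axis=0)                # a x b
    SA = y.mean(axis=2)                # n x a
    SB = y.mean(axis=1)                # n x b

    ss_A = n * b * np.sum((A - grand) ** 2)
    ss_B = n * a * np.sum((B - grand) ** 2)
    ss_AB = n * np.sum((AB - A[:, None] - B[None, :] + grand) ** 2)
    ss_SA = b * np.sum((SA - S[:, None] - A[None, :] + grand) ** 2)
    ss_SB = a * np.sum((SB - S[:, None] - B[None, :] + grand) ** 2)
    resid = (y - SA[:, :, None] - SB[:, None, :] - AB[None, :, :]
             + S[:, None, None] + A[None, :, None] + B[None, None, :]
             - grand)
    ss_SAB = np.sum(resid ** 2)

    scale = np.sum((y - grand) ** 2)

    def result(name, ss_eff, ss_err, df1, df2):
        return _f_result(name, ss_eff, ss_err, df1, df2, scale)

    fa, fb = factor_names
    return [
        result(fa, ss_A, ss_SA, a - 1, (n - 1) * (a - 1)),
        result(fb, ss_B, ss_SB, b - 1, (n - 1) * (b - 1)),
        result(f"{fa} x {fb}", ss_AB, ss_SAB,
               (a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1)),
    ]


def friedman_test(data, labels: tuple[str, ...] | None = None) -> StatResult:
    """Friedman rank test across matched conditions (columns).

    Midranks handle ties within a subject; the chi-square statistic carries
    the standard tie correction and df = k - 1.  If every subject's row is
    constant the statistic is undefined and the result is flagged degenerate.
    """
    y = _check_complete(data, 2)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least two conditions")
    ranks = np.apply_along_axis(stats.rankdata, 1, y)
    ssbn = np.sum(ranks.sum(axis=0) ** 2)
    ties = 0.0
    for row in y:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    c = 1.0 - ties / (n * k * (k * k - 1))
    comparison = labels if labels is not None else tuple(
        f"C{j + 1}" for j in range(k))
    if c <= 0:
        return StatResult("friedman", nan, nan, nan, "none", nan,
                          comparison=comparison, effect_size_name="none",
                          degenerate=True, df=k - 1)
    chi2 = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c
    p = float(stats.chi2.sf(chi2, k - 1))
    # Kendall's W as the descriptive effect size of agreement
    w = chi2 / (n * (k - 1))
    return StatResult("friedman", float(chi2), p, p, "none", float(w),
                      comparison=comparison, effect_size_name="kendall_w",
                      df=k - 1)


def cohens_d_from_z(z: float, n: int) -> float:
    """Cohen's d from a signed-rank Z statistic and the pair count.

    Uses r = Z / sqrt(n) followed by d = 2 r / sqrt(1 - r^2).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    r = z / sqrt(n)
    if abs(r) >= 1:
        raise ValueError(f"|Z|/sqrt(n) = {abs(r):.3f} >= 1: n too small "
                         "for this Z")
    return 2.0 * r / sqrt(1.0 - r * r)


def posthoc_pairwise(data, labels: tuple[str, ...] | None = None,
                     parametric: bool = True,
                     correction: str | None = None) -> list[StatResult]:
    """All pairwise comparisons between conditions (columns of data).

    Parametric branch: paired t tests, Bonferroni-corrected, paired Cohen's d
    (mean difference over SD of differences).  Non-parametric branch:
    Wilcoxon signed-rank tests (zeros dropped, normal approximation),
    Holm-corrected, Cohen's d converted from the Z statistic.
    """
    y = _check_complete(data, 2)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least two conditions")
    names = labels if labels is not None else tuple(
        f"C{j + 1}" for j in range(k))
    if correction is None:
        correction = "bonferroni" if parametric else "holm"
    if correction not in ("bonferroni", "holm", "none"):
        raise ValueError("correction must be bonferroni, holm or none")

    raws, stats_, effects, pairs = [], [], [], []
    for i, j in itertools.combinations(range(k), 2):
        x1, x2 = y[:, i], y[:, j]
        diff = x1 - x2
        if parametric:
            sd = diff.std(ddof=1)
            if sd == 0:
                t_stat, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf,
                                                                     0.0)
                d = 0.0 if np.allclose(diff, 0) else np.inf
            else:
                t_stat, p = stats.ttest_rel(x1, x2)
                d = diff.mean() / sd
            stats_.append(float(t_stat))
            effects.append(float(d))
        else:
            if np.allclose(diff, 0):
                stats_.append(0.0)
                effects.append(0.0)
                p = 1.0
            else:
                res = stats.wilcoxon(x1, x2, zero_method="wilcox",
                                     method="approx", correction=False)
                z = float(res.zstatistic)
                # orient Z with the direction of the median difference
                z = abs(z) * np.sign(np.median(diff[diff != 0]))
                stats_.append(z)
                effects.append(cohens_d_from_z(z, n))
                p = float(res.pvalue)
        raws.append(float(p))
        pairs.append((names[i], names[j]))

    if correction == "none":
        adjusted = list(raws)
    else:
        adjusted = multipletests(raws, method=correction)[1].tolist()
    test = "paired_t" if parametric else "wilcoxon_signed_rank"
    return [StatResult(test, s, pr, pa, correction, e, comparison=pair,
                       effect_size_name="d",
                       df=(n - 1 if parametric else None))
            for s, pr, pa, e, pair in zip(stats_, raws, adjusted, effects,
                                          pairs)]


def shapiro_gate(cells: dict[str, np.ndarray],
                 alpha: float = 0.05) -> GateResult:
    """Route a variable to the parametric branch iff no cell rejects normality.

    Each cell (e.g. one protocol x time group) is Shapiro-Wilk tested at
    ``alpha``; constant cells are flagged degenerate and force the
    non-parametric branch.
    """
    if not cells:
        raise ValueError("no cells supplied")
    p_values: dict[str, float] = {}
    degenerate: list[str] = []
    parametric = True
    for name, values in cells.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 3:
            raise ValueError(f"cell {name!r} has fewer than 3 observations")
        if np.ptp(arr) <= 1e-12 * max(np.abs(arr).max(), 1.0):
            degenerate.append(name)
            parametric = False
            p_values[name] = nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            p = float(stats.shapiro(arr).pvalue)
        if np.isnan(p):
            degenerate.append(name)
            parametric = False
            p_values[name] = nan
            continue
        p_values[name] = p
        if p < alpha:
            parametric = False
    return GateResult(parametric=parametric, p_values=p_values,
                      degenerate_cells=tuple(degenerate))
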