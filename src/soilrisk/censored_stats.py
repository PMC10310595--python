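"""Kaplan–Meier summary statistics and Peto–Peto comparisons for left-censored
concentration data, plus the XRF/ICP-MS QA regressions.

Left-censored nondetects ("<LOD") are handled by the flipping trick: values
are reflected about a constant ``M`` larger than every observation and bound,
turning "<L" into a right-censored survival time ``M − L``. The product-limit
(Kaplan–Meier) estimator is computed on the flipped data and means/quantiles
are flipped back, so no substitution value is ever invented for a nondetect.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import Measurement, SampleRecord, SiteGroup

__all__ = [
    "CensoredSummary",
    "GroupTestResult",
    "ScreenResult",
    "km_summary",
    "peto_peto",
    "pairwise_screen",
    "comparability_regression",
    "srm_recovery",
    "summary_table",
]


@dataclass
class CensoredSummary:
    """Kaplan–Meier summary for one censored sample of concentrations."""

    n: int
    pct_censored: float
    mean: float
    sd: float
    median: float
    p95: float
    maximum: float
    flags: set[str] = field(default_factory=set)


@dataclass
class GroupTestResult:
    element: str | None
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    flags: set[str] = field(default_factory=set)


def _coerce(values, censored=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept Measurements or (values, censored-mask) arrays; return numeric
    values (detection limits for censored entries) and a boolean mask."""
    vals = list(values)
    if vals and isinstance(vals[0], Measurement):
        nums = np.array([m.detection_limit if m.censored else m.value for m in vals], float)
        mask = np.array([m.censored for m in vals], bool)
        return nums, mask
    nums = np.asarray(vals, dtype=float)
    mask = np.zeros(len(nums), bool) if censored is None else np.asarray(censored, bool)
    if mask.shape != nums.shape:
        raise ValueError("values and censored mask must have the same length")
    return nums, mask


def _km_masses(nums: np.ndarray, mask: np.ndarray, flip_constant: float | None):
    """Product-limit probability masses on the original scale.

    Returns (points, masses, flags): censored survival mass that never reaches
    an event is carried to the smallest observation/bound (the restricted-mean
    convention for a censored minimum) and flagged.
    """
    flags: set[str] = set()
    M = flip_constant if flip_constant is not None else float(nums.max()) + 1.0
    if M <= nums.max():
        raise ValueError("flip constant must exceed every value and bound")
    t = M - nums
    events = ~mask
    kmf = KaplanMeierFitter().fit(t, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(float)
    surv = sf.to_numpy(float)
    prev = 1.0
    pts, masses = [], []
    for ti, si in zip(times, surv):
        jump = prev - si
        if jump > 0:
            pts.append(M - ti)
            masses.append(jump)
        prev = si
    leftover = prev
    if leftover > 1e-12:
        # smallest original point (a censored bound); mass carried there
        pts.append(float(nums.min()))
        masses.append(leftover)
        flags.add("censored_min")
    pts = np.asarray(pts)
    masses = np.asarray(masses)
    order = np.argsort(pts)
    return pts[order], masses[order], flags


def _discrete_quantile(pts: np.ndarray, masses: np.ndarray, q: float) -> float:
    cum = np.cumsum(masses)
    idx = int(np.searchsorted(cum, q - 1e-12))
    return float(pts[min(idx, len(pts) - 1)])


def km_summary(values, censored=None, *, flip_constant: float | None = None) -> CensoredSummary:
    """Kaplan–Meier summary statistics for a possibly left-censored sample.

    *values* is either a sequence of :class:`Measurement` or a numeric array
    (with *censored* a parallel boolean mask; censored entries hold their
    detection limit). With no censoring the result equals the arithmetic
    mean, sample SD and inverted-CDF empirical quantiles exactly.

    If every value is censored no distribution can be estimated: the mean and
    median are reported as upper bounds at the smallest detection limit and
    the summary is flagged ``all_censored``.
    """
    nums, mask = _coerce(values, censored)
    n = len(nums)
    if n == 0:
        raise ValueError("km_summary requires at least one value")
    if np.any(nums <= 0):
        raise ValueError("concentrations and bounds must be positive")
    pct = 100.0 * mask.sum() / n
    if mask.all():
        bound = float(nums.min())
        return CensoredSummary(n, 100.0, bound, math.nan, bound, bound, bound,
                               flags={"all_censored", "upper_bound"})
    pts, masses, flags = _km_masses(nums, mask, flip_constant)
    mean = float(np.sum(pts * masses))
    var = float(np.sum(masses * (pts - mean) ** 2))
    sd = math.sqrt(var * n / (n - 1)) if n > 1 else math.nan
    return CensoredSummary(
        n=n,
        pct_censored=pct,
        mean=mean,
        sd=sd,
        median=_discrete_quantile(pts, masses, 0.5),
        p95=_discrete_quantile(pts, masses, 0.95),
        maximum=float(nums[~mask].max()),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Peto–Peto generalized Wilcoxon test
# ---------------------------------------------------------------------------

def _peto_score(t: np.ndarray, events: np.ndarray, in_a: np.ndarray) -> tuple[float, float]:
    """Two-sample Peto–Peto weighted log-rank sums on right-censored data.

    Returns (U, V): the weighted observed-minus-expected score for group *a*
    and its hypergeometric variance. Weights are the Peto–Peto modified
    survival estimate S̃(t_i) = Π_{j ≤ i} (1 − d_j/(n_j + 1)).
    """
    order = np.argsort(t, kind="stable")
    t, events, in_a = t[order], events[order], in_a[order]
    n = len(t)
    U = 0.0
    V = 0.0
    stilde = 1.0
    i = 0
    n_at_risk = n
    n_a_at_risk = int(in_a.sum())
    while i < n:
        j = i
        d = d_a = removed = removed_a = 0
        while j < n and t[j] == t[i]:
            removed += 1
            removed_a += int(in_a[j])
            if events[j]:
                d += 1
                d_a += int(in_a[j])
            j += 1
        if d > 0:
            stilde *= 1.0 - d / (n_at_risk + 1.0)
            w = stilde
            e_a = d * n_a_at_risk / n_at_risk
            U += w * (d_a - e_a)
            if n_at_risk > 1:
                hyper = (d * (n_at_risk - d) * n_a_at_risk * (n_at_risk - n_a_at_risk)
                         / (n_at_risk ** 2 * (n_at_risk - 1.0)))
                V += w * w * hyper
        n_at_risk -= removed
        n_a_at_risk -= removed_a
        i = j
    return U, V


def peto_peto(a_values, b_values, a_censored=None, b_censored=None, *,
              method: str = "asymptotic", n_perm: int = 10_000,
              seed: int | None = None, element: str | None = None,
              group_a: str = "a", group_b: str = "b") -> GroupTestResult:
    """Peto–Peto generalized Wilcoxon score test between two possibly
    left-censored samples.

    Data are flipped about a shared constant so nondetects become
    right-censored, then the Peto–Peto weighted log-rank score is computed.
    ``method="asymptotic"`` refers U²/V to the χ²(1) distribution (two-sided);
    ``method="permutation"`` computes the permutation p-value of the same
    score statistic |U| — exhaustively when the number of group assignments is
    small, otherwise by Monte Carlo with *n_perm* draws.
    """
    a, am = _coerce(a_values, a_censored)
    b, bm = _coerce(b_values, b_censored)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n ≥ 2")
    result = GroupTestResult(element, group_a, group_b, math.nan, math.nan)
    for nums, mask in ((a, am), (b, bm)):
        if mask.all() and np.unique(nums).size == 1:
            result.flags.add("skipped_degenerate_group")
            return result
    nums = np.concatenate([a, b])
    mask = np.concatenate([am, bm])
    M = float(nums.max()) + 1.0
    t = M - nums
    events = ~mask
    in_a = np.zeros(len(nums), bool)
    in_a[: len(a)] = True
    U, V = _peto_score(t, events, in_a)
    if V <= 0:
        result.statistic = 0.0
        result.p_value = 1.0
        result.flags.add("zero_variance")
        return result
    chi2 = U * U / V
    result.statistic = chi2
    if method == "asymptotic":
        result.p_value = float(stats.chi2.sf(chi2, df=1))
        return result
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    n, na = len(nums), len(a)
    n_comb = math.comb(n, na)
    obs = abs(U)
    if n_comb <= n_perm:
        count = 0
        for combo in itertools.combinations(range(n), na):
            perm_mask = np.zeros(n, bool)
            perm_mask[list(combo)] = True
            u, _ = _peto_score(t, events, perm_mask)
            if abs(u) >= obs - 1e-12:
                count += 1
        result.p_value = count / n_comb
        result.flags.add("exhaustive_permutation")
    else:
        rng = np.random.default_rng(seed)
        count = 1  # observed assignment counts itself
        for _ in range(n_perm):
            perm_mask = np.zeros(n, bool)
            perm_mask[rng.choice(n, size=na, replace=False)] = True
            u, _ = _peto_score(t, events, perm_mask)
            if abs(u) >= obs - 1e-12:
                count += 1
        result.p_value = count / (n_perm + 1)
        result.flags.add("monte_carlo_permutation")
    return result


@dataclass
class ScreenResult:
    """All pairwise group tests plus the per-element screening verdict."""

    results: list[GroupTestResult]
    no_difference: list[str]  # elements with every adjusted p ≥ alpha
    skipped: list[str] = field(default_factory=list)


def _group_arrays(samples: Sequence[SampleRecord], element: str):
    by_group: dict[str, tuple[list, list]] = {}
    for s in samples:
        m = s.measurements.get(element)
        if m is None:
            continue
        vals, mask = by_group.setdefault(s.site_group.value, ([], []))
        vals.append(m.detection_limit if m.censored else m.value)
        mask.append(m.censored)
    return by_group


def pairwise_screen(samples: Sequence[SampleRecord], elements: Iterable[str],
                    alpha: float = 0.05, *, method: str = "asymptotic") -> ScreenResult:
    """Peto–Peto tests for every site-group pair × element, with
    Benjamini–Hochberg adjustment across the whole family.

    Elements for which no pairwise comparison reaches the adjusted *alpha*
    are flagged as showing no group difference (candidates for removal from
    further analysis).
    """
    groups_present = {s.site_group.value for s in samples}
    if len(groups_present) < 2:
        raise ValueError("pairwise_screen requires ≥ 2 site groups")
    results: list[GroupTestResult] = []
    skipped: list[str] = []
    tested_elements: set[str] = set()
    for element in elements:
        by_group = _group_arrays(samples, element)
        usable = {g: v for g, v in by_group.items() if len(v[0]) >= 2}
        if len(usable) < 2:
            skipped.append(element)
            continue
        tested_elements.add(element)
        for ga, gb in itertools.combinations(sorted(usable), 2):
            va, ma = usable[ga]
            vb, mb = usable[gb]
            results.append(peto_peto(va, vb, ma, mb, method=method,
                                     element=element, group_a=ga, group_b=gb))
    testable = [r for r in results if not math.isnan(r.p_value)]
    if testable:
        _, adj, _, _ = multipletests([r.p_value for r in testable], method="fdr_bh")
        for r, p_adj in zip(testable, adj):
            r.p_adjusted = float(p_adj)
    no_diff = sorted(
        e for e in tested_elements
        if all(r.p_adjusted is None or r.p_adjusted >= alpha
               for r in results if r.element == e)
    )
    return ScreenResult(results, no_diff, skipped)


# ---------------------------------------------------------------------------
# QA: method comparability and SRM recovery
# ---------------------------------------------------------------------------

def comparability_regression(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """OLS of confirmatory (ICP-MS) on field (XRF) concentrations: slope,
    intercept, R² and the slope p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired data with n ≥ 3 required")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    return {"slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.rvalue ** 2, "p": fit.pvalue}


def srm_recovery(measured: float, certified: float) -> float:
    """Percent recovery of a standard reference material."""
    if certified <= 0:
        raise ValueError("certified value must be positive")
    return 100.0 * measured / certified


# ---------------------------------------------------------------------------
# summary-table export
# ---------------------------------------------------------------------------

def summary_table(samples: Sequence[SampleRecord], elements: Iterable[str]):
    """Element × site-group KM summary table (n, %censored, median, mean, SD,
    95th percentile, maximum) in long format."""
    import pandas as pd

    rows = []
    for element in elements:
        for group, (vals, mask) in sorted(_group_arrays(samples, element).items()):
            if not vals:
                continue
            s = km_summary(np.asarray(vals), np.asarray(mask))
            rows.append({
                "element": element, "site_group": group, "n": s.n,
                "pct_censored": s.pct_censored, "median": s.median,
                "mean": s.mean, "sd": s.sd, "p95": s.p95,
                "maximum": s.maximum, "flags": ";".join(sorted(s.flags)),
            })
    return pd.DataFrame(rows)
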