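"""2-back performance scoring: d', correct-response RT, change index, group tests.

Sensitivity follows the signal-detection convention d' = Z(hit rate) -
Z(false-alarm rate) with an inverse normal transform; extreme rates are
corrected before the transform so d' stays finite.  The behavioral change
index X normalizes the pre-to-post reaction-time change by the pre value,
signed so that a speed-up is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .synth import BehavioralSession

__all__ = [
    "BehavioralSummary",
    "ChangeIndex",
    "dprime",
    "correct_extreme_rate",
    "mean_correct_rt",
    "summarize_session",
    "change_index",
    "compare_groups",
    "GroupComparison",
]


@dataclass(frozen=True)
class BehavioralSummary:
    dprime: float
    mean_rt: float  # seconds, correct responses only
    n_hits: int
    n_false_alarms: int
    n_targets: int
    n_nontargets: int


@dataclass(frozen=True)
class ChangeIndex:
    x: float
    pre: float
    post: float


def correct_extreme_rate(rate: float, n: int) -> float:
    """Log-linear style correction: 0 -> 0.5/n, 1 -> (n-0.5)/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rate <= 0.0:
        return 0.5 / n
    if rate >= 1.0:
        return (n - 0.5) / n
    return rate


def dprime(hit_rate: float, fa_rate: float, *, n_targets: int | None = None,
           n_nontargets: int | None = None) -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate).

    If trial counts are given, rates of exactly 0 or 1 are corrected to
    0.5/n and (n-0.5)/n before the transform; without counts an extreme
    rate raises, since the transform would be infinite.
    """
    for r in (hit_rate, fa_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"rate {r} outside [0, 1]")
    if hit_rate in (0.0, 1.0):
        if n_targets is None:
            raise ValueError("extreme hit rate needs n_targets for correction")
        hit_rate = correct_extreme_rate(hit_rate, n_targets)
    if fa_rate in (0.0, 1.0):
        if n_nontargets is None:
            raise ValueError("extreme false-alarm rate needs n_nontargets")
        fa_rate = correct_extreme_rate(fa_rate, n_nontargets)
    return float(sps.norm.ppf(hit_rate) - sps.norm.ppf(fa_rate))


def _correct_mask(session: BehavioralSession) -> np.ndarray:
    t = session.trials
    return (t["is_target"] & t["response"]) | (~t["is_target"] & ~t["response"])


def mean_correct_rt(session: BehavioralSession) -> float:
    """Mean reaction time over correct trials only (seconds)."""
    mask = _correct_mask(session)
    if not mask.any():
        raise ValueError("no correct trials in session")
    return float(session.trials.loc[mask, "rt_s"].mean())


def summarize_session(session: BehavioralSession) -> BehavioralSummary:
    t = session.trials
    n_targets = int(t["is_target"].sum())
    n_nontargets = int((~t["is_target"]).sum())
    n_hits = int((t["is_target"] & t["response"]).sum())
    n_fa = int((~t["is_target"] & t["response"]).sum())
    d = dprime(
        n_hits / n_targets if n_targets else 0.0,
        n_fa / n_nontargets if n_nontargets else 0.0,
        n_targets=n_targets or None,
        n_nontargets=n_nontargets or None,
    )
    return BehavioralSummary(
        dprime=d, mean_rt=mean_correct_rt(session),
        n_hits=n_hits, n_false_alarms=n_fa,
        n_targets=n_targets, n_nontargets=n_nontargets,
    )


def change_index(pre: float, post: float, *, literal: bool = False) -> ChangeIndex:
    """Normalized pre-to-post change X.

    Default sign convention is (pre - post) / pre, so a reaction-time
    reduction yields a positive X (matching how group improvements are
    tabulated); ``literal=True`` gives (post - pre) / pre instead.  X is a
    per-subject quantity: group values are means of per-subject ratios,
    not the ratio of group means.
    """
    if pre <= 0:
        raise ValueError("pre must be positive")
    x = (post - pre) / pre if literal else (pre - post) / pre
    return ChangeIndex(x=float(x), pre=float(pre), post=float(post))


@dataclass(frozen=True)
class GroupComparison:
    method: str                     # 'anova' or 'kruskal'
    statistic: float                # F or H
    df: tuple[float, float] | float
    pvalue: float
    pairwise_vs_reference: dict[str, float]  # Bonferroni-corrected p


def compare_groups(values: dict[str, np.ndarray], *, method: str = "anova",
                   reference: str | None = None) -> GroupComparison:
    """Omnibus group comparison with Bonferroni-corrected pairwise tests.

    ``method='anova'`` runs a one-way ANOVA (F, df=(k-1, N-k));
    ``'kruskal'`` the Kruskal-Wallis H test.  Pairwise tests against the
    ``reference`` group (two-sample t or Mann-Whitney) are Bonferroni
    corrected by the number of comparisons.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    arrays = list(groups.values())
    if method == "anova":
        stat, p = sps.f_oneway(*arrays)
        k, n = len(arrays), sum(a.size for a in arrays)
        df = (float(k - 1), float(n - k))
    elif method == "kruskal":
        stat, p = sps.kruskal(*arrays)
        df = float(len(arrays) - 1)
    else:
        raise ValueError("method must be 'anova' or 'kruskal'")

    pairwise: dict[str, float] = {}
    if reference is not None:
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} not present")
        others = [g for g in groups if g != reference]
        m = len(others)
        for g in others:
            if method == "anova":
                _, praw = sps.ttest_ind(groups[g], groups[reference])
            else:
                _, praw = sps.mannwhitneyu(
                    groups[g], groups[reference], alternative="two-sided")
            pairwise[g] = float(min(1.0, praw * m))
    return GroupComparison(method=method, statistic=float(stat), df=df,
                           pvalue=float(p), pairwise_vs_reference=pairwise)
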