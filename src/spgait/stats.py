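"""Cross-condition statistics: one-way ANOVA with Tukey HSD post-hoc.

Each gait component and each fitted model parameter is compared across the
five walking conditions.  The ANOVA is the classical between/within
sum-of-squares decomposition; the post-hoc test uses the studentized range
on MS_within, with the Tukey-Kramer harmonic adjustment for unequal group
sizes (trial counts per condition need not be balanced after exclusions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .errors import InvalidValueError, UndefinedStatisticError

__all__ = [
    "ConditionSamples",
    "AnovaResult",
    "PairwiseComparison",
    "ComparisonResult",
    "one_way_anova",
    "tukey_hsd",
    "compare_conditions",
]


@dataclass
class ConditionSamples:
    """Per-condition samples of one variable (condition label -> values)."""

    variable_name: str
    groups: dict[str, np.ndarray]

    def __post_init__(self):
        self.groups = {
            k: np.asarray(v, dtype=float).ravel() for k, v in self.groups.items()
        }
        if len(self.groups) < 2:
            raise InvalidValueError("need at least 2 groups")
        for k, v in self.groups.items():
            if v.size < 2:
                raise InvalidValueError(f"group {k!r} needs at least 2 values")
            if not np.all(np.isfinite(v)):
                raise InvalidValueError(f"group {k!r} contains non-finite values")


@dataclass(frozen=True)
class AnovaResult:
    F_stat: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q_stat: float
    p_adj: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "mean_diff": self.mean_diff,
            "q_stat": self.q_stat,
            "p_adj": self.p_adj,
            "significant": self.significant,
        }


@dataclass
class ComparisonResult:
    variable_name: str
    anova: AnovaResult
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "variable": self.variable_name,
            "anova": {
                "F": self.anova.F_stat,
                "p": self.anova.p_value,
                "df_between": self.anova.df_between,
                "df_within": self.anova.df_within,
            },
            "alpha": self.alpha,
            "pairwise": [p.to_dict() for p in self.pairwise],
        }


def _decompose(samples: ConditionSamples):
    groups = list(samples.groups.values())
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(groups)
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return ss_between, ss_within, k - 1, n_total - k


def one_way_anova(samples: ConditionSamples) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within with
    (k-1, N-k) degrees of freedom."""
    ss_b, ss_w, df_b, df_w = _decompose(samples)
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        if ss_b == 0.0:
            raise UndefinedStatisticError(
                "F undefined: zero within-group variance with equal means"
            )
        return AnovaResult(np.inf, 0.0, df_b, df_w, 0.0)
    F = (ss_b / df_b) / ms_w
    p = float(f_dist.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, float(ms_w))


def tukey_hsd(
    samples: ConditionSamples, alpha: float = 0.05
) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD using the studentized range on MS_within.

    For unequal group sizes the standard error uses the Tukey-Kramer form
    ``sqrt(MS_w / 2 * (1/n_a + 1/n_b))``.
    """
    anova = one_way_anova(samples)
    if anova.ms_within == 0.0:
        raise UndefinedStatisticError("Tukey HSD undefined: zero within-group variance")
    k = len(samples.groups)
    out = []
    for a, b in combinations(samples.groups, 2):
        ga, gb = samples.groups[a], samples.groups[b]
        diff = float(ga.mean() - gb.mean())
        se = np.sqrt(anova.ms_within / 2.0 * (1.0 / ga.size + 1.0 / gb.size))
        q = abs(diff) / se
        p = float(studentized_range.sf(q, k, anova.df_within))
        p = float(np.clip(p, 0.0, 1.0))
        out.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                mean_diff=diff,
                q_stat=float(q),
                p_adj=p,
                significant=bool(p < alpha),
            )
        )
    return out


def compare_conditions(
    samples: ConditionSamples, alpha: float = 0.05
) -> ComparisonResult:
    """ANOVA plus Tukey post-hoc for one variable across conditions."""
    anova = one_way_anova(samples)
    if anova.ms_within == 0.0:
        pairwise = []
    else:
        pairwise = tukey_hsd(samples, alpha)
    return ComparisonResult(
        variable_name=samples.variable_name,
        anova=anova,
        pairwise=pairwise,
        alpha=alpha,
    )
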