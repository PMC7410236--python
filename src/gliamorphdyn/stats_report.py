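"""Statistical layer: normality screening, paired in vivo comparisons,
multi-group ex vivo comparisons with Sidak multiplicity control, and
tabular mean +/- SD summaries.

The in vivo metrics (per-cell complexity and motility, pre vs during
anesthesia) are compared with a two-tailed paired t-test after a
d'Agostino-Pearson normality screen on the paired differences; the screen
is recorded and flagged but never gates the test. The ex vivo metrics are
compared across treatment groups with the Kruskal-Wallis test (Shapiro-Wilk
screened per group) followed by pairwise post-hoc comparisons with Sidak
adjustment p_adj = 1 - (1 - p)^m; the family-wise alpha adjusted for m
comparisons is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateInputError

ALPHA = 0.05

__all__ = [
    "PairedSample",
    "GroupSample",
    "TestResult",
    "PosthocComparison",
    "sidak_adjust",
    "sidak_alpha",
    "paired_comparison",
    "group_comparison",
    "summarize",
]


@dataclass
class PairedSample:
    """Matched per-cell metric values before and during anesthesia."""

    pre: np.ndarray
    post: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 1:
            raise DataError("pre and post must be matched 1D vectors")
        if self.pre.size < 3:
            raise DataError("need at least 3 pairs")

    @property
    def n(self) -> int:
        return int(self.pre.size)


@dataclass
class GroupSample:
    """Named treatment groups of per-cell metric values."""

    groups: dict
    metric: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise DataError("need at least 2 groups")
        for name, v in self.groups.items():
            if v.size < 3:
                raise DataError(f"group {name!r} needs at least 3 values")


@dataclass
class PosthocComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adj: float


@dataclass
class TestResult:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    alpha: float = ALPHA
    normality: dict = field(default_factory=dict)
    posthoc: list = field(default_factory=list)
    alpha_adjusted: float | None = None

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak-adjusted p-value for m comparisons: 1 - (1 - p)^m."""
    if not 0.0 <= p <= 1.0:
        raise DataError("p must be in [0, 1]")
    if m < 1:
        raise DataError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def sidak_alpha(alpha: float, m: int) -> float:
    """Per-comparison alpha keeping the family-wise level at ``alpha``."""
    return float(1.0 - (1.0 - alpha) ** (1.0 / m))


def paired_comparison(sample: PairedSample) -> TestResult:
    """Two-tailed paired t-test with a d'Agostino-Pearson screen on the
    paired differences.

    The screen outcome is recorded (it needs n >= 8; smaller samples record
    a note) and the t-test proceeds regardless. Zero-variance differences
    are degenerate.
    """
    diff = sample.post - sample.pre
    if np.var(diff, ddof=1) == 0:
        raise DegenerateInputError("zero-variance paired differences")
    normality: dict = {"test": "dagostino-pearson"}
    if sample.n >= 8:
        k2, p_norm = stats.normaltest(diff)
        normality.update(statistic=float(k2), p=float(p_norm), normal=bool(p_norm >= ALPHA))
    else:
        normality.update(note="n < 8: normality screen not applicable")
    t, p = stats.ttest_rel(sample.post, sample.pre)
    return TestResult(
        test_name="paired t-test (two-tailed)",
        statistic=float(t),
        p_value=float(p),
        n=sample.n,
        normality=normality,
    )


def group_comparison(sample: GroupSample, posthoc: bool = True) -> TestResult:
    """Kruskal-Wallis across groups with Shapiro-Wilk screening per group
    and Sidak-adjusted pairwise Mann-Whitney post-hoc comparisons.

    Ties are handled by the tie-corrected H statistic. All-tied data across
    every group is degenerate for the screen but still yields H = 0, p = 1.
    """
    names = list(sample.groups)
    values = [sample.groups[k] for k in names]
    normality: dict = {"test": "shapiro-wilk", "groups": {}}
    for name, v in zip(names, values):
        if np.ptp(v) == 0:
            normality["groups"][name] = {"note": "constant group"}
        else:
            w, p_sw = stats.shapiro(v)
            normality["groups"][name] = {
                "statistic": float(w),
                "p": float(p_sw),
                "normal": bool(p_sw >= ALPHA),
            }
    if np.ptp(np.concatenate(values)) == 0:
        h, p = 0.0, 1.0  # every observation tied: no group effect by construction
    else:
        h, p = stats.kruskal(*values)
    n_total = int(sum(v.size for v in values))
    result = TestResult(
        test_name="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        n=n_total,
        normality=normality,
    )
    if posthoc and len(names) > 2:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        m = len(pairs)
        result.alpha_adjusted = sidak_alpha(ALPHA, m)
        for a, b in pairs:
            if np.ptp(np.concatenate([sample.groups[a], sample.groups[b]])) == 0:
                u, p_raw = 0.0, 1.0
            else:
                u, p_raw = stats.mannwhitneyu(
                    sample.groups[a], sample.groups[b], alternative="two-sided"
                )
            result.posthoc.append(
                PosthocComparison(a, b, float(u), float(p_raw), sidak_adjust(float(p_raw), m))
            )
    return result


def summarize(
    records: pd.DataFrame,
    metrics: list[str] | None = None,
    group_by: list[str] = ("region", "condition"),
) -> pd.DataFrame:
    """Per-group n, mean, sample SD (divisor n-1), SEM and a display string
    per metric, one row per (group, metric)."""
    if records.empty:
        raise DataError("empty record collection")
    group_by = [g for g in group_by if g in records.columns]
    if not group_by:
        raise DataError("no grouping columns present")
    if metrics is None:
        metrics = [
            c
            for c in records.columns
            if c not in group_by and pd.api.types.is_numeric_dtype(records[c])
        ]
    rows = []
    for keys, sub in records.groupby(group_by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for metric in metrics:
            v = sub[metric].to_numpy(dtype=float)
            n = v.size
            mean = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
            sem = sd / np.sqrt(n) if n > 1 else float("nan")
            rows.append(
                {
                    **dict(zip(group_by, keys)),
                    "metric": metric,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "sem": sem,
                    "mean_sd": f"{mean:.3g}±{sd:.3g}",
                    "mean_sem": f"{mean:.3g}±{sem:.3g}",
                }
            )
    return pd.DataFrame(rows)
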