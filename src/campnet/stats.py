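"""Group summaries and one-tailed t-test comparisons of pooled metrics.

Pooled groups concatenate per-cell-per-pulse metric records (both stimulus
pulses of every cell contribute one measurement each).  Comparisons use the
paired one-tailed Student t-test when a pairing is defined (equal sample
sizes, records matched by position); with unequal sizes the comparison
falls back to the one-tailed Welch two-sample test and says so.

Two 95-percent confidence-interval conventions are reported side by side:
the standard one based on the standard error sd/sqrt(n), and an sd/n
convention (flagged ``ci95_sd_over_n``) for compatibility with analyses
that quote error bars in the mean as standard deviation divided by N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["MetricSample", "GroupSummary", "ComparisonResult",
           "group_summary", "compare_groups"]


@dataclass
class MetricSample:
    """Pooled metric records for one experimental group."""

    label: str
    values: np.ndarray
    cell_ids: np.ndarray | None = None
    pulse_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.pulse_indices is not None:
            self.pulse_indices = np.asarray(self.pulse_indices, dtype=int)
        if self.cell_ids is not None and self.pulse_indices is not None:
            pairs = list(zip(self.cell_ids, self.pulse_indices))
            if len(pairs) != len(set(pairs)):
                raise ValueError("one record per cell per pulse")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    sem: float
    median: float
    ci95_sem: tuple[float, float]
    ci95_sd_over_n: tuple[float, float]  # non-standard convention, flagged


def group_summary(sample: MetricSample) -> GroupSummary:
    """Mean, sample sd, sem, median and both CI conventions."""
    v = sample.values
    if v.size < 2:
        raise ValueError("group summary needs n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    sem = sd / np.sqrt(v.size)
    tcrit = float(sps.t.ppf(0.975, v.size - 1))
    return GroupSummary(
        label=sample.label,
        n=v.size,
        mean=mean,
        sd=sd,
        sem=float(sem),
        median=float(np.median(v)),
        ci95_sem=(mean - tcrit * sem, mean + tcrit * sem),
        ci95_sd_over_n=(mean - sd / v.size, mean + sd / v.size),
    )


@dataclass
class ComparisonResult:
    t: float
    p: float
    alternative: str
    paired: bool
    effect_size: float  # Cohen's d (of differences when paired)
    n_a: int
    n_b: int
    flags: list[str] = field(default_factory=list)

    def log_line(self, a: MetricSample, b: MetricSample) -> str:
        kind = "paired" if self.paired else "welch"
        return (
            f"{a.label} (n={self.n_a}, mean={a.values.mean():.4g}) vs "
            f"{b.label} (n={self.n_b}, mean={b.values.mean():.4g}): "
            f"{kind} one-tailed t={self.t:.4g}, p={self.p:.4g} "
            f"(alternative: a {self.alternative} b)"
        )


def compare_groups(
    a: MetricSample, b: MetricSample, alternative: str = "greater"
) -> ComparisonResult:
    """One-tailed comparison of two pooled metric groups.

    ``alternative="greater"`` tests whether group a's mean exceeds group
    b's.  Paired (per-record) testing when sizes match; Welch otherwise
    (flagged).  Identical paired samples with zero variance return the
    p = 0.5, t = 0 convention, flagged.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    flags: list[str] = []
    paired = a.n == b.n
    if paired:
        diff = a.values - b.values
        if np.allclose(diff.std(ddof=0), 0.0):
            if np.allclose(diff, 0.0):
                flags.append("zero-variance identical samples; p=0.5 by convention")
                return ComparisonResult(
                    0.0, 0.5, alternative, True, 0.0, a.n, b.n, flags
                )
            # perfectly separated constant shift
            t = np.inf if diff.mean() > 0 else -np.inf
            want_pos = alternative == "greater"
            p = 0.0 if (diff.mean() > 0) == want_pos else 1.0
            flags.append("zero within-pair variance; degenerate t")
            d = np.inf if diff.mean() > 0 else -np.inf
            return ComparisonResult(t, p, alternative, True, d, a.n, b.n, flags)
        res = sps.ttest_rel(a.values, b.values, alternative=alternative)
        d = float(diff.mean() / diff.std(ddof=1))
    else:
        flags.append("unequal group sizes; Welch two-sample fallback")
        res = sps.ttest_ind(
            a.values, b.values, equal_var=False, alternative=alternative
        )
        pooled = np.sqrt(
            (a.values.var(ddof=1) + b.values.var(ddof=1)) / 2.0
        )
        d = float((a.values.mean() - b.values.mean()) / pooled) if pooled else 0.0
    return ComparisonResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        alternative=alternative,
        paired=paired,
        effect_size=d,
        n_a=a.n,
        n_b=b.n,
        flags=flags,
    )
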