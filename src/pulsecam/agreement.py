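"""Method-comparison statistics for paired heart-rate monitors.

Device validation here follows the standard exercise-science recipe:
pooled Pearson correlation and the standard error of estimate (SEE) of an
ordinary-least-squares fit of the comparison device on the criterion
device, with the conventional validity rule r >= .90 and SEE <= 5 bpm;
plus Bland-Altman 95% limits of agreement.  Because each subject
contributes several paired minutes, the limits use the repeated-measures
variant: the variance of the differences is decomposed by a one-way ANOVA
of the differences grouped by subject into within-subject and
between-subject components, and the limits are

    mean_diff +/- 1.96 * sqrt(sigma2_between + sigma2_within)

with sigma2_within = MSW and sigma2_between = max(0, (MSB - MSW) / m0),
where m0 = (N - sum(m_i^2)/N) / (S - 1) for S subjects with m_i replicates
each.  Treating the 5 minutes per subject as independent would understate
the limits whenever subjects differ systematically.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, IncompleteStudyError, InsufficientSignalError

__all__ = [
    "AgreementReport",
    "pearson_r",
    "see",
    "validity_check",
    "bland_altman_rm",
    "condition_summary",
    "bland_altman_plot",
]

VALIDITY_R_MIN = 0.90
VALIDITY_SEE_MAX = 5.0  # bpm


@dataclass(frozen=True)
class AgreementReport:
    """Pooled agreement statistics for one device pair (one condition)."""

    r: float
    see: float
    mean_diff: float
    loa_lo: float
    loa_hi: float
    loa_width: float
    pct_within: float
    n_pairs: int

    @property
    def valid(self) -> bool:
        return validity_check(self.r, self.see)

    def to_dict(self) -> dict:
        return asdict(self)


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on fewer than 3 pairs or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise DegenerateInputError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def see(criterion, comparison) -> float:
    """Standard error of estimate of OLS comparison ~ criterion.

    SEE = sqrt( sum(residual^2) / (n - 2) ), the residual standard
    deviation about the regression line, in bpm here.
    """
    x = np.asarray(criterion, dtype=float)
    y = np.asarray(comparison, dtype=float)
    if len(x) != len(y):
        raise ValueError("criterion and comparison must have equal length")
    n = len(x)
    if n < 3:
        raise DegenerateInputError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("SEE undefined for zero-variance criterion")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return float(np.sqrt(np.sum(resid**2) / (n - 2)))


def validity_check(r: float, see_bpm: float) -> bool:
    """Conventional HR-monitor validity rule: r >= .90 and SEE <= 5 bpm."""
    return r >= VALIDITY_R_MIN and see_bpm <= VALIDITY_SEE_MAX


def _variance_components(d: np.ndarray, subject: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA variance components of differences grouped by subject."""
    groups = pd.Series(d).groupby(pd.Series(subject), sort=False)
    m = groups.size().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    S = len(m)
    N = float(m.sum())
    if S < 2:
        raise DegenerateInputError(
            "repeated-measures limits need differences from at least 2 subjects"
        )
    if N - S < 1:
        raise DegenerateInputError(
            "need at least one subject with 2 or more replicates"
        )
    grand = float(d.mean())
    ssb = float(np.sum(m * (means - grand) ** 2))
    ssw = float(groups.apply(lambda g: ((g - g.mean()) ** 2).sum()).sum())
    msb = ssb / (S - 1)
    msw = ssw / (N - S)
    m0 = (N - float(np.sum(m**2)) / N) / (S - 1)
    sigma2_within = msw
    sigma2_between = max(0.0, (msb - msw) / m0)
    return sigma2_between, sigma2_within


def bland_altman_rm(paired: pd.DataFrame) -> AgreementReport:
    """Repeated-measures Bland-Altman agreement for one device pair.

    ``paired`` needs columns ``subject``, ``hr_a`` (criterion) and ``hr_b``
    (comparison); one row per subject-minute.  Differences are
    ``hr_a - hr_b`` (criterion minus comparison).  ``pct_within`` counts
    differences inside the limits with inclusive bounds, so identical
    devices report 100%, not an indeterminate value.
    """
    required = {"subject", "hr_a", "hr_b"}
    if not required.issubset(paired.columns):
        raise ValueError(f"paired table needs columns {sorted(required)}")
    a = paired["hr_a"].to_numpy(float)
    b = paired["hr_b"].to_numpy(float)
    d = a - b
    sigma2_b, sigma2_w = _variance_components(d, paired["subject"].to_numpy())
    mean_diff = float(d.mean())
    half = 1.96 * float(np.sqrt(sigma2_b + sigma2_w))
    lo, hi = mean_diff - half, mean_diff + half
    pct = 100.0 * float(np.mean((d >= lo) & (d <= hi)))
    r = pearson_r(a, b)
    s = see(a, b)
    return AgreementReport(
        r=r,
        see=s,
        mean_diff=mean_diff,
        loa_lo=lo,
        loa_hi=hi,
        loa_width=hi - lo,
        pct_within=pct,
        n_pairs=len(d),
    )


def condition_summary(
    per_minute: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study-level summary tables.

    ``per_minute`` is the long table with columns ``subject``,
    ``condition``, ``minute``, ``device``, ``hr_bpm`` (quality-true rows
    only).  Returns:

    * ``hr_table`` — per condition and device, mean and SD of the
      per-minute HRs, plus a pooled all-conditions row;
    * ``agreement_table`` — per condition and ordered device pair
      (criterion first), pooled Pearson r, SEE and the repeated-measures
      Bland-Altman fields, plus a pooled all-conditions row.
    """
    required = {"subject", "condition", "minute", "device", "hr_bpm"}
    if not required.issubset(per_minute.columns):
        raise ValueError(f"per-minute table needs columns {sorted(required)}")
    devices = sorted(per_minute["device"].unique())
    conditions = list(pd.unique(per_minute["condition"]))
    if len(devices) < 2:
        raise DegenerateInputError("need at least 2 devices to compare")
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(devices) for b in devices[i + 1 :]
        ]
    for dev in devices:
        missing = set(conditions) - set(
            per_minute.loc[per_minute["device"] == dev, "condition"]
        )
        if missing:
            raise IncompleteStudyError(
                f"device {dev!r} has no data for condition(s) {sorted(missing)}"
            )

    rows = []
    for cond in conditions + ["all"]:
        sub = per_minute if cond == "all" else per_minute[per_minute["condition"] == cond]
        for dev in devices:
            hrs = sub.loc[sub["device"] == dev, "hr_bpm"]
            rows.append(
                {
                    "condition": cond,
                    "device": dev,
                    "mean_hr": hrs.mean(),
                    "sd_hr": hrs.std(ddof=1),
                    "n": len(hrs),
                }
            )
    hr_table = pd.DataFrame(rows)

    wide = per_minute.pivot_table(
        index=["subject", "condition", "minute"],
        columns="device",
        values="hr_bpm",
    ).reset_index()
    agree_rows = []
    for cond in conditions + ["all"]:
        sub = wide if cond == "all" else wide[wide["condition"] == cond]
        for a, b in pairs:
            paired = sub[["subject", a, b]].dropna()
            paired = paired.rename(columns={a: "hr_a", b: "hr_b"})
            if len(paired) < 3:
                raise InsufficientSignalError(
                    f"fewer than 3 complete pairs for {a} vs {b} in {cond}"
                )
            rep = bland_altman_rm(paired)
            agree_rows.append(
                {"condition": cond, "device_a": a, "device_b": b, **rep.to_dict(),
                 "valid": rep.valid}
            )
    return hr_table, pd.DataFrame(agree_rows)


def bland_altman_plot(paired: pd.DataFrame, report: AgreementReport, ax=None, title=""):
    """Mean-vs-difference scatter with mean and 95% limit lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    a = paired["hr_a"].to_numpy(float)
    b = paired["hr_b"].to_numpy(float)
    ax.scatter((a + b) / 2.0, a - b, s=12, alpha=0.7)
    ax.axhline(report.mean_diff, color="k", lw=1)
    for y in (report.loa_lo, report.loa_hi):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of devices (bpm)")
    ax.set_ylabel("difference (bpm)")
    if title:
        ax.set_title(title)
    return ax
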