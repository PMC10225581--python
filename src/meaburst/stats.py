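"""Group-comparison statistics: ROUT outlier removal, one-way ANOVA with
mean +/- SEM reporting, and qPCR relative quantification (2^-ddCt).

ROUT here is the one-sample reduction of the robust-regression-plus-FDR
outlier procedure of Motulsky & Brown (2006): with only a location
parameter the robust fit collapses to the median, the robust scale
(RSDR) is the 68.27th percentile of the absolute residuals with a
degrees-of-freedom correction, and outliers are flagged by a
Benjamini-Hochberg step-up test on two-sided t p-values at a maximum
desired false-discovery rate Q (10% by default, matching common
practice for grouped endpoint data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sst

__all__ = [
    "AnovaResult",
    "QpcrMeasurement",
    "DegenerateDataError",
    "rout_outliers",
    "one_way_anova",
    "delta_delta_ct",
    "compare_groups",
]


class DegenerateDataError(ValueError):
    """Data admit no meaningful test (e.g. zero within-group variance)."""


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus one-way ANOVA with per-group descriptive statistics."""

    f: float
    df_between: int
    df_within: int
    p: float
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    group_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class QpcrMeasurement:
    """Technical-triplicate Ct values for a target and the reference gene."""

    sample_id: str
    condition: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, cts in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            arr = np.asarray(cts, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name}: at least one Ct replicate required")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name}: Ct values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        """Mean target Ct minus mean reference Ct (averaged on the Ct scale)."""
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def rout_outliers(values: Sequence[float], q: float = 0.10) -> np.ndarray:
    """Flag outliers in one sample; returns a boolean *retain* mask.

    Residuals are taken from the median; the robust scale is
    ``RSDR = P68.27(|residual|) * n / (n - 1)``; each point gets a
    two-sided p-value from the t distribution on n-1 df, and the
    Benjamini-Hochberg step-up rule at rate ``q`` decides which extreme
    points are outliers. With zero robust scatter, any point off the
    median is flagged; identical values are never flagged.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("ROUT needs at least 3 values")
    if not 0 < q < 1:
        raise ValueError("Q must lie in (0, 1)")
    resid = x - np.median(x)
    absr = np.abs(resid)
    rsdr = float(np.percentile(absr, 68.27)) * n / (n - 1)
    if rsdr == 0:
        return resid == 0
    pvals = 2.0 * sst.t.sf(absr / rsdr, df=n - 1)
    order = np.argsort(pvals)  # most extreme first
    thresholds = q * np.arange(1, n + 1) / n
    passed = np.flatnonzero(pvals[order] <= thresholds)
    retain = np.ones(n, dtype=bool)
    if passed.size:
        retain[order[: passed[-1] + 1]] = False
    return retain


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> AnovaResult:
    """Omnibus F test of equal group means, with per-group mean and SEM.

    Standard between/within sum-of-squares decomposition:
    ``F = (SSB / (k-1)) / (SSW / (N-k))`` with the p-value from the
    F(k-1, N-k) distribution. Zero within-group variance is degenerate
    and signalled rather than reported as an infinite F.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 retained values")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    sizes = np.array([a.size for a in arrays])
    n_total = int(sizes.sum())
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if ssw == 0:
        raise DegenerateDataError("zero within-group variance: F undefined")
    f = (ssb / df_between) / (ssw / df_within)
    p = float(sst.f.sf(f, df_between, df_within))
    sems = tuple(float(a.std(ddof=1) / np.sqrt(a.size)) for a in arrays)
    return AnovaResult(
        f=float(f),
        df_between=df_between,
        df_within=df_within,
        p=p,
        group_means=tuple(float(m) for m in means),
        group_sems=sems,
        group_labels=tuple(labels),
    )


def delta_delta_ct(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression of treated vs control: ``2 ** -(dCt_t - dCt_c)``.

    Technical replicates are averaged on the Ct (cycle) scale before the
    differences are taken; the reference gene normalizes loading in both
    conditions.
    """
    ddct = treated.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    q: float = 0.10,
    rout: bool = True,
) -> dict:
    """ROUT-then-ANOVA comparison of one metric across condition groups.

    Groups with fewer than 3 values skip outlier screening; the ANOVA
    runs on the retained values of every group that keeps >= 2. Returns a
    dict with the retained values, number removed per group, and either
    the :class:`AnovaResult` or the reason no test was possible.
    """
    retained: dict[str, np.ndarray] = {}
    removed: dict[str, int] = {}
    for label, values in groups.items():
        x = np.asarray(values, dtype=float).ravel()
        if rout and x.size >= 3:
            mask = rout_outliers(x, q=q)
        else:
            mask = np.ones(x.size, dtype=bool)
        retained[label] = x[mask]
        removed[label] = int((~mask).sum())
    testable = {k: v for k, v in retained.items() if v.size >= 2}
    result: AnovaResult | None = None
    reason: str | None = None
    if len(testable) < 2:
        reason = "fewer than 2 groups with >= 2 retained values"
    else:
        try:
            result = one_way_anova(list(testable.values()), labels=list(testable))
        except DegenerateDataError as exc:
            reason = str(exc)
    return {
        "retained": {k: v.tolist() for k, v in retained.items()},
        "n_removed": removed,
        "anova": result,
        "skipped_reason": reason,
    }
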