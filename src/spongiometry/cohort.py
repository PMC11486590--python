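"""Paired ischemic-vs-control statistics over per-femoral-head measurements.

For each contrast and metric: two-sided paired t-test (df = n - 1), 95% CI
of the mean paired difference, Cohen's d for paired data
(|mean difference| / SD of differences) and per-subject percent change
aggregated as mean and SD across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import METRICS, MorphometryResult

__all__ = [
    "PairedCohort",
    "PairedStats",
    "DegenerateVarianceError",
    "paired_stats_from_arrays",
    "paired_analysis",
    "summarize_cohort",
    "format_summary",
]

THICKNESS_METRICS = ("ps_thickness", "ss_thickness", "total_thickness")

SIGNIFICANCE_LEVEL = 0.05


class DegenerateVarianceError(ValueError):
    """Paired differences have zero variance; the t-test is undefined."""


@dataclass(frozen=True)
class PairedStats:
    metric: str
    n: int
    mean_control: float
    mean_ischemic: float
    mean_diff: float
    sd_diff: float
    ci95_low: float
    ci95_high: float
    t_stat: float
    p_value: float
    cohens_d: float
    pct_change_mean: float
    pct_change_sd: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


@dataclass(frozen=True)
class PairedCohort:
    """Per-subject (control, ischemic) measurement pairs for one contrast."""

    subjects: tuple[tuple[str, MorphometryResult, MorphometryResult], ...]

    def __post_init__(self) -> None:
        subjects = tuple(self.subjects)
        if len(subjects) < 2:
            raise ValueError("a paired cohort needs at least 2 subjects")
        ids = [s[0] for s in subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        labels = {s[1].contrast_label for s in subjects} | {s[2].contrast_label for s in subjects}
        if len(labels) != 1:
            raise ValueError(f"cohort mixes contrast labels: {sorted(labels)}")
        object.__setattr__(self, "subjects", subjects)

    @property
    def contrast_label(self) -> str:
        return self.subjects[0][1].contrast_label

    @property
    def n(self) -> int:
        return len(self.subjects)

    def metric_arrays(self, metric: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        ids = [s[0] for s in self.subjects]
        control = np.array([getattr(s[1], metric) for s in self.subjects], dtype=float)
        ischemic = np.array([getattr(s[2], metric) for s in self.subjects], dtype=float)
        return control, ischemic, ids


def paired_stats_from_arrays(
    control: np.ndarray,
    ischemic: np.ndarray,
    metric: str = "",
    subject_ids: list[str] | None = None,
) -> PairedStats:
    """Paired statistics from matched control/ischemic value arrays."""
    control = np.asarray(control, dtype=float)
    ischemic = np.asarray(ischemic, dtype=float)
    if control.shape != ischemic.shape or control.ndim != 1:
        raise ValueError("control and ischemic must be 1D arrays of equal length")
    n = control.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    bad = ~(np.isfinite(control) & np.isfinite(ischemic))
    if bad.any():
        ids = subject_ids or [str(i) for i in range(n)]
        offenders = [ids[i] for i in np.where(bad)[0]]
        raise ValueError(f"non-finite values for metric {metric!r} in subjects: {offenders}")

    diff = ischemic - control
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0:
        raise DegenerateVarianceError(
            f"paired differences for metric {metric!r} have zero variance"
        )
    se = sd_diff / np.sqrt(n)
    t_stat = mean_diff / se
    df = n - 1
    p_value = float(2 * sps.t.sf(abs(t_stat), df))
    tcrit = float(sps.t.ppf(0.975, df))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(control != 0, 100.0 * diff / np.where(control != 0, control, 1.0), np.nan)
    return PairedStats(
        metric=metric,
        n=n,
        mean_control=float(control.mean()),
        mean_ischemic=float(ischemic.mean()),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        ci95_low=mean_diff - tcrit * se,
        ci95_high=mean_diff + tcrit * se,
        t_stat=float(t_stat),
        p_value=p_value,
        cohens_d=abs(mean_diff) / sd_diff,
        pct_change_mean=float(pct.mean()),
        pct_change_sd=float(pct.std(ddof=1)),
    )


def paired_analysis(cohort: PairedCohort, metric: str) -> PairedStats:
    """Paired statistics for one metric of a cohort."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    control, ischemic, ids = cohort.metric_arrays(metric)
    return paired_stats_from_arrays(control, ischemic, metric=metric, subject_ids=ids)


def summarize_cohort(
    cohorts: list[PairedCohort],
    contrasts: tuple[str, ...] | None = None,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Long-format results table, one row per contrast x metric.

    Missing cells (no cohort for a requested contrast, or a failing
    metric) are reported as rows with an ``error`` note, never silently
    dropped.
    """
    by_label = {c.contrast_label: c for c in cohorts}
    if contrasts is None:
        contrasts = tuple(by_label)
    rows = []
    for contrast in contrasts:
        cohort = by_label.get(contrast)
        for metric in metrics:
            base = {"contrast": contrast, "metric": metric}
            if cohort is None:
                rows.append({**base, "error": "no cohort for contrast"})
                continue
            try:
                st = paired_analysis(cohort, metric)
            except (ValueError, DegenerateVarianceError) as exc:
                rows.append({**base, "error": str(exc)})
                continue
            rows.append(
                {
                    **base,
                    "n": st.n,
                    "mean_control": st.mean_control,
                    "mean_ischemic": st.mean_ischemic,
                    "mean_diff": st.mean_diff,
                    "sd_diff": st.sd_diff,
                    "ci95_low": st.ci95_low,
                    "ci95_high": st.ci95_high,
                    "t_stat": st.t_stat,
                    "p_value": st.p_value,
                    "cohens_d": st.cohens_d,
                    "pct_change_mean": st.pct_change_mean,
                    "pct_change_sd": st.pct_change_sd,
                    "significant": st.significant,
                    "error": "",
                }
            )
    df = pd.DataFrame(rows)
    if "error" in df.columns:
        missing = df[df["error"].astype(str).str.len() > 0]
        if len(missing):
            warnings.warn(f"{len(missing)} contrast/metric cells missing or failed", stacklevel=2)
    # no multiple-testing correction applied; record the test count
    df.attrs["n_tests"] = int(len(df))
    df.attrs["alpha"] = SIGNIFICANCE_LEVEL
    return df


def format_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Apply table rounding: ms values and d to 1 decimal, mm to 2 decimals."""
    out = df.copy()
    is_thickness = out["metric"].isin(THICKNESS_METRICS)
    for col in ("mean_control", "mean_ischemic", "mean_diff", "sd_diff", "ci95_low", "ci95_high"):
        if col in out:
            out[col] = np.where(is_thickness, out[col].round(2), out[col].round(1))
    for col in ("cohens_d", "t_stat", "pct_change_mean", "pct_change_sd"):
        if col in out:
            out[col] = out[col].round(1)
    if "p_value" in out:
        out["p_value"] = out["p_value"].round(3)
    return out
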