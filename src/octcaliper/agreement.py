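"""Agreement statistics: Bland-Altman and absolute-agreement ICC.

Both statistics are computed from first principles — the ICC directly from
the two-way ANOVA mean squares rather than through a model-fitting package —
because the exact computing form is the point:

* **Bland-Altman**: bias = mean(a - b), limits of agreement
  bias ± 1.96 * SD(a - b) with the sample (n-1) SD.
* **ICC(A,1)**: single-measurement, two-way, absolute-agreement intraclass
  correlation.  With n subjects, k raters and mean squares MS_R (subjects),
  MS_C (raters), MS_E (residual):

      ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

  The 95% CI and the p-value for ICC = 0 follow McGraw & Wong's (1996)
  F-distribution procedure for this form.  Absolute agreement penalises a
  systematic offset between raters, unlike consistency-type ICCs.

:func:`stratified_report` applies both to a measurement table the way the
emulated study does: observer pairs per (eye, machine, parameter), or
machine pairs after averaging the two observers per (eye, machine,
parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import MeasurementRecord, records_to_frame

__all__ = [
    "InsufficientDataError",
    "PairedSample",
    "BlandAltmanResult",
    "ICCResult",
    "AgreementReport",
    "bland_altman",
    "icc_absolute",
    "stratified_report",
]

#: Standard-normal 97.5% quantile used for the limits of agreement (no
#: small-sample t correction: plain Bland-Altman).
LOA_MULTIPLIER = 1.96


class InsufficientDataError(ValueError):
    """Fewer complete pairs than the statistic requires."""


@dataclass(frozen=True)
class PairedSample:
    """Two paired measurement series over the same units, µm."""

    labels: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if not (len(self.labels) == a.size == b.size):
            raise ValueError("labels, a and b must have equal lengths")
        if a.size < 2:
            raise InsufficientDataError("need at least 2 pairs")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("missing/non-finite values must be removed upstream")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    #: per-pair plotting coordinates: mean of the pair vs difference a - b
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    n_raters: int
    ms_subjects: float
    ms_raters: float
    ms_error: float
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman bias/limits and ICC for one stratum of paired readings."""

    label: str
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    p_value: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "icc": self.icc,
            "icc_ci_low": self.icc_ci_low,
            "icc_ci_high": self.icc_ci_high,
            "p_value": self.p_value,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "degenerate": self.degenerate,
            "excluded": list(self.excluded),
        }
        return d


def bland_altman(s: PairedSample) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for a paired sample."""
    d = s.a - s.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=d.size,
        means=(s.a + s.b) / 2.0,
        diffs=d,
    )


def icc_absolute(matrix: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measurement absolute-agreement ICC of a subjects x raters matrix.

    A constant matrix has no subject variance to apportion; the ICC is then
    undefined and a flagged degenerate result (NaN estimate) is returned
    rather than raising.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InsufficientDataError("need a 2-D matrix with >= 2 subjects and >= 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("matrix must be complete (no missing values)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    scale = max(ss_total, 1.0)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if ss_total <= 1e-12 * n * k or abs(denom) <= 1e-15 * scale:
        return ICCResult(
            icc=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            n_subjects=n,
            n_raters=k,
            ms_subjects=msr,
            ms_raters=msc,
            ms_error=mse,
            degenerate=True,
        )

    icc = (msr - mse) / denom

    # Test of ICC = 0: F = MS_R / MS_E on (n-1, (n-1)(k-1)) df.
    if mse > 0.0:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0 if msr > 0.0 else float("nan")

    # 95% CI (McGraw & Wong absolute-agreement form, Satterthwaite df).
    one_minus = n * (1.0 - icc)
    if abs(one_minus) <= 1e-12 * n:
        ci_low = ci_high = icc  # perfect agreement: interval collapses
    else:
        a = k * icc / one_minus
        b = 1.0 + k * icc * (n - 1) / one_minus
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0.0 else float((n - 1) * (k - 1))
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        ci_low = (n * (msr - f_l * mse)) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = (n * (f_u * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci_low = float(np.clip(ci_low, -1.0, icc))
        ci_high = float(np.clip(ci_high, icc, 1.0))
    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        n_subjects=n,
        n_raters=k,
        ms_subjects=msr,
        ms_raters=msc,
        ms_error=mse,
    )


def _report_from_pairs(label: str, pairs: pd.DataFrame, excluded: tuple[str, ...]) -> AgreementReport:
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"stratum {label!r}: {len(pairs)} complete pair(s), need >= 2"
        )
    sample = PairedSample(
        labels=tuple(str(i) for i in pairs.index),
        a=pairs.iloc[:, 0].to_numpy(),
        b=pairs.iloc[:, 1].to_numpy(),
    )
    ba = bland_altman(sample)
    icc = icc_absolute(pairs.to_numpy())
    return AgreementReport(
        label=label,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        icc=icc.icc,
        icc_ci_low=icc.ci_low,
        icc_ci_high=icc.ci_high,
        p_value=icc.p_value,
        n_subjects=icc.n_subjects,
        n_raters=icc.n_raters,
        degenerate=icc.degenerate,
        excluded=excluded,
    )


def _ordered_levels(series: pd.Series) -> list[str]:
    # Pairing order = order of first appearance in the record list, so the
    # sign of the bias follows the caller's protocol/observer ordering.
    return list(dict.fromkeys(series))


def stratified_report(
    records: Sequence[MeasurementRecord],
    stratify_by: str = "observer",
    group_by: str = "pooled",
    filters: dict[str, Sequence[str]] | None = None,
) -> list[AgreementReport]:
    """Agreement reports over a measurement table, the emulated study's way.

    Parameters
    ----------
    stratify_by : {"observer", "machine"}
        ``"observer"`` pairs the two observers per (eye, machine,
        parameter) unit.  ``"machine"`` first averages the two observers
        per (eye, machine, parameter) — the study's rule for comparing
        machines — then pairs the two machines per (eye, parameter).
    group_by : {"pooled", "parameter", "machine"}
        Emit one report per level of the grouping variable in addition to
        the overall pooled report (always last, labelled ``"pooled"``).
        ``"machine"`` grouping is only meaningful in observer mode.
    filters : dict, optional
        Column -> allowed values, applied before pairing
        (e.g. ``{"parameter": ["MLD"]}``).

    Units missing one side of the pair are dropped (listwise) and listed in
    each report's exclusion log.

    Raises
    ------
    InsufficientDataError
        If any requested stratum retains fewer than 2 complete pairs.
    """
    if stratify_by not in ("observer", "machine"):
        raise ValueError("stratify_by must be 'observer' or 'machine'")
    if group_by not in ("pooled", "parameter", "machine"):
        raise ValueError("group_by must be 'pooled', 'parameter' or 'machine'")
    if stratify_by == "machine" and group_by == "machine":
        raise ValueError("cannot group by machine when pairing machines")

    df = records_to_frame(list(records))
    if filters:
        for col, allowed in filters.items():
            if col not in df.columns:
                raise ValueError(f"unknown filter column {col!r}")
            df = df[df[col].isin(list(allowed))]
    if df.empty:
        raise InsufficientDataError("no records after filtering")

    rater_col = "observer" if stratify_by == "observer" else "machine"
    levels = _ordered_levels(df[rater_col])
    if len(levels) != 2:
        raise ValueError(
            f"{rater_col} pairing requires exactly 2 levels, found {levels}"
        )

    if stratify_by == "observer":
        unit_cols = ["eye_id", "machine", "parameter"]
        work = df
    else:
        # The study averages the two observers before comparing machines.
        work = (
            df.groupby(["eye_id", "machine", "parameter"], as_index=False)["value_um"]
            .mean()
        )
        unit_cols = ["eye_id", "parameter"]

    wide = work.pivot_table(
        index=unit_cols, columns=rater_col, values="value_um", aggfunc="mean"
    )[levels]
    complete = wide.dropna()
    excluded = tuple(
        "/".join(map(str, idx if isinstance(idx, tuple) else (idx,)))
        for idx in wide.index.difference(complete.index)
    )

    reports: list[AgreementReport] = []
    if group_by != "pooled":
        group_level = unit_cols.index(group_by)
        for value in _ordered_levels(work[group_by]):
            sub = complete[
                complete.index.get_level_values(group_level) == value
            ]
            reports.append(_report_from_pairs(str(value), sub, excluded))
    reports.append(_report_from_pairs("pooled", complete, excluded))
    return reports
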