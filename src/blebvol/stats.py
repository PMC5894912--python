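"""Reproducibility and agreement statistics.

The measurement method is validated by re-imaging the same object under
different instrument settings (scan length, scan angle, focal length) and by
independent graders, then asking whether the volumes agree:

* paired *t*-test and two-way random absolute-agreement single-measure
  intraclass correlation, ICC(A,1), for two-condition designs;
* Wilcoxon signed rank for intergrader differences (exact for small n);
* a multivariate test of the pairwise differences among three conditions
  simultaneously, reported as Wilks' Λ via the one-sample Hotelling T²
  reduction (two difference contrasts per subject);
* coefficient of variation and a signed accuracy summary for the delivery
  device;
* surgeon-estimated vs image-measured volume loss, combining the paired *t*
  and ICC.

Negative ICC estimates are truncated at 0 for reporting (the conventional
presentation); the raw estimate is kept in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .exceptions import (
    DegenerateDataError,
    DesignError,
    FormatError,
    InsufficientDataError,
    InvariantError,
)

__all__ = [
    "MeasurementSeries",
    "AgreementReport",
    "paired_t",
    "icc_absolute_agreement",
    "wilcoxon_signed_rank",
    "wilks_lambda_repeated",
    "coefficient_of_variation",
    "delivery_accuracy",
    "surgeon_vs_measured",
]

_DESIGNS = ("two_condition_paired", "three_condition_repeated", "two_rater")


@dataclass(frozen=True)
class MeasurementSeries:
    """Tidy repeated measurements: one row per (subject, condition).

    ``design`` declares the intended analysis; construction verifies each
    subject appears exactly once per condition and that at least two subjects
    are present.
    """

    records: pd.DataFrame          # columns: subject_id, condition, volume_ul
    design: str = "two_condition_paired"

    def __post_init__(self) -> None:
        df = self.records
        for col in ("subject_id", "condition", "volume_ul"):
            if col not in df.columns:
                raise FormatError(f"records missing column {col!r}")
        if self.design not in _DESIGNS:
            raise DesignError(f"unknown design {self.design!r}")
        counts = df.groupby(["subject_id", "condition"]).size()
        if (counts > 1).any():
            raise DesignError("a subject appears more than once in a condition")
        wide = df.pivot(index="subject_id", columns="condition", values="volume_ul")
        if wide.isna().any().any():
            missing = wide.index[wide.isna().any(axis=1)].tolist()
            raise DesignError(f"incomplete pairing for subjects {missing[:5]}")
        if len(wide) < 2:
            raise InsufficientDataError("need >= 2 subjects")
        n_cond = wide.shape[1]
        if self.design == "three_condition_repeated" and n_cond != 3:
            raise DesignError(f"design needs 3 conditions, got {n_cond}")
        if self.design in ("two_condition_paired", "two_rater") and n_cond != 2:
            raise DesignError(f"design needs 2 conditions, got {n_cond}")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path: str | Path, design: str) -> "MeasurementSeries":
        return cls(records=pd.read_csv(path), design=design)

    def wide(self) -> pd.DataFrame:
        return self.records.pivot(
            index="subject_id", columns="condition", values="volume_ul"
        ).sort_index()

    @property
    def n_subjects(self) -> int:
        return self.records["subject_id"].nunique()


@dataclass(frozen=True)
class AgreementReport:
    """Result of one agreement/reproducibility test."""

    test: str
    statistic: float
    p_value: float
    n: int
    icc: Optional[float] = None                  # truncated at 0 for reporting
    icc_ci: Optional[Tuple[float, float]] = None
    icc_raw: Optional[float] = None              # untruncated estimate

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvariantError("p_value must be in [0, 1]")
        if self.icc is not None and self.icc_ci is not None:
            lo, hi = self.icc_ci
            if not lo - 1e-9 <= self.icc <= hi + 1e-9:
                raise InvariantError("ICC must lie within its CI")

    def summary(self) -> str:
        lines = [f"{self.test}: statistic = {self.statistic:.4g}, "
                 f"P = {self.p_value:.3g} (n = {self.n})"]
        if self.icc is not None:
            ci = ""
            if self.icc_ci is not None:
                ci = f" (95% CI, {self.icc_ci[0]:.2f}-{self.icc_ci[1]:.2f})"
            lines.append(f"intraclass correlation = {self.icc:.2f}{ci}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "icc": self.icc,
            "icc_ci": list(self.icc_ci) if self.icc_ci is not None else None,
            "icc_raw": self.icc_raw,
        }


def _paired_diffs(series: MeasurementSeries) -> np.ndarray:
    wide = series.wide()
    if wide.shape[1] != 2:
        raise DesignError("paired tests need exactly two conditions")
    cols = sorted(wide.columns)
    return (wide[cols[0]] - wide[cols[1]]).to_numpy(dtype=float)


def paired_t(series: MeasurementSeries) -> AgreementReport:
    """Classical paired t-test between two conditions (two-sided).

    Identical conditions give t = 0, p = 1.  Differences with zero variance
    but nonzero mean have an undefined t and raise
    :class:`DegenerateDataError`.
    """
    d = _paired_diffs(series)
    n = d.size
    if n < 2:
        raise InsufficientDataError("need >= 2 pairs")
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return AgreementReport(test="paired_t", statistic=0.0, p_value=1.0, n=n)
        raise DegenerateDataError("constant nonzero differences: t undefined")
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * _sps.t.sf(abs(t), df=n - 1)
    return AgreementReport(test="paired_t", statistic=float(t), p_value=float(p), n=n)


def icc_absolute_agreement(series: MeasurementSeries) -> AgreementReport:
    """Two-way random, absolute-agreement, single-measure ICC(A,1) with 95% CI.

    Conditions (scan settings, graders) are treated as random raters and
    absolute agreement — not mere consistency — is assessed, since the
    question is whether different settings yield the *same* volume.  The
    F-based CI follows McGraw & Wong, as implemented in pingouin.
    """
    import pingouin as pg  # heavy import deferred

    wide = series.wide()
    if len(wide) < 2:
        raise InsufficientDataError("need >= 2 subjects for ICC")
    if wide.shape[1] < 2:
        raise DesignError("ICC needs >= 2 conditions")
    long = wide.reset_index().melt(
        id_vars="subject_id", var_name="condition", value_name="volume_ul"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(
            data=long, targets="subject_id", raters="condition", ratings="volume_ul"
        )
    row = res[res["Type"] == "ICC(A,1)"].iloc[0]
    raw = float(row["ICC"])
    lo, hi = (float(v) for v in row["CI95"])
    icc = max(raw, 0.0)
    # degenerate inputs (zero error variance) leave the F-based CI undefined
    lo = icc if not np.isfinite(lo) else max(lo, 0.0)
    hi = icc if not np.isfinite(hi) else max(hi, 0.0)
    hi = max(hi, icc)
    lo = min(lo, icc)
    p_val = float(row["pval"])
    if not np.isfinite(p_val):
        p_val = 0.0
    return AgreementReport(
        test="icc_absolute_agreement",
        statistic=float(row["F"]),
        p_value=min(max(p_val, 0.0), 1.0),
        n=len(wide),
        icc=icc,
        icc_ci=(lo, hi),
        icc_raw=raw,
    )


def wilcoxon_signed_rank(series: MeasurementSeries) -> AgreementReport:
    """Wilcoxon signed rank test on paired differences (two-sided).

    Uses the exact null distribution for n ≤ 25 (when no ties or zeros make
    it invalid), the normal approximation otherwise.  All-zero differences
    leave the statistic undefined.
    """
    d = _paired_diffs(series)
    n = d.size
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties and nz.size == n) else "approx"
    res = _sps.wilcoxon(d, alternative="two-sided", method=method)
    return AgreementReport(
        test="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=n,
    )


def wilks_lambda_repeated(series: MeasurementSeries) -> AgreementReport:
    """Multivariate test of pairwise differences among three conditions.

    Forms the two difference contrasts (c1 − c2, c2 − c3) per subject and
    tests whether their mean vector is zero with a one-sample Hotelling T²:
    T² = n·d̄ᵀS⁻¹d̄, F = T²·(n − p)/(p·(n − 1)) with p = 2 on (p, n − p)
    degrees of freedom.  Wilks' Λ = 1/(1 + T²/(n − 1)) is reported as the
    statistic.
    """
    wide = series.wide()
    if wide.shape[1] != 3:
        raise DesignError("this test needs exactly three conditions")
    n = len(wide)
    p = 2
    if n <= p:
        raise InsufficientDataError("need > 2 subjects (singular covariance)")
    cols = sorted(wide.columns)
    contrasts = np.column_stack(
        [
            wide[cols[0]].to_numpy() - wide[cols[1]].to_numpy(),
            wide[cols[1]].to_numpy() - wide[cols[2]].to_numpy(),
        ]
    )
    mean = contrasts.mean(axis=0)
    if np.allclose(contrasts, 0.0):
        return AgreementReport(test="wilks_lambda", statistic=1.0, p_value=1.0, n=n)
    cov = np.cov(contrasts, rowvar=False, ddof=1)
    try:
        sol = np.linalg.solve(cov, mean)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"singular contrast covariance: {exc}") from exc
    t2 = float(n * mean @ sol)
    lam = 1.0 / (1.0 + t2 / (n - 1))
    f_stat = t2 * (n - p) / (p * (n - 1))
    p_val = float(_sps.f.sf(f_stat, p, n - p))
    return AgreementReport(test="wilks_lambda", statistic=lam, p_value=p_val, n=n)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD / mean × 100 (%)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 values for a CV")
    mean = v.mean()
    if mean == 0:
        raise InvariantError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)


def delivery_accuracy(values: Sequence[float], intended_ul: float) -> dict:
    """Accuracy/precision summary for a delivery device.

    Signed percent error = (mean measured − intended)/intended × 100 — the
    device-accuracy convention, negative when the device under-delivers —
    alongside the coefficient of variation of the repeats.
    """
    if intended_ul <= 0:
        raise InvariantError("intended volume must be > 0")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 delivery repeats")
    mean = float(v.mean())
    return {
        "n": int(v.size),
        "mean_ul": mean,
        "sd_ul": float(v.std(ddof=1)),
        "percent_error": (mean - intended_ul) / intended_ul * 100.0,
        "cv_pct": coefficient_of_variation(v),
    }


def surgeon_vs_measured(
    losses: pd.DataFrame | Sequence[Tuple[float, float]],
) -> AgreementReport:
    """Compare surgeon-estimated vs image-measured volume-loss percentages.

    Accepts a DataFrame with columns ``surgeon_loss_pct, measured_loss_pct``
    (an optional ``bleb_id`` column labels subjects) or a sequence of
    (surgeon, measured) pairs.  Runs the paired t-test for a systematic
    difference and ICC(A,1) for agreement; the report carries the t statistic
    and p-value with the ICC fields alongside.
    """
    if isinstance(losses, pd.DataFrame):
        df = losses
        for col in ("surgeon_loss_pct", "measured_loss_pct"):
            if col not in df.columns:
                raise FormatError(f"losses missing column {col!r}")
        ids = df["bleb_id"] if "bleb_id" in df.columns else np.arange(len(df))
        surgeon = df["surgeon_loss_pct"].to_numpy(dtype=float)
        measured = df["measured_loss_pct"].to_numpy(dtype=float)
    else:
        pairs = list(losses)
        ids = np.arange(len(pairs))
        surgeon = np.array([p[0] for p in pairs], dtype=float)
        measured = np.array([p[1] for p in pairs], dtype=float)
    records = pd.DataFrame(
        {
            "subject_id": np.concatenate([np.asarray(ids), np.asarray(ids)]),
            "condition": ["surgeon"] * len(surgeon) + ["measured"] * len(measured),
            "volume_ul": np.concatenate([surgeon, measured]),
        }
    )
    series = MeasurementSeries(records=records, design="two_rater")
    t_rep = paired_t(series)
    icc_rep = icc_absolute_agreement(series)
    return AgreementReport(
        test="surgeon_vs_measured",
        statistic=t_rep.statistic,
        p_value=t_rep.p_value,
        n=t_rep.n,
        icc=icc_rep.icc,
        icc_ci=icc_rep.icc_ci,
        icc_raw=icc_rep.icc_raw,
    )
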