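"""External-validation prediction-error metrics.

Bias is the mean prediction error (MPE) and precision the root mean square
prediction error (RMSPE), both in mg/L with normal-approximation 95%
confidence intervals, following the classic prediction-error framework for
pharmacokinetic model evaluation.  Prediction error is defined
observed - predicted, so observations running below the model give a
negative MPE.  A relative-bias acceptance rule (|MPE| within 20% of the
mean observed concentration of the evaluated subset) gives the pass/fail
verdict; the reference scale is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posterior import PredictionRecord

__all__ = [
    "ValidationReport",
    "prediction_errors",
    "mpe",
    "rmspe",
    "subset_by_concentration",
    "acceptance_check",
    "external_validation_report",
    "validation_table",
]

_Z95 = 1.96


@dataclass
class ValidationReport:
    """MPE/RMSPE summary of one external dataset (one subset rule)."""

    label: str
    n: int
    mpe: float
    mpe_ci: tuple[float, float] | None
    rmspe: float
    rmspe_ci: tuple[float, float] | None
    subset_rule: str
    mean_observed: float
    relative_bias_percent: float
    bias_acceptable: bool

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mpe_mg_L": self.mpe,
            "mpe_95ci": list(self.mpe_ci) if self.mpe_ci else None,
            "rmspe_mg_L": self.rmspe,
            "rmspe_95ci": list(self.rmspe_ci) if self.rmspe_ci else None,
            "subset_rule": self.subset_rule,
            "mean_observed_mg_L": self.mean_observed,
            "relative_bias_percent": self.relative_bias_percent,
            "bias_acceptable": self.bias_acceptable,
        }


def prediction_errors(
    records: list[PredictionRecord], which: str = "individual"
) -> np.ndarray:
    """Per-observation prediction errors observed - predicted, mg/L.

    ``which`` selects the population- or posterior-based (individual)
    prediction.
    """
    if not records:
        raise ValueError("no prediction records")
    if which == "population":
        pred = np.array([r.population_predicted for r in records])
    elif which == "individual":
        pred = np.array([r.individual_predicted for r in records])
    else:
        raise ValueError(f"which must be 'population' or 'individual', got {which!r}")
    obs = np.array([r.observed for r in records])
    return obs - pred


def mpe(errors: np.ndarray) -> tuple[float, tuple[float, float] | None]:
    """Mean prediction error with normal-approximation 95% CI.

    CI = MPE +/- 1.96 * SD(pe)/sqrt(n); undefined (None) at n = 1.
    """
    pe = np.asarray(errors, dtype=float)
    if pe.size == 0:
        raise ValueError("no prediction errors")
    m = float(pe.mean())
    if pe.size < 2:
        return m, None
    se = float(pe.std(ddof=1) / np.sqrt(pe.size))
    return m, (m - _Z95 * se, m + _Z95 * se)


def rmspe(errors: np.ndarray) -> tuple[float, tuple[float, float] | None]:
    """Root mean square prediction error with 95% CI.

    The CI is built on the mean squared error (mean(pe^2) +/- 1.96 * SE)
    and its endpoints square-rooted; a negative lower endpoint clamps to 0.
    Undefined (None) at n = 1.
    """
    pe = np.asarray(errors, dtype=float)
    if pe.size == 0:
        raise ValueError("no prediction errors")
    sq = pe * pe
    msq = float(sq.mean())
    point = float(np.sqrt(msq))
    if pe.size < 2:
        return point, None
    se = float(sq.std(ddof=1) / np.sqrt(sq.size))
    lo = float(np.sqrt(max(msq - _Z95 * se, 0.0)))
    hi = float(np.sqrt(msq + _Z95 * se))
    return point, (lo, hi)


def subset_by_concentration(
    records: list[PredictionRecord], max_obs: float
) -> list[PredictionRecord]:
    """Retain records with observed concentration strictly below ``max_obs``
    (e.g. the 100 mg/L upper limit of the developing study's assay range)."""
    if max_obs <= 0:
        raise ValueError("concentration cutoff must be positive")
    kept = [r for r in records if r.observed < max_obs]
    if not kept:
        raise ValueError(f"no observations below {max_obs} mg/L")
    return kept


def acceptance_check(
    mpe_value: float, reference_scale: float, limit_percent: float = 20.0
) -> tuple[bool, float]:
    """Relative-bias acceptance: pass iff 100*|MPE|/reference <= limit.

    ``reference_scale`` is the concentration scale the bias is judged
    against — by convention the mean observed concentration of the
    evaluated subset.
    """
    if reference_scale <= 0:
        raise ValueError("reference scale must be positive")
    rel = 100.0 * abs(mpe_value) / reference_scale
    return rel <= limit_percent, rel


def validation_table(reports: list[ValidationReport]) -> pd.DataFrame:
    """Human-readable predictive-performance table: one row per dataset and
    subset rule, MPE and RMSPE formatted as value (95% CI) in mg/L."""

    def fmt(v, ci):
        if ci is None:
            return f"{v:.1f}"
        return f"{v:.1f} ({ci[0]:.1f} to {ci[1]:.1f})"

    rows = [
        {
            "dataset": r.label,
            "subset": r.subset_rule,
            "n": r.n,
            "MPE (mg/L)": fmt(r.mpe, r.mpe_ci),
            "RMSPE (mg/L)": fmt(r.rmspe, r.rmspe_ci),
            "bias ok (<=20%)": r.bias_acceptable,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def external_validation_report(
    records: list[PredictionRecord],
    label: str = "external",
    which: str = "individual",
    max_obs: float | None = None,
    bias_limit_percent: float = 20.0,
) -> ValidationReport:
    """Full MPE/RMSPE report for one external dataset.

    ``max_obs`` optionally restricts the evaluation to observations below a
    concentration cutoff before computing the metrics.
    """
    rule = "full data"
    if max_obs is not None:
        records = subset_by_concentration(records, max_obs)
        rule = f"observed < {max_obs:g} mg/L"
    pe = prediction_errors(records, which)
    m, m_ci = mpe(pe)
    r, r_ci = rmspe(pe)
    mean_obs = float(np.mean([rec.observed for rec in records]))
    ok, rel = acceptance_check(m, mean_obs, bias_limit_percent)
    return ValidationReport(
        label=label,
        n=len(records),
        mpe=m,
        mpe_ci=m_ci,
        rmspe=r,
        rmspe_ci=r_ci,
        subset_rule=rule,
        mean_observed=mean_obs,
        relative_bias_percent=rel,
        bias_acceptable=ok,
    )
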