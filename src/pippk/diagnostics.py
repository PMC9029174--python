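"""Internal model evaluation.

Observed-vs-predicted regression, visual predictive check (VPC),
normalised prediction distribution errors (NPDE), Bland-Altman agreement,
and the weighted bias/imprecision summary used in model screening.

The simulation-based diagnostics (VPC, NPDE) resample parameters from the
discrete population distribution, add residual noise from the error model,
and compare each observation with its own simulated predictive
distribution.  With very sparse designs (1-3 observations per subject) no
within-subject decorrelation step is applied to the NPDE: the plain
rank-based prediction-distribution error is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .popfit import DiscreteDistribution, ErrorModel, _grid_predictions, residual_sd
from .posterior import PredictionRecord
from .records import SubjectRecord

__all__ = [
    "GofSummary",
    "VpcResult",
    "NpdeResult",
    "BlandAltman",
    "gof_regression",
    "vpc",
    "npde",
    "npde_from_replicates",
    "bland_altman",
    "bias_imprecision",
]


# ---------------------------------------------------------------------------
# Observed vs predicted regression
# ---------------------------------------------------------------------------


@dataclass
class GofSummary:
    """OLS of observed on predicted with slope CI, plus weighted bias and
    imprecision (see :func:`bias_imprecision`)."""

    slope: float
    intercept: float
    r2: float
    slope_ci: tuple[float, float]
    bias: float
    imprecision: float
    n: int


def gof_regression(
    records: list[PredictionRecord],
    which: str = "population",
    error_model: ErrorModel | None = None,
) -> GofSummary:
    """Ordinary least squares of observed on predicted concentrations.

    An adequate model shows slope near 1, intercept near 0 and r2 near 1.
    The slope CI uses the t distribution with n-2 degrees of freedom.  If
    an error model is given, the weighted bias/imprecision summary is
    attached; otherwise those fields are NaN.
    """
    if len(records) < 3:
        raise ValueError("goodness-of-fit regression requires >= 3 records")
    obs = np.array([r.observed for r in records])
    key = "population_predicted" if which == "population" else "individual_predicted"
    if which not in ("population", "individual"):
        raise ValueError(f"which must be 'population' or 'individual', got {which!r}")
    pred = np.array([getattr(r, key) for r in records])
    if np.ptp(pred) == 0:
        raise ValueError("predictions are constant; regression is undefined")
    res = stats.linregress(pred, obs)
    tcrit = stats.t.ppf(0.975, len(records) - 2)
    if error_model is not None:
        bias, imprecision = bias_imprecision(records, which, error_model)
    else:
        bias, imprecision = float("nan"), float("nan")
    return GofSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        slope_ci=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        bias=bias,
        imprecision=imprecision,
        n=len(records),
    )


# ---------------------------------------------------------------------------
# Simulation machinery shared by VPC and NPDE
# ---------------------------------------------------------------------------


def _simulate_replicates(
    subjects: list[SubjectRecord],
    dist: DiscreteDistribution,
    error_model: ErrorModel,
    n_sim: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the study design ``n_sim`` times from the population model.

    Returns (obs, times, sims): flattened observed values (m,), their
    nominal times (m,), and per-observation simulated replicates (m, n_sim).
    Parameters are resampled from the support points per subject per
    replicate; Gaussian residual noise (SD from the error model at the
    predicted value) is added and negative draws truncate to zero.
    """
    all_obs, all_times, all_sims = [], [], []
    for s in subjects:
        params = {name: dist.column(name) for name in dist.names}
        profiles = _grid_predictions(s, params)  # (k, n_obs)
        idx = dist.resample(n_sim, rng)  # (n_sim,)
        pred = profiles[idx, :]  # (n_sim, n_obs)
        sd = residual_sd(pred, error_model)
        sims = np.maximum(pred + rng.standard_normal(pred.shape) * sd, 0.0)
        all_obs.append(s.obs_conc)
        all_times.append(s.obs_times)
        all_sims.append(sims.T)  # (n_obs, n_sim)
    return (
        np.concatenate(all_obs),
        np.concatenate(all_times),
        np.vstack(all_sims),
    )


@dataclass
class VpcResult:
    """Simulated quantile bands per nominal time bin, plus band coverage."""

    bin_times: np.ndarray
    q05: np.ndarray
    q50: np.ndarray
    q95: np.ndarray
    observed_times: np.ndarray
    observed: np.ndarray
    coverage: float
    n_sim: int


def vpc(
    subjects: list[SubjectRecord],
    dist: DiscreteDistribution,
    error_model: ErrorModel,
    n_sim: int = 1000,
    seed: int = 0,
) -> VpcResult:
    """Visual predictive check against the fitted population model.

    Each observation is compared with the 5th-95th percentile band of its
    own n_sim simulated replicates; ``coverage`` is the fraction of
    observations inside their band (about 0.90 expected under a correct
    model).  The plotted bands pool simulated replicates by nominal
    observation time (sparse designs sample at a handful of nominal times,
    so no smoothing is needed).
    """
    if n_sim < 100:
        raise ValueError("VPC requires n_sim >= 100")
    rng = np.random.default_rng(seed)
    obs, times, sims = _simulate_replicates(subjects, dist, error_model, n_sim, rng)

    lo = np.quantile(sims, 0.05, axis=1)
    hi = np.quantile(sims, 0.95, axis=1)
    coverage = float(np.mean((obs >= lo) & (obs <= hi)))

    bins = np.unique(np.round(times, 6))
    q05, q50, q95 = [], [], []
    for b in bins:
        pool = sims[np.round(times, 6) == b].ravel()
        q05.append(np.quantile(pool, 0.05))
        q50.append(np.quantile(pool, 0.50))
        q95.append(np.quantile(pool, 0.95))
    return VpcResult(
        bin_times=bins,
        q05=np.array(q05),
        q50=np.array(q50),
        q95=np.array(q95),
        observed_times=times,
        observed=obs,
        coverage=coverage,
        n_sim=n_sim,
    )


def npde_from_replicates(obs: np.ndarray, sims: np.ndarray) -> np.ndarray:
    """Rank-based NPDE of observations against their simulated replicates.

    ``sims`` is (m, n_sim).  pde = mid-rank (ties counted half) of each
    observation among its replicates, clipped to [1/(2 n_sim),
    1 - 1/(2 n_sim)] so observations outside the simulated range map to
    finite extreme values; npde = Phi^-1(pde).
    """
    obs = np.asarray(obs, dtype=float)
    sims = np.asarray(sims, dtype=float)
    n_sim = sims.shape[1]
    below = (sims < obs[:, None]).sum(axis=1)
    ties = (sims == obs[:, None]).sum(axis=1)
    pde = (below + 0.5 * ties) / n_sim
    pde = np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
    return stats.norm.ppf(pde)


@dataclass
class NpdeResult:
    """Per-observation NPDE values and their normality summary."""

    values: np.ndarray
    mean: float
    variance: float
    shapiro_stat: float
    shapiro_pvalue: float


def npde(
    subjects: list[SubjectRecord],
    dist: DiscreteDistribution,
    error_model: ErrorModel,
    n_sim: int = 1000,
    seed: int = 0,
) -> NpdeResult:
    """Normalised prediction distribution errors (rank-based).

    For each observation, pde = mid-rank of the observation among its n_sim
    simulated replicates (ties counted half), clipped away from 0 and 1 by
    1/(2 n_sim); npde = Phi^-1(pde).  Under a correct model the values are
    approximately standard normal; mean, variance and a Shapiro-Wilk
    statistic summarise the check.
    """
    if n_sim < 500:
        raise ValueError("NPDE requires n_sim >= 500")
    rng = np.random.default_rng(seed)
    obs, _, sims = _simulate_replicates(subjects, dist, error_model, n_sim, rng)
    values = npde_from_replicates(obs, sims)
    sh = stats.shapiro(values)
    return NpdeResult(
        values=values,
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        shapiro_stat=float(sh.statistic),
        shapiro_pvalue=float(sh.pvalue),
    )


# ---------------------------------------------------------------------------
# Bland-Altman and weighted bias/imprecision
# ---------------------------------------------------------------------------


@dataclass
class BlandAltman:
    """Agreement between paired measurements: mean difference and
    +/-1.96 SD limits of agreement."""

    differences: np.ndarray
    bias: float
    lower_loa: float
    upper_loa: float
    scale: str
    n_excluded: int = 0


def bland_altman(
    pairs: list[tuple[float, float]], scale: str = "percent_of_mean"
) -> BlandAltman:
    """Bland-Altman analysis of (observed, predicted) pairs.

    In ``percent_of_mean`` mode each difference is expressed as a percent
    of the pair mean, 100*(obs - pred)/((obs + pred)/2); pairs with zero
    mean are excluded with a warning.  ``absolute`` mode uses obs - pred in
    mg/L.  Limits of agreement are bias +/- 1.96 * SD of the differences
    (sample SD).
    """
    if len(pairs) < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    arr = np.asarray(pairs, dtype=float)
    obs, pred = arr[:, 0], arr[:, 1]
    n_excluded = 0
    if scale == "percent_of_mean":
        means = 0.5 * (obs + pred)
        ok = means != 0
        n_excluded = int((~ok).sum())
        if n_excluded:
            warnings.warn(f"{n_excluded} pair(s) with zero mean excluded")
        if ok.sum() < 2:
            raise ValueError("fewer than 2 usable pairs after exclusions")
        diffs = 100.0 * (obs[ok] - pred[ok]) / means[ok]
    elif scale == "absolute":
        diffs = obs - pred
    else:
        raise ValueError(f"scale must be 'percent_of_mean' or 'absolute', got {scale!r}")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return BlandAltman(
        differences=diffs,
        bias=bias,
        lower_loa=bias - 1.96 * sd,
        upper_loa=bias + 1.96 * sd,
        scale=scale,
        n_excluded=n_excluded,
    )


def bias_imprecision(
    records: list[PredictionRecord],
    which: str,
    error_model: ErrorModel,
) -> tuple[float, float]:
    """Weighted-prediction-error bias and imprecision.

    Each error is weighted by the expected observation SD at its predicted
    value: wpe = (obs - pred)/SD(pred).  Bias is the mean weighted error;
    imprecision is the sample variance of the weighted errors.
    """
    if len(records) < 2:
        raise ValueError("bias/imprecision require >= 2 records")
    key = "population_predicted" if which == "population" else "individual_predicted"
    pred = np.array([getattr(r, key) for r in records])
    obs = np.array([r.observed for r in records])
    wpe = (obs - pred) / residual_sd(pred, error_model)
    return float(wpe.mean()), float(wpe.var(ddof=1))
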