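"""Nonparametric population estimation with an adaptive grid.

The population model is a discrete mixing distribution: support points in
the structural-parameter box, each carrying a probability weight.  Fitting
alternates two steps, in the spirit of nonparametric adaptive-grid (NPAG)
maximum-likelihood estimation:

1.  *Weights*: for a fixed grid, the mixture log-likelihood
    sum_i log sum_j w_j L_ij is concave in w on the simplex; it is maximised
    by multiplicative EM updates, which provably never decrease it.
2.  *Grid refinement*: low-weight points are pruned and +/-delta
    perturbations per axis are added around survivors, with delta halving
    each cycle (20% of the box range down to 0.1%).

The structural parameter is (TVCL, V, KCP, KPC) under the renal covariate
link CL = TVCL * (CRCL/60), or (CL, V, ...) when fitting without the link.
Observation likelihoods are Gaussian on untransformed concentrations with
heteroscedastic SD from the residual-error model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pk import TwoCompartmentEngine
from .records import SubjectRecord
from .reference import CRCL_REFERENCE, DEFAULT_BOUNDS, FINAL_ERROR_MODEL_KWARGS

__all__ = [
    "ErrorModel",
    "ParameterSpace",
    "SupportPoint",
    "DiscreteDistribution",
    "FitResult",
    "NPAGConfig",
    "residual_sd",
    "apply_covariate",
    "final_error_model",
    "subject_loglik",
    "loglik_matrix",
    "optimize_weights",
    "npag_fit",
    "fit_metrics",
    "cv_percent",
    "covariate_screen",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Residual-error model and covariate link
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Assay/residual error: polynomial SD inflated multiplicatively or
    combined additively.

    SD_poly(C) = c0 + c1 * C (mg/L).  In ``multiplicative_gamma`` mode the
    total SD is gamma * SD_poly; in ``additive_lambda`` mode it is
    sqrt(SD_poly^2 + lambda^2).
    """

    c0: float = 1.0
    c1: float = 0.1
    mode: str = "multiplicative_gamma"
    gamma: float = 1.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("multiplicative_gamma", "additive_lambda"):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if self.c0 <= 0 and self.c1 <= 0:
            raise ValueError("polynomial SD must be positive for C >= 0")
        if self.mode == "multiplicative_gamma" and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.mode == "additive_lambda" and self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def n_estimated(self) -> int:
        """Number of estimated error parameters (0: the model is fixed here)."""
        return 0


def final_error_model() -> ErrorModel:
    """The reference residual model: SD = 5 * (1 + 0.1 * C) mg/L."""
    return ErrorModel(**FINAL_ERROR_MODEL_KWARGS)


def residual_sd(concentration, error_model: ErrorModel):
    """Residual SD (mg/L) at a (predicted) concentration; vectorised."""
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    poly = error_model.c0 + error_model.c1 * conc
    if np.any(poly <= 0):
        raise ValueError("polynomial SD must be positive over the data range")
    if error_model.mode == "multiplicative_gamma":
        out = error_model.gamma * poly
    else:
        out = np.sqrt(poly * poly + error_model.lam**2)
    return out if out.ndim else float(out)


def apply_covariate(tvcl, crcl):
    """Clearance from the renal link: CL = TVCL * (CRCL / 60)."""
    tvcl = np.asarray(tvcl, dtype=float)
    crcl = np.asarray(crcl, dtype=float)
    if np.any(tvcl <= 0):
        raise ValueError("TVCL must be positive")
    if np.any(crcl <= 0):
        raise ValueError("CRCL must be positive")
    out = tvcl * (crcl / CRCL_REFERENCE)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Population distribution containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSpace:
    """Bounded box over named structural parameters (the grid search box).

    Use ``tvcl`` to fit under the covariate link, ``cl`` to fit without it;
    omit ``kcp``/``kpc`` for a one-compartment structural model.
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        allowed = {"tvcl", "cl", "v", "kcp", "kpc"}
        unknown = set(self.bounds) - allowed
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        if "v" not in self.bounds or not ({"tvcl", "cl"} & set(self.bounds)):
            raise ValueError("bounds must include 'v' and one of 'tvcl'/'cl'")
        if ("kcp" in self.bounds) != ("kpc" in self.bounds):
            raise ValueError("kcp and kpc must both be bounded, or neither")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"{name}: bounds must satisfy 0 < lower < upper")

    @property
    def names(self) -> tuple[str, ...]:
        order = ["tvcl", "cl", "v", "kcp", "kpc"]
        return tuple(n for n in order if n in self.bounds)

    @property
    def d(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in self.names])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in self.names])

    @classmethod
    def default(cls) -> "ParameterSpace":
        return cls(dict(DEFAULT_BOUNDS))


@dataclass(frozen=True)
class SupportPoint:
    """One candidate parameter vector with its probability weight."""

    params: dict[str, float]
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")


class DiscreteDistribution:
    """Weighted support points over the structural-parameter space.

    ``points`` is (k, d) in the order of ``names``; ``weights`` sums to 1.
    """

    def __init__(self, names, points, weights, merge_tol: float = 1e-9):
        self.names = tuple(names)
        points = np.atleast_2d(np.asarray(points, dtype=float))
        weights = np.asarray(weights, dtype=float)
        if points.shape[0] != weights.shape[0] or points.shape[1] != len(self.names):
            raise ValueError("points/weights/names shapes are inconsistent")
        if np.any(weights < -1e-12):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        points, weights = _merge_close(points, weights, merge_tol)
        self.points = points
        self.weights = weights / weights.sum()

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def support(self) -> list[SupportPoint]:
        return [
            SupportPoint(dict(zip(self.names, p)), float(w))
            for p, w in zip(self.points, self.weights)
        ]

    def column(self, name: str) -> np.ndarray:
        return self.points[:, self.names.index(name)]

    def mean(self) -> dict[str, float]:
        m = self.weights @ self.points
        return dict(zip(self.names, m))

    def sd(self) -> dict[str, float]:
        m = self.weights @ self.points
        var = self.weights @ (self.points - m) ** 2
        return dict(zip(self.names, np.sqrt(var)))

    def median(self) -> dict[str, float]:
        out = {}
        for j, name in enumerate(self.names):
            order = np.argsort(self.points[:, j])
            cum = np.cumsum(self.weights[order])
            idx = int(np.searchsorted(cum, 0.5))
            out[name] = float(self.points[order[min(idx, len(order) - 1)], j])
        return out

    def summary(self) -> pd.DataFrame:
        """Mean, SD, median and CV% per parameter (weighted moments)."""
        mean, sd, med = self.mean(), self.sd(), self.median()
        rows = [
            {
                "parameter": n,
                "mean": mean[n],
                "sd": sd[n],
                "median": med[n],
                "cv_percent": cv_percent(mean[n], sd[n]),
            }
            for n in self.names
        ]
        return pd.DataFrame(rows).set_index("parameter")

    def resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Indices of n support points drawn with replacement by weight."""
        return rng.choice(len(self), size=n, p=self.weights)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "points": self.points.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteDistribution":
        return cls(d["names"], d["points"], d["weights"])


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, percent: 100 * SD / mean."""
    if mean <= 0:
        raise ValueError("CV% requires a positive mean")
    return 100.0 * sd / mean


def _merge_close(points, weights, rel_tol):
    """Merge support points identical to within rel_tol of the column range."""
    if points.shape[0] <= 1:
        return points, weights
    scale = np.maximum(points.max(0) - points.min(0), np.abs(points).max(0) * 1e-9)
    scale[scale == 0] = 1.0
    keys = {}
    for i in range(points.shape[0]):
        # float keys: robust against overflow at very small tolerances
        key = tuple(np.round(points[i] / (scale * max(rel_tol, 1e-15))))
        keys.setdefault(key, []).append(i)
    if len(keys) == points.shape[0]:
        return points, weights
    new_p, new_w = [], []
    for idx in keys.values():
        w = weights[idx].sum()
        new_p.append((weights[idx] @ points[idx]) / w if w > 0 else points[idx[0]])
        new_w.append(w)
    return np.array(new_p), np.array(new_w)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _grid_predictions(subject: SubjectRecord, params: dict[str, np.ndarray]):
    """Predicted concentrations (k, n_obs) for k parameter vectors."""
    if "tvcl" in params:
        cl = params["tvcl"] * (subject.crcl / CRCL_REFERENCE)
    else:
        cl = params["cl"]
    zeros = np.zeros_like(np.asarray(cl, dtype=float))
    eng = TwoCompartmentEngine(
        cl, params["v"], params.get("kcp", zeros), params.get("kpc", zeros)
    )
    a0 = eng.steady_state(subject.regimen) if subject.steady_state else None
    return eng.profile(subject.doses, subject.obs_times, a0)


def subject_loglik(
    subject: SubjectRecord, params, error_model: ErrorModel
) -> float:
    """Gaussian log-likelihood of one subject's observations.

    ``params`` maps structural-parameter names to scalars (``tvcl`` invokes
    the covariate link using the subject's CRCL; ``cl`` is used directly).
    The observation SD is evaluated at the predicted concentration.
    """
    if subject.n_obs == 0:
        raise ValueError(f"subject {subject.subject_id}: no observations")
    arr = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in params.items()}
    return float(_loglik_rows(subject, arr, error_model)[0])


def _loglik_rows(subject, params, error_model):
    # the SD polynomial is evaluated at the model prediction: the residual
    # model describes dispersion around the true concentration, for which
    # the prediction is the model's estimate
    pred = _grid_predictions(subject, params)
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError(
            f"non-finite prediction for subject {subject.subject_id} "
            f"(parameter grid of size {pred.shape[0]})"
        )
    sd = residual_sd(pred, error_model)
    z = (subject.obs_conc[None, :] - pred) / sd
    return np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI, axis=1)


def loglik_matrix(
    subjects: list[SubjectRecord],
    params: dict[str, np.ndarray],
    error_model: ErrorModel,
) -> np.ndarray:
    """Log-likelihood matrix (n_subjects, k grid points)."""
    return np.stack([_loglik_rows(s, params, error_model) for s in subjects])


# ---------------------------------------------------------------------------
# Mixing-weight optimisation (EM on the simplex)
# ---------------------------------------------------------------------------


def optimize_weights(
    likelihoods: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
    w0: np.ndarray | None = None,
):
    """Maximise sum_i log sum_j w_j L_ij over the probability simplex.

    Multiplicative EM updates: w_j <- w_j * mean_i(L_ij / (L w)_i).  Each
    update is guaranteed not to decrease the objective; iteration stops at
    relative objective change below ``tol``.

    Returns ``(weights, objective, n_iter)``.  ``likelihoods`` must be
    non-negative with at least one positive entry per row (a subject whose
    row is all zero is incompatible with the grid and reported by index).
    """
    L = np.asarray(likelihoods, dtype=float)
    if L.ndim != 2:
        raise ValueError("likelihood matrix must be 2-D (subjects x points)")
    if np.any(L < 0):
        raise ValueError("likelihoods must be non-negative")
    zero_rows = np.flatnonzero(~(L > 0).any(axis=1))
    if zero_rows.size:
        raise ValueError(
            f"subject rows {zero_rows.tolist()} have zero likelihood at every "
            "support point: data are incompatible with the current grid"
        )
    n, k = L.shape
    if k == 1:
        return np.ones(1), float(np.sum(np.log(L[:, 0]))), 0
    w = np.full(k, 1.0 / k) if w0 is None else np.asarray(w0, dtype=float) / np.sum(w0)
    obj = -np.inf
    for it in range(1, max_iter + 1):
        psi = L @ w
        new_obj = float(np.sum(np.log(psi)))
        if new_obj - obj <= tol * max(1.0, abs(new_obj)) and it > 1:
            obj = new_obj
            break
        obj = new_obj
        w = w * (L.T @ (1.0 / psi)) / n
        w = np.maximum(w, 0.0)
        w /= w.sum()
    psi = L @ w
    return w, float(np.sum(np.log(psi))), it


# ---------------------------------------------------------------------------
# Adaptive-grid population fit
# ---------------------------------------------------------------------------


@dataclass
class NPAGConfig:
    """Tuning knobs of the adaptive-grid fit (all deterministic given seed)."""

    seed: int = 0
    n_init: int | None = None  # default 20 * 2^d quasi-random points
    max_cycles: int = 60
    delta_init: float = 0.20  # perturbation, fraction of each axis range
    delta_min: float = 1e-3
    prune_rel: float = 1e-8  # drop weights below prune_rel * max weight
    em_tol: float = 1e-8
    em_max_iter: int = 2000  # final weight solves
    em_cycle_iter: int = 500  # weight solves inside refinement cycles
    ll_tol: float = 1e-6  # -2LL improvement considered "no progress"
    max_survivors: int = 250  # cap on points carried between cycles
    n_protect: int = 20  # likelihood leaders exempt from weight pruning
    n_corner: int = 12  # top points also perturbed along diagonals
    n_polish: int = 8  # top points refined by simplex search after the cycles
    polish_maxiter: int = 200
    restarts: int = 1  # independent initial grids; best likelihood kept


@dataclass
class FitResult:
    """Outcome of a population fit."""

    distribution: DiscreteDistribution
    minus2ll: float
    aic: float
    bic: float
    n_cycles: int
    converged: bool
    n_observations: int
    minus2ll_per_cycle: list[float] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.distribution.summary()

    def to_dict(self) -> dict:
        return {
            "distribution": self.distribution.to_dict(),
            "minus2ll": self.minus2ll,
            "aic": self.aic,
            "bic": self.bic,
            "n_cycles": self.n_cycles,
            "converged": self.converged,
            "n_observations": self.n_observations,
            "minus2ll_per_cycle": self.minus2ll_per_cycle,
            "summary": self.summary().reset_index().to_dict(orient="records"),
        }


def fit_metrics(
    minus2ll: float,
    n_support: int,
    n_params_per_point: int,
    n_observations: int,
    n_error_params: int = 0,
) -> tuple[float, float]:
    """AIC and BIC of a fit: AIC = -2LL + 2p, BIC = -2LL + p ln(n_obs).

    By convention p counts the structural parameters per support point plus
    any estimated error parameters; the support-point count itself
    (``n_support``) is not penalised.
    """
    if n_params_per_point <= 0 or n_observations <= 0 or n_support <= 0:
        raise ValueError("counts must be positive")
    p = n_params_per_point + n_error_params
    return minus2ll + 2.0 * p, minus2ll + p * float(np.log(n_observations))


def _sobol_grid(space: ParameterSpace, n: int, seed: int) -> np.ndarray:
    from scipy.stats import qmc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n need not be a power of two
        u = qmc.Sobol(space.d, scramble=True, seed=seed).random(n)
    return space.lower + u * (space.upper - space.lower)


def npag_fit(
    subjects: list[SubjectRecord],
    space: ParameterSpace | None = None,
    error_model: ErrorModel | None = None,
    config: NPAGConfig | None = None,
) -> FitResult:
    """Adaptive-grid nonparametric maximum-likelihood population fit.

    Initialises a scrambled low-discrepancy grid in the bounded box, then
    cycles: optimise mixing weights (EM), prune negligible-weight points,
    and add +/-delta perturbations per axis around survivors with delta
    halving per cycle.  The reported -2LL sequence is non-increasing by
    construction (a cycle that fails to improve keeps the previous
    solution).  Non-convergence within ``max_cycles`` is flagged on the
    result, not raised.
    """
    if len(subjects) < 2:
        raise ValueError("population fit requires at least 2 subjects")
    # canonical subject order: the likelihood is exchangeable, but float
    # summation order is not — sorting makes the fit order-invariant
    subjects = sorted(subjects, key=lambda s: s.subject_id)
    space = space or ParameterSpace.default()
    error_model = error_model or final_error_model()
    cfg = config or NPAGConfig()
    if cfg.restarts > 1:
        # independent initial grids; the highest-likelihood fit wins
        best = None
        for r in range(cfg.restarts):
            sub_cfg = replace(cfg, restarts=1, seed=cfg.seed + 1000 * r)
            fit = npag_fit(subjects, space, error_model, sub_cfg)
            if best is None or fit.minus2ll < best.minus2ll:
                best = fit
        return best
    names, lo, hi = space.names, space.lower, space.upper
    rng_range = hi - lo
    n_obs_total = sum(s.n_obs for s in subjects)

    n_init = cfg.n_init or 20 * 2**space.d
    points = _sobol_grid(space, n_init, cfg.seed)

    def params_of(pts):
        return {name: pts[:, j] for j, name in enumerate(names)}

    log_l = loglik_matrix(subjects, params_of(points), error_model)
    row_max = log_l.max(axis=1, keepdims=True)
    w, obj, _ = optimize_weights(
        np.exp(log_l - row_max), tol=cfg.em_tol, max_iter=cfg.em_max_iter
    )
    total_ll = obj + float(row_max.sum())

    history = [-2.0 * total_ll]
    delta = cfg.delta_init
    converged = False
    cycle = 0
    for cycle in range(1, cfg.max_cycles + 1):
        keep = w > cfg.prune_rel * w.max()
        if keep.sum() > cfg.max_survivors:  # numerical safeguard on grid growth
            order = np.argsort(w)[::-1][: cfg.max_survivors]
            keep = np.zeros_like(keep)
            keep[order] = True
        # protect the best-likelihood points from weight pruning so the
        # search keeps several basins alive even when EM concentrates
        leaders = np.argsort(log_l.mean(axis=0))[::-1][: cfg.n_protect]
        keep[leaders] = True
        points, w, log_l = points[keep], w[keep], log_l[:, keep]
        w = w / w.sum()

        # +/-delta candidates per axis around each survivor, clipped to box
        cand = []
        for j in range(space.d):
            for sgn in (-1.0, 1.0):
                shifted = points.copy()
                shifted[:, j] = np.clip(
                    shifted[:, j] + sgn * delta * rng_range[j], lo[j], hi[j]
                )
                cand.append(shifted)
        # diagonal (corner) moves around the highest-weight points: axis
        # moves alone stall on correlated likelihood ridges
        top = points[np.argsort(w)[::-1][: cfg.n_corner]]
        offsets = np.array(
            np.meshgrid(*([[-1.0, 0.0, 1.0]] * space.d), indexing="ij")
        ).reshape(space.d, -1).T
        offsets = offsets[np.abs(offsets).sum(axis=1) > 1]  # skip axis/no-ops
        corner = top[:, None, :] + offsets[None, :, :] * (delta * rng_range)
        cand.append(np.clip(corner.reshape(-1, space.d), lo, hi))
        cand = np.unique(np.vstack(cand), axis=0)
        new_log_l = loglik_matrix(subjects, params_of(cand), error_model)

        ext_points = np.vstack([points, cand])
        ext_log_l = np.hstack([log_l, new_log_l])
        row_max = ext_log_l.max(axis=1, keepdims=True)
        L = np.exp(ext_log_l - row_max)

        # EM from a uniform start; fall back to a warm start (previous
        # weights, epsilon on the new points) if the cold start regresses
        best_w, best_obj, _ = optimize_weights(
            L, tol=cfg.em_tol, max_iter=cfg.em_cycle_iter
        )
        new_total_ll = best_obj + float(row_max.sum())
        if new_total_ll < total_ll:
            warm = np.concatenate(
                [w * (1 - 1e-6), np.full(cand.shape[0], 1e-6 / cand.shape[0])]
            )
            cw, cobj, _ = optimize_weights(
                L, tol=cfg.em_tol, max_iter=cfg.em_cycle_iter, w0=warm
            )
            if cobj > best_obj:
                best_w, best_obj = cw, cobj
            new_total_ll = best_obj + float(row_max.sum())

        if new_total_ll >= total_ll:
            points, w, log_l, total_ll = ext_points, best_w, ext_log_l, new_total_ll
        improvement = history[-1] - (-2.0 * total_ll)
        history.append(-2.0 * total_ll)

        # pattern-search radius schedule: expand while the radius pays off,
        # halve when it stops; converged once the finest radius stops paying
        if improvement < cfg.ll_tol:
            if delta <= cfg.delta_min:
                converged = True
                break
            delta = max(delta / 2.0, cfg.delta_min)
        else:
            delta = min(delta * 2.0, cfg.delta_init)

    # polish: slide the top support points along the (typically curved)
    # likelihood ridge by derivative-free continuous search on the mixture
    # objective with the remaining points held fixed, then refit weights
    if cfg.n_polish > 0:
        points, log_l, w, total_ll = _polish_support(
            subjects, error_model, space, points, log_l, w, total_ll, cfg
        )
        history.append(min(history[-1], -2.0 * total_ll))

    # condense: smallest support covering all but 1e-9 of the mass, weights
    # re-polished by EM; keep the full grid if condensation costs likelihood
    order = np.argsort(w)[::-1]
    cum = np.cumsum(w[order])
    n_keep = int(np.searchsorted(cum, 1.0 - 1e-9)) + 1
    sel = order[:n_keep]
    row_max = log_l[:, sel].max(axis=1, keepdims=True)
    cw, cobj, _ = optimize_weights(
        np.exp(log_l[:, sel] - row_max),
        tol=cfg.em_tol,
        max_iter=cfg.em_max_iter,
        w0=w[sel],
    )
    cond_ll = cobj + float(row_max.sum())
    if cond_ll >= total_ll - cfg.ll_tol:
        points, w, total_ll = points[sel], cw, max(cond_ll, total_ll)

    keep = w > cfg.prune_rel * w.max()
    points, w = points[keep], w[keep]
    dist = DiscreteDistribution(names, points, w / w.sum(), merge_tol=1e-9)
    minus2ll = -2.0 * total_ll
    aic, bic = fit_metrics(
        minus2ll, len(dist), space.d, n_obs_total, error_model.n_estimated
    )
    return FitResult(
        distribution=dist,
        minus2ll=minus2ll,
        aic=aic,
        bic=bic,
        n_cycles=cycle,
        converged=converged,
        n_observations=n_obs_total,
        minus2ll_per_cycle=history,
    )


def _polish_support(subjects, error_model, space, points, log_l, w, total_ll, cfg):
    """Nelder-Mead refinement of the highest-weight support points.

    Each selected point is moved to maximise the mixture log-likelihood
    with all other points (and all weights) held fixed; weights are then
    re-optimised.  The result is only accepted if it does not decrease the
    total log-likelihood.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    names, lo, hi = space.names, space.lower, space.upper
    groups = _design_groups(subjects)
    log_w = np.log(np.maximum(w, 1e-300))
    order = np.argsort(w)[::-1][: cfg.n_polish]
    new_points = points.copy()
    new_log_l = log_l.copy()
    for j in order:
        mask = np.ones(points.shape[0], dtype=bool)
        mask[j] = False
        rest = logsumexp(new_log_l[:, mask] + log_w[mask][None, :], axis=1)

        def neg_obj(x):
            x = np.clip(x, lo, hi)
            try:
                ll = _loglik_point(subjects, groups, x, names, error_model)
            except FloatingPointError:  # pragma: no cover
                return 1e300
            return -float(np.sum(np.logaddexp(rest, log_w[j] + ll)))

        res = minimize(
            neg_obj,
            new_points[j],
            method="Nelder-Mead",
            options={"maxiter": cfg.polish_maxiter, "xatol": 1e-6, "fatol": 1e-10},
        )
        cand = np.clip(res.x, lo, hi)
        if neg_obj(cand) < neg_obj(new_points[j]):
            new_points[j] = cand
            new_log_l[:, j] = _loglik_point(subjects, groups, cand, names, error_model)

    row_max = new_log_l.max(axis=1, keepdims=True)
    cw, cobj, _ = optimize_weights(
        np.exp(new_log_l - row_max), tol=cfg.em_tol, max_iter=cfg.em_max_iter, w0=w
    )
    new_total = cobj + float(row_max.sum())
    if new_total >= total_ll:
        return new_points, new_log_l, cw, new_total
    return points, log_l, w, total_ll


def _design_groups(subjects):
    """Group subject indices by shared dosing design so a single support
    point can be evaluated for the whole group in one vectorised sweep."""
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(subjects):
        key = (
            tuple((d.start_time, d.amount, d.duration) for d in s.doses),
            tuple(np.round(s.obs_times, 12)),
            s.steady_state,
            None
            if s.regimen is None
            else (s.regimen.dose, s.regimen.interval, s.regimen.infusion_duration),
        )
        groups.setdefault(key, []).append(i)
    return list(groups.values())


def _loglik_point(subjects, groups, point, names, error_model):
    """Log-likelihood of every subject at one support point (vectorised per
    design group, with per-subject clearance under the covariate link)."""
    out = np.empty(len(subjects))
    values = dict(zip(names, point))
    for idx in groups:
        ref = subjects[idx[0]]
        n_g = len(idx)
        if "tvcl" in values:
            crcl = np.array([subjects[i].crcl for i in idx])
            cl = values["tvcl"] * (crcl / CRCL_REFERENCE)
        else:
            cl = np.full(n_g, values["cl"])
        eng = TwoCompartmentEngine(
            cl,
            np.full(n_g, values["v"]),
            np.full(n_g, values.get("kcp", 0.0)),
            np.full(n_g, values.get("kpc", 0.0)),
        )
        a0 = eng.steady_state(ref.regimen) if ref.steady_state else None
        pred = eng.profile(ref.doses, ref.obs_times, a0)
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError("non-finite prediction during polish")
        obs = np.stack([subjects[i].obs_conc for i in idx])
        sd = residual_sd(pred, error_model)
        z = (obs - pred) / sd
        out[list(idx)] = np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI, axis=1)
    return out


# ---------------------------------------------------------------------------
# Covariate screening
# ---------------------------------------------------------------------------

_CONTINUOUS_FORMS = ("linear", "log", "power", "quadratic")


def _form_r2(x: np.ndarray, y: np.ndarray, form: str) -> float | None:
    """R^2 on the original y scale for one regression form, or None if the
    form is inapplicable (e.g. log/power with non-positive data)."""
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return None
    if form == "linear":
        yhat = np.polyval(np.polyfit(x, y, 1), x)
    elif form == "quadratic":
        yhat = np.polyval(np.polyfit(x, y, 2), x)
    elif form == "log":
        if np.any(x <= 0):
            return None
        yhat = np.polyval(np.polyfit(np.log(x), y, 1), np.log(x))
    elif form == "power":
        if np.any(x <= 0) or np.any(y <= 0):
            return None
        coef = np.polyfit(np.log(x), np.log(y), 1)
        yhat = np.exp(np.polyval(coef, np.log(x)))
    else:  # pragma: no cover
        raise ValueError(form)
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def covariate_screen(
    posterior_params: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Screen covariate-parameter relations by best-fitting regression form.

    For each (structural parameter, covariate) pair the best of linear, log,
    power and quadratic regressions is selected by R^2 (categorical
    covariates use the group-mean model).  Returns a table sorted by R^2,
    one row per pair, with the winning form.  Constant covariates are
    skipped with a warning.
    """
    if len(posterior_params) < 6:
        raise ValueError("covariate screening requires at least 6 subjects")
    if not posterior_params.index.equals(covariates.index):
        covariates = covariates.loc[posterior_params.index]

    rows = []
    for pname in posterior_params.columns:
        y = posterior_params[pname].to_numpy(dtype=float)
        for cname in covariates.columns:
            col = covariates[cname]
            if col.nunique(dropna=True) <= 1:
                warnings.warn(f"covariate {cname!r} is constant; skipped")
                continue
            if col.dtype == bool or col.dtype == object or col.nunique() <= 3:
                # group-mean (one-way) model
                groups = col.astype(str).to_numpy()
                yhat = pd.Series(y).groupby(groups).transform("mean").to_numpy()
                ss_tot = float(np.sum((y - y.mean()) ** 2))
                if ss_tot == 0:
                    continue
                r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
                rows.append((pname, cname, "categorical", r2))
                continue
            x = col.to_numpy(dtype=float)
            best_form, best_r2 = None, -np.inf
            for form in _CONTINUOUS_FORMS:
                r2 = _form_r2(x, y, form)
                if r2 is not None and r2 > best_r2:
                    best_form, best_r2 = form, r2
            if best_form is not None:
                rows.append((pname, cname, best_form, best_r2))
    out = pd.DataFrame(rows, columns=["parameter", "covariate", "form", "r2"])
    return out.sort_values("r2", ascending=False).reset_index(drop=True)
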