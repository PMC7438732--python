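"""Replicate aggregation and 1/variance-weighted nonlinear least squares.

Assay points are replicated 3-5 times; replicates at each substrate level are
collapsed to a weighted mean point (mean, unbiased sample variance, count),
and the rate law is fitted to the mean points by weighted nonlinear least
squares, each point weighted by the reciprocal of its replicate variance.
Asymptotic standard errors follow the usual nonlinear-regression convention
cov = s^2 (J^T W J)^-1 with s^2 = weighted SSE / (N - p).

Substrate-inhibited points (high PPi) are excluded before fitting by a simple
truncation of the substrate axis; the rate laws here do not model substrate
inhibition, so points above the truncation threshold would bias every
parameter.

The optimiser is SciPy's bounded trust-region-reflective least squares with a
data-driven multi-start over the cooperativity parameter (nH for Hill, L for
the allosteric model), which is the only parameter whose likelihood surface
is routinely multi-modal on sparse assay grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import HillParams, MWCParams, hill_rate, mm_rate, mwc_rate

__all__ = [
    "KineticDataset",
    "FitResult",
    "FitError",
    "UnderdeterminedError",
    "aggregate_replicates",
    "truncate_for_substrate_inhibition",
    "fit_model",
    "MODEL_PARAM_NAMES",
]

MODEL_PARAM_NAMES: Mapping[str, tuple[str, ...]] = {
    "hill": ("vm", "k_half", "n_h"),
    "mwc": ("vm", "l", "k_r"),
    "mm": ("vm", "km"),
}


class FitError(RuntimeError):
    """Raised when no multi-start of the optimiser converges."""


class UnderdeterminedError(ValueError):
    """Raised when fewer points than free parameters + 1 are available."""


@dataclass(frozen=True)
class KineticDataset:
    """Weighted mean-rate points for one assay condition.

    ``s`` in mM, ``mean_rate`` in U/mg, ``rate_variance`` in (U/mg)^2.
    """

    s: np.ndarray
    mean_rate: np.ndarray
    rate_variance: np.ndarray
    n_replicates: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if s.size and (np.any(s < 0) or len(np.unique(s)) != s.size):
            raise ValueError("substrate values must be unique and >= 0")
        if np.any(np.asarray(self.mean_rate) < 0):
            raise ValueError("mean rates must be >= 0")
        if np.any(np.asarray(self.rate_variance) < 0):
            raise ValueError("rate variances must be >= 0")
        if np.any(np.asarray(self.n_replicates) < 1):
            raise ValueError("replicate counts must be >= 1")

    def __len__(self) -> int:
        return int(np.asarray(self.s).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_mM": self.s,
                "mean_rate": self.mean_rate,
                "rate_variance": self.rate_variance,
                "n_replicates": self.n_replicates,
            }
        )


@dataclass(frozen=True)
class FitResult:
    """Point estimates, asymptotic SEs and diagnostics for one fitted model."""

    model: str
    params: Mapping[str, float]
    se: Mapping[str, float]
    wrss: float
    converged: bool
    points_used: int
    truncation_max_s: float | None = None
    weights_mode: str = "replicate-variance"
    warnings: tuple[str, ...] = ()

    def predict(self, s) -> np.ndarray | float:
        return _model_function(self.model)(np.asarray(s, dtype=float), *self.theta)

    @property
    def theta(self) -> tuple[float, ...]:
        return tuple(self.params[name] for name in MODEL_PARAM_NAMES[self.model])

    def param_object(self):
        if self.model == "hill":
            return HillParams(**self.params)
        if self.model == "mwc":
            return MWCParams(**self.params)
        return self.params


def aggregate_replicates(
    s,
    rates,
    *,
    metadata: dict | None = None,
    single_replicate: str = "error",
) -> KineticDataset:
    """Collapse replicate rates to per-level (mean, variance, count) points.

    Parameters
    ----------
    s, rates
        Parallel arrays: substrate level (mM) and observed rate (U/mg) per
        replicate record.
    single_replicate
        Contract for levels with one replicate, where the sample variance is
        undefined: ``"error"`` raises; ``"pooled"`` substitutes the mean of
        the variances from multi-replicate levels (never silent — a warning
        is emitted).

    Levels are returned sorted by substrate concentration; variances use the
    unbiased (n-1) estimator.
    """
    s = np.asarray(s, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if s.size == 0:
        raise ValueError("no replicate records provided")
    if s.shape != rates.shape:
        raise ValueError("s and rates must be parallel arrays")
    if not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("substrate values must be finite and >= 0")
    if single_replicate not in ("error", "pooled"):
        raise ValueError("single_replicate must be 'error' or 'pooled'")

    levels = np.unique(s)
    means = np.empty(levels.size)
    variances = np.full(levels.size, np.nan)
    counts = np.empty(levels.size, dtype=int)
    for i, level in enumerate(levels):
        r = rates[s == level]
        counts[i] = r.size
        means[i] = r.mean()
        if r.size > 1:
            variances[i] = r.var(ddof=1)

    singles = counts == 1
    if np.any(singles):
        if single_replicate == "error":
            raise ValueError(
                f"{singles.sum()} substrate level(s) have a single replicate; "
                "variance is undefined (use single_replicate='pooled' to "
                "substitute the pooled variance)"
            )
        pool = variances[~singles]
        if pool.size == 0:
            raise ValueError(
                "all levels have a single replicate; no variance can be pooled"
            )
        variances[singles] = pool.mean()
        warnings.warn(
            "single-replicate levels received the pooled variance of the "
            "multi-replicate levels",
            stacklevel=2,
        )

    return KineticDataset(
        s=levels,
        mean_rate=means,
        rate_variance=variances,
        n_replicates=counts,
        metadata=dict(metadata or {}),
    )


def truncate_for_substrate_inhibition(
    dataset: KineticDataset, max_s: float, min_points: int = 4
) -> KineticDataset:
    """Drop points with s > max_s before fitting.

    High PPi inhibits some pyrophosphatases and the rate laws fitted here do
    not model that regime, so inhibited points are excluded rather than
    fitted.  Raises :class:`UnderdeterminedError` when fewer than
    ``min_points`` (free parameters + 1 for the richest model) remain.
    """
    if not (max_s > 0):
        raise ValueError(f"max_s must be > 0, got {max_s!r}")
    keep = np.asarray(dataset.s) <= max_s
    if keep.sum() < min_points:
        raise UnderdeterminedError(
            f"truncation at {max_s} mM leaves {int(keep.sum())} point(s); "
            f"need at least {min_points}"
        )
    return KineticDataset(
        s=np.asarray(dataset.s)[keep],
        mean_rate=np.asarray(dataset.mean_rate)[keep],
        rate_variance=np.asarray(dataset.rate_variance)[keep],
        n_replicates=np.asarray(dataset.n_replicates)[keep],
        metadata=dict(dataset.metadata),
    )


def _model_function(model: str) -> Callable[..., np.ndarray]:
    if model == "hill":
        return lambda s, vm, k_half, n_h: hill_rate(s, HillParams(vm, k_half, n_h))
    if model == "mwc":
        return lambda s, vm, l, k_r: mwc_rate(s, MWCParams(vm, l, k_r))
    if model == "mm":
        return lambda s, vm, km: mm_rate(s, vm, km)
    raise ValueError(f"unknown model {model!r}; expected hill, mwc or mm")


def _half_max_s(s: np.ndarray, y: np.ndarray) -> float:
    """Data-driven half-saturation guess: first s where rate >= max/2."""
    half = y.max() / 2.0
    above = s[y >= half]
    return float(above.min()) if above.size else float(np.median(s))


def _starts_and_bounds(
    model: str, s: np.ndarray, y: np.ndarray
) -> tuple[list[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    tiny = 1e-9
    vm0 = max(float(y.max()), tiny)
    k0 = max(_half_max_s(s, y), float(s[s > 0].min()) if np.any(s > 0) else tiny)
    max_s = float(s.max())
    if model == "hill":
        lower = np.array([tiny, tiny, 0.5])
        upper = np.array([10.0 * vm0, 10.0 * max_s, 8.0])
        starts = [np.array([vm0, k0, n]) for n in (1.0, 2.0, 3.0, 5.0)]
    elif model == "mwc":
        # k_r carried in uM: bounds mirror the substrate scale x 1000.
        lower = np.array([tiny, 0.0, tiny])
        upper = np.array([10.0 * vm0, 1e7, 10.0 * max_s * 1000.0])
        starts = [np.array([vm0, l, k0 * 1000.0]) for l in (0.0, 10.0, 1e3, 1e5)]
    elif model == "mm":
        lower = np.array([tiny, tiny])
        upper = np.array([10.0 * vm0, 10.0 * max_s])
        starts = [np.array([vm0, k0])]
    else:
        raise ValueError(f"unknown model {model!r}")
    starts = [np.clip(x0, lower, upper) for x0 in starts]
    return starts, (lower, upper)


def _weights(
    dataset: KineticDataset, mode: str, notes: list[str]
) -> np.ndarray:
    var = np.asarray(dataset.rate_variance, dtype=float).copy()
    n = np.asarray(dataset.n_replicates, dtype=float)
    if mode == "unit":
        return np.ones_like(var)
    if mode not in ("replicate-variance", "sem"):
        raise ValueError(
            "weights must be 'replicate-variance', 'sem' or 'unit', "
            f"got {mode!r}"
        )
    bad = ~np.isfinite(var) | (var <= 0)
    if np.all(bad):
        notes.append(
            "no positive replicate variance in dataset; falling back to unit weights"
        )
        warnings.warn(notes[-1], stacklevel=3)
        return np.ones_like(var)
    if np.any(bad):
        fallback = var[~bad].min()
        var[bad] = fallback
        notes.append(
            f"{int(bad.sum())} point(s) with zero/undefined variance assigned the "
            f"smallest positive variance ({fallback:.3g})"
        )
        warnings.warn(notes[-1], stacklevel=3)
    w = 1.0 / var
    if mode == "sem":
        w = n / var  # weight by inverse variance of the mean
    return w


def fit_model(
    dataset: KineticDataset,
    model: str,
    *,
    weights: str = "replicate-variance",
    truncate_max_s: float | None = None,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    max_nfev: int = 2000,
) -> FitResult:
    """Fit a rate law to weighted mean points by nonlinear least squares.

    Minimises sum_i w_i (mean_rate_i - model(s_i))^2 with w_i = 1/variance_i
    (``weights="replicate-variance"``, the default; ``"sem"`` uses
    n_i/variance_i, ``"unit"`` uses 1).  A small multi-start grid over the
    cooperativity parameter guards against local minima; the lowest final
    cost wins, ties broken by grid order.  Deterministic for identical
    inputs and options.

    Raises
    ------
    UnderdeterminedError
        Fewer points than free parameters + 1.
    FitError
        No start converged; a bound-clipped non-converged answer is never
        returned silently.
    """
    param_names = MODEL_PARAM_NAMES.get(model)
    if param_names is None:
        raise ValueError(f"unknown model {model!r}; expected hill, mwc or mm")

    if truncate_max_s is not None:
        dataset = truncate_for_substrate_inhibition(
            dataset, truncate_max_s, min_points=len(param_names) + 1
        )

    s = np.asarray(dataset.s, dtype=float)
    y = np.asarray(dataset.mean_rate, dtype=float)
    n_points = s.size
    p = len(param_names)
    if n_points < p + 1:
        raise UnderdeterminedError(
            f"{n_points} points for {p} free parameters; need >= {p + 1}"
        )

    notes: list[str] = []
    w = _weights(dataset, weights, notes)
    if not np.any(w > 0):
        raise ValueError("all weights are zero or undefined")
    sqrt_w = np.sqrt(w)

    func = _model_function(model)
    starts, (lower, upper) = _starts_and_bounds(model, s, y)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return sqrt_w * (y - func(s, *theta))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                method="trf",
                ftol=ftol,
                xtol=xtol,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise FitError(
            f"no multi-start converged for model {model!r} on dataset "
            f"{dataset.metadata or '(unnamed)'}"
        )

    theta = best.x
    wrss = float(np.sum(best.fun**2))

    # cov = s^2 (J^T W J)^-1; best.jac is already the sqrt(W)-scaled Jacobian.
    if n_points > p:
        s2 = wrss / (n_points - p)
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            notes.append("curvature matrix singular; SEs from pseudo-inverse")
    else:  # saturated fit: SEs undefined
        se = np.full(p, np.nan)
        notes.append("saturated fit (points == parameters); SEs undefined")

    at_bound = (np.abs(theta - upper) < 1e-12 * np.maximum(np.abs(upper), 1.0)) | (
        (lower > 0) & (np.abs(theta - lower) < 1e-12)
    )
    for name, flag in zip(param_names, at_bound):
        if flag:
            notes.append(f"parameter {name} at optimisation bound")

    return FitResult(
        model=model,
        params={name: float(v) for name, v in zip(param_names, theta)},
        se={name: float(v) for name, v in zip(param_names, se)},
        wrss=wrss,
        converged=True,
        points_used=n_points,
        truncation_max_s=truncate_max_s,
        weights_mode=weights,
        warnings=tuple(notes),
    )
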