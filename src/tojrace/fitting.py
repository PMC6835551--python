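"""Binomial maximum-likelihood fitting and the BIC score.

Each model predicts a probe-first probability ``p_i`` at every SOA ``i``;
with ``k_i`` probe-first responses out of ``n_i`` trials the log-likelihood
is the binomial

    L = sum_i [ k_i ln p_i + (n_i - k_i) ln(1 - p_i) ]

(the binomial coefficient is constant across models and omitted).  Fits use
bounded Nelder-Mead from multiple Latin-hypercube starting points; the
optimizer works in unit-cube coordinates with the encoding rates mapped on
a log10 scale, since their bounds span four decades (0.1-1000 Hz) while
plausible values sit near 40-80 Hz.

Model complexity is scored with the Bayesian information criterion

    BIC = k ln(n) - 2 L

with ``n`` the total trial count (the binomial likelihood's unit of
observation is the trial) and ``k`` the number of free parameters.  In the
equal-complexity configuration of a basic (uncued) study, ``tau`` is frozen
at 0, giving both plateau models four free parameters and the bare race two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    FitFailureError,
    InvalidParameterError,
)
from .models import MODELS
from .race import RATE_MAX, RATE_MIN
from .synthetic import JudgmentData

__all__ = ["FitOptions", "FitResult", "binomial_loglik", "fit_model", "bic",
           "DEFAULT_BOUNDS"]

#: Probabilities are clipped here before taking logs; the models carry no
#: lapse/error parameters, so saturated cells would otherwise yield -inf.
P_CLIP = 1e-9

#: Default per-parameter fitting bounds (internal units: events/ms and ms).
#: They cover every plausible estimate for well-trained observers with wide
#: margin: rates 0.1-1000 Hz, indecision half-widths and reset thresholds up
#: to 200 ms, delays up to +/-200 ms.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "vp": (RATE_MIN, RATE_MAX),
    "vr": (RATE_MIN, RATE_MAX),
    "delta": (0.0, 200.0),
    "xi": (0.0, 1.0),
    "t0": (0.0, 200.0),
    "s0": (0.0, 100.0),
    "tau": (-200.0, 200.0),
}


@dataclass(frozen=True)
class FitOptions:
    """Options controlling a maximum-likelihood fit.

    Attributes
    ----------
    n_starts : int
        Number of Latin-hypercube starting points (>= 1).
    bounds : dict
        Per-parameter closed intervals overriding :data:`DEFAULT_BOUNDS`.
    fixed : dict
        Parameters frozen at stated values, e.g. ``{"tau": 0.0}`` for the
        equal-complexity basic-study configuration.  Fixed values must lie
        inside the bounds.
    seed : int
        Seed for the starting-point design.
    xatol, fatol : float
        Nelder-Mead convergence tolerances (unit-cube coordinates and
        log-likelihood units respectively).
    maxiter : int
        Iteration cap per start.
    """

    n_starts: int = 10
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    seed: int = 0
    xatol: float = 1e-6
    fatol: float = 1e-9
    maxiter: int = 5000

    def __post_init__(self):
        if self.n_starts < 1:
            raise ConfigurationError(f"n_starts must be >= 1, got {self.n_starts}")
        merged = {**DEFAULT_BOUNDS, **self.bounds}
        for name, value in self.fixed.items():
            lo, hi = merged.get(name, (-math.inf, math.inf))
            if not lo <= value <= hi:
                raise ConfigurationError(
                    f"fixed value {name}={value} outside bounds [{lo}, {hi}]"
                )

    def bound(self, name: str) -> tuple[float, float]:
        return {**DEFAULT_BOUNDS, **self.bounds}[name]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit.

    Estimated parameters are stored twice: ``params`` in internal units
    (events/ms, ms) for further computation, ``params_display`` with rates
    in Hz for reporting.
    """

    model: str
    params: dict
    params_display: dict
    loglik: float
    n_free_parameters: int
    n_trials: int
    bic: float
    converged: bool
    best_start: int
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = bic(self.loglik, self.n_free_parameters, self.n_trials)
        if abs(expected - self.bic) > 1e-9:
            raise ConfigurationError(
                f"inconsistent BIC: stored {self.bic}, recomputed {expected}"
            )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "params_display": dict(self.params_display),
            "loglik": self.loglik,
            "n_free_parameters": self.n_free_parameters,
            "n_trials": self.n_trials,
            "bic": self.bic,
            "converged": self.converged,
            "best_start": self.best_start,
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(model=d["model"], params=dict(d["params"]),
                   params_display=dict(d["params_display"]),
                   loglik=d["loglik"],
                   n_free_parameters=d["n_free_parameters"],
                   n_trials=d["n_trials"], bic=d["bic"],
                   converged=d["converged"], best_start=d["best_start"],
                   fixed=dict(d.get("fixed", {})))


def _display(values: dict) -> dict:
    out = {}
    for name, v in values.items():
        if name in ("vp", "vr"):
            out[name + "_hz"] = v * 1000.0
        else:
            out[name] = v
    return out


def binomial_loglik(model: str, params, data: JudgmentData) -> float:
    """Binomial log-likelihood of ``params`` under ``model`` on ``data``.

    Probabilities are clipped to ``[1e-9, 1 - 1e-9]``; the binomial
    coefficient is omitted (constant across models, so BIC differences are
    unaffected).  Invalid parameters raise rather than returning -inf.
    """
    from .models import model_probability

    p = np.asarray(model_probability(model, params, data.design.soa_array))
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    k = data.count_array
    n = data.design.repetition_array
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def bic(loglik: float, n_free_parameters: int, n_trials: int) -> float:
    """Bayesian information criterion: ``k ln(n) - 2 L``; smaller is better."""
    if n_trials < 1:
        raise InvalidParameterError(f"n_trials must be >= 1, got {n_trials}")
    return n_free_parameters * math.log(n_trials) - 2.0 * loglik


# --- unit-cube transform ---------------------------------------------------

def _to_value(u: float, lo: float, hi: float, log: bool) -> float:
    if log:
        llo, lhi = math.log10(lo), math.log10(hi)
        return 10.0 ** (llo + u * (lhi - llo))
    return lo + u * (hi - lo)


def fit_model(model: str, data: JudgmentData,
              options: FitOptions | None = None) -> FitResult:
    """Fit a model to judgment data by bounded multi-start Nelder-Mead.

    By default ``tau`` is frozen at 0 (the equal-complexity configuration
    of a basic, uncued study: four free parameters for either plateau
    model, two for the bare race).  Pass ``FitOptions(fixed={})`` to free
    ``tau``, or fix any other parameter the same way.

    Raises
    ------
    DegenerateDataError
        If every count is 0 or every count equals its trial number.
    FitFailureError
        If all starts fail (carries per-start diagnostics).
    """
    if model not in MODELS:
        raise InvalidParameterError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    if options is None:
        options = FitOptions(fixed={"tau": 0.0})
    spec = MODELS[model]

    k = data.count_array
    n = data.design.repetition_array
    if np.all(k == 0) or np.all(k == n):
        raise DegenerateDataError(
            "all counts saturated at 0 or n; the curve location is unidentified"
        )

    unknown = set(options.fixed) - set(spec.param_names)
    if unknown:
        raise ConfigurationError(
            f"fixed parameters {sorted(unknown)} are not parameters of model {model!r}"
        )
    free_names = [p for p in spec.param_names if p not in options.fixed]
    if not free_names:
        raise ConfigurationError("no free parameters left to fit")
    dim = len(free_names)
    bounds = [options.bound(p) for p in free_names]
    logs = [p in spec.log_scale for p in free_names]

    def unpack(u: np.ndarray) -> dict:
        values = dict(options.fixed)
        for name, ui, (lo, hi), lg in zip(free_names, u, bounds, logs):
            values[name] = _to_value(float(np.clip(ui, 0.0, 1.0)), lo, hi, lg)
        return values

    def objective(u: np.ndarray) -> float:
        return -binomial_loglik(model, unpack(u), data)

    sampler = qmc.LatinHypercube(d=dim, seed=options.seed)
    starts = sampler.random(options.n_starts)

    best = None
    best_idx = -1
    diagnostics = []
    for i, u0 in enumerate(starts):
        try:
            res = minimize(
                objective, u0, method="Nelder-Mead",
                bounds=[(0.0, 1.0)] * dim,
                options={"xatol": options.xatol, "fatol": options.fatol,
                         "maxiter": options.maxiter, "maxfev": 10 * options.maxiter},
            )
        except (FloatingPointError, ValueError) as exc:   # pragma: no cover
            diagnostics.append({"start": i, "error": str(exc)})
            continue
        diagnostics.append({"start": i, "fun": float(res.fun),
                            "success": bool(res.success)})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
            best_idx = i
    if best is None:
        raise FitFailureError("all optimization starts failed", diagnostics)

    values = unpack(best.x)
    loglik = -float(best.fun)
    n_trials = data.design.n_trials
    score = bic(loglik, dim, n_trials)
    return FitResult(
        model=model,
        params=values,
        params_display=_display(values),
        loglik=loglik,
        n_free_parameters=dim,
        n_trials=n_trials,
        bic=score,
        converged=bool(best.success),
        best_start=best_idx,
        fixed=dict(options.fixed),
    )
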