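"""Psychometric models of the binary "probe first" judgment.

Three models, all built on the exponential encoding race of
:mod:`tojrace.race`:

``simple``
    The bare race.  The psychometric function is S-shaped with no plateau;
    its only parameters are the two rates (plus an optional net delay tau).

``indecision``
    A range-of-indecision model: arrival-time differences smaller than a
    half-width ``delta`` cannot be ordered, yielding a "simultaneous"
    percept that a forced binary response resolves with bias ``xi``
    (probability ``1 - xi`` of answering "probe first").  The range of
    indecision produces a central plateau in the psychometric function;
    ``xi`` shifts the plateau vertically, ``tau`` shifts the whole curve
    along the SOA axis.

``reset``
    An encoding-reset model rooted in the theory of visual attention (TVA):
    if the second stimulus appears within ``t0`` ms of the first (TVA's
    maximum ineffective exposure duration, varying trial-by-trial with
    standard deviation ``s0``), all processing is reset and both stimuli
    race again from a common start, where the probe wins with the Luce
    ratio ``vp/(vp+vr)``.  The decision rule stays fully deterministic; the
    plateau arises before encoding completes, and its vertical position can
    leave 0.5 only through unequal rates.

The simple race is a special case of both plateau models (``delta = 0``
and ``t0 = 0, s0 -> 0`` respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .race import RaceParams, probe_first_probability, standard_normal_cdf

__all__ = [
    "IndecisionParams",
    "ResetParams",
    "PerceptProbs",
    "percept_probabilities_indecision",
    "prob_probe_first_indecision",
    "reset_probability",
    "prob_probe_first_reset",
    "prob_probe_first_simple",
    "MODELS",
    "model_probability",
]


@dataclass(frozen=True)
class IndecisionParams:
    """Parameters of the range-of-indecision model.

    Attributes
    ----------
    rates : RaceParams
        Encoding rates (events/ms).
    delta : float
        Half-width of the range of indecision, in ms (>= 0).  ``delta = 0``
        collapses the model to the simple race.
    xi : float
        Response bias used to resolve "simultaneous" percepts; the forced
        binary response is "probe first" with probability ``1 - xi``.
        ``xi = 0.5`` is neutral.
    tau : float
        Net processing delay in ms (any sign); a pure shift of the SOA axis.
    """

    rates: RaceParams
    delta: float
    xi: float
    tau: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.delta) or self.delta < 0:
            raise InvalidParameterError(f"delta must be >= 0, got {self.delta}")
        if not np.isfinite(self.xi) or not (0.0 <= self.xi <= 1.0):
            raise InvalidParameterError(f"xi must be in [0, 1], got {self.xi}")
        if not np.isfinite(self.tau):
            raise InvalidParameterError(f"tau must be finite, got {self.tau}")


@dataclass(frozen=True)
class ResetParams:
    """Parameters of the encoding-reset model.

    Attributes
    ----------
    rates : RaceParams
        Encoding rates (events/ms).
    t0 : float
        Reset threshold: the maximum ineffective exposure duration in ms.
        A second onset within ``t0`` of the first triggers a reset.
    s0 : float
        Standard deviation (ms, >= 0) of the trial-by-trial variability of
        ``t0``; ``s0 = 0`` is handled as the degenerate step-function limit.
    tau : float
        Net processing delay in ms.
    """

    rates: RaceParams
    t0: float
    s0: float
    tau: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.t0):
            raise InvalidParameterError(f"t0 must be finite, got {self.t0}")
        if not np.isfinite(self.s0) or self.s0 < 0:
            raise InvalidParameterError(f"s0 must be >= 0, got {self.s0}")
        if not np.isfinite(self.tau):
            raise InvalidParameterError(f"tau must be finite, got {self.tau}")


@dataclass(frozen=True)
class PerceptProbs:
    """Probabilities of the three percept classes at one SOA."""

    p_probe_first: float
    p_simultaneous: float
    p_reference_first: float

    def __post_init__(self):
        total = self.p_probe_first + self.p_simultaneous + self.p_reference_first
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"percept probabilities sum to {total}, not 1")


def percept_probabilities_indecision(params: IndecisionParams, soa: float) -> PerceptProbs:
    """Percept-class probabilities under the range-of-indecision model.

    A "probe first" percept requires the probe to beat the reference by more
    than ``delta`` ms, which is the bare race evaluated at an SOA handicapped
    by ``delta``; symmetrically for "reference first".  Whatever remains is
    perceived as simultaneous.
    """
    s = np.asarray(soa, dtype=float) + params.tau
    p_pf = probe_first_probability(params.rates, s + params.delta)
    p_pf_or_sim = probe_first_probability(params.rates, s - params.delta)
    if np.ndim(soa) != 0:
        raise InvalidParameterError("percept probabilities are per-SOA; pass a scalar")
    return PerceptProbs(
        p_probe_first=float(p_pf),
        p_simultaneous=float(p_pf_or_sim - p_pf),
        p_reference_first=float(1.0 - p_pf_or_sim),
    )


def prob_probe_first_indecision(params: IndecisionParams, soa) -> float | np.ndarray:
    """P(respond "probe first") under the range-of-indecision model.

    Equals P(probe-first percept) + (1 - xi) * P(simultaneous percept); for
    ``delta = 0`` this is exactly the simple race at ``soa + tau``.
    """
    s = np.asarray(soa, dtype=float) + params.tau
    p_pf = probe_first_probability(params.rates, s + params.delta)
    p_pf_or_sim = probe_first_probability(params.rates, s - params.delta)
    out = p_pf + (1.0 - params.xi) * (p_pf_or_sim - p_pf)
    if np.ndim(soa) == 0:
        return float(out)
    return out


def reset_probability(params: ResetParams, soa) -> float | np.ndarray:
    """Probability that a trial at this SOA triggers an encoding reset.

    The reset fires when the second onset falls within the trial's ``t0``
    window of the first, with ``t0`` drawn from Normal(t0, s0) without
    truncation.  With ``s0 = 0`` this degenerates to the indicator of
    ``|soa + tau| <= t0``.
    """
    s = np.asarray(soa, dtype=float) + params.tau
    if params.s0 == 0.0:
        out = (np.abs(s) <= params.t0).astype(float)
    else:
        from scipy.special import ndtr

        # tiny s0 can overflow the z-score to +/-inf; ndtr maps that to 0/1,
        # the correct step-function limit
        with np.errstate(over="ignore", divide="ignore"):
            z_neg = (s + params.t0) / params.s0
            z_pos = (s - params.t0) / params.s0
        out = np.where(s <= 0, ndtr(z_neg), 1.0 - ndtr(z_pos))
    if np.ndim(soa) == 0:
        return float(out)
    return out


def prob_probe_first_reset(params: ResetParams, soa) -> float | np.ndarray:
    """P(respond "probe first") under the encoding-reset model.

    A mixture: with the reset probability ``w`` the stimuli race from a
    common start and the probe wins with the Luce ratio; otherwise the bare
    race at ``soa + tau`` decides.  Continuous at ``soa + tau = 0`` with
    value ``vp/(vp+vr)`` regardless of ``t0`` and ``s0``.
    """
    s = np.asarray(soa, dtype=float) + params.tau
    w = reset_probability(params, soa)
    base = probe_first_probability(params.rates, s)
    out = w * params.rates.luce_ratio + (1.0 - np.asarray(w)) * base
    if np.ndim(soa) == 0:
        return float(out)
    return out


def prob_probe_first_simple(params: RaceParams, soa, tau: float = 0.0) -> float | np.ndarray:
    """P(respond "probe first") under the bare race (no plateau mechanism)."""
    if not np.isfinite(tau):
        raise InvalidParameterError(f"tau must be finite, got {tau}")
    return probe_first_probability(params, np.asarray(soa, dtype=float) + tau)


# ---------------------------------------------------------------------------
# Model registry: a uniform flat-dict surface over the three models, used by
# fitting, simulation and the CLI.  Rates are events/ms in the flat dicts.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Uniform description of one model for fitting and simulation."""

    name: str
    param_names: tuple[str, ...]        # flat-dict keys, fit order
    log_scale: frozenset = field(default_factory=frozenset)

    def make_params(self, values: dict):
        rates = RaceParams(vp=values["vp"], vr=values["vr"])
        tau = values.get("tau", 0.0)
        if self.name == "simple":
            return rates, tau
        if self.name == "indecision":
            return IndecisionParams(rates=rates, delta=values["delta"],
                                    xi=values["xi"], tau=tau)
        return ResetParams(rates=rates, t0=values["t0"], s0=values["s0"], tau=tau)

    def probability(self, values: dict, soa):
        if self.name == "simple":
            rates, tau = self.make_params(values)
            return prob_probe_first_simple(rates, soa, tau=tau)
        if self.name == "indecision":
            return prob_probe_first_indecision(self.make_params(values), soa)
        return prob_probe_first_reset(self.make_params(values), soa)


MODELS: dict[str, ModelSpec] = {
    "simple": ModelSpec("simple", ("vp", "vr", "tau"), frozenset({"vp", "vr"})),
    "indecision": ModelSpec("indecision", ("vp", "vr", "delta", "xi", "tau"),
                            frozenset({"vp", "vr"})),
    "reset": ModelSpec("reset", ("vp", "vr", "t0", "s0", "tau"),
                       frozenset({"vp", "vr"})),
}


def params_to_dict(params, tau: float | None = None) -> dict:
    """Flatten a params object to the registry's flat-dict form."""
    if isinstance(params, RaceParams):
        return {"vp": params.vp, "vr": params.vr, "tau": 0.0 if tau is None else tau}
    if isinstance(params, IndecisionParams):
        return {"vp": params.rates.vp, "vr": params.rates.vr,
                "delta": params.delta, "xi": params.xi, "tau": params.tau}
    if isinstance(params, ResetParams):
        return {"vp": params.rates.vp, "vr": params.rates.vr,
                "t0": params.t0, "s0": params.s0, "tau": params.tau}
    raise InvalidParameterError(f"unrecognized params object: {params!r}")


def model_probability(model: str, params, soa):
    """Evaluate any registered model's probe-first probability.

    ``params`` may be the model's dataclass or a flat dict of values.
    """
    if model not in MODELS:
        raise InvalidParameterError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    spec = MODELS[model]
    values = params if isinstance(params, dict) else params_to_dict(params)
    return spec.probability(values, soa)
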