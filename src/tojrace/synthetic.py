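"""Synthetic experiment designs, binomial judgment sampling, and the
per-trial Monte-Carlo simulators that serve as independent oracles for
every closed-form curve.

The design presets emulate two highly repeated temporal-order-judgment
studies:

``exp1``
    21 SOAs from -100 to 100 ms in 10 ms steps, 240 repetitions each
    (5040 trials) — dense enough that a central plateau spreads across
    several SOA levels and precise enough that it is not noise.

``exp2_neutral`` / ``exp2_cued``
    The same grid (neutral) or a grid shifted to -40..160 ms (cued, where a
    peripheral cue precedes the probe by 140 ms), with an uneven repetition
    schedule that concentrates trials at the informative central SOAs.  The
    printed schedule has 19 entries for a 21-SOA grid; the default aligns it
    with the central 19 SOAs and pads both extremes with the schedule's
    minimum count (8).  This padding is a documented default, and the
    schedule is fully configurable.

The Monte-Carlo simulators draw actual exponential arrival times (and, for
the reset model, actual per-trial reset windows) rather than evaluating any
closed form, so agreement between simulated frequencies and the model curves
is a genuine cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .models import (
    MODELS,
    IndecisionParams,
    ResetParams,
    model_probability,
)
from .race import RaceParams

__all__ = [
    "ExperimentDesign",
    "JudgmentData",
    "make_design",
    "sample_judgments",
    "simulate_trial_race",
    "simulate_trial_indecision",
    "simulate_trial_reset",
    "simulate_races",
    "monte_carlo_curve",
    "EXP2_SCHEDULE",
]

#: Printed uneven repetition schedule of the cued study (19 entries).
EXP2_SCHEDULE = (8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28,
                 26, 24, 22, 18, 16, 14, 12, 8)


@dataclass(frozen=True)
class ExperimentDesign:
    """An SOA grid with per-SOA repetition counts.

    SOAs must be sorted (ties are tolerated so that a dataset whose trials
    at one SOA were split across rows remains representable); repetitions
    are positive integers.  Designs built through :func:`make_design` have
    strictly increasing SOAs.
    """

    label: str
    soas: tuple[float, ...]
    repetitions: tuple[int, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        soas = tuple(float(s) for s in self.soas)
        reps = tuple(int(r) for r in self.repetitions)
        if len(soas) != len(reps):
            raise ConfigurationError(
                f"{len(soas)} SOAs but {len(reps)} repetition counts"
            )
        if len(soas) == 0:
            raise ConfigurationError("design needs at least one SOA")
        if any(b < a for a, b in zip(soas, soas[1:])):
            raise ConfigurationError("SOAs must be sorted in increasing order")
        if any(r < 1 for r in reps):
            raise ConfigurationError("every repetition count must be >= 1")
        object.__setattr__(self, "soas", soas)
        object.__setattr__(self, "repetitions", reps)

    @property
    def n_trials(self) -> int:
        """Total number of trials (sum of repetitions)."""
        return int(sum(self.repetitions))

    @property
    def soa_array(self) -> np.ndarray:
        return np.asarray(self.soas, dtype=float)

    @property
    def repetition_array(self) -> np.ndarray:
        return np.asarray(self.repetitions, dtype=int)

    def to_dict(self) -> dict:
        return {"label": self.label, "soas": list(self.soas),
                "repetitions": list(self.repetitions),
                "metadata": dict(self.metadata)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(label=d["label"], soas=tuple(d["soas"]),
                   repetitions=tuple(d["repetitions"]),
                   metadata=dict(d.get("metadata", {})))


@dataclass(frozen=True)
class JudgmentData:
    """Observed or simulated "probe first" counts on a design."""

    design: ExperimentDesign
    probe_first_counts: tuple[int, ...]

    def __post_init__(self):
        counts = tuple(int(k) for k in self.probe_first_counts)
        if len(counts) != len(self.design.soas):
            raise ConfigurationError(
                f"{len(counts)} counts for {len(self.design.soas)} SOAs"
            )
        for soa, k, n in zip(self.design.soas, counts, self.design.repetitions):
            if not (0 <= k <= n):
                raise ConfigurationError(
                    f"count {k} outside [0, {n}] at SOA {soa} ms"
                )
        object.__setattr__(self, "probe_first_counts", counts)

    @property
    def count_array(self) -> np.ndarray:
        return np.asarray(self.probe_first_counts, dtype=int)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-SOA empirical probe-first frequency."""
        return self.count_array / self.design.repetition_array


def _uneven_schedule(n_soas: int) -> tuple[int, ...]:
    pad = min(EXP2_SCHEDULE)
    core = list(EXP2_SCHEDULE)
    if n_soas < len(core):
        raise ConfigurationError("grid shorter than the uneven schedule")
    extra = n_soas - len(core)
    left = extra // 2 + extra % 2
    right = extra // 2
    return tuple([pad] * left + core + [pad] * right)


def make_design(preset: str | None = None, *, label: str | None = None,
                soas=None, repetitions=None, metadata: dict | None = None
                ) -> ExperimentDesign:
    """Build a design from a preset name or an explicit grid.

    Presets: ``exp1`` (21 SOAs -100..100 step 10, 240 reps each),
    ``exp2_neutral`` (same grid, uneven schedule), ``exp2_cued``
    (-40..160 step 10, uneven schedule, 140 ms cue interval as metadata).

    Explicit designs pass ``soas`` and ``repetitions`` instead of a preset;
    SOAs must then be strictly increasing.
    """
    if preset is not None:
        if soas is not None or repetitions is not None:
            raise ConfigurationError("give either a preset or an explicit grid, not both")
        grid = np.arange(-100.0, 101.0, 10.0)
        if preset == "exp1":
            return ExperimentDesign(label or "exp1", tuple(grid), (240,) * len(grid))
        if preset == "exp2_neutral":
            return ExperimentDesign(label or "exp2_neutral", tuple(grid),
                                    _uneven_schedule(len(grid)))
        if preset == "exp2_cued":
            grid = np.arange(-40.0, 161.0, 10.0)
            return ExperimentDesign(label or "exp2_cued", tuple(grid),
                                    _uneven_schedule(len(grid)),
                                    metadata={"cue_interval_ms": 140.0})
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose exp1, exp2_neutral or exp2_cued"
        )
    if soas is None or repetitions is None:
        raise ConfigurationError("explicit designs need both soas and repetitions")
    soas = tuple(float(s) for s in soas)
    if any(b <= a for a, b in zip(soas, soas[1:])):
        raise ConfigurationError("explicit design SOAs must be strictly increasing")
    return ExperimentDesign(label or "custom", soas, tuple(repetitions),
                            metadata=dict(metadata or {}))


def sample_judgments(model: str, params, design: ExperimentDesign,
                     seed: int | np.random.Generator) -> JudgmentData:
    """Draw binomial "probe first" counts from a model at every design SOA.

    Identical seeds give bit-identical counts.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(model_probability(model, params, design.soa_array))
    counts = rng.binomial(design.repetition_array, p)
    return JudgmentData(design=design, probe_first_counts=tuple(int(c) for c in counts))


# ---------------------------------------------------------------------------
# Per-trial simulators (the independent oracles).  The vectorized versions
# draw all trials of one SOA at once with identical per-trial semantics; the
# single-trial functions are n=1 wrappers over the same draws.
# ---------------------------------------------------------------------------

def simulate_races(params: RaceParams, soa: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n`` independent races; True where the probe arrives first.

    The probe's onset is at 0 and the reference's at ``-soa`` (negative SOA
    = probe shown first), each followed by an exponential encoding latency.
    Exact ties have probability zero and resolve toward the probe.
    """
    probe_arrival = rng.exponential(1.0 / params.vp, size=n)
    ref_arrival = -float(soa) + rng.exponential(1.0 / params.vr, size=n)
    return probe_arrival <= ref_arrival


def simulate_trial_race(params: RaceParams, soa: float,
                        rng: np.random.Generator) -> str:
    """One simulated race; returns ``"probe"`` or ``"reference"``."""
    return "probe" if simulate_races(params, soa, 1, rng)[0] else "reference"


def _simulate_indecision(params: IndecisionParams, soa: float, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """``n`` indecision-model trials; True where the response is "probe first".

    The percept is "probe first" iff the probe's arrival leads the
    reference's by more than ``delta`` ms; leads/lags within ``delta`` are
    perceived as simultaneous and resolved to "probe first" with
    probability ``1 - xi``.
    """
    s = float(soa) + params.tau
    probe_arrival = rng.exponential(1.0 / params.rates.vp, size=n)
    ref_arrival = -s + rng.exponential(1.0 / params.rates.vr, size=n)
    margin = ref_arrival - probe_arrival          # probe lead, in ms
    probe_percept = margin > params.delta
    sim_percept = np.abs(margin) <= params.delta
    guess = rng.random(size=n) < (1.0 - params.xi)
    return probe_percept | (sim_percept & guess)


def simulate_trial_indecision(params: IndecisionParams, soa: float,
                              rng: np.random.Generator) -> str:
    """One indecision-model trial; returns the binary response label."""
    return "probe" if _simulate_indecision(params, soa, 1, rng)[0] else "reference"


def _simulate_reset(params: ResetParams, soa: float, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """``n`` reset-model trials; True where the response is "probe first".

    Each trial draws its own reset window from Normal(t0, s0) without
    truncation (a negative draw simply never triggers).  If the onsets fall
    within the window both stimuli race from a common start; otherwise the
    plain race at ``soa + tau`` decides.
    """
    s = float(soa) + params.tau
    t0_trial = params.t0 + params.s0 * rng.standard_normal(size=n)
    reset = np.abs(s) <= t0_trial
    # Common-start race: fresh exponential draws from the same onset.
    common_probe = rng.exponential(1.0 / params.rates.vp, size=n)
    common_ref = rng.exponential(1.0 / params.rates.vr, size=n)
    race = simulate_races(params.rates, s, n, rng)
    return np.where(reset, common_probe <= common_ref, race)


def simulate_trial_reset(params: ResetParams, soa: float,
                         rng: np.random.Generator) -> str:
    """One reset-model trial; returns the binary response label."""
    return "probe" if _simulate_reset(params, soa, 1, rng)[0] else "reference"


_SIMULATORS = {
    "simple": lambda params, soa, n, rng: simulate_races(
        RaceParams(params["vp"], params["vr"]), soa + params.get("tau", 0.0), n, rng),
    "indecision": lambda params, soa, n, rng: _simulate_indecision(
        MODELS["indecision"].make_params(params), soa, n, rng),
    "reset": lambda params, soa, n, rng: _simulate_reset(
        MODELS["reset"].make_params(params), soa, n, rng),
}


def monte_carlo_curve(model: str, params, soas, n_per_soa: int,
                      seed: int | np.random.Generator):
    """Empirical probe-first frequency per SOA from the per-trial simulator.

    Returns ``(frequencies, standard_errors)`` with the binomial standard
    error ``sqrt(f (1-f) / n)`` at each SOA.  This never evaluates the
    closed-form curves, so it is usable as an independent oracle for them.
    """
    if model not in _SIMULATORS:
        raise InvalidParameterError(f"unknown model {model!r}; choose from {sorted(_SIMULATORS)}")
    if n_per_soa < 1:
        raise InvalidParameterError(f"n_per_soa must be >= 1, got {n_per_soa}")
    from .models import params_to_dict
    values = params if isinstance(params, dict) else params_to_dict(params)
    rng = np.random.default_rng(seed)
    soas = np.asarray(soas, dtype=float)
    freqs = np.empty_like(soas)
    for i, soa in enumerate(soas):
        wins = _SIMULATORS[model](values, float(soa), n_per_soa, rng)
        freqs[i] = np.mean(wins)
    se = np.sqrt(freqs * (1.0 - freqs) / n_per_soa)
    return freqs, se
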