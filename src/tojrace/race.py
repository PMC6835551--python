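"""The shared exponential-race encoding model.

Two stimuli — a *probe* and a *reference* — race toward encoding in visual
short-term memory.  Each stimulus ``x`` is encoded by time ``t`` after its
onset with probability ``1 - exp(-v_x * t)``, where ``v_x`` is its encoding
rate.  The onsets are separated by the stimulus onset asynchrony (SOA), with
the package-wide sign convention that **negative SOA means the probe is shown
first**.

The probability that the probe is encoded before the reference has the closed
form

    P(probe first | SOA) = 1 - exp(-vp*|SOA|) * vr/(vp+vr)   for SOA < 0
    P(probe first | SOA) =     exp(-vr*|SOA|) * vp/(vp+vr)   for SOA >= 0

At SOA < 0 the probe either finishes before the reference even appears, or
both race from the reference onset and the probe wins with the Luce ratio
``vp/(vp+vr)``.  The same function arises from the bilateral-exponential
distribution of the arrival-time difference; the two derivations are
mathematically identical.

Rates are kept internally in events/ms so that SOAs stay in milliseconds;
the field conventionally reports rates in Hz, which is exactly 1000 times
the internal value.  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["RaceParams", "probe_first_probability", "standard_normal_cdf"]

#: Rate bounds used by all downstream fitting, in events/ms (0.1-1000 Hz).
RATE_MIN = 1e-4
RATE_MAX = 1.0


@dataclass(frozen=True)
class RaceParams:
    """Encoding rates of the exponential race.

    Parameters
    ----------
    vp : float
        Encoding rate of the probe stimulus, in events/ms.  Strictly positive.
    vr : float
        Encoding rate of the reference stimulus, in events/ms.  Strictly
        positive.

    Notes
    -----
    The same two rates serve both model families: TVA-style ``vp, vr`` and
    the arrival-time-difference formulation's ``lambda_p, lambda_r`` are the
    same quantities.  The overall processing capacity ``C = vp + vr`` is a
    derived quantity, exposed as :attr:`capacity`.
    """

    vp: float
    vr: float

    def __post_init__(self):
        if not (np.isfinite(self.vp) and np.isfinite(self.vr)):
            raise InvalidParameterError(
                f"encoding rates must be finite, got vp={self.vp}, vr={self.vr}"
            )
        if self.vp <= 0 or self.vr <= 0:
            raise InvalidParameterError(
                f"encoding rates must be strictly positive, got vp={self.vp}, vr={self.vr}"
            )

    @classmethod
    def from_hz(cls, vp_hz: float, vr_hz: float) -> "RaceParams":
        """Build from rates in Hz (the display/report unit)."""
        return cls(vp=vp_hz / 1000.0, vr=vr_hz / 1000.0)

    @property
    def vp_hz(self) -> float:
        return self.vp * 1000.0

    @property
    def vr_hz(self) -> float:
        return self.vr * 1000.0

    @property
    def capacity(self) -> float:
        """Overall processing capacity C = vp + vr (events/ms)."""
        return self.vp + self.vr

    @property
    def luce_ratio(self) -> float:
        """Probability vp/(vp+vr) that the probe wins a simultaneous race."""
        return self.vp / (self.vp + self.vr)


def _check_soa(soa) -> np.ndarray:
    arr = np.asarray(soa, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"SOA must be finite, got {soa!r}")
    return arr


def probe_first_probability(params: RaceParams, soa) -> float | np.ndarray:
    """Probability that the probe is encoded before the reference.

    Parameters
    ----------
    params : RaceParams
        Encoding rates of the race.
    soa : float or array-like
        Stimulus onset asynchrony in ms; negative means the probe is
        presented first.

    Returns
    -------
    float or ndarray
        P(probe encoded first), in [0, 1]; strictly decreasing in ``soa``
        and continuous at 0 where both branches equal the Luce ratio.
    """
    arr = _check_soa(soa)
    luce = params.luce_ratio
    abs_soa = np.abs(arr)
    # SOA >= 0 branch includes SOA == 0; both branches agree there.
    out = np.where(
        arr < 0,
        1.0 - np.exp(-params.vp * abs_soa) * (1.0 - luce),
        np.exp(-params.vr * abs_soa) * luce,
    )
    if np.isscalar(soa) or np.ndim(soa) == 0:
        return float(out)
    return out


def standard_normal_cdf(x) -> float | np.ndarray:
    """Standard normal CDF Phi(x), used by the encoding-reset model."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"argument must be finite, got {x!r}")
    out = ndtr(arr)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out
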