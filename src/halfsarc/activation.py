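"""Actin permissiveness time courses.

Calcium/troponin/tropomyosin regulation is lumped into a single scalar in
[0, 1], the actin permissiveness: the fraction by which every binding
probability in the half sarcomere is multiplied.  The pulse shape is a
product of two exponentials — a saturating rise during the stimulus window
(Ca influx, time constant tau_rise) followed by an exponential decay
(re-uptake, half-life t_half_decay).  The rise window and time constants are
calibration artifacts fitted so that isometric model responses look like a
hawkmoth flight-muscle twitch (defaults below); they are not literature
constants.

For work loops the same single-twitch pulse recurs once per strain cycle with
onset at phase phi (fraction of the cycle measured from the start of
shortening); tails from earlier pulses are summed so the signal is continuous
and periodic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ActivationParams",
    "PhasedActivation",
    "permissiveness",
    "periodic_permissiveness",
    "fit_twitch",
]

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class ActivationParams:
    """Single activation pulse.

    onset: stimulus start, ms.  rise_window: stimulus duration, ms (the pulse
    peaks at its end; with the defaults peak permissiveness occurs 13 ms after
    onset).  tau_rise: influx time constant, ms.  t_half_decay: re-uptake
    half-life, ms.  peak_level: saturation level in [0, 1].
    """

    tau_rise: float = 4.0
    t_half_decay: float = 3.0
    onset: float = 0.0
    rise_window: float = 13.0
    peak_level: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.t_half_decay <= 0 or self.rise_window <= 0:
            raise ValueError("tau_rise, t_half_decay and rise_window must be > 0")
        if not 0.0 <= self.peak_level <= 1.0:
            raise ValueError("peak_level must be in [0, 1]")


def permissiveness(t, params: ActivationParams):
    """Pulse value at time(s) t (ms); always in [0, 1], continuous in t.

    0 before onset; peak_level*(1 - exp(-(t-onset)/tau_rise)) during the
    stimulus window; exponential decay with half-life t_half_decay afterwards.
    """
    t = np.asarray(t, dtype=float)
    dt_on = t - params.onset
    rise = params.peak_level * (1.0 - np.exp(-np.clip(dt_on, 0.0, None)
                                             / params.tau_rise))
    at_end = params.peak_level * (1.0 - math.exp(-params.rise_window
                                                 / params.tau_rise))
    dt_off = dt_on - params.rise_window
    decay = at_end * np.exp(-LOG2 * np.clip(dt_off, 0.0, None)
                            / params.t_half_decay)
    out = np.where(dt_on <= 0.0, 0.0, np.where(dt_off <= 0.0, rise, decay))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PhasedActivation:
    """One twitch-shaped pulse per cycle, onset at phase phi of the cycle.

    phi is the fraction of the strain cycle (t = 0 is the start of
    shortening) at which the stimulus begins; period T in ms.
    """

    phi: float = 0.0
    period: float = 40.0
    params: ActivationParams = ActivationParams()

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        # phases wrap: 1.05 is the same stimulus timing as 0.05
        object.__setattr__(self, "phi", self.phi % 1.0)


def periodic_permissiveness(t, phased: PhasedActivation):
    """Periodic activation signal at time(s) t (ms).

    The pulse onset sits at phi*T within each cycle; decaying tails of the
    previous pulses are summed (then clipped to the pulse ceiling) so the
    signal wraps smoothly across cycle boundaries.
    """
    t = np.asarray(t, dtype=float)
    onset0 = phased.phi * phased.period
    base = replace(phased.params, onset=0.0)
    # time since the most recent onset, plus the two preceding pulses' tails
    rel = (t - onset0) % phased.period
    out = np.zeros_like(rel)
    for k in range(3):
        out = out + permissiveness(rel + k * phased.period, base)
    out = np.minimum(out, base.peak_level)
    return out if out.ndim else float(out)


def fit_twitch(target: dict, simulate_twitch, x0: ActivationParams | None = None,
               xatol: float = 0.05, maxiter: int = 60) -> ActivationParams:
    """Fit (tau_rise, t_half_decay) so a simulated twitch matches descriptors.

    target: dict with any of ``time_to_peak`` (ms), ``half_relax`` (ms, time
    from peak to half-peak force) and ``peak_fraction`` (peak twitch force as
    a fraction of the tetanic plateau).  simulate_twitch: callable mapping an
    ActivationParams to a measured descriptor dict with the same keys (the
    caller owns the simulator configuration and its seed, so the fit is
    deterministic for a deterministic simulator).

    Returns the best parameters found; raises RuntimeError carrying them if
    the optimizer fails to converge.
    """
    from scipy.optimize import minimize

    x0 = x0 or ActivationParams()
    keys = sorted(target)
    if not keys:
        raise ValueError("target must contain at least one descriptor")

    def unpack(v):
        return replace(x0, tau_rise=math.exp(v[0]), t_half_decay=math.exp(v[1]))

    def loss(v):
        got = simulate_twitch(unpack(v))
        return sum(((got[k] - target[k]) / max(abs(target[k]), 1e-9)) ** 2
                   for k in keys)

    res = minimize(loss, [math.log(x0.tau_rise), math.log(x0.t_half_decay)],
                   method="Nelder-Mead",
                   options={"xatol": xatol, "fatol": 1e-4, "maxiter": maxiter})
    best = unpack(res.x)
    if not res.success and res.fun > 0.05:
        raise RuntimeError(
            f"twitch fit did not converge (loss {res.fun:.3g}); "
            f"best so far: tau_rise={best.tau_rise:.3g} ms, "
            f"t_half_decay={best.t_half_decay:.3g} ms")
    return best
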